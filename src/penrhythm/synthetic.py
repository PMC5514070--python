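"""Synthetic 200 Hz pen traces with controlled rhythm structure.

The generator emulates a tablet recording of a child writing a five-letter
word under size/tempo instructions, with full ground truth, so that
segmentation and both statistical analyses are testable end to end:

* **Isochrony** — total pen-down duration is drawn as ``T = c * L**beta *
  exp(eps)`` with lognormal noise, so duration–length regressions have a
  known exponent.
* **Homothety** — T is divided among letters according to a target
  relative-duration profile ``rho_star`` (plus optional jitter), so the
  per-letter rhythm is known.
* **Speed–curvature coupling** — within a letter the pen's speed follows
  ``v ∝ curvature**(-1/3)`` (the tangential form of the two-thirds power
  law), blended with uniform speed by ``two_thirds_gain``; cursive
  inter-letter connectors are high-curvature bumps, so letter boundaries
  sit at genuine speed minima.

Letterforms are abstract stand-ins with "burle"-like stroke structure
(smooth single-lobe loops for cursive; 1-3 separate strokes per letter for
block capitals), not faithful glyphs: the analyses depend only on timing
and length structure.  All pen-down segment boundaries are snapped to the
sampling grid, so measured durations equal the allocated ones exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .trace_io import (CONDITIONS, GROUPS, SCRIPTS, Trace, TraceMeta)

_CURVATURE_EPS = 1e-3
_DENSE_PTS = 3000
_INTRA_LIFT_S = 0.06    # pen-up between strokes of one block letter
_INTER_LIFT_S = 0.15    # pen-up between block letters


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters; defaults give a study-scale cohort."""

    word: str = "burle"
    rho_star: tuple[float, ...] = (18.0, 22.5, 21.5, 21.5, 16.5)
    beta: float = 0.30              # isochrony exponent
    c: float = 1.5                  # s * cm^-beta
    two_thirds_gain: float = 1.0    # 0 = uniform speed, 1 = full v ∝ k^(-1/3)
    condition_size_scales: dict = field(default_factory=lambda: {
        "Spontaneous": 1.0, "Big": 2.0, "Small": 0.5,
        "Fast": 1.0, "Slow": 1.0})
    condition_tempo_scales: dict = field(default_factory=lambda: {
        "Spontaneous": 1.0, "Big": 1.0, "Small": 1.0,
        "Fast": 0.7, "Slow": 1.6})
    sigma_T: float = 0.15           # lognormal sd of T given L
    pos_jitter: float = 0.02        # cm, per-sample positional noise
    rho_jitter: float = 1.0         # percentage points, per-trial
    participant_size_sigma: float = 0.15
    participant_tempo_sigma: float = 0.15
    sampling_rate: float = 200.0
    group_sizes: tuple[int, ...] = (57, 72, 61, 68, 40)
    seed: int = 0
    letter_height: float = 0.8      # cm at Spontaneous scale
    homothety_violation: float = 0.0  # pp shift of letter 1 in Fast
    isochrony_violation: float = 0.0  # 0..1, flattens the exponent
    ref_length: float = 10.0        # cm, pivot for isochrony violation

    def __post_init__(self):
        if len(self.rho_star) != len(self.word):
            raise ValueError("rho_star length must match the word")
        if not np.isclose(sum(self.rho_star), 100.0):
            raise ValueError("rho_star must sum to 100")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if any(s <= 0 for s in self.condition_size_scales.values()):
            raise ValueError("size scales must be positive")
        if any(s <= 0 for s in self.condition_tempo_scales.values()):
            raise ValueError("tempo scales must be positive")
        if any(n < 1 for n in self.group_sizes):
            raise ValueError("group sizes must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    trial_id: str
    boundaries: tuple[int, ...]         # sample index starting letters 2..n
    letter_durations: tuple[float, ...]  # pen-down seconds per letter
    letter_stroke_counts: tuple[int, ...]
    T: float
    L: float
    V: float
    size_scale: float
    tempo_scale: float
    rho_realized: tuple[float, ...]


def inject_violation(config: SyntheticConfig, kind: str,
                     magnitude: float) -> SyntheticConfig:
    """Return a config whose cohorts violate one rhythm principle.

    ``homothety``: the Fast condition shifts the first letter's target rho
    by ``magnitude`` percentage points (others renormalized).
    ``isochrony``: the exponent becomes beta*(1-magnitude) with the
    duration at ``ref_length`` held fixed, so length distributions and the
    overall tempo are unchanged while the length dependence flattens.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if kind == "homothety":
        if config.rho_star[0] + magnitude >= 100:
            raise ValueError("distortion drives the remaining rho below 0")
        return replace(config, homothety_violation=magnitude)
    if kind == "isochrony":
        if magnitude > 1:
            raise ValueError("isochrony magnitude is a fraction in [0, 1]")
        return replace(config, isochrony_violation=magnitude)
    raise ValueError(f"unknown violation kind {kind!r}")


# ---------------------------------------------------------------------------
# letterform templates (abstract stand-ins in letter-local units, baseline y=0)

# cursive: one semicircular lobe per letter, (width, height) with w = 2h so
# body curvature is constant — interior speed minima can then only occur at
# the sharp inter-letter connector bumps, keeping boundaries well defined
_CURSIVE_SHAPES = {
    "b": (1.3, 0.65), "u": (1.0, 0.50), "r": (0.9, 0.45),
    "l": (1.4, 0.70), "e": (0.8, 0.40),
}
_CURSIVE_DEFAULT = (1.1, 0.55)
_CONNECTOR_W = 0.35
_CONNECTOR_D = 0.25     # bump depth below baseline


def _cursive_body(width: float, height: float, npts: int = 80) -> np.ndarray:
    th = np.linspace(np.pi, 0.0, npts)
    return np.column_stack([width / 2 * (1 + np.cos(th)),
                            height * np.sin(th)])


def _connector(npts: int = 60) -> np.ndarray:
    u = np.linspace(0.0, 1.0, npts)
    return np.column_stack([_CONNECTOR_W * u,
                            -_CONNECTOR_D * 4 * u * (1 - u)])


# block capitals: 1-3 separate polyline strokes per letter in a unit box
def _arc(c, r, th0, th1, npts=40):
    th = np.linspace(th0, th1, npts)
    return np.column_stack([c[0] + r * np.cos(th), c[1] + r * np.sin(th)])


_BLOCK_STROKES = {
    "b": [np.array([[0.1, 0.0], [0.1, 1.0]]),
          np.vstack([_arc((0.1, 0.75), 0.25, np.pi / 2, -np.pi / 2),
                     _arc((0.1, 0.25), 0.25, np.pi / 2, -np.pi / 2)])],
    "u": [np.vstack([np.array([[0.1, 1.0], [0.1, 0.35]]),
                     _arc((0.45, 0.35), 0.35, np.pi, 2 * np.pi),
                     np.array([[0.8, 0.35], [0.8, 1.0]])])],
    "r": [np.array([[0.1, 0.0], [0.1, 1.0]]),
          np.vstack([_arc((0.1, 0.75), 0.25, np.pi / 2, -np.pi / 2),
                     np.array([[0.1, 0.5], [0.8, 0.0]])])],
    "l": [np.array([[0.15, 1.0], [0.15, 0.0]]),
          np.array([[0.15, 0.0], [0.8, 0.0]])],
    "e": [np.array([[0.15, 0.0], [0.15, 1.0]]),
          np.array([[0.15, 1.0], [0.8, 1.0]]),
          np.array([[0.15, 0.5], [0.65, 0.5]]),
          np.array([[0.15, 0.0], [0.8, 0.0]])],
}
_BLOCK_DEFAULT = [np.array([[0.1, 0.0], [0.1, 1.0]]),
                  np.array([[0.1, 1.0], [0.8, 0.0]])]


def _polyline_length(p: np.ndarray) -> float:
    return float(np.hypot(*np.diff(p, axis=0).T).sum())


def _resample_uniform(p: np.ndarray, npts: int) -> np.ndarray:
    """Resample a polyline at npts arc-length-uniform points."""
    seg = np.hypot(*np.diff(p, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    grid = np.linspace(0.0, s[-1], npts)
    return np.column_stack([np.interp(grid, s, p[:, 0]),
                            np.interp(grid, s, p[:, 1])])


def _curvature(p: np.ndarray) -> np.ndarray:
    """|d(theta)/ds| of an arc-length-uniform polyline, lightly smoothed."""
    d = np.diff(p, axis=0)
    theta = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    ds = np.hypot(d[:, 0], d[:, 1])
    k = np.zeros(len(p))
    k[1:-1] = np.abs(np.diff(theta)) / (0.5 * (ds[:-1] + ds[1:]))
    k[0], k[-1] = k[1], k[-2]
    kernel = np.ones(5) / 5
    return np.convolve(k, kernel, mode="same")


def _speed_profile(curv: np.ndarray, gain: float) -> np.ndarray:
    return np.power(curv + _CURVATURE_EPS, -gain / 3.0)


def _position_jitter(n: int, sd: float, rate: float,
                     rng: np.random.Generator,
                     cutoff_hz: float = 6.0) -> np.ndarray:
    """Band-limited positional noise (n x 2), SD ``sd`` cm per axis.

    Digitizer position error drifts slowly (spatial nonlinearity, paper
    flex); white noise at the full sampling rate would add a spurious
    random-walk component to chord-summed path lengths.
    """
    noise = rng.normal(0.0, 1.0, (n, 2))
    if n > 30:
        sos = butter(2, cutoff_hz, btype="low", fs=rate, output="sos")
        noise = sosfiltfilt(sos, noise, axis=0)
        std = noise.std(axis=0)
        std[std == 0] = 1.0
        noise = noise / std
    return sd * noise


def _snap(duration: float, dt: float, min_samples: int = 4) -> float:
    return max(int(round(duration / dt)), min_samples) * dt


def _allocate_rho(config: SyntheticConfig, condition: str,
                  rng: np.random.Generator) -> np.ndarray:
    rho = np.array(config.rho_star, float)
    if condition == "Fast" and config.homothety_violation:
        m = config.homothety_violation
        rho[0] += m
        rho[1:] *= (100.0 - rho[0]) / rho[1:].sum()
    if config.rho_jitter > 0:
        rho = rho + rng.normal(0.0, config.rho_jitter, len(rho))
        rho = np.clip(rho, 1.0, None)
        rho = 100.0 * rho / rho.sum()
    return rho


def _draw_duration(config: SyntheticConfig, L: float, tempo: float,
                   rng: np.random.Generator) -> float:
    beta = config.beta * (1.0 - config.isochrony_violation)
    # pivot at ref_length so a flattened exponent leaves overall tempo alone
    c_eff = config.c * config.ref_length ** (config.beta - beta)
    T = c_eff * L ** beta * tempo
    if config.sigma_T > 0:
        T *= np.exp(rng.normal(0.0, config.sigma_T))
    return float(T)


def _make_meta(participant_id, group, script, condition, config):
    trial_id = f"{participant_id}-{script}-{condition}"
    return TraceMeta(participant_id=participant_id, group=group,
                     script=script, condition=condition,
                     nominal_rate=config.sampling_rate, word=config.word,
                     trial_id=trial_id)


def _emit_cursive(config, meta, scale, tempo, rng):
    word = config.word
    n = len(word)
    # assemble the dense spatial path and the letter-boundary arc positions
    parts, apex_s = [], []
    cx, total = 0.0, 0.0
    for i, ch in enumerate(word):
        w, h = _CURSIVE_SHAPES.get(ch, _CURSIVE_DEFAULT)
        body = _cursive_body(w, h) * config.letter_height
        body[:, 0] += cx
        parts.append(body)
        cx += w * config.letter_height
        if i < n - 1:
            conn = _connector() * config.letter_height
            conn[:, 0] += cx
            parts.append(conn)
            total_before = sum(_polyline_length(q) for q in parts[:-1])
            apex_s.append(total_before + _polyline_length(conn) / 2.0)
            cx += _CONNECTOR_W * config.letter_height
    path = np.vstack([q for q in parts]) * scale
    apex_s = np.asarray(apex_s) * scale

    dense = _resample_uniform(path, _DENSE_PTS)
    seg = np.hypot(*np.diff(dense, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    L = float(s[-1])
    curv = _curvature(dense)
    v = _speed_profile(curv, config.two_thirds_gain)

    T_raw = _draw_duration(config, L, tempo, rng)
    rho = _allocate_rho(config, meta.condition, rng)
    dt = 1.0 / config.sampling_rate
    durs = np.array([_snap(T_raw * r / 100.0, dt, 12) for r in rho])
    T = float(durs.sum())

    # per-letter time parameterization: integrate ds/v, rescale per letter
    edges = np.concatenate([[0.0], apex_s, [s[-1]]])
    dtau = np.empty(len(seg))
    np.divide(seg, 0.5 * (v[:-1] + v[1:]), out=dtau)
    t = np.zeros(len(s))
    t_off = 0.0
    for i in range(n):
        mask = (s[:-1] >= edges[i] - 1e-12) & (s[:-1] < edges[i + 1] - 1e-12)
        tau = dtau[mask]
        cum = np.concatenate([[0.0], np.cumsum(tau)])
        cum *= durs[i] / cum[-1]
        idx = np.flatnonzero(mask)
        t[idx[0]:idx[-1] + 2] = t_off + cum
        t_off += durs[i]

    n_samp = int(round(T / dt)) + 1
    ts = np.arange(n_samp) * dt
    x = np.interp(ts, t, dense[:, 0])
    y = np.interp(ts, t, dense[:, 1])
    if config.pos_jitter > 0:
        jit = _position_jitter(n_samp, config.pos_jitter,
                               config.sampling_rate, rng)
        x = x + jit[:, 0]
        y = y + jit[:, 1]
    pressure = np.full(n_samp, 1.0)

    bounds = tuple(int(round(durs[:i + 1].sum() / dt)) for i in range(n - 1))
    truth = GroundTruth(
        trial_id=meta.trial_id, boundaries=bounds,
        letter_durations=tuple(durs), letter_stroke_counts=(1,) * n,
        T=T, L=L, V=L / T, size_scale=scale, tempo_scale=tempo,
        rho_realized=tuple(100.0 * durs / T))
    return Trace(meta=meta, t=ts, x=x, y=y, pressure=pressure), truth


def _emit_block(config, meta, scale, tempo, rng):
    word = config.word
    n = len(word)
    dt = 1.0 / config.sampling_rate
    box = config.letter_height * scale
    advance = 1.1 * box

    # dense per-stroke polylines, grouped by letter
    letters = []
    for i, ch in enumerate(word):
        strokes = []
        for st in _BLOCK_STROKES.get(ch, _BLOCK_DEFAULT):
            q = st * box
            q = q + np.array([i * advance, 0.0])
            npts = max(int(40 * _polyline_length(q) / box), 8)
            strokes.append(_resample_uniform(q, npts))
        letters.append(strokes)
    stroke_lengths = [[_polyline_length(st) for st in lst] for lst in letters]
    L = float(sum(sum(sl) for sl in stroke_lengths))

    T_raw = _draw_duration(config, L, tempo, rng)
    rho = _allocate_rho(config, meta.condition, rng)
    letter_durs = []
    for i in range(n):
        d_letter = T_raw * rho[i] / 100.0
        lens = np.asarray(stroke_lengths[i])
        d_strokes = [_snap(d_letter * l / lens.sum(), dt, 4) for l in lens]
        letter_durs.append(d_strokes)

    lift_intra = _snap(_INTRA_LIFT_S, dt, 2)
    lift_inter = _snap(_INTER_LIFT_S, dt, 2)

    ts_parts, x_parts, y_parts, p_parts = [], [], [], []
    bound_samples = []
    t0 = 0.0
    for i in range(n):
        if i > 0:
            bound_samples.append(int(round(t0 / dt)))
        for j, st in enumerate(letters[i]):
            # stroke samples (inclusive both ends, grid-aligned)
            d = letter_durs[i][j]
            k = int(round(d / dt))
            tt = t0 + np.arange(k + 1) * dt
            seg = np.hypot(*np.diff(st, axis=0).T)
            s = np.concatenate([[0.0], np.cumsum(seg)])
            frac = np.linspace(0.0, 1.0, k + 1) * s[-1]
            ts_parts.append(tt)
            x_parts.append(np.interp(frac, s, st[:, 0]))
            y_parts.append(np.interp(frac, s, st[:, 1]))
            p_parts.append(np.full(k + 1, 1.0))
            stroke_end_xy = st[-1]
            t0 = tt[-1]
            # pen-up gap to the next stroke, if any
            last_of_letter = j == len(letters[i]) - 1
            if not (i == n - 1 and last_of_letter):
                gap = lift_inter if last_of_letter else lift_intra
                kg = int(round(gap / dt))
                nxt = (letters[i][j + 1][0] if not last_of_letter
                       else letters[i + 1][0][0])
                u = np.arange(1, kg) / kg
                ts_parts.append(t0 + np.arange(1, kg) * dt)
                x_parts.append(stroke_end_xy[0] + u * (nxt[0] - stroke_end_xy[0]))
                y_parts.append(stroke_end_xy[1] + u * (nxt[1] - stroke_end_xy[1]))
                p_parts.append(np.zeros(kg - 1))
                t0 = t0 + gap

    ts = np.concatenate(ts_parts)
    x = np.concatenate(x_parts)
    y = np.concatenate(y_parts)
    pressure = np.concatenate(p_parts)
    if config.pos_jitter > 0:
        jit = _position_jitter(len(x), config.pos_jitter,
                               config.sampling_rate, rng)
        x = x + jit[:, 0]
        y = y + jit[:, 1]

    durs = np.array([sum(d) for d in letter_durs])
    T = float(durs.sum())
    truth = GroundTruth(
        trial_id=meta.trial_id, boundaries=tuple(bound_samples),
        letter_durations=tuple(durs),
        letter_stroke_counts=tuple(len(lst) for lst in letters),
        T=T, L=L, V=L / T, size_scale=scale, tempo_scale=tempo,
        rho_realized=tuple(100.0 * durs / T))
    return Trace(meta=meta, t=ts, x=x, y=y, pressure=pressure), truth


def simulate_word(config: SyntheticConfig, condition: str, script: str,
                  rng: np.random.Generator,
                  participant_id: str = "P000", group: str = "G1",
                  size_effect: float = 1.0,
                  tempo_effect: float = 1.0):
    """Generate one trial: a Trace plus its GroundTruth.

    ``size_effect``/``tempo_effect`` are per-participant multipliers (drawn
    once per participant by :func:`simulate_cohort`).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if script not in SCRIPTS:
        raise ValueError(f"unknown script {script!r}")
    meta = _make_meta(participant_id, group, script, condition, config)
    scale = config.condition_size_scales[condition] * size_effect
    tempo = config.condition_tempo_scales[condition] * tempo_effect
    emit = _emit_cursive if script == "cursive" else _emit_block
    return emit(config, meta, scale, tempo, rng)


def _participant_ids(group_sizes):
    out = []
    k = 0
    for g, size in zip(GROUPS, group_sizes):
        for _ in range(size):
            out.append((f"P{k:03d}", g))
            k += 1
    return out


def simulate_cohort(config: SyntheticConfig):
    """Generate a full cohort: every participant writes the word once per
    script x condition (10 trials each).

    Per-participant baseline size and tempo effects are drawn once and
    reused across that participant's trials.  Per-trial random streams are
    derived deterministically from (seed, participant, script, condition).

    Returns (traces, truths, manifest DataFrame).
    """
    ids = _participant_ids(config.group_sizes)
    traces, truths, rows = [], [], []
    for p_idx, (pid, grp) in enumerate(ids):
        eff_rng = np.random.default_rng(
            np.random.SeedSequence((config.seed, p_idx)))
        size_eff = float(np.exp(eff_rng.normal(
            0.0, config.participant_size_sigma)))
        tempo_eff = float(np.exp(eff_rng.normal(
            0.0, config.participant_tempo_sigma)))
        for s_idx, script in enumerate(SCRIPTS):
            for c_idx, condition in enumerate(CONDITIONS):
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        (config.seed, p_idx, s_idx, c_idx)))
                tr, gt = simulate_word(
                    config, condition, script, rng,
                    participant_id=pid, group=grp,
                    size_effect=size_eff, tempo_effect=tempo_eff)
                traces.append(tr)
                truths.append(gt)
                rows.append({
                    "trial_id": tr.meta.trial_id, "participant_id": pid,
                    "group": grp, "script": script, "condition": condition,
                    "nominal_rate": config.sampling_rate,
                    "word": config.word,
                })
    return traces, truths, pd.DataFrame(rows)


def simulate_homothety_profiles(
    config: SyntheticConfig,
    conditions=("Spontaneous", "Big", "Fast"),
    subject_sigma: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fast profile-level sampler: per-trial rho draws without trace
    rendering, for ANOVA calibration/power studies at cohort scale.

    Each participant gets a persistent letter-preference perturbation
    (sd ``subject_sigma`` pp) on top of rho_star; each condition adds
    independent trial jitter (``config.rho_jitter``); profiles are
    renormalized to 100.  Homothety (no Condition or Group dependence)
    holds unless ``config.homothety_violation`` is set, which shifts the
    first letter in the Fast condition.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    letters = list(config.word)
    rows = []
    for pid, grp in _participant_ids(config.group_sizes):
        subj = rng.normal(0.0, subject_sigma, len(letters))
        for cond in conditions:
            rho = np.array(config.rho_star, float)
            if cond == "Fast" and config.homothety_violation:
                m = config.homothety_violation
                rho[0] += m
                rho[1:] *= (100.0 - rho[0]) / rho[1:].sum()
            rho = rho + subj + rng.normal(0.0, config.rho_jitter,
                                          len(letters))
            rho = np.clip(rho, 0.5, None)
            rho = 100.0 * rho / rho.sum()
            for letter, r in zip(letters, rho):
                rows.append({"participant_id": pid, "group": grp,
                             "condition": cond, "letter": letter,
                             "rho": float(r)})
    return pd.DataFrame(rows)


def draw_length_duration_pairs(
    n: int, rng: np.random.Generator,
    beta: float = 0.30, c: float = 1.5, sigma: float = 0.15,
    length_range: tuple[float, float] = (3.0, 40.0),
) -> np.ndarray:
    """(length, duration) pairs with T = c * L**beta * exp(N(0, sigma)),
    lengths log-uniform over ``length_range``.  The light-weight counterpart
    of a full cohort for regression-recovery studies."""
    lo, hi = np.log(length_range)
    L = np.exp(rng.uniform(lo, hi, n))
    T = c * L ** beta * np.exp(rng.normal(0.0, sigma, n))
    return np.column_stack([L, T])


__all__ = [
    "SyntheticConfig", "GroundTruth", "simulate_word", "simulate_cohort",
    "simulate_homothety_profiles", "draw_length_duration_pairs",
    "inject_violation",
]
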