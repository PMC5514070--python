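"""Speed profiles and per-word / per-letter kinematic quantities.

The quantities mirror the standard graphonomic measures for a written word:

* ``T`` — word duration in seconds, counting only pen-down contact time;
* ``L`` — word length in cm, the summed path length of all strokes;
* ``V`` — word mean velocity in cm/s (``L / T`` by default, or the mean of
  per-sample pen-down speeds under the alternative definition);
* relative letter duration ``rho`` — each letter's pen-down duration as a
  percentage of ``T``; the per-word rhythm profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .trace_io import Trace, TraceMeta


@dataclass(frozen=True)
class SmoothingConfig:
    """Zero-phase Butterworth low-pass applied to x(t), y(t) before
    differentiation.  10 Hz retains the full handwriting band at a 200 Hz
    sampling rate while suppressing quantization noise."""

    cutoff_hz: float = 10.0
    order: int = 4
    enabled: bool = True

    def describe(self) -> str:
        if not self.enabled:
            return "none"
        return f"butterworth(order={self.order}, cutoff={self.cutoff_hz}Hz, zero-phase)"


@dataclass
class SpeedSeries:
    """Tangential speed per sample (cm/s), aligned to the trace samples."""

    values: np.ndarray
    pen_down: np.ndarray          # bool mask; in-air samples get speeds too
    smoothing_descriptor: str

    def __len__(self) -> int:
        return len(self.values)


def _smooth(series: np.ndarray, rate: float, cfg: SmoothingConfig) -> np.ndarray:
    if not cfg.enabled or cfg.cutoff_hz >= rate / 2:
        return series
    sos = butter(cfg.order, cfg.cutoff_hz, btype="low", fs=rate, output="sos")
    padlen = 3 * (2 * cfg.order + 1)
    if len(series) <= padlen:       # too short to filter stably
        return series
    return sosfiltfilt(sos, series)


def compute_speed(trace: Trace,
                  smoothing: SmoothingConfig = SmoothingConfig()) -> SpeedSeries:
    """Tangential speed from smoothed first derivatives of x and y.

    Interior samples use central differences (via ``np.gradient``),
    endpoints one-sided differences.  In-air samples receive speed values
    but are flagged by the ``pen_down`` mask.
    """
    if len(trace) < 3:
        raise ValueError("speed profile needs at least 3 samples")
    if np.any(np.diff(trace.t) <= 0):
        raise ValueError("duplicate or decreasing timestamps")
    rate = trace.meta.nominal_rate
    xs = _smooth(trace.x, rate, smoothing)
    ys = _smooth(trace.y, rate, smoothing)
    vx = np.gradient(xs, trace.t)
    vy = np.gradient(ys, trace.t)
    return SpeedSeries(
        values=np.hypot(vx, vy),
        pen_down=trace.pressure > 0,
        smoothing_descriptor=smoothing.describe(),
    )


@dataclass(frozen=True)
class WordRecord:
    """Per-trial word-level kinematics: (T, L, V) plus provenance."""

    meta: TraceMeta
    T: float                      # pen-down duration, s
    L: float                      # summed stroke path length, cm
    V: float                      # mean velocity, cm/s
    n_strokes: int
    velocity_definition: str = "L/T"


def path_length(trace: Trace, start: int, end: int) -> float:
    """Chord-summed path length over samples [start, end] inclusive."""
    dx = np.diff(trace.x[start:end + 1])
    dy = np.diff(trace.y[start:end + 1])
    return float(np.hypot(dx, dy).sum())


def word_metrics(word_group, trace: Trace,
                 velocity_definition: str = "L/T",
                 speed: SpeedSeries | None = None) -> WordRecord:
    """Word duration, length and mean velocity for one word group.

    ``word_group`` is a list of strokes (from the segmentation module).  T
    sums stroke durations — in-air time is excluded; L sums stroke chord
    lengths.  The default V = L/T; ``velocity_definition="mean_speed"``
    instead averages the instantaneous speed over pen-down samples (needs
    ``speed``).
    """
    if not word_group:
        raise ValueError("empty word group")
    T = sum(s.duration for s in word_group)
    if T <= 0:
        raise ValueError("word group has zero pen-down duration")
    L = sum(s.path_length for s in word_group)
    if velocity_definition == "L/T":
        V = L / T
    elif velocity_definition == "mean_speed":
        if speed is None:
            raise ValueError("mean_speed definition requires a SpeedSeries")
        idx = np.concatenate([np.arange(s.start_idx, s.end_idx + 1)
                              for s in word_group])
        V = float(np.mean(speed.values[idx]))
    else:
        raise ValueError(f"unknown velocity definition {velocity_definition!r}")
    return WordRecord(meta=trace.meta, T=float(T), L=float(L), V=float(V),
                      n_strokes=len(word_group),
                      velocity_definition=velocity_definition)


@dataclass(frozen=True)
class RelativeDurationProfile:
    """Per-letter durations as percentages of the word's pen-down time."""

    letters: tuple[str, ...]
    rho: tuple[float, ...]        # percentages, sum to 100

    def __post_init__(self):
        total = sum(self.rho)
        if not np.isclose(total, 100.0, rtol=1e-9):
            raise ValueError(f"rho sums to {total}, not 100")


def relative_letter_durations(letters, word: WordRecord) -> RelativeDurationProfile:
    """rho_i = 100 * letter_duration_i / T, in the word's letter order."""
    durs = np.array([seg.duration for seg in letters], dtype=float)
    if np.any(durs <= 0):
        bad = [seg.label for seg, d in zip(letters, durs) if d <= 0]
        raise ValueError(f"non-positive letter duration for {bad}")
    if not np.isclose(durs.sum(), word.T, rtol=1e-6):
        raise ValueError(
            f"letter durations sum to {durs.sum():.6f}s but word T={word.T:.6f}s")
    rho = 100.0 * durs / durs.sum()
    return RelativeDurationProfile(
        letters=tuple(seg.label for seg in letters),
        rho=tuple(rho),
    )


__all__ = [
    "SmoothingConfig", "SpeedSeries", "WordRecord",
    "RelativeDurationProfile", "compute_speed", "word_metrics",
    "relative_letter_durations", "path_length",
]
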