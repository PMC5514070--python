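"""Isochrony analysis: power-law regressions of word timing on trace length.

Isochrony is the tendency of movement speed to scale with trajectory
length, keeping total duration roughly constant.  Operationally: ordinary
least squares of ln(duration) — and ln(mean velocity) — on ln(length),
pooled and per grade group, with a leave-one-out outlier screen that
substitutes points falling more than 4 natural-log units from their
expected value, and Fisher r-to-z comparisons of per-group correlations.

Under the default V = L/T these two regressions are algebraically locked:
slope_V = 1 - slope_T and intercept_V = -intercept_T, since
ln V = ln L - ln T pair by pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class RegressionResult:
    """Natural-log OLS fit: ln(y) = intercept + slope * ln(x)."""

    intercept: float
    slope: float
    r: float          # Pearson correlation of the logs
    p: float
    n: int


@dataclass(frozen=True)
class Substitution:
    index: int                  # position in the input pair list
    variable: str               # which log value was replaced
    original_log: float
    expected_log: float
    residual: float


@dataclass(frozen=True)
class OutlierReport:
    threshold: float
    substituted: tuple[Substitution, ...]

    @property
    def n_substituted(self) -> int:
        return len(self.substituted)


def loglog_fit(x, y) -> RegressionResult:
    """OLS of ln(y) on ln(x); r is the Pearson correlation of the logs."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    bad = np.flatnonzero((x <= 0) | (y <= 0) | ~np.isfinite(x) | ~np.isfinite(y))
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"non-positive or non-finite value at pair {i}: "
            f"(x={x[i]!r}, y={y[i]!r})")
    lx, ly = np.log(x), np.log(y)
    if np.ptp(lx) == 0:
        raise ValueError("x is constant; slope undefined")
    if np.ptp(ly) == 0:     # constant response: flat fit, no correlation
        return RegressionResult(intercept=float(ly[0]), slope=0.0,
                                r=0.0, p=1.0, n=len(x))
    fit = stats.linregress(lx, ly)
    return RegressionResult(intercept=float(fit.intercept),
                            slope=float(fit.slope),
                            r=float(fit.rvalue), p=float(fit.pvalue),
                            n=len(x))


def substitute_outliers(pairs, threshold: float = 4.0):
    """Leave-one-out outlier screen on ln(duration) given ln(length).

    For each (length, duration) pair the expected ln(duration) is predicted
    from an OLS fit on all *other* pairs.  A pair whose residual magnitude
    strictly exceeds ``threshold`` log units has its log duration replaced
    by that expected value.  Detection is a single pass over the original
    data: substitutions never feed back into the screen.

    Returns ``(pairs_out, report)`` with pairs_out an (n, 2) array of
    (length, duration) after substitution.
    """
    arr = np.asarray(pairs, float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of (length, duration)")
    n = len(arr)
    if n < 4:
        raise ValueError("leave-one-out screen needs at least 4 pairs")
    if np.any(arr <= 0):
        raise ValueError("lengths and durations must be positive")
    lx, ly = np.log(arr[:, 0]), np.log(arr[:, 1])

    # leave-one-out OLS predictions via downdated sufficient statistics
    sx, sy = lx.sum(), ly.sum()
    sxx, sxy = (lx * lx).sum(), (lx * ly).sum()
    subs = []
    out = arr.copy()
    for i in range(n):
        m = n - 1
        sx_i, sy_i = sx - lx[i], sy - ly[i]
        sxx_i, sxy_i = sxx - lx[i] ** 2, sxy - lx[i] * ly[i]
        denom = sxx_i - sx_i ** 2 / m
        if denom <= 0:
            raise ValueError("remaining lengths are constant; screen undefined")
        slope = (sxy_i - sx_i * sy_i / m) / denom
        intercept = (sy_i - slope * sx_i) / m
        expected = intercept + slope * lx[i]
        resid = ly[i] - expected
        if abs(resid) > threshold:
            out[i, 1] = np.exp(expected)
            subs.append(Substitution(index=i, variable="duration",
                                     original_log=float(ly[i]),
                                     expected_log=float(expected),
                                     residual=float(resid)))
    return out, OutlierReport(threshold=float(threshold),
                              substituted=tuple(subs))


def per_group_fits(records: pd.DataFrame, y_col: str = "V",
                   x_col: str = "L") -> dict[str, RegressionResult]:
    """One log-log fit per grade group, conditions pooled.

    ``records`` needs columns group, ``x_col``, ``y_col`` (already filtered
    to one script and the analyzed conditions).
    """
    out = {}
    for grp, sub in records.groupby("group", sort=True, observed=True):
        if len(sub) < 3:
            raise ValueError(f"group {grp!r} has {len(sub)} pairs; need >= 3")
        out[str(grp)] = loglog_fit(sub[x_col].to_numpy(),
                                   sub[y_col].to_numpy())
    if not out:
        raise ValueError("no groups in records")
    return out


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> float:
    """Two-sided Fisher r-to-z test for correlations from independent samples."""
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1 for the z transform")
        if n < 4:
            raise ValueError("need n >= 4 on both sides")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(2 * stats.norm.sf(abs(z)))


def pairwise_r_comparisons(fits: dict[str, RegressionResult]) -> pd.DataFrame:
    """All pairwise Fisher r-to-z comparisons among per-group fits."""
    names = sorted(fits)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            rows.append({
                "group_a": a, "group_b": b,
                "r_a": fits[a].r, "r_b": fits[b].r,
                "p": compare_correlations(fits[a].r, fits[a].n,
                                          fits[b].r, fits[b].n),
            })
    return pd.DataFrame(rows)


def isochrony_scaling(length_ratio: float, slope: float) -> float:
    """Duration fold change implied by a length fold change under T ∝ L^slope.

    E.g. a 20-fold length increase at slope 0.30 gives 20**0.30 ≈ 2.5: the
    compensation at the heart of isochrony.
    """
    if length_ratio <= 0:
        raise ValueError("length_ratio must be positive")
    return float(length_ratio ** slope)


__all__ = [
    "RegressionResult", "OutlierReport", "Substitution",
    "loglog_fit", "substitute_outliers", "per_group_fits",
    "compare_correlations", "pairwise_r_comparisons", "isochrony_scaling",
]
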