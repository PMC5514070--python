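"""Homothety analysis: mixed-design ANOVA on relative letter durations.

Homothety — the invariance of the ratios between the durations of a
movement's sub-components — predicts that the percentage of word time spent
on each letter (rho) does not change when the word is written bigger or
faster.  The test is a split-plot repeated-measures ANOVA with grade Group
as a between-participants factor and Condition (Spontaneous, Big, Fast) and
Letter as within-participants factors, with Bonferroni-adjusted post-hoc
comparisons and partial eta squared effect sizes.

The ANOVA is computed stratum by stratum.  The per-participant data cube
``Y[i, c, l]`` is projected onto an orthonormal basis of R^(C*L) built from
Kronecker products of within-factor contrast bases; orthonormality makes
the squared projections equal the classical sums of squares, and each
stratum is then a one-way between-groups layout in the projected scores.
With unequal group sizes the within-effect tests use the unweighted grand
mean (Type III convention); in a balanced design everything reduces to the
textbook split-plot formulas.  Because the dependent variable is normalized
(rho sums to 100 within every participant x condition), the Group and
Condition main effects carry zero variance and are reported as untestable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trace_io import ANALYZED_CONDITIONS

#: canonical column layout of a homothety table
TABLE_COLUMNS = ["participant_id", "group", "condition", "letter", "rho"]

_NORMALIZED_NOTE = ("dv is normalized (rho sums to 100 per participant x "
                    "condition); across-level change of this factor is not "
                    "evaluable")


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    eta_p2: float
    ss_effect: float
    ss_error: float
    testable: bool = True
    note: str = ""


@dataclass(frozen=True)
class PosthocComparison:
    family: str
    cell_a: tuple
    cell_b: tuple
    mean_diff: float      # percentage points
    p_raw: float
    p_adj: float
    significant: bool


def build_homothety_table(records: pd.DataFrame,
                          conditions=ANALYZED_CONDITIONS) -> pd.DataFrame:
    """Assemble the long-format analysis table from per-trial rho records.

    ``records`` needs columns participant_id, group, condition, letter, rho.
    Small/Slow rows are dropped; participants missing any analyzed
    condition x letter cell are excluded listwise (their ids are kept in
    ``result.attrs["excluded_participants"]``).  Returns one row per
    participant x condition x letter.
    """
    missing = [c for c in TABLE_COLUMNS if c not in records.columns]
    if missing:
        raise DesignError(f"records missing columns {missing}")
    df = records[records["condition"].isin(conditions)].copy()
    dupes = df.duplicated(["participant_id", "condition", "letter"],
                          keep=False)
    if dupes.any():
        bad = df.loc[dupes, "participant_id"].unique()
        raise DesignError(
            f"duplicate participant x condition x letter rows for {list(bad)}")
    letters = df["letter"].unique()
    expected = len(conditions) * len(letters)
    counts = df.groupby("participant_id")["rho"].size()
    incomplete = counts[counts != expected].index
    if len(incomplete):
        df = df[~df["participant_id"].isin(incomplete)]
    out = df[TABLE_COLUMNS].reset_index(drop=True)
    out.attrs["excluded_participants"] = sorted(map(str, incomplete))
    return out


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """eta_p^2 = SS_effect / (SS_effect + SS_error)."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be non-negative")
    if ss_effect == 0 and ss_error == 0:
        raise ValueError("ss_effect and ss_error cannot both be zero")
    return float(ss_effect / (ss_effect + ss_error))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal basis of the sum-to-zero subspace (Helmert)."""
    c = np.zeros((k, k - 1))
    for j in range(1, k):
        c[:j, j - 1] = 1.0
        c[j, j - 1] = -j
        c[:, j - 1] /= np.linalg.norm(c[:, j - 1])
    return c


def _cube(table: pd.DataFrame):
    """Pivot the long table into Y[subject, condition, letter], preserving
    first-appearance order of the within-factor levels."""
    conds = list(pd.unique(table["condition"]))
    letters = list(pd.unique(table["letter"]))
    wide = table.pivot_table(index=["participant_id", "group"],
                             columns=["condition", "letter"],
                             values="rho", sort=False, aggfunc="mean")
    wide = wide.reindex(columns=pd.MultiIndex.from_product([conds, letters]))
    if wide.isna().any().any():
        bad = list(wide[wide.isna().any(axis=1)].index.get_level_values(0))
        raise DesignError(
            f"unbalanced within-subject cells for participants {bad}")
    y = wide.to_numpy().reshape(len(wide), len(conds), len(letters))
    groups = np.asarray(wide.index.get_level_values("group"))
    return y, groups, conds, letters


def _stratum_ss(z: np.ndarray, groups: np.ndarray, labels: np.ndarray):
    """One-way decomposition of projected scores z (n_subj x d).

    Returns (ss_effect, ss_group_x_effect, ss_error): ss_effect tests the
    unweighted grand mean of z against zero (Type III intercept), the
    group term is the usual weighted between-groups SS, the error term the
    pooled within-groups SS.
    """
    n_g = np.array([(groups == lbl).sum() for lbl in labels], float)
    g = len(labels)
    gmeans = np.stack([z[groups == lbl].mean(axis=0) for lbl in labels])
    m_unw = gmeans.mean(axis=0)
    ss_effect = float((m_unw ** 2).sum() * g ** 2 / (1.0 / n_g).sum())
    m_w = (n_g[:, None] * gmeans).sum(axis=0) / n_g.sum()
    ss_gx = float((n_g[:, None] * (gmeans - m_w) ** 2).sum())
    ss_err = 0.0
    for i, lbl in enumerate(labels):
        ss_err += float(((z[groups == lbl] - gmeans[i]) ** 2).sum())
    return ss_effect, ss_gx, ss_err


def _f_row(effect, ss, df_num, ss_err, df_den, testable=True, note=""):
    if not testable:
        return AnovaResult(effect, float("nan"), int(df_num), int(df_den),
                           float("nan"), float("nan"), ss, ss_err,
                           testable=False, note=note)
    F = (ss / df_num) / (ss_err / df_den)
    return AnovaResult(effect, float(F), int(df_num), int(df_den),
                       float(stats.f.sf(F, df_num, df_den)),
                       partial_eta_squared(ss, ss_err), ss, ss_err,
                       note=note)


def mixed_anova(table: pd.DataFrame) -> list[AnovaResult]:
    """Split-plot ANOVA of rho: Group between, Condition and Letter within.

    Requires a listwise-complete table (every participant has all
    condition x letter cells), as built by :func:`build_homothety_table`.
    Returns one AnovaResult per effect.  Group and Condition main effects
    are reported with testable=False: rho is normalized, so their
    across-level variance is identically zero.
    """
    y, groups, conds, letters = _cube(table)
    n, C, L = y.shape
    labels = np.unique(groups)
    g = len(labels)
    if g < 2:
        raise DesignError("need at least 2 between-participant groups")
    if n <= g:
        raise DesignError("need more participants than groups")

    results = []

    # between stratum: projection onto the constant direction
    z0 = y.sum(axis=(1, 2))[:, None] / np.sqrt(C * L)
    _, ss_group, ss_subj = _stratum_ss(z0, groups, labels)
    results.append(_f_row("Group", ss_group, g - 1, ss_subj, n - g,
                          testable=False, note=_NORMALIZED_NOTE))

    kc = _orthonormal_contrasts(C)
    kl = _orthonormal_contrasts(L)
    # orthonormal projections: Condition stratum pairs condition contrasts
    # with the constant letter direction (and vice versa); the interaction
    # stratum pairs contrast with contrast
    z_c = np.einsum("ncl,cj->nj", y, kc) / np.sqrt(L)
    z_l = np.einsum("ncl,lk->nk", y, kl) / np.sqrt(C)
    z_cl = np.einsum("ncl,cj,lk->njk", y, kc, kl).reshape(n, -1)

    for name, z, testable, note in [
        ("Condition", z_c, False, _NORMALIZED_NOTE),
        ("Letter", z_l, True, ""),
        ("Condition x Letter", z_cl, True, ""),
    ]:
        d = z.shape[1]
        ss_w, ss_gx, ss_err = _stratum_ss(z, groups, labels)
        err_df = (n - g) * d
        results.append(_f_row(name, ss_w, d, ss_err, err_df,
                              testable=testable, note=note))
        results.append(_f_row(f"Group x {name}", ss_gx, (g - 1) * d,
                              ss_err, err_df))
    return results


def anova_frame(results: list[AnovaResult]) -> pd.DataFrame:
    """Tabulate AnovaResults (effect, F, df_num, df_den, p, eta_p2, ...)."""
    return pd.DataFrame([{
        "effect": r.effect, "F": r.F, "df_num": r.df_num,
        "df_den": r.df_den, "p": r.p, "eta_p2": r.eta_p2,
        "testable": r.testable, "note": r.note,
    } for r in results])


# posthoc configuration: for each interaction, which factor's levels are
# compared, within the levels of which other factor
_POSTHOC_LAYOUT = {
    "Condition x Letter": ("condition", "letter"),
    "Group x Letter": ("group", "letter"),
    "Group x Condition": ("group", "condition"),
}


def bonferroni_posthoc(table: pd.DataFrame, effect: str,
                       alpha: float = 0.05) -> list[PosthocComparison]:
    """Bonferroni-protected pairwise cell-mean comparisons for an interaction.

    Levels of the effect's first factor are compared pairwise within each
    level of the second factor (e.g. for Condition x Letter: the three
    conditions compared within each letter, a family of C(3,2)*5 = 15).
    Raw p values use the t statistic built on the interaction stratum's
    error term; Bonferroni adjustment multiplies by the family size and
    caps at 1.
    """
    if effect not in _POSTHOC_LAYOUT:
        raise DesignError(
            f"no post-hoc layout for effect {effect!r}; "
            f"known: {sorted(_POSTHOC_LAYOUT)}")
    compare_col, within_col = _POSTHOC_LAYOUT[effect]
    results = {r.effect: r for r in mixed_anova(table)}
    if effect not in results:
        raise DesignError(f"effect {effect!r} not in the ANOVA output")
    res = results[effect]
    ms_err = res.ss_error / res.df_den

    # per-participant cell means, averaging over any factor not in the effect
    by = ["participant_id", "group"]
    by += [c for c in (compare_col, within_col) if c != "group"]
    per_subj = (table.groupby(by, sort=False, observed=True)["rho"]
                .mean().reset_index())
    cell_of = [compare_col, within_col]
    cells = per_subj.groupby(cell_of, sort=False, observed=True)["rho"]
    means = cells.mean()
    sizes = cells.size()

    comparisons = []
    levels = list(pd.unique(per_subj[cell_of[0]]))
    withins = list(pd.unique(per_subj[cell_of[1]]))
    pairs = [(a, b, w) for w in withins
             for a, b in itertools.combinations(levels, 2)]
    m = len(pairs)
    for a, b, w in pairs:
        diff = float(means[(a, w)] - means[(b, w)])
        se = float(np.sqrt(ms_err * (1.0 / sizes[(a, w)]
                                     + 1.0 / sizes[(b, w)])))
        tval = diff / se
        p_raw = float(2 * stats.t.sf(abs(tval), res.df_den))
        p_adj = min(1.0, p_raw * m)
        comparisons.append(PosthocComparison(
            family=effect, cell_a=(a, w), cell_b=(b, w),
            mean_diff=diff, p_raw=p_raw, p_adj=p_adj,
            significant=p_adj < alpha))
    return comparisons


__all__ = [
    "AnovaResult", "PosthocComparison", "DesignError", "TABLE_COLUMNS",
    "build_homothety_table", "mixed_anova", "anova_frame",
    "partial_eta_squared", "bonferroni_posthoc",
]
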