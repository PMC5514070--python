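"""Mixed-design ANOVA on relative letter durations.

The implementation computes sums of squares by orthonormal contrast
projection; the oracle here recomputes a small balanced design from the
textbook cell-mean formulas, a fully independent derivation.
"""

import numpy as np
import pandas as pd
import pytest

from penrhythm.homothety import (DesignError, bonferroni_posthoc,
                                 build_homothety_table, mixed_anova,
                                 partial_eta_squared)
from penrhythm.synthetic import SyntheticConfig, simulate_homothety_profiles


def random_table(group_sizes, n_cond=3, n_letter=5, seed=0, balanced_rho=True):
    """Long-format table with arbitrary (non-normalized) dv values."""
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for g, size in zip(["G1", "G2", "G3", "G4", "G5"], group_sizes):
        for _ in range(size):
            for c in range(n_cond):
                vals = rng.normal(20, 4, n_letter)
                for l in range(n_letter):
                    rows.append({"participant_id": f"P{pid}", "group": g,
                                 "condition": f"C{c}", "letter": f"L{l}",
                                 "rho": vals[l]})
            pid += 1
    return pd.DataFrame(rows)


def split_plot_oracle(table):
    """Textbook balanced split-plot SS decomposition from cell means."""
    piv = table.pivot_table(index=["group", "participant_id"],
                            columns=["condition", "letter"], values="rho")
    groups = piv.index.get_level_values("group")
    glabels = list(dict.fromkeys(groups))
    n = (groups == glabels[0]).sum()
    C = table["condition"].nunique()
    L = table["letter"].nunique()
    y = piv.to_numpy().reshape(len(piv), C, L)
    gidx = np.array([glabels.index(g) for g in groups])
    G = len(glabels)

    m = y.mean()
    m_g = np.array([y[gidx == g].mean() for g in range(G)])
    m_c = y.mean(axis=(0, 2))
    m_l = y.mean(axis=(0, 1))
    m_gc = np.stack([y[gidx == g].mean(axis=(0, 2)) for g in range(G)])
    m_gl = np.stack([y[gidx == g].mean(axis=(0, 1)) for g in range(G)])
    m_cl = y.mean(axis=0)
    m_gcl = np.stack([y[gidx == g].mean(axis=0) for g in range(G)])
    m_i = y.mean(axis=(1, 2))
    m_ic = y.mean(axis=2)
    m_il = y.mean(axis=1)

    ss = {}
    ss["Group"] = C * L * n * ((m_g - m) ** 2).sum()
    ss["subj"] = C * L * ((m_i - m_g[gidx]) ** 2).sum()
    ss["Condition"] = len(piv) * L * ((m_c - m) ** 2).sum()
    ss["Group x Condition"] = L * n * (
        (m_gc - m_g[:, None] - m_c[None, :] + m) ** 2).sum()
    ss["err_C"] = L * ((m_ic - m_i[:, None]
                        - m_gc[gidx] + m_g[gidx, None]) ** 2).sum()
    ss["Letter"] = len(piv) * C * ((m_l - m) ** 2).sum()
    ss["Group x Letter"] = C * n * (
        (m_gl - m_g[:, None] - m_l[None, :] + m) ** 2).sum()
    ss["err_L"] = C * ((m_il - m_i[:, None]
                        - m_gl[gidx] + m_g[gidx, None]) ** 2).sum()
    ss["Condition x Letter"] = len(piv) * (
        (m_cl - m_c[:, None] - m_l[None, :] + m) ** 2).sum()
    ss["Group x Condition x Letter"] = n * (
        (m_gcl - m_gc[:, :, None] - m_gl[:, None, :] - m_cl[None]
         + m_g[:, None, None] + m_c[None, :, None] + m_l[None, None, :]
         - m) ** 2).sum()
    resid = (y - m_ic[:, :, None] - m_il[:, None, :] + m_i[:, None, None]
             - m_gcl[gidx] + m_gc[gidx][:, :, None]
             + m_gl[gidx][:, None, :] - m_g[gidx][:, None, None])
    ss["err_CL"] = (resid ** 2).sum()
    return ss


def test_balanced_ss_match_textbook_oracle():
    table = random_table((3, 3, 3, 3, 3), seed=42)
    ora = split_plot_oracle(table)
    res = {r.effect: r for r in mixed_anova(table)}
    pairs = [
        ("Group x Condition", "err_C"),
        ("Letter", "err_L"),
        ("Group x Letter", "err_L"),
        ("Condition x Letter", "err_CL"),
        ("Group x Condition x Letter", "err_CL"),
    ]
    for eff, err in pairs:
        assert res[eff].ss_effect == pytest.approx(ora[eff], rel=1e-9), eff
        assert res[eff].ss_error == pytest.approx(ora[err], rel=1e-9), eff
    # untestable effects still expose the stratum SS
    assert res["Group"].ss_effect == pytest.approx(ora["Group"], rel=1e-9)
    assert res["Group"].ss_error == pytest.approx(ora["subj"], rel=1e-9)
    assert res["Condition"].ss_effect == pytest.approx(ora["Condition"],
                                                       rel=1e-9)


@pytest.mark.parametrize("group_sizes,n_cond,n_letter", [
    ((2, 3, 4), 3, 5),
    ((5, 2), 2, 4),
    ((3, 3, 3, 3, 3), 4, 2),
])
def test_df_closed_forms(group_sizes, n_cond, n_letter):
    """Between df g-1/N-g; within effect (q-1) with (N-g)(q-1) error;
    interaction dfs multiply."""
    sizes = group_sizes + (0,) * (5 - len(group_sizes))
    table = random_table(sizes, n_cond, n_letter, seed=1)
    N, g = sum(group_sizes), len(group_sizes)
    res = {r.effect: r for r in mixed_anova(table)}
    assert (res["Group"].df_num, res["Group"].df_den) == (g - 1, N - g)
    assert (res["Condition"].df_num, res["Condition"].df_den) == \
        (n_cond - 1, (N - g) * (n_cond - 1))
    assert (res["Group x Letter"].df_num, res["Group x Letter"].df_den) == \
        ((g - 1) * (n_letter - 1), (N - g) * (n_letter - 1))
    cl = res["Condition x Letter"]
    assert (cl.df_num, cl.df_den) == \
        ((n_cond - 1) * (n_letter - 1), (N - g) * (n_cond - 1) * (n_letter - 1))
    gcl = res["Group x Condition x Letter"]
    assert gcl.df_num == (g - 1) * (n_cond - 1) * (n_letter - 1)


def test_study_shape_dfs():
    cfg = SyntheticConfig(seed=11)
    table = build_homothety_table(simulate_homothety_profiles(cfg))
    res = {r.effect: r for r in mixed_anova(table)}
    assert (res["Condition x Letter"].df_num,
            res["Condition x Letter"].df_den) == (8, 2344)
    assert (res["Group x Letter"].df_num,
            res["Group x Letter"].df_den) == (16, 1172)
    assert res["Group x Condition x Letter"].df_num == 32


def test_normalized_main_effects_untestable():
    cfg = SyntheticConfig(group_sizes=(3, 3, 3, 3, 3), seed=2)
    table = build_homothety_table(simulate_homothety_profiles(cfg))
    res = {r.effect: r for r in mixed_anova(table)}
    for eff in ("Group", "Condition"):
        assert not res[eff].testable
        assert np.isnan(res[eff].F)
        # normalization leaves literally no variance in these strata
        assert res[eff].ss_effect == pytest.approx(0.0, abs=1e-18)


def test_eta_p2_matches_f_df_identity():
    table = random_table((4, 4, 4, 4, 4), seed=3)
    for r in mixed_anova(table):
        if not r.testable:
            continue
        implied = (r.F * r.df_num) / (r.F * r.df_num + r.df_den)
        assert r.eta_p2 == pytest.approx(implied, rel=1e-9), r.effect


@pytest.mark.parametrize("ss,expected", [((1, 9), 0.1), ((0, 5), 0.0)])
def test_partial_eta_squared_values(ss, expected):
    assert partial_eta_squared(*ss) == pytest.approx(expected)


def test_partial_eta_squared_rejects_negative():
    with pytest.raises(ValueError):
        partial_eta_squared(-1.0, 2.0)


# --- table building ------------------------------------------------------

def _records(participants, conditions, letters="burle"):
    rows = []
    for pid, grp in participants:
        for cond in conditions:
            for ch in letters:
                rows.append({"participant_id": pid, "group": grp,
                             "condition": cond, "letter": ch, "rho": 20.0})
    return pd.DataFrame(rows)


def test_build_table_drops_small_slow():
    recs = _records([("a", "G1"), ("b", "G2")],
                    ["Spontaneous", "Small", "Big", "Slow", "Fast"])
    table = build_homothety_table(recs)
    assert len(table) == 2 * 3 * 5
    assert set(table["condition"]) == {"Spontaneous", "Big", "Fast"}


def test_build_table_listwise_exclusion():
    recs = _records([("a", "G1"), ("b", "G2")], ["Spontaneous", "Big", "Fast"])
    recs = recs[~((recs.participant_id == "b") & (recs.condition == "Fast"))]
    table = build_homothety_table(recs)
    assert set(table["participant_id"]) == {"a"}
    assert table.attrs["excluded_participants"] == ["b"]


def test_build_table_rejects_duplicates():
    recs = _records([("a", "G1")], ["Spontaneous", "Big", "Fast"])
    dup = recs.iloc[[0]]
    with pytest.raises(DesignError, match="duplicate"):
        build_homothety_table(pd.concat([recs, dup]))


def test_unbalanced_within_cells_named():
    recs = _records([("a", "G1"), ("b", "G2"), ("c", "G2")],
                    ["Spontaneous", "Big", "Fast"])
    # sneak an incomplete participant past the builder
    broken = recs[~((recs.participant_id == "c") & (recs.letter == "e"))]
    with pytest.raises(DesignError, match="c"):
        mixed_anova(broken)


# --- post-hocs -----------------------------------------------------------

def test_posthoc_family_sizes():
    cfg = SyntheticConfig(group_sizes=(3, 3, 3, 3, 3), seed=4)
    table = build_homothety_table(simulate_homothety_profiles(cfg))
    cl = bonferroni_posthoc(table, "Condition x Letter")
    assert len(cl) == 3 * 5  # C(3,2) condition pairs within each letter
    gl = bonferroni_posthoc(table, "Group x Letter")
    assert len(gl) == 10 * 5  # C(5,2) group pairs within each letter


def test_posthoc_bonferroni_adjustment():
    cfg = SyntheticConfig(group_sizes=(3, 3, 3, 3, 3), seed=4)
    table = build_homothety_table(simulate_homothety_profiles(cfg))
    comps = bonferroni_posthoc(table, "Condition x Letter")
    m = len(comps)
    for c in comps:
        assert c.p_adj == pytest.approx(min(1.0, c.p_raw * m))
        assert c.significant == (c.p_adj < 0.05)


def test_posthoc_unknown_effect():
    cfg = SyntheticConfig(group_sizes=(3, 3, 3, 3, 3), seed=4)
    table = build_homothety_table(simulate_homothety_profiles(cfg))
    with pytest.raises(DesignError, match="layout"):
        bonferroni_posthoc(table, "Letter x Banana")
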