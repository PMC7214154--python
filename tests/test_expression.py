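"""Normalization, dispersion, NB Wald contrasts, BH, cascades, ddCt."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mirpoc.expression import (
    DifferentialExpression,
    anova_snk,
    bh_adjust,
    ddct_fold_change,
    estimate_dispersion,
    median_of_ratios_norm,
    nb_wald_contrast,
    stats_cascade,
)
from mirpoc.simulate import SimulationConfig, simulate_mir_counts

from conftest import nb_counts


# ---------------------------------------------------------------------------
# median-of-ratios
# ---------------------------------------------------------------------------

def test_size_factors_identical_samples():
    counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
    sf = median_of_ratios_norm(counts)
    assert np.allclose(sf, 1.0)


def test_size_factors_doubled_sample():
    """B = 2 x A forces factors (1/sqrt(2), sqrt(2)) through the
    geometric-mean reference."""
    a = np.array([10, 100, 40, 7])
    counts = pd.DataFrame({"A": a, "B": 2 * a})
    sf = median_of_ratios_norm(counts)
    assert sf["A"] == pytest.approx(1 / np.sqrt(2))
    assert sf["B"] == pytest.approx(np.sqrt(2))


def test_size_factors_error_without_all_nonzero_feature():
    counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
    with pytest.raises(ValueError, match="pseudo-reference"):
        median_of_ratios_norm(counts)


def test_size_factors_recover_planted_library_sizes():
    """Estimated factor ratios within 10% of the planted 4-fold span."""
    cfg = SimulationConfig(seed=21, n_mirs=400, n_de=0, n_up=0, n_down=0, lib_size_range=(0.5, 2.0))
    counts, truth = simulate_mir_counts(cfg)
    sf = median_of_ratios_norm(counts)
    lib = pd.Series(truth.attrs["lib_sizes"])
    est_ratio = (sf / sf.iloc[0]).to_numpy()
    true_ratio = (lib / lib.iloc[0]).to_numpy()
    assert np.all(np.abs(est_ratio / true_ratio - 1.0) < 0.10)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def test_dispersion_poisson_counts_near_zero():
    rng = np.random.default_rng(1)
    base = np.exp(rng.uniform(np.log(200), np.log(2000), 400))
    counts = pd.DataFrame(rng.poisson(np.tile(base[:, None], (1, 40))),
                          columns=[f"s{i}" for i in range(40)])
    sf = median_of_ratios_norm(counts)
    groups = pd.Series(["A"] * 20 + ["B"] * 20, index=counts.columns)
    d = estimate_dispersion(counts, sf, group_labels=groups)
    assert float(np.median(d)) < 0.01


def test_dispersion_nb_02_recovered_at_n20():
    """Method-of-moments at n=20/group: median in [0.1, 0.4] every seed."""
    base = np.exp(np.linspace(np.log(100), np.log(2000), 300))
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        counts = pd.DataFrame(
            nb_counts(np.tile(base[:, None], (1, 40)), 0.2, None, rng),
            columns=[f"s{i}" for i in range(40)],
        )
        sf = median_of_ratios_norm(counts)
        groups = pd.Series(["A"] * 20 + ["B"] * 20, index=counts.columns)
        d = estimate_dispersion(counts, sf, group_labels=groups)
        assert 0.1 <= float(np.median(d)) <= 0.4


def test_dispersion_constant_feature_floored():
    counts = pd.DataFrame({"a": [5, 10], "b": [5, 10], "c": [5, 10], "d": [5, 10]})
    sf = pd.Series(1.0, index=counts.columns)
    d = estimate_dispersion(counts, sf, shrinkage=0.0)
    assert (d > 0).all() and float(d.iloc[0]) <= 1e-6


def test_dispersion_needs_two_samples_per_group():
    counts = pd.DataFrame({"a": [5], "b": [5]}).T
    with pytest.raises(ValueError):
        estimate_dispersion(
            pd.DataFrame({"a": [5, 6], "b": [7, 8]}),
            pd.Series(1.0, index=["a", "b"]),
            group_labels=pd.Series(["A", "B"]),
        )


# ---------------------------------------------------------------------------
# NB Wald contrast
# ---------------------------------------------------------------------------

def test_wald_identical_groups_zero_lfc():
    counts = pd.DataFrame(
        {"a1": [10, 50], "a2": [20, 60], "b1": [10, 50], "b2": [20, 60]},
        index=["f1", "f2"],
    )
    sf = pd.Series(1.0, index=counts.columns)
    disp = pd.Series(0.1, index=counts.index)
    groups = pd.Series(["A", "A", "B", "B"], index=counts.columns)
    res = nb_wald_contrast(counts, sf, disp, groups, ("B", "A"))
    assert np.allclose(res["log2fc"], 0.0)


def test_wald_antisymmetry(two_group_counts):
    """Swapping treated and reference negates log2fc and keeps p."""
    counts, groups = two_group_counts
    sf = median_of_ratios_norm(counts)
    disp = estimate_dispersion(counts, sf, group_labels=groups)
    ab = nb_wald_contrast(counts, sf, disp, groups, ("B", "A"))
    ba = nb_wald_contrast(counts, sf, disp, groups, ("A", "B"))
    assert np.allclose(ab["log2fc"], -ba["log2fc"])
    assert np.allclose(ab["p"], ba["p"])


def test_wald_matches_glm_oracle():
    """Closed-form Wald equals an independent NB GLM fit (log link,
    two-group design, known dispersion)."""
    import statsmodels.api as sm

    rng = np.random.default_rng(5)
    alpha = 0.15
    y = nb_counts(np.concatenate([np.full(12, 80.0), np.full(12, 160.0)]), alpha, None, rng)
    counts = pd.DataFrame(y[None, :], index=["f"], columns=[f"s{i}" for i in range(24)])
    sf = pd.Series(1.0, index=counts.columns)
    disp = pd.Series(alpha, index=["f"])
    groups = pd.Series(["A"] * 12 + ["B"] * 12, index=counts.columns)
    res = nb_wald_contrast(counts, sf, disp, groups, ("B", "A"))

    X = sm.add_constant((groups == "B").astype(float).to_numpy())
    glm = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
    assert res["log2fc"].iloc[0] == pytest.approx(glm.params[1] / np.log(2), rel=1e-6)
    assert res["se"].iloc[0] == pytest.approx(glm.bse[1] / np.log(2), rel=1e-4)


def test_wald_zero_group_pseudocount_flagged():
    counts = pd.DataFrame(
        {"a1": [0], "a2": [0], "b1": [9], "b2": [11]}, index=["f"]
    )
    sf = pd.Series(1.0, index=counts.columns)
    disp = pd.Series(0.1, index=counts.index)
    groups = pd.Series(["A", "A", "B", "B"], index=counts.columns)
    res = nb_wald_contrast(counts, sf, disp, groups, ("B", "A"))
    assert bool(res["pseudo"].iloc[0])
    assert np.isfinite(res["log2fc"].iloc[0])


def test_wald_requires_group_presence(two_group_counts):
    counts, groups = two_group_counts
    sf = median_of_ratios_norm(counts)
    disp = estimate_dispersion(counts, sf, group_labels=groups)
    with pytest.raises(ValueError):
        nb_wald_contrast(counts, sf, disp, groups, ("C", "A"))


def test_normalization_removes_library_effect_for_null_features():
    """Post-normalization null group means differ by < 5%."""
    cfg = SimulationConfig(seed=31, n_mirs=500, n_de=0, n_up=0, n_down=0, lib_size_range=(0.5, 2.0))
    counts, truth = simulate_mir_counts(cfg)
    groups = pd.Series(truth.attrs["sample_groups"]).reindex(counts.columns)
    sf = median_of_ratios_norm(counts)
    norm = counts / sf
    m_ir = norm.loc[:, (groups == "IR").to_numpy()].mean(axis=1)
    m_sham = norm.loc[:, (groups == "Sham").to_numpy()].mean(axis=1)
    rel = (m_ir.mean() - m_sham.mean()) / m_sham.mean()
    assert abs(rel) < 0.05


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def _bh_oracle(p: np.ndarray) -> np.ndarray:
    """Direct-definition BH: padj_(i) = min_{j>=i} m p_(j) / j, capped."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = min(running, 1.0)
    return adj


def test_bh_single_and_closed_form():
    assert bh_adjust([0.03])[0] == pytest.approx(0.03)
    out = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(out, 0.04)


@settings(deadline=None, derandomize=True, max_examples=100)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
def test_bh_matches_definition_oracle(pvals):
    p = np.asarray(pvals)
    assert np.allclose(bh_adjust(p), _bh_oracle(p))


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=60))
def test_bh_monotone_and_bounded(pvals):
    p = np.asarray(pvals)
    adj = bh_adjust(p)
    assert np.all(adj <= 1.0) and np.all(adj >= p - 1e-12)
    order = np.argsort(p, kind="mergesort")
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# two-sample cascade
# ---------------------------------------------------------------------------

def test_cascade_identical_normal_samples_t_branch():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, 15)
    res = stats_cascade(a, a.copy())
    assert res.chosen_test == "t"
    assert res.p > 0.9


def test_cascade_unequal_variance_welch():
    """25-fold variance ratio at n=20: Levene sends >= 9/10 seeds to Welch."""
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 5, 20)
        res = stats_cascade(a, b)
        hits += res.chosen_test == "welch"
    assert hits >= 9


def test_cascade_heavy_tails_mann_whitney():
    """Cauchy-contaminated samples at n=20: Shapiro-Wilk catches >= 8/10."""
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(50 + seed)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 1, 20)
        b[:6] = rng.standard_cauchy(6) * 5
        res = stats_cascade(a, b)
        hits += res.chosen_test == "mann_whitney"
    assert hits >= 8


def test_cascade_paired_branches():
    rng = np.random.default_rng(2)
    a = rng.normal(0, 1, 12)
    res = stats_cascade(a, a + rng.normal(0.1, 0.2, 12), paired=True)
    assert res.chosen_test in {"t", "wilcoxon"}
    with pytest.raises(ValueError):
        stats_cascade([1, 2], [1, 2, 3])  # n < 3
    with pytest.raises(ValueError):
        stats_cascade([1, 2, 3, 4], [1, 2, 3], paired=True)


def test_cascade_records_trace():
    rng = np.random.default_rng(3)
    res = stats_cascade(rng.normal(0, 1, 10), rng.normal(0, 1, 10))
    assert any(t.startswith("shapiro") for t in res.trace)
    assert res.trace[-1].startswith("chosen=")


# ---------------------------------------------------------------------------
# ANOVA + SNK
# ---------------------------------------------------------------------------

def test_snk_identical_groups_no_pairs():
    g = [np.array([1.0, 2.0, 3.0, 4.0])] * 3
    out = anova_snk(g)
    assert not out["significant"].to_numpy().any()


def test_snk_shifted_group_all_pairs():
    """One group shifted 5 pooled SD: its pairs significant in >= 9/10."""
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        g = [rng.normal(0, 1, 10), rng.normal(0, 1, 10), rng.normal(5, 1, 10)]
        sig = anova_snk(g)["significant"]
        hits += bool(sig.loc[0, 2] and sig.loc[1, 2])
    assert hits >= 9


def test_snk_matches_manual_oracle():
    """Frozen hand computation on a fixed 3-group dataset: the widest range
    (q=11.90 > 3.773) and the (g1, g2) pair (q=10.71 > 3.081) reject; the
    (g2, g3) pair (q=1.19) does not."""
    g1 = [10.0, 11.0, 9.5, 10.5, 10.2]
    g2 = [12.0, 12.5, 11.8, 12.2, 12.6]
    g3 = [12.4, 12.1, 12.9, 12.3, 12.5]
    out = anova_snk([g1, g2, g3], alpha=0.05)
    assert out["anova_p"] == pytest.approx(3.400708e-06, rel=1e-4)
    sig = out["significant"]
    assert bool(sig.loc[0, 1]) and bool(sig.loc[0, 2])
    assert not bool(sig.loc[1, 2])


def test_snk_routes_two_groups_away():
    with pytest.raises(ValueError, match="stats_cascade"):
        anova_snk([[1, 2], [3, 4]])


def test_snk_protects_subranges():
    """A non-significant wide range blocks its inner pairs even when an
    inner q would exceed its own critical value."""
    # three groups with tiny spread differences but huge within-variance
    rng = np.random.default_rng(9)
    g = [rng.normal(0, 10, 5), rng.normal(1, 10, 5), rng.normal(2, 10, 5)]
    out = anova_snk(g)
    if out["anova_p"] > 0.05:
        assert not out["significant"].to_numpy().any()


# ---------------------------------------------------------------------------
# delta-delta-Ct
# ---------------------------------------------------------------------------

def test_ddct_closed_forms():
    # ddCt = 0 -> fold 1; ddCt = -1 -> fold 2
    ct = pd.DataFrame(
        {
            "r1": [15.0, 20.0], "r2": [15.0, 20.0],
            "t1": [15.0, 19.0], "t2": [15.0, 19.0],
        },
        index=["Hk", "GeneA"],
    )
    groups = pd.Series(["ref", "ref", "trt", "trt"], index=ct.columns)
    fold = ddct_fold_change(ct, "Hk", groups, "ref")
    assert fold.loc["GeneA", "ref"] == pytest.approx(1.0)
    assert fold.loc["GeneA", "trt"] == pytest.approx(2.0)


def test_ddct_matches_manual_arithmetic_oracle():
    """Random Ct table vs spreadsheet-style per-cell computation, 1e-12."""
    rng = np.random.default_rng(8)
    samples = [f"s{i}" for i in range(12)]
    groups = pd.Series(["g1"] * 4 + ["g2"] * 4 + ["g3"] * 4, index=samples)
    ct = pd.DataFrame(
        rng.uniform(14, 30, size=(4, 12)), index=["Hk", "A", "B", "C"], columns=samples
    )
    fold = ddct_fold_change(ct, "Hk", groups, "g1")
    for gene in ("A", "B", "C"):
        ref_dcts = [ct.loc[gene, s] - ct.loc["Hk", s] for s in samples if groups[s] == "g1"]
        for grp in ("g1", "g2", "g3"):
            dcts = [ct.loc[gene, s] - ct.loc["Hk", s] for s in samples if groups[s] == grp]
            expected = 2.0 ** -(np.mean(dcts) - np.mean(ref_dcts))
            assert abs(fold.loc[gene, grp] - expected) < 1e-12


def test_ddct_missing_housekeeping():
    ct = pd.DataFrame({"s1": [20.0], "s2": [21.0]}, index=["GeneA"])
    groups = pd.Series(["a", "b"], index=ct.columns)
    with pytest.raises(ValueError, match="housekeeping"):
        ddct_fold_change(ct, "Hk", groups, "a")


# ---------------------------------------------------------------------------
# model facade
# ---------------------------------------------------------------------------

def test_model_fit_and_summary(two_group_counts):
    counts, groups = two_group_counts
    model = DifferentialExpression(counts, groups)
    res = model.fit({"B_vs_A": ("B", "A")})
    tab = res.table("B_vs_A")
    assert {"log2fc", "se", "p", "padj", "mean_expression"} <= set(tab.columns)
    assert ((tab["padj"] >= tab["p"] - 1e-12) & (tab["padj"] <= 1.0)).all()
    assert "B_vs_A" in res.summary()


def test_model_rejects_negative_and_duplicates():
    with pytest.raises(ValueError):
        DifferentialExpression(
            pd.DataFrame({"a": [-1, 2], "b": [1, 2]}), pd.Series(["A", "B"])
        )
    dup = pd.DataFrame([[1, 2], [3, 4]], index=["f", "f"], columns=["a", "b"])
    with pytest.raises(ValueError):
        DifferentialExpression(dup, pd.Series(["A", "B"]))
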