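"""Calibrated differential expression: size factors, NB Wald test, BH,
shrinkage, significance classes, RPKM threshold."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from calq.de import (
    CountMatrix,
    bh_adjust,
    classify_significance,
    estimate_dispersions,
    kde_valley,
    nb_wald_test,
    prenormalize_spike,
    rpkm_and_threshold,
    run_calibrated_de,
    shrink_lfc,
    size_factors_median_of_ratios,
)
from calq.simulate import SimTruth, make_rna_genes, simulate_rna_counts


def test_prenormalize_spike_arithmetic():
    spike = pd.DataFrame({"s1": [100], "s2": [100]})
    rho = pd.Series([0.2, 0.4], index=["s1", "s2"])
    out = prenormalize_spike(spike, rho)
    assert out.loc[0, "s1"] == pytest.approx(500)
    assert out.loc[0, "s2"] == pytest.approx(250)
    with pytest.raises(ValueError):
        prenormalize_spike(spike, pd.Series([0.2, 0.0], index=["s1", "s2"]))


def test_prenormalize_constant_rho_preserves_sf_ratios():
    rng = np.random.default_rng(0)
    spike = pd.DataFrame(rng.poisson(100, (200, 4)), columns=list("abcd"))
    rho = pd.Series(0.3, index=list("abcd"))
    sf_raw = size_factors_median_of_ratios(spike)
    sf_pre = size_factors_median_of_ratios(prenormalize_spike(spike, rho))
    np.testing.assert_allclose(
        (sf_pre / sf_pre.iloc[0]).to_numpy(), (sf_raw / sf_raw.iloc[0]).to_numpy()
    )


def test_size_factors_hand_example():
    mat = pd.DataFrame({"s1": [4, 1, 9], "s2": [16, 4, 36]})
    sf = size_factors_median_of_ratios(mat)
    assert sf["s1"] == pytest.approx(0.5)
    assert sf["s2"] == pytest.approx(2.0)
    same = pd.DataFrame({"s1": [5, 8], "s2": [5, 8]})
    np.testing.assert_allclose(size_factors_median_of_ratios(same), 1.0)
    with pytest.raises(ValueError):
        size_factors_median_of_ratios(pd.DataFrame({"s1": [0, 1], "s2": [1, 0]}))


def test_size_factors_match_brute_force_oracle():
    rng = np.random.default_rng(1)
    for _ in range(100):
        mat = pd.DataFrame(
            rng.poisson(50, (rng.integers(5, 40), rng.integers(2, 6))) + 1
        )
        sf = size_factors_median_of_ratios(mat).to_numpy()
        # independent oracle: literal geometric means and per-sample medians
        x = mat.to_numpy(dtype=float)
        gm = np.array([np.prod(row) ** (1 / len(row)) for row in x])
        expected = np.array(
            [np.median(x[:, j] / gm) for j in range(x.shape[1])]
        )
        np.testing.assert_allclose(sf, expected, atol=1e-12, rtol=1e-12)


def test_wald_identical_conditions_null():
    counts = pd.DataFrame(
        {f"{c}_r{i}": [100, 30, 7] for c in "AB" for i in (1, 2, 3)},
        index=["g1", "g2", "g3"],
    )
    conds = pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns)
    sf = pd.Series(1.0, index=counts.columns)
    res = nb_wald_test(counts, sf, conds)
    np.testing.assert_allclose(res["lfc_mle"], 0.0, atol=1e-12)
    np.testing.assert_allclose(res["p"], 1.0, atol=1e-9)


def test_wald_all_zero_gene_is_na():
    counts = pd.DataFrame(
        {"A_r1": [0, 10], "A_r2": [0, 12], "B_r1": [0, 30], "B_r2": [0, 28]},
        index=["dead", "live"],
    )
    conds = pd.Series(["A", "A", "B", "B"], index=counts.columns)
    res = nb_wald_test(counts, pd.Series(1.0, index=counts.columns), conds)
    assert np.isnan(res.loc["dead", "p"])
    assert np.isfinite(res.loc["live", "p"])
    padj = bh_adjust(res["p"].to_numpy())
    assert np.isnan(padj[0]) and padj[1] == res.loc["live", "p"]  # m=1


def test_wald_matches_statsmodels_glm():
    """With equal size factors the closed-form group means are the exact NB
    MLE, so a statsmodels NB GLM with the same fixed dispersion must agree
    on both the coefficient and its standard error."""
    import statsmodels.api as sm

    rng = np.random.default_rng(2)
    n = 20
    counts = pd.DataFrame(
        rng.negative_binomial(20, 20 / (20 + 200), size=(n, 6)),
        columns=[f"{c}_r{i}" for c in "AB" for i in (1, 2, 3)],
    ) + 1
    conds = pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns)
    sf = pd.Series(1.0, index=counts.columns)
    alpha = pd.Series(0.05, index=counts.index)
    res = nb_wald_test(counts, sf, conds, dispersions=alpha)
    X = sm.add_constant(np.array([0, 0, 0, 1, 1, 1]))
    for g in range(n):
        y = counts.iloc[g].to_numpy()
        fit = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=0.05)).fit()
        assert res["lfc_mle"].iloc[g] == pytest.approx(fit.params[1] / np.log(2), abs=1e-6)
        assert res["se"].iloc[g] == pytest.approx(fit.bse[1] / np.log(2), rel=1e-4)


def test_bh_hand_example_and_single():
    np.testing.assert_allclose(
        bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
    )
    np.testing.assert_allclose(bh_adjust(np.array([0.123])), [0.123])
    with pytest.raises(ValueError):
        bh_adjust(np.array([0.5, 1.2]))


def test_bh_matches_statsmodels_oracle():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(3)
    for _ in range(100):
        p = rng.random(rng.integers(1, 50))
        mine = bh_adjust(p)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(mine, ref, atol=1e-12)


def test_bh_monotone_in_p():
    rng = np.random.default_rng(4)
    p = np.sort(rng.random(30))
    adj = bh_adjust(p)
    assert (np.diff(adj) >= -1e-15).all()


def test_shrinkage_limits_and_ordering():
    lfc = np.array([2.0, 2.0, 2.0])
    # tiny se -> no shrinkage; huge se -> toward zero
    shrunk, _ = shrink_lfc(lfc, np.array([1e-6, 1.0, 100.0]))
    assert shrunk[0] == pytest.approx(2.0, abs=1e-3)
    assert abs(shrunk[2]) < abs(shrunk[1]) < 2.0
    assert abs(shrunk[2]) < 0.01


def test_shrinkage_improves_rank_agreement_with_truth():
    rng = np.random.default_rng(5)
    true = rng.normal(0, 0.5, 2000)
    se = rng.uniform(0.05, 1.5, 2000)
    mle = true + rng.normal(0, se)
    shrunk, _ = shrink_lfc(mle, se)
    r_mle = sps.spearmanr(mle, true).statistic
    r_shrunk = sps.spearmanr(shrunk, true).statistic
    assert r_shrunk >= r_mle


@pytest.mark.parametrize(
    "padj,fc,expected",
    [
        (0.01, 1.6, "up"),
        (0.01, 1.4, "no_change"),  # below the fold-change threshold
        (0.2, 3.0, "no_change"),   # not significant
        (0.01, 1 / 1.6, "down"),
    ],
)
def test_significance_classes(padj, fc, expected):
    out = classify_significance(np.array([padj]), np.array([np.log2(fc)]))
    assert out[0] == expected


def test_rpkm_arithmetic_and_paper_threshold_rule():
    # 4 genes: one with mean normalized count 100 over 2 kb, total 1e6
    counts = pd.DataFrame(
        {"r1": [100.0, 500_000 - 100, 300_000, 200_000]},
        index=["g1", "g2", "g3", "g4"],
    )
    lengths = pd.Series([2000, 1000, 1000, 1000], index=counts.index)
    # bypass the valley finder (distribution here is arbitrary)
    with pytest.warns(UserWarning):
        out = rpkm_and_threshold(counts, lengths, fallback_threshold=2.838)
    assert out.loc["g1", "rpkm"] == pytest.approx(50.0)
    assert out.loc["g1", "log2_rpkm"] == pytest.approx(np.log2(51.0), abs=1e-9)
    # an RPKM of 3.0 exceeds the documented 2.838 expression cutoff
    assert out.attrs["rpkm_threshold"] == 2.838
    assert 3.0 > out.attrs["rpkm_threshold"]


def test_kde_valley_between_two_modes():
    rng = np.random.default_rng(6)
    values = np.concatenate([rng.normal(0, 1, 4000), rng.normal(5, 1, 4000)])
    valley = kde_valley(values)
    # grid-search oracle on the true mixture density
    grid = np.linspace(-2, 7, 2000)
    dens = 0.5 * sps.norm.pdf(grid, 0, 1) + 0.5 * sps.norm.pdf(grid, 5, 1)
    lo, hi = np.searchsorted(grid, 0.5), np.searchsorted(grid, 4.5)
    oracle = grid[lo + np.argmin(dens[lo:hi])]
    assert valley == pytest.approx(oracle, abs=0.3)
    with pytest.raises(ValueError, match="unimodal"):
        kde_valley(rng.normal(0, 1, 2000))


def test_size_factor_recovery_within_5pct():
    genes_t = make_rna_genes(800, seed=0, mean_baseline=150.0)
    genes_s = make_rna_genes(400, seed=1, mean_baseline=120.0, prefix="spk")
    truth = SimTruth(seed=21)
    sim = simulate_rna_counts(genes_t, genes_s, truth, dispersion=0.05)
    # spike-block depth ~ 400 genes x ~120 counts >> 1e4
    sf = size_factors_median_of_ratios(prenormalize_spike(sim["spike"], sim["rho"]))
    ratio = (sf / sim["size_factors"]).to_numpy()
    ratio = ratio / np.exp(np.mean(np.log(ratio)))  # size factors are scale-free
    assert np.abs(np.log(ratio)).max() < np.log(1.05)


def test_condition_swap_negates_lfc_preserves_p():
    genes_t = make_rna_genes(300, seed=2, mean_baseline=200.0)
    genes_s = make_rna_genes(100, seed=3, mean_baseline=100.0, prefix="spk")
    de = pd.Series(np.linspace(-2, 2, 300), index=genes_t["gene_id"])
    sim = simulate_rna_counts(genes_t, genes_s, SimTruth(de_table=de, seed=4))
    sf = size_factors_median_of_ratios(prenormalize_spike(sim["spike"], sim["rho"]))
    disp = estimate_dispersions(sim["target"], sf, sim["conditions"])
    fwd = nb_wald_test(sim["target"], sf, sim["conditions"], dispersions=disp)
    rev = nb_wald_test(sim["target"], sf, sim["conditions"], dispersions=disp,
                       reference="B")
    np.testing.assert_allclose(fwd["lfc_mle"], -rev["lfc_mle"], atol=1e-12)
    np.testing.assert_allclose(fwd["p"], rev["p"], atol=1e-12)


def test_run_calibrated_de_end_to_end_recovers_truth():
    genes_t = make_rna_genes(1000, seed=5, mean_baseline=300.0)
    genes_s = make_rna_genes(300, seed=6, mean_baseline=100.0, prefix="spk")
    true_lfc = np.zeros(1000)
    true_lfc[:100] = 2.0
    true_lfc[100:200] = -2.0
    de = pd.Series(true_lfc, index=genes_t["gene_id"])
    sim = simulate_rna_counts(genes_t, genes_s, SimTruth(de_table=de, seed=7))
    cm = CountMatrix(
        target=sim["target"], spike=sim["spike"],
        rho=sim["rho"], conditions=sim["conditions"],
    )
    res = run_calibrated_de(cm, gene_lengths_bp=genes_t.set_index("gene_id")["length_bp"],
                            fallback_rpkm_threshold=2.838)
    calls = res["sig_class"].to_numpy()
    # strong effects at decent baselines: the vast majority are recovered
    assert (calls[:100] == "up").mean() > 0.9
    assert (calls[100:200] == "down").mean() > 0.9
    assert (calls[200:] == "no_change").mean() > 0.9
    assert (res["padj"].dropna() >= res["p"].dropna()).all()


def test_count_matrix_validation():
    target = pd.DataFrame({"a": [1], "b": [2], "c": [3], "d": [4]})
    spike = target.copy()
    rho = pd.Series(0.1, index=list("abcd"))
    conds = pd.Series(["A", "A", "B", "B"], index=list("abcd"))
    CountMatrix(target, spike, rho, conds)  # valid
    with pytest.raises(ValueError, match="two conditions"):
        CountMatrix(target, spike, rho, pd.Series(["A"] * 4, index=list("abcd")))
    with pytest.raises(ValueError, match="rho"):
        CountMatrix(target, spike, rho * -1, conds)
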