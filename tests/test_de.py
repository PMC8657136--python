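"""Normalization, NB model fitting, QL testing and the selection rule."""

import numpy as np
import pandas as pd
import pytest

import dosegrade as dg
from dosegrade import de as de_mod
from dosegrade.synthetic import SimulationConfig

from conftest import tiny_design


# ---------------------------------------------------------------------------
# normalization / filtering
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("count,libsize,expected", [
    (10, 1e6, 10.0),
    (0, 1e6, 0.0),
    (19, 2e7, 0.95),
])
def test_cpm_values(count, libsize, expected):
    counts = pd.DataFrame({"s1": [count]}, index=["g1"])
    cpm = de_mod.compute_cpm(counts, pd.Series({"s1": libsize}))
    assert cpm.loc["g1", "s1"] == pytest.approx(expected)


def test_cpm_rejects_zero_library():
    counts = pd.DataFrame({"s1": [1]}, index=["g1"])
    with pytest.raises(ValueError):
        de_mod.compute_cpm(counts, pd.Series({"s1": 0.0}))


@pytest.mark.parametrize("count,libsize,length,expected", [
    (100, 1e6, 1000, 100.0),
    (100, 1e6, 500, 200.0),
    (0, 1e6, 1000, 0.0),
])
def test_rpkm_values(count, libsize, length, expected):
    counts = pd.DataFrame({"s1": [count]}, index=["g1"])
    rpkm = de_mod.compute_rpkm(counts, pd.Series({"g1": length}),
                               pd.Series({"s1": libsize}))
    assert rpkm.loc["g1", "s1"] == pytest.approx(expected)


def test_rpkm_drops_genes_without_length():
    counts = pd.DataFrame({"s1": [5, 5]}, index=["g1", "g2"])
    with pytest.warns(UserWarning):
        rpkm = de_mod.compute_rpkm(counts, pd.Series({"g1": 1000.0}),
                                   pd.Series({"s1": 1e6}))
    assert list(rpkm.index) == ["g1"]


def test_filter_boundary_inclusive():
    cpm = pd.DataFrame({
        "boundary": [0.95, 0.95, 0.95, 0.0, 0.0],
        "below": [0.94] * 5,
        "zero": [0.0] * 5,
    }).T
    cpm.columns = [f"s{i}" for i in range(5)]
    kept = de_mod.filter_genes(cpm, min_cpm=0.95, min_samples=3)
    assert list(kept) == ["boundary"]


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def test_saturated_fit_reproduces_condition_means():
    # equal library sizes: the NB cell MLE is the plain condition average
    rng = np.random.default_rng(0)
    design = tiny_design(("WT", "T58A", "T58I"), (0.0, 100.0, 1000.0), 3)
    counts = pd.DataFrame(rng.poisson(50, size=(10, len(design))),
                          index=[f"g{i}" for i in range(10)],
                          columns=design["sample_id"])
    ls = pd.Series(1e6, index=counts.columns)
    res = de_mod.fit_gene_models(counts, design, ls, dispersion=0.1)
    for (g, d) in res.fitted_cpm.columns:
        ids = design.loc[(design.genotype == g) & (design.dose == d), "sample_id"]
        expected = counts[ids].mean(axis=1) / 1e6 * 1e6
        np.testing.assert_allclose(res.fitted_cpm[(g, d)], expected, rtol=1e-6)


def test_shift_model_matches_statsmodels_glm():
    """The hand-rolled IRLS must agree with an independent NB GLM fit."""
    import statsmodels.api as sm

    rng = np.random.default_rng(3)
    design = tiny_design(("WT", "T58A"), (0.0, 100.0, 1000.0), 3)
    n = len(design)
    ls = np.exp(rng.uniform(np.log(8e5), np.log(1.2e6), n))
    mu = 40 * ls / ls.mean() * np.where(design["dose"] > 0, 2.0, 1.0)
    counts = rng.negative_binomial(1 / 0.1, (1 / 0.1) / (1 / 0.1 + mu),
                                   size=(5, n)).astype(float)

    doses = sorted(design["dose"].unique())
    X = np.zeros((n, len(doses) + 1))
    for j in range(n):
        X[j, doses.index(design["dose"][j])] = 1.0
        if design["genotype"][j] == "T58A":
            X[j, len(doses)] = 1.0
    dev, conv = de_mod.fit_shift_model(counts, np.log(ls), X, np.full(5, 0.1))
    assert conv.all()
    for g in range(5):
        glm = sm.GLM(counts[g], X, family=sm.families.NegativeBinomial(alpha=0.1),
                     offset=np.log(ls))
        fit = glm.fit()
        assert dev[g] == pytest.approx(fit.deviance, rel=1e-4)


def test_dispersion_poisson_limit():
    cfg = SimulationConfig(n_genes=400, frac_regulated=0.0,
                           dispersion_fixed=1e-9, rng_seed=3)
    data = dg.simulate(cfg, with_genome=False, with_sets=False)
    disp = dg.estimate_dispersion(data.counts, data.design)
    assert disp["genewise"].median() < 0.05
    assert disp["moderated"].median() < 0.05
    assert (disp["moderated"] >= 0).all()


def test_dispersion_recovery_at_point_four():
    cfg = SimulationConfig(n_genes=2000, frac_regulated=0.0,
                           dispersion_fixed=0.4, rng_seed=8)
    data = dg.simulate(cfg, with_genome=False, with_sets=False)
    disp = dg.estimate_dispersion(data.counts, data.design)
    assert 0.2 <= disp["genewise"].median() <= 0.6
    assert 0.2 <= disp["moderated"].median() <= 0.6


def test_dispersion_single_replicate_raises():
    design = tiny_design(("WT",), (0.0, 1000.0), 1)
    counts = pd.DataFrame(np.ones((5, len(design))), columns=design["sample_id"])
    with pytest.raises(ValueError, match="common"):
        dg.estimate_dispersion(counts, design)


def test_null_p_calibration_and_deviance_scale():
    """On null data the WT dose test is calibrated at the 5% level and the
    6-df deviance drop is of chi-square order."""
    cfg = SimulationConfig(n_genes=1000, frac_regulated=0.0, rng_seed=21)
    data = dg.simulate(cfg, with_genome=False, with_sets=False)
    res = dg.run_de(data.counts, data.design)
    p = res.results["p_wt"].dropna()
    assert 0.03 <= (p < 0.05).mean() <= 0.07
    assert 5.0 <= res.results["delta_dev_wt"].mean() <= 10.0


def test_null_fdp_over_repeated_runs():
    """BH at q<0.01 almost never rejects on all-null data."""
    fdps = []
    for seed in range(20):
        cfg = SimulationConfig(n_genes=500, frac_regulated=0.0, rng_seed=1000 + seed)
        data = dg.simulate(cfg, with_genome=False, with_sets=False)
        res = dg.run_de(data.counts, data.design)
        r = res.results
        rejected = int((r[["q_wt", "q_t58a", "q_t58i"]] < 0.01).any(axis=1).sum())
        fdps.append(1.0 if rejected else 0.0)
    assert np.mean(fdps) <= 0.05


def test_mutant_only_response_detected():
    """Genes flat in WT but responsive in one mutant get small mutant-family
    p-values and large WT p-values."""
    cfg = SimulationConfig(n_genes=250, frac_regulated=0.25,
                           frac_mutant_differential=0.25, frac_mutant_only=1.0,
                           mutant_amplitude_boost=1.0,
                           amplitude_range=(2.0, 2.0), dispersion_fixed=0.05,
                           baseline_log_mean_range=(5.0, 7.5),
                           rng_seed=12)
    data = dg.simulate(cfg, with_genome=False, with_sets=False)
    res = dg.run_de(data.counts, data.design)
    r = res.results
    truth = data.truth.set_index("gene_id").loc[r.index]
    t58a_only = truth["diff_t58a"] & ~truth["diff_t58i"]
    assert t58a_only.sum() >= 10
    assert (r.loc[t58a_only, "q_t58a"] < 0.01).all()
    assert r.loc[t58a_only, "p_wt"].median() > 0.1


def test_selection_rule_boundaries():
    res = pd.DataFrame({
        "q_wt": [0.005, 0.005, 0.02],
        "maxlfc_wt": [1.0, np.log2(1.9), np.log2(10)],
        "q_t58a": [1.0] * 3, "maxlfc_t58a": [0.0] * 3,
        "q_t58i": [1.0] * 3, "maxlfc_t58i": [0.0] * 3,
    }, index=["exactly_twofold", "below_fold", "above_q"])
    result = de_mod.DEResult(res, pd.DataFrame(), res.index, 1.0, 1.0, [])
    flags = de_mod.select_models(result, q_max=0.01, min_fold=2.0)
    assert flags.loc["exactly_twofold", "regulated_wt"]  # 2-fold inclusive
    assert not flags.loc["below_fold", "regulated_wt"]
    assert not flags.loc["above_q", "regulated_wt"]


def test_selection_invariant_to_orderings():
    cfg = SimulationConfig(n_genes=150, rng_seed=17)
    data = dg.simulate(cfg, with_genome=False, with_sets=False)
    rng = np.random.default_rng(2)
    res1 = dg.run_de(data.counts, data.design)
    gperm = rng.permutation(data.counts.index)
    sperm = rng.permutation(data.counts.columns)
    res2 = dg.run_de(data.counts.loc[gperm, sperm],
                     data.design.sample(frac=1, random_state=1))
    f1 = res1.results[["regulated_wt", "diff_t58a", "diff_t58i"]].sort_index()
    f2 = res2.results[["regulated_wt", "diff_t58a", "diff_t58i"]].sort_index()
    pd.testing.assert_frame_equal(f1, f2)
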