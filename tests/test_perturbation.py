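import numpy as np
import numpy.testing as npt
import pytest
from scipy.stats import kstest

from omnifisher.km_score import OmicsBlock, km_test
from omnifisher.null_model import Phenotype, fit_null
from omnifisher.perturbation import (PerturbConfig, combine_all_models,
                                     estimate_cov, model_subsets, optimal_test,
                                     perturb_layer_pvalues, run_gene)


def km_layers(rng, n=80, layers=("G", "M", "E"), family="gaussian",
              same_matrix=False, ids=None):
    """Null-data KM results on shared subjects (one shared null fit)."""
    ids = np.arange(n) if ids is None else ids
    y = (rng.standard_normal(n) if family == "gaussian"
         else (rng.uniform(size=n) < 0.5).astype(float))
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    fit = fit_null(Phenotype(y, "gaussian" if family == "gaussian" else "binomial",
                             ids), X)
    base = rng.standard_normal((n, 4))
    out = {}
    for layer in layers:
        mat = base if same_matrix else rng.standard_normal((n, 4))
        if layer == "G":
            mat = np.clip(np.round(np.abs(mat)), 0, 2)
        out[layer] = km_test(fit, OmicsBlock(mat, layer, ids))
    return out


class TestDraws:
    def test_zero_b_returns_only_observed(self, rng):
        km = km_layers(rng)
        draws = perturb_layer_pvalues(km, 0, rng)
        assert draws.B == 0 and draws.p_perturbed.shape == (0, 3)
        assert np.all((draws.p_observed > 0) & (draws.p_observed <= 1))

    def test_identical_layers_share_draws_exactly(self, rng):
        km = km_layers(rng, layers=("M", "E"), same_matrix=True)
        draws = perturb_layer_pvalues(km, 50, np.random.default_rng(5))
        npt.assert_allclose(draws.p_perturbed[:, 0], draws.p_perturbed[:, 1],
                            rtol=1e-10)

    def test_single_layer_null_draws_are_uniform(self, rng):
        km = km_layers(rng, layers=("M",))
        draws = perturb_layer_pvalues(km, 2000, np.random.default_rng(11))
        assert kstest(draws.p_perturbed[:, 0], "uniform").pvalue > 0.01

    def test_deterministic_under_seed(self, rng):
        km = km_layers(rng)
        d1 = perturb_layer_pvalues(km, 100, np.random.default_rng(3))
        d2 = perturb_layer_pvalues(km, 100, np.random.default_rng(3))
        npt.assert_array_equal(d1.p_perturbed, d2.p_perturbed)

    def test_layer_processing_order_is_irrelevant(self, rng):
        km = km_layers(rng)
        km_rev = {k: km[k] for k in reversed(list(km))}
        d1 = perturb_layer_pvalues(km, 64, np.random.default_rng(9))
        d2 = perturb_layer_pvalues(km_rev, 64, np.random.default_rng(9))
        assert d1.layers == d2.layers
        npt.assert_array_equal(d1.p_perturbed, d2.p_perturbed)

    def test_negative_b_rejected(self, rng):
        with pytest.raises(ValueError):
            perturb_layer_pvalues(km_layers(rng), -1, rng)

    def test_binomial_draws_uniform(self, rng):
        km = km_layers(rng, n=120, layers=("G",), family="binomial")
        draws = perturb_layer_pvalues(km, 3000, np.random.default_rng(22))
        assert kstest(draws.p_perturbed[:, 0], "uniform").pvalue > 0.01


class TestCovariance:
    def test_duplicated_layer_has_unit_correlation(self, rng):
        km = km_layers(rng, layers=("G", "M"), same_matrix=False)
        km["M"] = km_test(km["G"].null_fit, OmicsBlock(
            km["G"].block.matrix, "M", km["G"].subject_ids))
        draws = perturb_layer_pvalues(km, 500, np.random.default_rng(2))
        cov = estimate_cov(draws)
        corr = cov.loc["G", "M"] / np.sqrt(cov.loc["G", "G"] * cov.loc["M", "M"])
        assert corr == pytest.approx(1.0, abs=1e-10)

    def test_diagonal_near_four_at_large_b(self, rng):
        km = km_layers(rng, n=60)
        draws = perturb_layer_pvalues(km, 5000, np.random.default_rng(4))
        cov = estimate_cov(draws)
        for layer in cov.index:
            assert cov.loc[layer, layer] == pytest.approx(4.0, rel=0.10)

    def test_independent_layers_covariance_vanishes(self, rng):
        # disjoint subject sets -> layers are genuinely independent
        n = 60
        ids1, ids2 = np.arange(n), np.arange(n, 2 * n)
        km1 = km_layers(rng, n=n, layers=("G",), ids=ids1)
        km2 = km_layers(rng, n=n, layers=("M",), ids=ids2)
        km = {"G": km1["G"], "M": km2["M"]}
        draws = perturb_layer_pvalues(km, 5000, np.random.default_rng(6))
        cov = estimate_cov(draws)
        assert abs(cov.loc["G", "M"]) < 0.5


class TestModelsAndOptimal:
    def test_model_subsets_enumerates_seven(self):
        models = model_subsets(("G", "M", "E"))
        assert len(models) == 7
        assert ("G",) in models and ("G", "M", "E") in models
        assert len(model_subsets(("G", "M"))) == 3
        assert model_subsets(("E",)) == [("E",)]

    def test_combined_models_match_direct_combination(self, rng):
        km = km_layers(rng)
        draws = perturb_layer_pvalues(km, 200, np.random.default_rng(8))
        cov = estimate_cov(draws)
        models = combine_all_models(draws, cov)
        from omnifisher.fisher_combine import omnibus_fisher_combine
        stacked = draws.stacked()
        trip = omnibus_fisher_combine(stacked[0], cov.to_numpy())
        assert models[("G", "M", "E")][0] == pytest.approx(trip, rel=1e-12)

    def test_all_observed_pvalues_one_gives_optimal_one(self, rng):
        # zero residual -> Q = 0 -> all p = 1 -> every perturbed min <= 1
        n = 40
        y = np.full(n, 2.5)
        y[0] = 2.5  # constant trait, perfect intercept fit
        fit = fit_null(Phenotype(y, "gaussian", np.arange(n)))
        km = {"M": km_test(fit, OmicsBlock(rng.standard_normal((n, 3)), "M",
                                           np.arange(n)))}
        cfg = PerturbConfig(B_stage_schedule=(200,))
        p, B = optimal_test(km, cfg, np.random.default_rng(1))
        assert p == 1.0 and B == 200

    def test_single_layer_optimal_tracks_layer_pvalue(self, rng):
        n = 150
        y = rng.standard_normal(n)
        d = rng.standard_normal((n, 1))
        y = y + 0.35 * d[:, 0]          # mild signal
        fit = fit_null(Phenotype(y, "gaussian", np.arange(n)))
        km = {"E": km_test(fit, OmicsBlock(d, "E", np.arange(n)))}
        cfg = PerturbConfig(B_stage_schedule=(4000,))
        p_opt, _ = optimal_test(km, cfg, np.random.default_rng(12))
        p_obs = km["E"].p_value
        se = np.sqrt(p_obs * (1 - p_obs) / 4000)
        assert abs(p_opt - p_obs) < 4 * se + 2.0 / 4000

    def test_identical_layers_optimal_tracks_single_layer(self, rng):
        # three copies of the same block carry the same information
        n = 150
        y = rng.standard_normal(n)
        base = np.clip(np.round(np.abs(rng.standard_normal((n, 4)))), 0, 2)
        y = y + 0.25 * base[:, 0]
        ids = np.arange(n)
        fit = fit_null(Phenotype(y, "gaussian", ids))
        km3 = {l: km_test(fit, OmicsBlock(base, l, ids)) for l in ("G", "M", "E")}
        km1 = {"G": km_test(fit, OmicsBlock(base, "G", ids))}
        cfg = PerturbConfig(B_stage_schedule=(4000,))
        p3, _ = optimal_test(km3, cfg, np.random.default_rng(3))
        p1, _ = optimal_test(km1, cfg, np.random.default_rng(3))
        se = np.sqrt(max(p1, 1e-3) * (1 - min(p1, 0.999)) / 4000)
        assert abs(p3 - p1) < 5 * se + 2.0 / 4000

    def test_final_p_bounded_by_guard(self, rng):
        km = km_layers(rng)
        cfg = PerturbConfig(B_stage_schedule=(100,), escalation_threshold=0.0)
        p, B = optimal_test(km, cfg, np.random.default_rng(7))
        assert 1.0 / (B + 1) <= p <= 1.0

    def test_escalation_spends_more_draws_on_small_p(self, rng):
        n = 200
        d = rng.standard_normal((n, 1))
        y = 0.8 * d[:, 0] + rng.standard_normal(n)   # strong signal
        fit = fit_null(Phenotype(y, "gaussian", np.arange(n)))
        km = {"E": km_test(fit, OmicsBlock(d, "E", np.arange(n)))}
        cfg = PerturbConfig(B_stage_schedule=(500, 5000))
        p, B = optimal_test(km, cfg, np.random.default_rng(2))
        assert B == 5000 and p < 0.05


class TestRunGene:
    def make_inputs(self, rng, n=120, causal=False):
        ids = np.arange(n)
        G = np.clip(np.round(np.abs(rng.standard_normal((n, 6)))), 0, 2)
        M = rng.standard_normal((n, 4))
        E = rng.standard_normal((n, 1))
        y = rng.standard_normal(n)
        if causal:
            y = y + G[:, :2].sum(axis=1) * 0.4
        blocks = {"G": OmicsBlock(G, "G", ids), "M": OmicsBlock(M, "M", ids),
                  "E": OmicsBlock(E, "E", ids)}
        pheno = Phenotype(y, "gaussian", ids)
        return pheno, blocks

    def test_bit_identical_under_seed(self, rng):
        pheno, blocks = self.make_inputs(rng)
        cfg = PerturbConfig(B_cov=100, B_stage_schedule=(300,))
        r1 = run_gene(pheno, blocks, config=cfg, rng=np.random.default_rng(5))
        r2 = run_gene(pheno, blocks, config=cfg, rng=np.random.default_rng(5))
        assert r1.p_omnibus == r2.p_omnibus
        assert r1.p_optimal == r2.p_optimal
        npt.assert_array_equal(r1.cov_hat.to_numpy(), r2.cov_hat.to_numpy())

    def test_omnibus_consistent_with_direct_combination(self, rng):
        from omnifisher.fisher_combine import omnibus_fisher_combine
        pheno, blocks = self.make_inputs(rng)
        cfg = PerturbConfig(B_cov=150, B_stage_schedule=(300,))
        res = run_gene(pheno, blocks, config=cfg, rng=np.random.default_rng(5))
        direct = omnibus_fisher_combine(
            [res.p_layer[l] for l in res.layers], res.cov_hat.to_numpy())
        assert res.p_omnibus == pytest.approx(direct, rel=1e-12)

    def test_partial_layer_overlap_allowed(self, rng):
        pheno, blocks = self.make_inputs(rng, n=100)
        # M observed on half the subjects only
        m = blocks["M"]
        blocks["M"] = OmicsBlock(m.matrix[:50], "M", m.subject_ids[:50])
        cfg = PerturbConfig(B_cov=100, B_stage_schedule=(200,))
        res = run_gene(pheno, blocks, config=cfg, rng=np.random.default_rng(1))
        assert set(res.layers) == {"G", "M", "E"}
        assert 0 < res.p_omnibus <= 1 and 0 < res.p_optimal <= 1

    def test_two_layer_input_reduces_model_set(self, rng):
        pheno, blocks = self.make_inputs(rng)
        del blocks["E"]
        cfg = PerturbConfig(B_cov=100, B_stage_schedule=(200,))
        res = run_gene(pheno, blocks, config=cfg, rng=np.random.default_rng(1))
        assert set(res.p_model) == {"GM"}
        assert res.p_omnibus == res.p_model["GM"]

    def test_causal_gene_detected(self, rng):
        pheno, blocks = self.make_inputs(rng, causal=True)
        cfg = PerturbConfig(B_cov=150, B_stage_schedule=(500,))
        res = run_gene(pheno, blocks, config=cfg, rng=np.random.default_rng(2))
        assert res.p_layer["G"] < 0.01
        assert res.p_omnibus < 0.05
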