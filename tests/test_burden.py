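"""Rare-variant burden machinery: beta weights, null model, SKAT statistic,
weighted chi-square tails, SKAT-O, carrier enrichment and cohort subsetting."""

import numpy as np
import pytest
from scipy.stats import chi2

from chdprio import burden as bd
from chdprio.errors import ConfigError, DataError
from chdprio.synthetic_data import (
    CohortSimSpec,
    plant_exact_carriers,
    simulate_cohort,
)


class TestBetaWeights:
    def test_maf_zero_gives_density_maximum(self):
        # beta(1,25) density at 0 is b*(1-0)^(b-1) = 25
        w = bd.beta_weights(np.array([0.0]))
        assert w[0] == pytest.approx(25.0)

    def test_strictly_decreasing_in_maf(self):
        mafs = np.linspace(0.0, 0.5, 50)
        w = bd.beta_weights(mafs)
        assert np.all(np.diff(w) < 0)

    def test_uniform_spec_gives_unit_weights(self):
        w = bd.beta_weights(np.array([0.1, 0.3, 0.5]),
                            bd.WeightSpec(beta_a=1, beta_b=1))
        assert np.allclose(w, 1.0)

    def test_out_of_range_maf_errors(self):
        with pytest.raises(DataError):
            bd.beta_weights(np.array([-0.1]))


class TestNullModel:
    def test_balanced_intercept_only(self):
        y = np.r_[np.ones(500), np.zeros(500)]
        null = bd.null_model(y)
        assert np.allclose(null.fitted, 0.5)

    def test_cohort_proportions(self):
        y = np.r_[np.ones(130), np.zeros(861)]
        null = bd.null_model(y)
        assert np.allclose(null.fitted, 130 / 991)
        assert null.residuals.sum() == pytest.approx(0.0, abs=1e-9)

    def test_constant_phenotype_errors(self):
        with pytest.raises(DataError):
            bd.null_model(np.ones(10))

    def test_covariate_fit_reproduces_marginal_rate(self):
        rng = np.random.default_rng(0)
        y = (rng.random(300) < 0.3).astype(float)
        x = rng.normal(size=(300, 1))
        null = bd.null_model(y, covariates=x)
        assert null.fitted.mean() == pytest.approx(y.mean(), abs=1e-6)


class TestSkatStatistic:
    def test_zero_residuals_give_zero(self):
        null = bd.NullModel(fitted=np.full(10, 0.5),
                            residuals=np.zeros(10),
                            design=np.ones((10, 1)),
                            phenotype=np.zeros(10, int))
        G = np.ones((10, 3))
        assert bd.skat_statistic(G, np.ones(3, bool), np.ones(3), null) == 0.0

    def test_single_variant_reduces_to_weighted_score_squared(self):
        rng = np.random.default_rng(1)
        y = (rng.random(40) < 0.5).astype(int)
        null = bd.null_model(y)
        g = rng.binomial(2, 0.2, (40, 1)).astype(float)
        w = np.array([1.7])
        q = bd.skat_statistic(g, np.ones(1, bool), w, null)
        assert q == pytest.approx((1.7 * (g[:, 0] @ null.residuals)) ** 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 50, 10
        G = rng.binomial(2, rng.uniform(0.05, 0.3, m), (n, m)).astype(float)
        y = (rng.random(n) < 0.4).astype(int)
        w = rng.uniform(0.2, 3.0, m)
        null = bd.null_model(y)
        q = bd.skat_statistic(G, np.ones(m, bool), w, null)
        r = null.residuals
        oracle = 0.0
        for j in range(m):
            s = 0.0
            for i in range(n):
                s += G[i, j] * r[i]
            oracle += (w[j] * s) ** 2
        assert q == pytest.approx(oracle, abs=1e-10 * max(1.0, oracle))

    def test_empty_mask_errors(self):
        null = bd.null_model(np.r_[np.ones(5), np.zeros(5)])
        with pytest.raises(DataError, match="qualifying"):
            bd.skat_statistic(np.ones((10, 2)), np.zeros(2, bool),
                              np.ones(2), null)

    def test_missing_dosages_mean_imputed(self):
        G = np.array([[0.0], [2.0], [np.nan], [np.nan]])
        assert np.allclose(bd.impute_missing(G)[:, 0], [0, 2, 1, 1])


class TestQuadformPvalue:
    def test_single_eigenvalue_exact_chi2(self):
        for q, lam in [(0.5, 2.0), (3.2, 0.7), (10.0, 1.0)]:
            assert bd.quadform_pvalue(q, np.array([lam])) == pytest.approx(
                chi2.sf(q / lam, df=1), abs=1e-12)

    def test_equal_eigenvalues_exact_chi2_k(self):
        lam = np.full(6, 0.8)
        for q in (1.0, 4.8, 12.0):
            assert bd.quadform_pvalue(q, lam) == pytest.approx(
                chi2.sf(q / 0.8, df=6), abs=1e-12)

    def test_random_mixture_within_monte_carlo_error(self):
        rng = np.random.default_rng(9)
        lam = rng.uniform(0.1, 2.5, 8)
        q = float(lam.sum())
        p = bd.quadform_pvalue(q, lam)
        n_mc = 10 ** 6
        p_mc = bd.quadform_pvalue(q, lam, method="mc", n_mc=n_mc,
                                  rng=np.random.default_rng(10))
        se = np.sqrt(p_mc * (1 - p_mc) / n_mc)
        assert abs(p - p_mc) <= 3 * se

    def test_negative_statistic_errors(self):
        with pytest.raises(DataError):
            bd.quadform_pvalue(-1.0, np.array([1.0]))

    def test_all_zero_eigenvalues_error(self):
        with pytest.raises(DataError):
            bd.quadform_pvalue(1.0, np.zeros(3))


class TestSkatO:
    def test_single_variant_p_is_score_test_for_every_rho(self):
        rng = np.random.default_rng(2)
        n = 200
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
        g = rng.binomial(2, 0.1, (n, 1)).astype(float)
        null = bd.null_model(y)
        res = bd.skat_o(g, np.ones(1, bool), np.ones(1), null)
        B = bd._projected_gram(bd.impute_missing(g), np.ones(1), null)
        expected = chi2.sf(res["q_skat"] / B[0, 0], df=1)
        assert res["p_value"] == pytest.approx(expected, rel=1e-9)
        # Q(rho) is rho-invariant for one variant
        assert res["q_skat"] == pytest.approx(res["q_burden"])

    def test_rho_grid_must_span_zero_to_one(self):
        null = bd.null_model(np.r_[np.ones(10), np.zeros(10)])
        g = np.ones((20, 2))
        with pytest.raises(ConfigError):
            bd.skat_o(g, np.ones(2, bool), np.ones(2), null,
                      rho_grid=[0.0, 0.5])

    def test_permutation_invariance_under_relabeling(self):
        rng = np.random.default_rng(4)
        n, m = 120, 6
        G = rng.binomial(2, 0.1, (n, m)).astype(float)
        y = (rng.random(n) < 0.5).astype(int)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        perm = rng.permutation(n)
        res1 = bd.skat_o(G, np.ones(m, bool), np.ones(m), bd.null_model(y))
        res2 = bd.skat_o(G[perm], np.ones(m, bool), np.ones(m),
                         bd.null_model(y[perm]))
        assert res1["p_value"] == pytest.approx(res2["p_value"], rel=1e-9)
        assert res1["q_skat"] == pytest.approx(res2["q_skat"], rel=1e-9)

    def test_analytic_p_close_to_permutation_p(self):
        rng = np.random.default_rng(6)
        n, m = 80, 4
        G = rng.binomial(2, 0.15, (n, m)).astype(float)
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
        null = bd.null_model(y)
        res = bd.skat_o(G, np.ones(m, bool), np.ones(m), null,
                        n_permutations=20000, rng=np.random.default_rng(7))
        assert abs(res["p_value"] - res["p_permutation"]) <= 0.02


class TestCarrierEnrichment:
    def test_worked_example_case_frequency(self):
        ds = plant_exact_carriers(130, 861, 13, 29)
        enr = bd.carrier_enrichment(ds, np.ones(1, bool))
        assert enr["freq_cases"] == pytest.approx(0.10)
        assert round(enr["freq_controls"] * 100, 1) == 3.4

    def test_fold_enrichment_rounds_to_three(self):
        # computed case frequency against the reported control frequency
        fold = 0.10 / 0.034
        assert round(fold) == 3

    def test_zero_carriers_reports_null_fold(self):
        ds = plant_exact_carriers(50, 50, 0, 0)
        enr = bd.carrier_enrichment(ds, np.ones(1, bool))
        assert enr["freq_cases"] == 0.0 and enr["fold"] is None


class TestSubsettingAndThreshold:
    def test_ancestry_threshold_is_strict(self):
        # case fractions 0.85 / 0.80 / 0.79: only the first strictly exceeds
        ds = plant_exact_carriers(3, 3, 0, 0)
        ds.ancestry_fraction = np.array([0.85, 0.80, 0.79, 0.9, 0.9, 0.9])
        sub = bd.ancestry_subset(ds, 0.80)
        assert int((sub.phenotype == 1).sum()) == 1
        assert sub.n_samples == 4

    def test_all_above_threshold_is_identity(self):
        ds = plant_exact_carriers(5, 5, 1, 1)
        sub = bd.ancestry_subset(ds, 0.80)
        assert sub.n_samples == 10

    def test_missing_ancestry_errors(self):
        ds = plant_exact_carriers(5, 5, 1, 1)
        ds.ancestry_fraction = None
        with pytest.raises(DataError):
            bd.ancestry_subset(ds, 0.80)

    @pytest.mark.parametrize("alpha,n,expected", [
        (0.05, 2, 0.025), (0.05, 1, 0.05), (0.05, 10, 0.005)])
    def test_bonferroni(self, alpha, n, expected):
        assert bd.bonferroni_threshold(alpha, n) == pytest.approx(expected)

    def test_bonferroni_zero_tests_errors(self):
        with pytest.raises(ConfigError):
            bd.bonferroni_threshold(0.05, 0)


class TestRunBurden:
    def test_gene_without_qualifying_variants_gets_nan_row(self):
        ds, _truth = simulate_cohort(CohortSimSpec(
            n_cases=60, n_controls=60, n_genes=2, variants_per_gene=5,
            maf_range=(0.02, 0.05), seed=3))  # too common for the MAF rule
        res = bd.run_burden(ds, ["G0001"])
        assert res[0].n_variants == 0 and np.isnan(res[0].p_value)

    def test_per_gene_results_produced(self):
        ds, _truth = simulate_cohort(CohortSimSpec(
            n_cases=100, n_controls=100, n_genes=2, variants_per_gene=8,
            maf_range=(0.002, 0.009), seed=3))
        res = bd.run_burden(ds, ["G0001", "G0002"],
                            rng=np.random.default_rng(0))
        assert len(res) == 2
        for r in res:
            assert r.n_variants == 8
            assert 0.0 <= r.p_value <= 1.0

    def test_empty_gene_list_errors(self):
        ds, _ = simulate_cohort(CohortSimSpec(
            n_cases=30, n_controls=30, n_genes=1, variants_per_gene=2,
            carrier_log_odds=(0.0,), seed=1))
        with pytest.raises(ConfigError):
            bd.run_burden(ds, [])
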