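"""MR estimators: exact examples, oracle equivalence, dispatch, p-value sanity."""

import numpy as np
import pytest

from pqtlmr.mr import egger, ivw, mode_estimate, run_mr, wald_ratio, weighted_median

from conftest import make_hset


class TestWaldRatio:
    def test_arithmetic(self):
        hs = make_hset([0.5], [0.05], [0.1], [0.02])
        res = wald_ratio(hs)
        assert res.estimate == pytest.approx(0.2)
        assert res.se == pytest.approx(0.04)

    def test_zero_outcome_beta(self):
        res = wald_ratio(make_hset([0.5], [0.05], [0.0], [0.02]))
        assert res.estimate == 0.0
        assert res.pval == 1.0

    def test_negative_ratio(self):
        # orientation convention keeps beta_exp positive; a negative
        # outcome effect gives a negative causal estimate
        res = wald_ratio(make_hset([0.2], [0.02], [-0.1], [0.05]))
        assert res.estimate == pytest.approx(-0.5)
        assert res.se == pytest.approx(0.25)


class TestIvw:
    def test_identical_ratios_degenerate(self):
        hs = make_hset([0.5, 0.4], [0.05, 0.05], [0.1, 0.08], [0.02, 0.02])
        res = ivw(hs)
        assert res.estimate == pytest.approx(0.2)
        assert res.Q == pytest.approx(0.0, abs=1e-20)

    def test_single_snp_contract_error(self):
        with pytest.raises(ValueError):
            ivw(make_hset([0.5], [0.05], [0.1], [0.02]))

    def test_equals_wls_oracle(self, rng):
        """IVW must equal no-intercept WLS of beta_out on beta_exp, weights 1/se_out^2."""
        import statsmodels.api as sm

        for _ in range(20):
            k = int(rng.integers(3, 12))
            be = rng.uniform(0.05, 0.5, k)
            bo = 0.3 * be + rng.normal(0, 0.02, k)
            so = rng.uniform(0.01, 0.05, k)
            hs = make_hset(be, np.full(k, 0.02), bo, so)
            res = ivw(hs)
            fit = sm.WLS(bo, be, weights=1.0 / so**2).fit()
            assert res.estimate == pytest.approx(fit.params[0], abs=1e-10)
            se_fixed = float(fit.bse[0]) / np.sqrt(fit.scale)
            # multiplicative floor: se = se_fixed * max(1, sqrt(Q/(k-1)))
            Q = float(np.sum((1.0 / so**2) * (bo - fit.params[0] * be) ** 2))
            assert res.Q == pytest.approx(Q, abs=1e-10)
            assert res.se == pytest.approx(se_fixed * max(1.0, np.sqrt(Q / (k - 1))), abs=1e-10)

    def test_simulation_recovers_true_effect(self, rng):
        k, theta = 5, 0.3
        be = rng.uniform(0.1, 0.4, k)
        so = np.full(k, 0.01)
        bo = theta * be + rng.normal(0, 0.01, k)
        res = ivw(make_hset(be, np.full(k, 0.005), bo, so))
        assert abs(res.estimate - theta) < 3 * res.se


class TestEgger:
    def test_exact_fit_through_origin(self):
        be = np.array([0.1, 0.2, 0.3, 0.4])
        hs = make_hset(be, [0.01] * 4, 0.4 * be, [0.02] * 4)
        res = egger(hs)
        assert res.estimate == pytest.approx(0.4, abs=1e-12)
        assert res.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_fit_with_intercept(self):
        be = np.array([0.1, 0.2, 0.3, 0.4])
        hs = make_hset(be, [0.01] * 4, 0.4 * be + 0.05, [0.02] * 4)
        res = egger(hs)
        assert res.estimate == pytest.approx(0.4, abs=1e-12)
        assert res.egger_intercept == pytest.approx(0.05, abs=1e-12)

    def test_contract_needs_three(self):
        with pytest.raises(ValueError):
            egger(make_hset([0.1, 0.2], [0.01] * 2, [0.1, 0.2], [0.02] * 2))

    def test_equals_wls_oracle(self, rng):
        import statsmodels.api as sm

        for _ in range(20):
            k = int(rng.integers(4, 15))
            be = rng.uniform(0.05, 0.5, k)
            bo = 0.2 * be + 0.03 + rng.normal(0, 0.02, k)
            so = rng.uniform(0.01, 0.05, k)
            res = egger(make_hset(be, np.full(k, 0.02), bo, so))
            X = sm.add_constant(be)
            fit = sm.WLS(bo, X, weights=1.0 / so**2).fit()
            assert res.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)
            assert res.estimate == pytest.approx(fit.params[1], abs=1e-10)
            scale = max(1.0, np.sqrt(fit.scale))
            assert res.se == pytest.approx(float(fit.bse[1]) / np.sqrt(fit.scale) * scale, abs=1e-10)

    def test_directional_pleiotropy_intercept_recovery(self, rng):
        import statsmodels.api as sm

        k, theta, delta = 50, 0.3, 0.03
        be = rng.uniform(0.1, 0.5, k)
        so = np.full(k, 0.02)
        bo = theta * be + delta + rng.normal(0, so)
        res = egger(make_hset(be, np.full(k, 0.01), bo, so))
        fit = sm.WLS(bo, sm.add_constant(be), weights=1.0 / so**2).fit()
        intercept_se = float(fit.bse[0]) / np.sqrt(fit.scale) * max(1.0, np.sqrt(fit.scale))
        assert abs(res.egger_intercept - delta) < 3 * intercept_se


class TestWeightedMedian:
    def test_symmetric_median(self):
        hs = make_hset([1.0, 1.0, 1.0], [0.01] * 3, [0.1, 0.2, 0.3], [0.05] * 3)
        res = weighted_median(hs, n_boot=50)
        assert res.estimate == pytest.approx(0.2)

    def test_dominant_weight_limit(self):
        # one SNP holds ~99% of weight: estimate approaches its ratio 0.7
        be = np.array([1.0, 0.05, 0.05])
        bo = np.array([0.7, 0.005, 0.01])
        res = weighted_median(make_hset(be, [0.01] * 3, bo, [0.05] * 3), n_boot=50)
        assert res.estimate == pytest.approx(0.7, abs=0.05)

    def test_contract_needs_three(self):
        with pytest.raises(ValueError):
            weighted_median(make_hset([1.0, 1.0], [0.01] * 2, [0.1, 0.3], [0.05] * 2))

    def test_bootstrap_se_deterministic(self, random_hset):
        r1 = weighted_median(random_hset, n_boot=200, seed=7)
        r2 = weighted_median(random_hset, n_boot=200, seed=7)
        assert r1.se == r2.se


class TestMode:
    def test_point_mass(self):
        hs = make_hset([1.0] * 3, [0.01] * 3, [0.25] * 3, [0.05] * 3)
        res = mode_estimate(hs, n_boot=50)
        assert res.estimate == pytest.approx(0.25)

    def test_majority_cluster_wins(self):
        be = np.ones(4)
        bo = np.array([0.2, 0.2, 0.2, 0.9])
        res = mode_estimate(make_hset(be, [0.01] * 4, bo, [0.05] * 4), n_boot=50)
        # within grid resolution of the cluster at 0.2
        assert abs(res.estimate - 0.2) < (0.9 - 0.2) / 511 + 0.02

    def test_weighted_mode_dominant_snp(self):
        be = np.array([1.0, 0.05, 0.05, 0.05])
        bo = np.array([0.5, 0.04, 0.045, 0.005])
        res = mode_estimate(make_hset(be, [0.01] * 4, bo, [0.05] * 4), weighted=True, n_boot=50)
        assert res.estimate == pytest.approx(0.5, abs=0.05)


class TestDispatch:
    def _hs(self, k):
        rng = np.random.default_rng(k)
        be = rng.uniform(0.1, 0.5, k)
        return make_hset(be, np.full(k, 0.02), 0.3 * be, np.full(k, 0.02))

    @pytest.mark.parametrize("k,methods", [
        (1, ["wald"]),
        (2, ["ivw"]),
        (4, ["ivw"]),
        (5, ["ivw"]),
        (6, ["ivw", "egger", "weighted_median", "simple_mode", "weighted_mode"]),
        (8, ["ivw", "egger", "weighted_median", "simple_mode", "weighted_mode"]),
    ])
    def test_nsnp_conditional_methods(self, k, methods):
        results = run_mr(self._hs(k), n_boot=50)
        assert [r.method for r in results] == methods

    def test_q_reported_only_for_multi_snp(self):
        assert run_mr(self._hs(1))[0].Q is None
        assert run_mr(self._hs(3))[0].Q is not None

    def test_empty_set_hard_error(self):
        from pqtlmr.harmonise import HarmonisedSet

        with pytest.raises(ValueError):
            run_mr(HarmonisedSet(protein_id="P", outcome_label="o"))

    def test_all_pvalues_two_sided_in_unit_interval(self):
        for res in run_mr(self._hs(7), n_boot=50):
            assert 0.0 < res.pval <= 1.0


def test_ivw_reduces_to_wald_without_floor():
    """Two identical records: IVW estimate equals the Wald ratio and Q = 0."""
    hs2 = make_hset([0.4, 0.4], [0.02, 0.02], [0.12, 0.12], [0.03, 0.03])
    hs1 = make_hset([0.4], [0.02], [0.12], [0.03])
    res2, res1 = ivw(hs2), wald_ratio(hs1)
    assert res2.estimate == pytest.approx(res1.estimate, abs=1e-14)
    # with Q = 0 the random-effects floor is inactive; the meta-analysis
    # of two identical instruments halves the variance
    assert res2.se == pytest.approx(res1.se / np.sqrt(2), abs=1e-14)
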