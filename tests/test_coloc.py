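"""Wakefield ABF colocalisation and SuSiE fine-mapping."""

import numpy as np
import pytest
from scipy import integrate, stats

from pqtlmr.coloc import (
    RegionStats,
    coloc_abf,
    coloc_susie,
    evidence_call,
    log_abf,
    susie_rss,
)
from pqtlmr.ld import LDMatrix


def quadrature_log_abf(beta, se, prior_sd):
    """Numerical-integration oracle for the marginal likelihood ratio."""
    num, _ = integrate.quad(
        lambda b: stats.norm.pdf(beta, b, se) * stats.norm.pdf(b, 0, prior_sd),
        -10 * prior_sd, 10 * prior_sd, limit=200, epsabs=0.0, epsrel=1e-10,
        points=(beta - 4 * se, beta, beta + 4 * se),
    )
    return np.log(num) - stats.norm.logpdf(beta, 0, se)


class TestLogAbf:
    def test_null_point(self):
        # z = 0 with shrinkage 0.5: log ABF = 0.5 * ln(0.5)
        assert log_abf(0.0, 0.1, 0.1) == pytest.approx(0.5 * np.log(0.5), abs=1e-12)

    def test_matches_quadrature(self):
        val = log_abf(0.1, 0.02, 0.15)
        assert val == pytest.approx(quadrature_log_abf(0.1, 0.02, 0.15), abs=1e-4)

    def test_quadrature_grid(self):
        for beta in (0.0, 0.05, 0.2):
            for se in (0.01, 0.05):
                for w in (0.1, 0.2):
                    assert log_abf(beta, se, w) == pytest.approx(
                        quadrature_log_abf(beta, se, w), abs=1e-4
                    )

    def test_monotone_in_z(self):
        vals = [log_abf(b, 0.02, 0.15) for b in np.linspace(0.0, 0.3, 10)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_nonpositive_se_hard_error(self):
        with pytest.raises(ValueError):
            log_abf(0.1, 0.0, 0.15)


def _region(z, n=10_000, trait_type="quantitative"):
    se = np.full(len(z), 1.0 / np.sqrt(n))
    return RegionStats(
        keys=[f"1:{100 + i}:A:G" for i in range(len(z))],
        beta=np.asarray(z) * se,
        se=se,
        trait_type=trait_type,
        n=n,
    )


class TestColocAbf:
    def test_pp_sums_to_one(self, rng):
        t1 = _region(rng.normal(0, 1, 50))
        t2 = _region(rng.normal(0, 1, 50))
        res = coloc_abf(t1, t2)
        assert sum(res.pp.values()) == pytest.approx(1.0, abs=1e-9)

    def test_null_region_h0(self, rng):
        z1 = rng.normal(0, 1, 200)
        z2 = rng.normal(0, 1, 200)
        res = coloc_abf(_region(z1), _region(z2))
        assert res.pp["PP_H0"] > 0.9

    def test_shared_signal_h4(self, rng):
        z1 = rng.normal(0, 1, 200)
        z2 = rng.normal(0, 1, 200)
        z1[77] = 12.0
        z2[77] = 12.0
        res = coloc_abf(_region(z1), _region(z2))
        assert res.pp["PP_H4"] > 0.8

    def test_one_sided_signal_h1(self, rng):
        z1 = rng.normal(0, 1, 200)
        z2 = rng.normal(0, 1, 200)
        z1[77] = 12.0
        res = coloc_abf(_region(z1), _region(z2))
        assert res.pp["PP_H1"] > 0.8

    def test_distinct_signals_h3(self, rng):
        z1 = rng.normal(0, 1, 200)
        z2 = rng.normal(0, 1, 200)
        z1[50] = 12.0
        z2[150] = 12.0
        res = coloc_abf(_region(z1), _region(z2))
        assert res.pp["PP_H3"] > res.pp["PP_H4"]

    def test_variant_mismatch_hard_error(self, rng):
        t1 = _region(rng.normal(0, 1, 10))
        t2 = _region(rng.normal(0, 1, 11))
        with pytest.raises(ValueError):
            coloc_abf(t1, t2)

    def test_no_overflow_at_extreme_z(self):
        z1 = np.zeros(50)
        z2 = np.zeros(50)
        z1[3] = 100.0
        z2[3] = 100.0
        res = coloc_abf(_region(z1), _region(z2))
        assert np.isfinite(list(res.pp.values())).all()
        assert res.pp["PP_H4"] > 0.99

    def test_h3_h4_ratio_invariant_to_lbf_shift(self, rng):
        """Scaling one trait's ABFs by a constant leaves H3:H4 unchanged."""
        from pqtlmr.coloc import _coloc_from_labf

        l1 = rng.normal(0, 3, 80)
        l2 = rng.normal(0, 3, 80)
        a = _coloc_from_labf(l1, l2, 1e-4, 1e-4, 1e-5, 80)
        b = _coloc_from_labf(l1 + 50.0, l2, 1e-4, 1e-4, 1e-5, 80)
        assert a["PP_H3"] / a["PP_H4"] == pytest.approx(b["PP_H3"] / b["PP_H4"], rel=1e-6)


def _ar1_ld(p, rho):
    r = rho ** np.abs(np.subtract.outer(np.arange(p), np.arange(p)))
    return LDMatrix(keys=[f"1:{100 + i}:A:G" for i in range(p)], r=r)


def _simulate_z(R, causal, z_val, rng):
    mean = R.r @ (np.eye(R.r.shape[0])[list(causal)].T @ np.asarray(z_val, float))
    noise = rng.multivariate_normal(np.zeros(R.r.shape[0]), R.r)
    return mean + noise


class TestSusie:
    def test_single_causal_one_credible_set(self, rng):
        R = _ar1_ld(100, 0.5)
        z = _simulate_z(R, [40], [10.0], rng)
        fit = susie_rss(z, R, n=10_000)
        assert len(fit.credible_sets) == 1
        assert "1:140:A:G" in fit.credible_sets[0].keys

    def test_null_z_no_credible_sets(self):
        R = _ar1_ld(50, 0.5)
        fit = susie_rss(np.zeros(50), R, n=10_000)
        assert fit.credible_sets == []

    def test_two_unlinked_causals_two_sets(self, rng):
        R = _ar1_ld(100, 0.5)
        z = _simulate_z(R, [20, 80], [10.0, 10.0], rng)  # r^2 < 0.01 between them
        fit = susie_rss(z, R, n=10_000)
        assert len(fit.credible_sets) == 2
        found = {k for cs in fit.credible_sets for k in cs.keys}
        assert "1:120:A:G" in found and "1:180:A:G" in found

    def test_dimension_mismatch_hard_error(self):
        with pytest.raises(ValueError):
            susie_rss(np.zeros(10), _ar1_ld(9, 0.5), n=1000)

    def test_credible_set_coverage_and_purity(self, rng):
        R = _ar1_ld(80, 0.9)
        z = _simulate_z(R, [40], [9.0], rng)
        fit = susie_rss(z, R, n=5_000)
        for cs in fit.credible_sets:
            assert cs.coverage >= 0.95
            assert cs.purity >= 0.5


class TestColocSusie:
    def test_shared_causal_high_h4(self, rng):
        R = _ar1_ld(100, 0.5)
        z1 = _simulate_z(R, [40], [12.0], rng)
        z2 = _simulate_z(R, [40], [12.0], rng)
        f1 = susie_rss(z1, R, n=20_000)
        f2 = susie_rss(z2, R, n=20_000)
        results = coloc_susie(f1, f2)
        assert len(results) >= 1
        assert max(r.pp["PP_H4"] for r in results) > 0.8

    def test_unlinked_causals_h3(self, rng):
        R = _ar1_ld(100, 0.5)
        z1 = _simulate_z(R, [20], [12.0], rng)
        z2 = _simulate_z(R, [80], [12.0], rng)
        results = coloc_susie(susie_rss(z1, R, n=20_000), susie_rss(z2, R, n=20_000))
        assert results and all(r.pp["PP_H3"] > r.pp["PP_H4"] for r in results)

    def test_empty_when_one_trait_has_no_sets(self, rng):
        R = _ar1_ld(60, 0.5)
        z1 = _simulate_z(R, [30], [12.0], rng)
        f1 = susie_rss(z1, R, n=20_000)
        f2 = susie_rss(np.zeros(60), R, n=20_000)
        assert coloc_susie(f1, f2) == []

    def test_l1_susie_matches_single_variant_coloc(self, rng):
        """With one causal signal, credible-set coloc agrees with plain ABF coloc."""
        R = _ar1_ld(100, 0.5)
        n = 20_000
        z1 = _simulate_z(R, [40], [12.0], rng)
        z2 = _simulate_z(R, [40], [12.0], rng)
        t1, t2 = _region(z1, n=n), _region(z2, n=n)
        plain = coloc_abf(t1, t2)
        f1 = susie_rss(z1, R, n=n, L=1)
        f2 = susie_rss(z2, R, n=n, L=1)
        results = coloc_susie(f1, f2)
        assert len(results) == 1
        assert results[0].pp["PP_H4"] == pytest.approx(plain.pp["PP_H4"], abs=0.05)


def test_evidence_call_three_way(rng):
    shared = coloc_abf(_region([0, 12.0]), _region([0, 12.0]))
    assert evidence_call([shared]) == "H4_shared"
    t1 = _region(np.r_[rng.normal(0, 1, 99), 12.0])
    t2 = _region(rng.normal(0, 1, 100))
    assert evidence_call([coloc_abf(t1, t2)]) == "H1_underpowered"
    nul = coloc_abf(_region(rng.normal(0, 1, 100)), _region(rng.normal(0, 1, 100)))
    assert evidence_call([nul]) == "other"
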