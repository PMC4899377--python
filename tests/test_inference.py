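"""Likelihood, score, ML fitting, information, Wald/LR, model comparison."""

import math
import types

import numpy as np
import pytest
from scipy import optimize, special, stats

import betaburrx as bb
from betaburrx import ModelSpec, SampleVector


class TestSampleVector:
    @pytest.mark.parametrize("bad", [[1.0, -1.0], [0.0], [np.inf], [np.nan], []])
    def test_rejects_invalid(self, bad):
        with pytest.raises(ValueError):
            SampleVector(np.array(bad, dtype=float))


class TestNegLoglik:
    def test_equals_direct_sum(self, glass, p_ref):
        direct = -float(np.sum(np.log(bb.bbx_pdf(glass.values, p_ref))))
        assert bb.neg_loglik(glass, p_ref) == pytest.approx(direct, abs=1e-10)

    def test_value_at_published_burrx_estimates(self, glass):
        # at (alpha,beta)=(1,1), lam=0.9869, theta=5.4860 the negative
        # log-likelihood of the glass-fibre data is about 23.93
        p = bb.BBXParams(1, 1, 0.9869, 5.4860)
        assert bb.neg_loglik(glass, p) == pytest.approx(23.9287, abs=1e-3)

    def test_single_observation_closed_form(self):
        sv = SampleVector(np.array([1.0]))
        assert bb.neg_loglik(sv, bb.BBXParams(1, 1, 1, 1)) == pytest.approx(
            1.0 - math.log(2.0), abs=1e-12
        )


class TestScore:
    def test_matches_finite_differences_reference_point(self, glass, p_ref):
        names = ("alpha", "beta", "lam", "theta")
        vals = dict(zip(names, p_ref.astuple()))
        analytic = bb.score_vector(glass, p_ref)
        for idx, name in enumerate(names):
            h = 1e-6 * vals[name]
            up, dn = dict(vals), dict(vals)
            up[name] += h
            dn[name] -= h
            fd = (-bb.neg_loglik(glass, bb.BBXParams(**up))
                  + bb.neg_loglik(glass, bb.BBXParams(**dn))) / (2 * h)
            assert analytic[idx] == pytest.approx(fd, rel=1e-5)

    def test_matches_finite_differences_random_points(self):
        rng = np.random.default_rng(99)
        data = SampleVector(bb.bbx_rvs(80, bb.BBXParams(1, 1, 1, 2), 4))
        for _ in range(20):
            p = bb.BBXParams(*rng.uniform(0.4, 3.0, 4))
            vals = dict(zip(("alpha", "beta", "lam", "theta"), p.astuple()))
            analytic = bb.score_vector(data, p)
            for idx, name in enumerate(vals):
                h = 1e-6 * vals[name]
                up, dn = dict(vals), dict(vals)
                up[name] += h
                dn[name] -= h
                fd = (-bb.neg_loglik(data, bb.BBXParams(**up))
                      + bb.neg_loglik(data, bb.BBXParams(**dn))) / (2 * h)
                assert analytic[idx] == pytest.approx(fd, rel=2e-5, abs=1e-6)

    def test_digamma_term_at_unit_shapes(self):
        # psi(2) - psi(1) = 1 drives the alpha-score at alpha=beta=1
        assert special.digamma(2.0) - special.digamma(1.0) == pytest.approx(1.0, abs=1e-12)

    def test_score_vanishes_at_optimum(self, glass):
        fit = bb.fit_mle(glass, "bbx", seed=1, compute_cov=False)
        assert fit.grad_norm < 1e-4


class TestFitting:
    def test_rayleigh_closed_form_on_glass(self, glass):
        fit = bb.fit_mle(glass, "rayleigh")
        assert fit.estimates["lam"] == pytest.approx(0.6490, abs=5e-5)
        assert fit.converged

    def test_burrx_profile_on_glass(self, glass):
        fit = bb.fit_mle(glass, "burrx")
        assert fit.estimates["lam"] == pytest.approx(0.9869, abs=1e-3)
        assert fit.estimates["theta"] == pytest.approx(5.4860, abs=1e-3)
        assert fit.neg_loglik == pytest.approx(23.9287, abs=1e-3)

    def test_closed_forms_agree_with_generic_optimizer(self, glass):
        # generic path: root of the analytic score component by brentq
        lam_hat = bb.fit_mle(glass, "rayleigh").estimates["lam"]
        root = optimize.brentq(
            lambda lam: bb.score_vector(glass, bb.BBXParams(1, 1, lam, 1))[2],
            0.1, 3.0, xtol=1e-14)
        assert lam_hat == pytest.approx(root, abs=1e-8)
        th_hat = bb.fit_mle(glass, "burrx1").estimates["theta"]
        root = optimize.brentq(
            lambda th: bb.score_vector(glass, bb.BBXParams(1, 1, 1, th))[3],
            0.5, 50.0, xtol=1e-12)
        assert th_hat == pytest.approx(root, abs=1e-8)

    def test_nesting_never_fits_worse(self, glass):
        nll = {fam: bb.fit_mle(glass, fam, seed=3, compute_cov=False).neg_loglik
               for fam in ("bbx", "burrx", "rayleigh")}
        assert nll["bbx"] <= nll["burrx"] + 1e-6
        assert nll["burrx"] <= nll["rayleigh"] + 1e-6

    def test_requires_enough_observations(self):
        with pytest.raises(ValueError):
            bb.fit_mle(SampleVector(np.array([1.0, 2.0])), "bbx")

    def test_consistency_at_simulation_design_point(self):
        """Median absolute estimation error shrinks with n at the
        study's design point (alpha, beta, lam, theta) = (0.5, 0.2, 0.5, 8)."""
        truth = bb.BBXParams(0.5, 0.2, 0.5, 8)
        tr = np.array(truth.astuple())
        med = {}
        for n in (200, 1000, 5000):
            errs = []
            for seed in range(20):
                x = bb.bbx_rvs(n, truth, 1000 + seed)
                fit = bb.fit_mle(SampleVector(x), "bbx", seed=seed, n_starts=6,
                                 compute_cov=False)
                est = np.array([fit.estimates[k] for k in ("alpha", "beta", "lam", "theta")])
                errs.append(np.abs(est - tr))
            med[n] = np.median(np.array(errs), axis=0)
        for idx in range(4):
            steps = [med[200][idx] > med[1000][idx],
                     med[1000][idx] > med[5000][idx],
                     med[200][idx] > med[5000][idx]]
            assert sum(steps) >= 2, (idx, med)


class TestGenExponential:
    def test_recovers_exponential_limit(self):
        rng = np.random.default_rng(2020)
        x = rng.exponential(scale=0.5, size=2000)  # rate 2
        fit = bb.fit_gen_exponential(SampleVector(x))
        assert fit.estimates["shape"] == pytest.approx(1.0, rel=0.15)
        assert fit.estimates["rate"] == pytest.approx(2.0, rel=0.15)

    def test_glass_fit_value(self, glass):
        fit = bb.fit_gen_exponential(glass)
        assert fit.neg_loglik == pytest.approx(31.3834, abs=0.01)

    def test_score_vanishes_at_optimum(self, glass):
        fit = bb.fit_gen_exponential(glass)
        assert fit.grad_norm < 1e-4


class TestObservedInformation:
    def test_rayleigh_closed_form(self, glass):
        fit = bb.fit_mle(glass, "rayleigh")
        J = bb.observed_information(glass, fit)
        lam = fit.estimates["lam"]
        closed = 2 * glass.n / lam**2 + 2 * float(np.sum(glass.values**2))
        assert J[0, 0] == pytest.approx(closed, rel=1e-4)

    def test_symmetric(self, glass):
        fit = bb.fit_mle(glass, "burrx")
        J = bb.observed_information(glass, fit)
        assert np.max(np.abs(J - J.T)) == 0.0

    def test_positive_definite_at_burrx_optimum(self, glass):
        fit = bb.fit_mle(glass, "burrx")
        J = bb.observed_information(glass, fit)
        assert np.all(np.linalg.eigvalsh(J) > 0)


class TestWald:
    def test_normal_quantile(self):
        assert stats.norm.ppf(0.975) == pytest.approx(1.959964, abs=1e-6)

    def test_interval_construction(self, glass):
        fit = bb.fit_mle(glass, "burrx")
        ci = bb.wald_ci(fit, 0.95)
        z = stats.norm.ppf(0.975)
        for name, (lo, hi) in ci.items():
            assert hi - lo == pytest.approx(2 * z * fit.se[name], rel=1e-12)
            assert lo < fit.estimates[name] < hi

    def test_width_scales_with_sample_size(self):
        truth = bb.BBXParams(1, 1, 1, 2)
        widths = {}
        for n in (500, 2000):
            x = bb.bbx_rvs(n, truth, 61)
            fit = bb.fit_mle(SampleVector(x), "burrx")
            lo, hi = bb.wald_ci(fit, 0.95)["lam"]
            widths[n] = hi - lo
        assert widths[500] / widths[2000] == pytest.approx(2.0, rel=0.2)

    def test_degenerate_zero_se_gives_zero_width(self, glass):
        fit = bb.fit_mle(glass, "rayleigh")
        fit.se = {"lam": 0.0}
        lo, hi = bb.wald_ci(fit, 0.95)["lam"]
        assert lo == hi == fit.estimates["lam"]

    def test_missing_covariance_errors(self, glass):
        fit = bb.fit_mle(glass, "rayleigh", compute_cov=False)
        with pytest.raises(ValueError):
            bb.wald_ci(fit)


class TestLRTest:
    def test_nonnegative_statistic(self, glass):
        f = bb.fit_mle(glass, "burrx1", compute_cov=False)
        f2 = bb.fit_mle(glass, "bbx", seed=1, compute_cov=False)
        res = bb.lr_test(f, f2, 0.05)
        assert res.omega >= 0

    def test_chi2_critical_value(self, glass):
        f_null = bb.fit_mle(glass, "burrx", compute_cov=False)
        f_alt = bb.fit_mle(glass, "bbx", seed=1, compute_cov=False)
        res = bb.lr_test(f_null, f_alt, 0.05)
        assert res.critical == pytest.approx(5.991, abs=1e-3)
        assert res.df == 2
        # arithmetic identity against an independent evaluation
        assert res.omega == pytest.approx(
            2 * (f_null.neg_loglik - f_alt.neg_loglik), abs=1e-6
        )
        assert res.reject

    def test_zero_statistic_no_rejection(self, glass):
        f = bb.fit_mle(glass, "burrx", compute_cov=False)
        twin = types.SimpleNamespace(model=ModelSpec("bbx"), neg_loglik=f.neg_loglik, k=4)
        res = bb.lr_test(f, twin, 0.05)
        assert res.omega == 0.0
        assert not res.reject

    def test_non_nested_rejected(self, glass):
        f1 = bb.fit_mle(glass, "rayleigh", compute_cov=False)
        f2 = bb.fit_mle(glass, "burrx1", compute_cov=False)
        with pytest.raises(ValueError):
            bb.lr_test(f1, f2)


class TestInformationCriteria:
    def _stub(self, family, nll, k):
        return types.SimpleNamespace(model=types.SimpleNamespace(family=family),
                                     neg_loglik=nll, k=k)

    def test_published_bbx_row(self, glass):
        rows = bb.information_criteria([self._stub("bbx", 16.0016, 4)], glass)
        assert rows[0].aic == pytest.approx(40.003, abs=0.01)
        assert rows[0].caic == pytest.approx(40.691, abs=0.01)
        assert rows[0].bic == pytest.approx(48.576, abs=0.01)

    def test_published_rayleigh_row(self, glass):
        rows = bb.information_criteria([self._stub("rayleigh", 49.7909, 1)], glass)
        assert rows[0].aic == pytest.approx(101.5818, abs=1e-3)

    def test_zero_parameter_model(self, glass):
        rows = bb.information_criteria([self._stub("fixed", 10.0, 0)], glass)
        assert rows[0].aic == 20.0

    def test_sorted_by_aic(self, glass):
        fits = [bb.fit_mle(glass, fam, seed=1, compute_cov=False)
                for fam in ("rayleigh", "bbx", "burrx")]
        rows = bb.information_criteria(fits, glass)
        assert [r.model for r in rows] == ["bbx", "burrx", "rayleigh"]

    def test_caic_undefined_for_tiny_n(self):
        tiny = SampleVector(np.array([1.0, 1.2, 0.9]))
        rows = bb.information_criteria([self._stub("burrx", 5.0, 2)], tiny)
        assert rows[0].caic is None


class TestExpectedScore:
    def test_identities_at_reference_point(self):
        chk = bb.expected_score_check(bb.BBXParams(2, 3, 0.5, 1.5), reps=2000, n=200, seed=5)
        assert abs(chk["z_log_u"]) < 4
        assert abs(chk["z_log_1m_uth"]) < 4

    def test_unit_parameter_target(self):
        # theta=1, alpha=beta=1: the first digamma target is exactly -n
        chk = bb.expected_score_check(bb.BBXParams(1, 1, 1, 1), reps=50, n=100, seed=6)
        assert chk["target_log_u"] == pytest.approx(-100.0, abs=1e-10)

    def test_symmetric_shapes_structure(self):
        # alpha = beta makes the two digamma differences coincide up to 1/theta
        p = bb.BBXParams(1.7, 1.7, 1.0, 2.0)
        chk = bb.expected_score_check(p, reps=50, n=50, seed=7)
        assert chk["target_log_u"] == pytest.approx(chk["target_log_1m_uth"] / p.theta, rel=1e-12)
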