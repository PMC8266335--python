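import numpy as np
import pytest
from scipy import integrate
from scipy.special import expit, logit
from scipy.stats import binom, multivariate_normal

from dtameta.bivariate_model import (
    BivariateParams,
    fit,
    loglikelihood,
    summary_measures,
)
from dtameta.synthetic_data import SyntheticConfig, generate

from conftest import make_panel

P_MODERATE = BivariateParams(mu_A=1.2, mu_B=1.6, sigma_A=0.6, sigma_B=0.8, rho=-0.4)


def brute_force_loglik_dblquad(panel, p):
    """Independent oracle: per-study 2-D adaptive numerical integration."""
    total = 0.0
    mean = [p.mu_A, p.mu_B]
    for s in panel:
        def integrand(b, a):
            return (
                binom.pmf(s.tp, s.tp + s.fn, expit(a))
                * binom.pmf(s.tn, s.tn + s.fp, expit(b))
                * multivariate_normal.pdf([a, b], mean=mean, cov=p.cov)
            )
        lo_a, hi_a = p.mu_A - 8 * p.sigma_A, p.mu_A + 8 * p.sigma_A
        lo_b, hi_b = p.mu_B - 8 * p.sigma_B, p.mu_B + 8 * p.sigma_B
        val, _ = integrate.dblquad(integrand, lo_a, hi_a, lo_b, hi_b,
                                   epsabs=1e-13, epsrel=1e-11)
        total += np.log(val)
    return total


class TestLoglikelihood:
    def test_matches_adaptive_integration_oracle(self, toy4):
        ours = loglikelihood(toy4, P_MODERATE, n_quad=21)
        oracle = brute_force_loglik_dblquad(toy4, P_MODERATE)
        assert ours == pytest.approx(oracle, rel=1e-6)

    def test_matches_monte_carlo_oracle(self):
        panel = make_panel([(30, 5, 10, 40), (80, 3, 6, 20), (15, 8, 12, 60)])
        p = BivariateParams(mu_A=1.0, mu_B=1.3, sigma_A=0.5, sigma_B=0.5, rho=-0.3)
        rng = np.random.default_rng(42)
        n_draws = 1_000_000
        L = np.linalg.cholesky(p.cov)
        ab = rng.standard_normal((n_draws, 2)) @ L.T + [p.mu_A, p.mu_B]
        for s, ll_quad in zip(
            panel,
            [loglikelihood(make_panel([(s.tp, s.fp, s.fn, s.tn)]), p) for s in panel],
        ):
            vals = (binom.pmf(s.tp, s.tp + s.fn, expit(ab[:, 0]))
                    * binom.pmf(s.tn, s.tn + s.fp, expit(ab[:, 1])))
            mc, se = vals.mean(), vals.std(ddof=1) / np.sqrt(n_draws)
            assert abs(np.exp(ll_quad) - mc) < 3 * se

    def test_degenerate_variance_limit_is_fixed_effect_binomial(self, toy4):
        p = BivariateParams(mu_A=1.1, mu_B=1.8, sigma_A=1e-5, sigma_B=1e-5, rho=0.0)
        ll = loglikelihood(toy4, p, n_quad=21)
        fixed = sum(
            binom.logpmf(s.tp, s.tp + s.fn, expit(p.mu_A))
            + binom.logpmf(s.tn, s.tn + s.fp, expit(p.mu_B))
            for s in toy4
        )
        assert ll == pytest.approx(fixed, abs=1e-5)

    def test_margin_swap_symmetry(self, toy4):
        p = P_MODERATE
        swapped_panel = make_panel([(s.tn, s.fn, s.fp, s.tp) for s in toy4])
        p_sw = BivariateParams(mu_A=p.mu_B, mu_B=p.mu_A, sigma_A=p.sigma_B,
                               sigma_B=p.sigma_A, rho=p.rho)
        assert loglikelihood(toy4, p) == pytest.approx(
            loglikelihood(swapped_panel, p_sw), abs=1e-10
        )

    def test_accuracy_improves_with_n_quad(self, toy4):
        ref = brute_force_loglik_dblquad(toy4, P_MODERATE)
        errs = [abs(loglikelihood(toy4, P_MODERATE, n_quad=nq) - ref)
                for nq in (5, 9, 15, 25)]
        assert errs[-1] <= errs[0]
        assert errs[-1] < 1e-6

    def test_invalid_inputs(self, toy4):
        with pytest.raises(ValueError):
            loglikelihood(toy4, P_MODERATE, n_quad=3)
        with pytest.raises(ValueError):
            BivariateParams(np.nan, 0, 1, 1, 0)
        with pytest.raises(ValueError):
            BivariateParams(0, 0, -1, 1, 0)
        with pytest.raises(ValueError):
            BivariateParams(0, 0, 1, 1, 1.0)


class TestFit:
    def test_row_order_invariance(self, toy4):
        f1 = fit(toy4, n_quad=15, compute_vcov=False)
        rev = make_panel([(s.tp, s.fp, s.fn, s.tn) for s in reversed(toy4.rows)])
        f2 = fit(rev, n_quad=15, compute_vcov=False)
        # the likelihood function itself is exactly permutation invariant
        assert loglikelihood(rev, f1.params, 15) == pytest.approx(f1.loglik, abs=1e-9)
        assert loglikelihood(toy4, f2.params, 15) == pytest.approx(f2.loglik, abs=1e-9)
        # the two optima coincide up to optimizer termination noise
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-4)
        assert f1.params.mu_A == pytest.approx(f2.params.mu_A, abs=1e-3)

    def test_no_heterogeneity_pushes_sigma_to_floor(self):
        # identical huge studies with sens = spec = 0.9
        n = 10**6
        panel = make_panel([(int(0.9 * n), n - int(0.9 * n), n - int(0.9 * n),
                             int(0.9 * n))] * 4)
        f = fit(panel, n_quad=10, compute_vcov=False)
        assert expit(f.params.mu_A) == pytest.approx(0.9, abs=1e-3)
        assert expit(f.params.mu_B) == pytest.approx(0.9, abs=1e-3)
        assert f.params.sigma_A < 0.01 and f.params.sigma_B < 0.01
        assert f.boundary

    def test_parameter_recovery_large_panel(self):
        cfg = SyntheticConfig(K=200, arm_range_diseased=(200, 2000),
                              arm_range_nondiseased=(200, 2000), seed=7)
        panel = generate(cfg)
        f = fit(panel, n_quad=15)
        se_muA = np.sqrt(f.vcov[0, 0])
        se_muB = np.sqrt(f.vcov[1, 1])
        assert abs(f.params.mu_A - cfg.mu_A) < 3 * se_muA
        assert abs(f.params.mu_B - cfg.mu_B) < 3 * se_muB
        assert abs(f.params.rho - cfg.rho) < 0.2

    def test_too_few_studies_raises(self):
        with pytest.raises(ValueError):
            fit(make_panel([(5, 1, 2, 8)]))

    def test_small_panel_warns(self):
        import warnings
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            fit(make_panel([(5, 1, 2, 8), (9, 2, 3, 7), (6, 1, 1, 9)]),
                n_quad=7, compute_vcov=False)
        assert any("unstable" in str(w.message) for w in rec)


class TestSummaryMeasures:
    def test_closed_form_point_estimates(self, table3_fit):
        # independent algebra at the printed pooled point
        muA, muB = logit(0.84), logit(0.87)
        f = table3_fit
        import dataclasses
        p = dataclasses.replace(f.params, mu_A=float(muA), mu_B=float(muB))
        m = summary_measures(dataclasses.replace(f, params=p))
        assert m.dor == pytest.approx(np.exp(muA + muB), rel=1e-12)
        assert m.dor == pytest.approx(35.1, abs=0.1)
        assert m.plr == pytest.approx(6.46, abs=0.01)
        assert m.nlr == pytest.approx(0.184, abs=0.001)

    def test_uninformative_test_point(self, table3_fit):
        import dataclasses
        p = dataclasses.replace(table3_fit.params, mu_A=0.0, mu_B=0.0)
        m = summary_measures(dataclasses.replace(table3_fit, params=p))
        assert (m.sens, m.spec, m.plr, m.nlr, m.dor) == (0.5, 0.5, 1.0, 1.0, 1.0)

    def test_dor_is_plr_over_nlr(self, table3_fit):
        m = summary_measures(table3_fit)
        assert m.dor == pytest.approx(m.plr / m.nlr, abs=1e-10)
        assert m.plr == pytest.approx(m.sens / (1 - m.spec), abs=1e-10)
        assert m.nlr == pytest.approx((1 - m.sens) / m.spec, abs=1e-10)

    def test_ci_brackets_point(self, table3_fit):
        m = summary_measures(table3_fit)
        for point, ci in [(m.sens, m.sens_ci), (m.spec, m.spec_ci),
                          (m.plr, m.plr_ci), (m.nlr, m.nlr_ci), (m.dor, m.dor_ci)]:
            assert ci[0] <= point <= ci[1]

    def test_missing_vcov_gives_points_only(self, toy4):
        f = fit(toy4, n_quad=10, compute_vcov=False)
        m = summary_measures(f)
        assert m.sens_ci is None and m.dor_ci is None
        assert 0 < m.sens < 1
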