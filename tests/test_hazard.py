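import numpy as np
import pytest
from scipy.integrate import quad

import flexcif as fc
from flexcif import (CauseModelSpec, QuadratureRule, SplineSpec, SurvDataset,
                     cause_loglik, cumulative_hazard, fit_cause_model,
                     fit_competing, gl_integrate, log_hazard, select_by_aic)


def const_dataset(times, causes, extra_cov=False):
    times = np.asarray(times, float)
    causes = np.asarray(causes, int)
    cov = {"x": np.zeros(len(times))} if extra_cov else {}
    import pandas as pd
    return SurvDataset(times, (causes > 0).astype(int), causes,
                       pd.DataFrame(cov, index=range(len(times))))


class TestLogHazard:
    spec = CauseModelSpec(1, SplineSpec(3, (1.0, 5.0), (0.0, 10.0)), ("x",))

    def test_zero_beta_gives_unit_hazard(self):
        lh = log_hazard(self.spec, np.zeros(self.spec.n_params), [0.5, 3.0],
                        [1.7])
        assert np.allclose(lh, 0.0)

    def test_constant_hazard_config(self):
        spec = CauseModelSpec(1, SplineSpec(1, (), (0.0, 10.0)))
        gamma = 0.7
        lh = log_hazard(spec, np.full(2, gamma), [0.1, 5.0, 9.9], [])
        assert np.allclose(lh, gamma)

    def test_dot_product_oracle(self):
        rng = np.random.default_rng(3)
        beta = rng.normal(size=self.spec.n_params)
        t, x = 2.5, 1.3
        from flexcif.splines import bspline_basis
        row = np.concatenate([bspline_basis([t], self.spec.baseline)[0],
                              [x]])
        assert np.allclose(log_hazard(self.spec, beta, [t], [x])[0],
                           row @ beta)

    def test_dimension_mismatch_names_problem(self):
        with pytest.raises(ValueError, match="parameters"):
            log_hazard(self.spec, np.zeros(3), [1.0], [0.0])


class TestQuadrature:
    def test_low_order_polynomial_exact(self):
        val = gl_integrate(lambda t: 3 * t ** 2, 0.0, 1.0, QuadratureRule(2))
        assert np.isclose(val, 1.0, atol=1e-14)

    def test_empty_interval(self):
        assert gl_integrate(np.sin, 2.0, 2.0, QuadratureRule(8)) == 0.0

    def test_inverted_bounds_raise(self):
        with pytest.raises(ValueError):
            gl_integrate(np.sin, 1.0, 0.0, QuadratureRule(8))

    def test_generalized_weibull_vs_adaptive(self):
        f = lambda t: fc.gw_baseline_hazard(t, 2.0, 1.2, 0.1)
        ref, _ = quad(f, 0.0, 5.0, epsabs=1e-12)
        val = gl_integrate(f, 0.0, 5.0, QuadratureRule(64))
        assert abs(val - ref) < 1e-8

    def test_rule_invariants(self):
        rule = QuadratureRule(17)
        assert np.isclose(rule.weights.sum(), 2.0)
        assert np.allclose(rule.nodes, -rule.nodes[::-1])


class TestCumulativeHazard:
    def test_constant_hazard_linear(self):
        spec = CauseModelSpec(1, SplineSpec(1, (), (0.0, 10.0)))
        beta = np.full(2, np.log(0.4))
        t = np.array([0.0, 1.0, 7.5])
        lam = cumulative_hazard(spec, beta, t, [], QuadratureRule(20))
        assert np.allclose(lam, 0.4 * t, rtol=1e-10)

    def test_monotone_in_time(self):
        spec = CauseModelSpec(1, SplineSpec(3, (1.0, 5.0), (0.0, 10.0)), ("x",))
        rng = np.random.default_rng(8)
        beta = rng.normal(scale=0.5, size=spec.n_params)
        grid = np.linspace(0, 10, 100)
        lam = cumulative_hazard(spec, beta, grid, [0.7], QuadratureRule(32))
        assert lam[0] == 0.0
        assert np.all(np.diff(lam) > 0)


class TestCauseLoglik:
    def test_single_subject_closed_forms(self):
        spec = CauseModelSpec(1, SplineSpec(1, (), (0.0, 10.0)))
        lam, t = 0.3, 4.0
        beta = np.full(2, np.log(lam))
        event = const_dataset([t], [1])
        censored = const_dataset([t], [0])
        assert np.isclose(cause_loglik(spec, beta, event, QuadratureRule(20)),
                          -lam * t + np.log(lam), rtol=1e-10)
        assert np.isclose(cause_loglik(spec, beta, censored, QuadratureRule(20)),
                          -lam * t, rtol=1e-10)

    def test_matches_per_subject_adaptive_quadrature(self):
        """Spline-model likelihood vs a naive subject-by-subject oracle."""
        import pandas as pd
        rng = np.random.default_rng(12)
        n = 20
        status = (rng.random(n) < 0.6).astype(int)
        data = SurvDataset(rng.uniform(0.2, 9.5, n), status, status,
                           pd.DataFrame({"x": rng.normal(size=n)}))
        spec = CauseModelSpec(1, SplineSpec(2, (3.0,), (0.0, 10.0)), ("x",))
        beta = rng.normal(scale=0.3, size=spec.n_params)
        naive = 0.0
        for i in range(n):
            x = [data.covariates.x.iloc[i]]
            lam_i = lambda u: float(np.exp(log_hazard(spec, beta, [u], x))[0])
            cumh, _ = quad(lam_i, 0.0, data.time[i], epsabs=1e-10)
            naive -= cumh
            if data.cause[i] == 1:
                naive += log_hazard(spec, beta, [data.time[i]], x)[0]
        ours = cause_loglik(spec, beta, data, QuadratureRule(64))
        assert np.isclose(ours, naive, atol=1e-6)

    def test_overflow_reported(self):
        spec = CauseModelSpec(1, SplineSpec(1, (), (0.0, 10.0)))
        data = const_dataset([5.0], [1])
        with pytest.raises(FloatingPointError):
            cause_loglik(spec, np.full(2, 600.0), data, QuadratureRule(10))


@pytest.fixture(scope="module")
def const_sim():
    rng = np.random.default_rng(100)
    n, lam = 2000, 0.5
    t_event = rng.exponential(1 / lam, n)
    cens = rng.uniform(0, 8, n)
    time = np.minimum(t_event, cens)
    status = (t_event <= cens).astype(int)
    return const_dataset(time, status), lam


class TestFitting:
    def test_constant_hazard_recovery(self, const_sim):
        data, lam = const_sim
        spec = CauseModelSpec(1, SplineSpec(1, (), (0.0, float(data.time.max()))))
        fit = fit_cause_model(spec, data, QuadratureRule(20))
        assert fit.converged
        # flat log-hazard: both coefficients estimate log(lam)
        lam_hat = np.exp(fit.beta.mean())
        d = fit.n_events
        se_rate = lam_hat / np.sqrt(d)   # exponential-MLE closed form
        assert abs(lam_hat - lam) < 3 * se_rate

    def test_rate_se_matches_exponential_closed_form(self, const_sim):
        data, _ = const_sim
        spec = CauseModelSpec(1, SplineSpec(1, (), (0.0, float(data.time.max()))))
        fit = fit_cause_model(spec, data, QuadratureRule(20))
        # evaluate the fitted hazard at the person-time-weighted mean time,
        # where a (level, slope) parameterization is estimated with the same
        # precision as a single-rate exponential model
        t_star = float(np.sum(data.time ** 2) / 2 / np.sum(data.time))
        from flexcif.splines import bspline_basis
        row = bspline_basis([t_star], spec.baseline)[0]
        lam_hat = float(np.exp(row @ fit.beta))
        g = lam_hat * row
        se_delta = float(np.sqrt(g @ fit.cov @ g))
        se_closed = lam_hat / np.sqrt(fit.n_events)
        assert abs(se_delta - se_closed) / se_closed < 0.10

    def test_refit_from_optimum_is_idempotent(self, const_sim):
        data, _ = const_sim
        spec = CauseModelSpec(1, SplineSpec(1, (), (0.0, float(data.time.max()))))
        fit = fit_cause_model(spec, data, QuadratureRule(20))
        refit = fit_cause_model(spec, data, QuadratureRule(20), init=fit.beta)
        assert refit.n_iter <= 1
        assert np.allclose(refit.beta, fit.beta, atol=1e-8)

    def test_no_events_raises(self):
        data = const_dataset([1.0, 2.0], [0, 0])
        spec = CauseModelSpec(1, SplineSpec(1, (), (0.0, 3.0)))
        with pytest.raises(ValueError, match="no events"):
            fit_cause_model(spec, data)

    def test_loglik_concave_along_random_sections(self, const_sim):
        data, _ = const_sim
        spec = CauseModelSpec(1, SplineSpec(2, (2.0,), (0.0, float(data.time.max()))))
        rule = QuadratureRule(16)
        rng = np.random.default_rng(4)
        for _ in range(5):
            b0 = rng.normal(scale=0.5, size=spec.n_params)
            b1 = rng.normal(scale=0.5, size=spec.n_params)
            ll = [cause_loglik(spec, (1 - a) * b0 + a * b1, data, rule)
                  for a in (0.0, 0.5, 1.0)]
            assert ll[1] >= 0.5 * (ll[0] + ll[2]) - 1e-9


class TestCompeting:
    def test_block_structure_and_factorized_loglik(self, scenario1_data):
        specs = fc.study_model_specs("a")
        fit = fit_competing(specs, scenario1_data, QuadratureRule(16))
        p1 = fit.models[0].n_params
        off = fit.Sigma[:p1, p1:]
        assert np.all(off == 0.0)
        assert np.isclose(fit.loglik, sum(m.loglik for m in fit.models))

    def test_two_cause_rate_recovery(self):
        rng = np.random.default_rng(77)
        n, l1, l2 = 3000, 0.3, 0.15
        t1 = rng.exponential(1 / l1, n)
        t2 = rng.exponential(1 / l2, n)
        time = np.minimum(np.minimum(t1, t2), 10.0)
        cause = np.where(np.minimum(t1, t2) > 10.0, 0,
                         np.where(t1 <= t2, 1, 2))
        data = const_dataset(time, cause)
        b = (0.0, float(time.max()))
        specs = [CauseModelSpec(1, SplineSpec(1, (), b)),
                 CauseModelSpec(2, SplineSpec(1, (), b))]
        fit = fit_competing(specs, data, QuadratureRule(20))
        for m, lam in zip(fit.models, (l1, l2)):
            lam_hat = np.exp(m.beta.mean())
            assert abs(lam_hat - lam) < 3 * lam / np.sqrt(m.n_events)

    def test_duplicate_causes_rejected(self, scenario1_data):
        specs = [fc.study_model_specs("a")[0]] * 2
        with pytest.raises(ValueError, match="duplicate"):
            fit_competing(specs, scenario1_data, QuadratureRule(8))


class TestModelSelection:
    def test_single_candidate_returned(self, scenario1_data):
        spec = fc.study_model_specs("a")[0]
        best = select_by_aic([spec], scenario1_data, QuadratureRule(12))
        assert best.spec == spec

    def test_parsimony_when_likelihoods_tie(self, scenario1_data):
        # nested baselines: the richer spline can only raise the likelihood,
        # but if the gain is below the AIC penalty the smaller model wins;
        # an exact duplicate candidate falls back to input order
        b = (0.0, 10.0)
        small = CauseModelSpec(1, SplineSpec(1, (), b), ("age", "sex"))
        best = select_by_aic([small, small], scenario1_data, QuadratureRule(12))
        assert best.spec == small
        f_small = fit_cause_model(small, scenario1_data, QuadratureRule(12))
        rich = CauseModelSpec(1, SplineSpec(2, (), b), ("age", "sex"))
        f_rich = fit_cause_model(rich, scenario1_data, QuadratureRule(12))
        assert f_rich.loglik >= f_small.loglik - 1e-9
        if f_rich.loglik - f_small.loglik < 1.0:
            winner = select_by_aic([rich, small], scenario1_data,
                                   QuadratureRule(12))
            assert winner.n_params == f_small.n_params

    def test_strong_td_effect_selected(self):
        """A genuinely time-dependent sex effect should win the AIC contest
        for the TD model in most replicates."""
        cfg = fc.scenario2_config(n=800)
        cfg.cancer_params = {0: (2.0, 0.9, 0.15), 1: (2.0, 0.25, 0.35)}
        wins = 0
        n_rep = 20
        for r in range(n_rep):
            data = fc.simulate_dataset(cfg, seed=1000 + r)
            fixed, td = fc.study_model_specs("b")[0], fc.study_model_specs("c")[0]
            best = select_by_aic([fixed, td], data, QuadratureRule(16))
            wins += bool(best.spec.td_effects)
        assert wins >= 0.8 * n_rep

    def test_all_failures_reported(self):
        data = const_dataset([1.0, 2.0, 3.0], [1, 0, 1])
        bad = CauseModelSpec(2, SplineSpec(1, (), (0.0, 5.0)))  # no cause-2 events
        with pytest.raises(RuntimeError, match="all candidate models failed"):
            select_by_aic([bad], data)
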