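"""Hierarchical Poisson-lognormal model: density oracles, sampler checks."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize
from scipy.special import logsumexp

import roadrisk as rr
from roadrisk.model import TAU_PRIOR_RATE, TAU_PRIOR_SHAPE, _poisson_irls


def scipy_log_posterior(model, beta_full, delta, log_tau=None):
    """Independent term-by-term evaluation via scipy.stats densities."""
    eta = model.offset + beta_full[0] + model.X @ beta_full[1:] + delta
    total = float(np.sum(stats.poisson.logpmf(model.y, np.exp(eta))))
    if model.tau_fixed is not None:
        tau = model.tau_fixed
    else:
        tau = math.exp(log_tau)
        # log-Gamma density of log tau == Gamma density of tau times |dtau/dlogtau|
        total += stats.gamma.logpdf(tau, a=TAU_PRIOR_SHAPE, scale=1 / TAU_PRIOR_RATE)
        total += log_tau
    total += float(np.sum(stats.norm.logpdf(delta, scale=1 / math.sqrt(tau))))
    total += float(
        np.sum(stats.norm.logpdf(beta_full, scale=math.sqrt(model.prior_var)))
    )
    return total


def _toy_model(n=12, p=2, seed=0, tau_fixed=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    offset = np.log(rng.uniform(1e4, 1e6, size=n))
    eta = offset - 8.5 + X @ rng.normal(scale=0.3, size=p)
    y = rng.poisson(np.exp(eta) * np.exp(rng.normal(scale=0.3, size=n)))
    return rr.FatalityModel(
        y, X, offset, names=[f"x{j}" for j in range(p)], tau_fixed=tau_fixed
    )


class TestBuildDesign:
    @staticmethod
    def _design(study, model_id):
        frame, tables, _ = study
        exposures = {u: rr.build_exposure(t).distance_km for u, t in tables.items()}
        return rr.build_design(frame, exposures, rr.model_spec(model_id))

    def test_model_column_counts(self, small_study):
        X1, _, _ = self._design(small_study, 1)
        X4, off, y = self._design(small_study, 4)
        assert X1.shape[1] == 6
        assert X4.shape[1] == 10
        assert list(X1.columns) == [
            "ln_bus", "ln_IPT", "ln_car", "ln_walk", "ln_cycle", "ln_2W",
        ]
        assert off == pytest.approx(
            np.log([u.population for u in small_study[0].units])
        )
        assert np.all(y == np.round(y))

    def test_log_transform_forced(self, small_study):
        frame, tables, _ = small_study
        exposures = {u: rr.build_exposure(t).distance_km for u, t in tables.items()}
        uid = frame.units[0].unit_id
        exposures[uid] = dict(exposures[uid], car=math.exp(10.0))
        X, _, _ = rr.build_design(frame, exposures, rr.model_spec(1))
        assert X.loc[uid, "ln_car"] == pytest.approx(10.0)

    def test_zero_logged_covariate_names_unit(self, small_study):
        frame, tables, _ = small_study
        exposures = {u: rr.build_exposure(t).distance_km for u, t in tables.items()}
        uid = frame.units[3].unit_id
        exposures[uid] = dict(exposures[uid], cycle=0.0)
        with pytest.raises(ValueError, match=f"{uid}.*cycle|cycle.*{uid}"):
            rr.build_design(frame, exposures, rr.model_spec(1))

    def test_walk_covariate_includes_pt_access_walk(self, small_study):
        frame, tables, _ = small_study
        with_walk = {u: rr.build_exposure(t, walk_per_trip=1.0) for u, t in tables.items()}
        without = {u: rr.build_exposure(t, walk_per_trip=0.0) for u, t in tables.items()}
        Xw, _, _ = rr.build_design(
            frame, {u: e.distance_km for u, e in with_walk.items()}, rr.model_spec(1)
        )
        X0, _, _ = rr.build_design(
            frame, {u: e.distance_km for u, e in without.items()}, rr.model_spec(1)
        )
        for uid in Xw.index:
            expected = math.log(
                math.exp(X0.loc[uid, "ln_walk"]) + with_walk[uid].pt_walk_km
            )
            assert Xw.loc[uid, "ln_walk"] == pytest.approx(expected)


class TestLogPosterior:
    def test_matches_scipy_term_by_term(self):
        model = _toy_model()
        rng = np.random.default_rng(1)
        centre = np.r_[-8.5, np.zeros(model.p)]
        for _ in range(10):
            beta = centre + rng.normal(scale=0.4, size=model.p + 1)
            delta = rng.normal(scale=0.5, size=model.n)
            log_tau = rng.normal(loc=2.0)
            got = model.log_posterior(beta, delta, log_tau)
            want = scipy_log_posterior(model, beta, delta, log_tau)
            assert got == pytest.approx(want, abs=1e-9, rel=1e-13)

    def test_matches_scipy_with_fixed_tau(self):
        model = _toy_model(tau_fixed=11.1)
        rng = np.random.default_rng(2)
        beta = np.r_[-8.5, np.zeros(model.p)] + rng.normal(
            scale=0.4, size=model.p + 1
        )
        delta = rng.normal(scale=0.3, size=model.n)
        assert model.log_posterior(beta, delta) == pytest.approx(
            scipy_log_posterior(model, beta, delta), abs=1e-9
        )

    def test_intercept_delta_tradeoff_changes_only_priors(self):
        """Shifting c from delta to beta0 leaves the likelihood invariant."""
        model = _toy_model()
        rng = np.random.default_rng(3)
        beta = np.r_[-8.5, np.zeros(model.p)] + rng.normal(
            scale=0.3, size=model.p + 1
        )
        delta = rng.normal(scale=0.4, size=model.n)
        c = 0.7
        beta2 = beta.copy()
        beta2[0] += c
        delta2 = delta - c
        lp1 = model.log_posterior(beta, delta, 2.0)
        lp2 = model.log_posterior(beta2, delta2, 2.0)
        tau = math.exp(2.0)
        prior_diff = (
            -0.5 * tau * (float(delta2 @ delta2) - float(delta @ delta))
            - 0.5 * (beta2[0] ** 2 - beta[0] ** 2) / model.prior_var
        )
        assert lp2 - lp1 == pytest.approx(prior_diff, abs=1e-9)
        assert model.loglike(beta, delta) == pytest.approx(
            model.loglike(beta2, delta2), abs=1e-9
        )

    def test_zero_count_likelihood_closed_form(self):
        model = rr.FatalityModel(
            y=[0.0], X=np.empty((1, 0)), offset=[math.log(1e5)], tau_fixed=1.0
        )
        f = 1e5 * math.exp(-9.0)
        assert model.loglike(np.array([-9.0]), np.zeros(1)) == pytest.approx(-f)

    def test_non_finite_params_rejected(self):
        model = _toy_model()
        with pytest.raises(ValueError):
            model.log_posterior(
                np.full(model.p + 1, np.nan), np.zeros(model.n), 0.0
            )


class TestSignificance:
    @pytest.mark.parametrize(
        "q25,q5,q95,q975,expected",
        [
            (0.1, 0.15, 0.4, 0.5, "95%"),
            (-0.05, -0.01, 0.4, 0.5, "none"),
            (-0.01, 0.02, 0.4, 0.5, "90%"),
            (-0.5, -0.4, -0.1, -0.02, "95%"),
        ],
    )
    def test_forced_flags(self, q25, q5, q95, q975, expected):
        df = pd.DataFrame(
            {"q2.5": [q25], "q5": [q5], "q95": [q95], "q97.5": [q975]},
            index=["b"],
        )
        assert rr.classify_significance(df).loc["b"] == expected


class TestSampler:
    def test_deterministic_given_seed(self):
        model = _toy_model()
        r1 = model.fit(chains=2, warmup=200, draws=200, seed=7)
        r2 = model.fit(chains=2, warmup=200, draws=200, seed=7)
        pd.testing.assert_frame_equal(r1.summary_frame, r2.summary_frame)
        np.testing.assert_array_equal(r1.beta_draws, r2.beta_draws)

    def test_too_few_units_rejected(self):
        model = _toy_model(n=3, p=2)
        with pytest.raises(ValueError, match="units"):
            model.fit(chains=1, warmup=10, draws=10)

    def test_posterior_mean_matches_grid_integration(self):
        """Intercept-only model with fixed tau against dense quadrature."""
        rng = np.random.default_rng(11)
        n = 5
        pops = rng.uniform(1e5, 6e5, size=n)
        sigma = 0.3
        true_b0 = math.log(1.2e-4)
        y = rng.poisson(pops * np.exp(true_b0 + rng.normal(scale=sigma, size=n)))
        model = rr.FatalityModel(
            y, np.empty((n, 0)), np.log(pops), tau_fixed=1 / sigma**2
        )
        # oracle: p(y | b0) with delta integrated out by Gauss-Hermite,
        # then the posterior mean of b0 on a dense grid
        nodes, weights = np.polynomial.hermite.hermgauss(80)
        deltas = math.sqrt(2) * sigma * nodes  # (80,)
        log_w = np.log(weights / math.sqrt(math.pi))
        grid = np.linspace(true_b0 - 1.2, true_b0 + 1.2, 4001)
        log_post = np.empty_like(grid)
        for i, b0 in enumerate(grid):
            lam = pops[:, None] * np.exp(b0 + deltas[None, :])
            ll = stats.poisson.logpmf(y[:, None], lam)  # (n, 80)
            log_post[i] = float(np.sum(logsumexp(ll + log_w[None, :], axis=1)))
        log_post += stats.norm.logpdf(grid, scale=math.sqrt(model.prior_var))
        w = np.exp(log_post - logsumexp(log_post))
        oracle_mean = float(np.sum(w * grid))

        res = model.fit(chains=2, warmup=1500, draws=3000, seed=5)
        assert res.params["intercept"] == pytest.approx(oracle_mean, abs=0.02)

    def test_mode_matches_newton_glm_with_delta_pinned(self, small_study):
        """With tau huge (delta ~ 0) the posterior mode is the Poisson MLE."""
        import statsmodels.api as sm

        frame, tables, _ = small_study
        exposures = {u: rr.build_exposure(t).distance_km for u, t in tables.items()}
        X, offset, y = rr.build_design(frame, exposures, rr.model_spec(1))
        model = rr.FatalityModel(y, X, offset, tau_fixed=1e10)

        glm = sm.GLM(
            y, sm.add_constant(np.asarray(X)), family=sm.families.Poisson(),
            offset=offset,
        ).fit()

        def neg_lp(b):
            return -model.log_posterior(b, np.zeros(model.n))

        opt = minimize(neg_lp, glm.params, method="BFGS",
                       options={"gtol": 1e-8, "maxiter": 500})
        assert np.max(np.abs(opt.x - glm.params)) < 1e-3

    def test_internal_irls_agrees_with_statsmodels(self, small_study):
        import statsmodels.api as sm

        frame, tables, _ = small_study
        exposures = {u: rr.build_exposure(t).distance_km for u, t in tables.items()}
        X, offset, y = rr.build_design(frame, exposures, rr.model_spec(1))
        Xf = np.column_stack([np.ones(len(y)), np.asarray(X)])
        mode, _ = _poisson_irls(Xf, offset, y)
        glm = sm.GLM(y, Xf, family=sm.families.Poisson(), offset=offset).fit()
        assert np.max(np.abs(mode - glm.params)) < 1e-6

    def test_offset_contract_population_rescaling(self):
        """Scaling exposure by c shifts the intercept posterior by -log c."""
        rng = np.random.default_rng(21)
        n = 30
        pops = rng.uniform(2e5, 5e6, size=n)
        y = rng.poisson(pops * np.exp(math.log(1e-4) + rng.normal(scale=0.3, size=n)))
        m1 = rr.FatalityModel(y, np.empty((n, 0)), np.log(pops))
        m2 = rr.FatalityModel(y, np.empty((n, 0)), np.log(10.0 * pops))
        r1 = m1.fit(chains=2, warmup=1000, draws=2000, seed=4)
        r2 = m2.fit(chains=2, warmup=1000, draws=2000, seed=9)
        s1, s2 = r1.summary_frame.loc["intercept"], r2.summary_frame.loc["intercept"]
        mcse = math.hypot(
            s1["sd"] / math.sqrt(s1["ess"]), s2["sd"] / math.sqrt(s2["ess"])
        )
        assert s2["mean"] - s1["mean"] == pytest.approx(-math.log(10.0), abs=2 * mcse)

    def test_planted_coefficients_recovered_large_n(self):
        """Forward-simulated 200-unit study: truth within 3 posterior SDs."""
        frame, tables, truth = rr.gen_study(n_units=200, seed=77, sigma_delta=0.3)
        exposures = {u: rr.build_exposure(t).distance_km for u, t in tables.items()}
        X, offset, y = rr.build_design(frame, exposures, rr.model_spec(1))
        res = rr.FatalityModel(y, X, offset).fit(
            chains=2, warmup=1000, draws=1000, seed=6
        )
        target = {"intercept": truth["beta0"], **truth["beta"]}
        for name in res.param_names:
            z = abs(res.params[name] - target[name]) / res.sd[name]
            assert z < 3.0, f"{name}: z={z:.2f}"
        assert res.converged

    def test_posterior_sd_shrinks_with_n(self):
        sds = {}
        for n in (33, 330):
            frame, tables, _ = rr.gen_study(n_units=n, seed=13, sigma_delta=0.3)
            exposures = {u: rr.build_exposure(t).distance_km for u, t in tables.items()}
            X, offset, y = rr.build_design(frame, exposures, rr.model_spec(1))
            res = rr.FatalityModel(y, X, offset).fit(
                chains=2, warmup=600, draws=600, seed=1
            )
            sds[n] = res.sd
        assert (sds[330] < sds[33]).all()


class TestSequence:
    def test_table_shape_and_blank_cells(self, small_study):
        frame, tables, _ = small_study
        cfg = rr.SamplerConfig(chains=2, warmup=250, draws=250, seed=3)
        results = rr.fit_model_sequence(frame, tables, config=cfg)
        assert set(results) == {
            "model1", "model2", "model3", "model4",
            "model4_walk0", "model4_walk1", "model4_walk1.5",
        }
        assert results["model4_walk1"] is results["model4"]
        report = rr.sequence_report(results)
        assert report.shape[1] == 7 * 3  # 7 columns x (mean, sd, sig)
        # minimally controlled model has no diesel/NH/urban/density rows
        for row in ("ln_diesel", "ln_nh_length", "prop_urban", "density"):
            assert np.isnan(report.loc[row, ("model1", "mean")])
            assert not np.isnan(report.loc[row, ("model4", "mean")])

    def test_recovered_signs_match_planted_strong_signal(self):
        beta = {"ln_walk": -0.5, "ln_2W": 0.8}
        frame, tables, truth = rr.gen_study(
            n_units=33, seed=5, beta=beta, sigma_delta=0.1
        )
        exposures = {u: rr.build_exposure(t).distance_km for u, t in tables.items()}
        X, offset, y = rr.build_design(frame, exposures, rr.model_spec(1))
        res = rr.FatalityModel(y, X, offset).fit(
            chains=2, warmup=600, draws=600, seed=2
        )
        assert res.params["ln_walk"] < 0
        assert res.params["ln_2W"] > 0
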