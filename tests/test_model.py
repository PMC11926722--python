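import datetime as dt
import math

import numpy as np
import pytest
import scipy.optimize
import scipy.linalg

import sentirisk as sr
from sentirisk import model as M
from sentirisk.panel import ClimatePanel, SentimentPanel


class _Toy:
    def __init__(self, panel, climate, graph, params):
        self.panel, self.climate, self.graph, self.params = (
            panel, climate, graph, params)


def _toy_panels(n_rows, n_cols, n_weeks, seed, mean_ttw=50):
    """Small bundle; weeks below the generator minimum are sliced off."""
    gen_weeks = max(n_weeks, 8)
    b = sr.default_bundle(seed=seed, n_rows=n_rows, n_cols=n_cols,
                          n_weeks=gen_weeks, mean_ttw=mean_ttw)
    if gen_weeks == n_weeks:
        return b
    panel = SentimentPanel(b.panel.region_ids,
                           b.panel.week_starts[:n_weeks],
                           b.panel.ntw[:, :n_weeks],
                           b.panel.ttw[:, :n_weeks])
    climate = ClimatePanel(b.climate.region_ids,
                           b.climate.week_starts[:n_weeks],
                           b.climate.temperature[:, :n_weeks],
                           b.climate.precipitation[:, :n_weeks])
    return _Toy(panel, climate, b.graph, b.params)


class TestComputeThetaTot:
    def test_ratio_of_sums(self):
        origin = dt.date(2019, 1, 1)
        weeks = (origin, origin + dt.timedelta(days=7))
        panel = SentimentPanel(("a", "b"), weeks,
                               ntw=[[1, 0], [2, 0]], ttw=[[4, 2], [3, 1]])
        assert M.compute_theta_tot(panel) == pytest.approx(0.3)

    def test_all_negative_gives_one(self):
        origin = dt.date(2019, 1, 1)
        panel = SentimentPanel(("a", "b"), (origin,),
                               ntw=[[2], [3]], ttw=[[2], [3]])
        assert M.compute_theta_tot(panel) == 1.0

    def test_permutation_invariant(self):
        b = _toy_panels(2, 2, 20, seed=0)
        theta = M.compute_theta_tot(b.panel)
        flipped = SentimentPanel(
            b.panel.region_ids, b.panel.week_starts,
            b.panel.ntw[::-1], b.panel.ttw[::-1],
        )
        assert M.compute_theta_tot(flipped) == theta

    def test_zero_exposure_rejected(self):
        origin = dt.date(2019, 1, 1)
        panel = SentimentPanel(("a", "b"), (origin,), ntw=[[0], [0]],
                               ttw=[[0], [0]])
        with pytest.raises(ValueError):
            M.compute_theta_tot(panel)


class TestBuildModel:
    def test_block_dimensions(self):
        b = _toy_panels(1, 2, 10, seed=1)
        spec = M.build_model(b.panel, b.climate, b.graph)
        assert spec.slices["field"].stop - spec.slices["field"].start == 20
        assert spec.slices["temperature"].stop - \
            spec.slices["temperature"].start == 4
        assert spec.slices["precipitation"].stop - \
            spec.slices["precipitation"].start == 3
        assert spec.n_latent == 1 + 20 + 4 + 3

    def test_interaction_block(self):
        b = _toy_panels(1, 2, 10, seed=1)
        spec = M.build_model(b.panel, b.climate, b.graph,
                             config=M.FitConfig(interaction=True))
        sl = spec.slices["interaction"]
        assert sl.stop - sl.start == 12

    def test_zero_ttw_cells_dropped_from_likelihood(self):
        b = _toy_panels(1, 2, 10, seed=1)
        ttw = b.panel.ttw.copy()
        ntw = b.panel.ntw.copy()
        ttw[0, 0] = 0
        ntw[0, 0] = 0
        panel = SentimentPanel(b.panel.region_ids, b.panel.week_starts,
                               ntw, ttw)
        spec = M.build_model(panel, b.climate, b.graph)
        assert len(spec.y) == 19
        # the field coordinate is retained in the latent vector
        assert spec.slices["field"].stop - spec.slices["field"].start == 20

    def test_region_order_alignment(self):
        b = _toy_panels(1, 2, 10, seed=1)
        rev = SentimentPanel(
            tuple(reversed(b.panel.region_ids)), b.panel.week_starts,
            b.panel.ntw[::-1], b.panel.ttw[::-1],
        )
        spec = M.build_model(rev, b.climate, b.graph)
        assert np.array_equal(
            spec.panel.ntw, b.panel.ntw
        )


class TestLogPosterior:
    def test_null_latents_equal_poisson_loglik(self):
        b = _toy_panels(2, 2, 12, seed=2)
        spec = M.build_model(b.panel, b.climate, b.graph)
        u = np.zeros(spec.n_latent)
        value = M.log_posterior(u, spec)
        mask = b.panel.ttw > 0
        mu = spec.theta_tot * b.panel.ttw[mask]
        loglik = float((b.panel.ntw[mask] * np.log(mu) - mu).sum())
        # prior terms at zero contribute only normalization constants
        const = value - loglik
        value2 = M.log_posterior(u, spec)
        assert value2 - loglik == pytest.approx(const)

    def test_matches_hand_coded_dense_computation(self):
        """Joint posterior equals an independently assembled dense version."""
        b = _toy_panels(1, 2, 4, seed=3, mean_ttw=30)
        cfg = M.FitConfig(field_structure="iid", hypers=M.Hyperparameters(
            tau_field=2.0, rho=0.0, tau_temp=1.5, tau_precip=0.5))
        spec = M.build_model(b.panel, b.climate, b.graph, config=cfg)
        rng = np.random.default_rng(0)
        u = 0.01 * rng.standard_normal(spec.n_latent)
        # hand-build: likelihood + independent normal priors (all blocks
        # full-rank here), dropping x-independent constants consistently
        got = M.log_posterior(u, spec)
        b0 = u[0]
        field = u[spec.slices["field"]]
        ft = u[spec.slices["temperature"]]
        fp = u[spec.slices["precipitation"]]
        eta = (spec.offset + b0
               + field[spec.cell_index[:, 0] * 4 + spec.cell_index[:, 1]]
               + ft[spec.tcat[spec.cell_index[:, 0], spec.cell_index[:, 1]]]
               + fp[spec.pcat[spec.cell_index[:, 0], spec.cell_index[:, 1]]])
        loglik = float(spec.y @ eta - np.exp(eta).sum())

        def normal_term(x, tau):
            n = len(x)
            return (0.5 * n * math.log(tau) - 0.5 * n * math.log(2 * math.pi)
                    - 0.5 * tau * float(x @ x))

        expected = (
            loglik
            + normal_term(np.atleast_1d(b0), 1e-6)
            + normal_term(field, 2.0)
            + normal_term(ft, 1.5)
            + normal_term(fp, 0.5)
            + M._hyperprior_logpdf(cfg.hypers, cfg)
        )
        assert got == pytest.approx(expected, abs=1e-12 * max(1, abs(expected)))

    def test_intercept_field_tradeoff_keeps_likelihood(self):
        # adding c to the intercept and -c to every field cell leaves the
        # likelihood part unchanged (linear predictor identity)
        b = _toy_panels(1, 2, 4, seed=3, mean_ttw=30)
        cfg = M.FitConfig(field_structure="iid")
        spec = M.build_model(b.panel, b.climate, b.graph, config=cfg)
        u = np.zeros(spec.n_latent)
        v = u.copy()
        v[0] += 0.1
        v[spec.slices["field"]] -= 0.1
        eta_u = spec.offset + spec.design @ u
        eta_v = spec.offset + spec.design @ v
        assert np.allclose(eta_u, eta_v)

    def test_non_finite_latents_rejected(self):
        b = _toy_panels(1, 2, 4, seed=3)
        spec = M.build_model(b.panel, b.climate, b.graph)
        u = np.zeros(spec.n_latent)
        u[0] = np.inf
        with pytest.raises(ValueError):
            M.log_posterior(u, spec)


class TestFit:
    def test_intercept_only_closed_form(self):
        """Infinite random-effect precisions reduce to the Poisson GLM."""
        b = _toy_panels(2, 2, 20, seed=4, mean_ttw=200)
        theta = 0.17
        cfg = M.FitConfig(
            hypers=M.Hyperparameters(tau_field=1e10, tau_temp=1e10,
                                     tau_precip=1e10),
            theta_tot=theta,
        )
        spec = M.build_model(b.panel, b.climate, b.graph, config=cfg)
        res = M.fit(spec)
        b0 = res.block_mean("intercept")[0]
        closed = math.log(b.panel.ntw.sum() / (theta * b.panel.ttw.sum()))
        assert b0 == pytest.approx(closed, abs=1e-8)

    def test_mode_matches_brute_force(self):
        """Fitter's latent mode equals dense numerical maximization.

        The oracle parameterizes the constraint subspace with an
        orthonormal null-space basis and maximizes the exact joint log
        posterior with a generic optimizer.
        """
        b = _toy_panels(2, 2, 6, seed=5, mean_ttw=40)
        cfg = M.FitConfig(hypers=M.Hyperparameters(tau_field=4.0, rho=0.5,
                                                   tau_temp=2.0,
                                                   tau_precip=2.0))
        spec = M.build_model(b.panel, b.climate, b.graph, config=cfg)
        res = M.fit(spec)

        q, c = spec.prior_matrices()
        basis = scipy.linalg.null_space(c)
        qd = q.toarray()
        a = spec.design.toarray()

        def neg_logpost(z):
            u = basis @ z
            eta = spec.offset + a @ u
            return -(float(spec.y @ eta - np.exp(eta).sum())
                     - 0.5 * float(u @ qd @ u))

        z0 = np.zeros(basis.shape[1])
        opt = scipy.optimize.minimize(
            neg_logpost, z0, method="L-BFGS-B",
            options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12},
        )
        u_oracle = basis @ opt.x
        assert np.max(np.abs(u_oracle - res.mean)) < 1e-4

    def test_deterministic(self):
        b = _toy_panels(2, 2, 20, seed=6)
        spec = M.build_model(b.panel, b.climate, b.graph)
        r1, r2 = M.fit(spec), M.fit(spec)
        assert np.array_equal(r1.mean, r2.mean)
        assert np.array_equal(r1.sd, r2.sd)

    def test_constrained_blocks_sum_to_zero(self):
        b = _toy_panels(2, 2, 20, seed=6)
        spec = M.build_model(b.panel, b.climate, b.graph)
        res = M.fit(spec)
        assert abs(res.block_mean("temperature").sum()) < 1e-8
        assert abs(res.block_mean("precipitation").sum()) < 1e-8
        field = res.block_mean("field").reshape(4, 20)
        assert np.max(np.abs(field.sum(axis=0))) < 1e-8

    def test_sd_nonnegative_and_diagnostics(self):
        b = _toy_panels(2, 2, 20, seed=6)
        spec = M.build_model(b.panel, b.climate, b.graph)
        res = M.fit(spec)
        assert np.all(res.sd >= 0)
        assert res.converged
        assert res.n_iter >= 1
        assert np.isfinite(res.log_marginal_likelihood)

    def test_monotone_data_response(self):
        # more negatives in a cell never lower that cell's fitted log-RR
        b = _toy_panels(2, 2, 10, seed=7, mean_ttw=100)
        spec = M.build_model(b.panel, b.climate, b.graph)
        res = M.fit(spec)
        i, t = 1, 4
        ntw = b.panel.ntw.copy()
        ntw[i, t] = min(ntw[i, t] + 20, b.panel.ttw[i, t])
        panel2 = SentimentPanel(b.panel.region_ids, b.panel.week_starts,
                                ntw, b.panel.ttw)
        cfg2 = M.FitConfig(theta_tot=spec.theta_tot)
        spec2 = M.build_model(panel2, b.climate, b.graph, config=cfg2)
        res2 = M.fit(spec2)
        T = b.panel.n_weeks

        def cell_logrr(r, s):
            f = r.block_mean("field").reshape(4, T)
            return (r.block_mean("intercept")[0] + f[i, t]
                    + r.block_mean("temperature")[s.tcat[i, t]]
                    + r.block_mean("precipitation")[s.pcat[i, t]])

        assert cell_logrr(res2, spec2) >= cell_logrr(res, spec) - 1e-10

    def test_variance_covariance_consistency(self):
        b = _toy_panels(2, 2, 10, seed=8)
        spec = M.build_model(b.panel, b.climate, b.graph)
        res = M.fit(spec)
        e = np.zeros((2, spec.n_latent))
        e[0, spec.slices["temperature"].start] = 1.0
        e[1, spec.slices["temperature"].start + 1] = 1.0
        v = res.cov_linear(e)
        assert v[0, 0] == pytest.approx(
            res.block_sd("temperature")[0] ** 2, rel=1e-8)
        assert v[1, 1] == pytest.approx(
            res.block_sd("temperature")[1] ** 2, rel=1e-8)

    def test_field_structure_variants_fit(self):
        b = _toy_panels(2, 2, 12, seed=9)
        for structure in ("icar_ar1", "icar_iid", "iid_ar1", "iid"):
            cfg = M.FitConfig(field_structure=structure)
            spec = M.build_model(b.panel, b.climate, b.graph, config=cfg)
            res = M.fit(spec)
            assert res.converged

    def test_empirical_bayes_prefers_sensible_tau(self):
        """EB marginal likelihood peaks near the generative precision."""
        params = sr.TrueParams(field_tau=100.0, ar_rho=0.7,
                               event_effect=0.0)
        b = sr.default_bundle(seed=12, n_rows=2, n_cols=2, n_weeks=80,
                              mean_ttw=3000, params=params, with_event=False)
        cfg = M.FitConfig(
            hypers=M.Hyperparameters(tau_field=100.0, rho=0.7),
            empirical_bayes=True,
            eb_tau_factors=(0.04, 0.2, 1.0, 5.0, 25.0),
        )
        spec = M.build_model(b.panel, b.climate, b.graph, config=cfg)
        res = M.fit(spec)
        # the selected precision is within a factor 5 of the truth,
        # i.e. the interior of the grid, not the extremes
        assert 20.0 <= res.hypers.tau_field <= 500.0


class TestEffectSummary:
    def test_percent_scale_convention(self):
        b = _toy_panels(2, 2, 20, seed=6)
        spec = M.build_model(b.panel, b.climate, b.graph)
        res = M.fit(spec)
        es = M.effect_summary(res, spec, "temperature")
        assert np.allclose(es.percent_mean, 100 * (np.exp(es.mean) - 1))
        # a mean of 0.0198 on the log scale is ~ +2.0% relative risk
        assert 100 * (math.exp(0.0198) - 1) == pytest.approx(2.0, abs=0.01)

    def test_interval_ordering(self):
        b = _toy_panels(2, 2, 20, seed=6)
        spec = M.build_model(b.panel, b.climate, b.graph)
        res = M.fit(spec)
        for eff in ("temperature", "precipitation"):
            es = M.effect_summary(res, spec, eff)
            assert np.all(es.lower95 <= es.mean)
            assert np.all(es.mean <= es.upper95)
            assert np.array_equal(
                es.significant, (es.lower95 > 0) | (es.upper95 < 0))

    def test_occupancy_counts_cells(self):
        b = _toy_panels(2, 2, 20, seed=6)
        spec = M.build_model(b.panel, b.climate, b.graph)
        res = M.fit(spec)
        es = M.effect_summary(res, spec, "temperature")
        assert es.occupancy.sum() == len(spec.y)

    def test_unknown_effect_rejected(self):
        b = _toy_panels(2, 2, 10, seed=6)
        spec = M.build_model(b.panel, b.climate, b.graph)
        res = M.fit(spec)
        with pytest.raises(ValueError):
            M.effect_summary(res, spec, "humidity")
        with pytest.raises(ValueError):
            M.effect_summary(res, spec, "interaction")


class TestRRDifference:
    def _fit_long(self, seed=0, **params_kw):
        b = sr.default_bundle(seed=seed, n_rows=2, n_cols=2, n_weeks=140,
                              mean_ttw=800,
                              params=sr.TrueParams(**params_kw))
        spec = M.build_model(b.panel, b.climate, b.graph)
        return b, spec, M.fit(spec)

    def test_flag_iff_interval_excludes_zero(self):
        b, spec, res = self._fit_long(seed=3)
        rr = M.rr_difference(res, spec, sr.FLOOD_WINDOWS)
        assert np.array_equal(
            rr.significant, (rr.lower95 > 0) | (rr.upper95 < 0))
        assert np.all(rr.lower95 <= rr.delta)
        assert np.all(rr.delta <= rr.upper95)

    def test_identical_field_and_covariates_gives_zero(self):
        """Constant climate and a constant-rate panel: Delta == 0."""
        origin = dt.date(2019, 1, 1)
        n_weeks = 140
        weeks = tuple(origin + dt.timedelta(days=7 * t)
                      for t in range(n_weeks))
        g = sr.make_region_graph(1, 2, seed=0)
        temp = np.full((2, n_weeks), 10.0)
        prec = np.full((2, n_weeks), 0.02)
        climate = ClimatePanel(g.region_ids, weeks, temp, prec)
        ntw = np.full((2, n_weeks), 10)
        ttw = np.full((2, n_weeks), 100)
        panel = SentimentPanel(g.region_ids, weeks, ntw, ttw)
        spec = M.build_model(panel, climate, g)
        res = M.fit(spec)
        rr = M.rr_difference(res, spec, sr.FLOOD_WINDOWS)
        assert np.max(np.abs(rr.delta)) < 1e-6
        assert not rr.significant.any()

    def test_window_without_weeks_rejected(self):
        b = _toy_panels(2, 2, 20, seed=6)  # only 20 weeks: windows empty
        spec = M.build_model(b.panel, b.climate, b.graph)
        res = M.fit(spec)
        with pytest.raises(ValueError):
            M.rr_difference(res, spec, sr.FLOOD_WINDOWS)


class TestMcmcCrosscheck:
    def test_laplace_close_to_mcmc_on_small_model(self):
        b = _toy_panels(1, 2, 8, seed=10, mean_ttw=60)
        spec = M.build_model(b.panel, b.climate, b.graph)
        res = M.fit(spec)
        out = M.mcmc_crosscheck(spec, res, n_samples=3000, burn_in=300,
                                seed=1)
        assert out["acceptance_rate"] > 0.3
        sl = spec.slices["temperature"]
        diff = np.abs(out["mean"][sl] - res.mean[sl])
        # agreement within a fraction of the posterior sd
        assert np.all(diff < 0.5 * np.maximum(res.sd[sl], 1e-3))
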