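"""DHGLM joint density, gradient, sampling and diagnostics."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from urbanvar.design import DHGLMData
from urbanvar.dhglm import (
    DHGLMParams,
    PosteriorDraws,
    RandomEffects,
    _Layout,
    check_convergence,
    log_density,
    make_logp_grad,
    sample_posterior,
)
from urbanvar.types import MCMCSettings

LOG_2PI = math.log(2 * math.pi)


def tiny_data(n=20, seed=0, n_hab=2):
    """A hand-sized dataset with explicit arrays (no generator involvement)."""
    rng = np.random.default_rng(seed)
    K_y, K_s, K_c = 3, 2, 4
    data = DHGLMData(
        y=rng.standard_normal(n),
        X=np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)]),
        Z=np.column_stack([np.ones(n), rng.standard_normal(n)]),
        mean_names=["intercept", "habitat_urban"],
        disp_names=["intercept", "heterogeneity"],
        year_idx=rng.integers(0, K_y, n),
        sys_idx=rng.integers(0, K_s, n),
        clust_idx=rng.integers(0, K_c, n),
        cluster_habitat=(np.array([0, 1, 0, 1]) if n_hab == 2 else np.zeros(K_c, dtype=np.int64)),
        n_hab=n_hab,
        year_levels=[2015, 2016, 2017],
        sys_levels=["A", "B"],
        clust_levels=["c0", "c1", "c2", "c3"],
    )
    data.validate()
    return data


def random_params_effects(data, seed=1):
    rng = np.random.default_rng(seed)
    nh = data.n_hab
    params = DHGLMParams(
        beta=rng.standard_normal(len(data.mean_names)) * 0.5,
        gamma=rng.standard_normal(len(data.disp_names)) * 0.3,
        sd_year=0.4, sd_sys=0.8, sd_clust=rng.uniform(0.2, 0.6, nh),
        sdv_sys=0.3, sdv_clust=rng.uniform(0.1, 0.4, nh),
        r_sys=-0.2, r_clust=rng.uniform(-0.5, 0.5, nh),
    )
    eff = RandomEffects(
        a_year=0.3 * rng.standard_normal(data.n_years),
        a_sys=0.5 * rng.standard_normal(data.n_systems),
        b_sys=0.2 * rng.standard_normal(data.n_systems),
        a_clust=0.4 * rng.standard_normal(data.n_clusters),
        b_clust=0.2 * rng.standard_normal(data.n_clusters),
    )
    return params, eff


def oracle_log_density(data, params, eff):
    """Independent per-term computation with scipy distributions."""
    lp = 0.0
    for b in np.concatenate([params.beta, params.gamma]):
        lp += stats.norm.logpdf(b)
    for sd in [params.sd_year, params.sd_sys, params.sdv_sys, *params.sd_clust, *params.sdv_clust]:
        lp += stats.halfnorm.logpdf(sd)
    for r in [params.r_sys, *params.r_clust]:
        lp += math.log(0.75 * (1 - r**2))  # LKJ(2) for a 2x2 correlation
    for a in eff.a_year:
        lp += stats.norm.logpdf(a, scale=params.sd_year)
    for k in range(data.n_systems):
        cov = np.array(
            [[params.sd_sys**2, params.r_sys * params.sd_sys * params.sdv_sys],
             [params.r_sys * params.sd_sys * params.sdv_sys, params.sdv_sys**2]]
        )
        lp += stats.multivariate_normal.logpdf([eff.a_sys[k], eff.b_sys[k]], cov=cov)
    for c in range(data.n_clusters):
        h = data.cluster_habitat[c]
        s1, s2, r = params.sd_clust[h], params.sdv_clust[h], params.r_clust[h]
        cov = np.array([[s1**2, r * s1 * s2], [r * s1 * s2, s2**2]])
        lp += stats.multivariate_normal.logpdf([eff.a_clust[c], eff.b_clust[c]], cov=cov)
    for i in range(data.n):
        mu = (data.X[i] @ params.beta + eff.a_year[data.year_idx[i]]
              + eff.a_sys[data.sys_idx[i]] + eff.a_clust[data.clust_idx[i]])
        sig = math.exp(data.Z[i] @ params.gamma + eff.b_sys[data.sys_idx[i]]
                       + eff.b_clust[data.clust_idx[i]])
        lp += stats.norm.logpdf(data.y[i], loc=mu, scale=sig)
    return lp


class TestLogDensity:
    def test_matches_per_term_oracle(self):
        data = tiny_data()
        params, eff = random_params_effects(data)
        assert log_density(data, params, eff) == pytest.approx(
            oracle_log_density(data, params, eff), abs=1e-8
        )

    def test_matches_oracle_in_pooled_cluster_mode(self):
        data = tiny_data(n_hab=1)
        params, eff = random_params_effects(data)
        assert log_density(data, params, eff) == pytest.approx(
            oracle_log_density(data, params, eff), abs=1e-8
        )

    def test_standard_normal_data_term_at_zero(self):
        # y = 0, all effects zero, sigma = 1: the data term is -0.5 ln(2 pi)
        data = tiny_data(n=1)
        data.y = np.zeros(1)
        data.X = np.zeros((1, 2))
        data.Z = np.zeros((1, 2))
        params = DHGLMParams(
            beta=np.zeros(2), gamma=np.zeros(2), sd_year=0.5, sd_sys=0.5,
            sd_clust=[0.5, 0.5], sdv_sys=0.5, sdv_clust=[0.5, 0.5],
            r_sys=0.0, r_clust=[0.0, 0.0],
        )
        eff = RandomEffects(np.zeros(3), np.zeros(2), np.zeros(2), np.zeros(4), np.zeros(4))
        with_data = log_density(data, params, eff)
        empty = tiny_data(n=1)
        empty.y = np.empty(0)
        empty.X = np.empty((0, 2))
        empty.Z = np.empty((0, 2))
        empty.year_idx = empty.sys_idx = empty.clust_idx = np.empty(0, dtype=np.int64)
        without_data = log_density(empty, params, eff)
        assert with_data - without_data == pytest.approx(-0.5 * LOG_2PI, abs=1e-12)

    def test_data_term_decreases_with_residual_distance(self):
        data = tiny_data(n=1)
        data.X = np.zeros((1, 2))
        data.Z = np.zeros((1, 2))
        params, eff = random_params_effects(data)
        eff = RandomEffects(np.zeros(3), np.zeros(2), np.zeros(2), np.zeros(4), np.zeros(4))
        lps = []
        for y in (0.0, 0.5, 1.0, 2.0):
            data.y = np.array([y])
            lps.append(log_density(data, params, eff))
        assert all(a > b for a, b in zip(lps, lps[1:]))

    @staticmethod
    def _jacobians(theta, layout, data):
        """Log-Jacobian of the map from the packed unconstrained vector to
        (constrained parameters, random-effect values)."""
        s = layout.slices
        jac = sum(
            float(theta[s[nm]].sum())
            for nm in ("lam_year", "lam_sys", "lam_clust", "lam_vsys", "lam_vclust")
        )
        rs = np.concatenate([np.tanh(theta[s["rho_sys"]]), np.tanh(theta[s["rho_clust"]])])
        jac += float(np.sum(np.log1p(-rs**2)))
        r_s = math.tanh(theta[s["rho_sys"]][0])
        c_s = math.sqrt(1 - r_s**2)
        lam_vs = theta[s["lam_vsys"]][0]
        lam_vc = theta[s["lam_vclust"]]
        r_c = np.tanh(theta[s["rho_clust"]])
        c_c = np.sqrt(1 - r_c**2)
        h = data.cluster_habitat
        if layout.parameterisation in ("mixed", "noncentred"):
            # b | a innovations -> b values
            jac += data.n_systems * (lam_vs + math.log(c_s))
            jac += float(np.sum(lam_vc[h] + np.log(c_c[h])))
        if layout.parameterisation == "noncentred":
            jac += data.n_years * theta[s["lam_year"]][0]
            jac += data.n_systems * theta[s["lam_sys"]][0]
            jac += float(np.sum(theta[s["lam_clust"]][h]))
        return jac

    @pytest.mark.parametrize("mode", ["centred", "mixed", "noncentred"])
    def test_packed_density_equals_structured_plus_jacobians(self, mode):
        data = tiny_data()
        layout = _Layout.for_data(data, mode)
        rng = np.random.default_rng(4)
        theta = 0.4 * rng.standard_normal(layout.dim)
        lp_packed, _ = make_logp_grad(data, layout)(theta)
        params, eff = layout.unpack(theta)
        jac = self._jacobians(theta, layout, data)
        assert lp_packed == pytest.approx(log_density(data, params, eff) + jac, abs=1e-10)

    @pytest.mark.parametrize("mode", ["centred", "mixed", "noncentred"])
    def test_gradient_matches_finite_differences(self, mode):
        data = tiny_data()
        layout = _Layout.for_data(data, mode)
        lg = make_logp_grad(data, layout)
        rng = np.random.default_rng(5)
        theta = 0.4 * rng.standard_normal(layout.dim)
        _, grad = lg(theta)
        eps = 1e-6
        for i in range(layout.dim):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fd = (lg(tp)[0] - lg(tm)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=5e-5, abs=5e-5)

    def test_pack_unpack_round_trip_in_every_parameterisation(self):
        data = tiny_data()
        for mode in ("centred", "mixed", "noncentred"):
            layout = _Layout.for_data(data, mode)
            rng = np.random.default_rng(6)
            theta = 0.4 * rng.standard_normal(layout.dim)
            params, eff = layout.unpack(theta)
            np.testing.assert_allclose(layout.pack(params, eff), theta, atol=1e-12)


class TestSamplePosterior:
    def test_default_settings_retain_4000_draws(self):
        # 4 chains x (10000 - 6000) / 4
        assert MCMCSettings().retained == 4000

    def test_retained_count_honours_thinning(self):
        data = tiny_data(n=30)
        settings = MCMCSettings(chains=2, iterations=160, warmup=80, thin=2)
        draws = sample_posterior(data, settings, seed=0)
        assert draws.retained == settings.retained == 2 * 40

    def test_identical_seed_gives_identical_draws(self):
        data = tiny_data(n=30)
        settings = MCMCSettings(chains=2, iterations=200, warmup=100)
        a = sample_posterior(data, settings, seed=3)
        b = sample_posterior(data, settings, seed=3)
        np.testing.assert_array_equal(a.array, b.array)
        c = sample_posterior(data, settings, seed=4)
        assert not np.array_equal(a.array, c.array)

    def test_prior_only_run_reproduces_the_priors(self):
        # no data: fixed-effect posteriors are their N(0,1) priors
        data = tiny_data(n=1)
        data.y = np.empty(0)
        data.X = np.empty((0, 2))
        data.Z = np.empty((0, 2))
        data.year_idx = data.sys_idx = data.clust_idx = np.empty(0, dtype=np.int64)
        draws = sample_posterior(data, MCMCSettings(chains=2, iterations=1500, warmup=500), seed=1)
        for nm in ("b_mean[intercept]", "b_mean[habitat_urban]", "b_disp[intercept]"):
            x = draws.get(nm)
            assert abs(x.mean()) < 0.15
            assert x.std() == pytest.approx(1.0, abs=0.15)

    def test_fixed_effects_agree_with_independent_mixed_model_fit(self):
        """With dispersion effects generated at ~zero, the mean part is a
        standard Gaussian mixed model; posterior fixed effects must agree
        with a (frequentist) mixed-model fit within its standard errors."""
        import statsmodels.formula.api as smf
        import pandas as pd

        rng = np.random.default_rng(8)
        n, K_c = 600, 12
        clust = rng.integers(0, K_c, n)
        x1 = rng.integers(0, 2, n).astype(float)
        a_c = 0.4 * rng.standard_normal(K_c)
        beta0, beta1 = 0.3, -0.5
        y = beta0 + beta1 * x1 + a_c[clust] + 0.6 * rng.standard_normal(n)
        data = DHGLMData(
            y=y,
            X=np.column_stack([np.ones(n), x1]),
            Z=np.ones((n, 1)),
            mean_names=["intercept", "habitat_urban"],
            disp_names=["intercept"],
            year_idx=np.zeros(n, dtype=np.int64),
            sys_idx=np.zeros(n, dtype=np.int64),
            clust_idx=clust.astype(np.int64),
            cluster_habitat=np.zeros(K_c, dtype=np.int64),
            n_hab=1,
            year_levels=[0], sys_levels=[0], clust_levels=list(range(K_c)),
        )
        draws = sample_posterior(data, MCMCSettings(chains=2, iterations=900, warmup=450), seed=2)
        df = pd.DataFrame({"y": y, "x1": x1, "g": clust})
        ml = smf.mixedlm("y ~ x1", df, groups=df["g"]).fit()
        for nm, key in (("Intercept", "b_mean[intercept]"), ("x1", "b_mean[habitat_urban]")):
            post = draws.get(key).mean()
            assert post == pytest.approx(ml.params[nm], abs=3 * ml.bse[nm])


class TestCheckConvergence:
    @staticmethod
    def _draws_from(arr):
        names = ["p"]
        return PosteriorDraws(names, arr[..., None])

    def test_iid_chains_pass(self):
        rng = np.random.default_rng(0)
        d = self._draws_from(rng.standard_normal((4, 500)))
        rep = check_convergence(d, ess_min=400)
        assert rep["pass"]
        assert rep["worst_rhat"] == pytest.approx(1.0, abs=0.02)
        assert rep["min_ess"] > 0.5 * 2000

    def test_disjoint_constant_chains_fail(self):
        a = np.concatenate([np.zeros((1, 400)), np.ones((1, 400))]) + 1e-6 * np.random.default_rng(1).standard_normal((2, 400))
        rep = check_convergence(self._draws_from(a))
        assert not rep["pass"]
        assert rep["worst_rhat"] > 1.01

    def test_single_chain_is_an_error(self):
        d = self._draws_from(np.random.default_rng(0).standard_normal((1, 100)))
        with pytest.raises(ValueError, match="chain"):
            check_convergence(d)

    def test_ess_gate_is_strictly_above_400(self):
        rng = np.random.default_rng(2)
        d = self._draws_from(rng.standard_normal((2, 150)))  # only 300 draws
        rep = check_convergence(d)
        assert rep["min_ess"] <= 400 or rep["pass"] == (rep["min_ess"] > 400)
        assert not rep["pass"]
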