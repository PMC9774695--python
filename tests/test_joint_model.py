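"""Joint model: design assembly, hazard machinery against quadrature
oracles, log-posterior structure, and sampler correctness."""

import numpy as np
import pandas as pd
import pytest

from herdsurv import (
    JointModelParams,
    MCMCConfig,
    PriorConfig,
    build_design,
    cumulative_hazard,
    fit_mcmc,
    hazard,
    load_fit,
    log_posterior,
    make_knots,
    preprocess,
    save_fit,
    trajectory_value_and_slope,
)
from herdsurv.io import OUTCOME_KINDS
from herdsurv.joint_model import _beta_conditional, _init_state
from herdsurv.synthetic import SyntheticConfig, generate_herd


def _default_specs():
    grid = np.arange(5, 306)
    return {k: make_knots(grid, k) for k in OUTCOME_KINDS}


def _params(alpha=(0.0, 0.0, 0.0), gamma=(0.0, 0.0), log_h0=None, specs=None):
    specs = specs or _default_specs()
    cuts = np.linspace(0.0, 900.0, 7)
    beta = {}
    for k, (b0, scale) in zip(OUTCOME_KINDS, ((28.0, 5.0), (470.0, 80.0), (460.0, 30.0))):
        d = specs[k].dim
        beta[k] = np.r_[b0, np.linspace(scale, -scale / 2, d), 0.5, 1.0, -0.2]
    return JointModelParams(
        beta=beta,
        sigma={"MY": 3.0, "BW": 15.0, "RUM": 60.0},
        D=np.eye(13),
        gamma=np.asarray(gamma, dtype=float),
        alpha=dict(zip(OUTCOME_KINDS, alpha)),
        log_h0=np.full(6, -7.0) if log_h0 is None else np.asarray(log_h0, dtype=float),
        cuts=cuts,
    )


def _zero_b():
    return {k: np.zeros(1 + s.dim) for k, s in _default_specs().items()}


class TestDesign:
    def test_stacked_random_effect_dimension(self, design120):
        # 1 intercept + spline dim per outcome: (1+4) + (1+4) + (1+2)
        assert design120.q == 13

    def test_longitudinal_row_count(self, clean120):
        clean, _, quart = clean120
        specs = {k: make_knots(clean.sensor["dim"].to_numpy(), k) for k in OUTCOME_KINDS}
        design = build_design(clean, specs, afc_quartiles=quart)
        for k, col in zip(OUTCOME_KINDS, ("my_kg", "bw_kg", "rum_min")):
            assert design.outcomes[k].y.size == clean.sensor[col].notna().sum()

    def test_low_afc_is_reference_category(self, design120, clean120):
        clean, _, _ = clean120
        low = clean.cows["afc_cat"].to_numpy() == "low"
        assert np.all(design120.W[low] == 0.0)

    def test_cow_without_observations_rejected(self, clean120):
        clean, _, quart = clean120
        broken = clean.copy()
        cow0 = broken.cows["cow_id"].iloc[0]
        broken.sensor.loc[broken.sensor["cow_id"] == cow0, "rum_min"] = np.nan
        specs = _default_specs()
        with pytest.raises(ValueError, match=cow0):
            build_design(broken, specs, afc_quartiles=quart)


class TestTrajectoryAndHazard:
    def test_reference_cow_traces_fixed_curve(self):
        specs = _default_specs()
        params = _params()
        t = np.linspace(5, 305, 50)
        from herdsurv.splines import ns_basis

        for k in OUTCOME_KINDS:
            d = specs[k].dim
            m, _ = trajectory_value_and_slope(
                params, np.zeros(1 + d), {"afc_idx": 0, "seas_warm": 0}, t, k, specs[k]
            )
            expect = params.beta[k][0] + ns_basis(t, specs[k]) @ params.beta[k][1 : 1 + d]
            assert np.allclose(m, expect)

    def test_slope_matches_finite_difference(self):
        specs = _default_specs()
        params = _params()
        rng = np.random.default_rng(4)
        t = np.linspace(6, 300, 40)
        for k in OUTCOME_KINDS:
            b_i = rng.standard_normal(1 + specs[k].dim)
            cov = {"afc_idx": 1, "seas_warm": 1}
            h = 1e-4
            mp, _ = trajectory_value_and_slope(params, b_i, cov, t + h, k, specs[k])
            mm, _ = trajectory_value_and_slope(params, b_i, cov, t - h, k, specs[k])
            _, dm = trajectory_value_and_slope(params, b_i, cov, t, k, specs[k])
            assert np.max(np.abs((mp - mm) / (2 * h) - dm)) < 1e-6

    def test_afc_changes_value_not_slope(self):
        specs = _default_specs()
        params = _params()
        t = np.linspace(5, 305, 20)
        m0, d0 = trajectory_value_and_slope(
            params, np.zeros(5), {"afc_idx": 0}, t, "MY", specs["MY"]
        )
        m2, d2 = trajectory_value_and_slope(
            params, np.zeros(5), {"afc_idx": 2}, t, "MY", specs["MY"]
        )
        assert np.allclose(d0, d2)
        assert not np.allclose(m0, m2)

    def test_null_association_reduces_to_baseline(self):
        specs = _default_specs()
        params = _params()
        t = np.array([10.0, 200.0, 500.0])
        h = hazard(t, params, _zero_b(), {"afc_idx": 0}, specs)
        j = np.clip(np.searchsorted(params.cuts, t, "right") - 1, 0, 5)
        assert np.allclose(h, np.exp(params.log_h0[j]))

    def test_log_linearity_in_association(self):
        specs = _default_specs()
        b = _zero_b()
        cov = {"afc_idx": 0}
        t = np.array([100.0])
        p1 = _params(alpha=(0.0, 0.0, -0.5))
        p2 = _params(alpha=(0.0, 0.0, -0.5))
        b2 = {k: v.copy() for k, v in b.items()}
        # shift the RUM slope coefficient so alpha3 * m3' changes by delta
        from herdsurv.splines import ns_basis_deriv

        d1 = ns_basis_deriv(t, specs["RUM"])[0]
        delta_coef = 0.3 / (-0.5 * d1[0])
        b2["RUM"][1] += delta_coef
        h1 = hazard(t, p1, b, cov, specs)
        h2 = hazard(t, p2, b2, cov, specs)
        assert np.allclose(h2 / h1, np.exp(0.3))

    def test_falling_rumination_raises_risk_under_negative_alpha(self):
        """alpha3 < 0: the steeper the rumination decline, the higher the
        hazard, all else equal."""
        specs = _default_specs()
        params = _params(alpha=(0.0, 0.0, -0.6))
        cov = {"afc_idx": 0}
        t = np.array([250.0])
        b_flat = _zero_b()
        b_fall = _zero_b()
        b_fall["RUM"][1] = -300.0  # steep decline
        assert hazard(t, params, b_fall, cov, specs) > hazard(t, params, b_flat, cov, specs)

    def test_overflow_guard(self):
        specs = _default_specs()
        params = _params(alpha=(0.0, 0.0, -0.6))
        b = _zero_b()
        b["RUM"][1] = -1e6
        with pytest.raises(FloatingPointError):
            hazard(np.array([250.0]), params, b, {"afc_idx": 0}, specs)


class TestCumulativeHazard:
    def test_empty_interval_is_zero(self):
        params = _params()
        assert cumulative_hazard(100.0, 100.0, params, _zero_b(), {"afc_idx": 0}, _default_specs()) == 0.0
        with pytest.raises(ValueError):
            cumulative_hazard(100.0, 50.0, params, _zero_b(), {"afc_idx": 0}, _default_specs())

    def test_constant_hazard_closed_form(self):
        params = _params(log_h0=np.full(6, -6.0))
        H = cumulative_hazard(30.0, 430.0, params, _zero_b(), {"afc_idx": 0}, _default_specs())
        assert np.isclose(H, 400.0 * np.exp(-6.0), rtol=1e-12)

    def test_quadrature_matches_dense_trapezoid(self):
        """15-point Gauss-Legendre per smooth segment vs a 10^4-point
        trapezoid oracle: relative agreement better than 1e-5."""
        specs = _default_specs()
        params = _params(alpha=(0.05, 0.01, -0.01), gamma=(0.3, 0.6),
                         log_h0=np.array([-6.5, -6.0, -7.0, -6.2, -6.8, -5.9]))
        rng = np.random.default_rng(11)
        b = {k: rng.standard_normal(1 + specs[k].dim) * 0.5 for k in OUTCOME_KINDS}
        cov = {"afc_idx": 2}
        v, u = 12.0, 640.0
        H = cumulative_hazard(v, u, params, b, cov, specs)
        # trapezoid oracle with ~10^4 points, integrated piecewise between
        # the baseline cuts (the integrand jumps there)
        edges = np.r_[v, params.cuts[(params.cuts > v) & (params.cuts < u)], u]
        H_trap = 0.0
        for a_, b_ in zip(edges[:-1], edges[1:]):
            tt = np.linspace(a_ + 1e-9, b_ - 1e-9, 2500)
            H_trap += np.trapezoid(hazard(tt, params, b, cov, specs), tt)
        assert abs(H - H_trap) / H_trap < 1e-5

    def test_monotone_in_upper_limit_across_posterior_draws(self, fit120):
        specs = fit120.specs
        rng = np.random.default_rng(0)
        for s in rng.choice(fit120.n_draws, 5, replace=False):
            params = fit120.params_draw(int(s))
            b = {k: np.zeros(1 + specs[k].dim) for k in OUTCOME_KINDS}
            grid = np.linspace(60.0, 800.0, 8)
            H = [cumulative_hazard(60.0, u, params, b, {"afc_idx": 1}, specs) for u in grid]
            assert np.all(np.diff(H) >= 0)
            assert np.all(
                hazard(grid, params, b, {"afc_idx": 1}, specs) > 0
            )


class TestLogPosterior:
    def test_finite_at_reasonable_state(self, design120):
        priors = PriorConfig()
        state = _init_state(design120, priors, np.random.default_rng(0))
        val, comp = log_posterior(design120, state, priors)
        assert np.isfinite(val)
        assert set(comp) == {"longitudinal", "survival", "ranef_prior", "hyperprior"}

    def test_beta_conditional_reduces_to_ols(self, design120):
        """With b = 0 and a flat prior the Gaussian conditional mean of
        beta_k is exactly the least-squares estimate."""
        priors = PriorConfig(beta_var=1e12)
        state = _init_state(design120, priors, np.random.default_rng(0))
        state["b"][:] = 0.0
        for k in OUTCOME_KINDS:
            od = design120.outcomes[k]
            ols = np.linalg.lstsq(od.X, od.y, rcond=None)[0]
            mean, _ = _beta_conditional(design120, k, state, priors)
            assert np.max(np.abs(mean - ols)) < 1e-6

    def test_baseline_shift_perturbation(self, design120):
        """Adding c to every log baseline rate changes the survival term by
        d*c - (e^c - 1) * H_tot; verified from three evaluations."""
        priors = PriorConfig()
        state = _init_state(design120, priors, np.random.default_rng(1))
        d_events = design120.event.sum()

        def surv_at(c):
            st = {**state, "log_h0": state["log_h0"] + c}
            return log_posterior(design120, st, priors)[1]["survival"]

        s0, s1, s2 = surv_at(0.0), surv_at(0.3), surv_at(-0.7)
        H_tot = -(s1 - s0 - d_events * 0.3) / (np.exp(0.3) - 1.0)
        expect2 = s0 + d_events * (-0.7) - (np.exp(-0.7) - 1.0) * H_tot
        assert np.isclose(s2, expect2, rtol=1e-8)

    def test_invariant_under_cow_permutation(self, clean120):
        clean, _, quart = clean120
        specs = {k: make_knots(clean.sensor["dim"].to_numpy(), k) for k in OUTCOME_KINDS}
        d1 = build_design(clean, specs, obs_thin=3, afc_quartiles=quart)
        permuted = clean.copy()
        rng = np.random.default_rng(5)
        order = rng.permutation(len(permuted.cows))
        permuted.cows = permuted.cows.iloc[order].reset_index(drop=True)
        d2 = build_design(permuted, specs, obs_thin=3, afc_quartiles=quart)
        priors = PriorConfig()
        state1 = _init_state(d1, priors, np.random.default_rng(0))
        state1["b"] = np.random.default_rng(2).standard_normal((d1.n, d1.q)) * 0.3
        # map cows of d1 onto d2's order
        pos = {c: i for i, c in enumerate(d2.cow_ids)}
        perm = np.array([pos[c] for c in d1.cow_ids])
        state2 = {**state1, "b": np.empty_like(state1["b"])}
        state2["b"][perm] = state1["b"]
        v1, _ = log_posterior(d1, state1, priors)
        v2, _ = log_posterior(d2, state2, priors)
        assert np.isclose(v1, v2, rtol=1e-10)


class TestSampler:
    def _small_design(self, seed=3, n=60):
        cfg = SyntheticConfig(n_cows=n, seed=seed)
        ds, _ = generate_herd(cfg)
        clean, _, quart = preprocess(ds)
        specs = {k: make_knots(clean.sensor["dim"].to_numpy(), k) for k in OUTCOME_KINDS}
        return build_design(clean, specs, obs_thin=5, afc_quartiles=quart)

    def test_seed_reproducibility(self):
        design = self._small_design()
        f1 = fit_mcmc(design, MCMCConfig(chains=2, burn=30, keep=30), seed=5)
        f2 = fit_mcmc(design, MCMCConfig(chains=2, burn=30, keep=30), seed=5)
        for name in f1.draws:
            assert np.array_equal(f1.draws[name], f2.draws[name])

    def test_alpha_recovery_within_two_posterior_sd(self, fit120, herd120):
        cfg, _, _ = herd120
        an = fit120.alpha_natural()
        for j, k in enumerate(OUTCOME_KINDS):
            mean, sd = an[:, j].mean(), an[:, j].std()
            assert abs(mean - cfg.alpha_true[k]) < 2.0 * sd, k

    def test_sign_recovery_for_negative_rumination_association(self):
        """A clearly negative rumination-slope association must put > 90%
        posterior mass on alpha_RUM < 0 at 150 cows."""
        cfg = SyntheticConfig(
            n_cows=150, seed=31,
            alpha_true={"MY": 0.0, "BW": 0.0, "RUM": -2.0},
        )
        ds, _ = generate_herd(cfg)
        clean, _, quart = preprocess(ds)
        specs = {k: make_knots(clean.sensor["dim"].to_numpy(), k) for k in OUTCOME_KINDS}
        design = build_design(clean, specs, obs_thin=3, afc_quartiles=quart)
        fit = fit_mcmc(design, MCMCConfig(chains=1, burn=250, keep=300), seed=6)
        an = fit.alpha_natural()
        assert np.mean(an[:, 2] < 0) > 0.9

    def test_degenerate_survival_matches_mixed_model_oracle(self):
        """All cows censored at a common day and the hazard pinned at null:
        posterior means of beta and sigma agree with an independent
        linear-mixed-model fit (statsmodels MixedLM, one outcome)."""
        import statsmodels.api as sm

        design = self._small_design(seed=9, n=70)
        # censor everything at a common day
        design.event[:] = 0
        fit = fit_mcmc(
            design, MCMCConfig(chains=1, burn=200, keep=300), seed=4,
            longitudinal_only=True,
        )
        od = design.outcomes["MY"]
        md = sm.MixedLM(
            od.y, od.X, groups=od.cow, exog_re=od.X[:, : od.qk]
        ).fit(reml=False)
        post_beta = fit.draws["beta_MY"].mean(axis=0)
        post_sd = fit.draws["beta_MY"].std(axis=0)
        # the joint fit shares one unstructured D across outcomes, so the
        # two estimators shrink between-cow contrasts differently; agreement
        # is asserted on the scale of their estimation uncertainty
        tol = 1.5 * np.maximum(post_sd, np.asarray(md.bse)[: post_beta.size])
        assert np.all(np.abs(post_beta - md.fe_params) < tol)
        post_sigma = np.sqrt(fit.draws["sigma2_MY"]).mean()
        assert abs(post_sigma - np.sqrt(md.scale)) / np.sqrt(md.scale) < 0.02

    def test_rhat_recorded_for_association_parameters(self, fit120):
        rhat = fit120.diagnostics["split_rhat"]
        assert {"alpha_MY", "alpha_BW", "alpha_RUM", "gamma_afc_medium", "gamma_afc_high"} <= set(rhat)

    def test_save_load_round_trip(self, fit120, tmp_path):
        save_fit(fit120, tmp_path / "fit")
        back = load_fit(tmp_path / "fit")
        assert np.allclose(back.draws["alpha"], fit120.draws["alpha"])
        assert np.allclose(back.draws["D"], fit120.draws["D"])
        assert back.specs["MY"].interior_knots == fit120.specs["MY"].interior_knots
        assert back.scalers == {k: tuple(v) for k, v in fit120.scalers.items()}
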