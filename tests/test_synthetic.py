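"""Synthetic herd generator: distributional correctness of the random
effects, trajectories and event times, and reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from herdsurv import (
    SyntheticConfig,
    generate_herd,
    inject_outliers,
    remove_outliers,
    simulate_event_time,
    simulate_random_effects,
    simulate_trajectories,
)
from herdsurv.io import OUTCOME_COLS, OUTCOME_KINDS, write_herd
from herdsurv.preprocessing import CleaningReport, compute_herd_stats
from herdsurv.splines import ns_basis_deriv
from herdsurv.synthetic import simulate_event_times


def _null_alpha():
    return {"MY": 0.0, "BW": 0.0, "RUM": 0.0}


class TestConfigValidation:
    def test_rejects_invalid(self):
        with pytest.raises(ValueError, match="n_cows"):
            SyntheticConfig(n_cows=0)
        with pytest.raises(ValueError, match="symmetric"):
            bad = np.eye(13)
            bad[0, 1] = 1.0
            SyntheticConfig(D_true=bad)
        with pytest.raises(ValueError, match="semi-definite"):
            SyntheticConfig(D_true=-np.eye(13))
        with pytest.raises(ValueError, match="positive"):
            SyntheticConfig(sigma_true={"MY": -1.0, "BW": 15.0, "RUM": 60.0})
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticConfig(afc_probs=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError, match="non-negative"):
            SyntheticConfig(baseline_hazard=np.full(6, -1e-4))


class TestRandomEffects:
    def test_zero_covariance_gives_zero_draws(self, rng):
        cfg = SyntheticConfig(n_cows=10, D_true=np.zeros((13, 13)))
        b = simulate_random_effects(cfg, rng)
        assert np.all(b == 0.0)

    def test_sample_covariance_matches_identity(self):
        cfg = SyntheticConfig(n_cows=5000, D_true=np.eye(13))
        b = simulate_random_effects(cfg, np.random.default_rng(5))
        S = np.cov(b.T)
        assert np.max(np.abs(S - np.eye(13))) < 0.1

    def test_seed_determinism(self):
        cfg = SyntheticConfig(n_cows=20)
        b1 = simulate_random_effects(cfg, np.random.default_rng(9))
        b2 = simulate_random_effects(cfg, np.random.default_rng(9))
        assert np.array_equal(b1, b2)


class TestTrajectories:
    def _covariates(self, n, afc_idx=0):
        return pd.DataFrame(
            {
                "afc_idx": np.full(n, afc_idx),
                "calving1_date": [pd.Timestamp("2015-01-15")] * n,
            }
        )

    def test_noise_free_series_equals_fixed_curve(self):
        cfg = SyntheticConfig(n_cows=2)
        b = np.zeros((2, 13))
        means, _ = simulate_trajectories(cfg, b, self._covariates(2))
        specs = cfg.spline_specs()
        from herdsurv.splines import ns_basis

        for k in OUTCOME_KINDS:
            beta = cfg.beta_true[k]
            d = specs[k].dim
            B = ns_basis(cfg.obs_grid.astype(float), specs[k])
            seas = means[k][0] * 0.0  # calving Jan 15: first warm day is DIM >= 76
            expect = beta[0] + B @ beta[1 : 1 + d]
            warm = pd.date_range("2015-01-15", periods=301 + 5, freq="D")[5:].month
            expect = expect + beta[3 + d] * ((warm >= 4) & (warm <= 10))
            assert np.allclose(means[k][0], expect)
            assert np.allclose(means[k][0], means[k][1])

    def test_afc_category_is_constant_vertical_offset(self):
        cfg = SyntheticConfig(n_cows=1)
        b = np.zeros((1, 13))
        m_low, _ = simulate_trajectories(cfg, b, self._covariates(1, 0))
        m_high, _ = simulate_trajectories(cfg, b, self._covariates(1, 2))
        for k in OUTCOME_KINDS:
            d = cfg.spline_specs()[k].dim
            diff = m_high[k][0] - m_low[k][0]
            assert np.allclose(diff, cfg.beta_true[k][2 + d])

    def test_pooled_residual_sd_matches_truth(self):
        cfg = SyntheticConfig(n_cows=2000)
        rng = np.random.default_rng(17)
        b = simulate_random_effects(cfg, rng)
        means, obs = simulate_trajectories(cfg, b, self._covariates(2000), rng)
        for k in OUTCOME_KINDS:
            sd = np.std(obs[k] - means[k])
            assert abs(sd - cfg.sigma_true[k]) / cfg.sigma_true[k] < 0.02


class TestEventTimes:
    def test_exponential_when_association_off(self):
        lam = 2e-3
        cfg = SyntheticConfig(
            n_cows=5000, alpha_true=_null_alpha(), gamma_true=np.zeros(2),
            baseline_hazard=np.full(6, lam), censor_day=20000, entry_spread_days=0,
            D_true=np.zeros((13, 13)),
        )
        rng = np.random.default_rng(2)
        b = np.zeros((5000, 13))
        T, ev, ts, E = simulate_event_times(cfg, b, np.zeros(5000, dtype=int), rng)
        assert ev.all()
        assert abs(np.mean(ts) - 1 / lam) / (1 / lam) < 0.05

    def test_all_censored_when_horizon_short(self):
        cfg = SyntheticConfig(
            n_cows=50, baseline_hazard=np.full(6, 1e-7), censor_day=400,
        )
        rng = np.random.default_rng(3)
        b = simulate_random_effects(cfg, rng)
        T, ev, ts, E = simulate_event_times(cfg, b, np.zeros(50, dtype=int), rng)
        assert not ev.any()
        assert np.all(T == 400)

    def test_inverse_transform_identity(self):
        """H_i(T*) must reproduce the drawn Exp(1) variate; the cumulative
        hazard is recomputed here by brute-force fine trapezoid."""
        cfg = SyntheticConfig(n_cows=40, seed=8)
        rng = np.random.default_rng(8)
        b = simulate_random_effects(cfg, rng)
        afc = rng.choice(3, 40, p=cfg.afc_probs)
        T, ev, ts, E = simulate_event_times(cfg, b, afc, rng)
        specs = cfg.spline_specs()
        blocks, s0 = {}, 0
        for k in OUTCOME_KINDS:
            blocks[k] = slice(s0, s0 + 1 + specs[k].dim)
            s0 += 1 + specs[k].dim
        checked = 0
        for i in np.flatnonzero(ev):
            tt = np.linspace(0.0, ts[i], 200001)
            lp = np.full(tt.size, [0.0, *cfg.gamma_true][afc[i]])
            for k in OUTCOME_KINDS:
                coef = cfg.beta_true[k][1 : 1 + specs[k].dim] + b[i, blocks[k]][1:]
                lp += cfg.alpha_true[k] * (ns_basis_deriv(tt, specs[k]) @ coef)
            rates = cfg.baseline_hazard[
                np.clip(np.searchsorted(cfg.baseline_cuts(), tt, "right") - 1, 0, 5)
            ]
            H = np.trapezoid(rates * np.exp(lp), tt)
            assert abs(H - E[i]) < 1e-5
            checked += 1
            if checked >= 5:
                break
        assert checked > 0

    def test_single_cow_wrapper(self):
        cfg = SyntheticConfig(n_cows=1)
        rec = simulate_event_time(cfg, np.zeros(13), 0, np.random.default_rng(1))
        assert rec.event in (0, 1) and rec.T >= 1

    def test_overflow_guard_names_cow(self):
        cfg = SyntheticConfig(
            n_cows=2, alpha_true={"MY": 0.0, "BW": 0.0, "RUM": -500.0}
        )
        rng = np.random.default_rng(0)
        b = simulate_random_effects(cfg, rng)
        with pytest.raises(FloatingPointError, match="cow"):
            simulate_event_times(cfg, b, np.zeros(2, dtype=int), rng)

    def test_baseline_only_survival_matches_closed_form(self):
        """With the association off, event times follow the closed-form
        piecewise-exponential law of the baseline (KS distance < 0.03)."""
        rates = np.array([4e-3, 3e-3, 2e-3, 2e-3, 1e-3, 1e-3])
        cfg = SyntheticConfig(
            n_cows=2000, alpha_true=_null_alpha(), gamma_true=np.zeros(2),
            baseline_hazard=rates, censor_day=900, entry_spread_days=0,
        )
        rng = np.random.default_rng(6)
        b = simulate_random_effects(cfg, rng)
        T, ev, ts, E = simulate_event_times(cfg, b, np.zeros(2000, dtype=int), rng)
        cuts = cfg.baseline_cuts()

        def cdf(t):
            t = np.asarray(t, dtype=float)
            H = np.zeros_like(t)
            for j in range(6):
                H += rates[j] * np.clip(np.minimum(t, cuts[j + 1]) - cuts[j], 0, None)
            return 1.0 - np.exp(-H)

        uncensored = ts[np.isfinite(ts)]
        # condition the reference law on the censoring horizon
        p_event = cdf(np.array([900.0]))[0]
        res = stats.kstest(uncensored, lambda t: cdf(t) / p_event)
        assert res.statistic < 0.03


class TestOutliersAndHerd:
    def test_rate_zero_leaves_dataset_unchanged(self, herd120):
        cfg, dataset, _ = herd120
        out, log = inject_outliers(dataset, cfg, np.random.default_rng(1))
        assert log.empty
        pd.testing.assert_frame_equal(out.sensor, dataset.sensor)

    def test_injection_count_in_binomial_band(self):
        cfg = SyntheticConfig(
            n_cows=100, seed=21, outlier_rate=0.01, missing_rate=0.0,
            baseline_hazard=np.full(6, 1e-7), entry_spread_days=0,
        )
        dataset, truth = generate_herd(cfg)
        n_my = len(truth["outliers"].query("outcome == 'my_kg'"))
        n_cells = len(dataset.sensor)
        lo, hi = stats.binom.ppf([0.005, 0.995], n_cells, 0.01)
        assert lo <= n_my <= hi

    def test_cleaning_round_trip_recovers_injections(self):
        """With < 30 injected days per cow, the 3-SD rule removes nearly
        every injected position."""
        cfg = SyntheticConfig(n_cows=60, seed=13, outlier_rate=0.01, missing_rate=0.0)
        dataset, truth = generate_herd(cfg)
        stats_ = compute_herd_stats(dataset)
        cleaned, report = remove_outliers(dataset, stats_, CleaningReport(n_input_cows=60))
        inj = truth["outliers"]
        per_cow = inj.groupby(["cow_id", "outcome"]).size()
        assert (per_cow < 30).all()
        s = cleaned.sensor.set_index(["cow_id", "dim"])
        removed = 0
        for row in inj.itertuples(index=False):
            col = row.outcome
            if (row.cow_id, row.dim) in s.index and np.isnan(
                s.loc[(row.cow_id, row.dim), col]
            ):
                removed += 1
        assert removed / len(inj) >= 0.99

    def test_small_herd_row_bound(self):
        cfg = SyntheticConfig(n_cows=3, seed=2)
        dataset, _ = generate_herd(cfg)
        assert len(dataset.sensor) <= 3 * 301

    def test_same_seed_byte_identical_files(self, tmp_path):
        for sub in ("a", "b"):
            cfg = SyntheticConfig(n_cows=15, seed=33, outlier_rate=0.005)
            dataset, _ = generate_herd(cfg)
            write_herd(dataset, tmp_path / sub)
        for name in ("sensor.csv", "cows.csv", "herd.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_trajectories_independent_of_association_given_b(self):
        """Changing the hazard association must not alter the sensor series
        (conditional independence given the random effects)."""
        base = dict(n_cows=12, seed=77, missing_rate=0.0)
        d1, _ = generate_herd(SyntheticConfig(**base))
        d2, _ = generate_herd(
            SyntheticConfig(**base, alpha_true={"MY": 0.3, "BW": -0.2, "RUM": -1.0})
        )
        # the association changes culling times (series lengths) but must
        # not change any sensor value on the overlapping cow-days
        m = d1.sensor.merge(d2.sensor, on=["cow_id", "dim"], suffixes=("_1", "_2"))
        assert len(m) > 0
        for col in OUTCOME_COLS:
            assert np.allclose(m[f"{col}_1"], m[f"{col}_2"])

    def test_steep_rumination_decline_shortens_survival(self):
        """Strong negative association on the RUM slope: cows whose late-
        lactation rumination slope is lower are culled earlier."""
        cfg = SyntheticConfig(
            n_cows=500, seed=55, alpha_true={"MY": 0.0, "BW": 0.0, "RUM": -2.5},
            gamma_true=np.zeros(2), missing_rate=0.0, entry_spread_days=0,
        )
        dataset, truth = generate_herd(cfg)
        spec = cfg.spline_specs()["RUM"]
        blocks_start = 10  # RUM block follows MY (5) + BW (5)
        coef = cfg.beta_true["RUM"][1:3][None, :] + truth["b"][:, blocks_start + 1 :]
        slope_end = (ns_basis_deriv(np.array([290.0]), spec) @ coef.T)[0]
        rho = stats.spearmanr(slope_end, truth["T"]).statistic
        assert rho > 0.2  # lower slope -> earlier culling

    def test_default_culling_level_within_farm_range(self):
        cfg = SyntheticConfig(n_cows=400, seed=5)
        _, truth = generate_herd(cfg)
        frac_t1 = np.mean((truth["T"] <= cfg.t1) & (truth["event"] == 1))
        assert 0.06 <= frac_t1 <= 0.18
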