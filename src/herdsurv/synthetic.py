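"""Synthetic herd generator.

Simulates herds with exactly the statistical structure assumed by the joint
model, so parameter recovery and the whole pipeline can be exercised without
farm data (no commercial herd dataset is publicly available):

* three daily sensor outcomes per cow — milk yield (kg), body weight (kg),
  rumination time (min) — each following a linear mixed model with a natural
  cubic spline of days in milk (DIM), age-at-first-calving (AFC) category and
  warm/cold season fixed effects, plus a cow-level random intercept and
  random spline coefficients;
* the stacked random-effect vector b_i of all three outcomes drawn from one
  unstructured covariance matrix D (dimension 5 + 5 + 3 = 13 under the
  default spline layout), which is what correlates the outcomes;
* culling times drawn by inverse-transform sampling from a proportional
  hazards model whose log-hazard is linear in the AFC category and in the
  current slopes m'_ik(t) of the three noiseless trajectories, with a
  piecewise-constant baseline hazard on six equal intervals (closed-form
  baseline survival when the association is switched off);
* administrative right-censoring at the dataset end date, staggered first
  calvings, missing days, and optional injected recording-error outliers for
  the cleaning rules to remove.

Trajectory noise and event times are independent given b_i — the
conditional-independence assumption of the joint model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy.optimize import brentq

from .io import OUTCOME_COLS, OUTCOME_KINDS, HerdDataset, SurvivalRecord, logger
from .splines import SplineSpec, make_knots, ns_basis, ns_basis_deriv

__all__ = [
    "SyntheticConfig",
    "simulate_random_effects",
    "simulate_trajectories",
    "simulate_event_time",
    "inject_outliers",
    "generate_herd",
]

_LP_GUARD = 50.0  # |log-hazard linear predictor| beyond this is treated as overflow
_GL10 = leggauss(10)


#: the mean first-lactation curves are specified as values at anchor days
#: and solved exactly for spline coefficients, so they are independent of
#: the basis parameterization.  Shapes are typical for a Holstein first
#: lactation: milk rises to a ~35 kg/day peak near DIM 60 then declines;
#: body weight dips post-calving then regrows; rumination is flat-ish.
_CURVE_ANCHORS = {
    "MY": ((5.0, 60.0, 155.0, 230.0, 305.0), (25.0, 35.0, 28.0, 22.0, 18.0)),
    "BW": ((5.0, 60.0, 155.0, 230.0, 305.0), (560.0, 545.0, 560.0, 590.0, 620.0)),
    "RUM": ((5.0, 155.0, 305.0), (450.0, 480.0, 470.0)),
}
#: AFC-medium, AFC-high, SEAS-warm fixed effects per outcome (kg, kg, min)
_COVARIATE_EFFECTS = {
    "MY": (-0.27, 1.24, -0.02),
    "BW": (-3.6, 50.9, 0.92),
    "RUM": (-21.3, -24.8, -9.0),
}


def _default_betas() -> dict:
    out = {}
    for k in OUTCOME_KINDS:
        spec = make_knots(np.arange(5, 306), k)
        t, vals = _CURVE_ANCHORS[k]
        A = np.column_stack([np.ones(len(t)), ns_basis(np.asarray(t), spec)])
        coef = np.linalg.solve(A, np.asarray(vals))
        out[k] = np.concatenate([coef, _COVARIATE_EFFECTS[k]])
    return out


def _default_D() -> np.ndarray:
    # random-effect SDs per outcome (intercept + spline columns).  The
    # basis columns have unit RMS over the lactation, so a spline-column SD
    # is directly a cow-level trajectory-shape SD in outcome units.  Mild
    # positive correlation between the three intercepts and a mild negative
    # intercept/first-slope correlation within each outcome.
    sds = np.array([4.5, 1.5, 1.0, 0.8, 0.8,        # MY (kg)
                    50.0, 12.0, 8.0, 6.0, 6.0,      # BW (kg)
                    80.0, 25.0, 15.0])              # RUM (min)
    q = sds.size
    corr = np.eye(q)
    icpt = [0, 5, 10]
    for a in icpt:
        for b in icpt:
            if a != b:
                corr[a, b] = 0.3
    for a, s in ((0, 1), (5, 6), (10, 11)):
        corr[a, s] = corr[s, a] = -0.2
    return corr * np.outer(sds, sds)


@dataclass
class SyntheticConfig:
    """True parameter values and sampling layout for one simulated herd."""

    n_cows: int = 200
    seed: int = 0
    obs_grid: np.ndarray = field(default_factory=lambda: np.arange(5, 306))
    beta_true: dict = field(default_factory=_default_betas)
    sigma_true: dict = field(
        default_factory=lambda: {"MY": 3.0, "BW": 15.0, "RUM": 60.0}
    )
    D_true: np.ndarray = field(default_factory=_default_D)
    gamma_true: np.ndarray = field(default_factory=lambda: np.array([0.3, 0.6]))
    alpha_true: dict = field(
        default_factory=lambda: {"MY": 0.0, "BW": 0.1, "RUM": -0.6}
    )
    #: events/day on 6 equal intervals over [0, censor_day]; the default is
    #: calibrated so that roughly 10% of cows are culled before t1, the
    #: middle of the range reported across commercial herds (6-18%)
    baseline_hazard: np.ndarray = field(
        default_factory=lambda: np.full(6, 2.0e-4)
    )
    censor_day: int = 900
    entry_spread_days: int = 365
    calving_start: str = "2015-01-01"
    afc_probs: tuple[float, float, float] = (0.25, 0.50, 0.25)
    afc_day_bands: tuple = ((660, 720), (720, 810), (810, 880))
    missing_rate: float = 0.02
    outlier_rate: float = 0.0
    outlier_magnitude: float = 6.0
    t1: int = 414
    t2: int | None = None  # defaults to 2*t1

    def __post_init__(self):
        if self.n_cows <= 0:
            raise ValueError("n_cows must be positive")
        self.obs_grid = np.asarray(self.obs_grid, dtype=int)
        self.D_true = np.asarray(self.D_true, dtype=float)
        if not np.allclose(self.D_true, self.D_true.T):
            raise ValueError("D_true must be symmetric")
        eig = np.linalg.eigvalsh(self.D_true)
        if eig.min() < -1e-8 * max(1.0, eig.max()):
            raise ValueError("D_true must be positive semi-definite")
        if any(s <= 0 for s in self.sigma_true.values()):
            raise ValueError("residual SDs must be positive")
        self.baseline_hazard = np.asarray(self.baseline_hazard, dtype=float)
        if (self.baseline_hazard < 0).any():
            raise ValueError("baseline rates must be non-negative")
        if not np.isclose(sum(self.afc_probs), 1.0):
            raise ValueError("afc_probs must sum to 1")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError("outlier_rate must be in [0, 1)")
        if self.t2 is None:
            self.t2 = 2 * self.t1

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        """Load a configuration from YAML; the seed must be present."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("a seed is mandatory in the synthetic config")
        for key in ("obs_grid", "D_true", "gamma_true", "baseline_hazard"):
            if key in raw:
                raw[key] = np.asarray(raw[key])
        if "beta_true" in raw:
            raw["beta_true"] = {k: np.asarray(v) for k, v in raw["beta_true"].items()}
        return cls(**raw)

    # --- derived layout ------------------------------------------------
    def spline_specs(self) -> dict[str, SplineSpec]:
        return {k: make_knots(self.obs_grid, k) for k in OUTCOME_KINDS}

    @property
    def q(self) -> int:
        return sum(1 + s.dim for s in self.spline_specs().values())

    def _check_dims(self):
        specs = self.spline_specs()
        for k in OUTCOME_KINDS:
            want = 1 + specs[k].dim + 3
            if len(self.beta_true[k]) != want:
                raise ValueError(
                    f"beta_true[{k}] has {len(self.beta_true[k])} entries, "
                    f"design needs {want} (intercept + {specs[k].dim} spline + "
                    "AFC-medium + AFC-high + SEAS-warm)"
                )
        if self.D_true.shape != (self.q, self.q):
            raise ValueError(
                f"D_true is {self.D_true.shape}, stacked random effects need ({self.q}, {self.q})"
            )

    def baseline_cuts(self) -> np.ndarray:
        return np.linspace(0.0, float(self.censor_day), self.baseline_hazard.size + 1)


# ----------------------------------------------------------------------
# random effects and trajectories
# ----------------------------------------------------------------------

def _b_blocks(config: SyntheticConfig) -> dict[str, slice]:
    specs = config.spline_specs()
    out, start = {}, 0
    for k in OUTCOME_KINDS:
        out[k] = slice(start, start + 1 + specs[k].dim)
        start += 1 + specs[k].dim
    return out


def simulate_random_effects(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw the stacked random-effect vectors b_i ~ N(0, D), shape (n_cows, q)."""
    config._check_dims()
    w, V = np.linalg.eigh(config.D_true)
    w = np.clip(w, 0.0, None)
    z = rng.standard_normal((config.n_cows, config.D_true.shape[0]))
    return z * np.sqrt(w) @ V.T


def _season_warm(calving1: pd.Timestamp, dims: np.ndarray) -> np.ndarray:
    months = (pd.Timestamp(calving1) + pd.to_timedelta(dims, unit="D")).month
    return ((months >= 4) & (months <= 10)).astype(float)


def simulate_trajectories(
    config: SyntheticConfig,
    b_draws: np.ndarray,
    covariates: pd.DataFrame,
    rng: np.random.Generator | None = None,
):
    """Noiseless means m_ik(t) and noisy observations y_ik(t) on the grid.

    ``covariates`` needs one row per cow with ``afc_idx`` (0=low, 1=medium,
    2=high) and ``calving1_date``.  Returns ``(means, obs)`` as dicts of
    (n_cows, n_days) arrays keyed by outcome; ``obs`` is None when ``rng``
    is None.
    """
    config._check_dims()
    specs = config.spline_specs()
    blocks = _b_blocks(config)
    grid = config.obs_grid.astype(float)
    n = b_draws.shape[0]
    afc = covariates["afc_idx"].to_numpy()
    seas = np.vstack(
        [_season_warm(c, config.obs_grid) for c in covariates["calving1_date"]]
    )  # (n, n_days)
    means, obs = {}, ({} if rng is not None else None)
    for k in OUTCOME_KINDS:
        beta = np.asarray(config.beta_true[k], dtype=float)
        B = ns_basis(grid, specs[k])                      # (days, dim)
        d = specs[k].dim
        fixed_curve = beta[0] + B @ beta[1 : 1 + d]       # (days,)
        afc_eff = np.where(afc == 1, beta[1 + d], np.where(afc == 2, beta[2 + d], 0.0))
        bi = b_draws[:, blocks[k]]                        # (n, 1+dim)
        rand = bi[:, :1] + bi[:, 1:] @ B.T                # (n, days)
        m = fixed_curve[None, :] + afc_eff[:, None] + beta[3 + d] * seas + rand
        means[k] = m
        if rng is not None:
            obs[k] = m + rng.standard_normal((n, grid.size)) * config.sigma_true[k]
    return means, obs


# ----------------------------------------------------------------------
# event times (inverse-transform from the slope-association hazard)
# ----------------------------------------------------------------------

def _slope_coefs(config: SyntheticConfig, b_draws: np.ndarray) -> dict[str, np.ndarray]:
    """Per-cow spline coefficients of m'_ik: beta1_k + b_i1k, shape (n, dim_k)."""
    specs = config.spline_specs()
    blocks = _b_blocks(config)
    out = {}
    for k in OUTCOME_KINDS:
        beta = np.asarray(config.beta_true[k])
        d = specs[k].dim
        out[k] = beta[1 : 1 + d][None, :] + b_draws[:, blocks[k]][:, 1:]
    return out


def _quad_layout(config: SyntheticConfig, n_nodes: int = 10):
    """Gauss-Legendre nodes on [0, censor_day], split at baseline cuts and
    spline knots so every segment's integrand is smooth."""
    specs = config.spline_specs()
    edges = set(config.baseline_cuts())
    for s in specs.values():
        edges.update(s.interior_knots)
        edges.update(s.boundary_knots)
    edges = np.array(sorted(e for e in edges if 0.0 <= e <= config.censor_day))
    if edges[0] > 0.0:
        edges = np.concatenate([[0.0], edges])
    x, w = _GL10 if n_nodes == 10 else leggauss(n_nodes)
    a, b = edges[:-1], edges[1:]
    nodes = (0.5 * (b - a)[:, None] * x[None, :] + 0.5 * (a + b)[:, None]).ravel()
    weights = (0.5 * (b - a)[:, None] * w[None, :]).ravel()
    seg_end = b
    return nodes, weights, edges, seg_end


def _linear_predictors(config, coefs, afc_idx, times):
    """gamma + sum_k alpha_k m'_ik at ``times``; shape (n, len(times))."""
    specs = config.spline_specs()
    g = np.where(afc_idx == 1, config.gamma_true[0],
                 np.where(afc_idx == 2, config.gamma_true[1], 0.0))
    lp = np.broadcast_to(g[:, None], (len(afc_idx), len(times))).copy()
    for k in OUTCOME_KINDS:
        a_k = config.alpha_true[k]
        if a_k != 0.0:
            Bd = ns_basis_deriv(times, specs[k])          # (times, dim)
            lp += a_k * (coefs[k] @ Bd.T)
    return lp


def simulate_event_times(
    config: SyntheticConfig,
    b_draws: np.ndarray,
    afc_idx: np.ndarray,
    rng: np.random.Generator,
    censor_days: np.ndarray | None = None,
):
    """Vectorized inverse-transform sampling of culling times for all cows.

    Returns (T, event, t_star, E): integer-day survival times (ceiling of the
    continuous event time, capped by each cow's administrative censor day),
    event indicators, the continuous event times (NaN when censored past the
    horizon) and the Exp(1) draws.
    """
    config._check_dims()
    n = b_draws.shape[0]
    if censor_days is None:
        censor_days = np.full(n, config.censor_day)
    coefs = _slope_coefs(config, b_draws)
    nodes, weights, edges, _ = _quad_layout(config)
    rate_at = config.baseline_hazard[
        np.minimum(
            np.searchsorted(config.baseline_cuts(), nodes, side="right") - 1,
            config.baseline_hazard.size - 1,
        )
    ]
    lp = _linear_predictors(config, coefs, afc_idx, nodes)
    if np.abs(lp).max() > _LP_GUARD:
        i = int(np.argmax(np.abs(lp).max(axis=1)))
        raise FloatingPointError(
            f"hazard linear predictor overflow (|lp| > {_LP_GUARD}) for cow index {i}"
        )
    integrand = rate_at[None, :] * np.exp(lp) * weights[None, :]
    # cumulative hazard at segment edges
    nseg = edges.size - 1
    seg = integrand.reshape(n, nseg, -1).sum(axis=2)
    H_edges = np.concatenate([np.zeros((n, 1)), np.cumsum(seg, axis=1)], axis=1)

    E = rng.exponential(size=n)
    t_star = np.full(n, np.nan)
    T = np.empty(n, dtype=int)
    event = np.zeros(n, dtype=int)
    for i in range(n):
        if H_edges[i, -1] <= E[i]:
            T[i] = int(censor_days[i])
            continue
        j = int(np.searchsorted(H_edges[i], E[i], side="right") - 1)
        a = edges[j]

        def f(t, i=i, j=j, a=a):
            return H_edges[i, j] + _partial_hazard(config, coefs, afc_idx, i, a, t) - E[i]

        ts = brentq(f, a, edges[j + 1], xtol=1e-10, rtol=1e-12)
        t_star[i] = ts
        if ts > censor_days[i]:
            T[i] = int(censor_days[i])
        else:
            T[i] = max(1, int(np.ceil(ts)))
            event[i] = 1
    return T, event, t_star, E


def _partial_hazard(config, coefs, afc_idx, i, a, t, n_nodes=10):
    """Integral of cow i's hazard over [a, t] within one smooth segment."""
    if t <= a:
        return 0.0
    x, w = _GL10 if n_nodes == 10 else leggauss(n_nodes)
    nodes = 0.5 * (t - a) * x + 0.5 * (a + t)
    weights = 0.5 * (t - a) * w
    j = min(
        int(np.searchsorted(config.baseline_cuts(), 0.5 * (a + t), side="right") - 1),
        config.baseline_hazard.size - 1,
    )
    lp = _linear_predictors(
        config, {k: coefs[k][i : i + 1] for k in coefs}, afc_idx[i : i + 1], nodes
    )[0]
    return float(config.baseline_hazard[j] * np.exp(lp) @ weights)


def cumulative_hazard_true(config, b_i, afc_i, t) -> float:
    """H_i(t) under the true simulation hazard (for test oracles)."""
    coefs = _slope_coefs(config, b_i[None, :])
    edges = np.unique(np.concatenate([_quad_layout(config)[2], [float(t)]]))
    edges = edges[edges <= t + 1e-12]
    total = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        total += _partial_hazard(config, coefs, np.array([afc_i]), 0, a, b)
    return total


def simulate_event_time(
    config: SyntheticConfig, b_i: np.ndarray, afc_idx: int, rng: np.random.Generator
) -> SurvivalRecord:
    """Single-cow wrapper around :func:`simulate_event_times`."""
    T, event, _, _ = simulate_event_times(
        config, np.asarray(b_i)[None, :], np.array([afc_idx]), rng
    )
    return SurvivalRecord(T=int(T[0]), event=int(event[0]))


# ----------------------------------------------------------------------
# recording-error injection
# ----------------------------------------------------------------------

def inject_outliers(
    dataset: HerdDataset, config: SyntheticConfig, rng: np.random.Generator
) -> tuple[HerdDataset, pd.DataFrame]:
    """Displace random cow-days by >= outlier_magnitude herd-SDs.

    Emulates sensor recording errors.  Returns the modified dataset and a log
    of injected positions (cow_id, dim, outcome, original value) so cleaning
    can be checked against ground truth.
    """
    out = dataset.copy()
    logs = []
    if config.outlier_rate > 0:
        for col in OUTCOME_COLS:
            vals = out.sensor[col].to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            sd = np.nanstd(vals)
            hit = ok & (rng.random(vals.size) < config.outlier_rate)
            idx = np.flatnonzero(hit)
            delta = (config.outlier_magnitude + np.abs(rng.standard_normal(idx.size))) * sd
            sign = rng.choice([-1.0, 1.0], size=idx.size)
            sign[vals[idx] + sign * delta < 0] = 1.0
            for pos, d, s in zip(idx, delta, sign):
                logs.append(
                    {
                        "cow_id": out.sensor["cow_id"].iat[pos],
                        "dim": out.sensor["dim"].iat[pos],
                        "outcome": col,
                        "original": vals[pos],
                    }
                )
                vals[pos] = vals[pos] + s * d
            out.sensor[col] = vals
    log = pd.DataFrame(logs, columns=["cow_id", "dim", "outcome", "original"])
    return out, log


# ----------------------------------------------------------------------
# herd orchestration
# ----------------------------------------------------------------------

def generate_herd(config: SyntheticConfig) -> tuple[HerdDataset, dict]:
    """Generate a complete herd; returns (dataset, truth).

    ``truth`` carries everything a test oracle needs: the drawn random
    effects, true AFC categories, continuous event times, injected-outlier
    log and the configuration itself.  Fully reproducible from the seed.
    """
    config._check_dims()
    rng = np.random.default_rng(config.seed)
    n = config.n_cows
    start = pd.Timestamp(config.calving_start)

    afc_idx = rng.choice(3, size=n, p=config.afc_probs)
    bands = np.asarray(config.afc_day_bands, dtype=float)
    afc_days = np.rint(
        bands[afc_idx, 0] + rng.random(n) * (bands[afc_idx, 1] - bands[afc_idx, 0])
    ).astype(int)
    offset = rng.integers(0, max(1, config.entry_spread_days), size=n)
    calving1 = start + pd.to_timedelta(offset, unit="D")
    end_date = start + pd.Timedelta(days=config.censor_day)
    censor_days = (end_date - calving1).days.to_numpy()

    b = simulate_random_effects(config, rng)
    covariates = pd.DataFrame({"afc_idx": afc_idx, "calving1_date": calving1})
    _, obs = simulate_trajectories(config, b, covariates, rng)
    T, event, t_star, E = simulate_event_times(config, b, afc_idx, rng, censor_days)

    rows = []
    grid = config.obs_grid
    for i in range(n):
        last = min(T[i], grid.max())
        keep = grid <= last
        dims = grid[keep]
        rec = pd.DataFrame(
            {
                "cow_id": f"cow{i:04d}",
                "date": calving1[i] + pd.to_timedelta(dims, unit="D"),
                "dim": dims,
            }
        )
        for k, col in zip(OUTCOME_KINDS, OUTCOME_COLS):
            vals = obs[k][i, keep].copy()
            if config.missing_rate > 0:
                vals[rng.random(vals.size) < config.missing_rate] = np.nan
            rec[col] = np.clip(vals, 0.0, None)
        rows.append(rec)
    sensor = pd.concat(rows, ignore_index=True)

    cows = pd.DataFrame(
        {
            "cow_id": [f"cow{i:04d}" for i in range(n)],
            "birth_date": calving1 - pd.to_timedelta(afc_days, unit="D"),
            "calving1_date": calving1,
            "culling_date": [
                calving1[i] + pd.Timedelta(days=int(T[i])) if event[i] else pd.NaT
                for i in range(n)
            ],
            "afc_days": afc_days,
        }
    )
    dataset = HerdDataset(
        sensor=sensor, cows=cows, end_date=end_date, t1=config.t1, t2=config.t2
    )
    dataset, outlier_log = inject_outliers(dataset, config, rng)
    logger.info(
        "generated herd: %d cows, %d sensor rows, %d culled (%.0f%% before t1)",
        n, len(sensor), int(event.sum()), 100.0 * np.mean((T <= config.t1) & (event == 1)),
    )
    truth = {
        "config": config,
        "b": b,
        "afc_idx": afc_idx,
        "T": T,
        "event": event,
        "t_star": t_star,
        "exp_draws": E,
        "censor_days": censor_days,
        "outliers": outlier_log,
        "spline_specs": config.spline_specs(),
    }
    return dataset, truth


def truth_to_json(truth: dict) -> dict:
    """JSON-serializable snapshot of the true parameters (for truth.json)."""
    c: SyntheticConfig = truth["config"]
    return {
        "seed": c.seed,
        "n_cows": c.n_cows,
        "beta_true": {k: list(map(float, v)) for k, v in c.beta_true.items()},
        "sigma_true": {k: float(v) for k, v in c.sigma_true.items()},
        "alpha_true": {k: float(v) for k, v in c.alpha_true.items()},
        "gamma_true": list(map(float, c.gamma_true)),
        "baseline_hazard": list(map(float, c.baseline_hazard)),
        "D_true": np.asarray(c.D_true).tolist(),
        "censor_day": c.censor_day,
        "t1": c.t1,
        "t2": c.t2,
        "n_events": int(np.sum(truth["event"])),
    }
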