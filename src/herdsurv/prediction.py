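"""Dynamic survival prediction for new cows.

Given a fitted joint model and a new cow's sensor record up to day-in-milk
v, the survival probability to a later day u is

    pi_i(u | v) = Pr{ T_i >= u | T_i > v, Y_i(v), training fit }

estimated by Monte Carlo over the posterior: for each retained posterior
draw theta, one Metropolis draw of the cow's random effects from

    p(b | Y_i(v), T_i > v, theta)
      ~  N(Y_i; m_i(b), sigma) * exp(-H_i(0, v; b)) * N(b; 0, D),

using the exact Gaussian longitudinal-conditional as an independence
proposal (the survival factor exp(-H_i(0, v)) enters only through the
accept/reject step, and the scheme is exact when the association is null).
The curve for each draw is exp(-H_i(v, u; theta, b)), and the reported
prediction is the across-draw mean with 2.5/97.5-percentile bounds.

The quadrature layout places 15 Gauss-Legendre nodes on every smooth
segment — baseline-hazard intervals split at spline knots and at every
requested evaluation time — so pi at all grid points comes from one
cumulative pass.  Beyond the last training event time the baseline rate is
extrapolated as constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss

from .io import OUTCOME_COLS, OUTCOME_KINDS
from .joint_model import _LP_GUARD, JointModelFit
from .preprocessing import categorize_afc
from .splines import ns_basis, ns_basis_deriv

__all__ = [
    "SurvivalPrediction",
    "sample_conditional_random_effects",
    "predict_survival",
    "classify",
]

_N_GL = 15


@dataclass
class SurvivalPrediction:
    """pi_i(u|v) curve with pointwise 95% credible bounds for one cow."""

    cow_id: str
    v: float
    u_grid: np.ndarray
    pi: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_draws: int
    draws: np.ndarray | None = None      # (S, len(u_grid)) per-draw curves

    def at(self, u: float) -> float:
        """pi at one grid point (must be on the grid)."""
        j = np.flatnonzero(np.isclose(self.u_grid, u))
        if j.size == 0:
            raise ValueError(f"u={u} not on the prediction grid")
        return float(self.pi[j[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cow_id": self.cow_id, "u": self.u_grid, "pi": self.pi,
                "lo": self.ci_lower, "hi": self.ci_upper,
            }
        )


def classify(prediction: SurvivalPrediction, horizon: float, c: float = 0.5) -> str:
    """'culled' when pi(horizon | v) <= c, else 'alive' (boundary inclusive)."""
    return "culled" if prediction.at(horizon) <= c else "alive"


# ----------------------------------------------------------------------
# internals
# ----------------------------------------------------------------------

def _draw_indices(fit: JointModelFit, n_draws: int) -> np.ndarray:
    S = fit.n_draws
    m = min(n_draws, S)
    return np.unique(np.round(np.linspace(0, S - 1, m)).astype(int))


def _cow_afc_dummies(fit: JointModelFit, cow_row) -> np.ndarray:
    cat = cow_row.get("afc_cat") if hasattr(cow_row, "get") else None
    if cat is None or (isinstance(cat, float) and np.isnan(cat)):
        if fit.afc_quartiles is None:
            raise ValueError("need afc_cat on the cow row or AFC quartiles in the fit")
        cat = categorize_afc(float(cow_row["afc_days"]), fit.afc_quartiles)
    return np.array([float(cat == "medium"), float(cat == "high")])


def _cow_obs_design(fit: JointModelFit, cow_sensor: pd.DataFrame, w: np.ndarray, v: float):
    """Standardized observations and design rows per outcome, DIM in [5, v]."""
    sub = cow_sensor.loc[(cow_sensor["dim"] >= 5) & (cow_sensor["dim"] <= v)]
    seas = sub["date"].dt.month.between(4, 10).astype(float).to_numpy()
    out = {}
    for k, col in zip(OUTCOME_KINDS, OUTCOME_COLS):
        ok = sub[col].notna().to_numpy()
        if ok.sum() == 0:
            raise ValueError(
                f"no {k} observations in [5, {v:g}] DIM; univariate fallback is out of scope"
            )
        t = sub.loc[ok, "dim"].to_numpy(dtype=float)
        B = ns_basis(t, fit.specs[k])
        X = np.column_stack(
            [np.ones(ok.sum()), B, np.full(ok.sum(), w[0]), np.full(ok.sum(), w[1]), seas[ok]]
        )
        mu, sd = fit.scalers[k]
        y = (sub.loc[ok, col].to_numpy(dtype=float) - mu) / sd
        out[k] = (X, y)
    return out


def _layout(fit: JointModelFit, eval_times: np.ndarray):
    """Quadrature layout on [0, max(eval_times)] with edges at every
    baseline cut, spline knot and evaluation time."""
    umax = float(np.max(eval_times))
    edges = {0.0, umax}
    edges.update(float(t) for t in eval_times)
    edges.update(float(c) for c in fit.cuts if 0.0 < c < umax)
    for s in fit.specs.values():
        edges.update(k for k in s.interior_knots if k < umax)
        edges.update(k for k in s.boundary_knots if 0.0 < k < umax)
    edges = np.array(sorted(edges))
    x, gw = leggauss(_N_GL)
    a, b = edges[:-1], edges[1:]
    nodes = (0.5 * (b - a)[:, None] * x[None, :] + 0.5 * (a + b)[:, None]).ravel()
    weights = (0.5 * (b - a)[:, None] * gw[None, :]).ravel()
    iv = np.clip(np.searchsorted(fit.cuts, nodes, side="right") - 1, 0, fit.cuts.size - 2)
    return edges, nodes, weights, iv


def _assoc_at_nodes(fit: JointModelFit, nodes, b1_coefs, beta_draws, w, seas_nodes, b0=None):
    """Association covariate per outcome at the layout nodes, (S, L) each,
    on the sampler's internal scale (standardized outcome, scaled time)."""
    out = {}
    for j, k in enumerate(OUTCOME_KINDS):
        spec = fit.specs[k]
        lo, hi = spec.boundary_knots
        if fit.association == "slope":
            Bd = ns_basis_deriv(nodes, spec)
            out[k] = (hi - lo) * (b1_coefs[k] @ Bd.T)
        else:
            B = ns_basis(nodes, spec)
            d = spec.dim
            beta = beta_draws[k]
            base = beta[:, 0] + beta[:, 1 + d] * w[0] + beta[:, 2 + d] * w[1] + b0[k]
            out[k] = b1_coefs[k] @ B.T + base[:, None] + beta[:, 3 + d][:, None] * seas_nodes[None, :]
    return out


def _H_edges(fit, weights, iv, assoc, alpha, gamma, logh0, w, nseg):
    """Cumulative hazard at every layout edge, per draw: (S, nseg + 1)."""
    lp = (gamma @ w)[:, None] + sum(
        alpha[:, j][:, None] * assoc[k] for j, k in enumerate(OUTCOME_KINDS)
    )
    lp = np.clip(lp, -_LP_GUARD, _LP_GUARD)
    c = weights[None, :] * np.exp(logh0[:, iv] + lp)
    seg = c.reshape(c.shape[0], nseg, _N_GL).sum(axis=2)
    return np.concatenate([np.zeros((c.shape[0], 1)), np.cumsum(seg, axis=1)], axis=1)


def sample_conditional_random_effects(
    fit: JointModelFit,
    cow_sensor: pd.DataFrame,
    cow_row,
    v: float,
    n_draws: int = 500,
    seed: int = 0,
    sweeps: int = 4,
    eval_times: np.ndarray | None = None,
):
    """Random-effect draws b ~ p(b | Y(v), T > v, theta) per posterior draw.

    Returns ``(b, idx, aux)``: ``b`` is (S, q); ``idx`` the posterior-draw
    indices used; ``aux`` carries the per-draw parameter arrays and the
    quadrature layout so a caller can finish the survival curve without
    re-deriving anything.
    """
    rng = np.random.default_rng(seed)
    idx = _draw_indices(fit, n_draws)
    S = idx.size
    w = _cow_afc_dummies(fit, cow_row)
    obs = _cow_obs_design(fit, cow_sensor, w, v)

    beta = {k: fit.draws[f"beta_{k}"][idx] for k in OUTCOME_KINDS}
    sigma2 = {k: fit.draws[f"sigma2_{k}"][idx] for k in OUTCOME_KINDS}
    D = fit.draws["D"][idx]
    alpha = fit.draws["alpha"][idx]
    gamma = fit.draws["gamma"][idx]
    logh0 = fit.draws["log_h0"][idx]

    q = sum(1 + s.dim for s in fit.specs.values())
    blocks, s0 = {}, 0
    for k in OUTCOME_KINDS:
        blocks[k] = slice(s0, s0 + 1 + fit.specs[k].dim)
        s0 += 1 + fit.specs[k].dim

    # Gaussian longitudinal conditional per draw
    P = np.linalg.inv(D)
    rhs = np.zeros((S, q))
    for k in OUTCOME_KINDS:
        X, y = obs[k]
        qk = 1 + fit.specs[k].dim
        Z = X[:, :qk]
        r = y[None, :] - beta[k] @ X.T                     # (S, N)
        sl = blocks[k]
        P[:, sl, sl] += (Z.T @ Z)[None, :, :] / sigma2[k][:, None, None]
        rhs[:, sl] += (r @ Z) / sigma2[k][:, None]
    L = np.linalg.cholesky(P)
    mean = np.linalg.solve(P, rhs[:, :, None])[:, :, 0]

    if eval_times is None:
        eval_times = np.array([v])
    eval_times = np.asarray(eval_times, dtype=float)
    edges, nodes, weights, iv = _layout(fit, np.concatenate([[v], eval_times]))
    nseg = edges.size - 1
    m_v = int(np.flatnonzero(np.isclose(edges, v))[0])
    calving1 = cow_row.get("calving1_date") if hasattr(cow_row, "get") else None
    if fit.association == "value":
        months = (pd.Timestamp(calving1) + pd.to_timedelta(np.floor(nodes), unit="D")).month
        seas_nodes = ((np.asarray(months) >= 4) & (np.asarray(months) <= 10)).astype(float)
    else:
        seas_nodes = np.zeros(nodes.size)

    def H_v(b_cur):
        b1 = {k: beta[k][:, 1 : 1 + fit.specs[k].dim] + b_cur[:, blocks[k]][:, 1:]
              for k in OUTCOME_KINDS}
        b0 = {k: b_cur[:, blocks[k]][:, 0] for k in OUTCOME_KINDS}
        assoc = _assoc_at_nodes(fit, nodes, b1, beta, w, seas_nodes, b0)
        return _H_edges(fit, weights, iv, assoc, alpha, gamma, logh0, w, nseg)[:, m_v]

    b_cur = mean.copy()
    h_cur = H_v(b_cur)
    for _ in range(sweeps):
        z = rng.standard_normal((S, q))
        prop = mean + np.linalg.solve(np.swapaxes(L, 1, 2), z[:, :, None])[:, :, 0]
        h_prop = H_v(prop)
        acc = np.log(rng.random(S)) < (h_cur - h_prop)
        b_cur[acc] = prop[acc]
        h_cur[acc] = h_prop[acc]

    aux = {
        "idx": idx, "beta": beta, "alpha": alpha, "gamma": gamma, "logh0": logh0,
        "w": w, "blocks": blocks, "edges": edges, "nodes": nodes, "weights": weights,
        "iv": iv, "seas_nodes": seas_nodes, "m_v": m_v, "nseg": nseg,
    }
    return b_cur, idx, aux


def predict_survival(
    fit: JointModelFit,
    cow_sensor: pd.DataFrame,
    cow_row,
    v: float,
    u_grid: np.ndarray | None = None,
    n_draws: int = 500,
    seed: int = 0,
    keep_draws: bool = False,
) -> SurvivalPrediction:
    """pi_i(u|v) over ``u_grid`` (default: every 7 days from v to t2).

    Grid points at u == v return exactly 1; u < v is an error.  The mean
    curve and every per-draw curve are non-increasing in u by construction
    (each is exp(-H) with H non-decreasing).
    """
    if u_grid is None:
        if fit.t2 is None:
            raise ValueError("no default horizon available; pass u_grid")
        u_grid = np.arange(float(v), float(fit.t2) + 1e-9, 7.0)
        extra = [float(h) for h in (fit.t1, fit.t2) if h is not None and h >= v]
        u_grid = np.unique(np.concatenate([u_grid, extra]))
    u_grid = np.asarray(u_grid, dtype=float)
    if (u_grid < v).any():
        raise ValueError("prediction grid contains u < v")

    b, idx, aux = sample_conditional_random_effects(
        fit, cow_sensor, cow_row, v, n_draws=n_draws, seed=seed, eval_times=u_grid
    )
    blocks = aux["blocks"]
    beta = aux["beta"]
    b1 = {k: beta[k][:, 1 : 1 + fit.specs[k].dim] + b[:, blocks[k]][:, 1:]
          for k in OUTCOME_KINDS}
    b0 = {k: b[:, blocks[k]][:, 0] for k in OUTCOME_KINDS}
    assoc = _assoc_at_nodes(fit, aux["nodes"], b1, beta, aux["w"], aux["seas_nodes"], b0)
    H = _H_edges(
        fit, aux["weights"], aux["iv"], assoc, aux["alpha"], aux["gamma"],
        aux["logh0"], aux["w"], aux["nseg"],
    )
    edge_ix = np.array(
        [int(np.flatnonzero(np.isclose(aux["edges"], u))[0]) for u in u_grid]
    )
    curves = np.exp(-(H[:, edge_ix] - H[:, [aux["m_v"]]]))
    pi = curves.mean(axis=0)
    lo, hi = np.percentile(curves, [2.5, 97.5], axis=0)
    cow_id = cow_row["cow_id"] if "cow_id" in cow_row else "?"
    return SurvivalPrediction(
        cow_id=str(cow_id), v=float(v), u_grid=u_grid, pi=pi,
        ci_lower=lo, ci_upper=hi, n_draws=idx.size,
        draws=curves if keep_draws else None,
    )
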