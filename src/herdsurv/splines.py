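"""Natural cubic spline basis ns(t) with analytic first derivative.

The longitudinal submodels describe each sensor trajectory (milk yield,
body weight, rumination time) as a smooth function of days in milk (DIM)
through a natural cubic spline: piecewise cubic between knots, twice
continuously differentiable, and linear beyond the boundary knots.  The
basis here excludes the intercept (carried by the model's own intercept
term), so its dimension equals the number of interior knots plus one.

Construction: truncated-power representation on time rescaled to the unit
interval.  With scaled knots 0 = kappa_1 < kappa_2 < ... < kappa_K = 1
(interior plus the two boundaries) the basis columns are

    N_1(u) = u
    N_{j+1}(u) = d_j(u) - d_{K-1}(u),   j = 1..K-2

where d_j(u) = [(u - kappa_j)_+^3 - (u - kappa_K)_+^3] / (kappa_K - kappa_j).
The quadratic and cubic terms cancel beyond the upper boundary, and all
truncated powers vanish below the lower boundary, so extrapolation on both
sides is exactly linear (the "natural" condition).

Raw truncated-power columns are severely collinear (condition number in the
hundreds over a lactation), so the columns are linearly recombined once per
knot layout — centered and orthonormalized against the intercept over a
fixed 201-point reference grid on the boundary interval, then scaled to
unit root-mean-square.  The recombination is an affine map of columns: it
preserves the spanned function space, the C^2 smoothness and the linear
tails, and is fully determined by the knots (so serialized specs rebuild it
exactly).  Any valid natural-spline parameterization spans the same
function space; fitted curves, not raw coefficients, are the comparable
quantities across parameterizations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SplineSpec", "make_knots", "ns_basis", "ns_basis_deriv"]


@dataclass(frozen=True)
class SplineSpec:
    """Knot layout for one outcome's natural cubic basis.

    Attributes
    ----------
    interior_knots : tuple of float
        Interior knot positions on the DIM axis.
    boundary_knots : (float, float)
        Lower and upper boundary knots (observed min/max DIM).
    """

    interior_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.boundary_knots
        if not lo < hi:
            raise ValueError(f"boundary knots must be ordered, got {self.boundary_knots}")
        ik = tuple(float(k) for k in self.interior_knots)
        if any(not lo < k < hi for k in ik):
            raise ValueError("interior knots must lie strictly inside the boundary knots")
        if len(set((lo,) + ik + (hi,))) != len(ik) + 2:
            raise ValueError("duplicate knots")
        object.__setattr__(self, "interior_knots", ik)
        object.__setattr__(self, "boundary_knots", (float(lo), float(hi)))

    @property
    def dim(self) -> int:
        """Number of basis columns (interior knots + 1), intercept excluded."""
        return len(self.interior_knots) + 1

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "interior_knots": list(self.interior_knots),
            "boundary_knots": list(self.boundary_knots),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(tuple(d["interior_knots"]), tuple(d["boundary_knots"]))

    def _knot_arrays(self) -> tuple[np.ndarray, float, float]:
        lo, hi = self.boundary_knots
        kappa = (np.array((lo,) + self.interior_knots + (hi,)) - lo) / (hi - lo)
        return kappa, lo, hi - lo

    def _transform(self) -> tuple[np.ndarray, np.ndarray]:
        """(center, mix): conditioning recombination of the raw columns,
        computed once per spec from a fixed reference grid."""
        if not hasattr(self, "_tf_cache"):
            lo, hi = self.boundary_knots
            g = np.linspace(lo, hi, 201)
            R = _eval_raw(g, self)
            c = R.mean(axis=0)
            Q, S = np.linalg.qr(R - c)
            # fix signs so each column increases on average with t
            sign = np.sign(np.diag(S))
            sign[sign == 0] = 1.0
            mix = np.linalg.solve(S, np.diag(sign * np.sqrt(g.size)))
            object.__setattr__(self, "_tf_cache", (c, mix))
        return self._tf_cache


def make_knots(dim_values: np.ndarray, outcome_kind: str) -> SplineSpec:
    """Place knots for one outcome from the pooled observed DIM values.

    Rumination gets a single interior knot at the median DIM; milk yield and
    body weight get three interior knots at the DIM quartiles, capturing the
    well-defined rise-and-decline shape of lactation and growth curves.
    Boundary knots sit at the observed min and max DIM.
    """
    dim_values = np.asarray(dim_values, dtype=float)
    if np.unique(dim_values).size < 10:
        raise ValueError("need at least 10 distinct DIM values to place knots")
    lo, hi = float(dim_values.min()), float(dim_values.max())
    kind = outcome_kind.upper()
    if kind == "RUM":
        interior = (float(np.percentile(dim_values, 50)),)
    elif kind in ("MY", "BW"):
        interior = tuple(float(np.percentile(dim_values, q)) for q in (25, 50, 75))
    else:
        raise ValueError(f"unknown outcome kind {outcome_kind!r}")
    if len(set(interior)) != len(interior):
        raise ValueError("degenerate DIM distribution produced duplicate knots")
    return SplineSpec(interior, (lo, hi))


def _d_terms(u: np.ndarray, kappa: np.ndarray, deriv: bool) -> np.ndarray:
    """d_j(u) (or d_j'(u)) for j = 1..K-1, shape (len(u), K-1)."""
    uk = u[:, None] - kappa[None, :-1]     # u - kappa_j
    uK = u - kappa[-1]                     # u - kappa_K
    if deriv:
        num = 3.0 * np.clip(uk, 0.0, None) ** 2 - 3.0 * np.clip(uK, 0.0, None)[:, None] ** 2
    else:
        num = np.clip(uk, 0.0, None) ** 3 - np.clip(uK, 0.0, None)[:, None] ** 3
    return num / (kappa[-1] - kappa[:-1])[None, :]


def _eval_raw(t, spec: SplineSpec, deriv: bool = False) -> np.ndarray:
    t = np.atleast_1d(np.asarray(t, dtype=float))
    kappa, lo, span = spec._knot_arrays()
    u = (t - lo) / span
    out = np.empty((t.size, spec.dim))
    if deriv:
        out[:, 0] = 1.0 / span
    else:
        out[:, 0] = u
    if spec.dim > 1:
        d = _d_terms(u, kappa, deriv)
        cols = d[:, :-1] - d[:, -1:]
        out[:, 1:] = cols / span if deriv else cols
    return out


def ns_basis(t, spec: SplineSpec) -> np.ndarray:
    """Evaluate the basis at times ``t`` (days); shape (len(t), spec.dim)."""
    c, mix = spec._transform()
    return (_eval_raw(t, spec) - c) @ mix


def ns_basis_deriv(t, spec: SplineSpec) -> np.ndarray:
    """Analytic first derivative of each basis column, per day."""
    _, mix = spec._transform()
    return _eval_raw(t, spec, deriv=True) @ mix
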