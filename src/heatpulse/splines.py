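"""Natural cubic spline bases.

A natural cubic spline is cubic between knots, twice continuously
differentiable everywhere, and constrained to be linear beyond its boundary
knots.  The basis here is the truncated-power construction with the natural
constraints folded in: for knots ``xi_1 < ... < xi_K`` (boundary knots
included) the basis without intercept has ``K - 1`` columns

    N_1(x) = x,
    N_{j+1}(x) = d_j(x) - d_{K-1}(x),   j = 1..K-2,

where ``d_j(x) = [(x - xi_j)_+^3 - (x - xi_K)_+^3] / (xi_K - xi_j)``.

Any natural cubic spline with these knots is an affine combination of the
columns plus a constant, so regression fits are invariant to the particular
basis chosen (this is checked in the test suite against an independent
B-spline construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SplineSpec:
    """Specification of a natural cubic spline basis.

    Parameters
    ----------
    internal_knots : tuple of float
        Knots strictly inside the boundary, strictly increasing.
    boundary_knots : (float, float)
        Interval beyond which the spline is linear.
    intercept : bool
        Whether to include a constant column.
    """

    internal_knots: tuple = field(default=())
    boundary_knots: tuple = (0.0, 1.0)
    intercept: bool = False

    def __post_init__(self):
        ik = tuple(float(k) for k in self.internal_knots)
        bk = tuple(float(b) for b in self.boundary_knots)
        object.__setattr__(self, "internal_knots", ik)
        object.__setattr__(self, "boundary_knots", bk)
        if len(bk) != 2 or not bk[0] < bk[1]:
            raise ValueError(f"boundary knots must be an increasing pair, got {bk}")
        allk = (bk[0],) + ik + (bk[1],)
        if any(not np.isfinite(k) for k in allk):
            raise ValueError("non-finite knot")
        if any(a >= b for a, b in zip(allk, allk[1:])):
            raise ValueError(
                f"knots must be strictly increasing with internal knots inside "
                f"the boundary: internal={ik}, boundary={bk}"
            )

    @property
    def all_knots(self) -> np.ndarray:
        return np.array(
            (self.boundary_knots[0],) + self.internal_knots + (self.boundary_knots[1],)
        )

    @property
    def dim(self) -> int:
        """Number of basis columns: internal knots + 1 (+1 with intercept)."""
        return len(self.internal_knots) + 1 + (1 if self.intercept else 0)


def natural_cubic_basis(x, spec: SplineSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis at ``x``.

    Returns an array of shape ``(len(x), spec.dim)``.  Values outside the
    boundary knots extrapolate linearly, as the natural constraints require.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in x")
    knots = spec.all_knots
    K = len(knots)

    def d(j):
        num = np.clip(x - knots[j], 0.0, None) ** 3 - np.clip(x - knots[-1], 0.0, None) ** 3
        return num / (knots[-1] - knots[j])

    cols = [x]
    dK1 = d(K - 2)
    for j in range(K - 2):
        cols.append(d(j) - dK1)
    if spec.intercept:
        cols = [np.ones_like(x)] + cols
    out = np.column_stack(cols)
    return out[0] if scalar else out


def equal_quantile_spec(values, df: int, intercept: bool = False) -> SplineSpec:
    """Spline spec with ``df`` columns and internal knots at equally spaced
    quantiles of ``values`` (boundary knots at the data range), mirroring the
    common regression-spline default."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("need at least two finite values")
    n_internal = df - 1 - (1 if intercept else 0)
    if n_internal < 0:
        raise ValueError("df too small for the requested basis")
    probs = np.linspace(0, 1, n_internal + 2)[1:-1]
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise ValueError("degenerate values: zero range")
    ik = tuple(float(q) for q in np.quantile(values, probs))
    # nudge knots off the boundary when quantiles collide with the range ends
    eps = 1e-8 * (hi - lo)
    ik = tuple(min(max(k, lo + eps), hi - eps) for k in ik)
    if len(set(ik)) != len(ik):
        raise ValueError("duplicate internal knots from tied quantiles")
    return SplineSpec(internal_knots=ik, boundary_knots=(lo, hi), intercept=intercept)
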