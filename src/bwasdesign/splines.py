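"""Natural cubic spline bases with the knot policies used throughout the package.

A natural cubic spline is piecewise cubic between its knots and constrained to
be *linear* beyond the two boundary knots.  The basis returned here follows the
construction used by R's ``splines::ns``: a cubic B-spline basis on the full
knot sequence is projected onto the null space of the second-derivative
constraints at the boundary knots, and the leading (constant-like) column is
dropped so the basis excludes the intercept.

Knot policies
-------------
``df=2``  one interior knot at the median of ``x``; boundary knots at min/max.
``df=3``  interior knots at the 33rd and 66th percentiles; boundary at min/max.
Other ``df`` require explicit interior knots.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space

__all__ = ["natural_spline_basis", "spline_knots", "NaturalSplineBasis"]


def spline_knots(x: np.ndarray, df: int) -> tuple[np.ndarray, tuple[float, float]]:
    """Interior and boundary knots for the default policy at the given ``df``.

    Returns ``(interior_knots, (lo, hi))``.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if df == 2:
        interior = np.array([np.percentile(x, 50.0)])
    elif df == 3:
        interior = np.percentile(x, [100 / 3, 200 / 3])
    else:
        raise ValueError(
            f"no default knot policy for df={df}; pass interior knots explicitly"
        )
    return interior, (float(np.min(x)), float(np.max(x)))


class NaturalSplineBasis:
    """A fitted natural-spline transform that can be re-applied to new data.

    Stores the knots and the projection matrix so that prediction-time design
    matrices use exactly the training-time basis.
    """

    def __init__(self, interior_knots, boundary_knots):
        self.interior = np.atleast_1d(np.asarray(interior_knots, dtype=float))
        self.lo, self.hi = map(float, boundary_knots)
        if self.hi <= self.lo:
            raise ValueError("boundary knots must satisfy lo < hi")
        # full clamped cubic knot sequence
        self._t = np.concatenate(
            [[self.lo] * 4, np.sort(self.interior), [self.hi] * 4]
        )
        n_b = len(self._t) - 4  # number of cubic B-spline basis functions
        # second derivatives of each B-spline column at the boundary knots
        const = np.empty((2, n_b))
        for j in range(n_b):
            c = np.zeros(n_b)
            c[j] = 1.0
            d2 = BSpline(self._t, c, 3).derivative(2)
            const[0, j] = d2(self.lo)
            const[1, j] = d2(self.hi)
        # drop the leading column (intercept direction), then project the rest
        # onto the null space of the boundary second-derivative constraints
        self._proj = null_space(const[:, 1:])  # (n_b-1, n_b-3)
        self.df = self._proj.shape[1]

    def transform(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float).ravel()
        n_b = len(self._t) - 4
        xc = np.clip(x, self.lo, self.hi)
        cols = np.empty((x.size, n_b))
        d1 = np.zeros((x.size, n_b))
        below, above = x < self.lo, x > self.hi
        for j in range(n_b):
            c = np.zeros(n_b)
            c[j] = 1.0
            sp = BSpline(self._t, c, 3)
            cols[:, j] = sp(xc)
            # linear extension beyond the boundary knots (natural spline)
            if below.any():
                d1[below, j] = sp.derivative()(self.lo)
            if above.any():
                d1[above, j] = sp.derivative()(self.hi)
        out = (cols + d1 * (x - xc)[:, None])[:, 1:] @ self._proj
        return out

    @classmethod
    def from_data(cls, x, df: int, interior_knots=None) -> "NaturalSplineBasis":
        x = np.asarray(x, dtype=float)
        if interior_knots is None:
            interior_knots, bounds = spline_knots(x, df)
        else:
            interior_knots = np.atleast_1d(np.asarray(interior_knots, dtype=float))
            bounds = (float(np.min(x)), float(np.max(x)))
        if np.unique(x).size < len(interior_knots) + 2:
            raise ValueError(
                "fewer distinct values than knots: "
                f"{np.unique(x).size} distinct values, "
                f"{len(interior_knots) + 2} knots required"
            )
        basis = cls(interior_knots, bounds)
        if basis.df != df:
            raise RuntimeError(
                f"constructed basis has df={basis.df}, requested {df}"
            )
        return basis


def natural_spline_basis(x, df: int, interior_knots=None) -> np.ndarray:
    """Evaluate a natural cubic spline basis on ``x``.

    Parameters
    ----------
    x : array-like
        Covariate values.
    df : int
        Basis dimension (number of columns). ``df=2`` and ``df=3`` carry the
        default knot policies (median; 33rd/66th percentiles).
    interior_knots : array-like, optional
        Explicit interior knots, overriding the policy.

    Returns
    -------
    ndarray of shape ``(len(x), df)``; together with a constant column the
    span contains every linear function of ``x`` and is linear beyond the
    boundary knots.
    """
    return NaturalSplineBasis.from_data(x, df, interior_knots).transform(x)
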