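"""Monotone I-spline bases for generalized dissimilarity modelling.

An I-spline of order k is the integral of an M-spline of order k, so it
rises monotonically from 0 to 1 over its support.  We use order-2
M-splines (piecewise linear), giving piecewise-quadratic I-splines, with
knots placed at evenly spaced quantiles of the observed predictor values
(min / median / max for the default K = 3 basis functions).  A GDM with
non-negative coefficients on such a basis is monotone non-decreasing in
every predictor difference by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

ORDER = 2  # M-spline order: piecewise-linear M, piecewise-quadratic I


@dataclass
class ISplineBasis:
    name: str
    knots: np.ndarray  # quantile knot values, length n_basis
    n_basis: int = 3
    _isplines: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        t = np.asarray(self.knots, float)
        if t.size != self.n_basis:
            raise ValueError("need one quantile knot per basis function")
        if np.any(np.diff(t) < 0):
            raise ValueError("knots must be non-decreasing")
        # full M-spline knot sequence with repeated boundary knots
        full = np.concatenate([[t[0]], t, [t[-1]]])
        self._full_knots = full
        self._isplines = []
        for i in range(self.n_basis):
            sub = full[i : i + ORDER + 1]  # 3 knots, degree-1 B-spline element
            if sub[-1] <= sub[0]:
                raise ValueError("degenerate basis: repeated interior knots")
            bs = BSpline.basis_element(sub, extrapolate=False)
            m = ORDER / (sub[-1] - sub[0])
            anti = bs.antiderivative()
            self._isplines.append((sub[0], sub[-1], m, anti))

    @property
    def vmin(self) -> float:
        return float(self.knots[0])

    @property
    def vmax(self) -> float:
        return float(self.knots[-1])

    def evaluate(self, x, clamp: bool = True) -> np.ndarray:
        """Evaluate all basis functions: returns shape x.shape + (n_basis,).

        Values outside [min, max] are clamped to the range (the monotone
        extension: 0 below, 1 above each function's support).
        """
        x = np.asarray(x, float)
        if not clamp and (np.any(x < self.vmin) or np.any(x > self.vmax)):
            raise ValueError("value outside the basis range")
        xc = np.clip(x, self.vmin, self.vmax)
        out = np.empty(x.shape + (self.n_basis,))
        for i, (lo, hi, m, anti) in enumerate(self._isplines):
            below = xc <= lo
            above = xc >= hi
            mid = ~(below | above)
            vals = np.zeros_like(xc, dtype=float)
            vals[above] = 1.0
            if np.any(mid):
                vals[mid] = m * (anti(xc[mid]) - anti(lo))
            out[..., i] = vals
        return out

    def n_clamped(self, x) -> int:
        x = np.asarray(x, float)
        return int(np.sum((x < self.vmin) | (x > self.vmax)))

    def to_dict(self) -> dict:
        return {"name": self.name, "knots": self.knots.tolist(), "n_basis": self.n_basis}

    @classmethod
    def from_dict(cls, d: dict) -> "ISplineBasis":
        return cls(name=d["name"], knots=np.asarray(d["knots"], float), n_basis=d["n_basis"])


def build_ispline_basis(name: str, site_values, n_basis: int = 3) -> ISplineBasis:
    """Basis with knots at evenly spaced quantiles of the observed values
    (0/50/100 percentiles for the default K = 3)."""
    v = np.asarray(site_values, float)
    if np.unique(v).size < 3:
        raise ValueError(f"predictor '{name}' needs >= 3 distinct values")
    qs = np.linspace(0, 100, n_basis)
    knots = np.percentile(v, qs)
    if np.any(np.diff(knots) <= 0):
        raise ValueError(f"predictor '{name}' has coincident quantile knots")
    return ISplineBasis(name=name, knots=knots, n_basis=n_basis)


def build_distance_basis(distances, n_basis: int = 3, name: str = "geographic") -> ISplineBasis:
    """Geographic-distance basis: the lower knot is forced to 0 km so a
    zero-distance pair maps to a zero basis vector."""
    v = np.asarray(distances, float)
    qs = np.linspace(0, 100, n_basis)
    knots = np.percentile(v, qs)
    knots[0] = 0.0
    if np.any(np.diff(knots) <= 0):
        raise ValueError("degenerate distance knots")
    return ISplineBasis(name=name, knots=knots, n_basis=n_basis)
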