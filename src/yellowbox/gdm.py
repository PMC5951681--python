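"""Generalized dissimilarity modelling.

The GDM regresses pairwise genomic dissimilarity d in [0,1] on pairwise
predictor differences through a negative-exponential link:

    mu = 1 - exp(-eta),   eta = b0 + sum_p sum_k b_pk |I_pk(x_i) - I_pk(x_j)|

with all coefficients constrained non-negative so the fitted
dissimilarity is monotone non-decreasing in every predictor difference.
Geographic distance enters as one more I-spline predictor evaluated at
the pair's great-circle distance.  The fit minimizes the squared-error
deviance sum (d - mu)^2 by Gauss-Newton iterations, each solving a
non-negative least-squares subproblem; the procedure is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .distances import PairwiseMatrix
from .isplines import ISplineBasis, build_distance_basis, build_ispline_basis
from .sites import SiteTable

GEO = "geographic"
CONVERGENCE_TOL = 1e-10
MAX_ITER = 100


@dataclass
class PairTable:
    """One row per unordered site pair: response d plus non-negative
    basis-difference columns for every predictor (geography included)."""

    df: pd.DataFrame  # columns: site_a, site_b, d, then basis columns
    bases: dict[str, ISplineBasis]
    predictors: list[str]  # environmental predictors, excludes "geographic"

    @property
    def design_columns(self) -> list[str]:
        cols = []
        for p in self.predictors + [GEO]:
            cols += [f"{p}__i{k}" for k in range(self.bases[p].n_basis)]
        return cols

    def design(self) -> np.ndarray:
        return self.df[self.design_columns].to_numpy(float)

    def response(self) -> np.ndarray:
        return self.df["d"].to_numpy(float)


def make_pair_table(
    sites: SiteTable,
    predictors: list[str],
    response: PairwiseMatrix,
    geo: PairwiseMatrix,
    n_basis: int = 3,
) -> PairTable:
    ids = sites.site_ids
    if response.labels != ids or geo.labels != ids:
        raise ValueError("response/geo labels must match the site table order")
    env = sites.env_values(predictors)  # raises naming site+variable if missing
    bases: dict[str, ISplineBasis] = {
        p: build_ispline_basis(p, env[p].to_numpy(), n_basis) for p in predictors
    }
    tri = np.triu_indices(len(ids), k=1)
    bases[GEO] = build_distance_basis(geo.values[tri], n_basis)

    ai, bj = tri
    rows = {
        "site_a": [ids[i] for i in ai],
        "site_b": [ids[j] for j in bj],
        "d": response.values[tri],
    }
    for p in predictors:
        iv = bases[p].evaluate(env[p].to_numpy())
        diff = np.abs(iv[ai] - iv[bj])
        for k in range(n_basis):
            rows[f"{p}__i{k}"] = diff[:, k]
    gv = bases[GEO].evaluate(geo.values[tri])
    for k in range(n_basis):
        rows[f"{GEO}__i{k}"] = gv[:, k]
    return PairTable(df=pd.DataFrame(rows), bases=bases, predictors=list(predictors))


@dataclass
class GDMModel:
    intercept: float
    coefficients: dict[str, np.ndarray]  # predictor -> (n_basis,) weights >= 0
    bases: dict[str, ISplineBasis]
    predictors: list[str]
    null_deviance: float
    model_deviance: float
    degenerate: bool = False
    n_iterations: int = 0
    fitted_sites: list[str] = field(default_factory=list)
    clamp_count: int = 0  # out-of-range predictor values seen at prediction time

    @property
    def deviance_explained(self) -> float:
        if self.degenerate or self.null_deviance == 0:
            return 0.0
        return 1.0 - self.model_deviance / self.null_deviance

    # -- prediction -----------------------------------------------------

    def partial(self, predictor: str, x) -> np.ndarray:
        """Fitted partial function f_p(x) = sum_k beta_pk I_pk(x)."""
        basis = self.bases[predictor]
        self.clamp_count += basis.n_clamped(x)
        return basis.evaluate(x) @ self.coefficients[predictor]

    def eta(self, env_a: dict, env_b: dict, geo_km: float) -> float:
        s = 0.0
        for p in self.predictors:
            if p not in env_a or p not in env_b:
                raise ValueError(f"missing predictor '{p}'")
            s += abs(float(self.partial(p, env_a[p])) - float(self.partial(p, env_b[p])))
        s += float(self.partial(GEO, geo_km))
        return self.intercept + s

    def predict(self, env_a: dict, env_b: dict, geo_km: float = 0.0) -> float:
        """Predicted dissimilarity in [0, 1) between two environments."""
        return 1.0 - float(np.exp(-self.eta(env_a, env_b, geo_km)))

    # -- serialization --------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "model": "gdm",
            "intercept": self.intercept,
            "predictors": self.predictors,
            "coefficients": {p: c.tolist() for p, c in self.coefficients.items()},
            "bases": {p: b.to_dict() for p, b in self.bases.items()},
            "null_deviance": self.null_deviance,
            "model_deviance": self.model_deviance,
            "deviance_explained": self.deviance_explained,
            "degenerate": self.degenerate,
            "fitted_sites": self.fitted_sites,
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GDMModel":
        d = json.loads(text)
        return cls(
            intercept=d["intercept"],
            coefficients={p: np.asarray(c, float) for p, c in d["coefficients"].items()},
            bases={p: ISplineBasis.from_dict(b) for p, b in d["bases"].items()},
            predictors=d["predictors"],
            null_deviance=d["null_deviance"],
            model_deviance=d["model_deviance"],
            degenerate=d["degenerate"],
            fitted_sites=d.get("fitted_sites", []),
        )


def _deviance(d: np.ndarray, eta: np.ndarray) -> float:
    return float(((d - (1.0 - np.exp(-eta))) ** 2).sum())


def null_deviance(d: np.ndarray) -> tuple[float, float]:
    """Best intercept-only fit: (beta0, deviance).  The optimum matches
    mu = mean(d) when mean(d) > 0, else the boundary beta0 = 0."""
    mbar = float(np.mean(d))
    if mbar <= 0:
        return 0.0, float((d**2).sum())
    b0 = -np.log1p(-mbar) if mbar < 1 else 50.0
    return float(b0), float(((d - mbar) ** 2).sum())


def fit_gdm_design(x: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Core constrained fit on a raw design matrix.

    Minimizes sum (d - (1 - exp(-(b0 + X b))))^2 subject to b0, b >= 0 by
    zero-initialized Gauss-Newton: each iteration linearizes mu around the
    current coefficients and solves NNLS for the full coefficient vector,
    with step-halving if the deviance would increase.  Converges when the
    deviance improves by less than 1e-10, or after 100 iterations.
    Returns (beta with intercept first, deviance, n_iterations).
    """
    x = np.asarray(x, float)
    d = np.asarray(d, float)
    n, m = x.shape
    xt = np.column_stack([np.ones(n), x])
    beta = np.zeros(m + 1)
    dev = _deviance(d, xt @ beta)
    n_iter = 0
    for n_iter in range(1, MAX_ITER + 1):
        eta = xt @ beta
        w = np.exp(-eta)
        a = w[:, None] * xt
        rhs = d - (1.0 - np.exp(-eta)) + a @ beta
        beta_new, _ = nnls(a, rhs)
        dev_new = _deviance(d, xt @ beta_new)
        # step-halving safeguard: Gauss-Newton can overshoot the link
        step = 1.0
        while dev_new > dev and step > 1e-8:
            step /= 2.0
            beta_try = beta + step * (beta_new - beta)
            dev_new = _deviance(d, xt @ beta_try)
            if dev_new <= dev:
                beta_new = beta_try
        if dev_new > dev + CONVERGENCE_TOL:
            break  # no improving step; accept current beta
        improved = dev - dev_new
        beta, dev = beta_new, dev_new
        if improved < CONVERGENCE_TOL:
            break
    else:
        raise RuntimeError(
            f"GDM fit did not converge in {MAX_ITER} iterations (deviance {dev:.3e})"
        )
    return beta, dev, n_iter


def fit_gdm(pair_table: PairTable) -> GDMModel:
    """Fit the GDM on a pair table (see :func:`fit_gdm_design`)."""
    d = pair_table.response()
    if np.any(d < 0) or np.any(d > 1):
        raise ValueError("response values must lie in [0, 1]")
    x = pair_table.design()
    if x.shape[0] < 3:
        raise ValueError("too few pairs to fit")

    _, d_null = null_deviance(d)
    if np.allclose(d, 0.0):
        coefs = _unpack(np.zeros(x.shape[1]), pair_table)
        return GDMModel(
            intercept=0.0, coefficients=coefs, bases=dict(pair_table.bases),
            predictors=list(pair_table.predictors), null_deviance=0.0,
            model_deviance=0.0, degenerate=True,
            fitted_sites=_pair_sites(pair_table),
        )

    beta, dev, n_iter = fit_gdm_design(x, d)
    # a (near-)constant response leaves nothing to explain
    degenerate = d_null <= 1e-12 * max(1.0, float((d**2).sum()))
    return GDMModel(
        intercept=float(beta[0]),
        coefficients=_unpack(beta[1:], pair_table),
        bases=dict(pair_table.bases),
        predictors=list(pair_table.predictors),
        null_deviance=d_null,
        model_deviance=dev,
        degenerate=degenerate,
        n_iterations=n_iter,
        fitted_sites=_pair_sites(pair_table),
    )


def _unpack(flat: np.ndarray, pt: PairTable) -> dict[str, np.ndarray]:
    out, i = {}, 0
    for p in pt.predictors + [GEO]:
        k = pt.bases[p].n_basis
        out[p] = np.asarray(flat[i : i + k], float)
        i += k
    return out


def _pair_sites(pt: PairTable) -> list[str]:
    return sorted(set(pt.df["site_a"]).union(pt.df["site_b"]))


def predict_dissimilarity(model: GDMModel, env_a: dict, env_b: dict, geo_km: float = 0.0) -> float:
    return model.predict(env_a, env_b, geo_km)


def deviance_explained(model: GDMModel) -> float:
    return model.deviance_explained


def spline_curves(model: GDMModel, n_points: int = 200) -> pd.DataFrame:
    """Partial response curves f_p(x) on a grid over each training range.

    Long format: predictor, x, f.  Every curve starts at 0 and rises
    monotonically to sum_k beta_pk.
    """
    frames = []
    for p in model.predictors + [GEO]:
        b = model.bases[p]
        xs = np.linspace(b.vmin, b.vmax, n_points)
        f = b.evaluate(xs) @ model.coefficients[p]
        frames.append(pd.DataFrame({"predictor": p, "x": xs, "f": f}))
    return pd.concat(frames, ignore_index=True)
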