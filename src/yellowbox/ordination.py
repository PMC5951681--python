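"""Principal coordinates analysis and the Mantel test.

PCoA is classical metric scaling: double-center -D^2/2, eigendecompose,
keep positive eigenvalues.  The Mantel test correlates the lower
triangles of two labeled matrices, with significance from simultaneous
row/column permutation of one matrix; a natural-log transform of the
second matrix (geographic distance) is built in, with co-located pairs
floored at 1 m before the log so ln is defined.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .distances import PairwiseMatrix

#: 1 m in km: floor applied to zero geographic distances before ln
LOG_ZERO_FLOOR_KM = 0.001


@dataclass
class OrdinationResult:
    coordinates: np.ndarray  # items x axes
    eigenvalues: np.ndarray  # non-increasing, positive axes only
    percent_variance: np.ndarray
    labels: list[str] = field(default_factory=list)


def pcoa(dist: PairwiseMatrix, n_axes: int | None = None) -> OrdinationResult:
    d = dist.values
    n = len(dist.labels)
    d2 = d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-10 * abs(evals[0])) if n else 0.0
    pos = evals > tol
    lam = evals[pos]
    coords = evecs[:, pos] * np.sqrt(lam)
    pct = 100.0 * lam / lam.sum() if lam.size else lam
    if n_axes is not None:
        coords, lam, pct = coords[:, :n_axes], lam[:n_axes], pct[:n_axes]
    return OrdinationResult(
        coordinates=coords, eigenvalues=lam, percent_variance=pct, labels=list(dist.labels)
    )


@dataclass
class MantelResult:
    r: float
    r_squared: float
    p_value: float
    n_perm: int
    transform_b: str | None = None


def _tri(values: np.ndarray) -> np.ndarray:
    i, j = np.triu_indices(values.shape[0], k=1)
    return values[i, j]


def mantel_test(
    dm_a: PairwiseMatrix,
    dm_b: PairwiseMatrix,
    n_perm: int = 9999,
    transform_b: str | None = "ln",
    seed: int | None = None,
    exact: bool = False,
) -> MantelResult:
    """One-sided (positive association) Mantel test of dm_a vs dm_b.

    With ``exact=True`` all n! label permutations are enumerated instead of
    sampling (feasible for small matrices only); the p-value is then the
    exact proportion of permutations with r >= observed r.
    """
    if dm_a.labels != dm_b.labels:
        raise ValueError("matrix labels do not match")
    n = len(dm_a.labels)
    a = _tri(dm_a.values)
    bmat = dm_b.values.astype(float).copy()
    if transform_b in ("ln", "natural-log"):
        off = ~np.eye(n, dtype=bool)
        bmat[off] = np.log(np.maximum(bmat[off], LOG_ZERO_FLOOR_KM))
    elif transform_b is not None:
        raise ValueError(f"unknown transform: {transform_b}")

    b = _tri(bmat)
    r_obs = _pearson(a, b)

    iu = np.triu_indices(n, k=1)
    if exact:
        perms = itertools.permutations(range(n))
        count = total = 0
        for p in perms:
            pm = bmat[np.ix_(p, p)]
            total += 1
            if _pearson(a, pm[iu]) >= r_obs - 1e-12:
                count += 1
        return MantelResult(
            r=r_obs, r_squared=r_obs**2, p_value=count / total,
            n_perm=math.factorial(n), transform_b=transform_b,
        )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        pm = bmat[np.ix_(p, p)]
        if _pearson(a, pm[iu]) >= r_obs - 1e-12:
            count += 1
    p_value = (1 + count) / (n_perm + 1)
    return MantelResult(
        r=r_obs, r_squared=r_obs**2, p_value=p_value, n_perm=n_perm, transform_b=transform_b
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return 0.0
    return float((xc * yc).sum() / denom)
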