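"""Pairwise matrices: genomic Euclidean distance and great-circle geography."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import haversine_distances

from ._util import MISSING, check_symmetric
from .genotypes import GenotypeMatrix
from .sites import SiteTable

#: mean (authalic) Earth radius in km
EARTH_RADIUS_KM = 6371.0087714

DISTANCE_KINDS = {"genomic", "geographic", "environmental"}


@dataclass
class PairwiseMatrix:
    """A labeled symmetric matrix of pairwise statistics.

    ``kind`` tags the contents: genomic | geographic | environmental
    distances (non-negative, zero diagonal) or fst | scaled_fst (may be
    negative before scaling).
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "genomic"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        check_symmetric(v, name=f"{self.kind} matrix")
        if self.kind in DISTANCE_KINDS:
            if np.any(np.diag(v) != 0):
                raise ValueError("distance matrix must have a zero diagonal")
            if np.any(v < 0):
                raise ValueError("distance matrix must be non-negative")
        self.values = v

    def triu_values(self) -> np.ndarray:
        """Upper-triangle (i<j) entries in row-major pair order."""
        i, j = np.triu_indices(len(self.labels), k=1)
        return self.values[i, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path, kind: str) -> "PairwiseMatrix":
        df = pd.read_csv(path, index_col="id")
        return cls(labels=[str(c) for c in df.columns], values=df.to_numpy(float), kind=kind)

    def __len__(self) -> int:
        return len(self.labels)


def genomic_distance_euclidean(gm: GenotypeMatrix) -> PairwiseMatrix:
    """Euclidean distance between samples' genotype rows.

    Missing calls are handled pairwise-complete: each pair's squared
    distance is summed over loci called in both samples and rescaled by
    total_loci / shared_loci, so samples with different missingness stay
    on a common scale.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    g = gm.calls.astype(float)
    called = g != MISSING
    g0 = np.where(called, g, 0.0)
    m = called.astype(float)
    sq = g0**2
    # sum over shared loci of (gi - gj)^2, via masked cross-products
    s2 = sq @ m.T + m @ sq.T - 2.0 * (g0 @ g0.T)
    shared = m @ m.T
    if np.any(shared[np.triu_indices(gm.n_samples, k=1)] == 0):
        i, j = np.where(shared == 0)
        pair = (gm.samples[i[0]], gm.samples[j[0]])
        raise ValueError(f"sample pair shares zero called loci: {pair}")
    with np.errstate(invalid="ignore"):
        d = np.sqrt(np.maximum(s2, 0.0) * (gm.n_loci / shared))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against float noise
    return PairwiseMatrix(labels=list(gm.samples), values=d, kind="genomic")


def geographic_distance(source) -> PairwiseMatrix:
    """Great-circle distances in km on a sphere of the authalic radius.

    ``source`` is a SiteTable (site-level matrix) or a DataFrame/array of
    per-item (lat, lon) in decimal degrees with an index of labels.
    """
    if isinstance(source, SiteTable):
        labels, coords = source.site_ids, source.coords
    elif isinstance(source, pd.DataFrame):
        labels = [str(i) for i in source.index]
        coords = source[["lat", "lon"]].to_numpy(float)
    else:
        coords = np.asarray(source, dtype=float)
        labels = [str(i) for i in range(len(coords))]
    if np.any((coords[:, 0] < -90) | (coords[:, 0] > 90)):
        raise ValueError("latitude outside [-90, 90]")
    if np.any((coords[:, 1] < -180) | (coords[:, 1] > 180)):
        raise ValueError("longitude outside [-180, 180]")
    d = haversine_distances(np.radians(coords)) * EARTH_RADIUS_KM
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return PairwiseMatrix(labels=labels, values=d, kind="geographic")
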