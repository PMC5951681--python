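"""Weir-Cockerham F_st, per-site diversity, and unit-interval scaling.

The F_st estimator is the Weir & Cockerham (1984) analysis-of-variance
form for diploid data: per-locus variance components a (among
populations), b (among individuals within populations) and c (within
individuals), combined across loci as a ratio of sums
theta = sum(a) / sum(a + b + c).  Loci monomorphic in the populations
being compared carry no information and are skipped.  Single-locus
estimates, and multilocus estimates between very similar populations,
can be slightly negative; negative values are retained (they matter for
the downstream unit-interval scaling of the whole matrix).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import PairwiseMatrix
from .genotypes import GenotypeMatrix


def wc_components(p: np.ndarray, n: np.ndarray, het: np.ndarray):
    """Per-locus Weir-Cockerham variance components for r populations.

    Arguments are (r, n_loci) arrays: alt-allele frequency ``p``, number of
    genotyped diploids ``n``, and observed heterozygote count ``het``.
    Returns (a, b, c, valid): component arrays over loci and a mask of loci
    where the estimator is defined (every population has a called genotype,
    total sample large enough, locus polymorphic in these populations).
    """
    p = np.asarray(p, float)
    n = np.asarray(n, float)
    het = np.asarray(het, float)
    r = p.shape[0]
    if r < 2:
        raise ValueError("need at least 2 populations")
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n.mean(axis=0)
        nsum = n.sum(axis=0)
        nc = (nsum - (n**2).sum(axis=0) / nsum) / (r - 1)
        pbar = (n * p).sum(axis=0) / nsum
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = het.sum(axis=0) / nsum
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    valid = (n >= 1).all(axis=0) & (nsum >= 3) & (pbar > 0) & (pbar < 1)
    return a, b, c, valid


def multilocus_theta(p, n, het) -> float:
    """Ratio-of-sums multilocus Weir-Cockerham theta over valid loci."""
    a, b, c, valid = wc_components(p, n, het)
    if not valid.any():
        raise ValueError("no polymorphic locus with data in every population")
    num = a[valid].sum()
    den = (a[valid] + b[valid] + c[valid]).sum()
    return float(num / den)


def pairwise_fst_wc(gm: GenotypeMatrix) -> PairwiseMatrix:
    """Pairwise two-population Weir-Cockerham F_st between sites."""
    sites, p, n, het = gm.allele_counts_by_site()
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    thin = [s for k, s in enumerate(sites) if (n[k] >= 2).sum() == 0]
    if thin:
        raise ValueError(f"site(s) with <2 genotyped samples at every locus: {thin}")
    m = len(sites)
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            idx = np.array([i, j])
            out[i, j] = out[j, i] = multilocus_theta(p[idx], n[idx], het[idx])
    return PairwiseMatrix(labels=sites, values=out, kind="fst")


def global_fst_wc(gm: GenotypeMatrix) -> float:
    """Multilocus Weir-Cockerham theta across all sites at once."""
    _, p, n, het = gm.allele_counts_by_site()
    return multilocus_theta(p, n, het)


def per_locus_fst_components(gm: GenotypeMatrix):
    """Per-locus (a, a+b+c) over valid loci, for locus-bootstrap resampling."""
    _, p, n, het = gm.allele_counts_by_site()
    a, b, c, valid = wc_components(p, n, het)
    if not valid.any():
        raise ValueError("no polymorphic locus with data in every site")
    return a[valid], (a + b + c)[valid]


def scale_unit_interval(fst: PairwiseMatrix) -> PairwiseMatrix:
    """Map the off-diagonal values onto [0, 1]: subtract the minimum, then
    divide by the maximum of the shifted values.  The diagonal stays 0.
    """
    v = fst.values.copy()
    n = len(fst.labels)
    off = ~np.eye(n, dtype=bool)
    vals = v[off]
    vmin, vmax = vals.min(), vals.max()
    if vmax == vmin:
        raise ValueError("constant off-diagonal values: scaling is degenerate")
    v[off] = (vals - vmin) / (vmax - vmin)
    np.fill_diagonal(v, 0.0)
    return PairwiseMatrix(labels=list(fst.labels), values=v, kind="scaled_fst")


@dataclass
class DiversityTable:
    df: pd.DataFrame  # index site_id; columns n_alleles, expected_het, n_loci_called

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index_label="site_id")


def site_diversity(gm: GenotypeMatrix) -> DiversityTable:
    """Observed allele counts and mean expected heterozygosity per site.

    He is averaged over loci with at least one called genotype at the
    site: mean of 1 - p^2 - q^2 with p the site's alt-allele frequency.
    """
    sites, p, n, _het = gm.allele_counts_by_site()
    rows = []
    for k, site in enumerate(sites):
        called = n[k] > 0
        pk = p[k, called]
        ref_seen = pk < 1
        alt_seen = pk > 0
        n_alleles = int(ref_seen.sum() + alt_seen.sum())
        he = float((1 - pk**2 - (1 - pk) ** 2).mean()) if called.any() else np.nan
        rows.append((site, n_alleles, he, int(called.sum())))
    df = pd.DataFrame(
        rows, columns=["site_id", "n_alleles", "expected_het", "n_loci_called"]
    ).set_index("site_id")
    return DiversityTable(df)
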