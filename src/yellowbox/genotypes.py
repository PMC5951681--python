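"""Genotype matrix I/O and filtering.

Genotypes are stored as alt-allele counts (0/1/2) in an int8 matrix of
samples x loci, with -1 marking missing calls.  Loading goes through
cyvcf2; only biallelic SNP records are retained (others are dropped and
counted).  Filtering applies, in order: a per-sample missingness cut, a
per-locus missingness cut, and greedy physical thinning so no two
retained loci on a chromosome are closer than a minimum spacing.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from ._util import MISSING


@dataclass(frozen=True)
class Locus:
    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str


@dataclass
class GenotypeMatrix:
    """Samples x loci alt-allele counts with site assignments."""

    calls: np.ndarray  # int8, (n_samples, n_loci), values {0,1,2,MISSING}
    loci: list[Locus]
    samples: list[str]
    site_of: dict[str, str]  # sample_id -> site_id

    def __post_init__(self):
        calls = np.asarray(self.calls, dtype=np.int8)
        if calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError("calls shape does not match samples x loci")
        bad = ~np.isin(calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("calls must be in {0,1,2} or missing")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        keys = [(l.chrom, l.pos) for l in self.loci]
        if sorted(keys) != keys or len(set(keys)) != len(keys):
            raise ValueError("loci must be sorted by (chrom, pos) and unique")
        missing_site = [s for s in self.samples if s not in self.site_of]
        if missing_site:
            raise ValueError(f"samples without site assignment: {missing_site}")
        self.calls = calls

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def sample_sites(self) -> list[str]:
        return [self.site_of[s] for s in self.samples]

    def sample_missing_fraction(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=1)

    def locus_missing_fraction(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def site_ids(self) -> list[str]:
        return sorted(set(self.sample_sites))

    def subset(self, sample_idx=None, locus_idx=None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        li = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        return GenotypeMatrix(
            calls=self.calls[np.ix_(si, li)].copy(),
            loci=[self.loci[i] for i in li],
            samples=[self.samples[i] for i in si],
            site_of={self.samples[i]: self.site_of[self.samples[i]] for i in si},
        )

    def restrict_to_sites(self, site_ids) -> "GenotypeMatrix":
        keep = set(site_ids)
        idx = [i for i, s in enumerate(self.samples) if self.site_of[s] in keep]
        if not idx:
            raise ValueError(f"no samples from sites {sorted(keep)}")
        return self.subset(sample_idx=idx)

    def allele_counts_by_site(self):
        """Per-site, per-locus alt-allele frequency, called-sample count,
        and observed-heterozygote count.

        Returns (site_ids, p, n, het) with arrays shaped (n_sites, n_loci);
        p is nan where a site has no called genotype at a locus.
        """
        sites = self.site_ids()
        n_sites = len(sites)
        p = np.full((n_sites, self.n_loci), np.nan)
        n = np.zeros((n_sites, self.n_loci), dtype=np.int64)
        het = np.zeros((n_sites, self.n_loci), dtype=np.int64)
        sample_sites = np.asarray(self.sample_sites)
        for k, site in enumerate(sites):
            sub = self.calls[sample_sites == site]
            called = sub != MISSING
            n[k] = called.sum(axis=0)
            alt = np.where(called, sub, 0).sum(axis=0)
            het[k] = (sub == 1).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                p[k] = np.where(n[k] > 0, alt / (2.0 * n[k]), np.nan)
        return sites, p, n, het


@dataclass
class LoadReport:
    n_records: int = 0
    n_dropped_non_biallelic_snp: int = 0
    n_samples_unassigned: int = 0
    unassigned_samples: list[str] = field(default_factory=list)


def load_genotypes(vcf_source, site_assignments) -> tuple[GenotypeMatrix, LoadReport]:
    """Read biallelic SNP genotypes from a VCF into a GenotypeMatrix.

    ``vcf_source`` is a path or a text stream; ``site_assignments`` maps
    sample_id -> site_id (dict, or DataFrame/CSV path with columns
    sample_id, site_id).  Samples absent from the assignment table are
    excluded and counted in the report; non-biallelic / non-SNP records
    are dropped and counted.
    """
    assign = _as_assignment_dict(site_assignments)
    tmp_path = None
    try:
        if hasattr(vcf_source, "read"):
            text = vcf_source.read()
            fd, tmp_path = tempfile.mkstemp(suffix=".vcf")
            with os.fdopen(fd, "w") as fh:
                fh.write(text)
            path = tmp_path
        else:
            path = os.fspath(vcf_source)
            if not os.path.exists(path):
                raise IOError(f"VCF not found: {path}")
        try:
            vcf = VCF(path, gts012=True)
        except Exception as e:  # pragma: no cover - cyvcf2 raises various types
            raise IOError(f"unreadable VCF: {e}") from e

        report = LoadReport()
        all_samples = list(vcf.samples)
        keep = [i for i, s in enumerate(all_samples) if s in assign]
        dropped = [s for s in all_samples if s not in assign]
        report.n_samples_unassigned = len(dropped)
        report.unassigned_samples = dropped
        if not keep:
            raise ValueError("no VCF sample overlaps the site assignment table")
        keep_arr = np.asarray(keep)
        samples = [all_samples[i] for i in keep]

        rows, loci = [], []
        for variant in vcf:
            report.n_records += 1
            if (
                len(variant.ALT) != 1
                or len(variant.REF) != 1
                or len(variant.ALT[0]) != 1
                or variant.ALT[0] not in "ACGT"
                or variant.REF not in "ACGT"
            ):
                report.n_dropped_non_biallelic_snp += 1
                continue
            gt = np.asarray(variant.gt_types)[keep_arr].astype(np.int8)
            gt[gt == 3] = MISSING  # gts012: 3 == unknown
            rows.append(gt)
            loci.append(Locus(str(variant.CHROM), int(variant.POS), variant.REF, variant.ALT[0]))
    finally:
        if tmp_path is not None:
            os.unlink(tmp_path)

    calls = (
        np.stack(rows, axis=1) if rows else np.zeros((len(samples), 0), dtype=np.int8)
    )
    order = sorted(range(len(loci)), key=lambda i: (loci[i].chrom, loci[i].pos))
    calls = calls[:, order]
    loci = [loci[i] for i in order]
    gm = GenotypeMatrix(
        calls=calls,
        loci=loci,
        samples=samples,
        site_of={s: assign[s] for s in samples},
    )
    return gm, report


def _as_assignment_dict(site_assignments) -> dict[str, str]:
    if isinstance(site_assignments, dict):
        return {str(k): str(v) for k, v in site_assignments.items()}
    if isinstance(site_assignments, (str, os.PathLike)):
        site_assignments = pd.read_csv(site_assignments)
    df = site_assignments
    return dict(zip(df["sample_id"].astype(str), df["site_id"].astype(str)))


@dataclass
class FilterReport:
    n_samples_removed: int
    n_loci_removed_missing: int
    n_loci_removed_thinning: int
    removed_samples: list[str]


def filter_and_thin(
    gm: GenotypeMatrix,
    max_sample_missing: float = 0.60,
    max_locus_missing: float = 0.60,
    min_spacing_bp: int = 300,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the sample-missingness, locus-missingness, and spacing filters.

    Thresholds are strict-greater cutoffs: a sample or locus is removed only
    if its missing fraction exceeds the threshold.  Thinning keeps, per
    chromosome scanning left to right, each locus strictly more than
    ``min_spacing_bp`` from the last kept one.
    """
    if gm.n_samples == 0 or gm.n_loci == 0:
        raise ValueError("empty genotype matrix")

    smiss = gm.sample_missing_fraction()
    keep_s = np.where(smiss <= max_sample_missing)[0]
    removed_samples = [gm.samples[i] for i in np.where(smiss > max_sample_missing)[0]]
    if keep_s.size == 0:
        raise ValueError("all samples removed at the sample-missingness stage")
    gm1 = gm.subset(sample_idx=keep_s)

    lmiss = gm1.locus_missing_fraction()
    keep_l = np.where(lmiss <= max_locus_missing)[0]
    n_loci_missing = gm1.n_loci - keep_l.size
    if keep_l.size == 0:
        raise ValueError("all loci removed at the locus-missingness stage")
    gm2 = gm1.subset(locus_idx=keep_l)

    keep_thin = []
    last_pos: dict[str, int] = {}
    for i, loc in enumerate(gm2.loci):
        last = last_pos.get(loc.chrom)
        if last is None or loc.pos - last > min_spacing_bp:
            keep_thin.append(i)
            last_pos[loc.chrom] = loc.pos
    n_thinned = gm2.n_loci - len(keep_thin)
    if not keep_thin:
        raise ValueError("all loci removed at the thinning stage")
    out = gm2.subset(locus_idx=keep_thin)
    return out, FilterReport(
        n_samples_removed=len(removed_samples),
        n_loci_removed_missing=n_loci_missing,
        n_loci_removed_thinning=n_thinned,
        removed_samples=removed_samples,
    )
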