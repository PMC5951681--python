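"""Q_st-F_st comparison for maternal half-sib designs.

The observed statistic is Delta = Q_st - F_st, with Q_st from the nested
phenotypic variance components and F_st the multilocus Weir-Cockerham
estimate over the phenotyped sites.  The null distribution is built by
parametric simulation under neutrality:

  (a) bootstrap loci to draw F*;
  (b) set the neutral among-site variance implied by F*:
      s2_site* = [2 F* / (1 - F*)] * (4 * s2_fam_hat);
  (c) draw the variance components through their chi-square sampling
      distributions with the ANOVA degrees of freedom — concretely, each
      stratum MEAN SQUARE is scaled chi-square, so the mean squares are
      simulated and pushed back through the moment equations (components
      are differences of mean squares, which is where most of the
      among-site sampling noise lives, and are truncated at zero exactly
      as in the observed analysis);
  (d) Delta* = Q_st* - F*.

The family and residual variances that parameterize the null mean
squares are nuisance values; they are estimated by pooling every
experimental condition in the phenotype table (the family structure is
shared across conditions), which roughly doubles their degrees of
freedom and keeps the null width from being dominated by plug-in noise.
The default p-value is two-tailed with the +1 correction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .fst import multilocus_theta, per_locus_fst_components
from .genotypes import GenotypeMatrix
from .phenotypes import PhenotypeTable, VarComponents, nested_variance_components, qst_halfsib


@dataclass
class QstFstResult:
    qst: float
    fst: float
    delta: float
    null_delta: np.ndarray
    p_value: float
    n_sim: int
    seed: int
    components: VarComponents
    two_tailed: bool = True

    def to_json(self) -> str:
        return json.dumps(
            {
                "qst": self.qst,
                "fst": self.fst,
                "delta": self.delta,
                "p_value": self.p_value,
                "n_sim": self.n_sim,
                "seed": self.seed,
                "two_tailed": self.two_tailed,
                "sigma2_site": self.components.sigma2_site,
                "sigma2_fam": self.components.sigma2_fam,
                "sigma2_res": self.components.sigma2_res,
            },
            indent=2,
            sort_keys=True,
        )


def qst_fst_test(
    ph: PhenotypeTable,
    gm: GenotypeMatrix,
    trait: str,
    condition=None,
    n_sim: int = 10000,
    seed: int = 0,
    two_tailed: bool = True,
) -> QstFstResult:
    if n_sim < 100:
        warnings.warn(f"n_sim={n_sim} is small; the null sample will be coarse",
                      stacklevel=2)
    pheno_df = ph.for_condition(condition) if condition is not None else ph.df
    pheno_sites = sorted(pheno_df["site_id"].astype(str).unique())
    gm_sites = gm.restrict_to_sites(pheno_sites)

    vc = nested_variance_components(ph, trait, condition)
    qst = qst_halfsib(vc)
    fst = multilocus_theta(*_counts(gm_sites))
    delta = qst - fst
    fam0, res0 = _pooled_nuisances(ph, trait, vc)

    a_l, abc_l = per_locus_fst_components(gm_sites)
    n_loci = a_l.size
    rng = np.random.default_rng(seed)

    # (a) locus bootstrap of the multilocus theta
    idx = rng.integers(0, n_loci, size=(n_sim, n_loci))
    f_star = a_l[idx].sum(axis=1) / abc_l[idx].sum(axis=1)
    f_star = np.clip(f_star, -0.999, 0.999)

    # (b) neutral among-site variance implied by each F*
    s2_site_neutral = np.maximum(
        (2.0 * f_star / (1.0 - f_star)) * 4.0 * fam0, 0.0
    )

    # (c) chi-square sampling noise on the stratum mean squares, pushed
    # back through the same moment equations as the observed analysis;
    # the site mean square is centred on the replicate's own lower strata
    # so the moment subtraction is internally consistent
    ms_res = res0 * rng.chisquare(vc.df_res, n_sim) / vc.df_res
    ms_fam = (res0 + vc.n0 * fam0) * rng.chisquare(vc.df_fam, n_sim) / vc.df_fam
    s2_fam_star = np.maximum((ms_fam - ms_res) / vc.n0, 0.0)
    ems_site = ms_res + vc.n0p * s2_fam_star + vc.nb * s2_site_neutral
    ms_site = ems_site * rng.chisquare(vc.df_site, n_sim) / vc.df_site
    s2_site_star = np.maximum(
        (ms_site - ms_res - vc.n0p * s2_fam_star) / vc.nb, 0.0
    )

    denom = s2_site_star + 8.0 * s2_fam_star
    with np.errstate(invalid="ignore", divide="ignore"):
        qst_star = np.where(denom > 0, s2_site_star / denom, 0.0)
    null_delta = qst_star - f_star

    if two_tailed:
        n_extreme = int(np.sum(np.abs(null_delta) >= abs(delta)))
    else:
        n_extreme = int(np.sum(null_delta >= delta))
    p = (1 + n_extreme) / (n_sim + 1)
    return QstFstResult(
        qst=float(qst), fst=float(fst), delta=float(delta), null_delta=null_delta,
        p_value=float(p), n_sim=n_sim, seed=seed, components=vc, two_tailed=two_tailed,
    )


def _pooled_nuisances(ph: PhenotypeTable, trait: str, vc: VarComponents):
    """Family/residual variances pooled over all experimental conditions.

    Falls back to the analyzed condition's own estimates if another
    condition lacks the required replication.
    """
    fams, ress = [], []
    for cond in ph.df["condition"].unique():
        try:
            v = nested_variance_components(ph, trait, cond)
        except ValueError:
            continue
        fams.append(v.sigma2_fam)
        ress.append(v.sigma2_res)
    if not fams:
        return vc.sigma2_fam, vc.sigma2_res
    return float(np.mean(fams)), float(np.mean(ress))


def _counts(gm: GenotypeMatrix):
    _, p, n, het = gm.allele_counts_by_site()
    return p, n, het
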