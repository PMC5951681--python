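"""Seedling phenotype metrics and nested variance components.

The growth-trait table is long format: one row per seedling with site,
maternal line (nested in site), experimental condition, block and trait
value.  Variance components for the half-sib Q_st come from the nested
ANOVA (sites / maternal lines within sites / residual) by method of
moments, using the unbalanced-design expected-mean-square coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: relative height increments above this per-day rate are flagged for review
RHI_OUTLIER_THRESHOLD = 0.035

REQUIRED_COLUMNS = ("seedling_id", "site_id", "maternal_line", "condition")


def relative_height_increment(h1, h2, t1, t2):
    """Per-day relative growth rate: (ln h2 - ln h1) / (t2 - t1)."""
    h1, h2 = np.asarray(h1, float), np.asarray(h2, float)
    t1, t2 = np.asarray(t1, float), np.asarray(t2, float)
    if np.any(h1 <= 0) or np.any(h2 <= 0):
        raise ValueError("heights must be positive")
    if np.any(t2 <= t1):
        raise ValueError("t2 must exceed t1")
    return (np.log(h2) - np.log(h1)) / (t2 - t1)


def flag_rhi_outliers(rhi, threshold: float = RHI_OUTLIER_THRESHOLD) -> np.ndarray:
    """Boolean flags for implausibly fast growth; flagged, never removed."""
    return np.asarray(rhi, float) > threshold


def specific_leaf_area(area_mm2, mass_mg):
    """SLA: leaf area divided by dry mass (mm^2 / mg)."""
    area, mass = np.asarray(area_mm2, float), np.asarray(mass_mg, float)
    if np.any(area <= 0) or np.any(mass <= 0):
        raise ValueError("area and mass must be positive")
    return area / mass


@dataclass
class PhenotypeTable:
    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"phenotype table missing column(s): {missing}")
        # a maternal line belongs to exactly one site
        lines = self.df.groupby("maternal_line")["site_id"].nunique()
        bad = lines[lines > 1].index.tolist()
        if bad:
            raise ValueError(f"maternal line(s) appear in multiple sites: {bad}")

    def for_condition(self, condition) -> pd.DataFrame:
        return self.df[self.df["condition"] == condition]

    @classmethod
    def from_csv(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class VarComponents:
    sigma2_site: float
    sigma2_fam: float
    sigma2_res: float
    df_site: int
    df_fam: int
    df_res: int
    truncated: list[str] = field(default_factory=list)  # components floored at 0
    # unbalanced-design EMS coefficients (E[MS_fam] = s2_res + n0 s2_fam;
    # E[MS_site] = s2_res + n0p s2_fam + nb s2_site); kept so the sampling
    # distribution of the mean squares can be re-simulated
    n0: float = float("nan")
    n0p: float = float("nan")
    nb: float = float("nan")


def nested_variance_components(
    ph: PhenotypeTable, trait: str, condition=None
) -> VarComponents:
    """Method-of-moments components from the two-level nested ANOVA.

    Uses the standard unbalanced-design coefficients (Sokal-Rohlf style):
      E[MS_res]  = s2_res
      E[MS_fam]  = s2_res + n0 * s2_fam
      E[MS_site] = s2_res + n0' * s2_fam + nb * s2_site
    Negative moment estimates are truncated to zero and flagged.
    """
    df = ph.for_condition(condition) if condition is not None else ph.df
    df = df.dropna(subset=[trait])
    sites = df["site_id"].unique()
    if len(sites) < 2:
        raise ValueError("need >= 2 sites")
    for site, sub in df.groupby("site_id"):
        if sub["maternal_line"].nunique() < 2:
            raise ValueError(f"site {site!r} needs >= 2 maternal lines")
        counts = sub.groupby("maternal_line").size()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise ValueError(f"line(s) {bad} in site {site!r} need >= 2 seedlings")

    y = df[trait].to_numpy(float)
    n_tot = len(y)
    grand = y.mean()

    line_stats = (
        df.groupby(["site_id", "maternal_line"])[trait].agg(["mean", "size"]).reset_index()
    )
    site_stats = df.groupby("site_id")[trait].agg(["mean", "size"])

    a = len(sites)
    b_total = len(line_stats)
    df_site, df_fam, df_res = a - 1, b_total - a, n_tot - b_total

    line_mean = df.merge(
        line_stats.rename(columns={"mean": "_lm"})[["site_id", "maternal_line", "_lm"]],
        on=["site_id", "maternal_line"],
    )["_lm"].to_numpy()
    ss_res = float(((y - line_mean) ** 2).sum())
    site_mean_of_line = site_stats.loc[line_stats["site_id"], "mean"].to_numpy()
    ss_fam = float(
        (line_stats["size"].to_numpy() * (line_stats["mean"].to_numpy() - site_mean_of_line) ** 2).sum()
    )
    ss_site = float(
        (site_stats["size"].to_numpy() * (site_stats["mean"].to_numpy() - grand) ** 2).sum()
    )

    ms_res = ss_res / df_res
    ms_fam = ss_fam / df_fam
    ms_site = ss_site / df_site

    n_ij = line_stats["size"].to_numpy(float)
    n_i = site_stats["size"].to_numpy(float)
    sum_nij2_over_ni = (
        line_stats.assign(sq=n_ij**2)
        .groupby("site_id")["sq"]
        .sum()
        .to_numpy()
        / n_i
    ).sum()
    n0 = (n_tot - sum_nij2_over_ni) / df_fam
    n0p = (sum_nij2_over_ni - (n_ij**2).sum() / n_tot) / df_site
    nb = (n_tot - (n_i**2).sum() / n_tot) / df_site

    truncated = []
    s2_res = ms_res
    s2_fam = (ms_fam - ms_res) / n0
    if s2_fam < 0:
        s2_fam = 0.0
        truncated.append("sigma2_fam")
    s2_site = (ms_site - ms_res - n0p * s2_fam) / nb
    if s2_site < 0:
        s2_site = 0.0
        truncated.append("sigma2_site")
    return VarComponents(
        sigma2_site=float(s2_site), sigma2_fam=float(s2_fam), sigma2_res=float(s2_res),
        df_site=df_site, df_fam=df_fam, df_res=df_res, truncated=truncated,
        n0=float(n0), n0p=float(n0p), nb=float(nb),
    )


def qst_halfsib(vc: VarComponents) -> float:
    """Q_st for maternal half-sib families.

    With offspring related through shared mothers, the additive variance is
    V_A = 4 * sigma2_fam, so Q_st = s2_site / (s2_site + 2 V_A) =
    s2_site / (s2_site + 8 * s2_fam).
    """
    if vc.sigma2_site < 0 or vc.sigma2_fam < 0:
        raise ValueError("components must be non-negative")
    denom = vc.sigma2_site + 8.0 * vc.sigma2_fam
    if denom == 0:
        raise ValueError("Q_st undefined: site and family components are both zero")
    return float(vc.sigma2_site / denom)


def variance_partition(ph: PhenotypeTable, trait: str) -> pd.DataFrame:
    """Sequential (type-I) sums-of-squares percent-variance partition over
    condition, site, maternal line within site, and residual.

    A fixed-effects approximation of a mixed-model partition: the order is
    condition first, then site, then line-in-site, and percentages are of
    the total sum of squares.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = ph.df.dropna(subset=[trait]).copy()
    df["_y"] = df[trait]
    model = smf.ols(
        "_y ~ C(condition) + C(site_id) + C(site_id):C(maternal_line)", data=df
    ).fit()
    anova = sm.stats.anova_lm(model, typ=1)
    ss = anova["sum_sq"]
    total = ss.sum()
    if total == 0:
        raise ValueError("trait has zero variance")
    out = pd.DataFrame(
        {
            "term": ["condition", "site", "line_in_site", "residual"],
            "sum_sq": [
                ss.get("C(condition)", 0.0),
                ss.get("C(site_id)", 0.0),
                ss.get("C(site_id):C(maternal_line)", 0.0),
                ss.get("Residual", 0.0),
            ],
        }
    )
    out["percent"] = 100.0 * out["sum_sq"] / total
    return out
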