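"""Synthetic landscapes, genotypes and phenotypes with known truth.

The generator emulates the statistical structure the pipeline assumes: a
few dozen sampling sites scattered over a ~1000 km landscape, thousands
of biallelic SNPs whose between-site differentiation increases with a
known generalized-dissimilarity linear predictor eta (isolation by
distance with a flat region below a distance threshold, plus isolation
by environment along spatially autocorrelated layers), and half-sib
seedling phenotypes with site / maternal-line / residual variance
components.  Every draw is a pure function of (config, master seed), and
a TruthRecord stores everything needed to recompute expected values.

Site-frequency model: per locus, an ancestral frequency p0 ~ U(0.1, 0.9)
receives site-level logit deviations drawn from a multivariate normal
with covariance C_ij = s2 * exp(-eta_ij), so expected differentiation
rises monotonically with eta.  The realized F_st scale is calibrated
empirically by the logit variance s2, not analytically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

from ._util import MISSING, rng_for
from .distances import geographic_distance
from .genotypes import GenotypeMatrix, Locus
from .isplines import ISplineBasis
from .phenotypes import PhenotypeTable
from .rasters import EnvRasterStack
from .sites import SiteTable

#: reference lat/lon: km grid coordinates are mapped to WGS84 around here
REF_LAT, REF_LON = -35.0, 147.0
KM_PER_DEG_LAT = 110.574


@dataclass
class WorldConfig:
    # landscape
    grid_size: int = 64
    cell_km: float = 20.0
    n_layers: int = 4
    corr_length_cells: float = 8.0
    # sampling design
    n_sites: int = 36
    samples_per_site: tuple[int, int] = (3, 10)  # inclusive uniform range
    site_min_separation_km: float | None = None  # default: 1.5 grid cells
    n_loci: int = 9378
    missing_rate: float = 0.02
    # true GDM: intercept, per-layer spline weights on fixed env knots,
    # and a geographic effect flat below a distance threshold
    eta_intercept: float = 0.05
    env_weights: tuple[float, ...] = (0.35, 0.28, 0.22, 0.15)
    env_knots: tuple[float, float, float] = (-2.5, 0.0, 2.5)
    geo_threshold_km: float = 500.0
    geo_max: float = 0.7
    geo_ref_km: float = 1400.0  # distance at which the geographic term reaches geo_max
    # genotype noise scale (logit-deviation variance); sets the F_st scale
    logit_var: float = 0.5
    # phenotypes
    lines_per_site: int = 6
    seedlings_per_line: int = 8
    conditions: tuple[str, ...] = ("warm", "hot")
    condition_effects: tuple[float, ...] = (0.0, 1.0)
    sigma2_fam: float = 1.0
    sigma2_res: float = 4.0
    sigma2_site: float | None = None  # None => neutral, implied by realized F_st
    # future scenario: per-layer uniform shift plus west-east gradient, in sd units
    future_shift: tuple[float, ...] = (1.0, 0.5, 0.25, 0.0)
    future_gradient: tuple[float, ...] = (0.0, 0.0, 0.0, 0.5)
    seed: int = 0

    @property
    def layer_names(self) -> list[str]:
        return [f"env{i}" for i in range(self.n_layers)]

    @property
    def extent_km(self) -> float:
        return self.grid_size * self.cell_km


@dataclass
class TruthRecord:
    site_ids: list[str]
    env: dict  # site_id -> {layer: value}
    eta: np.ndarray  # true linear predictor, sites x sites
    mu: np.ndarray  # 1 - exp(-eta)
    drivers: list[str]  # layers with nonzero true weight
    config: dict
    sub_seeds: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "site_ids": self.site_ids,
                "env": self.env,
                "eta": self.eta.tolist(),
                "mu": self.mu.tolist(),
                "drivers": self.drivers,
                "config": self.config,
                "sub_seeds": self.sub_seeds,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        return cls(
            site_ids=d["site_ids"], env=d["env"], eta=np.asarray(d["eta"]),
            mu=np.asarray(d["mu"]), drivers=d["drivers"], config=d["config"],
            sub_seeds=d["sub_seeds"],
        )


# -- environment -----------------------------------------------------------


def generate_environment(cfg: WorldConfig) -> tuple[EnvRasterStack, EnvRasterStack]:
    """Gaussian-random-field layers (mean 0, sd 1 over the grid) and the
    deterministically shifted future scenario."""
    if cfg.corr_length_cells >= cfg.grid_size:
        raise ValueError("correlation length must be below the grid extent")
    rng = rng_for(cfg.seed, "environment")
    n = cfg.grid_size
    current, future = {}, {}
    xg = np.linspace(0.0, 1.0, n)[None, :].repeat(n, axis=0)  # west->east ramp
    shifts = _padded(cfg.future_shift, cfg.n_layers)
    grads = _padded(cfg.future_gradient, cfg.n_layers)
    for i, name in enumerate(cfg.layer_names):
        white = rng.standard_normal((n, n))
        smooth = gaussian_filter(white, sigma=cfg.corr_length_cells, mode="reflect")
        layer = (smooth - smooth.mean()) / smooth.std()
        current[name] = layer
        future[name] = layer + shifts[i] + grads[i] * xg
    mk = lambda layers, tag: EnvRasterStack(
        layers=layers, x_origin=0.0, y_origin=0.0, cell_size=cfg.cell_km,
        crs="local-km", scenario=tag,
    )
    return mk(current, "current"), mk(future, "future")


def _padded(values, n):
    v = list(values)[:n]
    return v + [0.0] * (n - len(v))


# -- sites -----------------------------------------------------------------


def place_sites(cfg: WorldConfig, stack: EnvRasterStack) -> SiteTable:
    """Scatter sites uniformly over the grid (2-cell margin, >= 1.5-cell
    mutual separation) and read their environments off the layers."""
    rng = rng_for(cfg.seed, "sites")
    lo = 2 * cfg.cell_km
    hi = cfg.extent_km - 2 * cfg.cell_km
    min_sep = cfg.site_min_separation_km or 1.5 * cfg.cell_km
    pts: list[tuple[float, float]] = []
    while len(pts) < cfg.n_sites:
        x, y = rng.uniform(lo, hi, size=2)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_sep**2 for px, py in pts):
            pts.append((float(x), float(y)))
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    lat = REF_LAT + ys / KM_PER_DEG_LAT
    lon = REF_LON + xs / (KM_PER_DEG_LAT * np.cos(np.deg2rad(REF_LAT)))
    n_lo, n_hi = cfg.samples_per_site
    n_genotyped = rng.integers(n_lo, n_hi + 1, size=cfg.n_sites)
    data = {
        "lat": lat, "lon": lon, "x_km": xs, "y_km": ys, "n_genotyped": n_genotyped,
    }
    for name in cfg.layer_names:
        data[name] = stack.sample(name, xs, ys)
    ids = [f"S{i:02d}" for i in range(cfg.n_sites)]
    df = pd.DataFrame(data, index=pd.Index(ids, name="site_id"))
    return SiteTable(df, env_columns=list(cfg.layer_names))


# -- truth -----------------------------------------------------------------


def true_env_basis(cfg: WorldConfig, name: str) -> ISplineBasis:
    return ISplineBasis(name=name, knots=np.asarray(cfg.env_knots, float), n_basis=3)


def true_geo_effect(cfg: WorldConfig, d_km) -> np.ndarray:
    """Flat below the threshold, then linear up to geo_max at geo_ref_km."""
    d = np.asarray(d_km, float)
    rise = (d - cfg.geo_threshold_km) / (cfg.geo_ref_km - cfg.geo_threshold_km)
    return cfg.geo_max * np.clip(rise, 0.0, None)


def true_eta(cfg: WorldConfig, sites: SiteTable) -> np.ndarray:
    env = sites.env_values(cfg.layer_names)
    s = len(sites)
    eta = np.full((s, s), cfg.eta_intercept)
    np.fill_diagonal(eta, 0.0)
    for w, name in zip(cfg.env_weights, cfg.layer_names):
        basis = true_env_basis(cfg, name)
        f = basis.evaluate(env[name].to_numpy()) @ (w * np.ones(3) / 3.0)
        eta += np.abs(f[:, None] - f[None, :])
    geo = geographic_distance(sites).values
    off = ~np.eye(s, dtype=bool)
    eta[off] += true_geo_effect(cfg, geo[off])
    return eta


def make_truth(cfg: WorldConfig, sites: SiteTable) -> TruthRecord:
    eta = true_eta(cfg, sites)
    mu = 1.0 - np.exp(-eta)
    np.fill_diagonal(mu, 0.0)
    env = sites.env_values(cfg.layer_names)
    drivers = [n for w, n in zip(cfg.env_weights, cfg.layer_names) if w > 0]
    return TruthRecord(
        site_ids=sites.site_ids,
        env={sid: {c: float(env.loc[sid, c]) for c in cfg.layer_names}
             for sid in sites.site_ids},
        eta=eta, mu=mu, drivers=drivers, config=asdict(cfg),
        sub_seeds={
            "environment": cfg.seed, "sites": cfg.seed, "genotypes": cfg.seed,
            "phenotypes": cfg.seed,
        },
    )


# -- genotypes -------------------------------------------------------------


def generate_genotypes(cfg: WorldConfig, sites: SiteTable) -> tuple[GenotypeMatrix, TruthRecord]:
    truth = make_truth(cfg, sites)
    rng = rng_for(cfg.seed, "genotypes")
    s = len(sites)
    cov = cfg.logit_var * np.exp(-truth.eta)
    np.fill_diagonal(cov, cfg.logit_var)
    # exp(-eta) need not be PSD for an arbitrary eta; lift the diagonal by
    # the most negative eigenvalue (a little extra site-independent noise)
    lam_min = float(np.linalg.eigvalsh(cov).min())
    jitter = max(0.0, -lam_min) + 1e-9
    try:
        chol = np.linalg.cholesky(cov + jitter * np.eye(s))
    except np.linalg.LinAlgError as e:
        rng_eta = (truth.eta.min(), truth.eta.max())
        raise ValueError(f"covariance not positive definite (eta range {rng_eta})") from e

    p0 = rng.uniform(0.1, 0.9, size=cfg.n_loci)
    z = chol @ rng.standard_normal((s, cfg.n_loci))
    p_site = expit(logit(p0)[None, :] + z)

    n_per_site = sites.df["n_genotyped"].to_numpy(int)
    samples, site_of, rows = [], {}, []
    for k, sid in enumerate(sites.site_ids):
        g = rng.binomial(2, p_site[k], size=(n_per_site[k], cfg.n_loci)).astype(np.int8)
        for j in range(n_per_site[k]):
            name = f"{sid}_t{j}"
            samples.append(name)
            site_of[name] = sid
        rows.append(g)
    calls = np.vstack(rows)
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = MISSING
    # physically distinct loci: one chromosome, positions 400 bp apart
    loci = [Locus("chr1", 1 + 400 * i, "A", "C") for i in range(cfg.n_loci)]
    gm = GenotypeMatrix(calls=calls, loci=loci, samples=samples, site_of=site_of)
    return gm, truth


# -- phenotypes ------------------------------------------------------------


def neutral_sigma2_site(fst: float, sigma2_fam: float) -> float:
    """Among-site variance for which Q_st equals the given F_st under the
    half-sib model: s2_site = [2F/(1-F)] * (4 * s2_fam)."""
    if not 0 <= fst < 1:
        raise ValueError("fst must lie in [0, 1)")
    return (2.0 * fst / (1.0 - fst)) * 4.0 * sigma2_fam


def generate_phenotypes(
    cfg: WorldConfig,
    sites: SiteTable | list[str],
    realized_fst: float | None = None,
    trait: str = "height",
) -> PhenotypeTable:
    """Half-sib seedling phenotypes: y = mu + condition + site + line + noise.

    If cfg.sigma2_site is None the among-site variance is the neutral value
    implied by ``realized_fst`` (required in that case), so Q_st tracks the
    genomic differentiation.
    """
    if cfg.lines_per_site < 2 or cfg.seedlings_per_line < 2:
        raise ValueError("need >= 2 lines per site and >= 2 seedlings per line")
    site_ids = sites.site_ids if isinstance(sites, SiteTable) else [str(x) for x in sites]
    if cfg.sigma2_site is not None:
        s2_site = cfg.sigma2_site
    else:
        if realized_fst is None:
            raise ValueError("neutral phenotypes need the realized F_st")
        s2_site = neutral_sigma2_site(realized_fst, cfg.sigma2_fam)
    rng = rng_for(cfg.seed, "phenotypes")
    base = 100.0
    cond_fx = dict(zip(cfg.conditions, _padded(cfg.condition_effects, len(cfg.conditions))))
    site_fx = rng.normal(0.0, np.sqrt(s2_site), size=len(site_ids))
    rows = []
    for si, sid in enumerate(site_ids):
        line_fx = rng.normal(0.0, np.sqrt(cfg.sigma2_fam), size=cfg.lines_per_site)
        for li in range(cfg.lines_per_site):
            line = f"{sid}_L{li}"
            for cond in cfg.conditions:
                noise = rng.normal(0.0, np.sqrt(cfg.sigma2_res), size=cfg.seedlings_per_line)
                for r in range(cfg.seedlings_per_line):
                    rows.append(
                        {
                            "seedling_id": f"{line}_{cond}_{r}",
                            "site_id": sid,
                            "maternal_line": line,
                            "condition": cond,
                            "block": r % 4,
                            trait: base + cond_fx[cond] + site_fx[si] + line_fx[li] + noise[r],
                        }
                    )
    return PhenotypeTable(pd.DataFrame(rows))


# -- VCF fixture -----------------------------------------------------------


def generate_vcf_fixture(gm: GenotypeMatrix, path=None) -> str:
    """Minimal VCF 4.2 text (GT only) encoding a genotype matrix."""
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        *(f"##contig=<ID={c}>" for c in dict.fromkeys(l.chrom for l in gm.loci)),
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples),
    ]
    for j, loc in enumerate(gm.loci):
        gts = "\t".join(gt_code[int(g)] for g in gm.calls[:, j])
        lines.append(
            f"{loc.chrom}\t{loc.pos}\t.\t{loc.ref}\t{loc.alt}\t.\tPASS\t.\tGT\t{gts}"
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# -- presets ---------------------------------------------------------------


def paper_scale_config(seed: int = 0) -> WorldConfig:
    """The full study-scale world: 36 sites, 3-10 samples each, 9,378 loci,
    four environmental drivers (plus four pure-noise candidate layers for
    selection experiments) and geography flat to 500 km."""
    return WorldConfig(
        n_layers=8,
        env_weights=(0.35, 0.28, 0.22, 0.15, 0.0, 0.0, 0.0, 0.0),
        seed=seed,
    )


def small_config(seed: int = 0) -> WorldConfig:
    """A reduced world for quick end-to-end runs and examples."""
    return WorldConfig(
        grid_size=40, cell_km=30.0, n_sites=18, n_loci=1500,
        samples_per_site=(4, 8), corr_length_cells=6.0, seed=seed,
    )
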