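import numpy as np
import pandas as pd
import pytest

import yellowbox as yb
from yellowbox.genotypes import GenotypeMatrix, Locus


def make_gm(calls, sites=None, positions=None, chrom="chr1"):
    """Build a GenotypeMatrix from a plain list-of-lists of calls."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_loci = calls.shape
    if positions is None:
        positions = [1 + 1000 * i for i in range(n_loci)]
    loci = [Locus(chrom, p, "A", "C") for p in positions]
    samples = [f"s{i}" for i in range(n_samples)]
    if sites is None:
        sites = ["site1"] * n_samples
    return GenotypeMatrix(
        calls=calls, loci=loci, samples=samples,
        site_of=dict(zip(samples, sites)),
    )


@pytest.fixture(scope="session")
def small_world():
    """One small synthetic world shared by read-only tests."""
    cfg = yb.small_config(seed=11)
    current, future = yb.generate_environment(cfg)
    sites = yb.place_sites(cfg, current)
    gm, truth = yb.generate_genotypes(cfg, sites)
    return {
        "cfg": cfg, "current": current, "future": future,
        "sites": sites, "gm": gm, "truth": truth,
    }


@pytest.fixture(scope="session")
def small_world_gdm(small_world):
    """Scaled F_st, geography and a fitted full GDM for the small world."""
    sites = small_world["sites"]
    fst = yb.pairwise_fst_wc(small_world["gm"])
    scaled = yb.scale_unit_interval(fst)
    geo = yb.geographic_distance(sites)
    cfg = small_world["cfg"]
    pt = yb.make_pair_table(sites, cfg.layer_names, scaled, geo)
    model = yb.fit_gdm(pt)
    return {"fst": fst, "scaled": scaled, "geo": geo, "pair_table": pt, "model": model}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_sites():
    """Four sites on a short latitudinal transect with two env variables."""
    df = pd.DataFrame(
        {
            "lat": [-36.0, -35.5, -35.0, -34.5],
            "lon": [147.0, 147.2, 147.4, 147.6],
            "temp": [10.0, 12.0, 15.0, 19.0],
            "rain": [700.0, 650.0, 500.0, 420.0],
        },
        index=pd.Index(["A", "B", "C", "D"], name="site_id"),
    )
    return yb.SiteTable(df)
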