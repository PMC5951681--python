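"""Project a fitted model onto the landscape.

Produces the three map products: an RGB genomic-composition map (similar
colors = similar predicted genomic composition), genomic vulnerability
(dissimilarity between each cell's current and future environments), and
a seed-source map for a restoration target (low values = good matches to
the target's future climate).
"""

import numpy as np

import yellowbox as yb

cfg = yb.small_config(seed=42)
current, future = yb.generate_environment(cfg)
sites = yb.place_sites(cfg, current)
gm, _ = yb.generate_genotypes(cfg, sites)
scaled = yb.scale_unit_interval(yb.pairwise_fst_wc(gm))
geo = yb.geographic_distance(sites)
model = yb.fit_gdm(yb.make_pair_table(sites, cfg.layer_names, scaled, geo))

proj = yb.pca_rgb(yb.transform_environment(model, current))
print(f"composition map: PCA of {len(proj.transformed.names)} transformed "
      f"layers; first three axes carry "
      f"{proj.pca_percent_variance[:3].sum():.1f}% of the variance")

vuln = yb.genomic_vulnerability(model, current, future)
valid = proj.mask.grid
print(f"genomic vulnerability: mean {vuln[valid].mean():.3f}, "
      f"max {vuln[valid].max():.3f} "
      "(genomic change required to track the climate shift in place)")

# a restoration site at the middle of the map, planted for 'future' climate
t = cfg.extent_km / 2
fut_env = {p: float(future.sample(p, t, t)) for p in model.predictors}
ssm = yb.seed_source_map(model, (t, t), fut_env, current)
best = np.unravel_index(np.argmin(np.where(valid, ssm, np.inf)), ssm.shape)
by, bx = (best[0] + 0.5) * cfg.cell_km, (best[1] + 0.5) * cfg.cell_km
print(f"seed sourcing: best-matching cell at ({bx:.0f}, {by:.0f}) km, "
      f"dissimilarity {ssm[best]:.3f}; target is at ({t:.0f}, {t:.0f}) km")
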