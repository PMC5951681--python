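"""Distances, ordination, isolation by distance, diversity, F_st.

Loads genotypes through the VCF round trip, applies the missing-data and
300 bp spacing filters, and prints the summary statistics that feed the
dissimilarity model.
"""

import io

import yellowbox as yb

cfg = yb.small_config(seed=42)
current, _ = yb.generate_environment(cfg)
sites = yb.place_sites(cfg, current)
gm0, _ = yb.generate_genotypes(cfg, sites)

# round-trip through VCF text, then filter: samples/loci over 60%
# missing are dropped, loci thinned so none are within 300 bp
vcf = yb.generate_vcf_fixture(gm0)
gm, load_report = yb.load_genotypes(io.StringIO(vcf), {s: gm0.site_of[s] for s in gm0.samples})
gm, filt = yb.filter_and_thin(gm)
print(f"{gm.n_samples} samples x {gm.n_loci} loci after filtering "
      f"({filt.n_loci_removed_thinning} loci thinned)")

gdist = yb.genomic_distance_euclidean(gm)
ordination = yb.pcoa(gdist, n_axes=2)
print(f"PCoA axes 1+2 explain {ordination.percent_variance[:2].sum():.1f}% "
      "of genomic variation (low values mean continuous structure)")

coords = sites.df.loc[[gm.site_of[s] for s in gm.samples], ["lat", "lon"]]
coords.index = gm.samples
geo = yb.geographic_distance(coords)
mantel = yb.mantel_test(gdist, geo, n_perm=999, seed=1)
print(f"Mantel: genomic vs ln(geographic) r^2 = {mantel.r_squared:.3f}, "
      f"p = {mantel.p_value:.4f} (isolation by distance)")

fst = yb.pairwise_fst_wc(gm)
print(f"pairwise Weir-Cockerham Fst: mean {fst.triu_values().mean():.4f}, "
      f"max {fst.triu_values().max():.4f} (low: high gene flow)")

div = yb.site_diversity(gm).df
print(f"expected heterozygosity per site: "
      f"{div['expected_het'].min():.3f}-{div['expected_het'].max():.3f}")
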