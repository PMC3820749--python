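"""DRB coverage analysis: RPKM, 75th-percentile normalization, Δlog2 groups.

Simulates K36me3 coverage with and without the elongation inhibitor DRB,
computes per-gene body RPKM, normalizes each condition to its 75th
percentile, groups genes by Δlog2(DRB+ over DRB−) at the ±0.6 boundary, and
tests whether RAR-associated genes are underrepresented in the "decreased"
group — the genomic signature of elongation-independent me3 maintenance at
nuclear-receptor sites.
"""

from ashkit.coverage import (
    drb_dlog2,
    group_by_response,
    metagene_profile,
    percentile75_normalize,
    region_rpkm_table,
    underrepresentation_test,
)
from ashkit.synth import SyntheticConfig, draw_labels, place_genes, simulate_coverage

config = SyntheticConfig(seed=3, n_genes=5000, n_chroms=8)
genome, genes = place_genes(config)
truth = draw_labels(config, genes)
tracks = simulate_coverage(config, genes, truth, genome, marks=("K36me3",))

plus = percentile75_normalize(region_rpkm_table(tracks[("K36me3", "DRB+")], genes))
minus = percentile75_normalize(region_rpkm_table(tracks[("K36me3", "DRB-")], genes))
print(f"75th-percentile normalizers: DRB+ {plus.normalizer:.3f}, "
      f"DRB- {minus.normalizer:.3f} (raw RPKM units)")

d = drb_dlog2(plus, minus)
groups = group_by_response(d)
print("group sizes:", dict(groups.value_counts()))

report = underrepresentation_test(groups, truth["rar_associated"])
for cat in report.categories:
    print(
        f"  {cat.category:<10} RAR in group: {cat.in_group:>4}  "
        f"ratio {cat.relative_ratio:.2f}  chi2 {cat.statistic:8.1f}  "
        f"p {cat.p_value:.2e}  {cat.direction}"
    )

profile = metagene_profile(tracks[("K36me3", "DRB-")], genes[:500], genome)
ratio = profile.log2_ratio_profile()
print(f"metagene (DRB-): {profile.values.shape[0]} genes x "
      f"{profile.values.shape[1]} bins; body log2 ratio to genome mean "
      f"{ratio[20:120].mean():.2f}, flank {ratio[:20].mean():.2f}")
print()
print("RAR-associated genes keep their me3 under DRB (configured loss -0.1")
print("vs -1.0 log2), so they are depleted from the 'decreased' group; the")
print("metagene shows body enrichment over the genomic background.")
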