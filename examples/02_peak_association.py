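"""Associate ChIP peaks with genes and measure RAR/Ash1l co-occupancy.

Ash1l-target genes carry an Ash1l peak within +/-4 kb of the TSS;
RAR-associated genes carry a RAR peak between 20 kb upstream of the TSS and
the transcription end.  Co-occupancy is the fraction of RAR peaks directly
overlapped by an Ash1l peak.
"""

from ashkit.association import AssociationRule, associate, co_occupancy, cross_tabulate
from ashkit.synth import SyntheticConfig, draw_labels, place_genes, simulate_peaks

config = SyntheticConfig(seed=11, n_genes=2000, co_occupancy=0.60)
genome, genes = place_genes(config)
truth = draw_labels(config, genes)
ash1l, rar = simulate_peaks(config, genes, truth, genome)

targets = associate(
    genes, ash1l, AssociationRule("tss_window", flank=4000), genome
).associated_genes()
rar_genes = associate(
    genes, rar, AssociationRule("upstream_and_body", upstream=20_000), genome
).associated_genes()

frac = co_occupancy(rar, ash1l, max_gap=0)
universe = {g.gene_id for g in genes}
impaired = set(truth.index[truth["impaired"]])
both, t_only, i_only, neither = cross_tabulate(targets, impaired, universe)

print(f"Ash1l-target genes:  {len(targets)}")
print(f"RAR-associated:      {len(rar_genes)}")
print(f"peak co-occupancy:   {100 * frac:.1f}% of {len(rar)} RAR peaks "
      f"(generator setting 60%)")
print(f"targets x impaired:  both={both}  target-only={t_only} "
      f"impaired-only={i_only}  neither={neither}")
print()
print("The co-occupancy fraction estimates how often the nuclear receptor")
print("and the methyltransferase bind the same site; the 2x2 table is the")
print("Venn-diagram input relating occupancy to expression impairment.")
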