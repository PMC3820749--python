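"""Peak-to-gene association and peak-level co-occupancy.

Two window rules are used: a target gene for a promoter-proximal factor
(e.g. Ash1l) carries a peak overlapping TSS ± 4 kb; a nuclear-receptor
associated gene (e.g. RAR) carries a peak anywhere from 20 kb upstream of
the TSS through the transcription end.  Association is any-overlap of the
peak interval with the window; a peak may associate with several genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

from .intervals import (
    GeneModel,
    Genome,
    GenomicInterval,
    Peak,
    PeakSet,
    ValidationError,
    tss_window,
    upstream_and_body_window,
)

__all__ = ["AssociationRule", "AssociationResult", "associate", "co_occupancy", "cross_tabulate"]


@dataclass(frozen=True)
class AssociationRule:
    """Which window to draw around each gene.

    ``tss_window`` mode uses ``flank`` (bp) either side of the TSS;
    ``upstream_and_body`` uses ``upstream`` (bp) 5' of the TSS through the TES.
    """

    mode: str = "tss_window"
    flank: int = 4000
    upstream: int = 20000

    def __post_init__(self) -> None:
        if self.mode not in ("tss_window", "upstream_and_body"):
            raise ValidationError(f"unknown association mode {self.mode!r}")
        if self.flank <= 0 or self.upstream <= 0:
            raise ValidationError("window distances must be positive")

    def window(self, gene: GeneModel, genome: Genome) -> GenomicInterval:
        if self.mode == "tss_window":
            return tss_window(gene, self.flank, genome)
        return upstream_and_body_window(gene, self.upstream, genome)


@dataclass
class AssociationResult:
    """Per-gene association flags and the supporting peak names."""

    rule: AssociationRule
    flags: Dict[str, bool]
    peak_names: Dict[str, List[str]]

    def associated_genes(self) -> Set[str]:
        return {g for g, ok in self.flags.items() if ok}


def associate(
    genes: Sequence[GeneModel],
    peaks: PeakSet,
    rule: AssociationRule,
    genome: Genome,
) -> AssociationResult:
    """Flag each gene whose rule window overlaps at least one peak."""
    for p in peaks:
        if p.interval.chrom not in genome.chrom_sizes:
            raise ValidationError(
                f"peak on unknown chromosome {p.interval.chrom!r}"
            )
    flags: Dict[str, bool] = {}
    names: Dict[str, List[str]] = {}
    for i, gene in enumerate(genes):
        window = rule.window(gene, genome)
        hit = peaks.any_overlap(window)
        flags[gene.gene_id] = hit
        if hit:
            names[gene.gene_id] = [
                p.name or f"{peaks.factor}_peak{j}"
                for j, p in enumerate(peaks.overlapping(window))
            ]
        else:
            names[gene.gene_id] = []
    return AssociationResult(rule, flags, names)


def co_occupancy(primary: PeakSet, secondary: PeakSet, max_gap: int = 0) -> float:
    """Fraction of primary peaks with a secondary peak within ``max_gap`` bp.

    ``max_gap=0`` demands direct overlap (half-open semantics).
    """
    if len(primary) == 0:
        raise ValidationError("primary peak set is empty")
    if max_gap < 0:
        raise ValidationError("max_gap must be >= 0")
    n_hit = 0
    for p in primary:
        iv = p.interval
        query = GenomicInterval(
            iv.chrom, max(0, iv.start - max_gap), iv.end + max_gap
        )
        if secondary.any_overlap(query):
            n_hit += 1
    return n_hit / len(primary)


def cross_tabulate(
    set_a: Set[str], set_b: Set[str], universe: Set[str]
) -> Tuple[int, int, int, int]:
    """2x2 counts (A∩B, A only, B only, neither); cells sum to |universe|."""
    if not set_a <= universe:
        raise ValidationError("set A contains genes outside the universe")
    if not set_b <= universe:
        raise ValidationError("set B contains genes outside the universe")
    both = len(set_a & set_b)
    a_only = len(set_a - set_b)
    b_only = len(set_b - set_a)
    neither = len(universe) - both - a_only - b_only
    return both, a_only, b_only, neither
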