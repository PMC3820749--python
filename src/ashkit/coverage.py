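"""Region RPKM, 75th-percentile normalization, DRB-response grouping and
metagene / anchor-centered coverage profiles.

The DRB analysis asks how a histone mark's gene-body density changes when
productive transcriptional elongation is blocked: per-gene RPKM is computed
from binned coverage, each (mark, condition) table is normalized to its 75th
percentile, and the per-gene Δlog2 of DRB(+) over DRB(−) partitions genes
into decreased / unchanged / increased groups (default boundary ±0.6,
strict).  Group composition is then tested for over/underrepresentation of a
gene flag (e.g. RAR association) against the total gene set by chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .intervals import (
    CoverageTrack,
    GeneModel,
    Genome,
    GenomicInterval,
    PeakSet,
    ValidationError,
)
from .signatures import CategoryEnrichment, EnrichmentReport, chi_square_2x2

__all__ = [
    "RegionRpkmTable",
    "region_rpkm",
    "region_rpkm_table",
    "percentile75_normalize",
    "drb_dlog2",
    "DEFAULT_RESPONSE_EDGES",
    "DEFAULT_RESPONSE_NAMES",
    "group_by_response",
    "underrepresentation_test",
    "ProfileMatrix",
    "metagene_profile",
    "anchor_profile",
]


@dataclass
class RegionRpkmTable:
    """Per-gene RPKM for one (mark, condition) track.

    ``normalizer`` records the 75th-percentile value (raw RPKM units) once
    :func:`percentile75_normalize` has been applied.
    """

    values: pd.Series
    mark: str = ""
    condition: str = ""
    normalized: bool = False
    normalizer: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValidationError("RPKM values must be non-negative")


def region_rpkm(track: CoverageTrack, region: GenomicInterval) -> float:
    """Reads per kb of region per million mapped reads.

    Reads overlapping the region partially (through a shared bin) count
    pro-rata by overlap fraction.
    """
    length_kb = len(region) / 1000.0
    millions = track.total_mapped_reads / 1e6
    return track.region_count(region) / (length_kb * millions)


def region_rpkm_table(
    track: CoverageTrack, genes: Sequence[GeneModel]
) -> RegionRpkmTable:
    """Vectorized gene-body RPKM for many genes."""
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    ids: List[str] = []
    vals: List[np.ndarray] = []
    millions = track.total_mapped_reads / 1e6
    for chrom, glist in by_chrom.items():
        starts = np.array([g.interval.start for g in glist], dtype=float)
        ends = np.array([g.interval.end for g in glist], dtype=float)
        counts = track.region_counts(chrom, starts, ends)
        rpkm = counts / ((ends - starts) / 1000.0 * millions)
        ids.extend(g.gene_id for g in glist)
        vals.append(rpkm)
    series = pd.Series(
        np.concatenate(vals) if vals else np.array([]), index=ids, name="rpkm"
    )
    # restore caller's gene order
    series = series.loc[[g.gene_id for g in genes]]
    return RegionRpkmTable(series, mark=track.mark, condition=track.condition)


def percentile75_normalize(table: RegionRpkmTable) -> RegionRpkmTable:
    """Divide every value by the 75th percentile of the input distribution.

    The percentile uses numpy's linear interpolation between order statistics
    (the common "type 7" convention).  Idempotent: the second normalizer is 1.
    """
    vals = table.values.to_numpy(dtype=float)
    if (vals > 0).sum() < 4:
        raise ValidationError(
            "need at least 4 genes with RPKM > 0 to normalize"
        )
    normalizer = float(np.percentile(vals, 75))
    if normalizer <= 0:
        raise ValidationError("degenerate 75th-percentile normalizer (<= 0)")
    return RegionRpkmTable(
        table.values / normalizer,
        mark=table.mark,
        condition=table.condition,
        normalized=True,
        normalizer=normalizer,
    )


def drb_dlog2(
    plus: RegionRpkmTable, minus: RegionRpkmTable, pseudocount: float = 0.1
) -> pd.Series:
    """Per-gene ``log2((plus + pc) / (minus + pc))`` on the normalized scale.

    The pseudocount (default 0.1, by analogy with the expression convention)
    guards against zero normalized RPKM.
    """
    if not (plus.normalized and minus.normalized):
        raise ValidationError("both tables must be 75th-percentile normalized")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    if set(plus.values.index) != set(minus.values.index):
        raise ValidationError("gene universes differ between tables")
    minus_aligned = minus.values.loc[plus.values.index]
    d = np.log2((plus.values + pseudocount) / (minus_aligned + pseudocount))
    d.name = "dlog2"
    return d


DEFAULT_RESPONSE_EDGES: Tuple[float, float] = (-0.6, 0.6)
DEFAULT_RESPONSE_NAMES: Tuple[str, str, str] = ("decreased", "unchanged", "increased")


def group_by_response(
    dlog2_values: pd.Series,
    edges: Sequence[float] = DEFAULT_RESPONSE_EDGES,
    names: Optional[Sequence[str]] = None,
) -> pd.Series:
    """Partition genes by Δlog2 bins; exhaustive and disjoint.

    With the default edges (−0.6, +0.6): decreased ⇔ Δlog2 < −0.6 strictly,
    unchanged ⇔ −0.6 ≤ Δlog2 ≤ +0.6, increased ⇔ Δlog2 > +0.6.  General
    edges yield len(edges)+1 groups: (−inf, e1), [e1, e2), ..., [e_{k-1}, e_k],
    (e_k, +inf); the last finite bin is closed on both sides so the top group
    stays strict, mirroring the default scheme.
    """
    edges = list(edges)
    if edges != sorted(edges) or len(set(edges)) != len(edges):
        raise ValidationError("bin edges must be strictly increasing")
    if not edges:
        raise ValidationError("need at least one bin edge")
    vals = dlog2_values.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValidationError("non-finite dlog2 values")
    k = len(edges)
    if names is None:
        if k == 2:
            names = DEFAULT_RESPONSE_NAMES
        else:
            names = [f"bin{i}" for i in range(k + 1)]
    if len(names) != k + 1:
        raise ValidationError(f"need {k + 1} group names, got {len(names)}")
    out = np.empty(len(vals), dtype=object)
    out[vals < edges[0]] = names[0]
    for i in range(1, k):
        lo, hi = edges[i - 1], edges[i]
        if i == k - 1:
            mask = (vals >= lo) & (vals <= hi)
        else:
            mask = (vals >= lo) & (vals < hi)
        out[mask] = names[i]
    out[vals > edges[-1]] = names[k]
    return pd.Series(out, index=dlog2_values.index, name="group")


def underrepresentation_test(
    groups: pd.Series,
    flags: pd.Series,
    flag_label: str = "RAR-associated",
) -> EnrichmentReport:
    """Per-group chi-square of a gene flag against the total gene set.

    Builds, for each response group, the 2x2 [in-group vs rest] x [flagged vs
    not] table and reports statistic, p and direction.  Empty groups are
    skipped (reported with NaN statistics).
    """
    if set(groups.index) != set(flags.index):
        raise ValidationError("groups and flags must cover the same genes")
    flags = flags.loc[groups.index].astype(bool)
    n = len(groups)
    n_flagged = int(flags.sum())
    report = EnrichmentReport(flag_label, n_flagged, n)
    for name in pd.unique(groups):
        mask = (groups == name).to_numpy()
        g_size = int(mask.sum())
        g_flag = int(flags.to_numpy()[mask].sum())
        expected = n_flagged * g_size / n
        table = [
            [g_flag, g_size - g_flag],
            [n_flagged - g_flag, (n - g_size) - (n_flagged - g_flag)],
        ]
        try:
            stat, df, p = chi_square_2x2(table)
        except ValidationError:
            stat, df, p = float("nan"), 1, float("nan")
        frac_group = g_flag / g_size if g_size else float("nan")
        frac_uni = n_flagged / n
        report.categories.append(
            CategoryEnrichment(
                category=str(name),
                in_group=g_flag,
                in_background=n_flagged,
                relative_ratio=frac_group / frac_uni if frac_uni else float("nan"),
                statistic=stat,
                df=df,
                p_value=p,
                direction=(
                    "enriched"
                    if g_flag > expected
                    else "depleted" if g_flag < expected else "none"
                ),
            )
        )
    return report


@dataclass
class ProfileMatrix:
    """Rows = regions, columns = positional bins of read counts.

    ``meta`` records the bin scheme and the base value used for log2 ratios.
    """

    values: np.ndarray
    row_ids: List[str]
    column_labels: List[str]
    meta: Dict[str, object] = field(default_factory=dict)

    def mean_profile(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def log2_ratio_profile(self, pseudo: float = 1e-9) -> np.ndarray:
        """log2 of the mean per-bp density in each column over the base density."""
        base = self.meta.get("base_density")
        if base is None or base <= 0:
            raise ValidationError("meta['base_density'] must be positive")
        widths = np.asarray(self.meta["column_widths"], dtype=float)
        dens = self.mean_profile() / widths
        return np.log2((dens + pseudo) / (base + pseudo))


def _gene_body_edges(gene: GeneModel, n_body_bins: int) -> np.ndarray:
    """Equal sub-intervals TSS->TES in genomic coordinates (5'->3' order)."""
    edges = np.linspace(gene.interval.start, gene.interval.end, n_body_bins + 1)
    return edges


def metagene_profile(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    genome: Genome,
    n_body_bins: int = 100,
    flank_bp: int = 2000,
    flank_bins: int = 20,
    base_density: Optional[float] = None,
) -> ProfileMatrix:
    """Scaled gene-body coverage matrix with fixed-width flanks.

    Each gene body (TSS->TES) is rescaled into ``n_body_bins`` equal bins
    (strand-flipped for − genes so column 0 is always the TSS end), flanked
    by ``flank_bins`` fixed-width bins covering ``flank_bp`` on each side.
    Genes shorter than ``n_body_bins`` bp are skipped (count recorded in
    ``meta['n_skipped']``).  ``base_density`` (reads/bp) defaults to the
    genome-wide mean density of the track and anchors the log2-ratio profile.
    """
    if n_body_bins <= 0 or flank_bins <= 0 or flank_bp <= 0:
        raise ValidationError("bin scheme parameters must be positive")
    flank_w = flank_bp / flank_bins
    rows: List[np.ndarray] = []
    ids: List[str] = []
    n_skipped = 0
    for gene in genes:
        if len(gene.interval) < n_body_bins:
            n_skipped += 1
            continue
        chrom = gene.interval.chrom
        size = genome.size(chrom)
        body = _gene_body_edges(gene, n_body_bins)
        up = gene.interval.start - flank_bp + flank_w * np.arange(flank_bins + 1)
        down = gene.interval.end + flank_w * np.arange(flank_bins + 1)
        edges = np.concatenate([up[:-1], body, down[1:]])
        edges = np.clip(edges, 0, size)
        prefix = track._prefix(chrom, edges)
        counts = np.diff(prefix)
        if gene.strand == "-":
            counts = counts[::-1]
        rows.append(counts)
        ids.append(gene.gene_id)
    if not rows:
        raise ValidationError("no gene was long enough to profile")
    values = np.vstack(rows)
    # per-column widths: flank bins are fixed; body bins vary per gene, use
    # the mean body-bin width across profiled genes for density conversion
    mean_body_w = float(
        np.mean([len(g.interval) / n_body_bins for g in genes if len(g.interval) >= n_body_bins])
    )
    column_widths = [flank_w] * flank_bins + [mean_body_w] * n_body_bins + [flank_w] * flank_bins
    labels = (
        [f"up{flank_bins - i}" for i in range(flank_bins)]
        + [f"body{i}" for i in range(n_body_bins)]
        + [f"down{i + 1}" for i in range(flank_bins)]
    )
    if base_density is None:
        base_density = track.mean_density()
    return ProfileMatrix(
        values,
        ids,
        labels,
        meta={
            "kind": "metagene",
            "n_body_bins": n_body_bins,
            "flank_bp": flank_bp,
            "flank_bins": flank_bins,
            "column_widths": column_widths,
            "base_density": float(base_density),
            "n_skipped": n_skipped,
        },
    )


def anchor_profile(
    track: CoverageTrack,
    anchors: PeakSet,
    genome: Genome,
    half_width_bp: int = 5000,
    n_bins: int = 100,
    base_density: Optional[float] = None,
) -> ProfileMatrix:
    """Fixed-width coverage matrix centered on peak summits/midpoints."""
    if half_width_bp <= 0 or n_bins <= 0:
        raise ValidationError("half_width_bp and n_bins must be positive")
    bin_w = 2 * half_width_bp / n_bins
    rows: List[np.ndarray] = []
    ids: List[str] = []
    for i, peak in enumerate(anchors):
        chrom = peak.interval.chrom
        size = genome.size(chrom)
        center = peak.center
        edges = center - half_width_bp + bin_w * np.arange(n_bins + 1)
        edges = np.clip(edges, 0, size)
        prefix = track._prefix(chrom, edges)
        rows.append(np.diff(prefix))
        ids.append(peak.name or f"{anchors.factor}_peak{i}")
    if not rows:
        raise ValidationError("empty anchor set")
    if base_density is None:
        base_density = track.mean_density()
    labels = [
        f"{int(-half_width_bp + k * bin_w)}..{int(-half_width_bp + (k + 1) * bin_w)}"
        for k in range(n_bins)
    ]
    return ProfileMatrix(
        np.vstack(rows),
        ids,
        labels,
        meta={
            "kind": "anchor",
            "half_width_bp": half_width_bp,
            "n_bins": n_bins,
            "column_widths": [bin_w] * n_bins,
            "base_density": float(base_density),
            "n_skipped": 0,
        },
    )
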