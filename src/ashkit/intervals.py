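"""Genomic coordinate primitives and window rules.

Everything downstream (peak-to-gene association, metagene profiles, region
RPKM) anchors to the types defined here.  The internal convention is BED-like
throughout: 0-based, half-open ``[start, end)``.  GTF input is converted at
the file boundary (see :mod:`ashkit.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "GenomicInterval",
    "Genome",
    "GeneModel",
    "Peak",
    "PeakSet",
    "CoverageTrack",
    "overlaps",
    "tss_window",
    "upstream_and_body_window",
]


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class Genome:
    """Chromosome name -> length (bp) lookup used to clip and validate."""

    chrom_sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValidationError(f"chromosome {chrom!r} has length {size}")

    def size(self, chrom: str) -> int:
        try:
            return self.chrom_sizes[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    def validate_interval(self, iv: GenomicInterval) -> None:
        if iv.end > self.size(iv.chrom):
            raise ValidationError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self.size(iv.chrom)}"
            )

    def clip(self, chrom: str, start: int, end: int) -> GenomicInterval:
        """Clip ``[start, end)`` to chromosome bounds (must stay non-empty)."""
        size = self.size(chrom)
        return GenomicInterval(chrom, max(0, start), min(size, end))


@dataclass(frozen=True)
class GeneModel:
    """One canonical transcription unit per gene.

    ``tss``/``tes`` are strand-aware: on ``+`` the TSS is ``interval.start``
    and the TES is ``interval.end - 1``; on ``-`` they swap.
    """

    gene_id: str
    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    name: Optional[str] = None
    score: Optional[float] = None
    summit_offset: Optional[int] = None  # narrowPeak column 10, -1 -> None

    def __post_init__(self) -> None:
        if self.score is not None and self.score < 0:
            raise ValidationError(f"peak score must be non-negative, got {self.score}")

    @property
    def center(self) -> int:
        """Summit position when known, else the interval midpoint."""
        if self.summit_offset is not None:
            return self.interval.start + self.summit_offset
        return (self.interval.start + self.interval.end) // 2


class PeakSet:
    """Sorted collection of peaks from one ChIP experiment.

    Peaks are sorted by (chrom, start) on construction so overlap queries are
    independent of input order.
    """

    def __init__(self, factor: str, peaks: Iterable[Peak]):
        self.factor = factor
        self.peaks: List[Peak] = sorted(
            peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
        )
        self._index: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._by_chrom: Dict[str, List[Peak]] = {}
        self._build_index()

    def _build_index(self) -> None:
        by_chrom = self._by_chrom
        for p in self.peaks:
            by_chrom.setdefault(p.interval.chrom, []).append(p)
        for chrom, plist in by_chrom.items():
            starts = np.array([p.interval.start for p in plist], dtype=np.int64)
            ends = np.array([p.interval.end for p in plist], dtype=np.int64)
            # prefix running maximum of ends supports "any overlap" queries in
            # O(log n) even with nested peaks
            max_ends = np.maximum.accumulate(ends)
            self._index[chrom] = (starts, ends, max_ends)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def chroms(self) -> Sequence[str]:
        return sorted(self._index)

    def any_overlap(self, iv: GenomicInterval) -> bool:
        """True iff at least one peak overlaps ``iv`` (half-open semantics)."""
        idx = self._index.get(iv.chrom)
        if idx is None:
            return False
        starts, _ends, max_ends = idx
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        if hi == 0:
            return False
        return bool(max_ends[hi - 1] > iv.start)

    def overlapping(self, iv: GenomicInterval) -> List[Peak]:
        """All peaks overlapping ``iv``."""
        idx = self._index.get(iv.chrom)
        if idx is None:
            return []
        starts, _ends, _ = idx
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        chrom_peaks = self._by_chrom[iv.chrom]
        return [p for p in chrom_peaks[:hi] if p.interval.end > iv.start]


class CoverageTrack:
    """Binned read counts for one (mark, condition) plus the library size.

    ``bins`` maps chromosome -> float array of read counts per fixed-width
    bin.  Bins may cover only a genome subset (unbinned chromosomes count as
    zero coverage); ``total_mapped_reads`` is the sequencing-library size used
    for the RPKM denominator and need not equal the binned sum.
    """

    def __init__(
        self,
        mark: str,
        condition: str,
        bins: Mapping[str, np.ndarray],
        bin_width: int,
        total_mapped_reads: float,
    ):
        if bin_width <= 0:
            raise ValidationError(f"bin_width must be positive, got {bin_width}")
        if total_mapped_reads <= 0:
            raise ValidationError(
                f"total_mapped_reads must be positive, got {total_mapped_reads}"
            )
        self.mark = mark
        self.condition = condition
        self.bin_width = int(bin_width)
        self.total_mapped_reads = float(total_mapped_reads)
        self.bins: Dict[str, np.ndarray] = {}
        self._cum: Dict[str, np.ndarray] = {}
        for chrom, arr in bins.items():
            a = np.asarray(arr, dtype=float)
            if a.ndim != 1:
                raise ValidationError(f"bins for {chrom!r} must be 1-D")
            if np.any(a < 0):
                raise ValidationError(f"negative bin count on {chrom!r}")
            self.bins[chrom] = a
            self._cum[chrom] = np.concatenate(([0.0], np.cumsum(a)))

    def total_binned_reads(self) -> float:
        return float(sum(a.sum() for a in self.bins.values()))

    def _prefix(self, chrom: str, pos) -> np.ndarray:
        """Reads in [0, pos) with pro-rating inside partially covered bins.

        Within a bin, reads are treated as uniformly distributed, so the
        prefix is piecewise linear and region counts are exact under that
        per-base model.
        """
        arr = self.bins.get(chrom)
        pos = np.asarray(pos, dtype=float)
        if arr is None:
            return np.zeros_like(pos, dtype=float)
        w = self.bin_width
        cum = self._cum[chrom]
        limit = len(arr) * w
        p = np.clip(pos, 0, limit)
        k = np.minimum((p // w).astype(np.int64), len(arr) - 1)
        frac = (p - k * w) / w
        return cum[k] + frac * arr[k]

    def region_count(self, iv: GenomicInterval) -> float:
        """Pro-rated read count overlapping ``iv``."""
        a = self._prefix(iv.chrom, np.array([iv.start, iv.end], dtype=float))
        return float(a[1] - a[0])

    def region_counts(self, chrom: str, starts, ends) -> np.ndarray:
        """Vectorized :meth:`region_count` for many regions on one chromosome."""
        starts = np.asarray(starts, dtype=float)
        ends = np.asarray(ends, dtype=float)
        return self._prefix(chrom, ends) - self._prefix(chrom, starts)

    def mean_density(self) -> float:
        """Genome-wide mean read density (reads/bp) over the binned portion."""
        nbins = sum(len(a) for a in self.bins.values())
        if nbins == 0:
            raise ValidationError("track has no bins")
        return self.total_binned_reads() / (nbins * self.bin_width)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open overlap test: touching intervals do NOT overlap."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def tss_window(gene: GeneModel, flank: int, genome: Genome) -> GenomicInterval:
    """Symmetric window ``[tss - flank, tss + flank + 1)`` clipped to bounds.

    The +1 keeps the window symmetric around the TSS base itself under
    half-open coordinates.
    """
    if flank <= 0:
        raise ValidationError(f"flank must be positive, got {flank}")
    tss = gene.tss
    return genome.clip(gene.interval.chrom, tss - flank, tss + flank + 1)


def upstream_and_body_window(
    gene: GeneModel, upstream: int, genome: Genome
) -> GenomicInterval:
    """Strand-aware window from ``upstream`` bp 5' of the TSS through the TES.

    Covers the promoter-upstream region plus the full transcription unit, the
    association window used for nuclear-receptor (RAR) peaks.
    """
    if upstream <= 0:
        raise ValidationError(f"upstream must be positive, got {upstream}")
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tes + 1
    else:
        start, end = gene.tes, gene.tss + upstream + 1
    return genome.clip(gene.interval.chrom, start, end)
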