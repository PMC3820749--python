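"""Readers and writers for the plain-text formats the pipeline touches.

All readers validate intervals against supplied chromosome sizes and raise
:class:`ParseError` naming the offending line.  Coordinate conventions: BED,
narrowPeak and bedGraph are 0-based half-open (kept as-is); GTF is 1-based
inclusive and converted on ingest (and back on write).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import (
    CoverageTrack,
    GeneModel,
    Genome,
    GenomicInterval,
    Peak,
    PeakSet,
    ValidationError,
)

__all__ = [
    "ParseError",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_gene_models_gtf",
    "write_gene_models_gtf",
    "read_gene_models_bed12",
    "write_gene_models_bed12",
    "read_bedgraph",
    "write_bedgraph",
    "read_track",
    "write_track",
    "read_expression_table",
    "write_expression_table",
    "read_signature_labels",
    "write_signature_labels",
]


class ParseError(ValueError):
    """Malformed input file; message names the file and 1-based line number."""


def _lines(path) -> Iterable[Tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def _fail(path, lineno: int, msg: str) -> None:
    raise ParseError(f"{path}:{lineno}: {msg}")


def _to_int(path, lineno, token, what) -> int:
    try:
        return int(token)
    except ValueError:
        _fail(path, lineno, f"{what} is not an integer: {token!r}")


def read_chrom_sizes(path) -> Genome:
    sizes: Dict[str, int] = {}
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            _fail(path, lineno, "expected 2 tab-separated fields (chrom, size)")
        sizes[fields[0]] = _to_int(path, lineno, fields[1], "chromosome size")
    return Genome(sizes)


def write_chrom_sizes(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome.chrom_sizes):
            fh.write(f"{chrom}\t{genome.chrom_sizes[chrom]}\n")


def _validated_interval(path, lineno, chrom, start, end, genome) -> GenomicInterval:
    try:
        iv = GenomicInterval(chrom, start, end)
        if genome is not None:
            genome.validate_interval(iv)
    except ValidationError as exc:
        _fail(path, lineno, str(exc))
    return iv


def read_bed(path, factor: str = "", genome: Optional[Genome] = None) -> PeakSet:
    """Read BED3/BED6 into a :class:`PeakSet`."""
    peaks: List[Peak] = []
    for lineno, line in _lines(path):
        f = line.split("\t")
        if len(f) < 3:
            _fail(path, lineno, "BED needs at least 3 fields")
        start = _to_int(path, lineno, f[1], "start")
        end = _to_int(path, lineno, f[2], "end")
        iv = _validated_interval(path, lineno, f[0], start, end, genome)
        name = f[3] if len(f) > 3 and f[3] != "." else None
        score = None
        if len(f) > 4 and f[4] != ".":
            try:
                score = float(f[4])
            except ValueError:
                _fail(path, lineno, f"score is not numeric: {f[4]!r}")
        peaks.append(Peak(iv, name=name, score=score))
    return PeakSet(factor or Path(path).stem, peaks)


def write_bed(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            score = "." if p.score is None else f"{p.score:g}"
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                f"\t{p.name or '.'}\t{score}\t.\n"
            )


def read_narrowpeak(path, factor: str = "", genome: Optional[Genome] = None) -> PeakSet:
    """Read ENCODE narrowPeak (BED6+4); column 10 is the summit offset."""
    peaks: List[Peak] = []
    for lineno, line in _lines(path):
        f = line.split("\t")
        if len(f) < 10:
            _fail(path, lineno, f"narrowPeak needs 10 fields, got {len(f)}")
        start = _to_int(path, lineno, f[1], "start")
        end = _to_int(path, lineno, f[2], "end")
        iv = _validated_interval(path, lineno, f[0], start, end, genome)
        summit = _to_int(path, lineno, f[9], "summit offset")
        peaks.append(
            Peak(
                iv,
                name=f[3] if f[3] != "." else None,
                score=float(f[4]) if f[4] != "." else None,
                summit_offset=None if summit < 0 else summit,
            )
        )
    return PeakSet(factor or Path(path).stem, peaks)


def write_narrowpeak(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            summit = -1 if p.summit_offset is None else p.summit_offset
            score = 0 if p.score is None else f"{p.score:g}"
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                f"\t{p.name or '.'}\t{score}\t.\t0\t-1\t-1\t{summit}\n"
            )


def _parse_gtf_attrs(attrs: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for chunk in attrs.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " in chunk:
            key, _, value = chunk.partition(" ")
            out[key] = value.strip().strip('"')
    return out


def read_gene_models_gtf(path, genome: Optional[Genome] = None) -> List[GeneModel]:
    """Read ``gene`` feature lines from a GTF (1-based inclusive -> half-open)."""
    genes: List[GeneModel] = []
    seen: Dict[str, int] = {}
    for lineno, line in _lines(path):
        f = line.split("\t")
        if len(f) < 9:
            _fail(path, lineno, f"GTF needs 9 fields, got {len(f)}")
        if f[2] != "gene":
            continue
        start1 = _to_int(path, lineno, f[3], "start")
        end1 = _to_int(path, lineno, f[4], "end")
        iv = _validated_interval(path, lineno, f[0], start1 - 1, end1, genome)
        strand = f[6]
        if strand not in ("+", "-"):
            _fail(path, lineno, f"strand must be + or -, got {strand!r}")
        attrs = _parse_gtf_attrs(f[8])
        gene_id = attrs.get("gene_id")
        if not gene_id:
            _fail(path, lineno, "missing gene_id attribute")
        if gene_id in seen:
            _fail(path, lineno, f"duplicate gene_id {gene_id!r} (first at line {seen[gene_id]})")
        seen[gene_id] = lineno
        genes.append(GeneModel(gene_id, iv, strand))
    return genes


def write_gene_models_gtf(genes: Sequence[GeneModel], path, source: str = "ashkit") -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.interval.chrom}\t{source}\tgene\t{g.interval.start + 1}"
                f"\t{g.interval.end}\t.\t{g.strand}\t.\tgene_id \"{g.gene_id}\";\n"
            )


def read_gene_models_bed12(path, genome: Optional[Genome] = None) -> List[GeneModel]:
    """Read BED12 (or BED6) gene lines; only the first six fields are used."""
    genes: List[GeneModel] = []
    seen: Dict[str, int] = {}
    for lineno, line in _lines(path):
        f = line.split("\t")
        if len(f) < 6:
            _fail(path, lineno, "BED gene line needs at least 6 fields")
        start = _to_int(path, lineno, f[1], "start")
        end = _to_int(path, lineno, f[2], "end")
        iv = _validated_interval(path, lineno, f[0], start, end, genome)
        gene_id = f[3]
        if gene_id in seen:
            _fail(path, lineno, f"duplicate gene_id {gene_id!r} (first at line {seen[gene_id]})")
        seen[gene_id] = lineno
        if f[5] not in ("+", "-"):
            _fail(path, lineno, f"strand must be + or -, got {f[5]!r}")
        genes.append(GeneModel(gene_id, iv, f[5]))
    return genes


def write_gene_models_bed12(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{g.strand}"
                f"\t{iv.start}\t{iv.end}\t0\t1\t{len(iv)},\t0,\n"
            )


def read_bedgraph(
    path,
    bin_width: int,
    genome: Genome,
    mark: str = "",
    condition: str = "",
    total_mapped_reads: float = 1.0,
) -> CoverageTrack:
    """Read a bedGraph of read counts into fixed-width bins.

    Each bedGraph value is interpreted as the read count of its interval;
    counts are distributed over the overlapped bins proportionally to the
    overlap fraction, so intervals need not be bin-aligned.
    """
    bins = {
        chrom: np.zeros(-(-size // bin_width), dtype=float)
        for chrom, size in genome.chrom_sizes.items()
    }
    for lineno, line in _lines(path):
        f = line.split("\t")
        if len(f) < 4:
            _fail(path, lineno, "bedGraph needs 4 fields")
        start = _to_int(path, lineno, f[1], "start")
        end = _to_int(path, lineno, f[2], "end")
        iv = _validated_interval(path, lineno, f[0], start, end, genome)
        try:
            value = float(f[3])
        except ValueError:
            _fail(path, lineno, f"value is not numeric: {f[3]!r}")
        if value < 0:
            _fail(path, lineno, f"negative coverage value {value}")
        arr = bins[iv.chrom]
        k0, k1 = start // bin_width, (end - 1) // bin_width
        if k0 == k1:
            arr[k0] += value
        else:
            length = end - start
            for k in range(k0, k1 + 1):
                lo = max(start, k * bin_width)
                hi = min(end, (k + 1) * bin_width)
                arr[k] += value * (hi - lo) / length
    return CoverageTrack(mark, condition, bins, bin_width, total_mapped_reads)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write one line per non-zero bin."""
    w = track.bin_width
    with open(path, "w") as fh:
        for chrom in sorted(track.bins):
            arr = track.bins[chrom]
            for k in np.nonzero(arr)[0]:
                fh.write(f"{chrom}\t{k * w}\t{(k + 1) * w}\t{arr[k]:g}\n")


def write_track(track: CoverageTrack, prefix) -> Tuple[Path, Path]:
    """Write a track as ``<prefix>.bedgraph`` plus a ``.meta.tsv`` sidecar."""
    prefix = Path(prefix)
    bg = prefix.with_suffix(".bedgraph")
    meta = prefix.with_suffix(".meta.tsv")
    write_bedgraph(track, bg)
    with open(meta, "w") as fh:
        fh.write("mark\tcondition\tbin_width\ttotal_mapped_reads\n")
        fh.write(
            f"{track.mark}\t{track.condition}\t{track.bin_width}"
            f"\t{track.total_mapped_reads:g}\n"
        )
    return bg, meta


def read_track(prefix, genome: Genome) -> CoverageTrack:
    """Read a track written by :func:`write_track`."""
    prefix = Path(prefix)
    meta = pd.read_csv(prefix.with_suffix(".meta.tsv"), sep="\t")
    row = meta.iloc[0]
    return read_bedgraph(
        prefix.with_suffix(".bedgraph"),
        bin_width=int(row["bin_width"]),
        genome=genome,
        mark=str(row["mark"]),
        condition=str(row["condition"]),
        total_mapped_reads=float(row["total_mapped_reads"]),
    )


def read_expression_table(path) -> pd.DataFrame:
    """TSV with a ``gene_id`` column plus one column per condition."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: expected a 'gene_id' column")
    return df.set_index("gene_id")


def write_expression_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_signature_labels(path) -> pd.DataFrame:
    """Reference TSV with gene_id, k4me3, k27me3 boolean columns."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "k4me3", "k27me3"):
        if col not in df.columns:
            raise ParseError(f"{path}: expected a {col!r} column")
    return df.set_index("gene_id").astype({"k4me3": bool, "k27me3": bool})


def write_signature_labels(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")
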