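"""Seeded synthetic-data generator for the whole pipeline.

The generator emits a small "stated world": non-overlapping gene models on a
toy genome, an FPKM table for {WT, dSET} x {undifferentiated, +RA}, Ash1l and
RAR peak sets, K36me2/me3 coverage tracks with and without DRB, a chromatin
signature reference and per-gene ground truth, so every downstream stage is
testable with no external download.

Default parameters mirror the magnitudes the analysis assumes: ~3.8% of
genes RA-responsive (543 of 14,255), 28% of those impaired in the catalytic
mutant, ~60% of RAR peaks co-occupied by Ash1l, a mean RA induction of
+3 log2 with the responsive call made at Δlog2 > 2.5, and a DRB-driven me3
loss of −1 log2 for most genes but only −0.1 for RAR-associated genes.
Gene placement keeps ≥50 kb between transcription units so the ±4 kb and
−20 kb association windows of distinct genes can never collide and the
generated labels stay unambiguous.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as aio
from .expression import ExpressionTable
from .intervals import (
    CoverageTrack,
    GeneModel,
    Genome,
    GenomicInterval,
    Peak,
    PeakSet,
    ValidationError,
)
from .signatures import SIGNATURES

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "place_genes",
    "draw_labels",
    "simulate_expression",
    "simulate_peaks",
    "simulate_coverage",
    "generate",
    "generate_qpcr_table",
    "generate_phenotype_table",
]

# per-gene signature state probabilities over SIGNATURES
# (Lys4me alone, Bivalent, Lys27me alone, None); responsive developmental
# genes are heavily bivalent, impaired ones even more so
_DEFAULT_SIGNATURE_PROBS: Dict[str, Tuple[float, float, float, float]] = {
    "background": (0.45, 0.15, 0.05, 0.35),
    "responsive": (0.25, 0.55, 0.10, 0.10),
    "impaired": (0.15, 0.65, 0.12, 0.08),
}

_DEFAULT_QPCR_MEANS: Dict[Tuple[str, str, str, str], float] = {
    # (region, antibody, genotype, condition) -> mean % input
    ("Hoxd4_proximal", "K36me2", "WT", "DRB-"): 0.50,
    ("Hoxd4_proximal", "K36me2", "WT", "DRB+"): 0.90,
    ("Hoxd4_proximal", "K36me2", "dSET", "DRB-"): 0.15,
    ("Hoxd4_proximal", "K36me2", "dSET", "DRB+"): 0.25,
    ("Hoxd4_proximal", "K36me3", "WT", "DRB-"): 0.40,
    ("Hoxd4_proximal", "K36me3", "WT", "DRB+"): 0.70,
    ("Hoxd4_proximal", "K36me3", "dSET", "DRB-"): 0.12,
    ("Hoxd4_proximal", "K36me3", "dSET", "DRB+"): 0.18,
    ("Gapdh_proximal", "K36me3", "WT", "DRB-"): 0.80,
    ("Gapdh_proximal", "K36me3", "WT", "DRB+"): 0.35,
}

_DEFAULT_PENETRANCE: Dict[str, Dict[str, float]] = {
    "+/+": {},
    "+/dSET": {"broadened_neural_arch": 0.42, "aaa_fusion": 0.17},
    "dSET/dSET": {"broadened_neural_arch": 0.56, "aaa_fusion": 0.20},
}

_DEFAULT_PHENOTYPE_N: Dict[str, int] = {"+/+": 12, "+/dSET": 36, "dSET/dSET": 25}


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_genes: int = 2000
    n_chroms: int = 4
    gene_length_range: Tuple[int, int] = (8000, 20000)
    # label fractions
    frac_ra_responsive: float = 543 / 14255
    frac_impaired_given_responsive: float = 0.28
    frac_ash1l_target: float = 0.30
    frac_rar_associated: float = 0.20
    co_occupancy: float = 0.60
    signature_probs: Mapping[str, Tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_SIGNATURE_PROBS)
    )
    # expression model (log2 scale)
    baseline_fpkm_log2_mean: float = 3.0
    baseline_fpkm_log2_sd: float = 1.5
    ra_effect_log2: float = 3.0
    impair_effect_log2: float = -1.5
    # DRB coverage response (log2 scale)
    drb_me3_loss_log2: float = -1.0
    drb_me3_loss_rar_log2: float = -0.1
    drb_me2_gain_log2: float = 0.3
    noise_sd_log2: float = 0.15
    # coverage realization; marks cover only a fraction of gene bodies
    # (me3 is restricted to actively transcribed genes, me2 is broad) and
    # the unmarked majority anchors the 75th-percentile normalizer
    frac_me3_marked: float = 0.20
    frac_me2_marked: float = 0.70
    bin_width: int = 200
    total_reads_per_track: float = 2e7
    body_density_log2_mean: float = -4.3  # reads/bp, ~0.05 -> ~500 reads / 10 kb
    body_density_log2_sd: float = 1.0
    background_density: float = 0.01      # reads/bp outside marked bodies
    peak_width: int = 400
    # qPCR / phenotype fixtures
    qpcr_means: Mapping[Tuple[str, str, str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_QPCR_MEANS)
    )
    qpcr_noise_sd_log2: float = 0.15
    qpcr_replicates: int = 3
    phenotype_penetrance: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_PENETRANCE.items()}
    )
    phenotype_n: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_PHENOTYPE_N)
    )

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_chroms <= 0:
            raise ValidationError("n_genes and n_chroms must be positive")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValidationError("invalid gene_length_range")
        if lo < 6000:
            raise ValidationError(
                "gene_length_range minimum must be >= 6000 bp so body peaks "
                "stay clear of the TSS +/-4 kb window"
            )
        for name in (
            "frac_ra_responsive",
            "frac_impaired_given_responsive",
            "frac_ash1l_target",
            "frac_rar_associated",
            "co_occupancy",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for key, probs in self.signature_probs.items():
            if len(probs) != len(SIGNATURES) or not np.isclose(sum(probs), 1.0):
                raise ValidationError(
                    f"signature_probs[{key!r}] must be 4 probabilities summing to 1"
                )
        if self.bin_width <= 0 or self.total_reads_per_track <= 0:
            raise ValidationError("bin_width and total_reads_per_track must be positive")


@dataclass
class SyntheticTruth:
    """Per-gene ground truth for every generated attribute."""

    genes: pd.DataFrame            # indexed by gene_id
    paths: Dict[str, Path] = field(default_factory=dict)


_SPACING = 50_000   # minimum gap between transcription units
_MARGIN = 30_000    # clearance at chromosome starts (> upstream window)


def _rng(config: SyntheticConfig, stream: str) -> np.random.Generator:
    """Independent deterministic stream per generator component."""
    digest = hashlib.sha256(f"{config.seed}:{stream}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def place_genes(config: SyntheticConfig) -> Tuple[Genome, List[GeneModel]]:
    """Lay out non-overlapping genes with >= 50 kb between units."""
    rng = _rng(config, "genes")
    max_len = config.gene_length_range[1]
    pitch = max_len + _SPACING
    per_chrom = -(-config.n_genes // config.n_chroms)
    chrom_size = _MARGIN + per_chrom * pitch + _MARGIN
    sizes = {f"chr{i + 1}": chrom_size for i in range(config.n_chroms)}
    genome = Genome(sizes)
    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, config.n_genes
    )
    strands = rng.choice(["+", "-"], size=config.n_genes)
    genes: List[GeneModel] = []
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        chrom = f"chr{i % config.n_chroms + 1}"
        slot = i // config.n_chroms
        start = _MARGIN + slot * pitch
        genes.append(
            GeneModel(
                f"g{i:0{width}d}",
                GenomicInterval(chrom, start, start + int(lengths[i])),
                str(strands[i]),
            )
        )
    return genome, genes


def _exact_subset(rng: np.random.Generator, ids: np.ndarray, frac: float) -> np.ndarray:
    n = int(round(frac * len(ids)))
    chosen = rng.choice(len(ids), size=n, replace=False)
    mask = np.zeros(len(ids), dtype=bool)
    mask[chosen] = True
    return mask


def draw_labels(config: SyntheticConfig, genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Draw ground-truth labels with exact configured fractions."""
    rng = _rng(config, "labels")
    ids = np.array([g.gene_id for g in genes])
    responsive = _exact_subset(rng, ids, config.frac_ra_responsive)
    impaired = np.zeros(len(ids), dtype=bool)
    resp_idx = np.nonzero(responsive)[0]
    n_imp = int(round(config.frac_impaired_given_responsive * len(resp_idx)))
    if n_imp:
        impaired[rng.choice(resp_idx, size=n_imp, replace=False)] = True
    ash1l_target = _exact_subset(rng, ids, config.frac_ash1l_target)
    rar_associated = _exact_subset(rng, ids, config.frac_rar_associated)

    signature = np.empty(len(ids), dtype=object)
    probs = config.signature_probs
    for i in range(len(ids)):
        if impaired[i] and "impaired" in probs:
            p = probs["impaired"]
        elif responsive[i]:
            p = probs.get("responsive", probs["background"])
        else:
            p = probs["background"]
        signature[i] = SIGNATURES[rng.choice(len(SIGNATURES), p=p)]
    k4 = np.isin(signature, ("Lys4me alone", "Bivalent"))
    k27 = np.isin(signature, ("Bivalent", "Lys27me alone"))

    me3_marked = _exact_subset(rng, ids, config.frac_me3_marked)
    me2_marked = _exact_subset(rng, ids, config.frac_me2_marked)
    me3_effect = np.where(
        me3_marked,
        np.where(rar_associated, config.drb_me3_loss_rar_log2, config.drb_me3_loss_log2),
        0.0,
    )
    truth = pd.DataFrame(
        {
            "responsive": responsive,
            "impaired": impaired,
            "ash1l_target": ash1l_target,
            "rar_associated": rar_associated,
            "signature": signature,
            "k4me3": k4,
            "k27me3": k27,
            "me3_marked": me3_marked,
            "me2_marked": me2_marked,
            "true_dlog2_ra": np.where(responsive, config.ra_effect_log2, 0.0),
            "true_dlog2_genotype": np.where(impaired, config.impair_effect_log2, 0.0),
            "true_drb_me3_log2": me3_effect,
            "true_drb_me2_log2": np.where(me2_marked, config.drb_me2_gain_log2, 0.0),
        },
        index=pd.Index(ids, name="gene_id"),
    )
    return truth


def simulate_expression(config: SyntheticConfig, truth: pd.DataFrame) -> ExpressionTable:
    """FPKM table for {WT, dSET} x {undiff, +RA} with lognormal noise."""
    rng = _rng(config, "expression")
    n = len(truth)
    base = rng.normal(config.baseline_fpkm_log2_mean, config.baseline_fpkm_log2_sd, n)
    ra = truth["true_dlog2_ra"].to_numpy()
    imp = truth["true_dlog2_genotype"].to_numpy()
    log2fpkm = {
        "WT": base,
        "dSET": base,
        "WT_RA": base + ra,
        "dSET_RA": base + ra + imp,
    }
    cols = {}
    for cond, mu in log2fpkm.items():
        noise = rng.normal(0.0, config.noise_sd_log2, n)
        cols[cond] = np.exp2(mu + noise)
    return ExpressionTable(pd.DataFrame(cols, index=truth.index))


def _clip_peak(genome: Genome, chrom: str, start: int, width: int) -> GenomicInterval:
    return genome.clip(chrom, start, start + width)


def simulate_peaks(
    config: SyntheticConfig,
    genes: Sequence[GeneModel],
    truth: pd.DataFrame,
    genome: Genome,
) -> Tuple[PeakSet, PeakSet]:
    """Ash1l and RAR peak sets realizing the configured labels.

    Ash1l-target genes receive a peak overlapping TSS ± 4 kb; RAR-associated
    genes receive a peak in the gene body >= 5 kb downstream of the TSS
    (inside the upstream/body window but clear of any TSS ± 4 kb window).
    Each RAR peak is additionally co-occupied by an Ash1l peak with
    probability ``co_occupancy``, realized as an overlapping companion peak.
    """
    rng = _rng(config, "peaks")
    w = config.peak_width
    ash1l: List[Peak] = []
    rar: List[Peak] = []
    for gene in genes:
        row = truth.loc[gene.gene_id]
        chrom = gene.interval.chrom
        if row["ash1l_target"]:
            center = gene.tss + int(rng.integers(-2000, 2001))
            ash1l.append(
                Peak(_clip_peak(genome, chrom, center - w // 2, w),
                     name=f"ash1l_{gene.gene_id}")
            )
        if row["rar_associated"]:
            max_off = len(gene.interval) - w
            offset = int(rng.integers(5000, max_off + 1))
            if gene.strand == "+":
                start = gene.interval.start + offset
            else:
                start = gene.interval.end - offset - w
            iv = _clip_peak(genome, chrom, start, w)
            rar.append(Peak(iv, name=f"rar_{gene.gene_id}"))
            if rng.random() < config.co_occupancy:
                shift = int(rng.integers(-w // 2, w // 2 + 1))
                ash1l.append(
                    Peak(_clip_peak(genome, chrom, iv.start + shift, w),
                         name=f"ash1l_co_{gene.gene_id}")
                )
    return PeakSet("Ash1l", ash1l), PeakSet("RAR", rar)


def simulate_coverage(
    config: SyntheticConfig,
    genes: Sequence[GeneModel],
    truth: pd.DataFrame,
    genome: Genome,
    marks: Sequence[str] = ("K36me2", "K36me3"),
) -> Dict[Tuple[str, str], CoverageTrack]:
    """Poisson-binned coverage for each mark x {DRB-, DRB+}.

    Genes carrying the mark (per the truth table's ``me3_marked`` /
    ``me2_marked`` flags) get a lognormal body density (reads/bp) in the
    DRB(−) track; unmarked genes sit at the uniform background density, which
    also covers 3 kb flanks.  The DRB(+) density is the baseline times
    ``2**(effect + noise)`` with the per-gene effect from the truth table
    (zero for unmarked genes — DRB does not move background).  Because the
    marked population is a minority for me3, the 75th percentile of the
    per-gene RPKM table sits in the stable background and the configured
    effects survive percentile normalization.  Bins outside gene
    neighborhoods are zero (tracks may cover a genome subset);
    ``total_mapped_reads`` is the configured library size.
    """
    rng = _rng(config, "coverage")
    w = config.bin_width
    nbins = {c: -(-s // w) for c, s in genome.chrom_sizes.items()}
    by_chrom: Dict[str, List[int]] = {c: [] for c in genome.chrom_sizes}
    for i, g in enumerate(genes):
        by_chrom[g.interval.chrom].append(i)

    starts = np.array([g.interval.start for g in genes], dtype=np.int64)
    ends = np.array([g.interval.end for g in genes], dtype=np.int64)
    flank = 3000
    tracks: Dict[Tuple[str, str], CoverageTrack] = {}
    for mark in marks:
        base = np.exp2(
            rng.normal(config.body_density_log2_mean, config.body_density_log2_sd, len(genes))
        )
        if mark == "K36me3":
            effect = truth["true_drb_me3_log2"].to_numpy()
            marked = truth["me3_marked"].to_numpy()
        elif mark == "K36me2":
            effect = truth["true_drb_me2_log2"].to_numpy()
            marked = truth["me2_marked"].to_numpy()
        else:
            effect = np.zeros(len(genes))
            marked = np.ones(len(genes), dtype=bool)
        base = np.where(marked, base, config.background_density)
        noise = rng.normal(0.0, config.noise_sd_log2, len(genes))
        dens = {"DRB-": base, "DRB+": base * np.exp2(effect + noise)}
        for cond, d in dens.items():
            bins = {c: np.zeros(nbins[c]) for c in genome.chrom_sizes}
            for chrom, idx in by_chrom.items():
                if not idx:
                    continue
                idx = np.asarray(idx)
                # region = body plus background flanks, all bins it touches
                r0 = np.maximum(starts[idx] - flank, 0)
                r1 = np.minimum(ends[idx] + flank, genome.size(chrom))
                k0 = r0 // w
                k1 = (r1 - 1) // w
                m = (k1 - k0 + 1).astype(np.int64)
                rep = np.repeat(np.arange(len(idx)), m)
                flat = np.arange(m.sum()) - np.repeat(np.cumsum(m) - m, m) + k0[rep]
                bs = flat * w
                be = bs + w
                body_ov = np.maximum(
                    0,
                    np.minimum(be, ends[idx][rep]) - np.maximum(bs, starts[idx][rep]),
                )
                bg_ov = (
                    np.maximum(0, np.minimum(be, r1[rep]) - np.maximum(bs, r0[rep]))
                    - body_ov
                )
                lam = d[idx][rep] * body_ov + config.background_density * bg_ov
                counts = rng.poisson(lam).astype(float)
                np.add.at(bins[chrom], flat, counts)
            tracks[(mark, cond)] = CoverageTrack(
                mark, cond, bins, w, config.total_reads_per_track
            )
    return tracks


def generate(config: SyntheticConfig, out_dir) -> SyntheticTruth:
    """Write the full synthetic dataset to ``out_dir`` and return the truth.

    Identical (seed, config) pairs produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, genes = place_genes(config)
    truth = draw_labels(config, genes)
    table = simulate_expression(config, truth)
    ash1l, rar = simulate_peaks(config, genes, truth, genome)
    tracks = simulate_coverage(config, genes, truth, genome)

    paths: Dict[str, Path] = {}

    paths["chrom_sizes"] = out / "genome.chrom.sizes"
    aio.write_chrom_sizes(genome, paths["chrom_sizes"])
    paths["genes_gtf"] = out / "genes.gtf"
    aio.write_gene_models_gtf(genes, paths["genes_gtf"])
    paths["genes_bed12"] = out / "genes.bed12"
    aio.write_gene_models_bed12(genes, paths["genes_bed12"])
    paths["expression"] = out / "expression.tsv"
    aio.write_expression_table(table.fpkm.round(6), paths["expression"])
    paths["ash1l_peaks"] = out / "ash1l_peaks.bed"
    aio.write_bed(ash1l, paths["ash1l_peaks"])
    paths["rar_peaks"] = out / "rar_peaks.bed"
    aio.write_bed(rar, paths["rar_peaks"])
    for (mark, cond), track in tracks.items():
        tag = f"{mark.lower()}_{'plus' if cond == 'DRB+' else 'minus'}"
        bg, meta = aio.write_track(track, out / tag)
        paths[f"track_{tag}"] = bg
    paths["signatures"] = out / "signatures.tsv"
    aio.write_signature_labels(truth[["k4me3", "k27me3"]], paths["signatures"])
    paths["truth"] = out / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index_label="gene_id", float_format="%.6g")
    paths["qpcr"] = out / "qpcr.tsv"
    generate_qpcr_table(config).to_csv(paths["qpcr"], sep="\t", index=False,
                                       float_format="%.6g")
    paths["phenotypes"] = out / "phenotypes.tsv"
    generate_phenotype_table(config).to_csv(paths["phenotypes"], sep="\t", index=False)
    return SyntheticTruth(truth, paths)


def generate_qpcr_table(config: SyntheticConfig) -> pd.DataFrame:
    """Long-format %-input triplicates per (region, antibody, genotype, DRB).

    Replicates are lognormal around the configured mean; zero noise makes
    every replicate equal its mean.
    """
    rng = _rng(config, "qpcr")
    rows = []
    for (region, antibody, genotype, condition), mean in sorted(
        config.qpcr_means.items()
    ):
        for rep in range(1, config.qpcr_replicates + 1):
            noise = (
                rng.normal(0.0, config.qpcr_noise_sd_log2)
                if config.qpcr_noise_sd_log2 > 0
                else 0.0
            )
            rows.append(
                {
                    "region": region,
                    "antibody": antibody,
                    "genotype": genotype,
                    "condition": condition,
                    "replicate": rep,
                    "percent_input": mean * float(np.exp2(noise)),
                }
            )
    return pd.DataFrame(rows)


def generate_phenotype_table(config: SyntheticConfig) -> pd.DataFrame:
    """Genotype x phenotype affected-count table from configured penetrances.

    Each animal is affected by each phenotype independently with that
    phenotype's penetrance; the total-affected row counts animals with at
    least one phenotype, so phenotypes may co-occur as in real litters.
    """
    rng = _rng(config, "phenotype")
    phenotypes = sorted(
        {p for pens in config.phenotype_penetrance.values() for p in pens}
    )
    rows = []
    for genotype, n in config.phenotype_n.items():
        pens = config.phenotype_penetrance.get(genotype, {})
        hits = np.zeros((n, len(phenotypes)), dtype=bool)
        for j, p in enumerate(phenotypes):
            prob = pens.get(p, 0.0)
            if prob > 0:
                hits[:, j] = rng.random(n) < prob
        for j, p in enumerate(phenotypes):
            rows.append(
                {"genotype": genotype, "phenotype": p,
                 "affected": int(hits[:, j].sum()), "total": n}
            )
        rows.append(
            {"genotype": genotype, "phenotype": "any",
             "affected": int(hits.any(axis=1).sum()), "total": n}
        )
    return pd.DataFrame(rows)
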