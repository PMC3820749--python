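"""Generator contracts: determinism, label/file consistency, effect realization."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from ashkit import io as aio
from ashkit.association import AssociationRule, associate, co_occupancy
from ashkit.coverage import region_rpkm_table
from ashkit.expression import classify_ra_responsive
from ashkit.synth import (
    SyntheticConfig,
    draw_labels,
    generate,
    generate_phenotype_table,
    generate_qpcr_table,
    place_genes,
    simulate_coverage,
    simulate_expression,
    simulate_peaks,
)


def sha256_dir(path: Path) -> dict:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(path.iterdir())
        if p.is_file()
    }


def test_gene_placement_spacing_and_bounds(small_world):
    cfg, genome, genes, _ = small_world
    by_chrom = {}
    for g in genes:
        genome.validate_interval(g.interval)
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    for glist in by_chrom.values():
        glist.sort(key=lambda g: g.interval.start)
        for a, b in zip(glist, glist[1:]):
            assert b.interval.start - a.interval.end >= 50_000


def test_labels_have_exact_fractions(small_world):
    cfg, _, genes, truth = small_world
    assert truth["responsive"].sum() == round(cfg.frac_ra_responsive * cfg.n_genes)
    n_resp = truth["responsive"].sum()
    assert truth["impaired"].sum() == round(cfg.frac_impaired_given_responsive * n_resp)
    assert truth["ash1l_target"].sum() == round(cfg.frac_ash1l_target * cfg.n_genes)
    assert truth["rar_associated"].sum() == round(cfg.frac_rar_associated * cfg.n_genes)
    # impaired implies responsive
    assert (truth["impaired"] <= truth["responsive"]).all()
    # signature consistent with the mark booleans
    biv = truth["signature"] == "Bivalent"
    assert (truth.loc[biv, "k4me3"] & truth.loc[biv, "k27me3"]).all()


def test_generate_is_byte_deterministic(tmp_path):
    cfg = SyntheticConfig(seed=7, n_genes=60, n_chroms=2)
    generate(cfg, tmp_path / "a")
    generate(cfg, tmp_path / "b")
    da, db = sha256_dir(tmp_path / "a"), sha256_dir(tmp_path / "b")
    assert da == db
    # a different seed changes at least the stochastic outputs
    generate(SyntheticConfig(seed=8, n_genes=60, n_chroms=2), tmp_path / "c")
    assert sha256_dir(tmp_path / "c") != da


def test_zero_responsive_fraction_gives_zero_calls():
    cfg = SyntheticConfig(seed=1, n_genes=300, frac_ra_responsive=0.0)
    _, genes = place_genes(cfg)
    truth = draw_labels(cfg, genes)
    table = simulate_expression(cfg, truth)
    labels = classify_ra_responsive(table, "WT_RA", "WT")
    assert labels["responsive"].sum() == 0


def test_peak_labels_recovered_exactly(small_world):
    """Every labeled target is recovered at the stated window; no extras."""
    cfg, genome, genes, truth = small_world
    ash1l, rar = simulate_peaks(cfg, genes, truth, genome)
    got_ash = associate(
        genes, ash1l, AssociationRule("tss_window", flank=4000), genome
    ).associated_genes()
    assert got_ash == set(truth.index[truth["ash1l_target"]])
    got_rar = associate(
        genes, rar, AssociationRule("upstream_and_body", upstream=20_000), genome
    ).associated_genes()
    assert got_rar == set(truth.index[truth["rar_associated"]])


def test_co_occupancy_parameter_recovery():
    """Measured RAR/Ash1l overlap within 3 binomial SE of the setting."""
    cfg = SyntheticConfig(seed=5, n_genes=2000, n_chroms=4, co_occupancy=0.6)
    genome, genes = place_genes(cfg)
    truth = draw_labels(cfg, genes)
    ash1l, rar = simulate_peaks(cfg, genes, truth, genome)
    frac = co_occupancy(rar, ash1l, max_gap=0)
    n = len(rar)
    se = np.sqrt(0.6 * 0.4 / n)
    assert abs(frac - 0.6) <= 3 * se


def test_expression_recovery_across_seeds():
    """Recovered class fractions track configured ones within 3 binomial SE."""
    for seed in range(10):
        cfg = SyntheticConfig(seed=seed, n_genes=2000)
        _, genes = place_genes(cfg)
        truth = draw_labels(cfg, genes)
        table = simulate_expression(cfg, truth)
        labels = classify_ra_responsive(table, "WT_RA", "WT")
        n = len(labels)
        p = cfg.frac_ra_responsive
        se = np.sqrt(p * (1 - p) / n)
        assert abs(labels["responsive"].mean() - p) <= 3 * se


def test_coverage_effect_realization(small_world):
    """Raw per-gene Δlog2 of body RPKM recovers the configured effects."""
    cfg, genome, genes, truth = small_world
    tracks = simulate_coverage(cfg, genes, truth, genome, marks=("K36me3",))
    plus = region_rpkm_table(tracks[("K36me3", "DRB+")], genes).values
    minus = region_rpkm_table(tracks[("K36me3", "DRB-")], genes).values
    d = np.log2(plus / minus)  # marked genes have ample counts, no pseudocount
    marked = truth["me3_marked"]
    rar = truth["rar_associated"]
    non_rar = d[(marked & ~rar).to_numpy()]
    rar_marked = d[(marked & rar).to_numpy()]
    tol = 4 * max(cfg.noise_sd_log2, 0.2)
    assert abs(non_rar.mean() - cfg.drb_me3_loss_log2) <= tol / np.sqrt(len(non_rar)) + 0.1
    if len(rar_marked) >= 3:
        assert abs(rar_marked.mean() - cfg.drb_me3_loss_rar_log2) <= 0.3


def test_generated_files_parse_back(tmp_path):
    cfg = SyntheticConfig(seed=3, n_genes=40, n_chroms=2)
    truth = generate(cfg, tmp_path)
    genome = aio.read_chrom_sizes(truth.paths["chrom_sizes"])
    genes = aio.read_gene_models_gtf(truth.paths["genes_gtf"], genome)
    assert len(genes) == 40
    genes_b = aio.read_gene_models_bed12(truth.paths["genes_bed12"], genome)
    assert [(g.gene_id, g.interval) for g in genes] == [
        (g.gene_id, g.interval) for g in genes_b
    ]
    table = aio.read_expression_table(truth.paths["expression"])
    assert list(table.columns) == ["WT", "dSET", "WT_RA", "dSET_RA"]
    track = aio.read_track(str(truth.paths["track_k36me3_minus"])[: -len(".bedgraph")], genome)
    assert track.total_binned_reads() > 0
    sig = aio.read_signature_labels(truth.paths["signatures"])
    assert len(sig) == 40


def test_qpcr_zero_noise_equals_means():
    cfg = SyntheticConfig(seed=1, qpcr_noise_sd_log2=0.0)
    df = generate_qpcr_table(cfg)
    for (region, ab, geno, cond), mean in cfg.qpcr_means.items():
        sub = df.query(
            "region == @region and antibody == @ab and genotype == @geno "
            "and condition == @cond"
        )
        assert len(sub) == 3
        assert np.allclose(sub["percent_input"], mean)


def test_phenotype_generator_respects_penetrance():
    cfg = SyntheticConfig(seed=2)
    df = generate_phenotype_table(cfg)
    wt = df[df["genotype"] == "+/+"]
    assert (wt["affected"] == 0).all()  # zero configured penetrance
    # binomial expectation: pen 0.42, n=36 -> mean affected ~ 15.1
    counts = []
    for seed in range(40):
        d = generate_phenotype_table(SyntheticConfig(seed=seed))
        row = d.query("genotype == '+/dSET' and phenotype == 'broadened_neural_arch'")
        counts.append(int(row["affected"].iloc[0]))
    mean = np.mean(counts)
    se = np.sqrt(36 * 0.42 * 0.58 / 40)
    assert abs(mean - 0.42 * 36) <= 3 * se


def test_config_validation():
    with pytest.raises(Exception):
        SyntheticConfig(frac_ra_responsive=1.5)
    with pytest.raises(Exception):
        SyntheticConfig(gene_length_range=(1000, 2000))
    with pytest.raises(Exception):
        SyntheticConfig(signature_probs={"background": (0.5, 0.5, 0.5, 0.5)})
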