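"""Region RPKM, percentile normalization, DRB grouping and profiles."""

import numpy as np
import pandas as pd
import pytest

from ashkit.coverage import (
    ProfileMatrix,
    RegionRpkmTable,
    anchor_profile,
    drb_dlog2,
    group_by_response,
    metagene_profile,
    percentile75_normalize,
    region_rpkm,
    region_rpkm_table,
    underrepresentation_test,
)
from ashkit.intervals import (
    CoverageTrack,
    GeneModel,
    Genome,
    GenomicInterval,
    Peak,
    PeakSet,
    ValidationError,
)
from ashkit.signatures import chi_square_2x2


def flat_track(genome, density, bin_width=100, total=1e7, mark="M", cond="C"):
    bins = {
        c: np.full(-(-s // bin_width), density * bin_width, dtype=float)
        for c, s in genome.chrom_sizes.items()
    }
    return CoverageTrack(mark, cond, bins, bin_width, total)


def test_region_rpkm_definition_arithmetic():
    """1000 reads in a 2 kb region with 10M mapped reads -> RPKM 50."""
    genome = Genome({"c": 10_000})
    bins = {"c": np.zeros(100)}
    bins["c"][20:40] = 50.0  # 1000 reads over [2000, 4000)
    track = CoverageTrack("M", "C", bins, 100, 1e7)
    assert region_rpkm(track, GenomicInterval("c", 2000, 4000)) == pytest.approx(50.0)
    # empty neighborhood
    assert region_rpkm(track, GenomicInterval("c", 6000, 8000)) == 0.0


def test_region_rpkm_prorates_partial_bins():
    genome = Genome({"c": 1000})
    bins = {"c": np.array([10.0, 20.0, 30.0])}
    track = CoverageTrack("M", "C", bins, 100, 1e6)
    # [50, 150): half of bin0 + half of bin1 = 5 + 10 = 15 reads over 100 bp
    iv = GenomicInterval("c", 50, 150)
    assert track.region_count(iv) == pytest.approx(15.0)
    assert region_rpkm(track, iv) == pytest.approx(15.0 / 0.1 / 1.0)


def test_region_count_matches_per_base_oracle():
    """Pro-rated counts equal a per-base uniform-density oracle."""
    rng = np.random.default_rng(0)
    for _ in range(30):
        nbins = int(rng.integers(5, 50))
        w = int(rng.choice([10, 25, 100]))
        bins = {"c": rng.poisson(5.0, nbins).astype(float)}
        track = CoverageTrack("M", "C", bins, w, 1e6)
        per_base = np.repeat(bins["c"] / w, w)
        s = int(rng.integers(0, nbins * w - 1))
        e = int(rng.integers(s + 1, nbins * w))
        assert track.region_count(GenomicInterval("c", s, e)) == pytest.approx(
            per_base[s:e].sum(), rel=1e-9
        )


def test_region_rpkm_table_matches_scalar_path():
    rng = np.random.default_rng(1)
    genome = Genome({"c1": 50_000, "c2": 30_000})
    bins = {
        "c1": rng.poisson(3.0, 500).astype(float),
        "c2": rng.poisson(1.0, 300).astype(float),
    }
    track = CoverageTrack("M", "C", bins, 100, 5e6)
    genes = [
        GeneModel("a", GenomicInterval("c1", 1000, 9000), "+"),
        GeneModel("b", GenomicInterval("c2", 2000, 4500), "-"),
        GeneModel("c", GenomicInterval("c1", 20_050, 21_130), "+"),
    ]
    table = region_rpkm_table(track, genes)
    for g in genes:
        assert table.values[g.gene_id] == pytest.approx(
            region_rpkm(track, g.interval), rel=1e-12
        )


def test_percentile75_normalize_linear_interpolation():
    """[1,2,3,4] -> normalizer 3.25 (type-7 percentile), values divided by it."""
    t = RegionRpkmTable(pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd")))
    out = percentile75_normalize(t)
    assert out.normalizer == pytest.approx(3.25)
    np.testing.assert_allclose(out.values, np.array([1, 2, 3, 4]) / 3.25)
    assert out.normalized


def test_percentile75_constant_vector_gives_ones():
    t = RegionRpkmTable(pd.Series([7.0] * 8, index=[f"g{i}" for i in range(8)]))
    out = percentile75_normalize(t)
    np.testing.assert_allclose(out.values, 1.0)


def test_percentile75_invariant_and_idempotence():
    rng = np.random.default_rng(2)
    vals = pd.Series(rng.lognormal(0, 1, 500), index=[f"g{i}" for i in range(500)])
    once = percentile75_normalize(RegionRpkmTable(vals))
    assert np.percentile(once.values, 75) == pytest.approx(1.0, abs=1e-9)
    twice = percentile75_normalize(once)
    assert twice.normalizer == pytest.approx(1.0, abs=1e-9)
    np.testing.assert_allclose(twice.values, once.values)


def test_percentile75_degenerate_inputs():
    with pytest.raises(ValidationError):
        percentile75_normalize(
            RegionRpkmTable(pd.Series([0.0, 0.0, 0.0, 0.0, 1.0], index=list("abcde")))
        )


def test_drb_dlog2_identities():
    idx = [f"g{i}" for i in range(6)]
    vals = pd.Series(np.linspace(0.5, 3.0, 6), index=idx)
    plus = RegionRpkmTable(vals, normalized=True, normalizer=1.0)
    minus = RegionRpkmTable(vals.copy(), normalized=True, normalizer=1.0)
    assert np.allclose(drb_dlog2(plus, minus), 0.0)
    # antisymmetry under swapping tracks
    plus2 = RegionRpkmTable(vals * 1.7, normalized=True, normalizer=1.0)
    np.testing.assert_allclose(
        drb_dlog2(plus2, minus).to_numpy(), -drb_dlog2(minus, plus2).to_numpy()
    )
    # doubling in the small-pseudocount limit -> +1
    doubled = RegionRpkmTable(vals * 2, normalized=True, normalizer=1.0)
    d = drb_dlog2(doubled, minus, pseudocount=1e-9)
    assert np.allclose(d, 1.0, atol=1e-6)


def test_drb_dlog2_requires_normalized_and_same_universe():
    vals = pd.Series([1.0, 2.0], index=["a", "b"])
    raw = RegionRpkmTable(vals)
    norm = RegionRpkmTable(vals, normalized=True, normalizer=1.0)
    with pytest.raises(ValidationError):
        drb_dlog2(raw, norm)
    other = RegionRpkmTable(pd.Series([1.0], index=["a"]), normalized=True, normalizer=1.0)
    with pytest.raises(ValidationError):
        drb_dlog2(norm, other)


def test_group_by_response_boundaries():
    """Δlog2 = −0.7 is 'decreased'; exactly −0.6 is 'unchanged' (strict <)."""
    d = pd.Series([-0.7, -0.6, 0.0, 0.6, 0.61], index=list("abcde"))
    g = group_by_response(d)
    assert g["a"] == "decreased"
    assert g["b"] == "unchanged"
    assert g["c"] == "unchanged"
    assert g["d"] == "unchanged"
    assert g["e"] == "increased"


def test_group_by_response_partition_property():
    rng = np.random.default_rng(3)
    d = pd.Series(rng.normal(0, 1.5, 1000), index=[f"g{i}" for i in range(1000)])
    g = group_by_response(d)
    assert g.notna().all()
    assert set(g.unique()) <= {"decreased", "unchanged", "increased"}
    # custom edges: still exhaustive and disjoint
    g4 = group_by_response(d, edges=[-1.0, 0.0, 1.0])
    assert g4.notna().all() and len(set(g4.unique())) == 4


def test_group_by_response_rejects_bad_edges():
    d = pd.Series([0.0], index=["a"])
    with pytest.raises(ValidationError):
        group_by_response(d, edges=[0.6, -0.6])
    with pytest.raises(ValidationError):
        group_by_response(pd.Series([np.nan], index=["a"]))


def test_underrepresentation_hand_built_example():
    """4-gene example matches the hand-computed 2x2 statistic."""
    groups = pd.Series(
        ["decreased", "decreased", "unchanged", "unchanged"], index=list("abcd")
    )
    flags = pd.Series([False, False, True, True], index=list("abcd"))
    rep = underrepresentation_test(groups, flags).by_category()
    # decreased: [[0,2],[2,0]] -> chi2 = 4 by hand
    stat, _, p = chi_square_2x2([[0, 2], [2, 0]])
    assert rep["decreased"].statistic == pytest.approx(stat)
    assert rep["decreased"].statistic == pytest.approx(4.0, abs=1e-10)
    assert rep["decreased"].direction == "depleted"
    assert rep["unchanged"].direction == "enriched"


def test_underrepresentation_null_calibration():
    """Random flags: no group significant at 0.001 in >=95% of seeded runs."""
    hits = 0
    n_runs = 40
    for seed in range(n_runs):
        rng = np.random.default_rng(seed)
        idx = [f"g{i}" for i in range(2000)]
        groups = pd.Series(
            rng.choice(["decreased", "unchanged", "increased"], 2000, p=[0.2, 0.6, 0.2]),
            index=idx,
        )
        flags = pd.Series(rng.random(2000) < 0.2, index=idx)
        rep = underrepresentation_test(groups, flags)
        if any(c.p_value < 0.001 for c in rep.categories if np.isfinite(c.p_value)):
            hits += 1
    assert hits <= int(0.05 * n_runs) + 1


def test_metagene_uniform_coverage_is_flat_zero():
    """Uniform density everywhere -> log2 ratio to genome mean is ~0."""
    genome = Genome({"c": 100_000})
    track = flat_track(genome, density=0.05)
    genes = [
        GeneModel("a", GenomicInterval("c", 10_000, 30_000), "+"),
        GeneModel("b", GenomicInterval("c", 50_000, 65_000), "-"),
    ]
    prof = metagene_profile(track, genes, genome, n_body_bins=50, flank_bp=2000, flank_bins=10)
    ratio = prof.log2_ratio_profile()
    assert np.allclose(ratio, 0.0, atol=1e-9)
    assert prof.values.shape == (2, 70)


def test_metagene_minus_strand_mirrors_plus():
    """A coverage ramp profiles as the mirror image on the − strand."""
    genome = Genome({"c": 40_000})
    nbins = 400
    bins = {"c": np.linspace(1, 100, nbins)}
    track = CoverageTrack("M", "C", bins, 100, 1e6)
    iv = GenomicInterval("c", 10_000, 30_000)
    plus = metagene_profile(
        track, [GeneModel("p", iv, "+")], genome, n_body_bins=40, flank_bp=1000, flank_bins=5
    )
    minus = metagene_profile(
        track, [GeneModel("m", iv, "-")], genome, n_body_bins=40, flank_bp=1000, flank_bins=5
    )
    np.testing.assert_allclose(plus.values[0], minus.values[0][::-1], rtol=1e-9)


def test_metagene_conserves_region_reads():
    """Body-bin sums equal the pro-rated total reads of TSS->TES."""
    rng = np.random.default_rng(4)
    genome = Genome({"c": 50_000})
    bins = {"c": rng.poisson(4.0, 500).astype(float)}
    track = CoverageTrack("M", "C", bins, 100, 1e6)
    gene = GeneModel("g", GenomicInterval("c", 12_345, 33_017), "+")
    prof = metagene_profile(track, [gene], genome, n_body_bins=100, flank_bp=2000, flank_bins=20)
    body = prof.values[0][20:120]
    assert body.sum() == pytest.approx(track.region_count(gene.interval), rel=1e-9)


def test_metagene_skips_short_genes():
    genome = Genome({"c": 10_000})
    track = flat_track(genome, 0.1)
    genes = [
        GeneModel("ok", GenomicInterval("c", 1000, 5000), "+"),
        GeneModel("short", GenomicInterval("c", 6000, 6050), "+"),
    ]
    prof = metagene_profile(track, genes, genome, n_body_bins=100, flank_bp=500, flank_bins=5)
    assert prof.meta["n_skipped"] == 1
    assert prof.row_ids == ["ok"]


def test_metagene_mean_profile_order_invariant():
    rng = np.random.default_rng(5)
    genome = Genome({"c": 100_000})
    bins = {"c": rng.poisson(3.0, 1000).astype(float)}
    track = CoverageTrack("M", "C", bins, 100, 1e6)
    genes = [
        GeneModel(f"g{i}", GenomicInterval("c", s, s + 8000), "+")
        for i, s in enumerate(range(1000, 90_000, 10_000))
    ]
    p1 = metagene_profile(track, genes, genome)
    p2 = metagene_profile(track, genes[::-1], genome)
    np.testing.assert_array_equal(p1.mean_profile(), p2.mean_profile())


def test_anchor_profile_centers_on_summit():
    genome = Genome({"c": 20_000})
    bins = {"c": np.zeros(200)}
    bins["c"][100] = 500.0  # spike in [10000, 10100)
    track = CoverageTrack("M", "C", bins, 100, 1e6)
    peaks = PeakSet(
        "RAR",
        [Peak(GenomicInterval("c", 9000, 11_000), name="pk", summit_offset=1050)],
    )
    prof = anchor_profile(track, peaks, genome, half_width_bp=2000, n_bins=40)
    center_cols = prof.values[0][18:22]
    assert center_cols.sum() == pytest.approx(500.0, rel=1e-9)
    assert prof.values[0].sum() == pytest.approx(500.0, rel=1e-9)
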