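"""Modified-FPKM transform and the RA-response / impairment classifiers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ashkit.expression import (
    ExpressionTable,
    ResponseThresholds,
    classify_dysregulated,
    classify_impaired,
    classify_ra_responsive,
    dlog2,
    eligible_genes,
    modified_log2,
    summarize_fraction,
)
from ashkit.intervals import ValidationError


def make_table(wt, wt_ra, mut=None, mut_ra=None, ids=None):
    n = len(wt)
    data = {"WT": wt, "WT_RA": wt_ra}
    if mut is not None:
        data["dSET"] = mut
    if mut_ra is not None:
        data["dSET_RA"] = mut_ra
    idx = ids or [f"g{i}" for i in range(n)]
    return ExpressionTable(pd.DataFrame(data, index=idx, dtype=float))


@pytest.mark.parametrize(
    "fpkm,expected",
    [(0.0, np.log2(0.1)), (0.9, 0.0), (7.9, 3.0)],
)
def test_modified_log2_closed_form(fpkm, expected):
    assert modified_log2(fpkm, 0.1) == pytest.approx(expected, abs=1e-12)


def test_modified_log2_rejects_negative():
    with pytest.raises(ValidationError):
        modified_log2(-1.0)
    with pytest.raises(ValidationError):
        modified_log2(1.0, pseudocount=0.0)


def test_dlog2_examples():
    assert dlog2(3.9, 0.9, 0.1) == pytest.approx(2.0)
    assert dlog2(5.0, 5.0) == 0.0


@given(
    a=st.floats(0, 1e6, allow_nan=False),
    b=st.floats(0, 1e6, allow_nan=False),
)
@settings(deadline=None, max_examples=200)
def test_dlog2_antisymmetry(a, b):
    assert dlog2(a, b) == pytest.approx(-dlog2(b, a), abs=1e-9)


def test_nan_fpkm_is_a_validation_error():
    df = pd.DataFrame({"WT": [1.0, np.nan], "WT_RA": [1.0, 1.0]}, index=["a", "b"])
    with pytest.raises(ValidationError, match="NaN"):
        ExpressionTable(df)


def test_duplicate_gene_ids_rejected():
    df = pd.DataFrame({"WT": [1.0, 2.0]}, index=["a", "a"])
    with pytest.raises(ValidationError, match="duplicate"):
        ExpressionTable(df)


def test_eligibility_filter():
    """A gene below the FPKM floor in every condition is excluded."""
    t = make_table([0.05, 0.2, 0.0], [0.08, 0.0, 5.0])
    assert list(eligible_genes(t)) == ["g1", "g2"]


def test_ra_responsive_boundary_is_strict():
    """Δlog2 exactly 2.5 is NOT responsive; 2.51 is ('a value over 2.5')."""
    pc = 0.1
    base = 1.0
    at = (base + pc) * 2**2.5 - pc     # lands exactly on the threshold
    above = (base + pc) * 2**2.51 - pc
    t = make_table([base, base], [at, above])
    labels = classify_ra_responsive(t, "WT_RA", "WT")
    assert labels.loc["g0", "dlog2_ra"] == pytest.approx(2.5, abs=1e-12)
    assert not labels.loc["g0", "responsive"]
    assert labels.loc["g1", "responsive"]


def test_all_zero_gene_is_not_responsive():
    t = make_table([0.0, 1.0], [0.0, 100.0], ids=["z", "x"])
    labels = classify_ra_responsive(t, "WT_RA", "WT")
    # all-zero gene fails the eligibility floor entirely
    assert "z" not in labels.index
    assert labels.loc["x", "responsive"]


def test_impaired_requires_responsive_and_strict_boundary():
    pc = 0.1
    wt_ra = [80.0, 80.0, 80.0, 0.3]
    # g0: mut == wt -> not impaired; g1: exactly -1 -> not impaired;
    # g2: just below -1 -> impaired; g3: not responsive -> never impaired
    at = (80.0 + pc) * 2**-1.0 - pc
    below = (80.0 + pc) * 2**-1.01 - pc
    t = make_table([1.0, 1.0, 1.0, 0.3], wt_ra, mut_ra=[80.0, at, below, 0.0])
    labels = classify_ra_responsive(t, "WT_RA", "WT")
    labels = classify_impaired(t, "dSET_RA", "WT_RA", labels)
    assert not labels.loc["g0", "impaired"]
    assert labels.loc["g1", "dlog2_genotype"] == pytest.approx(-1.0, abs=1e-12)
    assert not labels.loc["g1", "impaired"]
    assert labels.loc["g2", "impaired"]
    assert not labels.loc["g3", "responsive"] and not labels.loc["g3", "impaired"]
    # invariant: impaired => responsive
    assert (labels["impaired"] <= labels["responsive"]).all()


def test_dysregulated_hand_enumeration():
    """Counts on a hand-built 20-gene table match direct enumeration."""
    rng = np.random.default_rng(5)
    wt = rng.uniform(0.5, 50, 20)
    mut = wt * 2 ** rng.uniform(-3, 3, 20)
    t = make_table(wt, wt, mut=mut)
    down, up = classify_dysregulated(t, "dSET", "WT")
    exp_down = {
        f"g{i}"
        for i in range(20)
        if np.log2((mut[i] + 0.1) / (wt[i] + 0.1)) < -1
    }
    exp_up = {
        f"g{i}"
        for i in range(20)
        if np.log2((mut[i] + 0.1) / (wt[i] + 0.1)) > 1
    }
    assert down == exp_down and up == exp_up
    assert not (down & up)


def test_dysregulated_boundary_and_empty():
    pc = 0.1
    wt = [4.0, 4.0]
    mut = [(4.0 + pc) / 2 - pc, 4.0]  # exactly -1, and 0
    t = make_table(wt, wt, mut=mut)
    down, up = classify_dysregulated(t, "dSET", "WT")
    assert down == set() and up == set()


def test_threshold_monotonicity():
    """Raising the responsive threshold never enlarges the responsive set."""
    rng = np.random.default_rng(7)
    wt = rng.uniform(0.2, 20, 300)
    wt_ra = wt * 2 ** rng.uniform(-1, 5, 300)
    t = make_table(wt, wt_ra)
    prev = None
    for thr in (1.0, 2.0, 2.5, 3.0, 4.0):
        labels = classify_ra_responsive(
            t, "WT_RA", "WT", ResponseThresholds(ra_responsive_dlog2=thr)
        )
        current = set(labels.index[labels["responsive"]])
        if prev is not None:
            assert current <= prev
        prev = current


def test_scale_property_with_pseudocount():
    """Scaling both conditions by c shifts Δlog2 by a bounded, computable amount."""
    pc = 0.1
    a, b, c = 4.0, 2.0, 10.0
    got = dlog2(c * a, c * b, pc)
    expected = np.log2((c * a + pc) / (c * b + pc))
    assert got == pytest.approx(expected, abs=1e-12)
    # with pseudocount -> 0 the scaled and unscaled values converge
    assert dlog2(c * a, c * b, 1e-9) == pytest.approx(dlog2(a, b, 1e-9), abs=1e-6)


def test_summarize_fraction():
    assert summarize_fraction(152, 543) == 28.0
    assert summarize_fraction(0, 10) == 0.0
    assert summarize_fraction(10, 10) == 100.0
    assert summarize_fraction({"a"}, {"a", "b", "c"}) == 33.3
    with pytest.raises(ValidationError):
        summarize_fraction(5, 0)
    with pytest.raises(ValidationError):
        summarize_fraction({"a", "z"}, {"a", "b"})
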