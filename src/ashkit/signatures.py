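"""Chromatin-signature classification and enrichment against a background.

Promoter state in ES cells is summarized by the presence of H3K4me3 and/or
H3K27me3: "Lys4me alone" (active), "Bivalent" (both marks, poised
developmental genes), "Lys27me alone" (Polycomb-repressed), "None" (neither).
Gene groups are tested for enrichment or depletion of each state against the
total gene set with a Pearson chi-square on the 2x2 group-vs-rest table
(default; a k-category goodness-of-fit alternative is provided).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import ValidationError

__all__ = [
    "SIGNATURES",
    "classify_signature",
    "signature_table",
    "chi_square_2x2",
    "chi_square_goodness_of_fit",
    "CategoryEnrichment",
    "EnrichmentReport",
    "enrichment_vs_background",
]

SIGNATURES: Tuple[str, ...] = ("Lys4me alone", "Bivalent", "Lys27me alone", "None")

_SIGNATURE_MAP = {
    (True, False): "Lys4me alone",
    (True, True): "Bivalent",
    (False, True): "Lys27me alone",
    (False, False): "None",
}


def classify_signature(k4me3: bool, k27me3: bool) -> str:
    """Deterministic mapping from the two promoter marks to the state."""
    return _SIGNATURE_MAP[(bool(k4me3), bool(k27me3))]


def signature_table(labels: pd.DataFrame) -> pd.Series:
    """Per-gene signature from a DataFrame with k4me3/k27me3 boolean columns."""
    for col in ("k4me3", "k27me3"):
        if col not in labels.columns:
            raise ValidationError(f"labels need a {col!r} column")
    return pd.Series(
        [
            classify_signature(k4, k27)
            for k4, k27 in zip(labels["k4me3"], labels["k27me3"])
        ],
        index=labels.index,
        name="signature",
    )


def chi_square_2x2(table, continuity: bool = False) -> Tuple[float, int, float]:
    """Pearson chi-square on a 2x2 contingency table.

    Returns ``(statistic, df, p)`` with ``df = 1`` and the upper-tail
    p-value.  Expected counts come from the product of marginals; the Yates
    continuity correction is off by default (counts in this pipeline are
    large).  A zero marginal leaves the test undefined.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {obs.shape}")
    if (obs < 0).any():
        raise ValidationError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValidationError("zero marginal: chi-square test undefined")
    expected = np.outer(row, col) / total
    diff = np.abs(obs - expected)
    if continuity:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    return stat, 1, float(stats.chi2.sf(stat, 1))


def chi_square_goodness_of_fit(
    observed: Sequence[float], expected_probs: Sequence[float]
) -> Tuple[float, int, float]:
    """k-category goodness-of-fit of observed counts vs background proportions."""
    obs = np.asarray(observed, dtype=float)
    probs = np.asarray(expected_probs, dtype=float)
    if obs.shape != probs.shape:
        raise ValidationError("observed and expected_probs must align")
    if not np.isclose(probs.sum(), 1.0):
        raise ValidationError("expected_probs must sum to 1")
    if (probs <= 0).any():
        raise ValidationError("expected_probs must be positive")
    expected = probs * obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    return stat, df, float(stats.chi2.sf(stat, df))


@dataclass(frozen=True)
class CategoryEnrichment:
    category: str
    in_group: int
    in_background: int
    relative_ratio: float
    statistic: float
    df: int
    p_value: float
    direction: str  # "enriched" | "depleted" | "none"


@dataclass
class EnrichmentReport:
    group_label: str
    group_size: int
    universe_size: int
    categories: List[CategoryEnrichment] = field(default_factory=list)

    def by_category(self) -> Dict[str, CategoryEnrichment]:
        return {c.category: c for c in self.categories}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.categories]).set_index("category")


def enrichment_vs_background(
    group: Set[str],
    category_labels: pd.Series,
    universe: Set[str],
    group_label: str = "group",
    categories: Sequence[str] = SIGNATURES,
    method: str = "two_by_two",
    continuity: bool = False,
) -> EnrichmentReport:
    """Test a gene group for category enrichment against the total gene set.

    For each category the 2x2 table [in-group vs rest] x [in-category vs not]
    is tested (default); ``method="goodness_of_fit"`` instead tests the full
    observed category vector against universe proportions (df = k - 1).  The
    relative-ratio vector (category fraction in group over fraction in
    universe) is emitted for chart reproduction.
    """
    if not group:
        raise ValidationError("empty gene group")
    if not group <= universe:
        raise ValidationError("group contains genes outside the universe")
    labels = category_labels.loc[sorted(universe)]
    if labels.isna().any():
        missing = labels.index[labels.isna()].tolist()
        raise ValidationError(f"unlabeled universe genes: {missing[:5]}")
    in_group = labels.loc[sorted(group)]

    report = EnrichmentReport(group_label, len(group), len(universe))
    uni_counts = labels.value_counts()
    grp_counts = in_group.value_counts()

    if method == "goodness_of_fit":
        obs = np.array([grp_counts.get(c, 0) for c in categories], dtype=float)
        probs = np.array([uni_counts.get(c, 0) for c in categories], dtype=float)
        stat, df, p = chi_square_goodness_of_fit(obs, probs / probs.sum())
    elif method != "two_by_two":
        raise ValidationError(f"unknown method {method!r}")

    for cat in categories:
        g_in = int(grp_counts.get(cat, 0))
        u_in = int(uni_counts.get(cat, 0))
        frac_group = g_in / len(group)
        frac_uni = u_in / len(universe)
        ratio = np.inf if frac_uni == 0 and frac_group > 0 else (
            frac_group / frac_uni if frac_uni > 0 else np.nan
        )
        if method == "two_by_two":
            table = [
                [g_in, len(group) - g_in],
                [u_in - g_in, (len(universe) - len(group)) - (u_in - g_in)],
            ]
            try:
                stat, df, p = chi_square_2x2(table, continuity=continuity)
            except ValidationError:
                # degenerate table (e.g. group == universe): ratios are still
                # defined, the test is not
                stat, df, p = float("nan"), 1, float("nan")
        expected = frac_uni * len(group)
        if g_in > expected:
            direction = "enriched"
        elif g_in < expected:
            direction = "depleted"
        else:
            direction = "none"
        report.categories.append(
            CategoryEnrichment(cat, g_in, u_in, float(ratio), stat, df, p, direction)
        )
    return report
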