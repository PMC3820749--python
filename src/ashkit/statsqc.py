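"""Small-statistics layer: ChIP-qPCR %-input, triplicate summaries with
Student's t-test, and phenotype penetrance tabulation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .expression import round_half_up
from .intervals import ValidationError

__all__ = [
    "percent_input",
    "subtract_background",
    "summarize_replicates",
    "two_sample_t",
    "summarize_qpcr_table",
    "PhenotypeCounts",
    "penetrance_table",
]


def percent_input(ip_quantity: float, input_quantity: float, input_fraction: float = 1.0) -> float:
    """ChIP signal as a percentage of the dilution-corrected input.

    ``input_fraction`` is the fraction of chromatin the input aliquot
    represents (e.g. 0.1 for a 10% input): the input quantity is scaled up by
    ``1/input_fraction`` before taking the ratio.
    """
    if ip_quantity <= 0 or input_quantity <= 0:
        raise ValidationError("quantities must be positive")
    if not (0 < input_fraction <= 1):
        raise ValidationError("input_fraction must be in (0, 1]")
    return 100.0 * ip_quantity / (input_quantity / input_fraction)


def subtract_background(values, background: float) -> Tuple[np.ndarray, int]:
    """Subtract a constant %-input background, clipping at zero.

    Background signals in this assay run around 0.01% input; values below
    background floor at 0.  Returns the adjusted array and how many values
    were clipped.
    """
    if background < 0:
        raise ValidationError("background must be >= 0")
    arr = np.asarray(values, dtype=float)
    adjusted = arr - background
    n_clipped = int((adjusted < 0).sum())
    return np.maximum(adjusted, 0.0), n_clipped


def summarize_replicates(values) -> Tuple[float, float]:
    """(mean, sample sd) with the n−1 denominator."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValidationError("need at least 2 replicates")
    return float(arr.mean()), float(arr.std(ddof=1))


def two_sample_t(values_a, values_b, welch: bool = False) -> Tuple[float, float, float]:
    """Two-sided two-sample t-test, pooled-variance Student's form by default.

    Returns ``(t, df, p)``.  ``welch=True`` switches to the unequal-variance
    form.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need at least 2 replicates per group")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else float(a.size + b.size - 2)
    return float(res.statistic), df, float(res.pvalue)


def summarize_qpcr_table(
    df: pd.DataFrame,
    value_col: str = "percent_input",
    background: float = 0.0,
    group_cols: Sequence[str] = ("region", "antibody", "genotype", "condition"),
) -> pd.DataFrame:
    """Mean/sd per (region, antibody, genotype, condition) after background
    subtraction of the replicate %-input values."""
    missing = [c for c in (*group_cols, value_col) if c not in df.columns]
    if missing:
        raise ValidationError(f"qPCR table missing columns: {missing}")
    rows = []
    for keys, sub in df.groupby(list(group_cols), sort=True):
        adj, n_clipped = subtract_background(sub[value_col].to_numpy(), background)
        mean, sd = summarize_replicates(adj)
        rows.append({**dict(zip(group_cols, keys)), "mean": mean, "sd": sd,
                     "n": len(adj), "n_clipped": n_clipped})
    return pd.DataFrame(rows)


@dataclass
class PhenotypeCounts:
    """Affected counts per genotype x phenotype plus totals analyzed."""

    affected: Mapping[str, Mapping[str, int]]  # genotype -> {phenotype: count}
    totals: Mapping[str, int]                  # genotype -> n analyzed

    def __post_init__(self) -> None:
        for genotype, n in self.totals.items():
            if n <= 0:
                raise ValidationError(f"total for {genotype!r} must be positive")
        for genotype, counts in self.affected.items():
            if genotype not in self.totals:
                raise ValidationError(f"no total for genotype {genotype!r}")
            for phenotype, c in counts.items():
                if not (0 <= c <= self.totals[genotype]):
                    raise ValidationError(
                        f"count {c} for ({genotype!r}, {phenotype!r}) outside "
                        f"[0, {self.totals[genotype]}]"
                    )


def penetrance_table(counts: PhenotypeCounts) -> pd.DataFrame:
    """Percent affected per genotype and phenotype, half-up to the integer.

    Returns a DataFrame indexed by phenotype with one column per genotype,
    holding integer percentages (100 x affected / total analyzed).
    """
    genotypes = list(counts.totals)
    phenotypes: list = []
    for g in genotypes:
        for p in counts.affected.get(g, {}):
            if p not in phenotypes:
                phenotypes.append(p)
    data: Dict[str, list] = {}
    for g in genotypes:
        total = counts.totals[g]
        col = []
        for p in phenotypes:
            c = counts.affected.get(g, {}).get(p, 0)
            col.append(int(round_half_up(100.0 * c / total)))
        data[g] = col
    return pd.DataFrame(data, index=pd.Index(phenotypes, name="phenotype"))
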