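"""RNA-seq response classification on the modified-FPKM scale.

All fold changes are computed on ``log2(FPKM + pseudocount)`` ("modified
FPKM"); the pseudocount (default 0.1 FPKM) damps dispersion of near-zero
values.  A gene is called retinoic-acid (RA) responsive when its Δlog2
between the RA-treated and undifferentiated condition exceeds 2.5 (strictly),
i.e. somewhat more than 5-fold on raw values; an RA-responsive gene is called
impaired in the catalytic mutant when its Δlog2 between mutant+RA and
wild-type+RA falls below −1 (a more-than-2-fold decrease).  All thresholds
are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Set, Tuple, Union

import numpy as np
import pandas as pd

from .intervals import ValidationError

__all__ = [
    "ExpressionTable",
    "ResponseThresholds",
    "modified_log2",
    "dlog2",
    "eligible_genes",
    "classify_ra_responsive",
    "classify_impaired",
    "classify_dysregulated",
    "summarize_fraction",
    "round_half_up",
]


@dataclass(frozen=True)
class ResponseThresholds:
    """Classification thresholds on the Δlog2 (modified FPKM) scale."""

    pseudocount: float = 0.1
    ra_responsive_dlog2: float = 2.5   # strict >
    impaired_dlog2: float = -1.0       # strict <  (more-than-2-fold decrease)
    dysregulated_dlog2: float = 1.0    # strict |Δ| >
    eligibility_min_fpkm: float = 0.1  # FPKM floor in >=1 condition

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")
        for name in ("ra_responsive_dlog2", "impaired_dlog2", "dysregulated_dlog2"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")


class ExpressionTable:
    """Genes x conditions FPKM matrix.

    Wraps a DataFrame indexed by gene_id with one column per condition.
    NaN and negative entries are validation errors, never silently dropped.
    """

    def __init__(self, fpkm: pd.DataFrame):
        if fpkm.index.has_duplicates:
            dupes = fpkm.index[fpkm.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene_ids: {dupes[:5]}")
        values = fpkm.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValidationError("NaN FPKM values are not allowed")
        if (values < 0).any():
            raise ValidationError("negative FPKM values are not allowed")
        self.fpkm = fpkm.astype(float)

    @property
    def gene_ids(self) -> pd.Index:
        return self.fpkm.index

    @property
    def conditions(self) -> list:
        return list(self.fpkm.columns)

    def condition(self, name: str) -> pd.Series:
        if name not in self.fpkm.columns:
            raise ValidationError(
                f"condition {name!r} not in table (have {self.conditions})"
            )
        return self.fpkm[name]


def modified_log2(fpkm, pseudocount: float = 0.1):
    """``log2(fpkm + pseudocount)``; accepts scalars or arrays."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    arr = np.asarray(fpkm, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("FPKM must be non-negative")
    out = np.log2(arr + pseudocount)
    return float(out) if np.isscalar(fpkm) else out


def dlog2(a_fpkm, b_fpkm, pseudocount: float = 0.1):
    """Modified-log2 fold change of ``a`` over ``b``."""
    return modified_log2(a_fpkm, pseudocount) - modified_log2(b_fpkm, pseudocount)


def eligible_genes(
    table: ExpressionTable, thresholds: ResponseThresholds = ResponseThresholds()
) -> pd.Index:
    """Genes with FPKM >= the eligibility floor in at least one condition.

    The upstream annotation set is typically larger than the analyzable set;
    this floor removes never-expressed annotations and is configurable.
    """
    mask = (table.fpkm >= thresholds.eligibility_min_fpkm).any(axis=1)
    return table.gene_ids[mask]


def classify_ra_responsive(
    table: ExpressionTable,
    cond_ra: str,
    cond_undiff: str,
    thresholds: ResponseThresholds = ResponseThresholds(),
) -> pd.DataFrame:
    """Call RA-responsive genes among the eligible set.

    Returns a DataFrame indexed by eligible gene_id with columns
    ``dlog2_ra`` and boolean ``responsive`` (Δlog2 strictly > threshold).
    """
    elig = eligible_genes(table, thresholds)
    ra = table.condition(cond_ra).loc[elig]
    undiff = table.condition(cond_undiff).loc[elig]
    d = dlog2(ra.to_numpy(), undiff.to_numpy(), thresholds.pseudocount)
    return pd.DataFrame(
        {"dlog2_ra": d, "responsive": d > thresholds.ra_responsive_dlog2}, index=elig
    )


def classify_impaired(
    table: ExpressionTable,
    cond_mut_ra: str,
    cond_wt_ra: str,
    responsive_labels: pd.DataFrame,
    thresholds: ResponseThresholds = ResponseThresholds(),
) -> pd.DataFrame:
    """Call mutant-impaired genes within the responsive set.

    ``impaired`` implies ``responsive``: impairment is only defined on genes
    that responded to RA in the wild type.
    """
    if "responsive" not in responsive_labels.columns:
        raise ValidationError("responsive_labels must carry a 'responsive' column")
    idx = responsive_labels.index
    mut = table.condition(cond_mut_ra).loc[idx]
    wt = table.condition(cond_wt_ra).loc[idx]
    d = dlog2(mut.to_numpy(), wt.to_numpy(), thresholds.pseudocount)
    out = responsive_labels.copy()
    out["dlog2_genotype"] = d
    out["impaired"] = out["responsive"] & (d < thresholds.impaired_dlog2)
    return out


def classify_dysregulated(
    table: ExpressionTable,
    cond_mut: str,
    cond_wt: str,
    thresholds: ResponseThresholds = ResponseThresholds(),
) -> Tuple[Set[str], Set[str]]:
    """(down, up) gene sets with |Δlog2(mut over wt)| strictly above threshold."""
    elig = eligible_genes(table, thresholds)
    mut = table.condition(cond_mut).loc[elig]
    wt = table.condition(cond_wt).loc[elig]
    d = pd.Series(
        dlog2(mut.to_numpy(), wt.to_numpy(), thresholds.pseudocount), index=elig
    )
    down = set(elig[(d < -thresholds.dysregulated_dlog2).to_numpy()])
    up = set(elig[(d > thresholds.dysregulated_dlog2).to_numpy()])
    return down, up


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Deterministic half-up rounding at printed precision."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_fraction(subset: Union[int, set, frozenset], superset) -> float:
    """Percentage of ``superset`` covered by ``subset``, half-up to 1 decimal.

    Accepts either two sets (subset ⊆ superset enforced) or two counts.
    """
    if isinstance(subset, (set, frozenset)):
        if not subset <= superset:
            raise ValidationError("subset is not contained in superset")
        n_sub, n_sup = len(subset), len(superset)
    else:
        n_sub, n_sup = int(subset), int(superset)
        if n_sub > n_sup:
            raise ValidationError("subset count exceeds superset count")
    if n_sup == 0:
        raise ValidationError("superset is empty")
    return round_half_up(100.0 * n_sub / n_sup, 1)
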