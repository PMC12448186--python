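"""Contingency-table enrichment of gene classes among DE genes and among
log-fold-change directionality classes.

The 2x2 layout is (class ∧ condition, ¬class ∧ condition,
class ∧ ¬condition, ¬class ∧ ¬condition) over the expressed-gene universe,
tested with the two-sided Fisher's exact test (summation of hypergeometric
probabilities no larger than the observed table's — the R convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSet

__all__ = [
    "ContingencyTable2x2",
    "build_de_table",
    "build_direction_table",
    "fisher_exact",
    "enrichment_summary",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """a = class & condition, b = not-class & condition,
    c = class & not-condition, d = not-class & not-condition."""

    a: int
    b: int
    c: int
    d: int
    row_label: str = "class"
    col_label: str = "condition"

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0:
                raise ValueError("contingency cells must be non-negative")
        if self.total == 0:
            raise ValueError("empty contingency table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def build_de_table(de: pd.DataFrame, gene_set: GeneSet) -> ContingencyTable2x2:
    """Cross-tabulate class membership × DE flag over expressed genes."""
    genes = de["gene_id"].to_numpy()
    in_class = np.array([g in gene_set for g in genes])
    if not in_class.any():
        raise ValueError(
            f"gene set {gene_set.label!r} does not intersect the expressed universe"
        )
    is_de = de["is_de"].to_numpy().astype(bool)
    return ContingencyTable2x2(
        a=int((in_class & is_de).sum()),
        b=int((~in_class & is_de).sum()),
        c=int((in_class & ~is_de).sum()),
        d=int((~in_class & ~is_de).sum()),
        row_label=gene_set.label, col_label="DE",
    )


def build_direction_table(de: pd.DataFrame, gene_set: GeneSet) -> ContingencyTable2x2:
    """Cross-tabulate class membership × sign(log_fc) over expressed genes.

    Convention follows the latitudinal contrast: the *condition* column is
    +logFC (higher in the low-latitude population).  Genes with log_fc
    exactly 0 belong to neither sign class and are dropped with a warning.
    """
    genes = de["gene_id"].to_numpy()
    in_class = np.array([g in gene_set for g in genes])
    if not in_class.any():
        raise ValueError(
            f"gene set {gene_set.label!r} does not intersect the expressed universe"
        )
    lfc = de["log_fc"].to_numpy()
    zero = lfc == 0.0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} genes with log_fc == 0 "
                      "from the direction table", stacklevel=2)
        in_class, lfc = in_class[~zero], lfc[~zero]
    pos = lfc > 0
    return ContingencyTable2x2(
        a=int((in_class & pos).sum()),
        b=int((~in_class & pos).sum()),
        c=int((in_class & ~pos).sum()),
        d=int((~in_class & ~pos).sum()),
        row_label=gene_set.label, col_label="+logFC",
    )


def fisher_exact(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher's exact test.

    Returns (sample odds ratio, two-sided p).  The odds ratio is the
    unconditional sample estimate a*d/(b*c); with a zero margin the test is
    degenerate (p = 1) and the odds ratio is NaN.
    """
    arr = table.as_array()
    if min(arr.sum(axis=0).min(), arr.sum(axis=1).min()) == 0:
        warnings.warn("zero margin: Fisher's test degenerate, odds ratio undefined",
                      stacklevel=2)
        return float("nan"), 1.0
    if table.b == 0 or table.c == 0:
        oddsr = float("inf") if table.a * table.d > 0 else float("nan")
    else:
        oddsr = table.a * table.d / (table.b * table.c)
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(oddsr), float(p)


def enrichment_summary(table: ContingencyTable2x2) -> tuple[float, float, float]:
    """(pct class among condition, pct class among not-condition, fold).

    Percentages are rounded to one decimal; fold is their unrounded ratio.
    """
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise ValueError("zero condition margin: percentages undefined")
    pct_in = 100.0 * table.a / (table.a + table.b)
    pct_out = 100.0 * table.c / (table.c + table.d)
    fold = pct_in / pct_out if pct_out > 0 else float("inf")
    return round(pct_in, 1), round(pct_out, 1), fold
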