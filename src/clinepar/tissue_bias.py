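"""Tissue-specificity scoring (tau) and the calibrated organ-vs-whole-male
tissue-bias classifier.

tau is computed on a multi-tissue reference (log2(TPM+1) per tissue); genes
with tau >= 0.9 are treated as biased toward their most highly expressing
tissue.  Because a multi-tissue atlas exists for only one species, the
classifier translates the tau calls into thresholds on an organ-vs-whole-male
DE contrast that can be applied uniformly across species.

Contrast orientation: the organ-vs-whole-male coefficient is
(whole male − organ) on the log2 scale, so organ-enriched genes are strongly
negative (default cutoffs −3.59 for accessory gland, −0.46 for testis) while
the companion requirement of >= +1 against the *other* organ's contrast
depletes genes enriched there.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TauTable",
    "BiasThresholds",
    "AG_THRESHOLDS",
    "TESTIS_THRESHOLDS",
    "compute_tau",
    "classify_tissue_bias",
    "calibrate_thresholds",
    "biased_in_either",
]


@dataclass
class TauTable:
    """Per-gene tissue-specificity index and its argmax tissue."""

    table: pd.DataFrame  # index gene_id, columns: tau, argmax_tissue
    excluded: list[str]  # genes with zero expression everywhere (tau undefined)

    def biased_genes(self, tissue: str, cutoff: float = 0.9) -> set[str]:
        t = self.table
        mask = (t["tau"] >= cutoff) & (t["argmax_tissue"] == tissue)
        return set(t.index[mask])


@dataclass(frozen=True)
class BiasThresholds:
    """Cutoffs defining organ-biased genes from organ-vs-whole-male contrasts."""

    organ: str
    logfc_organ_vs_whole: float  # (whole − organ) must be <= this (negative)
    p_adj_max: float = 0.01
    min_tpm: float = 1.0
    min_ave_expr: float = 0.0
    ave_expr_strict: bool = True  # strict > for AG, non-strict >= for testis
    other_organ_logfc_min: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.p_adj_max < 1):
            raise ValueError("p_adj_max must be in (0,1)")
        if self.min_tpm < 0:
            raise ValueError("min_tpm must be >= 0")


AG_THRESHOLDS = BiasThresholds(
    organ="AG", logfc_organ_vs_whole=-3.59, p_adj_max=0.01,
    min_tpm=1.0, min_ave_expr=0.0, ave_expr_strict=True,
    other_organ_logfc_min=1.0,
)
TESTIS_THRESHOLDS = BiasThresholds(
    organ="testis", logfc_organ_vs_whole=-0.46, p_adj_max=0.01,
    min_tpm=5.0, min_ave_expr=0.0, ave_expr_strict=False,
    other_organ_logfc_min=1.0,
)


def compute_tau(expr: pd.DataFrame) -> TauTable:
    """Tissue-specificity index on a gene × tissue expression matrix.

    ``expr`` should already be on the log2(TPM+1) scale (non-negative).
    tau = sum_i(1 − x_i/x_max) / (n_tissues − 1): 0 for uniform expression,
    1 for single-tissue expression.  Genes with x_max = 0 are excluded.
    """
    if expr.shape[1] < 2:
        raise ValueError("tau needs at least two tissues")
    x = expr.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("expression must be non-negative (log2(TPM+1))")
    xmax = x.max(axis=1)
    ok = xmax > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = (1.0 - x / np.where(xmax > 0, xmax, 1.0)[:, None]).sum(axis=1) \
            / (x.shape[1] - 1)
    argmax = expr.columns.to_numpy()[np.argmax(x, axis=1)]
    table = pd.DataFrame(
        {"tau": tau[ok], "argmax_tissue": argmax[ok]},
        index=expr.index[ok],
    )
    return TauTable(table=table, excluded=list(expr.index[~ok]))


def classify_tissue_bias(organ_vs_whole: pd.DataFrame,
                         other_organ_vs_whole: pd.DataFrame,
                         organ_tpm: pd.Series,
                         thresholds: BiasThresholds) -> set[str]:
    """Organ-biased genes under the calibrated cutoff criteria.

    A gene is organ-biased iff, on the same gene universe,

    * (whole male − organ) log_fc  <= ``logfc_organ_vs_whole``,
    * its adjusted p               <= ``p_adj_max``,
    * its organ median TPM         >= ``min_tpm``,
    * its average expression passes ``min_ave_expr`` (strict or not), and
    * (whole male − other organ)   >= ``other_organ_logfc_min``.
    """
    a = organ_vs_whole.set_index("gene_id") if "gene_id" in organ_vs_whole \
        else organ_vs_whole
    b = other_organ_vs_whole.set_index("gene_id") \
        if "gene_id" in other_organ_vs_whole else other_organ_vs_whole
    if set(a.index) != set(b.index):
        raise ValueError("organ and other-organ tables have different gene universes")
    b = b.loc[a.index]
    tpm = organ_tpm.reindex(a.index)
    if tpm.isna().any():
        raise ValueError("organ_tpm missing genes from the contrast universe")
    passes = (
        (a["log_fc"] <= thresholds.logfc_organ_vs_whole)
        & (a["p_adj"] <= thresholds.p_adj_max)
        & (tpm >= thresholds.min_tpm)
        & ((a["ave_expr"] > thresholds.min_ave_expr) if thresholds.ave_expr_strict
           else (a["ave_expr"] >= thresholds.min_ave_expr))
        & (b["log_fc"] >= thresholds.other_organ_logfc_min)
    )
    return set(a.index[passes])


def _jaccard(a: set, b: set) -> float:
    u = len(a | b)
    return len(a & b) / u if u else 0.0


def calibrate_thresholds(tau_calls: set[str],
                         organ_vs_whole: pd.DataFrame,
                         other_organ_vs_whole: pd.DataFrame,
                         organ_tpm: pd.Series,
                         organ: str,
                         logfc_grid: np.ndarray | list[float],
                         min_tpm_grid: np.ndarray | list[float] = (1.0, 5.0),
                         p_adj_max: float = 0.01,
                         other_organ_logfc_min: float = 1.0,
                         ave_expr_strict: bool = True) -> BiasThresholds:
    """Grid-search thresholds maximizing Jaccard overlap with the tau-based set.

    Ties are broken toward stricter thresholds (more negative organ log_fc
    cutoff, then larger minimum TPM).
    """
    if not tau_calls:
        raise ValueError("tau-based gene set is empty; cannot calibrate")
    best: tuple[float, float, float] | None = None  # (jaccard, -logfc, tpm)
    best_thr: BiasThresholds | None = None
    for lfc, tpm_min in itertools.product(logfc_grid, min_tpm_grid):
        thr = BiasThresholds(
            organ=organ, logfc_organ_vs_whole=float(lfc), p_adj_max=p_adj_max,
            min_tpm=float(tpm_min), min_ave_expr=0.0,
            ave_expr_strict=ave_expr_strict,
            other_organ_logfc_min=other_organ_logfc_min,
        )
        called = classify_tissue_bias(organ_vs_whole, other_organ_vs_whole,
                                      organ_tpm, thr)
        score = (_jaccard(tau_calls, called), -float(lfc), float(tpm_min))
        if best is None or score > best:
            best, best_thr = score, thr
    assert best_thr is not None
    return best_thr


def biased_in_either(per_species_sets: dict[str, set[str]],
                     omap_pairs: dict[str, list[str]] | None = None) -> set[str]:
    """Union rule for species comparisons: a gene (ortholog row) counts as
    tissue-biased if biased in either or both species.

    When ``omap_pairs`` maps species → ortholog-ordered gene lists, returns
    the set of ortholog row indices (as strings) biased in >=1 species;
    otherwise returns the plain union of the per-species gene-id sets.
    """
    if omap_pairs is None:
        out: set[str] = set()
        for s in per_species_sets.values():
            out |= s
        return out
    n = len(next(iter(omap_pairs.values())))
    rows: set[str] = set()
    for sp, genes in omap_pairs.items():
        biased = per_species_sets.get(sp, set())
        for i in range(n):
            if genes[i] in biased:
                rows.add(str(i))
    return rows
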