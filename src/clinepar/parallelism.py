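"""Ortholog-restricted cross-species parallelism statistics.

Given per-species latitudinal DE tables restricted to 1:1 (or 1:1:1)
orthologs that are expressed in every species of a comparison, this module
quantifies three forms of parallelism:

* an excess of *shared* DE genes over the independence expectation
  (E = N * prod(n_i / N), the hypergeometric mean), tested with a one-sided
  upper-tail binomial;
* concordant log-fold-change *direction* among shared DE genes, tested
  against the transcriptome-wide same-direction fraction; and
* rank correlation (Spearman's rho) of log fold changes across all expressed
  orthologs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import OrthologMap

__all__ = [
    "ParallelismReport",
    "restrict_to_orthologs",
    "shared_de_counts",
    "expected_shared",
    "shared_de_enrichment_test",
    "sign_concordance",
    "concordance_test",
    "logfc_correlation",
    "parallelism_report",
]

logger = logging.getLogger(__name__)


@dataclass
class ParallelismReport:
    """Shared-DE and directionality statistics for one species comparison × tissue."""

    species: list[str]
    tissue: str
    n_orthologs_expressed: int
    n_de_each: list[int]
    observed_shared: int
    expected_shared: float
    enrichment_p: float
    pct_higher_in_maine: float  # among same-direction shared-DE genes
    pct_same_direction_shared: float
    pct_same_direction_all: float
    concordance_p: float
    spearman_rho: float
    spearman_p: float

    def to_row(self) -> dict:
        d = {f"species_{i + 1}": s for i, s in enumerate(self.species)}
        d.update(
            tissue=self.tissue,
            n_orthologs_expressed=self.n_orthologs_expressed,
            observed_shared=self.observed_shared,
            expected_shared=self.expected_shared,
            enrichment_p=self.enrichment_p,
            pct_higher_in_maine=self.pct_higher_in_maine,
            pct_same_direction_shared=self.pct_same_direction_shared,
            pct_same_direction_all=self.pct_same_direction_all,
            concordance_p=self.concordance_p,
            spearman_rho=self.spearman_rho,
            spearman_p=self.spearman_p,
        )
        for i, n in enumerate(self.n_de_each):
            d[f"n_de_{i + 1}"] = n
        return d


def restrict_to_orthologs(tables: dict[str, pd.DataFrame],
                          omap: OrthologMap) -> pd.DataFrame:
    """Join per-species DE tables on an ortholog map.

    One row per ortholog whose genes are in every species' (expressed-gene)
    DE table; carries each species' ``log_fc``, ``p_adj`` and ``is_de`` with
    the species label as a column suffix.
    """
    for sp in omap.species_ids:
        if sp not in tables:
            raise ValueError(f"species {sp!r} in ortholog map has no DE table")
    keep = np.ones(len(omap), dtype=bool)
    cols: dict[str, list[str]] = {}
    indexed: dict[str, pd.DataFrame] = {}
    for sp in omap.species_ids:
        genes = omap.column(sp)
        t = tables[sp].set_index("gene_id")
        keep &= np.array([g in t.index for g in genes])
        cols[sp] = genes
        indexed[sp] = t
    idx = np.flatnonzero(keep)
    out = pd.DataFrame({"ortholog_row": idx})
    for sp in omap.species_ids:
        t = indexed[sp]
        sel = [cols[sp][i] for i in idx]
        sub = t.loc[sel]
        out[f"gene_{sp}"] = sel
        out[f"log_fc_{sp}"] = sub["log_fc"].to_numpy()
        out[f"p_adj_{sp}"] = sub["p_adj"].to_numpy()
        out[f"is_de_{sp}"] = sub["is_de"].to_numpy().astype(bool)
    out.attrs["species"] = list(omap.species_ids)
    return out


def _species_of(joined: pd.DataFrame) -> list[str]:
    sp = joined.attrs.get("species")
    if sp is None:
        sp = [c[len("is_de_"):] for c in joined.columns if c.startswith("is_de_")]
    return sp


def shared_de_counts(joined: pd.DataFrame) -> tuple[int, list[int], int]:
    """(k_obs, per-species DE counts among orthologs, N joined rows)."""
    if joined.shape[0] == 0:
        raise ValueError("joined ortholog table is empty")
    sp = _species_of(joined)
    de = np.column_stack([joined[f"is_de_{s}"].to_numpy() for s in sp])
    k_obs = int(de.all(axis=1).sum())
    n_each = [int(de[:, j].sum()) for j in range(de.shape[1])]
    return k_obs, n_each, int(joined.shape[0])


def expected_shared(n_de_each: list[int], N: int) -> float:
    """Independence expectation of the shared-DE count.

    Pairwise n1*n2/N; three-way n1*n2*n3/N² — the mean of the hypergeometric
    sharing null in which each species' DE labels are shuffled independently
    over the N expressed orthologs.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    for n in n_de_each:
        if not 0 <= n <= N:
            raise ValueError(f"DE count {n} outside [0, {N}]")
    e = float(N)
    for n in n_de_each:
        e *= n / N
    return e


def shared_de_enrichment_test(k_obs: int, n_de_each: list[int], N: int) -> float:
    """One-sided upper-tail binomial test of shared-DE excess.

    P(X >= k_obs) with X ~ Binomial(N, prod(n_i / N)).
    """
    if N <= 0 or k_obs < 0 or k_obs > N:
        raise ValueError("invalid counts")
    p_hat = 1.0
    for n in n_de_each:
        if not 0 <= n <= N:
            raise ValueError(f"DE count {n} outside [0, {N}]")
        p_hat *= n / N
    return float(stats.binom.sf(k_obs - 1, N, p_hat))


def sign_concordance(joined: pd.DataFrame, scope: str = "shared_de"
                     ) -> tuple[int, int, float, float]:
    """Direction concordance of log fold changes across the compared species.

    scope="shared_de" restricts to genes DE in every species; "all" uses all
    joined orthologs.  Same direction means all species' log_fc share one
    sign; exact zeros are ties and are excluded (with a warning).  Returns
    ``(k_same, n, pct_same, pct_higher_in_maine)`` where the last is the
    fraction of same-direction genes whose common sign is positive — higher
    in the high-latitude (Maine-role) population under the convention that
    log_fc is low-latitude minus high-latitude... i.e. negative log_fc; see
    note below.
    """
    sp = _species_of(joined)
    sub = joined
    if scope == "shared_de":
        mask = np.ones(len(joined), dtype=bool)
        for s in sp:
            mask &= joined[f"is_de_{s}"].to_numpy()
        sub = joined.loc[mask]
        if sub.shape[0] == 0:
            raise ValueError("no shared DE genes; concordance undefined")
    elif scope != "all":
        raise ValueError(f"unknown scope {scope!r}")
    lfc = np.column_stack([sub[f"log_fc_{s}"].to_numpy() for s in sp])
    ties = (lfc == 0).any(axis=1)
    if ties.any():
        warnings.warn(f"excluding {int(ties.sum())} zero-log_fc ties from "
                      "direction concordance", stacklevel=2)
        lfc = lfc[~ties]
    n = lfc.shape[0]
    signs = np.sign(lfc)
    same = (signs == signs[:, [0]]).all(axis=1)
    k_same = int(same.sum())
    pct_same = 100.0 * k_same / n if n else float("nan")
    # log_fc < 0 means lower in the low-latitude population, i.e. higher in
    # the Maine-role (high-latitude) population.
    if k_same:
        higher_maine = (signs[same, 0] < 0).sum()
        pct_maine = 100.0 * float(higher_maine) / k_same
    else:
        pct_maine = float("nan")
    return k_same, n, pct_same, pct_maine


def concordance_test(k_same: int, n: int, p0: float) -> float:
    """One-sided upper-tail binomial test: P(X >= k_same), X ~ Bin(n, p0)."""
    if not (0 <= k_same <= n):
        raise ValueError(f"k_same={k_same} outside [0, {n}]")
    if not (0 < p0 < 1):
        raise ValueError(f"null proportion must be in (0,1), got {p0}")
    return float(stats.binom.sf(k_same - 1, n, p0))


def logfc_correlation(joined: pd.DataFrame,
                      species_pair: tuple[str, str] | None = None
                      ) -> tuple[float, float]:
    """Spearman's rho (average ranks for ties; t-approximation p) between two
    species' log fold changes across all expressed orthologs."""
    sp = _species_of(joined)
    if species_pair is None:
        if len(sp) != 2:
            raise ValueError("specify species_pair for a three-way table")
        species_pair = (sp[0], sp[1])
    x = joined[f"log_fc_{species_pair[0]}"].to_numpy()
    y = joined[f"log_fc_{species_pair[1]}"].to_numpy()
    if x.size < 3:
        raise ValueError("need >=3 orthologs for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant log_fc vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def parallelism_report(tables: dict[str, pd.DataFrame], omap: OrthologMap,
                       tissue: str = "") -> ParallelismReport:
    """Full parallelism summary for one species pair/triple in one tissue."""
    joined = restrict_to_orthologs(tables, omap)
    k_obs, n_each, N = shared_de_counts(joined)
    E = expected_shared(n_each, N)
    p_enr = shared_de_enrichment_test(k_obs, n_each, N)
    _, n_all, pct_all, _ = sign_concordance(joined, scope="all")
    if k_obs > 0:
        k_same, n_sh, pct_sh, pct_maine = sign_concordance(joined, "shared_de")
        p_conc = concordance_test(k_same, n_sh, pct_all / 100.0) \
            if 0 < pct_all < 100 else float("nan")
    else:
        pct_sh = pct_maine = p_conc = float("nan")
    sp = _species_of(joined)
    if len(sp) == 2:
        rho, p_rho = logfc_correlation(joined)
    else:
        rho = p_rho = float("nan")
    logger.info("parallelism %s/%s: N=%d k_obs=%d E=%.2f p=%.3g",
                "-".join(sp), tissue, N, k_obs, E, p_enr)
    return ParallelismReport(
        species=sp, tissue=tissue, n_orthologs_expressed=N,
        n_de_each=n_each, observed_shared=k_obs, expected_shared=E,
        enrichment_p=p_enr, pct_higher_in_maine=pct_maine,
        pct_same_direction_shared=pct_sh, pct_same_direction_all=pct_all,
        concordance_p=p_conc, spearman_rho=rho, spearman_p=p_rho,
    )
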