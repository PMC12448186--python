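"""Latitudinal differential expression: TPM, expression filtering, and an
empirical-Bayes moderated-t engine with Benjamini–Hochberg adjustment.

The moderated t follows the standard construction: per-gene pooled residual
variances on log2-CPM are shrunk toward a scaled inverse-chi-square prior
fitted by method of moments, and the resulting statistic is referred to a t
distribution with ``d0 + d_g`` degrees of freedom (normal in the
``d0 = +inf`` limit).  No precision weights and no mean–variance trend are
applied — a deliberate simplification for the small-replicate design this
package targets (see docs/methods.md).

Sign convention: ``log_fc = mean log2-CPM (low-latitude) − (high-latitude)``,
so negative log-fold-changes mean lower expression in the low-latitude
("Panama"-role) population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import CountsDataset, SampleInfo, TpmMatrix

__all__ = [
    "EBHyperparams",
    "compute_tpm",
    "median_population_tpm",
    "filter_expressed",
    "log_cpm",
    "estimate_eb_hyperparams",
    "moderated_t_test",
    "adjust_bh",
    "call_de",
    "de_pipeline",
    "percent_de",
    "DE_TABLE_COLUMNS",
]

DE_TABLE_COLUMNS = [
    "gene_id", "log_fc", "ave_expr", "t_mod", "df_total",
    "p_raw", "p_adj", "is_de", "species", "tissue",
]


@dataclass(frozen=True)
class EBHyperparams:
    """Prior df and prior variance of the scaled inverse-chi-square variance prior."""

    d0: float  # prior degrees of freedom; 0 = no shrinkage, may be +inf
    s0_sq: float  # prior variance

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError(f"d0 must be non-negative, got {self.d0}")
        if not (self.s0_sq > 0):
            raise ValueError(f"s0_sq must be positive, got {self.s0_sq}")


def compute_tpm(ds: CountsDataset) -> TpmMatrix:
    """Transcripts per million from counts and gene lengths.

    tpm[g, s] = 1e6 * (count[g, s] / length_kb[g]) / sum_g'(count[g', s] / length_kb[g']);
    an all-zero sample column stays all-zero.
    """
    length_kb = ds.lengths / 1e3
    rate = ds.counts / length_kb[:, None]
    denom = rate.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = np.where(denom > 0, rate / denom * 1e6, 0.0)
    return TpmMatrix(genes=list(ds.genes), samples=list(ds.samples), tpm=tpm)


def median_population_tpm(tpm: TpmMatrix, species: str, tissue: str,
                          populations: list[str] | None = None) -> pd.DataFrame:
    """Per-gene median TPM across each population's replicate columns.

    Returns a gene × population DataFrame restricted to one species × tissue.
    """
    cols = [
        (j, s) for j, s in enumerate(tpm.samples)
        if s.species == species and s.tissue == tissue
    ]
    present = sorted({s.population for _, s in cols})
    if populations is None:
        populations = present
    out = {}
    for pop in populations:
        idx = [j for j, s in cols if s.population == pop]
        if not idx:
            raise ValueError(
                f"population {pop!r} absent for species={species!r} "
                f"tissue={tissue!r} (present: {present})"
            )
        out[pop] = np.median(tpm.tpm[:, idx], axis=1)
    return pd.DataFrame(out, index=tpm.genes)


def filter_expressed(medians: pd.DataFrame, threshold: float = 1.0) -> set[str]:
    """Genes with median TPM strictly above ``threshold`` in at least one of
    the two focal populations."""
    if medians.shape[1] != 2:
        raise ValueError(
            f"expected exactly two focal populations, got {list(medians.columns)}"
        )
    mask = (medians > threshold).any(axis=1)
    return set(medians.index[mask])


def log_cpm(ds: CountsDataset, prior_count: float = 0.5) -> np.ndarray:
    """log2 counts-per-million with a stabilizing prior count.

    log2( (count + prior) / (library_size + 2*prior) * 1e6 )
    """
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    lib = ds.counts.sum(axis=0).astype(float)
    return np.log2((ds.counts + prior_count) / (lib + 2 * prior_count) * 1e6)


def _trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 80) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    trigamma is strictly decreasing; ~1/y for large y and ~1/y^2 near 0.
    """
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    y = 0.5 + 1.0 / x  # good starting value across scales
    for _ in range(max_iter):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if y <= 0:
            y = 1e-8
        if abs(dif) < tol * y:
            break
    return y


def estimate_eb_hyperparams(s_sq: np.ndarray, d_g: float) -> EBHyperparams:
    """Method-of-moments fit of a scaled inverse-chi-square prior to
    per-gene residual variances with common residual df ``d_g``.

    Uses the log-variance moments: with z = log(s²),
    var(z) − trigamma(d_g/2) estimates trigamma(d0/2), and the mean of z,
    corrected by the digamma/log terms of both chi-square factors, gives
    log(s0²).  When the excess spread is ≤ 0 the prior is degenerate:
    d0 = +inf and s0² is the (geometric-mean-based) common variance.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    pos = s_sq[s_sq > 0]
    if pos.size < 10:
        raise ValueError(f"need >=10 positive variances, got {pos.size}")
    z = np.log(pos)
    if np.ptp(z) == 0:  # all variances identical: degenerate point-mass prior
        return EBHyperparams(d0=math.inf, s0_sq=float(pos[0]))
    e = z - float(special.digamma(d_g / 2.0)) + math.log(d_g / 2.0)
    evar = float(np.var(z, ddof=1)) - float(special.polygamma(1, d_g / 2.0))
    if evar <= 0:
        return EBHyperparams(d0=math.inf, s0_sq=float(np.exp(np.mean(e))))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(
        np.mean(e) + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
    ))
    return EBHyperparams(d0=d0, s0_sq=s0_sq)


def moderated_t_test(logcpm: np.ndarray, groups: np.ndarray,
                     eb: EBHyperparams | None = None,
                     genes: list[str] | None = None,
                     species: str = "", tissue: str = "") -> pd.DataFrame:
    """Two-group moderated t-test on a log2-CPM matrix.

    ``groups`` is a boolean/0-1 vector over columns: 1 marks the low-latitude
    group (log_fc = mean(low) − mean(high)).  If ``eb`` is None the prior is
    estimated from the data.  ``eb.d0 = 0`` is accepted as the no-shrinkage
    limit and reproduces the ordinary pooled two-sample t.
    """
    logcpm = np.asarray(logcpm, dtype=float)
    g = np.asarray(groups).astype(bool)
    n1 = int(g.sum())        # low-latitude group
    n2 = int((~g).sum())     # high-latitude group
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >=2 samples, got {n1} and {n2}")
    m1 = logcpm[:, g].mean(axis=1)
    m2 = logcpm[:, ~g].mean(axis=1)
    log_fc = m1 - m2
    ave_expr = logcpm.mean(axis=1)
    d_g = n1 + n2 - 2
    ss1 = ((logcpm[:, g] - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((logcpm[:, ~g] - m2[:, None]) ** 2).sum(axis=1)
    s_sq = (ss1 + ss2) / d_g

    if eb is None:
        eb = estimate_eb_hyperparams(s_sq, d_g)

    if eb.d0 == 0:  # no-shrinkage limit: ordinary pooled t
        s_post = s_sq
        df_total = float(d_g)
    elif math.isinf(eb.d0):
        s_post = np.full_like(s_sq, eb.s0_sq)
        df_total = math.inf
    else:
        s_post = (eb.d0 * eb.s0_sq + d_g * s_sq) / (eb.d0 + d_g)
        df_total = eb.d0 + d_g

    se = np.sqrt(s_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log_fc / se, 0.0)
    if math.isinf(df_total):
        p_raw = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p_raw = np.clip(p_raw, np.nextafter(0.0, 1.0), 1.0)

    if genes is None:
        genes = [f"g{i}" for i in range(logcpm.shape[0])]
    return pd.DataFrame({
        "gene_id": genes,
        "log_fc": log_fc,
        "ave_expr": ave_expr,
        "t_mod": t_mod,
        "df_total": df_total,
        "p_raw": p_raw,
        "species": species,
        "tissue": tissue,
    })


def adjust_bh(p_raw: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def call_de(table: pd.DataFrame, alpha: float = 0.1) -> pd.DataFrame:
    """Attach BH-adjusted p-values (if absent) and the DE flag at ``alpha``."""
    out = table.copy()
    if "p_adj" not in out.columns:
        out["p_adj"] = adjust_bh(out["p_raw"].to_numpy())
    out["is_de"] = out["p_adj"] <= alpha
    return out


def percent_de(n_de: int, n_expressed: int) -> float:
    """Percent DE among expressed genes, to one decimal (presentation layer)."""
    if n_expressed <= 0:
        raise ValueError("n_expressed must be positive")
    return round(100.0 * n_de / n_expressed, 1)


def de_pipeline(ds: CountsDataset, species: str, tissue: str,
                low_population: str, high_population: str,
                alpha: float = 0.1, tpm_threshold: float = 1.0,
                prior_count: float = 0.5) -> pd.DataFrame:
    """Full latitudinal DE call for one species × tissue.

    Filters to genes with median TPM > ``tpm_threshold`` in at least one
    focal population, then runs the moderated t on log2-CPM and flags DE at
    BH-adjusted p ≤ ``alpha``.
    """
    sub = ds.select(species=species, tissue=tissue,
                    populations=[low_population, high_population])
    tpm = compute_tpm(sub)
    med = median_population_tpm(tpm, species, tissue,
                                [low_population, high_population])
    expressed = filter_expressed(med, tpm_threshold)
    keep = [g in expressed for g in sub.genes]
    if sum(keep) < 10:
        raise ValueError(
            f"only {sum(keep)} expressed genes for {species}/{tissue}; "
            "cannot fit the variance prior"
        )
    sub_expr = CountsDataset(
        genes=[g for g, k in zip(sub.genes, keep) if k],
        lengths=sub.lengths[np.asarray(keep)],
        samples=list(sub.samples),
        counts=sub.counts[np.asarray(keep), :],
    )
    lc = log_cpm(sub_expr, prior_count=prior_count)
    groups = np.array([s.population == low_population for s in sub_expr.samples])
    tbl = moderated_t_test(lc, groups, genes=sub_expr.genes,
                           species=species, tissue=tissue)
    return call_de(tbl, alpha=alpha)[DE_TABLE_COLUMNS]
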