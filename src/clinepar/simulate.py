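"""Synthetic multi-species count data with planted latitudinal effects.

Emulates the structure of a three-species, two-population, two-tissue bulk
RNA-seq study of clinal expression differentiation: for each species,
negative-binomial read counts for replicate pools of a high-latitude
("Maine"-role) and low-latitude ("Panama"-role) population in each tissue,
plus two outgroup populations for rooting expression branch lengths.

True latitudinal log2 effects (low minus high latitude) are drawn per tissue
from an equicorrelated multivariate normal across species over the 1:1(:1)
orthologs, so ``cross_species_corr`` is the Pearson correlation of true
effects between any two species.  A ``de_direction_bias`` above 0.5 shifts
the effect distribution's mean so that the stated fraction of effects is
negative (lower expression in the low-latitude population) without altering
the cross-species correlation.  A ``shared_outlier_fraction`` of orthologs
instead receives a large common-sign effect in every species (the
shared-outlier mode of parallelism).  Non-orthologous genes get independent
effects.

Counts: gene g in sample s is NB(mean mu, size r) with variance
mu + mu^2/r, where mu = library_size * w_g and w_g is the gene's
length-weighted share of expressed transcripts; r (= ``1/dispersion`` in the
common parameterization; here given directly as the size) is constant across
genes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (CountsDataset, GeneSet, OrthologMap, SampleInfo,
                 write_counts, write_gene_set, write_ortholog_map)

__all__ = ["SimConfig", "SimResult", "simulate_dataset", "emit_fixture"]

# fixed offsets for per-purpose RNG streams derived from the master seed
_SHARED_STREAM = 10_000
_SPECIES_STREAM_BASE = 20_000


@dataclass
class SimConfig:
    """Generator parameters; defaults emulate a desk-scale version of the
    three-species latitudinal design (3 replicate pools per population ×
    tissue, ~8000 genes of which ~80% are 1:1 orthologs)."""

    n_genes: int = 8000
    species_list: tuple[str, ...] = ("melanogaster", "simulans", "hydei")
    tissues: tuple[str, ...] = ("AG", "testis")
    n_replicates: int = 3
    focal_populations: tuple[str, str] = ("Maine", "Panama")  # (high, low) latitude
    outgroup_populations: tuple[str, str] = ("Madagascar", "Zimbabwe")
    baseline_log_mean_range: tuple[float, float] = (1.0, 9.0)  # log2 abundance
    dispersion: float = 100.0  # NB size r; variance = mu + mu^2/r (overdispersion 1/r)
    effect_sd: float = 0.25  # SD of latitudinal log2 effects
    cross_species_corr: float = 0.46
    shared_outlier_fraction: float = 0.02
    outlier_effect: float = 2.0
    de_direction_bias: float = 0.5  # P(effect < 0), i.e. lower in low-latitude pop
    class_enrichment: dict = field(default_factory=lambda: {"Sfp": 3.0})
    class_base_rate: float = 0.03
    ortholog_coverage: float = 0.8
    outgroup_drift_sd: float = 0.5
    library_size_range: tuple[int, int] = (5_000_000, 10_000_000)
    gene_length_range: tuple[int, int] = (500, 5000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ValueError("n_genes and n_replicates must be positive")
        if not 2 <= len(self.species_list) <= 3:
            raise ValueError("species_list must have 2 or 3 labels")
        if not (0 <= self.shared_outlier_fraction <= 1):
            raise ValueError("shared_outlier_fraction must be in [0,1]")
        if not (0 <= self.de_direction_bias <= 1):
            raise ValueError("de_direction_bias must be in [0,1]")
        if not (0 < self.ortholog_coverage <= 1):
            raise ValueError("ortholog_coverage must be in (0,1]")
        if not (-1 <= self.cross_species_corr <= 1):
            raise ValueError("cross_species_corr must be in [-1,1]")
        k = len(self.species_list)
        if k > 2 and self.cross_species_corr < -1.0 / (k - 1):
            raise ValueError(
                f"cross_species_corr={self.cross_species_corr} gives a "
                f"non-positive-semidefinite correlation matrix for {k} species "
                f"(needs >= {-1.0 / (k - 1):.3f})"
            )
        if self.effect_sd < 0 or self.outgroup_drift_sd < 0 or self.dispersion <= 0:
            raise ValueError("effect_sd/outgroup_drift_sd must be >=0, dispersion >0")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid library_size_range")


@dataclass
class SimResult:
    """Datasets plus ground truth from one simulator run."""

    datasets: dict[str, CountsDataset]  # per species
    ortholog_map: OrthologMap  # all-species map (2- or 3-way)
    gene_sets: list[GeneSet]
    truth: pd.DataFrame  # species, tissue, gene_id, true_log2_effect, ...

    def pairwise_map(self, sp_a: str, sp_b: str) -> OrthologMap:
        return self.ortholog_map.restrict([sp_a, sp_b])


def _effect_matrix(n: int, k: int, corr: float, sd: float, bias: float,
                   rng: np.random.Generator) -> np.ndarray:
    """n x k true effects: equicorrelated MVN with P(effect < 0) = bias."""
    if sd == 0:
        return np.zeros((n, k))
    C = np.full((k, k), corr)
    np.fill_diagonal(C, 1.0)
    # tiny jitter guards the Cholesky at the PSD boundary (corr = ±1)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(k))
    z = rng.standard_normal((n, k)) @ L.T
    from scipy.stats import norm
    shift = -sd * norm.ppf(bias) if 0 < bias < 1 else 0.0
    return shift + sd * z


def simulate_dataset(config: SimConfig) -> SimResult:
    """Generate per-species count datasets, ortholog map, gene-class sets and
    a ground-truth table.  Deterministic given ``config.seed``.
    """
    cfg = config
    k = len(cfg.species_list)
    n_orth = int(round(cfg.ortholog_coverage * cfg.n_genes))
    n_priv = cfg.n_genes - n_orth

    shared = np.random.default_rng([cfg.seed, _SHARED_STREAM])
    sp_rngs = {
        sp: np.random.default_rng([cfg.seed, _SPECIES_STREAM_BASE + i])
        for i, sp in enumerate(cfg.species_list)
    }

    # shared (ortholog-row) quantities
    lo_b, hi_b = cfg.baseline_log_mean_range
    orth_baseline = {
        t: shared.uniform(lo_b, hi_b, n_orth) for t in cfg.tissues
    }
    lo_l, hi_l = cfg.gene_length_range
    orth_lengths = shared.integers(lo_l, hi_l + 1, n_orth)

    orth_effects = {}  # tissue -> (n_orth, k)
    outlier_rows = {}
    for t in cfg.tissues:
        eff = _effect_matrix(n_orth, k, cfg.cross_species_corr,
                             cfg.effect_sd, cfg.de_direction_bias, shared)
        n_out = int(round(cfg.shared_outlier_fraction * n_orth))
        rows = shared.choice(n_orth, size=n_out, replace=False) if n_out else \
            np.empty(0, dtype=int)
        if n_out:
            signs = np.where(shared.random(n_out) < cfg.de_direction_bias, -1.0, 1.0)
            eff[rows, :] = (signs * cfg.outlier_effect)[:, None]
        orth_effects[t] = eff
        outlier_rows[t] = set(int(r) for r in rows)

    datasets: dict[str, CountsDataset] = {}
    truth_rows: list[dict] = []
    gene_sets: list[GeneSet] = []
    map_rows = [tuple(f"{sp}_g{r:05d}" for sp in cfg.species_list)
                for r in range(n_orth)]

    for si, sp in enumerate(cfg.species_list):
        rng = sp_rngs[sp]
        genes = [f"{sp}_g{r:05d}" for r in range(n_orth)] + \
                [f"{sp}_p{i:05d}" for i in range(n_priv)]
        lengths = np.concatenate([
            orth_lengths.astype(float),
            rng.integers(lo_l, hi_l + 1, n_priv).astype(float),
        ])
        priv_baseline = {t: rng.uniform(lo_b, hi_b, n_priv) for t in cfg.tissues}
        priv_effects = {
            t: _effect_matrix(n_priv, 1, 0.0, cfg.effect_sd,
                              cfg.de_direction_bias, rng)[:, 0]
            for t in cfg.tissues
        }

        samples: list[SampleInfo] = []
        cols: list[np.ndarray] = []
        hi_pop, lo_pop = cfg.focal_populations
        for t in cfg.tissues:
            baseline = np.concatenate([orth_baseline[t], priv_baseline[t]])
            effect = np.concatenate([orth_effects[t][:, si], priv_effects[t]])
            pop_logmean = {hi_pop: baseline, lo_pop: baseline + effect}
            for o in cfg.outgroup_populations:
                drift = rng.normal(0.0, cfg.outgroup_drift_sd, cfg.n_genes)
                pop_logmean[o] = baseline + drift
            for pop in (hi_pop, lo_pop) + tuple(cfg.outgroup_populations):
                q = 2.0 ** pop_logmean[pop]
                w = q * lengths
                w = w / w.sum()
                for rep in range(1, cfg.n_replicates + 1):
                    lib = int(rng.integers(cfg.library_size_range[0],
                                           cfg.library_size_range[1] + 1))
                    mu = lib * w
                    r = cfg.dispersion
                    counts = rng.negative_binomial(r, r / (r + mu))
                    samples.append(SampleInfo(
                        sample_id=f"{sp}_{t}_{pop}_r{rep}",
                        species=sp, population=pop, tissue=t, replicate=rep,
                    ))
                    cols.append(counts)

            for gi, g in enumerate(genes):
                truth_rows.append({
                    "species": sp, "tissue": t, "gene_id": g,
                    "true_log2_effect": float(effect[gi]),
                    "ortholog_row": gi if gi < n_orth else -1,
                    "is_outlier": gi < n_orth and gi in outlier_rows[t],
                })

        counts = np.column_stack(cols).astype(np.int64)
        datasets[sp] = CountsDataset(genes=genes, lengths=lengths,
                                     samples=samples, counts=counts)

        # gene-class memberships, enriched among strongly affected genes
        max_eff = np.zeros(cfg.n_genes)
        any_outlier = np.zeros(cfg.n_genes, dtype=bool)
        for t in cfg.tissues:
            eff = np.concatenate([orth_effects[t][:, si], priv_effects[t]])
            max_eff = np.maximum(max_eff, np.abs(eff))
            for r in outlier_rows[t]:
                any_outlier[r] = True
        affect_thr = max(2.0 * cfg.effect_sd, 0.5)
        affected = any_outlier | (max_eff > affect_thr)
        for label, rr in cfg.class_enrichment.items():
            p = np.where(affected,
                         np.clip(cfg.class_base_rate * rr, 0.0, 0.95),
                         cfg.class_base_rate)
            member = rng.random(cfg.n_genes) < p
            if member.any():
                gene_sets.append(GeneSet(
                    label=label,
                    members={g for g, m in zip(genes, member) if m},
                    species=sp,
                ))

    truth = pd.DataFrame(truth_rows)
    # annotate class memberships onto the truth table
    classes_by_gene: dict[str, list[str]] = {}
    for gs in gene_sets:
        for g in gs.members:
            classes_by_gene.setdefault(g, []).append(gs.label)
    truth["classes"] = [",".join(sorted(classes_by_gene.get(g, [])))
                        for g in truth["gene_id"]]

    omap = OrthologMap(species_ids=list(cfg.species_list), rows=map_rows)
    return SimResult(datasets=datasets, ortholog_map=omap,
                     gene_sets=gene_sets, truth=truth)


def emit_fixture(config: SimConfig, out_dir: str | Path) -> dict[str, str]:
    """Run the simulator and write every TSV the pipeline readers consume.

    Returns a manifest mapping logical names to file paths; also writes the
    manifest itself, the config (YAML) and the ground-truth table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = simulate_dataset(config)
    manifest: dict[str, str] = {}

    for sp, ds in res.datasets.items():
        paths = {
            f"counts_{sp}": out / f"counts_{sp}.tsv",
            f"metadata_{sp}": out / f"metadata_{sp}.tsv",
            f"lengths_{sp}": out / f"lengths_{sp}.tsv",
        }
        write_counts(ds, paths[f"counts_{sp}"], paths[f"metadata_{sp}"],
                     paths[f"lengths_{sp}"])
        manifest.update({k: str(v) for k, v in paths.items()})

    species = list(config.species_list)
    if len(species) == 3:
        p = out / "orthologs_3way.tsv"
        write_ortholog_map(res.ortholog_map, p)
        manifest["orthologs_3way"] = str(p)
    for i in range(len(species)):
        for j in range(i + 1, len(species)):
            a, b = species[i], species[j]
            p = out / f"orthologs_{a}_{b}.tsv"
            write_ortholog_map(res.ortholog_map.restrict([a, b]), p)
            manifest[f"orthologs_{a}_{b}"] = str(p)

    for gs in res.gene_sets:
        p = out / f"geneset_{gs.label}_{gs.species}.tsv"
        write_gene_set(gs, p)
        manifest[f"geneset_{gs.label}_{gs.species}"] = str(p)

    truth_path = out / "truth.tsv"
    res.truth.to_csv(truth_path, sep="\t", index=False, float_format="%.6g")
    manifest["truth"] = str(truth_path)

    cfg_path = out / "sim_config.yaml"
    cfg = asdict(config)
    for key in ("species_list", "tissues", "focal_populations",
                "outgroup_populations", "baseline_log_mean_range",
                "library_size_range", "gene_length_range"):
        cfg[key] = list(cfg[key])
    cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    manifest["config"] = str(cfg_path)

    man_path = out / "manifest.yaml"
    man_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    manifest["manifest"] = str(man_path)
    return manifest


def fixture_digest(out_dir: str | Path) -> dict[str, str]:
    """SHA-256 of every TSV in a fixture directory (determinism checks)."""
    out = Path(out_dir)
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.glob("*.tsv"))
    }
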