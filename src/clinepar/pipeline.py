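"""End-to-end orchestration: run the full latitudinal-parallelism analysis on
a dataset directory and emit the five report tables.

Report tables mirror the structure of a comparative clinal-expression study:

* table1 — DE counts and percent DE per species × tissue;
* table2 — shared-DE parallelism statistics per species comparison × tissue;
* table3 — lineage-specific expression divergence (LED) contrasts;
* table4 — gene-class × DE enrichment (Fisher's exact);
* table5 — gene-class × logFC-direction tables.

Percentages are rounded to one decimal and p-values to three significant
figures in the formatted tables; full-precision companions are written
alongside (suffix ``_full``).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import de as de_mod
from . import enrichment, led, parallelism
from .io import read_counts, read_gene_set, read_ortholog_map

__all__ = ["PipelineConfig", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Analysis constants plus the focal/outgroup population labels."""

    species: list[str] = field(default_factory=lambda: [
        "melanogaster", "simulans", "hydei"])
    tissues: list[str] = field(default_factory=lambda: ["AG", "testis"])
    high_latitude: str = "Maine"
    low_latitude: str = "Panama"
    outgroups: list[str] = field(default_factory=lambda: ["Madagascar", "Zimbabwe"])
    led_species: str | None = None  # default: first species with outgroup samples
    alpha_de: float = 0.1
    alpha_bias: float = 0.01
    tpm_threshold: float = 1.0
    tau_cutoff: float = 0.9
    gene_class_label: str = "Sfp"

    def __post_init__(self) -> None:
        if not (0 < self.alpha_de < 1) or not (0 < self.alpha_bias < 1):
            raise ValueError("alpha thresholds must be in (0,1)")
        if self.tpm_threshold < 0 or not (0 <= self.tau_cutoff <= 1):
            raise ValueError("tpm_threshold must be >=0 and tau_cutoff in [0,1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _fmt_p(p: float) -> str:
    return "NA" if pd.isna(p) else f"{p:.2E}"


def run_all(config: PipelineConfig, data_dir: str | Path,
            out_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Run DE, parallelism, LED and enrichment on a fixture-style directory.

    ``data_dir`` must contain ``counts_<sp>.tsv``, ``metadata_<sp>.tsv`` and
    ``lengths_<sp>.tsv`` per species, ortholog maps
    (``orthologs_<a>_<b>.tsv``, optionally ``orthologs_3way.tsv``) and
    optional gene sets ``geneset_<label>_<sp>.tsv``.  Deterministic given the
    same inputs and config.
    """
    data = Path(data_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config
    logger.info("pipeline config: alpha_de=%g tpm_threshold=%g focal=%s/%s",
                cfg.alpha_de, cfg.tpm_threshold, cfg.high_latitude,
                cfg.low_latitude)

    datasets = {}
    for sp in cfg.species:
        try:
            datasets[sp] = read_counts(
                data / f"counts_{sp}.tsv", data / f"metadata_{sp}.tsv",
                data / f"lengths_{sp}.tsv",
            )
        except FileNotFoundError as e:
            raise FileNotFoundError(f"stage read_counts[{sp}]: {e}") from e
        logger.info("read %s: %d genes x %d samples", sp,
                    datasets[sp].n_genes, datasets[sp].n_samples)

    # --- stage 1: differential expression per species x tissue -------------
    de_tables: dict[tuple[str, str], pd.DataFrame] = {}
    t1_rows = []
    for sp, t in itertools.product(cfg.species, cfg.tissues):
        tbl = de_mod.de_pipeline(
            datasets[sp], sp, t, low_population=cfg.low_latitude,
            high_population=cfg.high_latitude, alpha=cfg.alpha_de,
            tpm_threshold=cfg.tpm_threshold,
        )
        de_tables[(sp, t)] = tbl
        n_de, n_expr = int(tbl["is_de"].sum()), len(tbl)
        t1_rows.append({
            "species": sp, "tissue": t, "total_de_genes": n_de,
            "expressed_genes": n_expr,
            "percent_de": de_mod.percent_de(n_de, n_expr),
        })
        tbl.to_csv(out / f"de_{sp}_{t}.tsv", sep="\t", index=False,
                   float_format="%.6g")
        logger.info("de[%s/%s]: %d DE of %d expressed", sp, t, n_de, n_expr)
    table1 = pd.DataFrame(t1_rows)

    # --- stage 2: cross-species parallelism --------------------------------
    maps = {}
    for a, b in itertools.combinations(cfg.species, 2):
        p = data / f"orthologs_{a}_{b}.tsv"
        if p.exists():
            maps[(a, b)] = read_ortholog_map(p, 2)
    three = data / "orthologs_3way.tsv"
    omap3 = read_ortholog_map(three, 3) if three.exists() else None

    t2_rows = []
    for t in cfg.tissues:
        for (a, b), omap in maps.items():
            rep = parallelism.parallelism_report(
                {a: de_tables[(a, t)], b: de_tables[(b, t)]}, omap, tissue=t)
            t2_rows.append(rep.to_row())
        if omap3 is not None:
            rep = parallelism.parallelism_report(
                {sp: de_tables[(sp, t)] for sp in omap3.species_ids},
                omap3, tissue=t)
            t2_rows.append(rep.to_row())
    table2 = pd.DataFrame(t2_rows)

    # --- stage 3: lineage-specific expression divergence --------------------
    led_sp = cfg.led_species
    if led_sp is None:
        for sp in cfg.species:
            pops = {s.population for s in datasets[sp].samples}
            if set(cfg.outgroups) <= pops:
                led_sp = sp
                break
    t3_rows = []
    if led_sp is not None:
        for t in cfg.tissues:
            tpm = de_mod.compute_tpm(datasets[led_sp].select(tissue=t))
            med = de_mod.median_population_tpm(tpm, led_sp, t)
            prof = led.QuartetProfile.from_medians(
                med, cfg.high_latitude, cfg.low_latitude,
                cfg.outgroups[0], cfg.outgroups[1])
            ltab = led.led_table(prof, cfg.high_latitude, cfg.low_latitude)
            ltab = ltab.set_index("gene_id")
            expressed = de_tables[(led_sp, t)].set_index("gene_id")
            ltab = ltab.loc[ltab.index.intersection(expressed.index)]
            bm = ltab[f"b_{cfg.high_latitude}"].to_numpy()
            bp = ltab[f"b_{cfg.low_latitude}"].to_numpy()
            s = led.led_summary(bm, bp, cfg.high_latitude, cfg.low_latitude)
            t3_rows.append({"species": led_sp, "comparison": f"All {t}",
                            "population": cfg.high_latitude,
                            "led": s["mean_a"], "t_test_p": s["p"]})
            t3_rows.append({"species": led_sp, "comparison": f"All {t}",
                            "population": cfg.low_latitude,
                            "led": s["mean_b"], "t_test_p": float("nan")})
            is_de = expressed.loc[ltab.index, "is_de"].to_numpy().astype(bool)
            if 2 <= is_de.sum() and 2 <= (~is_de).sum():
                for pop, vec in ((cfg.high_latitude, bm), (cfg.low_latitude, bp)):
                    s = led.led_summary(vec[is_de], vec[~is_de],
                                        f"{t} DE", f"{t} not DE")
                    t3_rows.append({
                        "species": led_sp, "comparison": f"{t} DE",
                        "population": pop, "led": s["mean_a"],
                        "t_test_p": s["p"]})
                    t3_rows.append({
                        "species": led_sp, "comparison": f"{t} not DE",
                        "population": pop, "led": s["mean_b"],
                        "t_test_p": float("nan")})
    table3 = pd.DataFrame(t3_rows)

    # --- stages 4-5: gene-class enrichment ----------------------------------
    t4_rows, t5_rows = [], []
    label = cfg.gene_class_label
    for sp, t in itertools.product(cfg.species, cfg.tissues):
        gs_path = data / f"geneset_{label}_{sp}.tsv"
        if not gs_path.exists():
            continue
        gs = read_gene_set(gs_path, label, species=sp)
        tbl = de_tables[(sp, t)]
        expressed_members = len(set(tbl["gene_id"]) & gs.members)
        if expressed_members == 0:
            logger.warning("enrich[%s/%s]: no expressed %s genes", sp, t, label)
            continue
        ct = enrichment.build_de_table(tbl, gs)
        _, p = enrichment.fisher_exact(ct)
        pct_in, pct_out, fold = enrichment.enrichment_summary(ct)
        t4_rows.append({
            "species": sp, "tissue": t, f"expressed_{label}": ct.a + ct.c,
            f"{label}_de": ct.a, f"not_{label}_de": ct.b,
            f"{label}_not_de": ct.c, f"not_{label}_not_de": ct.d,
            "total": ct.total, f"{label}_de_pct": pct_in,
            f"{label}_not_de_pct": pct_out, "fold": round(fold, 1),
            "fisher_p": p,
        })
        dt = enrichment.build_direction_table(tbl, gs)
        _, p5 = enrichment.fisher_exact(dt)
        n_class = dt.a + dt.c
        pct_neg = round(100.0 * dt.c / n_class, 1) if n_class else float("nan")
        t5_rows.append({
            "species": sp, "tissue": t, f"{label}_expressed": n_class,
            f"{label}_pos_logfc": dt.a, f"not_{label}_pos_logfc": dt.b,
            f"{label}_neg_logfc": dt.c, f"not_{label}_neg_logfc": dt.d,
            "total": dt.total, f"pct_{label}_neg_logfc": pct_neg,
            "fisher_p": p5,
        })
    table4 = pd.DataFrame(t4_rows)
    table5 = pd.DataFrame(t5_rows)

    tables = {"table1": table1, "table2": table2, "table3": table3,
              "table4": table4, "table5": table5}
    for name, tbl in tables.items():
        tbl.to_csv(out / f"{name}_full.tsv", sep="\t", index=False,
                   float_format="%.10g")
        fmt = tbl.copy()
        for col in fmt.columns:
            if col.endswith("_p") or col == "t_test_p":
                fmt[col] = [_fmt_p(v) for v in fmt[col]]
            elif fmt[col].dtype.kind == "f":
                fmt[col] = fmt[col].round(4)
        fmt.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        logger.info("wrote %s (%d rows)", name, len(tbl))
    return tables
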