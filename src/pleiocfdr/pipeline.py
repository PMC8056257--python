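"""End-to-end orchestration: read -> harmonize -> prune -> stratified Q-Q ->
cFDR/ccFDR -> significance -> novelty -> gene mapping -> expression
validation, from a single declarative config.

Pruning precedes the cFDR stage because the counting estimator assumes
quasi-independent SNPs.  Stages whose inputs are absent are skipped with a
log notice.  Reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import annotate as ann
from . import cfdr_core, enrichment_qq, gwas_io, ld_tools, synthetic_data

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration of a full run (paths may be None to skip
    the corresponding stage)."""

    out_dir: str = "results/run"
    seed: int = 0

    # input summary stats (or simulate when absent)
    stats1: str | None = None
    stats2: str | None = None
    dialect1: dict = field(default_factory=dict)
    dialect2: dict = field(default_factory=dict)
    trait1: str = "trait1"
    trait2: str = "trait2"
    simulate: dict | None = None  # SimConfig overrides when simulating

    # LD source: pair file, dosage panel file, or simulate-from-merged
    ld_pairs: str | None = None
    ld_panel: str | None = None
    simulate_ld: bool = False

    prune_r2: float = 0.2
    threshold: float = 0.05
    qq_thresholds: tuple = enrichment_qq.DEFAULT_THRESHOLDS
    block_r2: float = 0.8
    flank_bp: int = 10_000

    catalog: str | None = None
    genes_bed: str | None = None
    expression: str | None = None
    expression_meta: str | None = None
    trait_col: str | None = None
    plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must lie in (0, 1)")
        if self.prune_r2 < 0:
            raise ValueError("prune_r2 must be nonnegative")
        for name in ("stats1", "stats2", "ld_pairs", "ld_panel", "catalog",
                     "genes_bed", "expression", "expression_meta"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name} = {p!r} does not exist")


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the machine-readable report
    (also written as report.json under the output directory)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stale = out / ".stale"
    stale.write_text("run in progress\n")
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
        "counts": {},
    }

    # --- input stage -------------------------------------------------------
    truth = None
    try:
        if config.stats1 and config.stats2:
            t1 = gwas_io.read_summary_stats(
                config.stats1, gwas_io.Dialect(**config.dialect1), config.trait1)
            t2 = gwas_io.read_summary_stats(
                config.stats2, gwas_io.Dialect(**config.dialect2), config.trait2)
            report["stages"]["read"] = {
                "n1": len(t1), "rejected1": t1.n_rejected,
                "n2": len(t2), "rejected2": t2.n_rejected,
            }
        else:
            sim = synthetic_data.SimConfig(seed=config.seed, **(config.simulate or {}))
            t1, t2, truth = synthetic_data.simulate_joint_gwas(sim)
            _tsv(truth, out / "truth.tsv")
            report["stages"]["simulate"] = {"n_snps": sim.n_snps}
        merged = gwas_io.harmonize(t1, t2)
        gwas_io.write_merged(merged, out / "merged.tsv")
        report["counts"]["merged"] = len(merged)
    except (OSError, ValueError, KeyError) as e:
        raise StageError("input", str(e)) from e

    # --- LD + pruning ------------------------------------------------------
    ld = None
    try:
        if config.ld_pairs:
            ld = ld_tools.read_ld_file(config.ld_pairs)
        elif config.ld_panel:
            ld = ld_tools.compute_r2(ld_tools.read_dosage_panel(config.ld_panel))
        elif config.simulate_ld:
            sim = synthetic_data.SimConfig(seed=config.seed, **(config.simulate or {}))
            panel, ld, _ = synthetic_data.simulate_ld_panel(merged.df, sim)
            ld_tools.write_dosage_panel(panel, out / "panel.tsv")
        if ld is not None:
            kept, removed = ld_tools.prune_ld(merged.df, ld, config.prune_r2)
            pruned_df = merged.df[merged.df["snp_id"].isin(kept)].reset_index(drop=True)
            merged = gwas_io.MergedPairTable(df=pruned_df, trait1=merged.trait1,
                                             trait2=merged.trait2)
            _tsv(removed, out / "pruned_removed.tsv")
            gwas_io.write_merged(merged, out / "merged_pruned.tsv")
            report["counts"]["pruned_kept"] = len(kept)
            report["counts"]["pruned_removed"] = len(removed)
        else:
            logger.info("no LD source configured; pruning skipped")
            report["stages"]["prune"] = "skipped"
    except (OSError, ValueError, KeyError) as e:
        raise StageError("prune", str(e)) from e

    # --- stratified Q-Q ----------------------------------------------------
    try:
        strata_frames = {}
        for principal, tag in ((1, f"{merged.trait1}|{merged.trait2}"),
                               (2, f"{merged.trait2}|{merged.trait1}")):
            strata = enrichment_qq.stratified_qq(merged, principal,
                                                 config.qq_thresholds)
            frame = enrichment_qq.strata_to_frame(strata)
            _tsv(frame, out / f"qq_strata_{principal}.tsv")
            _tsv(enrichment_qq.enrichment_area(strata),
                 out / f"qq_enrichment_{principal}.tsv")
            strata_frames[tag] = strata
        report["stages"]["qq"] = {tag: len(s) for tag, s in strata_frames.items()}
    except ValueError as e:
        raise StageError("qq", str(e)) from e

    # --- cFDR / ccFDR ------------------------------------------------------
    try:
        table = cfdr_core.cfdr_table(merged, threshold=config.threshold)
        _tsv(_cfdr_export(table), out / "cfdr.tsv")
        for col, name in (("cfdr_1_given_2", "manhattan_cfdr_1g2"),
                          ("cfdr_2_given_1", "manhattan_cfdr_2g1"),
                          ("ccfdr", "manhattan_ccfdr")):
            mh, line = cfdr_core.manhattan_table(table[col], config.threshold,
                                                 snps=table)
            _tsv(mh.assign(line=line), out / f"{name}.tsv")
        report["counts"]["significant_1_given_2"] = int(table["sig_1_given_2"].sum())
        report["counts"]["significant_2_given_1"] = int(table["sig_2_given_1"].sum())
        report["counts"]["significant_conjunction"] = int(table["sig_conjunction"].sum())
        if truth is not None:
            aligned = truth.set_index("snp_id").loc[table["snp_id"]].reset_index()
            report["counts"]["fdp_1_given_2"] = synthetic_data.empirical_fdp(
                table["sig_1_given_2"].to_numpy(), aligned, trait=1)
    except ValueError as e:
        raise StageError("cfdr", str(e)) from e

    if config.plots:
        from . import plotting

        plotting.qq_plot(strata_frames, out / "qq.png")
        mh, line = cfdr_core.manhattan_table(table["ccfdr"], config.threshold, snps=table)
        plotting.manhattan_plot(mh, line, out / "manhattan_ccfdr.png",
                                title="conjunction ccFDR")

    # --- novelty -----------------------------------------------------------
    if config.catalog and ld is not None:
        try:
            catalog = ann.read_catalog(config.catalog)
            for sig_col, tag in (("sig_1_given_2", "cfdr1"),
                                 ("sig_conjunction", "conjunction")):
                sig_ids = table.loc[table[sig_col], "snp_id"]
                calls = ann.classify_novelty(sig_ids, catalog, ld, config.block_r2)
                _tsv(calls, out / f"novelty_{tag}.tsv")
                report["counts"][f"novelty_{tag}"] = ann.novelty_counts(calls)
        except (OSError, ValueError, KeyError) as e:
            raise StageError("novelty", str(e)) from e
    else:
        logger.info("novelty stage skipped (needs catalog and an LD source)")
        report["stages"]["novelty"] = "skipped"

    # --- gene mapping ------------------------------------------------------
    gene_labels = None
    if config.genes_bed:
        try:
            genes = ann.read_gene_bed(config.genes_bed)
            sig = table.loc[table["sig_1_given_2"] | table["sig_conjunction"],
                            ["snp_id", "chrom", "pos"]]
            gene_labels = ann.map_genes(sig, genes, config.flank_bp)
            _tsv(gene_labels.assign(genes=gene_labels["genes"].str.join("/"),
                                    relations=gene_labels["relations"].str.join("/")),
                 out / "gene_assignments.tsv")
            report["counts"]["snps_with_gene"] = int((gene_labels["label"] != "").sum())
        except (OSError, ValueError, KeyError) as e:
            raise StageError("genes", str(e)) from e
    else:
        report["stages"]["genes"] = "skipped"

    # --- expression validation --------------------------------------------
    if config.expression and config.expression_meta:
        try:
            from . import expression_validation as ev

            expr = ev.read_expression(config.expression, config.expression_meta)
            wanted = None
            if gene_labels is not None:
                wanted = sorted({g for gl in gene_labels["genes"] for g in gl})
            res = ev.validate_genes(expr, genes=wanted, trait_col=config.trait_col)
            _tsv(res, out / "expression_validation.tsv")
            if "ranksum_p" in res.columns:
                report["counts"]["genes_validated"] = int(
                    (res["ranksum_p"] < config.threshold).sum())
            report["counts"]["genes_tested"] = int(res["detected"].sum())
        except (OSError, ValueError, KeyError) as e:
            raise StageError("expression", str(e)) from e
    else:
        report["stages"]["expression"] = "skipped"

    # internal consistency of the bookkeeping
    for tag in ("cfdr1", "conjunction"):
        nc = report["counts"].get(f"novelty_{tag}")
        if nc:
            assert (nc["n_replicate_direct"] + nc["n_replicate_ld"] + nc["n_novel"]
                    == nc["n_significant"])

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    stale.unlink()
    return report


def _cfdr_export(table: pd.DataFrame) -> pd.DataFrame:
    return table.rename(
        columns={"snp_id": "SNP", "chrom": "CHR", "pos": "BP", "p1": "P1", "p2": "P2",
                 "cfdr_1_given_2": "CFDR_1G2", "cfdr_2_given_1": "CFDR_2G1",
                 "ccfdr": "CCFDR", "sig_1_given_2": "SIG_1G2",
                 "sig_2_given_1": "SIG_2G1", "sig_conjunction": "SIG_CONJ"}
    )[["SNP", "CHR", "BP", "P1", "P2", "CFDR_1G2", "CFDR_2G1", "CCFDR",
       "SIG_1G2", "SIG_2G1", "SIG_CONJ"]]
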