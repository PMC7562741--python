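"""End-to-end pipeline orchestration.

Stages run in the order the analysis proceeds: simulate (or load) ->
preprocess -> differential expression -> taxonomy enrichment ->
co-expression network -> per-sample scoring -> signature refinement ->
connectivity summaries. Every intermediate is written as plain
CSV/GMT/JSON so each stage can be audited and re-run independently; a
manifest records parameters, input hashes and produced files. All
randomness flows from the single configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catenrich import enrich_all, records_to_frame
from .coexnet import (
    NetworkParams,
    build_tom,
    compute_eigengenes,
    correlate_traits,
    detect_modules,
    merge_modules,
    qc_module,
)
from .connectivity import (
    filter_connectivity,
    format_target_table,
    rank_regulators,
    summarize_targets,
)
from .diffexpr import fit_moderated
from .exprio import (
    ExpressionBundle,
    detect_outlier_samples,
    filter_low_intensity,
    load_clinical,
    load_expression,
    read_gmt,
    write_expression,
    write_gmt,
)
from .samplescore import compare_groups, enrichment_scores, expression_statistic
from .sigrefine import SignatureRefinementParams, refine_signature
from .synthdata import (
    SimulationConfig,
    generate_connectivity_table,
    generate_expression,
    generate_taxonomy,
    write_ground_truth,
    write_taxonomy,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("synopipe")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str = "synopipe-run"
    seed: int = 0
    log_level: str = "INFO"
    # synthetic inputs (used when expression_path is None)
    simulation: dict = field(default_factory=dict)
    # real inputs
    expression_path: str | None = None
    clinical_path: str | None = None
    cohort: dict | None = None
    taxonomy_path: str | None = None
    signature_path: str | None = None
    connectivity_path: str | None = None
    # stage parameters
    low_intensity_threshold: float = 2.34
    outlier_k: float = 3.0
    drop_outliers: bool = False
    fdr: float = 0.2
    network: dict = field(default_factory=dict)
    score_tau: float = 1.0
    score_mode: str = "diff"
    refine: dict = field(default_factory=dict)
    min_target_count: int = 2
    top_regulators: int = 50

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**payload)
        for key in ("expression_path", "clinical_path", "taxonomy_path",
                    "signature_path", "connectivity_path"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{key} does not exist: {p}")
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": {},
        "inputs": {},
        "warnings": [],
    }
    stage = "setup"
    try:
        # ------------------------------------------------ inputs
        stage = "simulate"
        if config.expression_path is None:
            sim = SimulationConfig(**{**config.simulation, "seed": config.seed})
            bundle = generate_expression(sim)
            truth = bundle.ground_truth
            taxonomy = generate_taxonomy(sim, truth)
            conn_table = generate_connectivity_table(sim, truth=truth)
            write_expression(bundle, outdir / "expression.tsv")
            bundle.clinical.to_csv(outdir / "clinical.csv")
            write_taxonomy(taxonomy, outdir / "taxonomy.gmt")
            conn_table.to_csv(outdir / "connectivity.csv", index=False)
            write_ground_truth(truth, outdir / "ground_truth.json")
            manifest["stages"]["simulate"] = [
                "expression.tsv", "clinical.csv", "taxonomy.gmt",
                "connectivity.csv", "ground_truth.json",
            ]
            signature = None
            if truth.module_members:
                first = next(iter(truth.module_members))
                signature = truth.module_members[first][:30]
        else:
            clinical = (
                load_clinical(config.clinical_path)
                if config.clinical_path
                else None
            )
            cohort = config.cohort
            if cohort is None and clinical is not None and "cohort" in clinical:
                cohort = clinical["cohort"].to_dict()
            bundle = load_expression(
                config.expression_path, cohort=cohort, clinical=clinical
            )
            taxonomy = read_gmt(config.taxonomy_path) if config.taxonomy_path else None
            conn_table = (
                pd.read_csv(config.connectivity_path)
                if config.connectivity_path
                else None
            )
            signature = None
            if config.signature_path:
                sets = read_gmt(config.signature_path)
                signature = next(iter(sets.values()))
            for key in ("expression_path", "clinical_path", "taxonomy_path",
                        "signature_path", "connectivity_path"):
                p = getattr(config, key)
                if p:
                    manifest["inputs"][key] = _sha256(Path(p))
            manifest["stages"]["simulate"] = []
        logger.info("inputs ready: %d genes x %d samples", bundle.n_genes, bundle.n_samples)

        # ------------------------------------------------ preprocess
        stage = "preprocess"
        bundle, report = filter_low_intensity(
            bundle, threshold=config.low_intensity_threshold
        )
        outliers = detect_outlier_samples(bundle, k=config.outlier_k)
        if outliers.flagged:
            logger.warning("outlier sample(s) flagged: %s", outliers.flagged)
            manifest["warnings"].append(f"outliers flagged: {outliers.flagged}")
            if config.drop_outliers:
                keep = [s for s in bundle.samples if s not in outliers.flagged]
                bundle = bundle.subset_samples(keep)
        write_expression(bundle, outdir / "expression.filtered.tsv")
        (outdir / "preprocess.json").write_text(
            json.dumps(
                {
                    "low_intensity_removed": report.n_removed,
                    "cutoff": report.cutoff,
                    "outliers_flagged": outliers.flagged,
                    "outliers_dropped": bool(config.drop_outliers and outliers.flagged),
                },
                indent=1,
            )
        )
        manifest["stages"]["preprocess"] = ["expression.filtered.tsv", "preprocess.json"]

        # ------------------------------------------------ differential expression
        stage = "de"
        de = fit_moderated(bundle, fdr=config.fdr)
        de.table.to_csv(outdir / "de.csv", index=False)
        manifest["stages"]["de"] = ["de.csv"]
        n_sig = int(de.table["significant"].sum())
        logger.info("differential expression: %d significant genes (q < %s)", n_sig, config.fdr)

        # ------------------------------------------------ enrichment
        stage = "enrich"
        if taxonomy is not None:
            sig_up = de.table.loc[
                de.table["significant"] & (de.table["lfc"] > 0), "gene"
            ].tolist()
            universe = bundle.genes
            gene_list = sig_up if sig_up else de.table["gene"].tolist()[:50]
            records = enrich_all(gene_list, taxonomy, universe)
            records_to_frame(records).to_csv(outdir / "enrichment.csv", index=False)
            manifest["stages"]["enrich"] = ["enrichment.csv"]
        else:
            manifest["warnings"].append("no taxonomy supplied; enrichment skipped")
            manifest["stages"]["enrich"] = []

        # ------------------------------------------------ co-expression network
        stage = "net"
        params = NetworkParams(**config.network) if config.network else NetworkParams()
        net_genes = bundle.values.var(axis=1).nlargest(
            min(3000, bundle.n_genes)
        ).index
        sub = bundle.subset_genes(list(net_genes))
        tom = build_tom(sub, params)
        modules = detect_modules(tom, params)
        files = ["modules.csv"]
        if modules.module_names:
            modules = compute_eigengenes(sub, modules)
            modules = merge_modules(sub, modules, params.merge_height)
            modules.me.to_csv(outdir / "module_eigengenes.csv")
            modules.kme.to_csv(outdir / "module_kme.csv")
            files += ["module_eigengenes.csv", "module_kme.csv"]
            if bundle.clinical is not None:
                clin = bundle.clinical.copy()
                clin["cohort"] = bundle.cohort
                r, p, notes = correlate_traits(modules.me, clin)
                modules.trait_cor, modules.trait_p, modules.trait_notes = r, p, notes
                r.to_csv(outdir / "module_trait_r.csv")
                p.to_csv(outdir / "module_trait_p.csv")
                files += ["module_trait_r.csv", "module_trait_p.csv"]
                qc = {
                    mod: qc_module(mod, sub, modules)
                    for mod in modules.module_names
                }
                (outdir / "module_qc.json").write_text(json.dumps(qc, indent=1, default=float))
                files.append("module_qc.json")
            else:
                logger.warning("no clinical table; module-trait correlation skipped")
                manifest["warnings"].append("module-trait correlation skipped (no clinical table)")
        modules.labels.rename("module").to_csv(outdir / "modules.csv")
        manifest["stages"]["net"] = files

        # ------------------------------------------------ per-sample scoring
        stage = "score"
        if taxonomy is not None:
            cats = taxonomy.categories if hasattr(taxonomy, "categories") else taxonomy
            usable = {
                name: genes
                for name, genes in cats.items()
                if 0 < len(set(genes) & set(bundle.genes)) < bundle.n_genes
            }
            stat = expression_statistic(bundle)
            score_matrix = enrichment_scores(
                stat, usable, tau=config.score_tau, mode=config.score_mode
            )
            contrast = compare_groups(score_matrix, bundle.cohort)
            score_matrix.scores.to_csv(outdir / "scores.csv")
            contrast.to_csv(outdir / "score_contrast.csv")
            manifest["stages"]["score"] = ["scores.csv", "score_contrast.csv"]
        else:
            manifest["warnings"].append("no taxonomy supplied; scoring skipped")
            manifest["stages"]["score"] = []

        # ------------------------------------------------ signature refinement
        stage = "refine"
        if signature:
            rp = SignatureRefinementParams(**config.refine) if config.refine else SignatureRefinementParams()
            refined = refine_signature(bundle, signature, rp)
            write_gmt({"refined_signature": refined.genes}, outdir / "refined_signature.gmt")
            (outdir / "refine_audit.json").write_text(
                json.dumps(refined.audit, indent=1, default=str)
            )
            manifest["stages"]["refine"] = ["refined_signature.gmt", "refine_audit.json"]
        else:
            manifest["warnings"].append("no signature supplied; refinement skipped")
            manifest["stages"]["refine"] = []

        # ------------------------------------------------ connectivity
        stage = "connect"
        if conn_table is not None:
            filtered = filter_connectivity(conn_table)
            summaries = summarize_targets(filtered, min_count=config.min_target_count)
            format_target_table(summaries).to_csv(outdir / "target_summary.csv", index=False)
            burs = rank_regulators(filtered, top_n=config.top_regulators)
            (outdir / "burs.json").write_text(
                json.dumps(burs.to_dict(orient="records"), indent=1)
            )
            manifest["stages"]["connect"] = ["target_summary.csv", "burs.json"]
        else:
            manifest["warnings"].append("no connectivity table; connect skipped")
            manifest["stages"]["connect"] = []
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        manifest["error"] = {"stage": stage, "message": str(exc)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        logger.removeHandler(handler)
        handler.close()
        raise PipelineError(stage, str(exc)) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    logger.removeHandler(handler)
    handler.close()
    return manifest
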