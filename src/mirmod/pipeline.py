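"""End-to-end orchestration of the integrated mRNA-miRNA analysis.

Stage order: miRNA cpm normalization -> expressed-miRNA filter -> differential
expression (genes and miRNAs) -> coexpression modules -> module-trait
correlation (disease modules flagged at FDR < 0.05) -> permutation screen of
down-regulated DE miRNAs against disease modules -> seed-based target
prediction + inverse-correlation filter in patients -> target-count ranking
-> optional eigengene ROC for therapy response.  Every output is written as
TSV/JSON and listed in a manifest with content checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ExpressionMatrix, SampleAnnotation
from .coexpression import (
    EigengeneMatrix,
    ModuleAssignment,
    adjacency,
    correlation_matrix,
    detect_modules,
    module_eigengene,
    module_membership,
    module_trait_correlation,
    pick_soft_threshold,
    tom_similarity,
)
from .evaluation import eigengene_predictor
from .integration import (
    MirProfile,
    inverse_correlation_filter,
    predict_targets,
    rank_mirs_by_target_count,
    screen_mirs,
)
from .io import read_annotation, read_fasta, read_matrix_tsv, write_matrix_tsv
from .preprocess import cpm_normalize, differential_expression, filter_expressed

log = logging.getLogger("mirmod")

__all__ = ["PipelineConfig", "ResultsBundle", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    gene_matrix: str
    mir_counts: str
    annotation: str
    utr_fasta: str
    mir_fasta: str
    outdir: str
    external_predictions: str | None = None

    case_label: str = "case"
    control_label: str = "control"
    expressed_cutoff: float = 2.0          # cpm
    expressed_min_fraction: float = 0.5
    de_fdr: float = 0.05                   # DE call for miRNAs entering the screen
    min_module_size: int = 30
    merge_cut: float = 0.25
    soft_power: int | None = None          # None -> scale-free criterion
    network_type: str = "unsigned"
    trait_fdr: float = 0.05                # disease-module flag
    permutations: int = 10_000
    screen_p_cut: float = 0.05
    screen_q_cut: float = 0.25
    target_mode: str = "seed-only"
    inverse_p_cut: float = 0.05
    mm_cut: float = 0.5
    response_field: str = "response"
    response_positive: str = "nonresponder"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ResultsBundle:
    assignment: ModuleAssignment
    eigengenes: EigengeneMatrix
    module_trait: pd.DataFrame
    gene_de: pd.DataFrame
    mir_de: pd.DataFrame
    expressed_mirs: list[str]
    screen: pd.DataFrame
    integrated: pd.DataFrame
    ranking: pd.DataFrame
    roc_summary: dict | None
    manifest: dict
    outdir: Path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    """Run every stage on the configured inputs and write all outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "read-inputs"

    def emit(df: pd.DataFrame, name: str, index_label: str | None = None) -> Path:
        path = outdir / name
        df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)
        written.append(path)
        return path

    try:
        genes = read_matrix_tsv(config.gene_matrix, kind="gene")
        mir_counts = read_matrix_tsv(config.mir_counts, kind="counts")
        annotation = read_annotation(config.annotation)
        utrs = read_fasta(config.utr_fasta, alphabet="DNA")
        mir_seqs = read_fasta(config.mir_fasta, alphabet="RNA")
        external = (
            pd.read_csv(config.external_predictions, sep="\t")
            if config.external_predictions
            else None
        )

        stage = "normalize"
        cpm = cpm_normalize(mir_counts)
        log_cpm = cpm_normalize(mir_counts, log=True)
        log.info("normalized %d miRNAs over %d samples", *mir_counts.data.shape)

        stage = "filter-expressed"
        expressed = filter_expressed(
            cpm, annotation, cutoff=config.expressed_cutoff,
            min_fraction=config.expressed_min_fraction,
        )
        log.info("%d/%d miRNAs expressed at %.3g cpm",
                 len(expressed), len(cpm.feature_ids), config.expressed_cutoff)

        stage = "differential-expression"
        gene_de = differential_expression(genes, annotation,
                                          config.case_label, config.control_label)
        mir_de = differential_expression(
            ExpressionMatrix(log_cpm.data.loc[expressed], kind="mir"),
            annotation, config.case_label, config.control_label,
        )
        emit(gene_de, "gene_de.tsv", index_label="feature_id")
        emit(mir_de, "mir_de.tsv", index_label="feature_id")

        stage = "modules"
        if config.soft_power is None:
            report = pick_soft_threshold(genes, network_type=config.network_type)
            power = report.chosen_power
            emit(report.to_frame(), "soft_threshold.tsv")
        else:
            power = config.soft_power
        r, _p = correlation_matrix(genes)
        tom = tom_similarity(adjacency(r, power, config.network_type))
        assignment = detect_modules(tom, genes, min_size=config.min_module_size,
                                    merge_cut=config.merge_cut)
        eigengenes = module_eigengene(genes, assignment)
        mm = module_membership(genes, eigengenes)
        emit(assignment.labels.rename("module").to_frame(), "module_assignment.tsv",
             index_label="gene_id")
        emit(eigengenes.eigengenes, "eigengenes.tsv", index_label="module")
        emit(mm.mm, "module_membership.tsv", index_label="gene_id")
        log.info("detected %d modules (power %s)", len(assignment.modules), power)

        stage = "module-trait"
        coded = annotation.table.copy()
        coded["disease"] = (coded["group"] == config.case_label).astype(int)
        trait_table = module_trait_correlation(
            eigengenes, SampleAnnotation(coded), ["disease"], fdr_cut=config.trait_fdr
        )
        emit(trait_table, "module_trait.tsv")
        disease_modules = list(trait_table.loc[trait_table["significant"], "module"])
        log.info("disease-associated modules: %s", disease_modules)

        stage = "permutation-screen"
        down = mir_de[(mir_de["qvalue"] < config.de_fdr) & (mir_de["log2fc"] < 0)].index
        module_exprs = {
            m: genes.subset_features(assignment.genes_in(m)) for m in disease_modules
        }
        screen = screen_mirs(
            list(down), log_cpm, module_exprs,
            p_cut=config.screen_p_cut, q_cut=config.screen_q_cut,
            B=config.permutations, seed=config.seed,
        )
        emit(screen, "permutation_screen.tsv")
        hits = screen.loc[screen["selected"], "mir_id"].unique() if not screen.empty else []
        log.info("screen: %d/%d DE miRNAs selected", len(hits), len(down))

        stage = "target-prediction"
        profiles = [MirProfile(m, mir_seqs.get(m, ""), log_cpm.data.loc[m]) for m in hits]
        predictions = predict_targets(profiles, utrs=utrs, external_table=external,
                                      mode=config.target_mode)
        module_gene_set = {g for m in disease_modules for g in assignment.genes_in(m)}
        predictions = predictions[predictions["gene_id"].isin(module_gene_set)]
        integrated = inverse_correlation_filter(
            predictions, genes, log_cpm, annotation,
            subset=config.case_label, p_cut=config.inverse_p_cut,
        )
        ranking = rank_mirs_by_target_count(integrated)
        emit(integrated, "integrated_targets.tsv")
        emit(ranking, "mir_ranking.tsv")

        stage = "response-roc"
        roc_summary = None
        labelled = annotation.table.get(config.response_field)
        if labelled is not None and labelled.notna().any() and disease_modules:
            roc = eigengene_predictor(
                eigengenes, annotation, disease_modules[0],
                response_field=config.response_field,
                positive_class=config.response_positive,
            )
            roc_summary = {
                "auc": roc.auc,
                "module": disease_modules[0],
                "n_pos": roc.n_pos,
                "n_neg": roc.n_neg,
                "positive_class": roc.positive_class,
                "higher_score_positive": roc.higher_score_positive,
            }
            emit(roc.curve_frame(), "roc_curve.tsv")
            (outdir / "roc_summary.json").write_text(json.dumps(roc_summary, indent=1))
            written.append(outdir / "roc_summary.json")
        else:
            log.info("no response labels (or no disease module); ROC stage skipped")
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        _write_manifest(outdir, config, written, failed_stage=stage)
        raise PipelineError(stage, exc) from exc

    manifest = _write_manifest(
        outdir, config, written,
        extra={"roc_skipped": roc_summary is None, "disease_modules": disease_modules},
    )
    return ResultsBundle(
        assignment=assignment,
        eigengenes=eigengenes,
        module_trait=trait_table,
        gene_de=gene_de,
        mir_de=mir_de,
        expressed_mirs=expressed,
        screen=screen,
        integrated=integrated,
        ranking=ranking,
        roc_summary=roc_summary,
        manifest=manifest,
        outdir=outdir,
    )


def _write_manifest(outdir: Path, config: PipelineConfig, written: list[Path],
                    failed_stage: str | None = None, extra: dict | None = None) -> dict:
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "version": __version__,
        "python": platform.python_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "files": {p.name: _sha256(p) for p in written},
    }
    if failed_stage:
        manifest["failed_stage"] = failed_stage
    if extra:
        manifest.update(extra)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
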