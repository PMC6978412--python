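"""End-to-end orchestration.

Flow: filter annotations/domains -> split genes into train/test -> fit the
three stages on training genes -> evaluate each stage on held-out test
genes -> refit every stage on the complete gene set -> predict isoform
functions -> gain/loss calls and principal-isoform consistency.  Held-out
evaluation happens before the full refit, so reported performance never
touches test labels.

Every run writes a manifest (config hash, seed, output checksums) that is
byte-identical across reruns with the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .combine import (
    fit_combination,
    predict_combined_logits,
    save_combination_models,
)
from .correlation import spearman_correlation, wilcoxon_zscores
from .datatypes import (
    AnnotationSet,
    DomainAnnotation,
    ExpressionMatrix,
    GeneModelMap,
    LogitMatrix,
)
from .domains import fit_domain_models, predict_domain_logits, save_domain_models
from .evaluate import EvalReport, per_term_metrics, split_train_test, summarize
from .io import (
    aggregate_gene_expression,
    build_gene_domains,
    filter_domains,
    filter_go_terms,
    read_annotations,
    read_domains,
    read_expression,
    read_isoform_map,
    write_scores,
)
from .isoforms import gain_loss_calls, main_isoform_consistency, predict_isoform_functions

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_pipeline_objects"]


@dataclass
class RunConfig:
    """Configuration of a full run; defaults mirror the documented design
    decisions of each stage."""

    # input paths (optional when running on in-memory objects)
    isoform_expression: str | None = None
    annotations: str | None = None
    isoform_domains: str | None = None
    isoform_map: str | None = None
    out_dir: str = "isofunc_run"

    # filters
    go_min_genes: int = 10
    go_max_genes: int = 299
    domain_min_genes: int = 6
    domain_max_genes: int = 500

    # split
    n_test: int = 400
    seed: int = 1

    # domain regression
    alpha: float = 0.5
    folds: int = 10
    n_lambda: int = 100

    # combination
    prior_scale: float = 2.5

    # gain/loss thresholds and consistency aggregation
    lower_threshold: float = -3.0
    upper_threshold: float = 3.0
    aggregation: str = "majority"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    reports: dict[str, EvalReport]
    iso_logits: LogitMatrix
    gain_loss: pd.DataFrame
    consistency_per_term: pd.DataFrame
    consistency_summary: dict
    models_domain: dict
    models_combination: dict
    split: tuple
    extras: dict = field(default_factory=dict)


def _evaluate_stage_scores(scores, ann_test) -> EvalReport:
    return summarize(per_term_metrics(scores, ann_test))


def run_pipeline_objects(
    iso_expr: ExpressionMatrix,
    ann: AnnotationSet,
    iso_domains: DomainAnnotation,
    gene_map: GeneModelMap,
    cfg: RunConfig,
) -> PipelineResult:
    """Run the full train/validate/refit/predict flow on in-memory objects."""
    # --- stage: filters ---------------------------------------------------
    gene_expr = aggregate_gene_expression(iso_expr, gene_map)
    gene_domains = build_gene_domains(iso_domains, gene_map)
    if not gene_domains.entity_ids.equals(gene_expr.entity_ids):
        # sparse pair files omit all-zero rows; restore the full gene universe
        import scipy.sparse as sp

        idx = gene_domains.entity_ids.get_indexer(gene_expr.entity_ids)
        present = (idx >= 0).astype(np.int8)
        rows = gene_domains.pairs.tocsr()[idx.clip(min=0)].multiply(present[:, None])
        gene_domains = DomainAnnotation(
            gene_expr.entity_ids, gene_domains.domain_ids, sp.csc_matrix(rows)
        )
    # align annotation entities to the expressed genes; genes without any
    # annotation row are all-negative for every term
    genes = gene_expr.entity_ids
    if not ann.entity_ids.equals(genes):
        ann = ann.reindex_entities(genes)
    ann_f = filter_go_terms(ann, cfg.go_min_genes, cfg.go_max_genes)
    dom_f = filter_domains(gene_domains, cfg.domain_min_genes, cfg.domain_max_genes)
    iso_dom_f = DomainAnnotation(
        iso_domains.entity_ids,
        dom_f.domain_ids,
        iso_domains.pairs[:, iso_domains.domain_ids.get_indexer(dom_f.domain_ids)],
    )

    # --- stage: split -----------------------------------------------------
    split = split_train_test(genes, cfg.n_test, cfg.seed)
    train = pd.Index(split.train_entity_ids)
    test = pd.Index(split.test_entity_ids)
    # a term with no training positives cannot be fit by any stage
    train_counts = ann_f.subset_entities(train).term_counts()
    if (train_counts == 0).any():
        dropped = ann_f.term_ids[train_counts == 0].tolist()
        logger.warning(
            "dropping %d term(s) with no training positives: %s",
            len(dropped),
            dropped[:5],
        )
        ann_f = ann_f.select_terms(train_counts > 0)
    expr_train = gene_expr.subset(train)
    expr_test = gene_expr.subset(test)
    ann_train = ann_f.subset_entities(train)
    ann_test = ann_f.subset_entities(test)
    dom_train = dom_f.subset_entities(train)
    dom_test = dom_f.subset_entities(test)

    # --- stage: correlation method (train + test) -------------------------
    logger.info("correlation method: training genes")
    corr_train = spearman_correlation(expr_train, expr_train)
    z_train = wilcoxon_zscores(corr_train, ann_train, exclude_self=True)
    corr_test = spearman_correlation(expr_test, expr_train)
    z_test = wilcoxon_zscores(corr_test, ann_train, exclude_self=True)

    # --- stage: domain regression ------------------------------------------
    logger.info("domain regression: fitting %d terms", ann_train.n_terms)
    models_dom_train = fit_domain_models(
        dom_train, ann_train, folds=cfg.folds, alpha=cfg.alpha, seed=cfg.seed,
        n_lambda=cfg.n_lambda,
    )
    d_train = predict_domain_logits(models_dom_train, dom_train)
    d_test = predict_domain_logits(models_dom_train, dom_test)

    # --- stage: combination -------------------------------------------------
    logger.info("combination method: fitting %d terms", ann_train.n_terms)
    models_comb_train = fit_combination(
        z_train, d_train, ann_train, prior_scale=cfg.prior_scale, seed=cfg.seed
    )
    comb_test = predict_combined_logits(models_comb_train, z_test, d_test)

    # --- stage: held-out evaluation ----------------------------------------
    reports = {
        "correlation": _evaluate_stage_scores(z_test, ann_test),
        "domain": _evaluate_stage_scores(d_test, ann_test),
        "combination": _evaluate_stage_scores(comb_test, ann_test),
    }

    # --- stage: refit on the complete gene set ------------------------------
    logger.info("refitting all stages on the complete gene set")
    corr_all = spearman_correlation(gene_expr, gene_expr)
    z_all = wilcoxon_zscores(corr_all, ann_f, exclude_self=True)
    models_dom_all = fit_domain_models(
        dom_f, ann_f, folds=cfg.folds, alpha=cfg.alpha, seed=cfg.seed,
        n_lambda=cfg.n_lambda,
    )
    d_all = predict_domain_logits(models_dom_all, dom_f)
    models_comb_all = fit_combination(
        z_all, d_all, ann_f, prior_scale=cfg.prior_scale, seed=cfg.seed
    )

    # --- stage: isoform prediction ------------------------------------------
    logger.info("predicting isoform functions")
    iso_logits = predict_isoform_functions(
        iso_expr,
        gene_expr,
        iso_dom_f,
        models_dom_all,
        models_comb_all,
        ann_f,
        gene_map,
    )
    calls = gain_loss_calls(
        iso_logits, ann_f, gene_map, cfg.lower_threshold, cfg.upper_threshold
    )
    cons_per_term, cons_summary = main_isoform_consistency(
        iso_logits, ann_f, gene_map, aggregation=cfg.aggregation
    )

    return PipelineResult(
        reports=reports,
        iso_logits=iso_logits,
        gain_loss=calls,
        consistency_per_term=cons_per_term,
        consistency_summary=cons_summary,
        models_domain=models_dom_all,
        models_combination=models_comb_all,
        split=(tuple(train), tuple(test)),
        extras={
            "z_test": z_test,
            "d_test": d_test,
            "comb_test": comb_test,
            "ann_test": ann_test,
            "models_domain_train": models_dom_train,
            "models_combination_train": models_comb_train,
        },
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> Path:
    """File-based entry point: read inputs, run, write a reproducible run
    directory with models, matrices, reports and a manifest."""
    for name in ("isoform_expression", "annotations", "isoform_domains", "isoform_map"):
        p = getattr(cfg, name)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"input '{name}' missing: {p}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("isofunc")
    root.addHandler(handler)
    stage = "read inputs"
    try:
        iso_expr = read_expression(cfg.isoform_expression)
        ann = read_annotations(cfg.annotations)
        iso_dom = read_domains(cfg.isoform_domains)
        gmap = read_isoform_map(cfg.isoform_map)
        stage = "pipeline"
        result = run_pipeline_objects(iso_expr, ann, iso_dom, gmap, cfg)
        stage = "write outputs"
        write_scores(result.iso_logits, out / "isoform_logits.tsv")
        result.gain_loss.to_csv(out / "gain_loss.tsv", sep="\t", index=False)
        result.consistency_per_term.to_csv(
            out / "consistency.tsv", sep="\t", index=False
        )
        save_domain_models(result.models_domain, out / "domain_models.json")
        save_combination_models(
            result.models_combination, out / "combination_models.json"
        )
        for name, report in result.reports.items():
            report.to_tsv(out / f"eval_{name}.tsv")
            report.to_json(out / f"eval_{name}.json")
        (out / "consistency_summary.json").write_text(
            json.dumps(result.consistency_summary, indent=1)
        )
    except Exception:
        logger.exception("pipeline failed at stage: %s", stage)
        root.removeHandler(handler)
        handler.close()
        raise
    root.removeHandler(handler)
    handler.close()

    cfg_dict = cfg.to_dict()
    manifest = {
        "version": __version__,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.suffix in {".tsv", ".json"} and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
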