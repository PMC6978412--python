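"""Applying gene-trained models to isoforms.

The final product is the isoform x GO-term logit matrix, plus two
downstream readouts: gain/loss-of-function calls against the prevalence
baseline (expected logit), and the principal-isoform consistency check —
does the isoform with the highest logit for a gene-annotated function tend
to be the gene's principal (APPRIS-style) isoform?
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .combine import CombinationModel, predict_combined_logits
from .correlation import spearman_correlation, wilcoxon_zscores
from .datatypes import (
    AnnotationSet,
    DomainAnnotation,
    ExpressionMatrix,
    GeneModelMap,
    LogitMatrix,
)
from .domains import DomainModel, predict_domain_logits
from .evaluate import expected_logit

logger = logging.getLogger(__name__)

__all__ = [
    "predict_isoform_functions",
    "gain_loss_calls",
    "main_isoform_consistency",
]

AGGREGATIONS = ("any-gene", "majority", "all-genes")


def predict_isoform_functions(
    iso_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    iso_domains: DomainAnnotation,
    models_domain: dict[str, DomainModel],
    models_combination: dict[str, CombinationModel],
    ann: AnnotationSet,
    gene_map: GeneModelMap,
) -> LogitMatrix:
    """Full isoform-level prediction with gene-trained models.

    Isoform z-scores come from isoform-vs-gene Spearman correlations and the
    per-term Wilcoxon contrast (excluding each isoform's host gene);
    domain logits from the per-term domain models; both fused by the
    combination models.  Isoforms lacking an expression or domain row are
    excluded with a warning.
    """
    common = iso_expr.entity_ids.intersection(iso_domains.entity_ids)
    dropped = len(iso_expr.entity_ids.union(iso_domains.entity_ids)) - len(common)
    if dropped:
        logger.warning(
            "%d isoform(s) lack an expression or domain row and are excluded",
            dropped,
        )
    iso_expr = iso_expr.subset(common)
    iso_domains = iso_domains.subset_entities(common)

    host = {iso: gene_map.gene_of(iso) for iso in common}
    corr = spearman_correlation(iso_expr, gene_expr)
    z = wilcoxon_zscores(corr, ann, exclude_self=True, host_gene=host)
    d = predict_domain_logits(models_domain, iso_domains)
    d = LogitMatrix(
        d.query_ids, z.term_ids, d.to_frame().reindex(columns=z.term_ids).to_numpy()
    )
    return predict_combined_logits(models_combination, z, d)


def gain_loss_calls(
    iso_logits: LogitMatrix,
    ann: AnnotationSet,
    gene_map: GeneModelMap,
    lower: float,
    upper: float,
) -> pd.DataFrame:
    """Per (isoform, term) gain/loss status against the expected logit.

    delta = predicted logit - ln(n_annotated / n_not_annotated).  A term
    annotated to the isoform's gene is "lost" when delta is strictly below
    ``lower``; a non-annotated term is "gained" when delta is strictly above
    ``upper``; anything else (including deltas exactly at a threshold) is
    "unchanged".
    """
    counts = ann.term_counts()
    n_genes = ann.n_entities
    exp_logits = np.array(
        [expected_logit(c, n_genes - c) for c in counts], dtype=float
    )
    term_pos = ann.term_ids.get_indexer(iso_logits.term_ids)
    if (term_pos < 0).any():
        raise KeyError(
            f"term(s) without annotations: {iso_logits.term_ids[term_pos < 0].tolist()[:5]}"
        )
    gene_rows = []
    for iso in iso_logits.query_ids:
        g = gene_map.gene_of(iso)
        if g not in ann.entity_ids:
            raise KeyError(f"isoform {iso} maps to unannotated gene {g}")
        gene_rows.append(ann.entity_ids.get_loc(g))
    annotated = ann.dense()[gene_rows][:, term_pos]

    delta = iso_logits.values - exp_logits[term_pos]
    status = np.full(delta.shape, "unchanged", dtype=object)
    status[annotated & (delta < lower)] = "lost"
    status[~annotated & (delta > upper)] = "gained"
    status[~np.isfinite(delta)] = "unchanged"

    iso_rep = np.repeat(iso_logits.query_ids.to_numpy(), len(iso_logits.term_ids))
    term_rep = np.tile(iso_logits.term_ids.to_numpy(), len(iso_logits.query_ids))
    return pd.DataFrame(
        {
            "isoform_id": iso_rep,
            "term_id": term_rep,
            "status": status.ravel(),
            "delta": delta.ravel(),
            "annotated": annotated.ravel(),
        }
    )


def main_isoform_consistency(
    iso_logits: LogitMatrix,
    ann: AnnotationSet,
    gene_map: GeneModelMap,
    aggregation: str = "majority",
) -> tuple[pd.DataFrame, dict]:
    """Check whether top-logit isoforms are the principal ones.

    For each term and each annotated gene with >= 2 isoforms, the gene
    "succeeds" when a principal isoform is among the argmax-logit isoforms
    (ties all count as top).  A term "fulfils" the hypothesis under the
    chosen aggregation over its checked genes: any-gene (>= 1 success),
    majority (fraction >= 0.5) or all-genes.  Terms with no multi-isoform
    annotated genes are skipped and counted.
    """
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
    frame = iso_logits.to_frame()
    iso_meta = gene_map.to_frame().loc[frame.index]
    by_gene = {
        g: (frame.index.get_indexer(sub.index), sub["principal"].to_numpy(bool))
        for g, sub in iso_meta.groupby("gene_id")
        if len(sub) >= 2 and sub["principal"].any()
    }
    records = []
    n_skipped = 0
    term_pos = ann.term_ids.get_indexer(iso_logits.term_ids)
    dense = ann.dense()
    values = iso_logits.values
    for tj, term in enumerate(iso_logits.term_ids):
        if term_pos[tj] < 0:
            n_skipped += 1
            continue
        annotated_genes = ann.entity_ids[dense[:, term_pos[tj]]]
        n_checked = n_success = 0
        for g in annotated_genes:
            if g not in by_gene:
                continue
            rows, is_principal = by_gene[g]
            logits = values[rows, tj]
            if np.isnan(logits).all():
                continue
            top = logits == np.nanmax(logits)
            n_checked += 1
            if bool(is_principal[top].any()):
                n_success += 1
        if n_checked == 0:
            n_skipped += 1
            continue
        frac = n_success / n_checked
        fulfilled = {
            "any-gene": n_success >= 1,
            "majority": frac >= 0.5,
            "all-genes": n_success == n_checked,
        }[aggregation]
        records.append(
            {
                "term_id": term,
                "n_genes_checked": n_checked,
                "n_success": n_success,
                "fraction": frac,
                "fulfilled": fulfilled,
            }
        )
    per_term = pd.DataFrame(
        records,
        columns=["term_id", "n_genes_checked", "n_success", "fraction", "fulfilled"],
    )
    summary = {
        "n_terms_checked": int(len(per_term)),
        "n_terms_skipped": int(n_skipped),
        "n_fulfilled": int(per_term["fulfilled"].sum()) if len(per_term) else 0,
        "fraction_fulfilled": (
            float(per_term["fulfilled"].mean()) if len(per_term) else float("nan")
        ),
        "aggregation": aggregation,
    }
    return per_term, summary
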