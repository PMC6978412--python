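"""Reading, writing, filtering and aggregation of the tabular inputs.

Formats
-------
Expression: TSV, first column entity id, header row sample ids.
Annotations / domains: two-column TSV pairs ``entity<TAB>term``; GO
annotations may carry a third ``ontology`` column (CC/MF/BP).
Isoform map: TSV with columns ``isoform, gene, principal`` (principal in
{0, 1}).
Score matrices: TSV, first column query id, header row term ids.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import (
    AnnotationSet,
    DomainAnnotation,
    ExpressionMatrix,
    GeneModelMap,
    ScoreMatrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_annotations",
    "write_annotations",
    "read_domains",
    "write_domains",
    "read_isoform_map",
    "write_isoform_map",
    "read_scores",
    "write_scores",
    "aggregate_gene_expression",
    "build_gene_domains",
    "filter_go_terms",
    "filter_domains",
]


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression table (rows = entities, columns = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate entity id(s) in {path}: {dup[:5]}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression value in {path}: {exc}") from exc
    return ExpressionMatrix(df.index.astype(str), df.columns.astype(str), values)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="entity_id")


def _pairs_to_sparse(
    entities: pd.Series, labels: pd.Series
) -> tuple[pd.Index, pd.Index, sp.csc_matrix]:
    entity_ids = pd.Index(pd.unique(entities))
    label_ids = pd.Index(pd.unique(labels))
    rows = entity_ids.get_indexer(entities)
    cols = label_ids.get_indexer(labels)
    mat = sp.csc_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(entity_ids), len(label_ids)),
    )
    mat.data[:] = 1  # collapse duplicate pairs
    return entity_ids, label_ids, mat


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read entity-GO pairs; an optional third column is the ontology."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"annotation file {path} needs >= 2 columns")
    entity_ids, term_ids, mat = _pairs_to_sparse(df.iloc[:, 0], df.iloc[:, 1])
    term_meta = None
    if df.shape[1] >= 3:
        onto = df.groupby(df.columns[1])[df.columns[2]].first()
        term_meta = pd.DataFrame({"ontology": onto.reindex(term_ids)})
    return AnnotationSet(entity_ids, term_ids, mat, term_meta)


def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    rows, cols = ann.pairs.nonzero()
    onto = ann.ontologies()
    out = pd.DataFrame(
        {"entity_id": ann.entity_ids[rows], "term_id": ann.term_ids[cols]}
    )
    if onto is not None:
        out["ontology"] = onto.reindex(out["term_id"]).to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_domains(path: str | Path) -> DomainAnnotation:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"domain file {path} needs >= 2 columns")
    entity_ids, domain_ids, mat = _pairs_to_sparse(df.iloc[:, 0], df.iloc[:, 1])
    return DomainAnnotation(entity_ids, domain_ids, mat)


def write_domains(dom: DomainAnnotation, path: str | Path) -> None:
    rows, cols = dom.pairs.nonzero()
    pd.DataFrame(
        {"entity_id": dom.entity_ids[rows], "domain_id": dom.domain_ids[cols]}
    ).to_csv(path, sep="\t", index=False)


def read_isoform_map(path: str | Path) -> GeneModelMap:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"isoform map {path} needs >= 2 columns")
    principal = (
        df.iloc[:, 2].astype(int).to_numpy().astype(bool)
        if df.shape[1] >= 3
        else np.zeros(len(df), dtype=bool)
    )
    return GeneModelMap(pd.Index(df.iloc[:, 0]), df.iloc[:, 1].to_numpy(), principal)


def write_isoform_map(gmap: GeneModelMap, path: str | Path) -> None:
    gmap.to_frame().to_csv(path, sep="\t", index_label="isoform_id")


def read_scores(path: str | Path) -> ScoreMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ScoreMatrix(df.index.astype(str), df.columns.astype(str), df.to_numpy(float))


def write_scores(scores: ScoreMatrix, path: str | Path) -> None:
    scores.to_frame().to_csv(path, sep="\t", index_label="query_id")


# ---------------------------------------------------------------------------
# derivations and filters


def aggregate_gene_expression(
    iso_expr: ExpressionMatrix, gmap: GeneModelMap
) -> ExpressionMatrix:
    """Gene TPM = sum of its isoforms' TPM, per sample; no expression filter."""
    idx = gmap.isoform_ids.get_indexer(iso_expr.entity_ids)
    if (idx < 0).any():
        missing = iso_expr.entity_ids[idx < 0].tolist()
        raise ValueError(f"isoform(s) missing from gene map: {missing[:5]}")
    genes = pd.Index(pd.unique(gmap.gene_ids[idx]))
    gene_pos = genes.get_indexer(gmap.gene_ids[idx])
    agg = np.zeros((len(genes), iso_expr.n_samples))
    np.add.at(agg, gene_pos, iso_expr.values)
    return ExpressionMatrix(genes, iso_expr.sample_ids, agg)


def build_gene_domains(iso_dom: DomainAnnotation, gmap: GeneModelMap) -> DomainAnnotation:
    """Gene domain row = logical OR over the gene's isoforms' domain rows."""
    idx = gmap.isoform_ids.get_indexer(iso_dom.entity_ids)
    if (idx < 0).any():
        missing = iso_dom.entity_ids[idx < 0].tolist()
        raise ValueError(f"isoform(s) missing from gene map: {missing[:5]}")
    genes = pd.Index(pd.unique(gmap.gene_ids[idx]))
    gene_pos = genes.get_indexer(gmap.gene_ids[idx])
    indicator = sp.csr_matrix(
        (np.ones(len(gene_pos), dtype=np.int8), (gene_pos, np.arange(len(gene_pos)))),
        shape=(len(genes), iso_dom.n_entities),
    )
    merged = (indicator @ iso_dom.pairs).tocsc()
    merged.data = np.ones_like(merged.data)
    return DomainAnnotation(genes, iso_dom.domain_ids, merged)


def filter_go_terms(
    ann: AnnotationSet, min_genes: int = 10, max_genes: int = 299
) -> AnnotationSet:
    """Keep GO terms annotated to between ``min_genes`` and ``max_genes``
    genes, both bounds inclusive."""
    if min_genes > max_genes:
        raise ValueError(f"min_genes ({min_genes}) > max_genes ({max_genes})")
    counts = ann.term_counts()
    keep = (counts >= min_genes) & (counts <= max_genes)
    logger.info("filter_go_terms: kept %d of %d terms", int(keep.sum()), len(keep))
    return ann.select_terms(keep)


def filter_domains(
    dom: DomainAnnotation, min_genes: int = 6, max_genes: int = 500
) -> DomainAnnotation:
    """Keep domains present in between ``min_genes`` and ``max_genes`` genes,
    both bounds inclusive."""
    if min_genes > max_genes:
        raise ValueError(f"min_genes ({min_genes}) > max_genes ({max_genes})")
    counts = dom.domain_counts()
    keep = (counts >= min_genes) & (counts <= max_genes)
    logger.info("filter_domains: kept %d of %d domains", int(keep.sum()), len(keep))
    return dom.select_domains(keep)
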