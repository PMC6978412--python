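"""Coexpression evidence: Spearman correlations and Wilcoxon rank-sum z-scores.

The guilt-by-association signal: genes sharing a GO function tend to be
coexpressed, so the correlations of a query entity with the genes annotated
to a term should be stochastically larger than its correlations with
non-annotated genes.  That contrast is scored with a two-sample Wilcoxon
rank-sum (Mann-Whitney) z-score per (query, term) pair, vectorized over the
sparse annotation structure.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .datatypes import AnnotationSet, CorrelationMatrix, ExpressionMatrix, ZScoreMatrix

logger = logging.getLogger(__name__)

__all__ = ["spearman_correlation", "wilcoxon_zscores"]


def spearman_correlation(
    query: ExpressionMatrix, reference: ExpressionMatrix
) -> CorrelationMatrix:
    """Spearman rho of every query row against every reference row.

    Computed as the Pearson correlation of mid-rank transforms (ties get
    average ranks).  Rows with zero rank variance (constant expression)
    produce rho = 0 for all their pairs and are logged.

    Both matrices must share the same samples in the same order and have at
    least 3 samples.
    """
    if not query.sample_ids.equals(reference.sample_ids):
        raise ValueError("query and reference sample ids differ (order matters)")
    n = query.n_samples
    if n < 3:
        raise ValueError(f"need >= 3 samples for Spearman correlation, got {n}")

    def _standardized_ranks(values: np.ndarray, label: str) -> np.ndarray:
        ranks = rankdata(values, axis=1)
        ranks -= ranks.mean(axis=1, keepdims=True)
        norms = np.sqrt((ranks**2).sum(axis=1))
        degenerate = norms == 0
        if degenerate.any():
            logger.warning(
                "%d constant %s row(s); their correlations are set to 0",
                int(degenerate.sum()),
                label,
            )
        norms[degenerate] = 1.0  # rows are all-zero after centering
        return ranks / norms[:, None]

    rq = _standardized_ranks(query.values, "query")
    rr = _standardized_ranks(reference.values, "reference")
    rho = np.clip(rq @ rr.T, -1.0, 1.0)
    return CorrelationMatrix(query.entity_ids, reference.entity_ids, rho)


def _rank_and_tie_term(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Mid-ranks of ``values`` and the tie-correction sum ``sum(t^3 - t)``."""
    ranks = rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    return ranks, tie_sum


def wilcoxon_zscores(
    corr: CorrelationMatrix,
    ann: AnnotationSet,
    exclude_self: bool = True,
    host_gene: Mapping[str, str] | None = None,
    continuity: bool = False,
) -> ZScoreMatrix:
    """Per (query, term) Wilcoxon rank-sum z-scores on correlation rows.

    For query q and term j the annotated reference genes' correlations are
    compared against the non-annotated ones with the normal approximation of
    the rank-sum statistic, using tie-corrected variance.  z > 0 means the
    annotated group's correlations are stochastically larger.

    ``exclude_self`` removes the reference gene equal to the query (gene
    queries) or, via ``host_gene``, the query isoform's host gene, so a
    gene's own perfect self-correlation never inflates its evidence.

    Terms with fewer than 2 members in either group (after exclusion) get a
    NaN score and a warning; an all-tied correlation row gives z = 0.
    """
    ref_ids = corr.term_ids  # reference genes are the "term" axis of corr
    if not ann.entity_ids.equals(ref_ids):
        ann = ann.reindex_entities(ref_ids)
    membership = ann.pairs.tocsc()
    n_ref = len(ref_ids)
    n_terms = ann.n_terms
    n_pos_all = ann.term_counts().astype(float)

    # membership transposed once for the per-query sparse W accumulation
    memT = membership.T.tocsr()
    member_dense = None
    if n_terms and n_ref and membership.nnz:
        member_dense = membership.toarray().astype(bool)

    z = np.full((len(corr.query_ids), n_terms), np.nan)
    warned_terms: set[int] = set()
    ref_pos_of_query = ref_ids.get_indexer(corr.query_ids)

    for qi, qid in enumerate(corr.query_ids):
        row = corr.values[qi]
        excl = -1
        if exclude_self:
            if host_gene is not None:
                g = host_gene.get(qid)
                excl = ref_ids.get_loc(g) if g is not None and g in ref_ids else -1
            else:
                excl = ref_pos_of_query[qi]
        if excl >= 0:
            keep = np.ones(n_ref, dtype=bool)
            keep[excl] = False
            vals = row[keep]
            n_pos = n_pos_all - (member_dense[excl].astype(float) if member_dense is not None else 0.0)
        else:
            keep = None
            vals = row
            n_pos = n_pos_all

        n = vals.size
        ranks, tie_sum = _rank_and_tie_term(vals)
        if keep is not None:
            full_ranks = np.zeros(n_ref)
            full_ranks[keep] = ranks
            w = memT @ full_ranks
        else:
            w = memT @ ranks
        n_neg = n - n_pos
        mu = n_pos * (n + 1) / 2.0
        var = n_pos * n_neg / 12.0 * ((n + 1) - tie_sum / (n * (n - 1)))
        var = np.maximum(var, 0.0)

        valid = (n_pos >= 2) & (n_neg >= 2)
        bad = np.nonzero(~valid)[0]
        for t in bad:
            if t not in warned_terms:
                warned_terms.add(t)
                logger.warning(
                    "term %s has < 2 members in a group after exclusion; "
                    "z-score recorded as missing",
                    ann.term_ids[t],
                )
        diff = w - mu
        if continuity:
            diff = diff - 0.5 * np.sign(diff)
        with np.errstate(divide="ignore", invalid="ignore"):
            zq = diff / np.sqrt(var)
        zq[var == 0] = 0.0  # all-tied rows: no evidence either way
        zq[~valid] = np.nan
        z[qi] = zq

    return ZScoreMatrix(corr.query_ids, ann.term_ids, z)
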