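"""Held-out evaluation: AUROC/AUPRC per GO term and summary reports.

AUROC uses the Mann-Whitney convention (ties get half credit); AUPRC is the
non-interpolated step-curve (average-precision) estimator with tied scores
grouped, whose random-classifier baseline equals the class prevalence —
the relevant yardstick under the heavy class imbalance of GO annotation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .datatypes import AnnotationSet, ScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SplitSpec",
    "EvalReport",
    "split_train_test",
    "auroc",
    "auprc",
    "per_term_metrics",
    "summarize",
    "expected_logit",
]

# Term-size bins used for the size-stratified medians: first bin closed on
# both sides, the rest left-open right-closed.
DEFAULT_BINS = ((10, 20), (20, 27), (27, 40), (40, 64), (64, 114), (114, 300))
PERFECT_TOL = 1e-12


@dataclass(frozen=True)
class SplitSpec:
    """A reproducible train/test partition of the entity set."""

    train_entity_ids: tuple
    test_entity_ids: tuple
    seed: int

    def __post_init__(self):
        if set(self.train_entity_ids) & set(self.test_entity_ids):
            raise ValueError("train and test sets overlap")


def split_train_test(entities, n_test: int, seed: int) -> SplitSpec:
    """Uniform random split into (N - n_test) training and n_test test ids."""
    entities = pd.Index(entities)
    if n_test <= 0:
        raise ValueError(f"n_test must be positive, got {n_test}")
    if n_test >= len(entities):
        raise ValueError(f"n_test ({n_test}) must be < number of entities")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(entities))
    test = entities[np.sort(perm[:n_test])]
    train = entities[np.sort(perm[n_test:])]
    return SplitSpec(tuple(train), tuple(test), seed)


def auroc(scores, labels) -> float:
    """P(score+ > score-) + 0.5 * P(tie); NaN if only one class present."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        logger.warning("AUROC undefined: single-class labels")
        return float("nan")
    return float(roc_auc_score(labels, scores))


def auprc(scores, labels) -> float:
    """Average-precision estimate of the area under the PR curve.

    Descending-score sweep with tied scores grouped; NaN (with a warning)
    when there are no positives.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.sum() == 0:
        logger.warning("AUPRC undefined: no positive labels")
        return float("nan")
    return float(average_precision_score(labels, scores))


def expected_logit(n_annotated: int, n_not_annotated: int) -> float:
    """Prevalence baseline on the logit scale: ln(annotated / not annotated)."""
    if n_annotated <= 0 or n_not_annotated <= 0:
        raise ValueError("both group sizes must be positive")
    return float(np.log(n_annotated / n_not_annotated))


def per_term_metrics(scores: ScoreMatrix, ann: AnnotationSet) -> pd.DataFrame:
    """Per-term AUROC and AUPRC of score columns against annotation columns.

    Rows of ``scores`` are the evaluation entities; columns with missing
    scores or single-class labels yield NaN metrics.
    """
    if not ann.entity_ids.equals(scores.query_ids):
        ann = ann.reindex_entities(scores.query_ids)
    Y = ann.dense()
    counts = ann.term_counts()
    onto = ann.ontologies()
    records = []
    for j, term in enumerate(scores.term_ids):
        s = scores.values[:, j]
        y = Y[:, j]
        ok = np.isfinite(s)
        a = p = float("nan")
        if ok.any() and len(np.unique(y[ok])) == 2:
            a = auroc(s[ok], y[ok])
            p = auprc(s[ok], y[ok])
        records.append(
            {
                "term_id": term,
                "n_annotated": int(counts[j]),
                "ontology": (onto.get(term) if onto is not None else None),
                "auroc": a,
                "auprc": p,
            }
        )
    return pd.DataFrame(records).set_index("term_id")


@dataclass
class EvalReport:
    """Per-term metrics plus overall / size-bin / ontology summaries."""

    per_term: pd.DataFrame
    summary: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary, indent=1))

    def to_tsv(self, path: str | Path) -> None:
        self.per_term.to_csv(path, sep="\t")


def _median(x: pd.Series) -> float:
    x = x.dropna()
    return float(x.median()) if len(x) else float("nan")


def summarize(
    per_term: pd.DataFrame,
    bins=DEFAULT_BINS,
    restricted_range: tuple[int, int] = (20, 300),
) -> EvalReport:
    """Build the evaluation report from a per-term metric table.

    Medians are taken over terms with defined metrics; terms with undefined
    metrics are counted separately.  "Perfect" means AUROC and AUPRC both
    equal one (to PERFECT_TOL).  The restricted medians cover terms with
    restricted_range[0] < n_annotated <= restricted_range[1], a comparison
    convention for methods evaluated only on mid-sized terms.
    """
    t = per_term
    defined = t.dropna(subset=["auroc", "auprc"])
    perfect = defined[
        (defined["auroc"] >= 1 - PERFECT_TOL) & (defined["auprc"] >= 1 - PERFECT_TOL)
    ]
    lo, hi = restricted_range
    restricted = defined[(defined["n_annotated"] > lo) & (defined["n_annotated"] <= hi)]
    summary = {
        "n_terms": int(len(t)),
        "n_terms_undefined": int(len(t) - len(defined)),
        "median_auroc": _median(defined["auroc"]),
        "median_auprc": _median(defined["auprc"]),
        "n_perfect": int(len(perfect)),
        "median_auroc_restricted": _median(restricted["auroc"]),
        "median_auprc_restricted": _median(restricted["auprc"]),
        "by_size_bin": {},
        "by_ontology": {},
    }
    for k, (lo_b, hi_b) in enumerate(bins):
        if k == 0:  # first bin closed on both sides
            mask = (defined["n_annotated"] >= lo_b) & (defined["n_annotated"] <= hi_b)
            label = f"[{lo_b}, {hi_b}]"
        else:
            mask = (defined["n_annotated"] > lo_b) & (defined["n_annotated"] <= hi_b)
            label = f"({lo_b}, {hi_b}]"
        sub = defined[mask]
        summary["by_size_bin"][label] = {
            "n_terms": int(len(sub)),
            "median_auroc": _median(sub["auroc"]),
            "median_auprc": _median(sub["auprc"]),
        }
    if defined["ontology"].notna().any():
        for onto, sub in defined.groupby("ontology"):
            sub_perfect = sub[
                (sub["auroc"] >= 1 - PERFECT_TOL) & (sub["auprc"] >= 1 - PERFECT_TOL)
            ]
            summary["by_ontology"][onto] = {
                "n_terms": int(len(sub)),
                "median_auroc": _median(sub["auroc"]),
                "median_auprc": _median(sub["auprc"]),
                "pct_perfect": 100.0 * len(sub_perfect) / len(sub),
            }
    return EvalReport(per_term=t, summary=summary)
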