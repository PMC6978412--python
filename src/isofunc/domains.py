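"""Per-GO-term domain-based regression.

Each GO term gets an elastic-net regularized logistic regression predicting
term membership from binary Pfam-domain presence.  Coefficients are
constrained to be non-negative (a function should be predicted by the
presence of domains, not their absence) and the penalty strength lambda is
chosen by cross-validated AUROC over a descending 100-value path.

Binary features are deliberately not standardized: presence/absence already
shares a scale, and standardizing would turn absences into (penalized)
negative evidence.  The solver is a warm-started IRLS / coordinate-descent
path (see ``isofunc._enet``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.model_selection import StratifiedKFold

from scipy.stats import rankdata

from ._enet import enet_path_binary
from .datatypes import AnnotationSet, DomainAnnotation, LogitMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DomainModel",
    "fit_domain_models",
    "predict_domain_logits",
    "nonzero_domains",
    "save_domain_models",
    "load_domain_models",
]

N_LAMBDA = 100
LAMBDA_MIN_RATIO = 1e-4


@dataclass
class DomainModel:
    """A fitted per-term non-negative elastic-net logistic model."""

    term_id: str
    intercept: float
    coefficients: pd.Series  # indexed by domain id, all >= 0
    lam: float
    alpha: float
    cv_auroc: float
    folds_used: int
    lambda_path: np.ndarray = field(repr=False)
    cv_trace: np.ndarray = field(repr=False)  # mean out-of-fold AUROC per lambda

    def nonzero(self) -> pd.Series:
        return self.coefficients[self.coefficients > 0]


def _auroc_rows(score_rows: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Mann-Whitney AUROC (mid-rank ties) of each row of scores against y."""
    pos = y == 1
    n1 = int(pos.sum())
    n0 = len(y) - n1
    ranks = rankdata(score_rows, axis=1)
    return (ranks[:, pos].sum(axis=1) - n1 * (n1 + 1) / 2) / (n1 * n0)


def _lambda_path(X, y, alpha, n_lambda=N_LAMBDA, min_ratio=LAMBDA_MIN_RATIO):
    """Descending log-spaced path from the smallest lambda that zeroes every
    (non-negative) coefficient.

    Under the non-negativity constraint only positively associated features
    can activate, so lambda_max = max_j (x_j'(y - ybar))_+ / (n * alpha).
    """
    n = len(y)
    grad0 = np.asarray(X.T @ (y - y.mean())).ravel() / n
    lam_max = float(np.max(grad0)) / max(alpha, 1e-3)
    if lam_max <= 0:
        lam_max = 1e-3  # no domain positively associated; path is nominal
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def fit_domain_models(
    dom: DomainAnnotation,
    ann: AnnotationSet,
    folds: int = 10,
    alpha: float = 0.5,
    seed: int = 0,
    n_lambda: int = N_LAMBDA,
) -> dict[str, DomainModel]:
    """Fit one non-negative elastic-net logistic model per GO term.

    Lambda is selected as the path value maximizing mean out-of-fold AUROC
    over class-stratified folds (largest lambda wins ties), then the model
    is refit on all entities at the selected lambda.  Terms with fewer
    positives than ``folds`` get a reduced fold count with a warning.
    """
    if not dom.entity_ids.equals(ann.entity_ids):
        dom = dom.subset_entities(ann.entity_ids)
    X = dom.pairs.tocsr()
    models: dict[str, DomainModel] = {}
    Y = ann.dense()
    for j, term in enumerate(ann.term_ids):
        y = Y[:, j].astype(float)
        n_pos = int(y.sum())
        if n_pos == 0:
            raise ValueError(f"term {term} has no positive genes")
        k = folds
        if n_pos < folds:
            k = max(2, n_pos)
            logger.warning(
                "term %s has %d positives < %d folds; using %d folds",
                term,
                n_pos,
                folds,
                k,
            )
        lambdas = _lambda_path(X, y, alpha, n_lambda=n_lambda)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        fold_auc = np.full((k, len(lambdas)), np.nan)
        for f, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
            if len(np.unique(y[te])) < 2:
                continue  # single-class fold (possible when positives < 2)
            thetas = enet_path_binary(X[tr], y[tr], lambdas, alpha)
            logits = thetas[:, :1] + thetas[:, 1:] @ X[te].T.toarray()
            fold_auc[f] = _auroc_rows(logits, y[te])
        cv_trace = np.nanmean(fold_auc, axis=0) if np.isfinite(fold_auc).any() else fold_auc[0]
        if np.isnan(cv_trace).all():
            best = 0  # AUROC undefined in every fold: keep the most regularized fit
        else:
            best = int(np.nanargmax(cv_trace))  # first max = largest lambda
        lam = float(lambdas[best])
        theta = enet_path_binary(X, y, lambdas[: best + 1], alpha)[-1]
        coefs = pd.Series(theta[1:], index=dom.domain_ids)
        models[term] = DomainModel(
            term_id=term,
            intercept=float(theta[0]),
            coefficients=coefs.where(coefs > 1e-10, 0.0),
            lam=lam,
            alpha=alpha,
            cv_auroc=float(cv_trace[best]) if not np.isnan(cv_trace).all() else float("nan"),
            folds_used=k,
            lambda_path=lambdas,
            cv_trace=cv_trace,
        )
    return models


def predict_domain_logits(
    models: dict[str, DomainModel], dom: DomainAnnotation
) -> LogitMatrix:
    """logit[q, j] = intercept_j + sum_d coef_{j,d} * presence[q, d].

    Domains known to a model but absent from ``dom`` are treated as absent
    (and logged); extra domains in ``dom`` are ignored.
    """
    terms = pd.Index(models.keys())
    coef = np.zeros((dom.pairs.shape[1], len(terms)))
    intercepts = np.empty(len(terms))
    missing_logged = False
    for j, term in enumerate(terms):
        m = models[term]
        aligned = m.coefficients.reindex(dom.domain_ids)
        lost = m.coefficients.index.difference(dom.domain_ids)
        if len(lost) and not missing_logged:
            logger.warning(
                "%d model domain(s) absent from prediction matrix; treated as absent",
                len(lost),
            )
            missing_logged = True
        intercepts[j] = m.intercept
        coef[:, j] = aligned.fillna(0.0).to_numpy()
    logits = dom.pairs @ coef + intercepts
    return LogitMatrix(dom.entity_ids, terms, logits)


def nonzero_domains(model: DomainModel, top_k: int | None = None) -> list[tuple[str, float]]:
    """Domains with positive coefficients, descending, truncated to top_k."""
    nz = model.nonzero().sort_values(ascending=False)
    if top_k is not None:
        nz = nz.iloc[:top_k]
    return list(nz.items())


# ---------------------------------------------------------------------------
# JSON (de)serialization for the CLI


def save_domain_models(models: dict[str, DomainModel], path: str | Path) -> None:
    payload = []
    for m in models.values():
        nz = m.nonzero()
        payload.append(
            {
                "term_id": m.term_id,
                "intercept": m.intercept,
                "coefficients": {str(k): float(v) for k, v in nz.items()},
                "domain_ids": list(map(str, m.coefficients.index)),
                "lambda": m.lam,
                "alpha": m.alpha,
                "cv_auroc": m.cv_auroc,
                "folds_used": m.folds_used,
            }
        )
    Path(path).write_text(json.dumps(payload, indent=1))


def load_domain_models(path: str | Path) -> dict[str, DomainModel]:
    payload = json.loads(Path(path).read_text())
    models = {}
    for rec in payload:
        domain_ids = pd.Index(rec["domain_ids"])
        coefs = pd.Series(0.0, index=domain_ids)
        for k, v in rec["coefficients"].items():
            coefs[k] = v
        models[rec["term_id"]] = DomainModel(
            term_id=rec["term_id"],
            intercept=rec["intercept"],
            coefficients=coefs,
            lam=rec["lambda"],
            alpha=rec["alpha"],
            cv_auroc=rec["cv_auroc"],
            folds_used=rec["folds_used"],
            lambda_path=np.array([]),
            cv_trace=np.array([]),
        )
    return models
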