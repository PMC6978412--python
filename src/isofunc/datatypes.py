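"""Core in-memory containers for expression, annotation and model-map data.

All containers are thin, validated wrappers around numpy / scipy.sparse /
pandas objects.  Entity identifiers are kept as ordered ``pandas.Index``
objects so that positional matrices and label-based lookup stay in sync.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "AnnotationSet",
    "DomainAnnotation",
    "GeneModelMap",
    "ScoreMatrix",
]

VALID_ONTOLOGIES = ("CC", "MF", "BP")


def _check_unique(ids: pd.Index, what: str) -> pd.Index:
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} id(s): {dup[:5]}")
    return ids


@dataclass(eq=False)
class ExpressionMatrix:
    """Entities (genes or isoforms) x samples matrix of TPM values.

    Values must be finite and non-negative; ids must be unique.
    """

    entity_ids: pd.Index
    sample_ids: pd.Index
    values: np.ndarray

    def __post_init__(self) -> None:
        self.entity_ids = _check_unique(pd.Index(self.entity_ids), "entity")
        self.sample_ids = _check_unique(pd.Index(self.sample_ids), "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.entity_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.entity_ids)} entities x {len(self.sample_ids)} samples"
            )
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at entity {self.entity_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative expression value at entity {self.entity_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.entity_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.index, df.columns, df.to_numpy(dtype=float))

    def subset(self, entity_ids) -> "ExpressionMatrix":
        idx = self.entity_ids.get_indexer(pd.Index(entity_ids))
        if (idx < 0).any():
            missing = pd.Index(entity_ids)[idx < 0].tolist()
            raise KeyError(f"unknown entity id(s): {missing[:5]}")
        return ExpressionMatrix(pd.Index(entity_ids), self.sample_ids, self.values[idx])


@dataclass(eq=False)
class AnnotationSet:
    """Sparse binary entity x GO-term membership with optional term metadata.

    ``term_meta`` is indexed by term id and may carry an ``ontology`` column
    with values in {CC, MF, BP}; it is optional and evaluation degrades
    gracefully without it.
    """

    entity_ids: pd.Index
    term_ids: pd.Index
    pairs: sp.csc_matrix
    term_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.entity_ids = _check_unique(pd.Index(self.entity_ids), "entity")
        self.term_ids = _check_unique(pd.Index(self.term_ids), "term")
        self.pairs = sp.csc_matrix(self.pairs, dtype=np.int8)
        self.pairs.eliminate_zeros()
        if self.pairs.shape != (len(self.entity_ids), len(self.term_ids)):
            raise ValueError(
                f"pair matrix shape {self.pairs.shape} does not match id lists"
            )
        if self.pairs.nnz and not np.all(self.pairs.data == 1):
            raise ValueError("membership matrix must be binary (0/1)")
        if self.term_meta is not None:
            meta = self.term_meta.reindex(self.term_ids)
            if "ontology" in meta:
                bad = meta["ontology"].dropna()
                bad = bad[~bad.isin(VALID_ONTOLOGIES)]
                if len(bad):
                    raise ValueError(
                        f"invalid ontology label(s): {bad.unique().tolist()[:5]}"
                    )
            self.term_meta = meta

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    @property
    def n_terms(self) -> int:
        return len(self.term_ids)

    def term_counts(self) -> np.ndarray:
        """Number of annotated entities per term (column sums)."""
        return np.asarray(self.pairs.sum(axis=0)).ravel().astype(int)

    def ontologies(self) -> pd.Series | None:
        if self.term_meta is None or "ontology" not in self.term_meta:
            return None
        return self.term_meta["ontology"]

    def dense(self) -> np.ndarray:
        return self.pairs.toarray().astype(bool)

    def select_terms(self, mask: np.ndarray) -> "AnnotationSet":
        meta = self.term_meta.loc[self.term_ids[mask]] if self.term_meta is not None else None
        return AnnotationSet(self.entity_ids, self.term_ids[mask], self.pairs[:, mask], meta)

    def subset_entities(self, entity_ids) -> "AnnotationSet":
        idx = self.entity_ids.get_indexer(pd.Index(entity_ids))
        if (idx < 0).any():
            missing = pd.Index(entity_ids)[idx < 0].tolist()
            raise KeyError(f"unknown entity id(s): {missing[:5]}")
        return AnnotationSet(
            pd.Index(entity_ids), self.term_ids, self.pairs[idx, :], self.term_meta
        )

    def reindex_entities(self, entity_ids) -> "AnnotationSet":
        """Align to ``entity_ids``; entities without any recorded pair get an
        all-negative row (sparse pair files omit such rows)."""
        entity_ids = pd.Index(entity_ids)
        idx = self.entity_ids.get_indexer(entity_ids)
        present = (idx >= 0).astype(np.int8)
        rows = self.pairs.tocsr()[idx.clip(min=0)].multiply(present[:, None])
        return AnnotationSet(entity_ids, self.term_ids, sp.csc_matrix(rows), self.term_meta)


@dataclass(eq=False)
class DomainAnnotation:
    """Sparse binary entity x Pfam-domain presence matrix."""

    entity_ids: pd.Index
    domain_ids: pd.Index
    pairs: sp.csc_matrix

    def __post_init__(self) -> None:
        self.entity_ids = _check_unique(pd.Index(self.entity_ids), "entity")
        self.domain_ids = _check_unique(pd.Index(self.domain_ids), "domain")
        self.pairs = sp.csc_matrix(self.pairs, dtype=np.int8)
        self.pairs.eliminate_zeros()
        if self.pairs.shape != (len(self.entity_ids), len(self.domain_ids)):
            raise ValueError(
                f"pair matrix shape {self.pairs.shape} does not match id lists"
            )
        if self.pairs.nnz and not np.all(self.pairs.data == 1):
            raise ValueError("domain matrix must be binary (0/1)")

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    def domain_counts(self) -> np.ndarray:
        return np.asarray(self.pairs.sum(axis=0)).ravel().astype(int)

    def dense(self) -> np.ndarray:
        return self.pairs.toarray().astype(float)

    def select_domains(self, mask: np.ndarray) -> "DomainAnnotation":
        return DomainAnnotation(self.entity_ids, self.domain_ids[mask], self.pairs[:, mask])

    def subset_entities(self, entity_ids) -> "DomainAnnotation":
        idx = self.entity_ids.get_indexer(pd.Index(entity_ids))
        if (idx < 0).any():
            missing = pd.Index(entity_ids)[idx < 0].tolist()
            raise KeyError(f"unknown entity id(s): {missing[:5]}")
        return DomainAnnotation(pd.Index(entity_ids), self.domain_ids, self.pairs[idx, :])


@dataclass(eq=False)
class GeneModelMap:
    """Isoform -> gene mapping with an optional principal-isoform flag.

    At most one principal isoform per gene (the APPRIS-style representative
    transcript).
    """

    isoform_ids: pd.Index
    gene_ids: np.ndarray = field(repr=False)  # aligned with isoform_ids
    principal: np.ndarray = field(repr=False)  # boolean, aligned

    def __post_init__(self) -> None:
        self.isoform_ids = _check_unique(pd.Index(self.isoform_ids), "isoform")
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.principal = np.asarray(self.principal, dtype=bool)
        if len(self.gene_ids) != len(self.isoform_ids) or len(self.principal) != len(
            self.isoform_ids
        ):
            raise ValueError("gene_ids / principal must align with isoform_ids")
        counts = pd.Series(self.principal).groupby(pd.Series(self.gene_ids)).sum()
        multi = counts[counts > 1]
        if len(multi):
            raise ValueError(
                f"gene(s) with more than one principal isoform: {multi.index.tolist()[:5]}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.gene_ids, "principal": self.principal.astype(int)},
            index=self.isoform_ids.rename("isoform_id"),
        )

    def gene_of(self, isoform_id: str) -> str:
        pos = self.isoform_ids.get_loc(isoform_id)
        return self.gene_ids[pos]

    def genes(self) -> pd.Index:
        return pd.Index(pd.unique(self.gene_ids))

    def isoforms_of(self, gene_id: str) -> list[str]:
        return list(self.isoform_ids[self.gene_ids == gene_id])


@dataclass(eq=False)
class ScoreMatrix:
    """Dense query x term matrix of real-valued evidence.

    Used for Wilcoxon z-scores, domain logits and combined logits alike;
    NaN marks a score that could not be computed (degenerate term).
    """

    query_ids: pd.Index
    term_ids: pd.Index
    values: np.ndarray

    def __post_init__(self) -> None:
        self.query_ids = _check_unique(pd.Index(self.query_ids), "query")
        self.term_ids = _check_unique(pd.Index(self.term_ids), "term")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.query_ids), len(self.term_ids)):
            raise ValueError(
                f"score matrix shape {self.values.shape} does not match id lists"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.query_ids, columns=self.term_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScoreMatrix":
        return cls(df.index, df.columns, df.to_numpy(dtype=float))

    def subset_queries(self, query_ids) -> "ScoreMatrix":
        idx = self.query_ids.get_indexer(pd.Index(query_ids))
        if (idx < 0).any():
            missing = pd.Index(query_ids)[idx < 0].tolist()
            raise KeyError(f"unknown query id(s): {missing[:5]}")
        return ScoreMatrix(pd.Index(query_ids), self.term_ids, self.values[idx])


# Role aliases used across the pipeline.
ZScoreMatrix = ScoreMatrix
LogitMatrix = ScoreMatrix
CorrelationMatrix = ScoreMatrix
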