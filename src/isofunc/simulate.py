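"""Fully in-silico datasets with planted coexpression, domain and isoform
structure.

The generative model mirrors the assumptions the predictor exploits:

* every GO term t has a latent per-sample factor f_t ~ N(0, 1); genes
  annotated to t load on it with strength ``rho_signal`` plus independent
  Gaussian noise, so two genes sharing a term have expected latent Pearson
  correlation rho^2 / (rho^2 + noise^2) — a closed form used by the moment
  tests;
* a configurable fraction of terms is "domain-informative": each such term
  owns a dedicated domain present in its annotated genes with a stated
  true-positive rate and in background genes with a false-positive rate;
* every gene spawns isoforms; per-sample isoform usage is a softmax over
  latent usage scores, so isoform TPMs sum exactly to the gene TPM
  (aggregation inverts the generator).  The principal isoform keeps stable
  usage (hence the gene's expression signal) with probability
  ``principal_fidelity`` and keeps all gene domains; alternative isoforms
  have volatile usage and drop domains at ``domain_loss_rate``.

TPM non-negativity comes from a softplus link on the latent expression;
Spearman-based downstream stages are invariant to that monotone transform.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import (
    AnnotationSet,
    DomainAnnotation,
    ExpressionMatrix,
    GeneModelMap,
)
from .io import build_gene_domains

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate_dataset", "worked_example_fixture"]

ONTOLOGIES = ("CC", "MF", "BP")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Defaults are the package's standard in-silico evaluation setting:
    2,000 genes x 300 samples, 60 GO terms of 15-40 genes (inside the
    10-299 annotation filter), mid-strength coexpression signal and 40% of
    terms carrying an informative domain.
    """

    n_genes: int = 2000
    n_samples: int = 300
    n_terms: int = 60
    term_size_range: tuple[int, int] = (15, 40)
    n_domains: int = 120
    rho_signal: float = 0.5
    noise_scale: float = 1.0
    frac_informative_domains: float = 0.4
    domain_tpr: float = 0.9
    domain_fpr: float = 0.01
    mean_extra_isoforms: float = 3.0  # isoforms per gene = 1 + Poisson(mean)
    principal_fidelity: float = 0.95
    domain_loss_rate: float = 0.5
    usage_volatility: float = 2.0  # sd of alternative isoforms' usage scores
    seed: int = 1

    def __post_init__(self):
        if min(self.n_genes, self.n_samples, self.n_terms, self.n_domains) <= 0:
            raise ValueError("all counts must be positive")
        if not (0.0 <= self.rho_signal <= 1.0):
            raise ValueError("rho_signal must be in [0, 1]")
        for name in ("frac_informative_domains", "domain_tpr", "domain_fpr",
                     "principal_fidelity", "domain_loss_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.term_size_range[0] > self.term_size_range[1]:
            raise ValueError("term_size_range must be (lo, hi) with lo <= hi")
        if self.term_size_range[1] > self.n_genes:
            raise ValueError("term sizes cannot exceed the number of genes")


@dataclass
class SimulatedDataset:
    iso_expr: ExpressionMatrix
    gene_expr: ExpressionMatrix
    annotations: AnnotationSet
    gene_domains: DomainAnnotation
    iso_domains: DomainAnnotation
    gene_map: GeneModelMap
    truth: pd.DataFrame
    config: SimulationConfig


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Draw a complete synthetic dataset from ``cfg`` (seed-deterministic)."""
    rng = np.random.default_rng(cfg.seed)
    genes = pd.Index([f"G{i:05d}" for i in range(cfg.n_genes)])
    terms = pd.Index([f"T{j:03d}" for j in range(cfg.n_terms)])
    samples = pd.Index([f"S{s:04d}" for s in range(cfg.n_samples)])

    # --- term membership -------------------------------------------------
    lo, hi = cfg.term_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_terms)
    member_rows, member_cols = [], []
    if sizes.sum() <= cfg.n_genes:
        # disjoint gene modules: keeps the within-term correlation closed form
        pool = rng.permutation(cfg.n_genes)
        start = 0
        for j, size in enumerate(sizes):
            chosen = pool[start : start + size]
            start += size
            member_rows.extend(chosen)
            member_cols.extend([j] * size)
    else:
        for j, size in enumerate(sizes):
            chosen = rng.choice(cfg.n_genes, size=size, replace=False)
            member_rows.extend(chosen)
            member_cols.extend([j] * size)
    pairs = sp.csc_matrix(
        (np.ones(len(member_rows), dtype=np.int8), (member_rows, member_cols)),
        shape=(cfg.n_genes, cfg.n_terms),
    )
    term_meta = pd.DataFrame(
        {"ontology": rng.choice(ONTOLOGIES, size=cfg.n_terms)}, index=terms
    )
    ann = AnnotationSet(genes, terms, pairs, term_meta)

    # --- gene expression --------------------------------------------------
    factors = rng.standard_normal((cfg.n_terms, cfg.n_samples))
    membership = pairs.toarray().astype(float)
    n_member = membership.sum(axis=1)
    loading = membership / np.sqrt(np.maximum(n_member, 1.0))[:, None]
    latent = cfg.rho_signal * (loading @ factors)
    latent += cfg.noise_scale * rng.standard_normal((cfg.n_genes, cfg.n_samples))
    baseline = rng.normal(2.0, 1.0, size=cfg.n_genes)
    gene_values = _softplus(baseline[:, None] + latent)
    gene_expr = ExpressionMatrix(genes, samples, gene_values)

    # --- domains ----------------------------------------------------------
    n_informative = int(round(cfg.frac_informative_domains * cfg.n_terms))
    informative_terms = rng.choice(cfg.n_terms, size=n_informative, replace=False)
    dom_matrix = np.zeros((cfg.n_genes, cfg.n_domains), dtype=np.int8)
    informative_domain_of_term = {}
    d = 0
    for j in informative_terms:
        informative_domain_of_term[int(j)] = d
        members = membership[:, j].astype(bool)
        present = np.zeros(cfg.n_genes, dtype=bool)
        present[members] = rng.random(members.sum()) < cfg.domain_tpr
        present[~members] |= rng.random((~members).sum()) < cfg.domain_fpr
        dom_matrix[present, d] = 1
        d += 1
    # background domains with no functional association
    for k in range(d, cfg.n_domains):
        p = rng.uniform(0.005, 0.08)
        dom_matrix[:, k] = (rng.random(cfg.n_genes) < p).astype(np.int8)
    domains = pd.Index(
        [f"PF{k:04d}" for k in range(cfg.n_domains)]
    )

    # --- isoforms ---------------------------------------------------------
    n_iso_per_gene = 1 + rng.poisson(cfg.mean_extra_isoforms, size=cfg.n_genes)
    iso_ids, iso_gene, principal = [], [], []
    faithful = []
    for i, g in enumerate(genes):
        for k in range(n_iso_per_gene[i]):
            iso_ids.append(f"{g}.{k + 1}")
            iso_gene.append(g)
            principal.append(k == 0)
            faithful.append(k == 0 and rng.random() < cfg.principal_fidelity)
    iso_ids = pd.Index(iso_ids)
    principal = np.array(principal)
    faithful = np.array(faithful)
    gmap = GeneModelMap(iso_ids, np.array(iso_gene, dtype=object), principal)

    # per-sample usage: softmax over latent usage scores; faithful principals
    # get a large stable score, others volatile ones
    iso_values = np.empty((len(iso_ids), cfg.n_samples))
    iso_dom_rows = np.zeros((len(iso_ids), cfg.n_domains), dtype=np.int8)
    pos = 0
    for i in range(cfg.n_genes):
        k = n_iso_per_gene[i]
        scores = cfg.usage_volatility * rng.standard_normal((k, cfg.n_samples))
        if faithful[pos]:
            scores[0] = 2.0 + 0.1 * rng.standard_normal(cfg.n_samples)
        w = np.exp(scores - scores.max(axis=0))
        w /= w.sum(axis=0)
        iso_values[pos : pos + k] = gene_values[i] * w
        gene_doms = dom_matrix[i].astype(bool)
        iso_dom_rows[pos, gene_doms] = 1  # principal keeps all gene domains
        for q in range(1, k):
            kept = gene_doms & (rng.random(cfg.n_domains) >= cfg.domain_loss_rate)
            iso_dom_rows[pos + q, kept] = 1
        pos += k
    iso_expr = ExpressionMatrix(iso_ids, samples, iso_values)
    iso_domains = DomainAnnotation(iso_ids, domains, sp.csc_matrix(iso_dom_rows))
    gene_domains = build_gene_domains(iso_domains, gmap)

    # --- truth table ------------------------------------------------------
    iso_index = np.repeat(np.arange(cfg.n_genes), n_iso_per_gene)
    records = []
    rows, cols = pairs.nonzero()
    term_of_gene: dict[int, list[int]] = {}
    for r, c in zip(rows, cols):
        term_of_gene.setdefault(r, []).append(c)
    for p_iso, g_idx in enumerate(iso_index):
        for j in term_of_gene.get(g_idx, []):
            dom_id = informative_domain_of_term.get(j)
            records.append(
                {
                    "isoform_id": iso_ids[p_iso],
                    "term_id": terms[j],
                    "gene_id": genes[g_idx],
                    "principal": bool(principal[p_iso]),
                    "expression_faithful": bool(faithful[p_iso]),
                    "has_informative_domain": bool(
                        dom_id is not None and iso_dom_rows[p_iso, dom_id]
                    ),
                }
            )
    truth = pd.DataFrame(
        records,
        columns=[
            "isoform_id",
            "term_id",
            "gene_id",
            "principal",
            "expression_faithful",
            "has_informative_domain",
        ],
    )

    return SimulatedDataset(
        iso_expr=iso_expr,
        gene_expr=gene_expr,
        annotations=ann,
        gene_domains=gene_domains,
        iso_domains=iso_domains,
        gene_map=gmap,
        truth=truth,
        config=cfg,
    )


def worked_example_fixture() -> SimulatedDataset:
    """Deterministic micro-dataset (18 genes, 4 terms) for docs and golden
    tests.

    Deliberately exercises awkward code paths: a two-gene term whose
    members lose their own self-correlation evidence (per-row missing
    z-scores), a singleton term that any sensible annotation filter drops,
    a pair of genes with identical expression (tied correlations), and an
    isoform that loses its gene's informative domain.
    """
    cfg = SimulationConfig(
        n_genes=18,
        n_samples=40,
        n_terms=4,
        term_size_range=(1, 6),
        n_domains=8,
        rho_signal=0.8,
        noise_scale=0.5,
        seed=20200123,
    )
    rng = np.random.default_rng(cfg.seed)
    genes = pd.Index([f"G{i:05d}" for i in range(18)])
    terms = pd.Index([f"T{j:03d}" for j in range(4)])
    samples = pd.Index([f"S{s:04d}" for s in range(40)])

    # fixed memberships with sizes {6, 5, 2, 1}
    mat = np.zeros((18, 4), dtype=np.int8)
    mat[0:6, 0] = 1
    mat[6:11, 1] = 1
    mat[11:13, 2] = 1
    mat[13:14, 3] = 1
    meta = pd.DataFrame({"ontology": ["BP", "MF", "CC", "BP"]}, index=terms)
    ann = AnnotationSet(genes, terms, sp.csc_matrix(mat), meta)

    factors = rng.standard_normal((4, 40))
    membership = mat.astype(float)
    n_member = membership.sum(axis=1)
    loading = membership / np.sqrt(np.maximum(n_member, 1.0))[:, None]
    latent = cfg.rho_signal * (loading @ factors)
    latent += cfg.noise_scale * rng.standard_normal((18, 40))
    baseline = rng.normal(2.0, 1.0, size=18)
    gene_values = _softplus(baseline[:, None] + latent)
    gene_values[5] = gene_values[4]  # planted tie: identical expression rows
    gene_expr = ExpressionMatrix(genes, samples, gene_values)

    # domains: PF0000 diagnostic of term 0, PF0001 of term 1, rest background
    dom = np.zeros((18, 8), dtype=np.int8)
    dom[0:6, 0] = 1
    dom[6:11, 1] = 1
    dom[:, 2:] = (rng.random((18, 6)) < 0.2).astype(np.int8)
    domains = pd.Index([f"PF{k:04d}" for k in range(8)])

    # isoforms: genes 0-5 have two isoforms, the rest one; the alternative
    # isoform of gene 0 loses the informative domain PF0000
    iso_ids, iso_gene, principal = [], [], []
    for i, g in enumerate(genes):
        iso_ids.append(f"{g}.1")
        iso_gene.append(g)
        principal.append(True)
        if i < 6:
            iso_ids.append(f"{g}.2")
            iso_gene.append(g)
            principal.append(False)
    iso_ids = pd.Index(iso_ids)
    gmap = GeneModelMap(iso_ids, np.array(iso_gene, dtype=object), np.array(principal))

    iso_values = np.empty((len(iso_ids), 40))
    iso_dom = np.zeros((len(iso_ids), 8), dtype=np.int8)
    for p_iso, (iid, g) in enumerate(zip(iso_ids, iso_gene)):
        i = genes.get_loc(g)
        if principal[p_iso]:
            share = 0.8 if i < 6 else 1.0
            iso_dom[p_iso] = dom[i]
        else:
            share = 0.2
            iso_dom[p_iso] = dom[i]
            if i == 0:
                iso_dom[p_iso, 0] = 0  # lost informative domain
        iso_values[p_iso] = gene_values[i] * share
    iso_expr = ExpressionMatrix(iso_ids, samples, iso_values)
    iso_domains = DomainAnnotation(iso_ids, domains, sp.csc_matrix(iso_dom))
    # gene-level domains stay the union of isoform rows by construction
    gene_domains = DomainAnnotation(genes, domains, sp.csc_matrix(dom))

    truth = pd.DataFrame(
        [
            {
                "isoform_id": "G00000.2",
                "term_id": "T000",
                "gene_id": "G00000",
                "principal": False,
                "expression_faithful": True,
                "has_informative_domain": False,
            }
        ]
    )
    return SimulatedDataset(
        iso_expr=iso_expr,
        gene_expr=gene_expr,
        annotations=ann,
        gene_domains=gene_domains,
        iso_domains=iso_domains,
        gene_map=gmap,
        truth=truth,
        config=cfg,
    )


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["term_size_range"] = list(d["term_size_range"])
    return d
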