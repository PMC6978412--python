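"""Isoform-level inference: identity, gain/loss rules and principal-isoform
consistency."""

import numpy as np
import pandas as pd
import pytest

from isofunc.combine import fit_combination, predict_combined_logits
from isofunc.correlation import spearman_correlation, wilcoxon_zscores
from isofunc.datatypes import (
    DomainAnnotation,
    ExpressionMatrix,
    GeneModelMap,
    ScoreMatrix,
)
from isofunc.domains import fit_domain_models, predict_domain_logits
from isofunc.evaluate import expected_logit
from isofunc.isoforms import (
    gain_loss_calls,
    main_isoform_consistency,
    predict_isoform_functions,
)

from conftest import make_annotations


@pytest.fixture(scope="module")
def gene_models(small_simulated_module):
    ds = small_simulated_module
    corr = spearman_correlation(ds.gene_expr, ds.gene_expr)
    z = wilcoxon_zscores(corr, ds.annotations, exclude_self=True)
    m_dom = fit_domain_models(
        ds.gene_domains, ds.annotations, folds=5, alpha=0.5, seed=1, n_lambda=30
    )
    d = predict_domain_logits(m_dom, ds.gene_domains)
    m_comb = fit_combination(z, d, ds.annotations, seed=1)
    return ds, m_dom, m_comb


@pytest.fixture(scope="module")
def small_simulated_module():
    from isofunc.simulate import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(
        n_genes=250,
        n_samples=60,
        n_terms=10,
        term_size_range=(10, 20),
        n_domains=30,
        mean_extra_isoforms=1.0,
        seed=17,
    )
    return simulate_dataset(cfg)


class TestPredictIsoforms:
    def test_isoform_identical_to_gene_gets_gene_logits(self, gene_models):
        ds, m_dom, m_comb = gene_models
        # build one synthetic isoform per gene, identical to the gene
        iso_ids = pd.Index([f"{g}.x" for g in ds.gene_expr.entity_ids])
        iso_expr = ExpressionMatrix(
            iso_ids, ds.gene_expr.sample_ids, ds.gene_expr.values.copy()
        )
        iso_dom = DomainAnnotation(
            iso_ids, ds.gene_domains.domain_ids, ds.gene_domains.pairs.copy()
        )
        gmap = GeneModelMap(
            iso_ids,
            ds.gene_expr.entity_ids.to_numpy(dtype=object),
            np.ones(len(iso_ids), dtype=bool),
        )
        iso_logits = predict_isoform_functions(
            iso_expr, ds.gene_expr, iso_dom, m_dom, m_comb, ds.annotations, gmap
        )
        # gene-side reference: same models applied to the genes themselves
        corr = spearman_correlation(ds.gene_expr, ds.gene_expr)
        z = wilcoxon_zscores(corr, ds.annotations, exclude_self=True)
        d = predict_domain_logits(m_dom, ds.gene_domains)
        gene_logits = predict_combined_logits(m_comb, z, d)
        mask = np.isfinite(gene_logits.values)
        np.testing.assert_allclose(
            iso_logits.values[mask], gene_logits.values[mask], atol=1e-9
        )

    def test_domainless_isoform_falls_to_intercept_logits(self, gene_models):
        ds, m_dom, m_comb = gene_models
        g = ds.gene_expr.entity_ids[0]
        iso_ids = pd.Index([f"{g}.a", f"{g}.b"])
        import scipy.sparse as sp

        gene_row = ds.gene_domains.pairs[ds.gene_domains.entity_ids.get_loc(g)]
        iso_dom = DomainAnnotation(
            iso_ids,
            ds.gene_domains.domain_ids,
            sp.vstack([gene_row, sp.csr_matrix(gene_row.shape, dtype=np.int8)]).tocsc(),
        )
        d = predict_domain_logits(m_dom, iso_dom)
        intercepts = np.array([m_dom[t].intercept for t in d.term_ids])
        np.testing.assert_allclose(d.values[1], intercepts, atol=1e-12)

    def test_function_losing_isoform_scores_below_principal(self, gene_models):
        """Planted losers (decorrelated expression + dropped domains) rank
        below their faithful sibling for the gene's annotated term."""
        ds, m_dom, m_comb = gene_models
        rng = np.random.default_rng(21)
        ann_dense = ds.annotations.dense()
        annotated_genes = np.flatnonzero(ann_dense.any(axis=1))[:50]
        iso_ids, genes_of, vals, dom_rows = [], [], [], []
        dom_dense = ds.gene_domains.pairs.toarray()
        for gi in annotated_genes:
            g = ds.gene_expr.entity_ids[gi]
            iso_ids += [f"{g}.main", f"{g}.lost"]
            genes_of += [g, g]
            vals.append(ds.gene_expr.values[gi] * 0.7)
            # loser: expression decorrelated from the gene, domains dropped
            vals.append(
                np.exp(rng.normal(1.0, 1.0)) * (1 + rng.random(ds.gene_expr.n_samples))
            )
            dom_rows.append(dom_dense[gi])
            dom_rows.append(np.zeros_like(dom_dense[gi]))
        import scipy.sparse as sp

        iso_expr = ExpressionMatrix(
            pd.Index(iso_ids), ds.gene_expr.sample_ids, np.array(vals)
        )
        iso_dom = DomainAnnotation(
            pd.Index(iso_ids), ds.gene_domains.domain_ids,
            sp.csc_matrix(np.array(dom_rows)),
        )
        gmap = GeneModelMap(
            pd.Index(iso_ids),
            np.array(genes_of, dtype=object),
            np.array([True, False] * len(annotated_genes)),
        )
        logits = predict_isoform_functions(
            iso_expr, ds.gene_expr, iso_dom, m_dom, m_comb, ds.annotations, gmap
        )
        frame = logits.to_frame()
        wins = checks = 0
        for k, gi in enumerate(annotated_genes):
            g = ds.gene_expr.entity_ids[gi]
            for tj in np.flatnonzero(ann_dense[gi]):
                term = ds.annotations.term_ids[tj]
                main = frame.loc[f"{g}.main", term]
                lost = frame.loc[f"{g}.lost", term]
                if np.isnan(main) or np.isnan(lost):
                    continue
                checks += 1
                wins += main > lost
        assert checks >= 40
        assert wins / checks >= 0.95


class TestGainLoss:
    @staticmethod
    def _setup(delta_values, annotated):
        """One isoform, len(delta) terms, constructed so that
        logit - expected_logit equals delta exactly."""
        n_terms = len(delta_values)
        n_genes = 100
        mat = np.zeros((n_genes, n_terms), dtype=int)
        for j, is_ann in enumerate(annotated):
            mat[: (10 if is_ann else 10), j] = 1
        ann = make_annotations(mat)
        # gene G0 annotated (row 0 is 1) where requested
        for j, is_ann in enumerate(annotated):
            if not is_ann:
                ann.pairs = ann.pairs.tolil()
                ann.pairs[0, j] = 0
                ann.pairs[10, j] = 1
                ann.pairs = ann.pairs.tocsc()
        exp = np.array([expected_logit(10, 90)] * n_terms)
        logits = ScoreMatrix(
            pd.Index(["I0"]), ann.term_ids, (exp + np.asarray(delta_values))[None, :]
        )
        gmap = GeneModelMap(
            pd.Index(["I0"]), np.array(["G0"], dtype=object), np.array([True])
        )
        return logits, ann, gmap

    def test_rule_application(self):
        logits, ann, gmap = self._setup([-5.0, 4.0, 0.0], [True, False, True])
        calls = gain_loss_calls(logits, ann, gmap, lower=-3.0, upper=3.0)
        by_term = calls.set_index("term_id")["status"]
        assert by_term["T0"] == "lost"
        assert by_term["T1"] == "gained"
        assert by_term["T2"] == "unchanged"

    def test_threshold_equality_is_unchanged(self):
        logits, ann, gmap = self._setup([-3.0, 3.0], [True, False])
        # thresholds equal to the realized float deltas: strict inequalities
        # mean neither term changes status
        probe = gain_loss_calls(logits, ann, gmap, lower=-100.0, upper=100.0)
        deltas = probe.set_index("term_id")["delta"]
        calls = gain_loss_calls(
            logits, ann, gmap, lower=float(deltas["T0"]), upper=float(deltas["T1"])
        )
        assert (calls["status"] == "unchanged").all()

    def test_lost_requires_annotation_gained_requires_absence(self):
        logits, ann, gmap = self._setup([-5.0, -5.0, 5.0, 5.0],
                                        [True, False, True, False])
        calls = gain_loss_calls(logits, ann, gmap, lower=-3.0, upper=3.0)
        by_term = calls.set_index("term_id")
        assert by_term.loc["T0", "status"] == "lost"
        assert by_term.loc["T1", "status"] == "unchanged"  # not annotated
        assert by_term.loc["T2", "status"] == "unchanged"  # annotated
        assert by_term.loc["T3", "status"] == "gained"

    def test_raising_upper_threshold_shrinks_gained_set(self):
        rng = np.random.default_rng(2)
        deltas = rng.uniform(-8, 8, size=12)
        logits, ann, gmap = self._setup(list(deltas), [False] * 12)
        gained = set()
        for upper in (2.0, 4.0, 6.0):
            calls = gain_loss_calls(logits, ann, gmap, lower=-3.0, upper=upper)
            now = set(calls[calls["status"] == "gained"]["term_id"])
            if gained:
                assert now <= gained
            gained = now

    def test_unmapped_isoform_rejected(self):
        logits, ann, _ = self._setup([0.0], [True])
        bad_map = GeneModelMap(
            pd.Index(["I0"]), np.array(["G999"], dtype=object), np.array([True])
        )
        with pytest.raises(KeyError):
            gain_loss_calls(logits, ann, bad_map, lower=-3.0, upper=3.0)


class TestConsistency:
    @staticmethod
    def _logits(rows, iso_ids, terms=("T0",)):
        return ScoreMatrix(pd.Index(iso_ids), pd.Index(terms), np.asarray(rows, float))

    def test_all_principals_top_fulfils_every_aggregation(self):
        mat = np.zeros((6, 1), dtype=int)
        mat[:3, 0] = 1  # G0..G2 annotated
        ann = make_annotations(np.vstack([mat[:3], np.zeros((0, 1), int)]))
        iso_ids = []
        genes, principal, logit_rows = [], [], []
        for gi in range(3):
            iso_ids += [f"I{gi}a", f"I{gi}b"]
            genes += [f"G{gi}", f"G{gi}"]
            principal += [True, False]
            logit_rows += [[5.0], [1.0]]
        gmap = GeneModelMap(
            pd.Index(iso_ids), np.array(genes, dtype=object), np.array(principal)
        )
        logits = self._logits(logit_rows, iso_ids)
        for agg in ("any-gene", "majority", "all-genes"):
            per_term, summary = main_isoform_consistency(logits, ann, gmap, agg)
            assert summary["n_fulfilled"] == 1
            assert per_term["fraction"].iloc[0] == 1.0

    def test_two_of_three_fulfils_majority_not_all(self):
        mat = np.ones((3, 1), dtype=int)
        ann = make_annotations(mat)
        iso_ids, genes, principal, rows = [], [], [], []
        tops = [True, True, False]
        for gi, top in enumerate(tops):
            iso_ids += [f"I{gi}a", f"I{gi}b"]
            genes += [f"G{gi}", f"G{gi}"]
            principal += [True, False]
            rows += [[5.0 if top else 1.0], [2.0]]
        gmap = GeneModelMap(
            pd.Index(iso_ids), np.array(genes, dtype=object), np.array(principal)
        )
        logits = self._logits(rows, iso_ids)
        assert main_isoform_consistency(logits, ann, gmap, "majority")[1]["n_fulfilled"] == 1
        assert main_isoform_consistency(logits, ann, gmap, "all-genes")[1]["n_fulfilled"] == 0
        assert main_isoform_consistency(logits, ann, gmap, "any-gene")[1]["n_fulfilled"] == 1

    def test_tied_top_counts_principal_as_success(self):
        ann = make_annotations(np.ones((1, 1), dtype=int))
        gmap = GeneModelMap(
            pd.Index(["Ia", "Ib"]),
            np.array(["G0", "G0"], dtype=object),
            np.array([True, False]),
        )
        logits = self._logits([[3.0], [3.0]], ["Ia", "Ib"])
        per_term, summary = main_isoform_consistency(logits, ann, gmap, "all-genes")
        assert summary["n_fulfilled"] == 1

    def test_single_isoform_genes_skipped(self):
        ann = make_annotations(np.ones((1, 1), dtype=int))
        gmap = GeneModelMap(
            pd.Index(["Ia"]), np.array(["G0"], dtype=object), np.array([True])
        )
        logits = self._logits([[3.0]], ["Ia"])
        per_term, summary = main_isoform_consistency(logits, ann, gmap)
        assert summary["n_terms_checked"] == 0
        assert summary["n_terms_skipped"] == 1

    def test_simulated_principals_fulfil_majority(self, gene_models):
        ds, m_dom, m_comb = gene_models
        iso_logits = predict_isoform_functions(
            ds.iso_expr, ds.gene_expr, ds.iso_domains, m_dom, m_comb,
            ds.annotations, ds.gene_map,
        )
        per_term, summary = main_isoform_consistency(
            iso_logits, ds.annotations, ds.gene_map, "majority"
        )
        assert summary["n_terms_checked"] >= 5
        assert summary["fraction_fulfilled"] >= 0.9
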