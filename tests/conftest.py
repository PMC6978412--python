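import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from isofunc.datatypes import AnnotationSet, DomainAnnotation, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_expression(values, prefix="G", samples=None):
    values = np.asarray(values, dtype=float)
    ids = pd.Index([f"{prefix}{i}" for i in range(values.shape[0])])
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(ids, pd.Index(samples), values)


def make_annotations(matrix, prefix="G", term_prefix="T", ontology=None):
    matrix = np.asarray(matrix, dtype=np.int8)
    genes = pd.Index([f"{prefix}{i}" for i in range(matrix.shape[0])])
    terms = pd.Index([f"{term_prefix}{j}" for j in range(matrix.shape[1])])
    meta = None
    if ontology is not None:
        meta = pd.DataFrame({"ontology": ontology}, index=terms)
    return AnnotationSet(genes, terms, sp.csc_matrix(matrix), meta)


def make_domains(matrix, prefix="G", domain_prefix="PF"):
    matrix = np.asarray(matrix, dtype=np.int8)
    genes = pd.Index([f"{prefix}{i}" for i in range(matrix.shape[0])])
    doms = pd.Index([f"{domain_prefix}{j}" for j in range(matrix.shape[1])])
    return DomainAnnotation(genes, doms, sp.csc_matrix(matrix))


@pytest.fixture
def small_simulated():
    """A small but non-trivial simulated dataset shared across tests."""
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
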