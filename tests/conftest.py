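import numpy as np
import pandas as pd
import pytest

import edgeqnet as eq


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at generator defaults (31 samples, 3 planted edges)."""
    return eq.generate_cohort(eq.SynthConfig(seed=101))


@pytest.fixture(scope="session")
def planted_cohort():
    """Larger cohort (n=40) with the default planted structure, plus its
    edge-strength matrix — the workhorse for selection tests."""
    cfg = eq.SynthConfig(n_samples=40, seed=7)
    protein, phospho, relations, responses, truth = eq.generate_cohort(cfg)
    edges = eq.build_edges(relations, protein, phospho)
    matrix = eq.edge_strength(protein, phospho, edges)
    return protein, phospho, relations, responses, truth, edges, matrix


@pytest.fixture()
def tiny_two_state():
    """Hand-built two-layer cohort: 4+4 samples, one kinase, one site."""
    states = np.array([1, 1, 1, 1, 2, 2, 2, 2])
    sample_ids = [f"P{i}" for i in range(8)]
    protein = eq.CohortMatrix(
        sample_ids=sample_ids,
        molecule_ids=["AKT1"],
        values=np.array([[1.0], [2.0], [3.0], [4.0], [10.0], [12.0], [14.0], [16.0]]),
        states=states,
        layer="protein",
    )
    phospho = eq.CohortMatrix(
        sample_ids=sample_ids,
        molecule_ids=["GSK3B_S9"],
        values=np.array([[2.0], [4.0], [6.0], [8.0], [5.0], [4.0], [3.0], [2.0]]),
        states=states,
        layer="phosphosite",
    )
    edge = eq.KinaseSubstrateEdge("AKT1→GSK3B_S9", "AKT1", "GSK3B_S9")
    return protein, phospho, [edge]


def random_cohort_pair(rng, n_samples, n_proteins, n_sites, min_per_state=2):
    """Random two-layer cohort with both states, for property tests."""
    n1 = int(rng.integers(min_per_state, n_samples - min_per_state + 1))
    states = np.array([1] * n1 + [2] * (n_samples - n1))
    sample_ids = [f"S{i}" for i in range(n_samples)]
    protein = eq.CohortMatrix(
        sample_ids=sample_ids,
        molecule_ids=[f"K{i}" for i in range(n_proteins)],
        values=rng.normal(size=(n_samples, n_proteins)),
        states=states,
        layer="protein",
    )
    phospho = eq.CohortMatrix(
        sample_ids=sample_ids,
        molecule_ids=[f"G{i}_S{i+1}" for i in range(n_sites)],
        values=rng.normal(size=(n_samples, n_sites)),
        states=states,
        layer="phosphosite",
    )
    edges = [
        eq.KinaseSubstrateEdge(f"K{i}→G{j}_S{j+1}", f"K{i}", f"G{j}_S{j+1}")
        for i in range(n_proteins)
        for j in range(n_sites)
    ]
    return protein, phospho, edges


@pytest.fixture()
def responses_for():
    def _make(sample_ids, values, drug="drugA"):
        return eq.DrugResponseTable(
            pd.DataFrame({drug: values}, index=pd.Index(list(sample_ids), name="sample_id"))
        )

    return _make
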