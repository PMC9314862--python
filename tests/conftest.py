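import networkx as nx
import numpy as np
import pytest

from bganmda.io_formats import (
    AssociationMatrix,
    DiseaseDagForest,
    EntityIndex,
    SequenceSet,
)
from bganmda.similarity import SimilarityMatrix, SimilarityParams
from bganmda.synthetic_data import SyntheticSpec, gen_dataset


@pytest.fixture(scope="session")
def default_synthetic():
    """The standard planted-block dataset used across the suite."""
    return gen_dataset(SyntheticSpec())


@pytest.fixture(scope="session")
def micro_synthetic():
    """A small dataset for protocols that retrain many times."""
    return gen_dataset(SyntheticSpec(nm=16, nd=10, latent_rank=2, density=0.15,
                                     n_dags=2, seed=7))


@pytest.fixture
def chain_forest():
    """Two-node chain: root r with child c, in one DAG."""
    g = nx.DiGraph()
    g.add_edge("r", "c")
    return DiseaseDagForest({"g1": g})


@pytest.fixture
def three_chain_forest():
    """Three-node chain r -> a -> b in one DAG."""
    g = nx.DiGraph()
    g.add_edges_from([("r", "a"), ("a", "b")])
    return DiseaseDagForest({"g1": g})


@pytest.fixture
def toy_dsn():
    """Hand-specified 3-disease similarity network."""
    idx = EntityIndex(["d1", "d2", "d3"], "disease")
    values = np.array([
        [1.0, 0.6, 0.2],
        [0.6, 1.0, 0.4],
        [0.2, 0.4, 1.0],
    ])
    return SimilarityMatrix(values, idx, "DSN")


@pytest.fixture
def toy_bm():
    """2 miRNAs x 3 diseases: D(m1) = {d1, d2}, D(m2) = {d2, d3}."""
    mirna_index = EntityIndex(["m1", "m2"], "mirna")
    disease_index = EntityIndex(["d1", "d2", "d3"], "disease")
    bm = np.array([  # rows = diseases, cols = miRNAs
        [1, 0],
        [1, 1],
        [0, 1],
    ])
    return AssociationMatrix(bm, disease_index, mirna_index)


@pytest.fixture
def params():
    return SimilarityParams()
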