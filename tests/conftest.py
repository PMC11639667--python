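"""Shared fixtures: tiny deterministic structures, graphs and datasets."""

import numpy as np
import pytest

from funfuse.structure import ContactGraph, ProteinStructure


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_structure(L: int, rng: np.random.Generator, spread: float = 8.0) -> ProteinStructure:
    """Random coordinate cloud with a random sequence (for graph tests)."""
    from funfuse.encodings import AMINO_ACIDS

    seq = "".join(rng.choice(list(AMINO_ACIDS), size=L))
    return ProteinStructure(id=f"rand{L}", sequence=seq,
                            coords=rng.normal(scale=spread, size=(L, 3)))


def random_graph(L: int, rng: np.random.Generator, p: float = 0.35) -> ContactGraph:
    """Erdős–Rényi-style undirected graph on L nodes."""
    iu, iv = np.triu_indices(L, k=1)
    mask = rng.random(iu.size) < p
    return ContactGraph(n_nodes=L, edges=np.vstack([iu[mask], iv[mask]]), theta=10.0)


@pytest.fixture
def tiny_dataset():
    """Small synthetic world shared by training-level tests (12 proteins)."""
    from funfuse.synthetic import SyntheticConfig, make_annotated_dataset

    return make_annotated_dataset(SyntheticConfig(n_proteins=12, seed=7))
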