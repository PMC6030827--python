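import numpy as np
import pytest

from tissuenets.io import GeneSetCollection, GwasResult, Network, canonical_pair


def random_network(rng, n_genes=12, edge_prob=0.5, tissue="t"):
    """Random weighted network without isolated nodes (edge-list representable)."""
    genes = [f"N{i:02d}" for i in range(n_genes)]
    edges = {}
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < edge_prob:
                edges[canonical_pair(genes[i], genes[j])] = round(float(rng.random()), 6)
    nodes = {g for pair in edges for g in pair}
    return Network(tissue=tissue, nodes=nodes, edges=edges)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def star_network():
    """Hub Q with three neighbours of distinct confidence."""
    edges = {
        canonical_pair("Q", "A"): 0.9,
        canonical_pair("Q", "B"): 0.5,
        canonical_pair("Q", "C"): 0.1,
    }
    return Network(tissue="brain", nodes={"Q", "A", "B", "C"}, edges=edges)


@pytest.fixture
def toy_collection():
    return GeneSetCollection(
        name="toy",
        terms={
            "apoptosis": ("prog. cell death", frozenset({"TP53", "BAX", "CASP3"})),
            "transport": ("membrane transport", frozenset({"ABCA1", "SLC1A1"})),
        },
    )


@pytest.fixture
def uniform_gwas():
    rng = np.random.default_rng(7)
    genes = [f"G{i:03d}" for i in range(120)]
    p = rng.uniform(1e-4, 1.0, size=len(genes))
    return GwasResult(study_id="toy", pvalues=dict(zip(genes, p.tolist())))
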