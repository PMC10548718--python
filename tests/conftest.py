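import numpy as np
import pytest

from hesiagraph.embedding import EmbeddingConfig, EmbeddingTable
from hesiagraph.kg import build_kg
from hesiagraph.synthetic import SyntheticConfig, generate

# The 13-edge toy graph: one drug with every drug feature, one disease with
# every disease feature, and the inter-relations connecting them.
TOY_NODES = [
    ("r1", "drug"),
    ("c1", "chemical_substructure"), ("c2", "chemical_substructure"),
    ("t1", "target_protein"), ("d1", "protein_domain"),
    ("s1", "side_effect"), ("a1", "atc_code"),
    ("p1", "disease"), ("g1", "gene"),
    ("cl1", "disease_class"), ("ty1", "disease_type"), ("se1", "semantic_type"),
]

TOY_EDGES = [
    ("r1", "has_chemical_substructure", "c1"),
    ("r1", "has_chemical_substructure", "c2"),
    ("r1", "has_target", "t1"),
    ("r1", "has_domain", "d1"),
    ("t1", "has_domain_target", "d1"),
    ("r1", "has_side_effect", "s1"),
    ("r1", "has_ATC_code", "a1"),
    ("p1", "has_gene", "g1"),
    ("p1", "has_class", "cl1"),
    ("p1", "has_type", "ty1"),
    ("p1", "has_semantic_type", "se1"),
    ("g1", "has_encoded", "t1"),
    ("r1", "has_treatment", "p1"),
]


@pytest.fixture
def toy_kg():
    return build_kg(TOY_NODES, TOY_EDGES, "V1")


@pytest.fixture(scope="session")
def synth_tables():
    """Small planted-signal tables shared across tests."""
    cfg = SyntheticConfig(n_drugs=30, n_diseases=12, n_clusters=3, seed=11)
    return generate(cfg)


@pytest.fixture(scope="session")
def random_table():
    """Handcrafted embedding table over a small drug/disease vocabulary."""
    rng = np.random.default_rng(5)
    tokens = [f"drug:r{i}" for i in range(6)] + [f"disease:p{i}" for i in range(4)]
    vectors = rng.standard_normal((len(tokens), 8))
    return EmbeddingTable(tokens, vectors, EmbeddingConfig(vector_size=8))
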