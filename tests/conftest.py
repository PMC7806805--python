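import numpy as np
import pytest

from foodgraph import (
    Fingerprint,
    NodeRecord,
    NodeType,
    RecipeCorpus,
    build_graph,
)
from foodgraph.synthetic import SyntheticSpec, make_corpus, make_graph_and_fingerprints


def make_fingerprint(rng: np.random.Generator, density: float = 0.1) -> Fingerprint:
    return Fingerprint((rng.random(881) < density).astype(np.uint8))


@pytest.fixture(scope="session")
def tiny_spec() -> SyntheticSpec:
    return SyntheticSpec(
        ingredients_per_community=8,
        compounds_per_community=4,
        n_recipes=300,
        recipe_size=4,
        signal_bits_per_community=20,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_fixture(tiny_spec):
    corpus, cbk = make_corpus(tiny_spec)
    graph, fps, cats, gbk = make_graph_and_fingerprints(tiny_spec, corpus, cbk)
    return {
        "spec": tiny_spec,
        "corpus": corpus,
        "corpus_bookkeeping": cbk,
        "graph": graph,
        "fingerprints": fps,
        "categories": cats,
        "graph_bookkeeping": gbk,
    }


@pytest.fixture()
def small_graph():
    """Hand-built 7-node graph: 2 hubs, 2 non-hubs, 3 compounds."""
    rng = np.random.default_rng(0)
    nodes = [
        NodeRecord("h1", "h1", NodeType.INGREDIENT),
        NodeRecord("h2", "h2", NodeType.INGREDIENT),
        NodeRecord("n1", "n1", NodeType.INGREDIENT),
        NodeRecord("n2", "n2", NodeType.INGREDIENT),
        NodeRecord("c1", "c1", NodeType.FLAVOR_COMPOUND, fingerprint=make_fingerprint(rng)),
        NodeRecord("c2", "c2", NodeType.FLAVOR_COMPOUND, fingerprint=make_fingerprint(rng)),
        NodeRecord("d1", "d1", NodeType.DRUG_COMPOUND, fingerprint=make_fingerprint(rng)),
    ]
    ii = [("h1", "n1", 0.4), ("h1", "n2", 0.2), ("h2", "n1", 0.3), ("h2", "n2", 0.1)]
    ic = [("h1", "c1"), ("h1", "d1"), ("h2", "c1"), ("h2", "c2")]
    return build_graph(nodes, ii, ic)


@pytest.fixture()
def random_corpus():
    rng = np.random.default_rng(11)
    tokens = [f"t{i}" for i in range(12)]
    recipes = []
    for _ in range(200):
        size = int(rng.integers(2, 6))
        recipes.append(frozenset(rng.choice(tokens, size=size, replace=False)))
    return RecipeCorpus(recipes)
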