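"""Deterministic synthetic fixtures: recipe corpora with planted ingredient
communities, matching heterogeneous graphs, and fingerprints whose bit
signatures follow the communities.

The planted premise mirrors real food data: ingredients of the same
category co-occur in recipes and share chemical compounds, and compounds of
one community share a disjoint block of fingerprint bits.  Every generator
is byte-deterministic under its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Set, Tuple, Union

import numpy as np

from . import cooccurrence, io
from .cooccurrence import RecipeCorpus, count_cooccurrence, select_ingredient_edges
from .graph import (
    CATEGORIES,
    FINGERPRINT_BITS,
    Fingerprint,
    HeteroGraph,
    NodeRecord,
    NodeType,
    build_graph,
)


@dataclass
class SyntheticSpec:
    """Knobs for the planted-community generators.

    Defaults are sized so the full pipeline (corpus -> edges -> walks ->
    training -> clustering) runs in minutes on one CPU.
    """

    n_communities: int = 3
    ingredients_per_community: int = 20
    hub_fraction: float = 0.3
    compounds_per_community: int = 10
    n_recipes: int = 600
    recipe_size: int = 6
    within_community_prob: float = 0.9
    cross_community_prob: float = 0.02
    signal_bits_per_community: int = 40
    bit_noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.hub_fraction <= 1.0:
            raise ValueError("hub_fraction must lie in (0, 1]")
        for p in (self.within_community_prob, self.cross_community_prob, self.bit_noise):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_communities * self.signal_bits_per_community > FINGERPRINT_BITS:
            raise ValueError("signal bit blocks must fit in the fingerprint and be disjoint")
        if self.n_communities > len(CATEGORIES):
            raise ValueError(f"at most {len(CATEGORIES)} communities (category labels)")

    def ingredient_token(self, community: int, index: int) -> str:
        return f"ing_c{community}_{index:03d}"

    def compound_token(self, community: int, index: int) -> str:
        return f"cmp_c{community}_{index:03d}"


@dataclass
class CorpusBookkeeping:
    """Ground truth recorded by the corpus generator."""

    community_of: Dict[str, int]
    n_ingredients: int
    n_recipes: int
    home_community: List[int] = field(default_factory=list)


def make_corpus(spec: SyntheticSpec) -> Tuple[RecipeCorpus, CorpusBookkeeping]:
    """Sample recipes with a home community per recipe.

    Each recipe draws ``recipe_size`` distinct ingredients, weighting
    home-community ingredients by ``within_community_prob`` and all others
    by ``cross_community_prob``; with cross probability 0 every recipe is
    single-community.
    """
    rng = np.random.default_rng(spec.seed)
    tokens: List[str] = []
    community_of: Dict[str, int] = {}
    for c in range(spec.n_communities):
        for i in range(spec.ingredients_per_community):
            tok = spec.ingredient_token(c, i)
            tokens.append(tok)
            community_of[tok] = c
    if spec.recipe_size > len(tokens):
        raise ValueError("recipe_size exceeds the number of ingredients")
    communities = np.asarray([community_of[t] for t in tokens])
    recipes: List[frozenset] = []
    homes: List[int] = []
    for _ in range(spec.n_recipes):
        home = int(rng.integers(spec.n_communities))
        weights = np.where(
            communities == home, spec.within_community_prob, spec.cross_community_prob
        ).astype(np.float64)
        if weights.sum() == 0.0:
            raise ValueError("all selection weights are zero")
        probs = weights / weights.sum()
        chosen = rng.choice(len(tokens), size=spec.recipe_size, replace=False, p=probs)
        recipes.append(frozenset(tokens[i] for i in chosen))
        homes.append(home)
    bookkeeping = CorpusBookkeeping(
        community_of=community_of,
        n_ingredients=len(tokens),
        n_recipes=spec.n_recipes,
        home_community=homes,
    )
    return RecipeCorpus(recipes), bookkeeping


@dataclass
class GraphBookkeeping:
    """Ground truth recorded by the graph generator."""

    n_nodes: int
    n_ii_edges: int
    n_if_edges: int
    n_id_edges: int
    hubs: Set[str]
    community_of: Dict[str, int]
    signal_bits: Dict[int, List[int]]


def make_graph_and_fingerprints(
    spec: SyntheticSpec,
    corpus: RecipeCorpus,
    bookkeeping: CorpusBookkeeping,
    min_unigram: int = 20,
    min_joint: int = 5,
    npmi_min: float = 0.25,
    rescue_top_k: int = 20,
) -> Tuple[HeteroGraph, Dict[str, Fingerprint], Dict[str, str], GraphBookkeeping]:
    """Build the heterogeneous graph, fingerprints and category labels.

    Ingredient-ingredient edges come from the co-occurrence pipeline on the
    corpus.  Per community, the first ``ceil(hub_fraction * n)`` ingredients
    become hubs, each linked to every compound of its community; the last
    compound of each community is a drug compound, the rest are flavor
    compounds.  Compound fingerprints set their community's disjoint signal
    bit block to 1 and then flip every bit independently with probability
    ``bit_noise``.  Categories are the community labels.
    """
    rng = np.random.default_rng(spec.seed + 1)
    nodes: List[NodeRecord] = []
    ic_edges: List[Tuple[str, str]] = []
    fingerprints: Dict[str, Fingerprint] = {}
    community_of = dict(bookkeeping.community_of)
    categories: Dict[str, str] = {}
    hubs: Set[str] = set()
    signal_bits: Dict[int, List[int]] = {}

    for c in range(spec.n_communities):
        label = CATEGORIES[c]
        ing_tokens = [
            spec.ingredient_token(c, i) for i in range(spec.ingredients_per_community)
        ]
        for tok in ing_tokens:
            nodes.append(NodeRecord(tok, tok, NodeType.INGREDIENT, category=label))
            categories[tok] = label
        n_hubs = math.ceil(spec.hub_fraction * len(ing_tokens))
        community_hubs = ing_tokens[:n_hubs]
        hubs.update(community_hubs)

        bits_lo = c * spec.signal_bits_per_community
        signal = list(range(bits_lo, bits_lo + spec.signal_bits_per_community))
        signal_bits[c] = signal
        for k in range(spec.compounds_per_community):
            tok = spec.compound_token(c, k)
            ntype = (
                NodeType.DRUG_COMPOUND
                if k == spec.compounds_per_community - 1
                else NodeType.FLAVOR_COMPOUND
            )
            bits = np.zeros(FINGERPRINT_BITS, dtype=np.uint8)
            bits[signal] = 1
            flips = rng.random(FINGERPRINT_BITS) < spec.bit_noise
            bits = np.where(flips, 1 - bits, bits).astype(np.uint8)
            fp = Fingerprint(bits)
            fingerprints[tok] = fp
            community_of[tok] = c
            nodes.append(
                NodeRecord(tok, tok, ntype, category=None, fingerprint=fp)
            )
            for hub in community_hubs:
                ic_edges.append((hub, tok))

    stats = count_cooccurrence(corpus)
    ii_edges = select_ingredient_edges(
        stats,
        min_unigram=min_unigram,
        min_joint=min_joint,
        npmi_min=npmi_min,
        rescue_top_k=rescue_top_k,
    )
    graph = build_graph(nodes, ii_edges, ic_edges)
    gbk = GraphBookkeeping(
        n_nodes=len(nodes),
        n_ii_edges=len(ii_edges),
        n_if_edges=sum(
            1 for _, tok in ic_edges if graph.nodes[tok].node_type is NodeType.FLAVOR_COMPOUND
        ),
        n_id_edges=sum(
            1 for _, tok in ic_edges if graph.nodes[tok].node_type is NodeType.DRUG_COMPOUND
        ),
        hubs=hubs,
        community_of=community_of,
        signal_bits=signal_bits,
    )
    return graph, fingerprints, categories, gbk


PRESETS: Dict[str, SyntheticSpec] = {
    "small": SyntheticSpec(),
    "tiny": SyntheticSpec(
        ingredients_per_community=8,
        compounds_per_community=4,
        n_recipes=300,
        recipe_size=4,
        signal_bits_per_community=20,
    ),
}


def write_fixture_dir(
    spec: SyntheticSpec, out_dir: Union[str, Path]
) -> Dict[str, Path]:
    """Generate a full fixture and write it in the standard CSV dialects."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    corpus, cbk = make_corpus(spec)
    graph, fingerprints, categories, _ = make_graph_and_fingerprints(spec, corpus, cbk)
    paths = {
        "recipes": out_dir / "recipes.txt",
        "nodes": out_dir / "nodes.csv",
        "edges": out_dir / "edges.csv",
        "fingerprints": out_dir / "fingerprints.csv",
    }
    cooccurrence.write_recipes(corpus, paths["recipes"])
    io.write_nodes_csv(sorted(graph.nodes.values(), key=lambda r: r.node_id), paths["nodes"])
    io.write_edges_csv(graph, paths["edges"])
    io.write_fingerprints_csv(fingerprints, paths["fingerprints"])
    return paths
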