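"""Walk-corpus generation: class-constrained metapath walks and uniform walks.

Two built-in metapath schemas route chemical signal through hub ingredients:
compound -> hub -> non-hub -> hub' -> compound' (``CHNHC``) and its mirror
starting and ending at non-hub ingredients (``NHCHN``).  Patterns whose
first and last symbol agree are extended cyclically (the junction symbol is
not duplicated) until the length cap, so a 5-symbol schema yields walks of
up to ``max_len`` nodes.  Plain uniform random walks over all node types
round out the corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .graph import HeteroGraph, NeighborClass

#: Walk-schema symbol -> neighbor class used to filter candidates.
_SYMBOL_CLASS = {
    "C": NeighborClass.ANY_COMPOUND,
    "H": NeighborClass.HUB_INGREDIENT,
    "N": NeighborClass.NONHUB_INGREDIENT,
}

#: Edge families of the graph schema, as unordered symbol pairs.
_CONNECTABLE = {
    frozenset({"C", "H"}),
    frozenset({"H", "N"}),
    frozenset({"H"}),  # hub-hub via ingredient-ingredient edges
    frozenset({"N"}),  # non-hub pairs also share ii edges
}


@dataclass(frozen=True)
class MetapathSchema:
    """An ordered node-class pattern constraining a random walk."""

    name: str
    pattern: Tuple[str, ...]
    distinct_rule: bool = True

    def __post_init__(self) -> None:
        if len(self.pattern) < 2:
            raise ValueError("pattern must have at least 2 symbols")
        for sym in self.pattern:
            if sym not in _SYMBOL_CLASS:
                raise ValueError(f"unknown schema symbol {sym!r}")
        for a, b in zip(self.pattern, self.pattern[1:]):
            if frozenset({a, b}) not in _CONNECTABLE:
                raise ValueError(f"symbols {a}-{b} are not connectable in the graph schema")

    @property
    def period(self) -> Tuple[str, ...]:
        """Repeating unit for cyclic extension (junction symbol dropped)."""
        if self.pattern[0] == self.pattern[-1]:
            return self.pattern[:-1]
        return self.pattern

    def symbol_at(self, position: int) -> str:
        """Class symbol expected at a 0-based walk position."""
        return self.period[position % len(self.period)]


CHNHC = MetapathSchema("CHNHC", ("C", "H", "N", "H", "C"))
NHCHN = MetapathSchema("NHCHN", ("N", "H", "C", "H", "N"))

SCHEMAS: Dict[str, MetapathSchema] = {"CHNHC": CHNHC, "NHCHN": NHCHN}

UNIFORM = "UNIFORM"


@dataclass
class WalkCorpus:
    """Node-token sequences plus a per-walk provenance tag."""

    walks: List[List[str]] = field(default_factory=list)
    provenance: List[str] = field(default_factory=list)
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.walks)

    def append(self, walk: List[str], tag: str) -> None:
        self.walks.append(walk)
        self.provenance.append(tag)


def generate_metapath_walks(
    graph: HeteroGraph,
    schema: MetapathSchema,
    walks_per_start: int = 100,
    max_len: int = 50,
    rng_seed: int = 0,
) -> WalkCorpus:
    """Generate schema-constrained walks from every node of the start class.

    Each step draws uniformly among neighbors of the next class in the
    (cyclically extended) pattern.  With the schema's distinct rule, the
    most recently visited node of the candidate class is excluded; a walk
    terminates early whenever no valid candidate remains — never an error.
    """
    rng = np.random.default_rng(rng_seed)
    corpus = WalkCorpus(seed=rng_seed)
    starts = graph.nodes_of_class(_SYMBOL_CLASS[schema.symbol_at(0)])
    if not starts:
        import warnings

        warnings.warn(f"no start nodes for schema {schema.name}; empty corpus")
        return corpus
    for start in starts:
        for _ in range(walks_per_start):
            corpus.append(_one_metapath_walk(graph, schema, start, max_len, rng), schema.name)
    return corpus


def _one_metapath_walk(
    graph: HeteroGraph,
    schema: MetapathSchema,
    start: str,
    max_len: int,
    rng: np.random.Generator,
) -> List[str]:
    walk = [start]
    last_of_class: Dict[str, str] = {graph.node_class(start): start}
    while len(walk) < max_len:
        symbol = schema.symbol_at(len(walk))
        candidates = graph.neighbors_by_type(walk[-1], _SYMBOL_CLASS[symbol])
        if schema.distinct_rule:
            prev = last_of_class.get(symbol)
            if prev is not None:
                candidates = [c for c in candidates if c != prev]
        if not candidates:
            break
        nxt = candidates[rng.integers(len(candidates))]
        walk.append(nxt)
        last_of_class[symbol] = nxt
    return walk


def generate_uniform_walks(
    graph: HeteroGraph,
    walks_per_start: int = 100,
    max_len: int = 50,
    rng_seed: int = 0,
) -> WalkCorpus:
    """Plain random walks from every node, uniform over all neighbors."""
    if not graph.nodes:
        raise ValueError("empty graph")
    rng = np.random.default_rng(rng_seed)
    corpus = WalkCorpus(seed=rng_seed)
    for start in sorted(graph.nodes):
        for _ in range(walks_per_start):
            walk = [start]
            while len(walk) < max_len:
                candidates = graph.neighbors(walk[-1])
                if not candidates:
                    break
                walk.append(candidates[rng.integers(len(candidates))])
            corpus.append(walk, UNIFORM)
    return corpus


def merge_corpora(corpora: Sequence[WalkCorpus], rng_seed: int = 0) -> WalkCorpus:
    """Concatenate corpora and shuffle deterministically under the seed."""
    merged = WalkCorpus(seed=rng_seed)
    for corpus in corpora:
        for walk, tag in zip(corpus.walks, corpus.provenance):
            merged.append(walk, tag)
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(merged.walks))
    merged.walks = [merged.walks[i] for i in order]
    merged.provenance = [merged.provenance[i] for i in order]
    return merged


def validate_walk(walk: Sequence[str], schema: MetapathSchema, graph: HeteroGraph) -> bool:
    """True iff every step is a graph edge and classes follow the schema."""
    if not walk:
        return False
    for position, node in enumerate(walk):
        if node not in graph:
            return False
        if graph.node_class(node) != schema.symbol_at(position):
            return False
    for a, b in zip(walk, walk[1:]):
        if b not in graph._adj.get(a, ()):
            return False
    return True


def write_walks(corpus: WalkCorpus, path: Union[str, Path]) -> None:
    """One walk per line, space-separated; provenance and seed in comments."""
    with open(path, "w") as fh:
        fh.write(f"#seed={corpus.seed}\n")
        for walk, tag in zip(corpus.walks, corpus.provenance):
            fh.write(f"#schema={tag}\n")
            fh.write(" ".join(walk) + "\n")


def read_walks(path: Union[str, Path]) -> WalkCorpus:
    corpus = WalkCorpus()
    tag = UNIFORM
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#seed="):
                corpus.seed = int(line.split("=", 1)[1]) if line != "#seed=None" else None
            elif line.startswith("#schema="):
                tag = line.split("=", 1)[1]
            elif not line.startswith("#"):
                corpus.append(line.split(), tag)
    return corpus
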