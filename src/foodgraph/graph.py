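"""Typed heterogeneous graph of food ingredients and chemical compounds.

Three node types (ingredients, flavor compounds, drug compounds) and three
edge families: weighted ingredient-ingredient edges (co-occurrence scores),
and unweighted ingredient-compound edges split by compound type.  Ingredient
nodes that touch at least one compound are flagged as *hubs*; the remaining
ingredients only receive chemical signal transitively through hubs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

#: Length of the binary substructure fingerprint attached to compounds.
FINGERPRINT_BITS = 881

#: The nine food category labels used by evaluation.
CATEGORIES: Tuple[str, ...] = (
    "Bakery/Dessert/Snack",
    "Beverage Alcoholic",
    "Cereal/Crop/Bean",
    "Dairy",
    "Fruit",
    "Meat/Animal Product",
    "Plant/Vegetable",
    "Seafood",
    "Others",
)


class NodeType(str, enum.Enum):
    INGREDIENT = "ingredient"
    FLAVOR_COMPOUND = "flavor_compound"
    DRUG_COMPOUND = "drug_compound"


COMPOUND_TYPES = frozenset({NodeType.FLAVOR_COMPOUND, NodeType.DRUG_COMPOUND})


class NeighborClass(str, enum.Enum):
    """Node classes selectable when filtering neighbors or walk candidates."""

    FLAVOR_COMPOUND = "flavor_compound"
    DRUG_COMPOUND = "drug_compound"
    ANY_COMPOUND = "any_compound"
    HUB_INGREDIENT = "hub_ingredient"
    NONHUB_INGREDIENT = "nonhub_ingredient"
    ANY_INGREDIENT = "any_ingredient"


class GraphError(ValueError):
    """Raised on malformed graph inputs (unknown ids, type-violating edges)."""


class Fingerprint:
    """An 881-bit presence/absence vector for one chemical compound.

    Each bit flags whether a particular molecular substructure occurs in the
    compound.  Stored as a uint8 array; immutable by convention.
    """

    __slots__ = ("bits",)

    def __init__(self, bits: Iterable[int]) -> None:
        arr = np.asarray(list(bits) if not isinstance(bits, np.ndarray) else bits,
                         dtype=np.uint8)
        if arr.ndim != 1 or arr.shape[0] != FINGERPRINT_BITS:
            raise ValueError(
                f"fingerprint must have exactly {FINGERPRINT_BITS} bits, "
                f"got {arr.shape}"
            )
        if not np.all((arr == 0) | (arr == 1)):
            raise ValueError("fingerprint bits must be 0 or 1")
        arr.setflags(write=False)
        self.bits = arr

    @classmethod
    def from_string(cls, s: str) -> "Fingerprint":
        if len(s) != FINGERPRINT_BITS or set(s) - {"0", "1"}:
            raise ValueError(
                f"fingerprint string must be {FINGERPRINT_BITS} chars of 0/1, "
                f"got length {len(s)}"
            )
        return cls(np.frombuffer(s.encode("ascii"), dtype=np.uint8) - ord("0"))

    def to_string(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Fingerprint) and bool(
            np.array_equal(self.bits, other.bits)
        )

    def __hash__(self) -> int:
        return hash(self.bits.tobytes())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Fingerprint(popcount={int(self.bits.sum())})"


@dataclass
class NodeRecord:
    """A single node: id token, display name, type, optional category label.

    ``is_hub`` is derived (ingredient with >=1 compound edge) and only
    meaningful for ingredients; ``fingerprint`` attaches to compound nodes.
    """

    node_id: str
    name: str
    node_type: NodeType
    category: Optional[str] = None
    is_hub: bool = False
    fingerprint: Optional[Fingerprint] = None

    def __post_init__(self) -> None:
        self.node_type = NodeType(self.node_type)
        if self.category is not None and self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r} for node {self.node_id!r}"
            )


def canonical_pair(a: str, b: str) -> Tuple[str, str]:
    """Unordered pair key: lexicographically smaller id first."""
    return (a, b) if a <= b else (b, a)


@dataclass
class HeteroGraph:
    """Container for nodes plus the three edge families.

    ``edges_ii`` maps canonical ingredient pairs to their co-occurrence
    weight; ``edges_if`` / ``edges_id`` hold (ingredient, compound) pairs.
    """

    nodes: Dict[str, NodeRecord] = field(default_factory=dict)
    edges_ii: Dict[Tuple[str, str], float] = field(default_factory=dict)
    edges_if: Set[Tuple[str, str]] = field(default_factory=set)
    edges_id: Set[Tuple[str, str]] = field(default_factory=set)
    _adj: Dict[str, Set[str]] = field(default_factory=dict, repr=False)

    # -- queries ---------------------------------------------------------

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    def node_class(self, node_id: str) -> str:
        """Walk-schema class of a node: 'C' compound, 'H' hub, 'N' non-hub."""
        rec = self._require(node_id)
        if rec.node_type in COMPOUND_TYPES:
            return "C"
        return "H" if rec.is_hub else "N"

    def neighbors(self, node_id: str) -> List[str]:
        """Sorted neighbor ids over all edge families."""
        self._require(node_id)
        return sorted(self._adj.get(node_id, ()))

    def neighbors_by_type(self, node_id: str, wanted: NeighborClass) -> List[str]:
        """Sorted, deduplicated neighbors restricted to a node class."""
        self._require(node_id)
        wanted = NeighborClass(wanted)
        out = [n for n in self._adj.get(node_id, ()) if self._matches(n, wanted)]
        return sorted(out)

    def _matches(self, node_id: str, wanted: NeighborClass) -> bool:
        rec = self.nodes[node_id]
        t = rec.node_type
        if wanted is NeighborClass.FLAVOR_COMPOUND:
            return t is NodeType.FLAVOR_COMPOUND
        if wanted is NeighborClass.DRUG_COMPOUND:
            return t is NodeType.DRUG_COMPOUND
        if wanted is NeighborClass.ANY_COMPOUND:
            return t in COMPOUND_TYPES
        if wanted is NeighborClass.ANY_INGREDIENT:
            return t is NodeType.INGREDIENT
        if wanted is NeighborClass.HUB_INGREDIENT:
            return t is NodeType.INGREDIENT and rec.is_hub
        if wanted is NeighborClass.NONHUB_INGREDIENT:
            return t is NodeType.INGREDIENT and not rec.is_hub
        raise GraphError(f"unknown neighbor class {wanted!r}")

    def nodes_of_class(self, wanted: NeighborClass) -> List[str]:
        """All node ids matching a class filter, sorted."""
        wanted = NeighborClass(wanted)
        return sorted(n for n in self.nodes if self._matches(n, wanted))

    def compound_set(self, ingredient_id: str) -> Set[str]:
        """Compound neighbors of an ingredient (its chemical profile)."""
        return set(self.neighbors_by_type(ingredient_id, NeighborClass.ANY_COMPOUND))

    def _require(self, node_id: str) -> NodeRecord:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise GraphError(f"unknown node id {node_id!r}") from None

    # -- mutation used by the builder -----------------------------------

    def _link(self, a: str, b: str) -> None:
        self._adj.setdefault(a, set()).add(b)
        self._adj.setdefault(b, set()).add(a)


def classify_hubs(graph: HeteroGraph) -> HeteroGraph:
    """Set ``is_hub`` on every ingredient with >=1 compound edge (in place).

    Pure function of compound-edge incidence; idempotent.
    """
    hub_ids = {i for i, _ in graph.edges_if} | {i for i, _ in graph.edges_id}
    for rec in graph.nodes.values():
        rec.is_hub = rec.node_type is NodeType.INGREDIENT and rec.node_id in hub_ids
    return graph


def build_graph(
    nodes: Sequence[NodeRecord],
    ii_edges: Iterable[Tuple[str, str, float]] = (),
    ic_edges: Iterable[Tuple[str, str]] = (),
) -> HeteroGraph:
    """Assemble and validate a :class:`HeteroGraph`.

    Parameters
    ----------
    nodes
        Node records; ids must be unique.
    ii_edges
        ``(ingredient, ingredient, weight)`` triples; stored unordered with
        canonical orientation (weights are symmetric scores).
    ic_edges
        ``(ingredient, compound)`` pairs; the compound's node type decides
        whether the edge lands in ``edges_if`` or ``edges_id``.

    Raises
    ------
    GraphError
        On duplicate node ids, unknown edge endpoints, self-loops, or edges
        violating the type schema.
    """
    g = HeteroGraph()
    for rec in nodes:
        if rec.node_id in g.nodes:
            raise GraphError(f"duplicate node id {rec.node_id!r}")
        g.nodes[rec.node_id] = rec

    for u, v, w in ii_edges:
        ru, rv = g._require(u), g._require(v)
        if u == v:
            raise GraphError(f"self-loop on {u!r}")
        if ru.node_type is not NodeType.INGREDIENT or rv.node_type is not NodeType.INGREDIENT:
            raise GraphError(f"ii edge endpoints must be ingredients: ({u!r}, {v!r})")
        g.edges_ii[canonical_pair(u, v)] = float(w)
        g._link(u, v)

    for u, v in ic_edges:
        ru, rv = g._require(u), g._require(v)
        if ru.node_type is not NodeType.INGREDIENT or rv.node_type not in COMPOUND_TYPES:
            raise GraphError(
                f"ingredient-compound edge must be (ingredient, compound): ({u!r}, {v!r})"
            )
        target = g.edges_if if rv.node_type is NodeType.FLAVOR_COMPOUND else g.edges_id
        target.add((u, v))
        g._link(u, v)

    return classify_hubs(g)
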