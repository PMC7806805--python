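"""Recipe co-occurrence counts, PMI / NPMI scoring, and edge selection.

PMI is ``ln p(x,y) / (p(x) p(y))`` with probabilities estimated as recipe
fractions; NPMI divides by ``-ln p(x,y)`` which bounds the score in [-1, 1]:
-1 never together, 0 independent, +1 perfectly co-occurring.  Ingredient
pairs become graph edges when they pass at least one of three filters
(raw-count floor, NPMI threshold, or a fixed-size rescue of the best
sub-threshold pairs).
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Tuple, Union

from .graph import canonical_pair

Pair = Tuple[str, str]


@dataclass
class RecipeCorpus:
    """A list of recipes, each a set of ingredient tokens."""

    recipes: List[FrozenSet[str]] = field(default_factory=list)

    @property
    def n_recipes(self) -> int:
        return len(self.recipes)

    @classmethod
    def from_iterable(cls, recipes: Iterable[Iterable[str]]) -> "RecipeCorpus":
        return cls([frozenset(r) for r in recipes])


def read_recipes(path: Union[str, Path], delim: str = "auto") -> RecipeCorpus:
    """Read a recipes file: one recipe per line, tokens space- or
    comma-separated.  ``delim='auto'`` sniffs commas on the first
    non-empty line; pass ``' '`` or ``','`` to force."""
    recipes: List[FrozenSet[str]] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if delim == "auto":
        delim = "," if lines and "," in lines[0] else " "
    for ln in lines:
        tokens = [t.strip() for t in ln.split(delim) if t.strip()]
        recipes.append(frozenset(tokens))
    return RecipeCorpus(recipes)


def write_recipes(corpus: RecipeCorpus, path: Union[str, Path], delim: str = " ") -> None:
    with open(path, "w") as fh:
        for recipe in corpus.recipes:
            fh.write(delim.join(sorted(recipe)) + "\n")


@dataclass
class CooccurrenceStats:
    """Unigram and joint recipe counts backing the probability estimates."""

    n_recipes: int
    unigram: Dict[str, int]
    joint: Dict[Pair, int]

    def p(self, x: str) -> float:
        return self.unigram[x] / self.n_recipes

    def p_joint(self, x: str, y: str) -> float:
        return self.joint.get(canonical_pair(x, y), 0) / self.n_recipes

    def joint_count(self, x: str, y: str) -> int:
        return self.joint.get(canonical_pair(x, y), 0)

    def _require(self, token: str) -> None:
        if self.unigram.get(token, 0) <= 0:
            raise KeyError(f"token {token!r} has no occurrences")


def count_cooccurrence(corpus: RecipeCorpus) -> CooccurrenceStats:
    """Count, per token, the recipes containing it and, per unordered pair,
    the recipes containing both.  Rejects an empty corpus."""
    if corpus.n_recipes == 0:
        raise ValueError("empty corpus")
    unigram: Counter = Counter()
    joint: Counter = Counter()
    for recipe in corpus.recipes:
        tokens = sorted(recipe)
        unigram.update(tokens)
        joint.update(itertools.combinations(tokens, 2))
    return CooccurrenceStats(corpus.n_recipes, dict(unigram), dict(joint))


def pmi(stats: CooccurrenceStats, x: str, y: str) -> float:
    """Pointwise mutual information in nats; ``-inf`` when the pair never
    co-occurs (callers must handle)."""
    stats._require(x)
    stats._require(y)
    p_xy = stats.p_joint(x, y)
    if p_xy == 0.0:
        return -math.inf
    return math.log(p_xy / (stats.p(x) * stats.p(y)))


def npmi(stats: CooccurrenceStats, x: str, y: str) -> float:
    """Normalized PMI in [-1, 1].

    Conventions: joint count 0 -> -1 (limit value); joint probability 1
    (pair present in every recipe) -> +1 with a warning, since the
    ``-ln p(x,y)`` normalizer vanishes.
    """
    stats._require(x)
    stats._require(y)
    p_xy = stats.p_joint(x, y)
    if p_xy == 0.0:
        return -1.0
    if p_xy == 1.0:
        warnings.warn(
            f"pair ({x!r}, {y!r}) occurs in every recipe; NPMI denominator is 0, "
            "returning 1 by limit convention"
        )
        return 1.0
    value = pmi(stats, x, y) / (-math.log(p_xy))
    return max(-1.0, min(1.0, value))


def select_ingredient_edges(
    stats: CooccurrenceStats,
    min_unigram: int = 20,
    min_joint: int = 5,
    npmi_min: float = 0.25,
    rescue_top_k: int = 20,
) -> List[Tuple[str, str, float]]:
    """Select ingredient-ingredient edges; each carries its NPMI weight.

    A pair is kept when it satisfies at least one of:

    A. both tokens appear in more than ``min_unigram`` recipes and the pair
       co-occurs in more than ``min_joint`` (strict inequalities);
    B. its NPMI is at least ``npmi_min``;
    C. it ranks in the global top ``rescue_top_k`` by NPMI among pairs below
       the ``npmi_min`` threshold (ties broken by canonical pair id).

    The candidate universe is every unordered pair of observed tokens, so
    this is quadratic in the vocabulary; intended for filtered vocabularies.
    Output is deduplicated and sorted by canonical pair id.
    """
    tokens = sorted(stats.unigram)
    selected: Dict[Pair, float] = {}
    below: List[Tuple[float, Pair]] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for x, y in itertools.combinations(tokens, 2):
            score = npmi(stats, x, y)
            pair = (x, y)
            rule_a = (
                stats.unigram[x] > min_unigram
                and stats.unigram[y] > min_unigram
                and stats.joint_count(x, y) > min_joint
            )
            if rule_a or score >= npmi_min:
                selected[pair] = score
            if score < npmi_min:
                below.append((score, pair))
    below.sort(key=lambda item: (-item[0], item[1]))
    for score, pair in below[:rescue_top_k]:
        selected.setdefault(pair, score)
    return [(x, y, selected[(x, y)]) for x, y in sorted(selected)]
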