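"""Downstream evaluation: clustering, similarity search, pairing queries,
category Jaccard profiles, and thresholded relation prediction."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import normalized_mutual_info_score, roc_auc_score

from .embedding import EmbeddingModel
from .graph import Fingerprint

Edge = Tuple[str, str]


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two non-zero vectors, in [-1, 1]."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def pairing_query(
    model: EmbeddingModel,
    query_tokens: Sequence[str],
    k: int,
    candidates: Optional[Iterable[str]] = None,
) -> List[Tuple[str, float]]:
    """Rank candidate tokens by cosine similarity to the summed query vector.

    The query vector is the element-wise sum of the tokens' center vectors.
    ``candidates`` restricts the searched tokens (e.g. to non-hub
    ingredients); by default the whole vocabulary is searched and query
    tokens are *not* excluded.  Ties break by token id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    for tok in query_tokens:
        if tok not in model:
            raise KeyError(f"query token {tok!r} not in vocabulary")
    query = np.sum([model.vector(t) for t in query_tokens], axis=0)
    pool = sorted(candidates) if candidates is not None else model.tokens
    scored = []
    for tok in pool:
        if tok not in model:
            raise KeyError(f"candidate token {tok!r} not in vocabulary")
        scored.append((tok, cosine_similarity(query, model.vector(tok))))
    scored.sort(key=lambda item: (-item[1], item[0]))
    return scored[:k]


@dataclass
class ClusteringResult:
    assignments: Dict[str, int]
    nmi: float
    k: int
    seed: int


def cluster_and_score(
    model: EmbeddingModel,
    labeled_nodes: Mapping[str, str],
    k: int = 9,
    n_init: int = 10,
    seed: int = 0,
) -> ClusteringResult:
    """K-means over the labeled nodes' center vectors, scored by NMI.

    NMI uses arithmetic-mean normalization, ``2 I(A;B) / (H(A) + H(B))``,
    scaled to [0, 1].
    """
    tokens = sorted(labeled_nodes)
    if len(tokens) < k:
        raise ValueError(f"need at least k={k} labeled nodes, got {len(tokens)}")
    X = np.stack([model.vector(t) for t in tokens])
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    pred = km.fit_predict(X)
    truth = [labeled_nodes[t] for t in tokens]
    nmi = float(
        normalized_mutual_info_score(truth, pred, average_method="arithmetic")
    )
    return ClusteringResult(dict(zip(tokens, (int(p) for p in pred))), nmi, k, seed)


def jaccard_category_matrix(
    compound_sets: Mapping[str, Set[str]],
    categories: Mapping[str, str],
) -> Tuple[List[str], np.ndarray]:
    """Mean pairwise Jaccard similarity of chemical profiles between (and
    within) categories.

    Entry (g, h) averages ``|C_i & C_j| / |C_i | C_j|`` over all pairs with
    i in g, j in h and i != j.  Undefined entries (no such pair) are NaN.
    Every node must have a non-empty compound set and a category.
    """
    for node, cset in compound_sets.items():
        if not cset:
            raise ValueError(f"node {node!r} has an empty compound set")
        if node not in categories:
            raise ValueError(f"node {node!r} has no category")
    cats = sorted(set(categories[n] for n in compound_sets))
    by_cat: Dict[str, List[str]] = {c: [] for c in cats}
    for node in sorted(compound_sets):
        by_cat[categories[node]].append(node)
    matrix = np.full((len(cats), len(cats)), np.nan)
    for gi, g in enumerate(cats):
        for hi, h in enumerate(cats):
            if hi < gi:
                continue
            values = []
            for i in by_cat[g]:
                for j in by_cat[h]:
                    if i == j:
                        continue
                    ci, cj = compound_sets[i], compound_sets[j]
                    values.append(len(ci & cj) / len(ci | cj))
            if values:
                matrix[gi, hi] = matrix[hi, gi] = float(np.mean(values))
    return cats, matrix


def predict_relations(
    model: EmbeddingModel,
    compound_tokens: Sequence[str],
    food_tokens: Sequence[str],
    threshold: float,
) -> Set[Edge]:
    """Predict (compound, food) edges whose cosine similarity meets the
    threshold; monotone in ``threshold``."""
    for tok in list(compound_tokens) + list(food_tokens):
        if tok not in model:
            raise KeyError(f"token {tok!r} not in vocabulary")
    predicted: Set[Edge] = set()
    for c in compound_tokens:
        vc = model.vector(c)
        for f in food_tokens:
            if cosine_similarity(vc, model.vector(f)) >= threshold:
                predicted.add((c, f))
    return predicted


def calibrate_threshold(
    model: EmbeddingModel,
    compound_tokens: Sequence[str],
    food_tokens: Sequence[str],
    gold: Set[Edge],
    grid: Optional[Sequence[float]] = None,
) -> float:
    """Pick the F1-maximizing similarity threshold on a labeled split."""
    scores = sorted(
        cosine_similarity(model.vector(c), model.vector(f))
        for c in compound_tokens
        for f in food_tokens
    )
    grid = grid if grid is not None else scores
    best_t, best_f1 = 1.0, -1.0
    for t in grid:
        pred = predict_relations(model, compound_tokens, food_tokens, t)
        tp = len(pred & gold)
        p = tp / len(pred) if pred else 0.0
        r = tp / len(gold) if gold else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        if f1 > best_f1:
            best_t, best_f1 = t, f1
    return best_t


@dataclass
class RelationPredictionEval:
    n_gold: int
    n_pred: int
    tp: int
    fp_unknown: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "n_gold": self.n_gold,
            "n_pred": self.n_pred,
            "tp": self.tp,
            "fp_unknown": self.fp_unknown,
            "fn": self.fn,
            "tn": self.tn,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mcc": self.mcc,
        }


def confusion_metrics(
    predicted: Set[Edge], gold: Set[Edge], candidate_universe: Set[Edge]
) -> RelationPredictionEval:
    """Confusion counts and derived metrics over an explicit edge universe.

    The universe supplies the denominator for true negatives; accuracy and
    MCC are only meaningful relative to it.  MCC is 0 by convention when any
    factor of its denominator vanishes.
    """
    if not candidate_universe:
        raise ValueError("candidate universe must be non-empty")
    if not predicted <= candidate_universe or not gold <= candidate_universe:
        raise ValueError("predicted and gold sets must lie within the universe")
    tp = len(predicted & gold)
    fp = len(predicted - gold)
    fn = len(gold - predicted)
    tn = len(candidate_universe) - tp - fp - fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    accuracy = (tp + tn) / len(candidate_universe)
    return RelationPredictionEval(
        n_gold=len(gold),
        n_pred=len(predicted),
        tp=tp,
        fp_unknown=fp,
        fn=fn,
        tn=tn,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        mcc=mcc,
    )


def head_fingerprint_auc(
    model: EmbeddingModel,
    fingerprints: Mapping[str, Fingerprint],
    bits: Optional[Sequence[int]] = None,
) -> float:
    """Mean per-bit AUC of the chemical head's predictions on the given
    compounds.

    Intended for compounds whose fingerprints were *held out* of training:
    it then measures how well chemical structure generalizes through the
    embedding geometry to unlabeled nodes.  Without a trained head
    (``lambda == 0``) predictions are uninformative and the AUC is 0.5.
    """
    tokens = sorted(t for t in fingerprints if t in model)
    if len(tokens) < 2:
        raise ValueError("need at least 2 labeled tokens")
    P = np.stack([model.predict_fingerprint(t) for t in tokens])
    Y = np.stack([fingerprints[t].bits for t in tokens]).astype(np.float64)
    bit_idx = range(Y.shape[1]) if bits is None else bits
    aucs = []
    for d in bit_idx:
        col = Y[:, d]
        if col.min() == col.max():
            continue
        aucs.append(roc_auc_score(col, P[:, d]))
    if not aucs:
        raise ValueError("no fingerprint bit shows both classes")
    return float(np.mean(aucs))


def fingerprint_reconstruction_auc(
    model: EmbeddingModel,
    fingerprints: Mapping[str, Fingerprint],
    bits: Optional[Sequence[int]] = None,
) -> float:
    """Mean per-bit AUC of leave-one-out fingerprint reconstruction.

    Each labeled compound's bit is scored by a similarity-weighted vote of
    the other compounds' bits (weights ``(cos + 1) / 2`` from the center
    vectors), relative to the exchangeable baseline ``(m - y_i) / (n - 1)``
    (the leave-one-out mean the node would see if geometry carried no
    information; subtracting it removes the composition bias of excluding
    one's own label).  AUC is computed per bit over compounds and averaged
    over bits showing both classes.  Measures how much chemical structure
    the embedding geometry carries, independent of the trained head.
    """
    tokens = sorted(t for t in fingerprints if t in model)
    if len(tokens) < 3:
        raise ValueError("need at least 3 labeled tokens")
    X = np.stack([model.vector(t) for t in tokens])
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero embedding vector among labeled tokens")
    sims = (X @ X.T) / np.outer(norms, norms)
    weights = (sims + 1.0) / 2.0
    np.fill_diagonal(weights, 0.0)
    Y = np.stack([fingerprints[t].bits for t in tokens]).astype(np.float64)
    scores = (weights @ Y) / weights.sum(axis=1, keepdims=True)
    n = Y.shape[0]
    baseline = (Y.sum(axis=0, keepdims=True) - Y) / (n - 1)
    scores = scores - baseline
    bit_idx = range(Y.shape[1]) if bits is None else bits
    aucs = []
    for d in bit_idx:
        col = Y[:, d]
        if col.min() == col.max():
            continue
        aucs.append(roc_auc_score(col, scores[:, d]))
    if not aucs:
        raise ValueError("no fingerprint bit shows both classes")
    return float(np.mean(aucs))
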