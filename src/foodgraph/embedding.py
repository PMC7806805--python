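"""Skip-gram node embeddings with negative sampling plus a semi-supervised
chemical-structure head.

The base objective is skip-gram over walk windows: for a center token ``u``
and a context ``c`` the pair loss is::

    -ln sigmoid(x_c . x_u) - sum_m ln sigmoid(-x_m . x_c)

with ``M`` negatives drawn from the corpus unigram distribution raised to a
power (0.75 by default).  Compound tokens that carry an 881-bit fingerprint
additionally receive a weighted auxiliary loss: a linear head maps the
center vector to 881 logits and the mean binary cross-entropy against the
fingerprint is added with weight ``lambda``.  Gradients flow through both
the head and the embedding, so chemical structure shapes the vector space;
tokens without labels are simply skipped (semi-supervised masking).
Training is plain single-threaded SGD with a linearly decaying rate and is
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .graph import FINGERPRINT_BITS, Fingerprint
from .io import read_embeddings_text, write_embeddings_text
from .walks import WalkCorpus

#: Logit clip applied before exp/log for numerical stability.
LOGIT_CLIP = 30.0


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -LOGIT_CLIP, LOGIT_CLIP)))


@dataclass
class TrainingConfig:
    dim: int = 300
    window: int = 5
    negatives: int = 5
    lambda_csp: float = 0.5
    epochs: int = 5
    learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    neg_power: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_csp <= 1.0:
            raise ValueError("lambda_csp must lie in [0, 1]")
        if self.negatives < 1:
            raise ValueError("negatives must be >= 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")


class EmbeddingModel:
    """Center/context vector tables plus the chemical-structure head."""

    def __init__(
        self,
        vocab: Mapping[str, int],
        center_vectors: np.ndarray,
        context_vectors: np.ndarray,
        csp_weights: np.ndarray,
        csp_bias: np.ndarray,
    ) -> None:
        self.vocab: Dict[str, int] = dict(vocab)
        self.tokens: List[str] = [None] * len(self.vocab)  # type: ignore[list-item]
        for tok, idx in self.vocab.items():
            self.tokens[idx] = tok
        self.center_vectors = np.asarray(center_vectors, dtype=np.float64)
        self.context_vectors = np.asarray(context_vectors, dtype=np.float64)
        self.csp_weights = np.asarray(csp_weights, dtype=np.float64)
        self.csp_bias = np.asarray(csp_bias, dtype=np.float64)
        if self.center_vectors.shape != self.context_vectors.shape:
            raise ValueError("center/context tables must have identical shape")
        if self.csp_weights.shape != (self.dim, FINGERPRINT_BITS):
            raise ValueError(
                f"csp_weights must be (dim, {FINGERPRINT_BITS}), got {self.csp_weights.shape}"
            )

    @property
    def dim(self) -> int:
        return self.center_vectors.shape[1]

    def __contains__(self, token: str) -> bool:
        return token in self.vocab

    def index(self, token: str) -> int:
        try:
            return self.vocab[token]
        except KeyError:
            raise KeyError(f"token {token!r} not in vocabulary") from None

    def vector(self, token: str) -> np.ndarray:
        """Center vector for a token (the representation used downstream)."""
        return self.center_vectors[self.index(token)]

    def predict_fingerprint(self, token: str) -> np.ndarray:
        """Per-bit substructure probabilities from the chemical head."""
        return sigmoid(self.vector(token) @ self.csp_weights + self.csp_bias)

    def is_finite(self) -> bool:
        return all(
            np.isfinite(m).all()
            for m in (self.center_vectors, self.context_vectors, self.csp_weights, self.csp_bias)
        )

    # -- persistence ------------------------------------------------------

    def save(self, directory: Union[str, Path]) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_embeddings_text(self.tokens, self.center_vectors, directory / "center.vec")
        write_embeddings_text(self.tokens, self.context_vectors, directory / "context.vec")
        with open(directory / "csp_weights.tsv", "w") as fh:
            for row in self.csp_weights:
                fh.write("\t".join(repr(float(x)) for x in row) + "\n")
            fh.write("\t".join(repr(float(x)) for x in self.csp_bias) + "\n")

    @classmethod
    def load(cls, directory: Union[str, Path]) -> "EmbeddingModel":
        directory = Path(directory)
        tokens, center = read_embeddings_text(directory / "center.vec")
        tokens2, context = read_embeddings_text(directory / "context.vec")
        if tokens != tokens2:
            raise ValueError("center/context token order mismatch")
        with open(directory / "csp_weights.tsv") as fh:
            rows = [[float(x) for x in line.split("\t")] for line in fh if line.strip()]
        matrix = np.asarray(rows, dtype=np.float64)
        return cls(
            {tok: i for i, tok in enumerate(tokens)},
            center,
            context,
            matrix[:-1],
            matrix[-1],
        )


# ---------------------------------------------------------------------------
# loss primitives (vector-level; model-level wrappers below)
# ---------------------------------------------------------------------------


def skipgram_loss_and_grads(
    x_u: np.ndarray, x_c: np.ndarray, x_neg: np.ndarray
) -> Tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Pair loss and analytic gradients for one (center, context, negatives).

    Returns ``(loss, g_center, g_context, g_negatives)`` where the loss is
    ``-ln s(x_c.x_u) - sum_m ln s(-x_m.x_c)``; the negatives interact with
    the *context* vector.
    """
    pos = float(np.clip(x_c @ x_u, -LOGIT_CLIP, LOGIT_CLIP))
    neg = np.clip(x_neg @ x_c, -LOGIT_CLIP, LOGIT_CLIP)
    s_pos = 1.0 / (1.0 + np.exp(-pos))
    s_neg = 1.0 / (1.0 + np.exp(-neg))  # sigmoid(neg_m)
    loss = -np.log(s_pos) - float(np.sum(np.log(1.0 / (1.0 + np.exp(neg)))))
    d_pos = s_pos - 1.0
    g_center = d_pos * x_c
    g_context = d_pos * x_u + s_neg @ x_neg
    g_neg = s_neg[:, None] * x_c[None, :]
    return float(loss), g_center, g_context, g_neg


def csp_loss_and_grads(
    x_u: np.ndarray, weights: np.ndarray, bias: np.ndarray, y: np.ndarray
) -> Tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Mean binary cross-entropy of the chemical head against a fingerprint.

    Returns ``(loss, g_center, g_weights, g_bias)``.
    """
    y = np.asarray(y, dtype=np.float64)
    d = y.shape[0]
    logits = np.clip(x_u @ weights + bias, -LOGIT_CLIP, LOGIT_CLIP)
    p = 1.0 / (1.0 + np.exp(-logits))
    loss = -float(np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    dz = (p - y) / d
    g_center = weights @ dz
    g_weights = np.outer(x_u, dz)
    g_bias = dz
    return loss, g_center, g_weights, g_bias


# ---------------------------------------------------------------------------
# model-level operations
# ---------------------------------------------------------------------------


def negative_sample(
    probs: np.ndarray, m: int, exclude: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``m`` indices i.i.d. from the noise distribution, none equal to
    ``exclude`` (collisions are resampled)."""
    probs = np.asarray(probs, dtype=np.float64)
    if probs.shape[0] < 2:
        raise ValueError("cannot exclude a token from a vocabulary of size 1")
    if probs[exclude] >= 1.0:
        raise ValueError("noise distribution puts all mass on the excluded token")
    cdf = np.cumsum(probs)
    cdf[-1] = 1.0
    draws = np.searchsorted(cdf, rng.random(m), side="right")
    while True:
        bad = draws == exclude
        n_bad = int(bad.sum())
        if n_bad == 0:
            return draws
        draws[bad] = np.searchsorted(cdf, rng.random(n_bad), side="right")


def skipgram_pair_loss(
    model: EmbeddingModel, center: str, context: str, negatives: Sequence[str]
) -> Tuple[float, Dict[str, np.ndarray]]:
    """Loss and gradients keyed by parameter for one skip-gram pair."""
    iu, ic = model.index(center), model.index(context)
    ineg = np.asarray([model.index(t) for t in negatives], dtype=np.intp)
    loss, g_u, g_c, g_neg = skipgram_loss_and_grads(
        model.center_vectors[iu], model.context_vectors[ic], model.center_vectors[ineg]
    )
    return loss, {"center": g_u, "context": g_c, "negatives": g_neg}


def csp_loss(
    model: EmbeddingModel, node: str, fingerprint: Fingerprint
) -> Tuple[float, Dict[str, np.ndarray]]:
    """Chemical-head loss and gradients for one labeled node."""
    iu = model.index(node)
    loss, g_u, g_w, g_b = csp_loss_and_grads(
        model.center_vectors[iu], model.csp_weights, model.csp_bias, fingerprint.bits
    )
    return loss, {"center": g_u, "csp_weights": g_w, "csp_bias": g_b}


def combined_step_loss(
    model: EmbeddingModel,
    center: str,
    context: str,
    negatives: Sequence[str],
    fingerprint_lookup: Mapping[str, Fingerprint],
    lambda_csp: float,
) -> float:
    """Skip-gram pair loss plus the weighted chemical term when the center
    carries a fingerprint; with ``lambda_csp == 0`` this reduces exactly to
    the plain skip-gram loss."""
    loss, _ = skipgram_pair_loss(model, center, context, negatives)
    if lambda_csp != 0.0 and center in fingerprint_lookup:
        aux, _ = csp_loss(model, center, fingerprint_lookup[center])
        loss += lambda_csp * aux
    return loss


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def build_noise_distribution(counts: np.ndarray, power: float) -> np.ndarray:
    weighted = np.asarray(counts, dtype=np.float64) ** power
    return weighted / weighted.sum()


@dataclass
class EpochStats:
    skipgram_loss: float
    csp_loss: float
    pairs: int

    @property
    def mean_pair_loss(self) -> float:
        return (self.skipgram_loss + self.csp_loss) / max(self.pairs, 1)


def train(
    walks: WalkCorpus,
    fingerprints: Optional[Mapping[str, Fingerprint]] = None,
    config: Optional[TrainingConfig] = None,
    loss_log: Optional[List[EpochStats]] = None,
) -> EmbeddingModel:
    """Train embeddings on a walk corpus with SGD.

    For every center position and every context within the window one
    skip-gram update is applied; centers carrying a fingerprint additionally
    receive one weighted chemical-head update per occurrence.  The learning
    rate decays linearly from ``learning_rate`` to ``min_learning_rate``
    over all scheduled updates.  Deterministic given the seed.
    """
    config = config or TrainingConfig()
    fingerprints = fingerprints or {}
    if len(walks.walks) == 0:
        raise ValueError("empty walk corpus")

    # vocabulary in sorted token order (deterministic)
    counts_map: Dict[str, int] = {}
    for walk in walks.walks:
        for tok in walk:
            counts_map[tok] = counts_map.get(tok, 0) + 1
    tokens = sorted(counts_map)
    vocab = {tok: i for i, tok in enumerate(tokens)}
    counts = np.asarray([counts_map[t] for t in tokens], dtype=np.float64)
    noise = build_noise_distribution(counts, config.neg_power)
    noise_cdf = np.cumsum(noise)
    noise_cdf[-1] = 1.0

    rng = np.random.default_rng(config.seed)
    dim = config.dim
    # center vectors first so the lambda=0 trajectory matches a head-free
    # trainer drawing from the same stream; the head init comes after.
    center = rng.uniform(-0.5 / dim, 0.5 / dim, size=(len(tokens), dim))
    context = np.zeros((len(tokens), dim))
    use_csp = config.lambda_csp != 0.0 and len(fingerprints) > 0
    if use_csp:
        bound = np.sqrt(6.0 / (dim + FINGERPRINT_BITS))
        csp_w = rng.uniform(-bound, bound, size=(dim, FINGERPRINT_BITS))
    else:
        csp_w = np.zeros((dim, FINGERPRINT_BITS))
    csp_b = np.zeros(FINGERPRINT_BITS)

    walk_idx = [np.asarray([vocab[t] for t in w], dtype=np.intp) for w in walks.walks]
    labels: Dict[int, np.ndarray] = {}
    if use_csp:
        for tok, fp in fingerprints.items():
            if tok in vocab:
                labels[vocab[tok]] = fp.bits.astype(np.float64)

    window, m_neg, lam = config.window, config.negatives, config.lambda_csp
    total_pairs = config.epochs * sum(
        _n_window_pairs(len(w), window) for w in walk_idx
    )
    lr0, lr_min = config.learning_rate, config.min_learning_rate
    step = 0

    for _epoch in range(config.epochs):
        sg_sum = 0.0
        csp_sum = 0.0
        pairs = 0
        for widx in walk_idx:
            n = widx.shape[0]
            for i in range(n):
                iu = widx[i]
                lr = max(lr_min, lr0 - (lr0 - lr_min) * (step / max(total_pairs, 1)))
                lo, hi = max(0, i - window), min(n, i + window + 1)
                for j in range(lo, hi):
                    if j == i:
                        continue
                    ic = widx[j]
                    # negatives: i.i.d. from noise, resampled on collision
                    draws = np.searchsorted(noise_cdf, rng.random(m_neg), side="right")
                    while True:
                        bad = draws == ic
                        nb = int(bad.sum())
                        if nb == 0:
                            break
                        draws[bad] = np.searchsorted(
                            noise_cdf, rng.random(nb), side="right"
                        )
                    x_u = center[iu]
                    x_c = context[ic]
                    x_neg = center[draws]
                    pos = x_c @ x_u
                    if pos > LOGIT_CLIP:
                        pos = LOGIT_CLIP
                    elif pos < -LOGIT_CLIP:
                        pos = -LOGIT_CLIP
                    neg = np.clip(x_neg @ x_c, -LOGIT_CLIP, LOGIT_CLIP)
                    s_pos = 1.0 / (1.0 + np.exp(-pos))
                    s_neg = 1.0 / (1.0 + np.exp(neg))  # sigmoid(-neg)
                    if loss_log is not None:
                        sg_sum += -np.log(s_pos) - float(np.sum(np.log(s_neg)))
                    d_pos = s_pos - 1.0
                    coef_neg = 1.0 - s_neg  # sigmoid(+neg)
                    g_context = d_pos * x_u + coef_neg @ x_neg
                    # np.add.at: duplicated negative draws must accumulate
                    np.add.at(center, draws, (-lr) * coef_neg[:, None] * x_c[None, :])
                    center[iu] -= lr * d_pos * x_c
                    context[ic] = x_c - lr * g_context
                    pairs += 1
                    step += 1
                # one chemical-head update per labeled center occurrence
                if use_csp and iu in labels:
                    y = labels[iu]
                    x_u = center[iu]
                    logits = np.clip(x_u @ csp_w + csp_b, -LOGIT_CLIP, LOGIT_CLIP)
                    p = 1.0 / (1.0 + np.exp(-logits))
                    if loss_log is not None:
                        csp_sum += -lam * float(
                            np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
                        )
                    dz = lam * (p - y) / FINGERPRINT_BITS
                    g_u = csp_w @ dz
                    csp_w -= lr * np.outer(x_u, dz)
                    csp_b -= lr * dz
                    center[iu] = x_u - lr * g_u
        if loss_log is not None:
            loss_log.append(EpochStats(sg_sum, csp_sum, pairs))

    model = EmbeddingModel(vocab, center, context, csp_w, csp_b)
    if not model.is_finite():
        raise FloatingPointError("training produced non-finite parameters")
    return model


def _n_window_pairs(n: int, window: int) -> int:
    return sum(min(n, i + window + 1) - max(0, i - window) - 1 for i in range(n))
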