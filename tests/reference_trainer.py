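"""A chemical-head-free skip-gram trainer used as the reduction oracle.

Written independently of the library's trainer: it contains no auxiliary
head whatsoever.  Given the same config (with lambda 0) and seed it must
reproduce the library's training byte for byte, because the head must not
perturb the base objective or the RNG stream when disabled.
"""

import numpy as np

CLIP = 30.0


def plain_skipgram_train(walks, config):
    counts = {}
    for walk in walks.walks:
        for tok in walk:
            counts[tok] = counts.get(tok, 0) + 1
    tokens = sorted(counts)
    vocab = {t: i for i, t in enumerate(tokens)}
    freq = np.asarray([counts[t] for t in tokens], dtype=np.float64)
    weighted = freq**config.neg_power
    noise_cdf = np.cumsum(weighted / weighted.sum())
    noise_cdf[-1] = 1.0

    rng = np.random.default_rng(config.seed)
    dim = config.dim
    center = rng.uniform(-0.5 / dim, 0.5 / dim, size=(len(tokens), dim))
    context = np.zeros((len(tokens), dim))

    walk_idx = [np.asarray([vocab[t] for t in w], dtype=np.intp) for w in walks.walks]
    window, m_neg = config.window, config.negatives

    def n_pairs(n):
        return sum(min(n, i + window + 1) - max(0, i - window) - 1 for i in range(n))

    total = config.epochs * sum(n_pairs(len(w)) for w in walk_idx)
    lr0, lr_min = config.learning_rate, config.min_learning_rate
    step = 0
    for _ in range(config.epochs):
        for widx in walk_idx:
            n = widx.shape[0]
            for i in range(n):
                iu = widx[i]
                lr = max(lr_min, lr0 - (lr0 - lr_min) * (step / max(total, 1)))
                for j in range(max(0, i - window), min(n, i + window + 1)):
                    if j == i:
                        continue
                    ic = widx[j]
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
                    if pos > CLIP:
                        pos = CLIP
                    elif pos < -CLIP:
                        pos = -CLIP
                    neg = np.clip(x_neg @ x_c, -CLIP, CLIP)
                    s_pos = 1.0 / (1.0 + np.exp(-pos))
                    s_neg = 1.0 / (1.0 + np.exp(neg))
                    d_pos = s_pos - 1.0
                    coef_neg = 1.0 - s_neg
                    g_context = d_pos * x_u + coef_neg @ x_neg
                    np.add.at(center, draws, (-lr) * coef_neg[:, None] * x_c[None, :])
                    center[iu] -= lr * d_pos * x_c
                    context[ic] = x_c - lr * g_context
                    step += 1
    return center, context, tokens
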