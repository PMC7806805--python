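"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the library's own code paths: plain loops, literal
set arithmetic, and direct formula evaluation.
"""

import itertools
import math


def brute_counts(recipes):
    """Double loop over recipes for unigram and pair counts."""
    unigram = {}
    joint = {}
    for recipe in recipes:
        for tok in recipe:
            unigram[tok] = unigram.get(tok, 0) + 1
        for x in recipe:
            for y in recipe:
                if x < y:
                    joint[(x, y)] = joint.get((x, y), 0) + 1
    return unigram, joint


def brute_npmi(n_recipes, unigram, joint, x, y):
    pair = (x, y) if x < y else (y, x)
    c_xy = joint.get(pair, 0)
    if c_xy == 0:
        return -1.0
    p_xy = c_xy / n_recipes
    if p_xy == 1.0:
        return 1.0
    p_x = unigram[x] / n_recipes
    p_y = unigram[y] / n_recipes
    return math.log(p_xy / (p_x * p_y)) / (-math.log(p_xy))


def brute_select_edges(n_recipes, unigram, joint, min_unigram, min_joint, npmi_min, rescue_top_k):
    """Literal A-union-B-union-C filter over all token pairs."""
    tokens = sorted(unigram)
    all_pairs = list(itertools.combinations(tokens, 2))
    scores = {p: brute_npmi(n_recipes, unigram, joint, *p) for p in all_pairs}
    rule_a = {
        p
        for p in all_pairs
        if unigram[p[0]] > min_unigram
        and unigram[p[1]] > min_unigram
        and joint.get(p, 0) > min_joint
    }
    rule_b = {p for p in all_pairs if scores[p] >= npmi_min}
    under = sorted(
        (p for p in all_pairs if scores[p] < npmi_min),
        key=lambda p: (-scores[p], p),
    )
    rule_c = set(under[:rescue_top_k])
    chosen = rule_a | rule_b | rule_c
    return sorted((x, y, scores[(x, y)]) for x, y in chosen)


def brute_topk(vectors, query, k, pool):
    """Full-scan cosine ranking; ties by token id."""
    scored = []
    for tok in pool:
        v = vectors[tok]
        num = sum(a * b for a, b in zip(query, v))
        den = math.sqrt(sum(a * a for a in query)) * math.sqrt(sum(b * b for b in v))
        scored.append((tok, num / den))
    scored.sort(key=lambda item: (-item[1], item[0]))
    return scored[:k]


def brute_threshold_edges(vectors, compounds, foods, threshold):
    out = set()
    for c in compounds:
        for f in foods:
            vc, vf = vectors[c], vectors[f]
            num = sum(a * b for a, b in zip(vc, vf))
            den = math.sqrt(sum(a * a for a in vc)) * math.sqrt(sum(b * b for b in vf))
            if num / den >= threshold:
                out.add((c, f))
    return out


def brute_jaccard_matrix(compound_sets, categories):
    cats = sorted({categories[n] for n in compound_sets})
    matrix = {}
    for g in cats:
        for h in cats:
            vals = []
            for i in compound_sets:
                for j in compound_sets:
                    if i == j or categories[i] != g or categories[j] != h:
                        continue
                    ci, cj = compound_sets[i], compound_sets[j]
                    vals.append(len(ci & cj) / len(ci | cj))
            matrix[(g, h)] = sum(vals) / len(vals) if vals else None
    return cats, matrix


def brute_confusion(predicted, gold, universe):
    tp = len(predicted & gold)
    fp = len(predicted - gold)
    fn = len(gold - predicted)
    tn = len(universe - predicted - gold)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "mcc": mcc,
        "accuracy": (tp + tn) / len(universe),
    }
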