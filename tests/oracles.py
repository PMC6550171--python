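"""Independent reference implementations used to check the package.

Everything here is deliberately naive (plain loops, literal transcriptions
of rule tables) and shares no code with the package internals.
"""
from __future__ import annotations

import numpy as np


# Brute-force prior-adjusted CART -------------------------------------------

def _impurity_mass(counts, weights):
    joint = [w * c for w, c in zip(weights, counts)]
    mass = sum(joint)
    if mass == 0:
        return 0.0
    return mass - sum(j * j for j in joint) / mass


def brute_force_best_split(X, y_idx, n_classes, weights, min_leaf):
    """Exhaustive loop over every (feature, midpoint threshold) pair.

    Returns (feature, threshold, delta) or None. Ties: lower feature
    index, then lower threshold (strict > comparison, ascending scan).
    """
    n, m = X.shape
    parent_counts = [int(np.sum(y_idx == j)) for j in range(n_classes)]
    parent = _impurity_mass(parent_counts, weights)
    best = None
    for f in range(m):
        vals = sorted(set(X[:, f].tolist()))
        for a, b in zip(vals[:-1], vals[1:]):
            thr = (a + b) / 2.0
            left = X[:, f] >= thr
            nl = int(left.sum())
            if nl < min_leaf or n - nl < min_leaf:
                continue
            cl = [int(np.sum(y_idx[left] == j)) for j in range(n_classes)]
            cr = [p - c for p, c in zip(parent_counts, cl)]
            delta = parent - _impurity_mass(cl, weights) - _impurity_mass(cr, weights)
            if delta <= 0:
                continue
            if best is None or delta > best[2]:
                best = (f, thr, delta)
    return best


def brute_force_tree(X, y_idx, n_classes, weights, min_split, min_leaf,
                     cp, max_depth):
    """Recursive brute-force tree; nodes are dicts, left = value >= thr."""
    totals = [int(np.sum(y_idx == j)) for j in range(n_classes)]
    root_mass = _impurity_mass(totals, weights)
    min_gain = cp * root_mass

    def build(Xn, yn, depth):
        counts = [int(np.sum(yn == j)) for j in range(n_classes)]
        joint = [w * c for w, c in zip(weights, counts)]
        mass = sum(joint)
        pred = int(np.argmax(joint))
        node = {"pred": pred, "counts": counts}
        if depth >= max_depth or yn.size < min_split:
            return node
        if sum(1 for c in counts if c > 0) < 2:
            return node
        res = brute_force_best_split(Xn, yn, n_classes, weights, min_leaf)
        if res is None or res[2] < min_gain:
            return node
        f, thr, _ = res
        left = Xn[:, f] >= thr
        node["feature"] = f
        node["threshold"] = thr
        node["left"] = build(Xn[left], yn[left], depth + 1)
        node["right"] = build(Xn[~left], yn[~left], depth + 1)
        return node

    return build(X, y_idx, 0)


def brute_force_predict(node, x):
    while "feature" in node:
        node = node["left"] if x[node["feature"]] >= node["threshold"] else node["right"]
    return node["pred"]


# Hand Benjamini-Hochberg ---------------------------------------------------

def hand_bh(pvals):
    """Step-up BH computed the long way."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = min(val, 1.0)
        prev = adj[i]
    return adj


# Literal transcriptions of the criteria rule tables ------------------------
# Inputs: dict with keys pa (3-PA), map2 (2'-MAP), mba (2-MBA), hpa (4-HPA),
# md (manuka DNA Cq), kd (kanuka DNA Cq). Chemical units mg/kg, DNA Cq.

def hand_final(v):
    gates = v["map2"] >= 1 and v["mba"] >= 1 and v["hpa"] >= 1 and v["md"] < 36
    if gates and v["pa"] >= 400:
        return "monofloral"
    if gates and 20 <= v["pa"] < 400:
        return "multifloral"
    return "not_manuka"


def hand_option1(v):
    mba, hpa = v["mba"] >= 1, v["hpa"] >= 1
    mono_a = v["pa"] >= 50 and mba and hpa and v["md"] < 30 and v["kd"] < 30
    mono_b = v["pa"] >= 400 and mba and hpa and v["md"] < 36 and v["kd"] < 25
    if mono_a or mono_b:
        return "monofloral"
    multi_a = 50 <= v["pa"] < 400 and mba and hpa and v["md"] < 36 and v["kd"] > 25
    multi_b = 20 <= v["pa"] < 50 and mba and hpa and v["md"] < 36
    if multi_a or multi_b:
        return "multifloral"
    return "not_manuka"


def hand_option2(v):
    gates = v["mba"] >= 1 and v["hpa"] >= 1 and v["md"] < 36
    if gates and v["pa"] >= 400:
        return "monofloral"
    if gates and v["pa"] < 400:
        return "multifloral"
    return "not_manuka"


def hand_option3(v):
    g = v["map2"] >= 1 and v["mba"] >= 1 and v["hpa"] >= 1
    mono_a = v["pa"] >= 50 and g and v["md"] < 30 and v["kd"] < 25
    mono_b = v["pa"] >= 400 and g and v["md"] < 36 and v["kd"] >= 25
    if mono_a or mono_b:
        return "monofloral"
    multi_a = 50 <= v["pa"] < 400 and g and v["md"] < 36 and v["kd"] >= 25
    multi_b = 20 <= v["pa"] < 50 and g and v["md"] < 36
    if multi_a or multi_b:
        return "multifloral"
    return "not_manuka"


def hand_option4(v):
    gates = (
        v["map2"] >= 1 and v["mba"] >= 1 and v["hpa"] >= 1 and v["md"] < 36
    )
    if gates and v["pa"] >= 400:
        return "monofloral"
    if gates and v["pa"] < 400:
        return "multifloral"
    return "not_manuka"


HAND_EVALUATORS = {
    "option1": hand_option1,
    "option2": hand_option2,
    "option3": hand_option3,
    "option4": hand_option4,
    "final": hand_final,
}
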