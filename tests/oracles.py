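"""Independent brute-force reference implementations used only by tests.

These deliberately favour clarity over speed: every quantity is recomputed
from scratch with plain Python loops so they share no code path with the
package implementations they check.
"""

import math

import numpy as np


def entropy(labels) -> float:
    labels = list(labels)
    n = len(labels)
    if n == 0:
        return 0.0
    out = 0.0
    for c in set(labels):
        p = labels.count(c) / n
        out -= p * math.log2(p)
    return out


def mdlp_oracle(values, labels) -> list:
    """Exhaustive recursive MDLP: try every boundary midpoint, pick the
    weighted-entropy minimiser (leftmost on ties), accept iff the
    Fayyad-Irani inequality holds, recurse into both sides."""
    pairs = sorted(zip([float(v) for v in values], [int(l) for l in labels]),
                   key=lambda p: p[0])
    cuts: list[float] = []
    _recurse(pairs, cuts)
    return sorted(cuts)


def _candidates(pairs):
    """Midpoints between adjacent distinct values that are class boundaries."""
    out = []
    values = [p[0] for p in pairs]
    for i in range(len(pairs) - 1):
        a, b = values[i], values[i + 1]
        if a == b:
            continue
        left_lab = {l for v, l in pairs if v == a}
        right_lab = {l for v, l in pairs if v == b}
        if len(left_lab) == 1 and left_lab == right_lab:
            continue
        out.append((a + b) / 2.0)
    return out


def _recurse(pairs, cuts):
    labels = [l for _, l in pairs]
    if len(set(labels)) < 2:
        return
    n = len(pairs)
    best = None
    for t in _candidates(pairs):
        left = [l for v, l in pairs if v <= t]
        right = [l for v, l in pairs if v > t]
        went = (len(left) / n) * entropy(left) + (len(right) / n) * entropy(right)
        if best is None or went < best[0]:
            best = (went, t, left, right)
    if best is None:
        return
    went, t, left, right = best
    gain = entropy(labels) - went
    c = len(set(labels))
    c1, c2 = len(set(left)), len(set(right))
    delta = math.log2(3**c - 2) - (
        c * entropy(labels) - c1 * entropy(left) - c2 * entropy(right)
    )
    if gain <= math.log2(n - 1) / n + delta / n:
        return
    cuts.append(t)
    _recurse([p for p in pairs if p[0] <= t], cuts)
    _recurse([p for p in pairs if p[0] > t], cuts)


def knn_impute_oracle(reference, ref_types, ranges, query, observed, k):
    """Brute-force HEOM k-nearest-neighbour imputation of one record.

    Sorts all reference distances (stable, so index breaks ties), then
    imputes each unobserved feature by neighbour mean (continuous) or
    majority vote with smallest-code ties (discrete).
    """
    reference = np.asarray(reference, float)
    query = np.asarray(query, float)
    dists = []
    for r, row in enumerate(reference):
        s = 0.0
        for j, obs in enumerate(observed):
            if not obs:
                continue
            if ref_types[j] == "continuous":
                rng = ranges[j]
                d = abs(row[j] - query[j]) / rng if rng > 0 else float(row[j] != query[j])
            else:
                d = float(row[j] != query[j])
            s += d * d
        dists.append((math.sqrt(s), r))
    dists.sort(key=lambda p: (p[0], p[1]))
    nbr = [reference[r] for _, r in dists[:k]]
    out = query.copy()
    for j, obs in enumerate(observed):
        if obs:
            continue
        vals = [row[j] for row in nbr]
        if ref_types[j] == "continuous":
            out[j] = sum(vals) / len(vals)
        else:
            counts = {}
            for v in vals:
                counts[v] = counts.get(v, 0) + 1
            best = max(counts.values())
            out[j] = min(v for v, c in counts.items() if c == best)
    return out
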