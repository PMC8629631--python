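"""Independent brute-force oracles for the candidate-selection algorithm.

Deliberately naive: explicit Python loops over the distance definition and
full sorts, sharing no code with fatiguekit.fsvm.
"""

import math

import numpy as np


def brute_force_selection(X, y, gamma, r):
    """Direct loop evaluation of the kernel-distance selection.

    Returns (selected_pos, selected_neg) as sorted original-index arrays.
    Mirrors the documented contract: per class, intersect the top-ceil(l*r)
    by same-class mean distance (descending, ties by index) with the
    top-ceil(l*r) by opposite-class mean distance (ascending, ties by
    index); empty intersection falls back to the opposite-class ranking.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)

    def dist(i, j):
        k = math.exp(-gamma * float(np.sum((X[i] - X[j]) ** 2)))
        return math.sqrt(max(2.0 - 2.0 * k, 0.0))

    out = {}
    for cls in (1, 0):
        own = [i for i in range(n) if y[i] == cls]
        other = [i for i in range(n) if y[i] != cls]
        same_mean = {}
        opp_mean = {}
        for k_idx in own:
            same_mean[k_idx] = sum(dist(k_idx, i) for i in own) / len(own)
            opp_mean[k_idx] = sum(dist(k_idx, j) for j in other) / len(other)
        m = math.ceil(len(own) * r)
        by_same = sorted(own, key=lambda i: (-same_mean[i], i))[:m]
        by_opp = sorted(own, key=lambda i: (opp_mean[i], i))[:m]
        chosen = sorted(set(by_same) & set(by_opp))
        if not chosen:
            chosen = sorted(by_opp)
        out[cls] = np.array(chosen, dtype=int)
    return out[1], out[0]
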