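"""Independent reference implementations used only to check the package.

Each oracle is deliberately naive (grid search, pair counting, exhaustive
enumeration) and shares no code with the implementation it validates.
"""

import math

import numpy as np


def brute_force_plr_1feature(x, y, lam, span=8.0, coarse=81, rounds=6):
    """Minimize the ridge-logistic objective over (beta0, beta1) by a dense
    2-D grid, zooming the grid around the best point each round."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def objective(b0, b1):
        eta = b0[..., None] + b1[..., None] * x
        return np.sum(np.logaddexp(0.0, eta) - y * eta, axis=-1) + 0.5 * lam * b1**2

    center = np.zeros(2)
    width = span
    for _ in range(rounds):
        g0 = np.linspace(center[0] - width, center[0] + width, coarse)
        g1 = np.linspace(center[1] - width, center[1] + width, coarse)
        B0, B1 = np.meshgrid(g0, g1, indexing="ij")
        vals = objective(B0, B1)
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        center = np.array([g0[i], g1[j]])
        width = 4.0 * width / (coarse - 1)  # keep the best cell well inside
    return center


def auc_pair_count(scores, labels):
    """AUC as the fraction of concordant positive-negative pairs, ties half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def hand_till_enumeration(prob, labels, classes):
    """Hand-Till AUC via explicit per-pair pair-counting."""
    prob = np.asarray(prob, dtype=float)
    labels = np.asarray(labels)
    total = 0.0
    pairs = 0
    for i, ci in enumerate(classes):
        for j, cj in enumerate(classes):
            if j <= i:
                continue
            mask = (labels == ci) | (labels == cj)
            a_ij = auc_pair_count(prob[mask, i], (labels[mask] == ci).astype(int))
            a_ji = auc_pair_count(prob[mask, j], (labels[mask] == cj).astype(int))
            total += 0.5 * (a_ij + a_ji)
            pairs += 1
    return total / pairs


def fisher_enumeration(a, b, c, d, alternative):
    """Fisher's exact p by enumerating every table with the fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {
        k: math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        for k in range(lo, hi + 1)
    }
    if alternative == "greater":
        return sum(v for k, v in probs.items() if k >= a)
    if alternative == "less":
        return sum(v for k, v in probs.items() if k <= a)
    p_obs = probs[a]
    return sum(v for v in probs.values() if v <= p_obs * (1.0 + 1e-12))
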