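"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: exact-fraction
hypergeometric enumeration for the Fisher test, a naive O(n^3) centroid
linkage, and projection-matrix R-squared for the redundancy analysis.
"""

from fractions import Fraction
from math import comb

import numpy as np
from scipy.optimize import minimize_scalar


def fisher_oracle(table):
    """Exact two-sided Fisher P and conditional-MLE odds ratio by enumeration.

    P sums exact-rational hypergeometric probabilities no larger than the
    observed table's. The odds ratio maximizes the enumerated noncentral
    hypergeometric log-likelihood by bounded scalar search on log-psi.
    """
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    xs = list(range(lo, hi + 1))
    weights = {x: comb(r1, x) * comb(r2, c1 - x) for x in xs}
    total = sum(weights.values())
    w_obs = weights[a]
    p = Fraction(sum(w for w in weights.values() if w <= w_obs), total)

    if a == lo:
        odds = 0.0 if len(xs) > 1 else float("nan")
    elif a == hi:
        odds = float("inf") if len(xs) > 1 else float("nan")
    else:
        logw = {x: float(np.log(float(weights[x]))) for x in xs}

        def negloglik(log_psi):
            terms = np.array([logw[x] + x * log_psi for x in xs])
            m = terms.max()
            denom = m + np.log(np.exp(terms - m).sum())
            return -(logw[a] + a * log_psi - denom)

        res = minimize_scalar(negloglik, bounds=(-40, 40), method="bounded",
                              options={"xatol": 1e-12})
        odds = float(np.exp(res.x))
    return float(p), odds


def centroid_linkage_oracle(points):
    """Naive agglomerative centroid linkage; returns sorted merge heights.

    At each step merges the pair of clusters whose centroids are closest in
    Euclidean distance; the merge height is that centroid distance.
    """
    clusters = [(np.asarray(p, dtype=float), 1) for p in points]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = float(np.linalg.norm(clusters[i][0] - clusters[j][0]))
                if best is None or dist < best[0]:
                    best = (dist, i, j)
        dist, i, j = best
        (ci, ni), (cj, nj) = clusters[i], clusters[j]
        merged = ((ci * ni + cj * nj) / (ni + nj), ni + nj)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        heights.append(dist)
    return sorted(heights)


def projection_r2_oracle(Y, X):
    """R-squared via the explicit hat matrix X (X'X)^+ X' on centered data."""
    Yc = Y - Y.mean(axis=0, keepdims=True)
    Xc = X - X.mean(axis=0, keepdims=True)
    hat = Xc @ np.linalg.pinv(Xc.T @ Xc) @ Xc.T
    fitted = hat @ Yc
    return float((fitted**2).sum() / (Yc**2).sum())
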