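"""Independent brute-force oracles used to cross-check the implementations."""

import numpy as np
from scipy.spatial.distance import cdist


def trustworthiness_bruteforce(x_high, x_low, k):
    """Double-loop rank-penalty trustworthiness.

    For each cell, every embedded k-neighbor that is not a true
    k-neighbor contributes its high-dimensional rank minus k; the sum
    is scaled by 2 / (n k (2n - 3k - 1)) and subtracted from 1.
    """
    n = x_high.shape[0]
    d_high = cdist(x_high, x_high)
    d_low = cdist(x_low, x_low)
    penalty = 0.0
    for i in range(n):
        order_high = [j for j in np.argsort(d_high[i], kind="stable") if j != i]
        order_low = [j for j in np.argsort(d_low[i], kind="stable") if j != i]
        true_nn = set(order_high[:k])
        rank_high = {j: r + 1 for r, j in enumerate(order_high)}
        for j in order_low[:k]:
            if j not in true_nn:
                penalty += rank_high[j] - k
    return 1.0 - 2.0 / (n * k * (2 * n - 3 * k - 1)) * penalty


def nnls_orthogonal(signature_totals, spot):
    """Closed-form NNLS proportions for an orthogonal (one gene per type) design.

    With disjoint marker genes the least-squares solution decouples:
    each type's coefficient is its marker signal over its signature
    magnitude, and the proportions are the normalized coefficients.
    """
    coef = np.asarray(spot, dtype=float) / np.asarray(signature_totals, dtype=float)
    return coef / coef.sum()
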