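"""Independent brute-force oracles used to verify the fast implementations.

Each function here deliberately avoids the code paths it checks: the
2-Wasserstein oracle solves the discrete-transport linear program, the KS
oracle enumerates the ECDF difference pointwise with explicit loops, and
the AUC oracle enumerates positive-negative pairs.
"""

import itertools

import numpy as np
from scipy.optimize import linprog


def w2_lp(a, b) -> float:
    """1-D 2-Wasserstein via the discrete-transport LP between empiricals."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    cost = (a[:, None] - b[None, :]) ** 2
    # marginal constraints: rows sum to 1/na, columns to 1/nb
    A_eq = []
    b_eq = []
    for i in range(na):
        row = np.zeros(na * nb)
        row[i * nb : (i + 1) * nb] = 1.0
        A_eq.append(row)
        b_eq.append(1.0 / na)
    for j in range(nb):
        col = np.zeros(na * nb)
        col[j::nb] = 1.0
        A_eq.append(col)
        b_eq.append(1.0 / nb)
    res = linprog(cost.ravel(), A_eq=np.array(A_eq), b_eq=np.array(b_eq),
                  bounds=(0, None), method="highs")
    assert res.success
    return float(np.sqrt(res.fun))


def ks_enumerate(a, b) -> float:
    """Sup |F_a - F_b| by explicit evaluation at every sample point."""
    a = list(a)
    b = list(b)
    best = 0.0
    for t in a + b:
        fa = sum(1 for x in a if x <= t) / len(a)
        fb = sum(1 for x in b if x <= t) / len(b)
        best = max(best, abs(fa - fb))
    return best


def auc_pairs(labels, scores) -> float:
    """AUC by enumeration over all positive-negative pairs; ties give 1/2."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))
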