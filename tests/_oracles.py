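"""Independent reference implementations used only as test oracles.

These deliberately use naive, transparent computations (exhaustive
enumeration, explicit loops, separate library calls) and share no code with
the package paths they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def all_set_partitions(n: int):
    """Every partition of n items as a label array (restricted growth strings)."""
    labels = [0] * n

    def rec(i: int, max_label: int):
        if i == n:
            yield np.array(labels, dtype=int)
            return
        for lab in range(max_label + 1):
            labels[i] = lab
            yield from rec(i + 1, max(max_label, lab + 1))

    yield from rec(0, 0)


def signed_modularity_reference(W: np.ndarray, labels: np.ndarray,
                                gamma: float) -> float:
    """Direct double-loop evaluation of the asymmetric signed quality, with
    ordered-pair sums including diagonal null terms."""
    n = W.shape[0]
    wp = np.clip(W, 0, None)
    wn = np.clip(-W, 0, None)
    sp = wp.sum(axis=1)
    sn = wn.sum(axis=1)
    vp, vn = sp.sum(), sn.sum()
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] != labels[j]:
                continue
            q += (wp[i, j] - gamma * sp[i] * sp[j] / vp) / vp
            if vn > 0:
                q -= (wn[i, j] - gamma * sn[i] * sn[j] / vn) / (vp + vn)
    return q


def ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    """Plain OLS R-squared with an intercept."""
    Xc = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    resid = y - Xc @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def dominance_reference(y: np.ndarray, X: np.ndarray):
    """Brute-force dominance analysis: explicit loop over all submodels and
    the two-stage (within-size, then across-size) averaging."""
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    p = X.shape[1]
    r2 = {frozenset(): 0.0}
    for size in range(1, p + 1):
        for combo in combinations(range(p), size):
            r2[frozenset(combo)] = ols_r2(y, X[:, list(combo)])
    total = np.zeros(p)
    inter = np.zeros(p)
    full = frozenset(range(p))
    for j in range(p):
        size_means = []
        for size in range(p):
            incs = [r2[s | {j}] - r2[s]
                    for s in r2 if len(s) == size and j not in s]
            size_means.append(np.mean(incs))
        total[j] = np.mean(size_means)
        inter[j] = r2[full] - r2[full - {j}]
    return total, inter, r2[full]
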