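"""Independent brute-force oracles used by several test modules."""

import numpy as np


def brute_force_mi(r, a, bin_width=0.05):
    """Naive double-loop histogram mutual information in bits."""
    lr, la = np.log2(r), np.log2(a)

    def bin_of(x):
        return np.floor(x / bin_width).astype(int)

    bx, by = bin_of(lr), bin_of(la)
    mi = 0.0
    for i in np.unique(bx):
        for j in np.unique(by):
            pij = np.mean((bx == i) & (by == j))
            if pij == 0:
                continue
            pi, pj = np.mean(bx == i), np.mean(by == j)
            mi += pij * np.log2(pij / (pi * pj))
    return mi


def bh_step_up_oracle(pvals):
    """Brute-force Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return adj
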