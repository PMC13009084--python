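"""Independent brute-force statistical oracles used by the test suite.

Deliberately naive implementations (explicit loops, textbook formulas)
kept separate from the package so they cannot share code with the paths
they check.
"""

import numpy as np


def average_ranks(x):
    x = np.asarray(x, dtype=float)
    ranks = np.empty(len(x))
    for i, v in enumerate(x):
        less = np.sum(x < v)
        equal = np.sum(x == v)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def spearman_oracle(a, b):
    """Pearson correlation of midrank-tied average ranks."""
    ra, rb = average_ranks(a), average_ranks(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    return float((ra @ rb) / np.sqrt((ra @ ra) * (rb @ rb)))


def rmse_oracle(a, b):
    return float(np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)) / len(a)))


def r2_oracle(a, b):
    a = np.asarray(a, dtype=float) - np.mean(a)
    b = np.asarray(b, dtype=float) - np.mean(b)
    r = (a @ b) / np.sqrt((a @ a) * (b @ b))
    return float(r * r)


def ols_oracle(x, y):
    """Closed-form simple OLS slope and squared correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    slope = (xc @ yc) / (xc @ xc)
    r2 = (xc @ yc) ** 2 / ((xc @ xc) * (yc @ yc))
    return float(slope), float(r2)
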