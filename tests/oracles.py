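"""Independent brute-force information measures used as test oracles.

Everything here enumerates the full dense joint probability table and sums
the defining expression cell by cell; no code is shared with the package's
estimators (which work through entropy decompositions of sparse count
tables).
"""

import numpy as np


def _joint_table(*cols):
    cols = [np.asarray(c, dtype=int) for c in cols]
    shape = tuple(c.max() + 1 for c in cols)
    table = np.zeros(shape)
    np.add.at(table, tuple(cols), 1)
    return table / len(cols[0])


def entropy(x):
    p = _joint_table(x).ravel()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mutual_information(x, y):
    pxy = _joint_table(x, y)
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    return float((pxy[mask] * np.log2(pxy[mask] / (px * py)[mask])).sum())


def conditional_entropy(x, y):
    """H(X|Y) = -sum p(x,y) log p(x|y)."""
    pxy = _joint_table(x, y)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = pxy / py
    return float(-(pxy[mask] * np.log2(cond[mask])).sum())


def conditional_mutual_information(x, y, z):
    """I(X;Y|Z) as sum_z p(z) * MI of the slice conditioned on z."""
    x, y, z = (np.asarray(a, dtype=int) for a in (x, y, z))
    total = 0.0
    n = len(z)
    for zv in np.unique(z):
        sel = z == zv
        total += (sel.sum() / n) * mutual_information(x[sel], y[sel])
    return total


def joint_mutual_information(x, y, z):
    """I(X,Y;Z) via a product code over (x, y)."""
    x, y = np.asarray(x, dtype=int), np.asarray(y, dtype=int)
    xy = x * (y.max() + 1) + y
    return mutual_information(xy, z)


def interaction_information(x, y, z):
    return (
        mutual_information(x, z)
        + mutual_information(y, z)
        - joint_mutual_information(x, y, z)
    )
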