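"""Plug-in estimators of discrete information measures.

All quantities are estimated from empirical (maximum-likelihood) cell
frequencies of the joint contingency table, with no smoothing, and are
reported in bits (log base 2).  The ``0 * log 0 := 0`` convention is used
throughout: empty cells simply contribute nothing.

Variables are 1-D sequences of small non-negative integer category codes.
Mutual information and conditional mutual information are clamped at zero
(they are non-negative in exact arithmetic; tiny negative values are
floating-point noise).  Interaction information is legitimately signed and
is never clamped.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "JointDistribution",
    "entropy",
    "joint_entropy",
    "conditional_entropy",
    "mutual_information",
    "conditional_mutual_information",
    "joint_mutual_information",
    "interaction_information",
    "label_mi_matrix",
]

#: negative values of magnitude below this are treated as rounding noise
_CLAMP_EPS = 1e-12


def _as_codes(x: ArrayLike, name: str = "variable") -> NDArray[np.int64]:
    arr = np.asarray(x)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"{name} is empty; entropy of zero observations is undefined")
    if not np.issubdtype(arr.dtype, np.integer):
        if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.floor(arr)):
            arr = arr.astype(np.int64)
        else:
            raise TypeError(f"{name} must hold integer category codes, got dtype {arr.dtype}")
    if arr.min() < 0:
        raise ValueError(f"{name} contains negative category codes")
    return arr.astype(np.int64, copy=False)


def _check_lengths(*arrays: NDArray[np.int64]) -> int:
    n = len(arrays[0])
    for a in arrays[1:]:
        if len(a) != n:
            raise ValueError(f"variables have mismatched lengths {n} != {len(a)}")
    return n


def _joint_codes(arrays: tuple[NDArray[np.int64], ...]) -> NDArray[np.int64]:
    """Flatten a tuple of code vectors into a single mixed-radix code vector."""
    codes = arrays[0].copy()
    for a in arrays[1:]:
        codes *= int(a.max()) + 1
        codes += a
    return codes


def _entropy_from_counts(counts: NDArray[np.int64]) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


class JointDistribution:
    """Empirical joint distribution over 1-3 discrete variables.

    Holds the dense contingency table of co-occurrence counts; probabilities
    are counts normalised by the number of observations.  Marginalising over
    an axis yields the lower-order joint distribution of the remaining axes.
    """

    def __init__(self, counts: NDArray[np.int64]):
        counts = np.asarray(counts, dtype=np.int64)
        if counts.ndim < 1 or counts.ndim > 3:
            raise ValueError("JointDistribution supports 1 to 3 axes")
        if counts.sum() <= 0:
            raise ValueError("contingency table has no observations")
        self.counts = counts

    @classmethod
    def from_variables(cls, *variables: ArrayLike) -> "JointDistribution":
        arrs = tuple(_as_codes(v, f"variable {i}") for i, v in enumerate(variables))
        _check_lengths(*arrs)
        shape = tuple(int(a.max()) + 1 for a in arrs)
        counts = np.zeros(shape, dtype=np.int64)
        np.add.at(counts, arrs, 1)
        return cls(counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> NDArray[np.float64]:
        return self.counts / self.n

    def marginal(self, keep: int | tuple[int, ...]) -> "JointDistribution":
        """Marginalise onto the given axis (or axes)."""
        if isinstance(keep, int):
            keep = (keep,)
        drop = tuple(ax for ax in range(self.counts.ndim) if ax not in keep)
        return JointDistribution(self.counts.sum(axis=drop))

    def entropy(self) -> float:
        return _entropy_from_counts(self.counts.ravel())


def entropy(x: ArrayLike) -> float:
    """Shannon entropy H(X) in bits."""
    codes = _as_codes(x, "x")
    _, counts = np.unique(codes, return_counts=True)
    return _entropy_from_counts(counts)


def joint_entropy(*variables: ArrayLike) -> float:
    """Joint entropy H(X1, ..., Xk) in bits."""
    arrs = tuple(_as_codes(v, f"variable {i}") for i, v in enumerate(variables))
    _check_lengths(*arrs)
    _, counts = np.unique(_joint_codes(arrs), return_counts=True)
    return _entropy_from_counts(counts)


def conditional_entropy(x: ArrayLike, y: ArrayLike) -> float:
    """H(X | Y) = H(X, Y) - H(Y), in bits; lies in [0, H(X)]."""
    xa, ya = _as_codes(x, "x"), _as_codes(y, "y")
    _check_lengths(xa, ya)
    return max(0.0, joint_entropy(xa, ya) - entropy(ya))


def _clamp(value: float) -> float:
    if value < 0.0:
        if value < -1e-6:  # genuine negativity would indicate a bug
            raise AssertionError(f"information measure below numerical tolerance: {value}")
        return 0.0
    return value


def mutual_information(x: ArrayLike, y: ArrayLike) -> float:
    """I(X;Y) = H(X) + H(Y) - H(X,Y), in bits, clamped at 0."""
    xa, ya = _as_codes(x, "x"), _as_codes(y, "y")
    _check_lengths(xa, ya)
    return _clamp(entropy(xa) + entropy(ya) - joint_entropy(xa, ya))


def conditional_mutual_information(x: ArrayLike, y: ArrayLike, z: ArrayLike) -> float:
    """I(X;Y|Z) = H(X,Z) + H(Y,Z) - H(Z) - H(X,Y,Z), in bits, clamped at 0."""
    xa, ya, za = _as_codes(x, "x"), _as_codes(y, "y"), _as_codes(z, "z")
    _check_lengths(xa, ya, za)
    return _clamp(
        joint_entropy(xa, za) + joint_entropy(ya, za) - entropy(za) - joint_entropy(xa, ya, za)
    )


def joint_mutual_information(x: ArrayLike, y: ArrayLike, z: ArrayLike) -> float:
    """I(X,Y;Z) = H(X,Y) + H(Z) - H(X,Y,Z): information the pair carries about Z."""
    xa, ya, za = _as_codes(x, "x"), _as_codes(y, "y"), _as_codes(z, "z")
    _check_lengths(xa, ya, za)
    return _clamp(joint_entropy(xa, ya) + entropy(za) - joint_entropy(xa, ya, za))


def interaction_information(x: ArrayLike, y: ArrayLike, z: ArrayLike) -> float:
    """I(X;Y;Z) = I(X;Z) + I(Y;Z) - I(X,Y;Z).

    Signed: positive values indicate redundancy between X and Y about Z,
    negative values synergy.  Symmetric under permutation of the arguments.
    """
    xa, ya, za = _as_codes(x, "x"), _as_codes(y, "y"), _as_codes(z, "z")
    _check_lengths(xa, ya, za)
    return (
        mutual_information(xa, za)
        + mutual_information(ya, za)
        - joint_mutual_information(xa, ya, za)
    )


def label_mi_matrix(labels: list[ArrayLike] | NDArray) -> NDArray[np.float64]:
    """Pairwise mutual-information matrix over a list of label variables.

    Symmetric; the diagonal holds per-label entropies (I(X;X) = H(X)).
    Accepts a list of 1-D code vectors or an (n, q) matrix of columns.
    """
    if isinstance(labels, np.ndarray) and labels.ndim == 2:
        cols = [labels[:, j] for j in range(labels.shape[1])]
    else:
        cols = list(labels)
    q = len(cols)
    if q == 0:
        raise ValueError("need at least one label")
    out = np.zeros((q, q))
    for i in range(q):
        out[i, i] = entropy(cols[i])
        for j in range(i + 1, q):
            out[i, j] = out[j, i] = mutual_information(cols[i], cols[j])
    return out
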