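"""Greedy information-theoretic multi-label feature selectors.

The central method is max-correlation selection (MCMFS): feature relevance
is the *maximum* mutual information between a candidate feature and any
single label, rather than the sum over labels.  When labels cluster into
semantic groups (several near-synonymous labels driven by one underlying
concept), summing per-label informativeness overweights large groups and
keeps selecting near-duplicates of their features; taking the maximum makes
a feature's score independent of how many labels echo the same concept, so
small groups are not drowned out.  The greedy objective at each step is

    J(f_k) = max_l I(f_k; l)  -  (1/|S|) * sum_{f_j in S} I(f_k; f_j),

i.e. max-correlation relevance minus mean redundancy with the
already-selected set S (the first feature is chosen by relevance alone).

Five published cumulative-summation criteria (D2F, SCLS, MDMR, PMU, LRFS)
are implemented under the same sequential-forward interface for comparison,
as are the pruned-problem-transformation baselines (label powerset with
rare-combination pruning, ranked by mutual information or chi-squared).

All selectors are deterministic: score ties are broken by the lowest
feature index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.stats import chi2_contingency

from .info_theory import (
    conditional_mutual_information,
    entropy,
    interaction_information,
    mutual_information,
)
from .preprocessing import DiscreteDataset

__all__ = [
    "SelectionResult",
    "SemanticGrouping",
    "max_correlation",
    "correlation_vector",
    "mcmfs_select",
    "d2f_select",
    "scls_select",
    "mdmr_select",
    "pmu_select",
    "lrfs_select",
    "ppt_transform",
    "ppt_mi_rank",
    "ppt_chi_rank",
    "SELECTORS",
    "select",
]


@dataclass
class SelectionResult:
    """Ordered outcome of a forward selection run."""

    method: str
    order: list[int]  # feature indices in selection order
    names: list[str]
    scores: list[float]  # criterion value J at the moment of selection
    b: int

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValueError("selected feature order contains duplicates")
        if len(self.order) != self.b:
            raise ValueError("order length does not match b")

    def to_tsv(self, path: str | Path | None = None) -> str:
        lines = ["rank\tfeature\tscore"]
        lines += [
            f"{r + 1}\t{self.names[r]}\t{self.scores[r]:.6f}" for r in range(self.b)
        ]
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "method": self.method,
            "order": self.order,
            "names": self.names,
            "scores": self.scores,
            "b": self.b,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class SemanticGrouping:
    """A disjoint partition of label indices into semantic groups."""

    groups: list[list[int]]
    q: int

    def __post_init__(self) -> None:
        flat = [i for g in self.groups for i in g]
        if any(len(g) == 0 for g in self.groups):
            raise ValueError("semantic groups must be nonempty")
        if sorted(flat) != list(range(self.q)):
            raise ValueError("groups must partition the label indices 0..q-1")

    @property
    def m(self) -> int:
        return len(self.groups)

    def group_of(self, label_index: int) -> int:
        for gi, g in enumerate(self.groups):
            if label_index in g:
                return gi
        raise KeyError(label_index)


def max_correlation(fk: ArrayLike, labels: list[ArrayLike] | NDArray) -> float:
    """Max-correlation relevance: the largest MI between ``fk`` and any label.

    Because the per-group restricted maximum is itself a maximum, the
    grouping drops out and the measure equals ``max_l I(fk; l)`` over the
    whole label set — no partition needs to be known.
    """
    cols = _label_list(labels)
    if not cols:
        raise ValueError("empty label set")
    return max(mutual_information(fk, l) for l in cols)


def correlation_vector(
    fk: ArrayLike, labels: list[ArrayLike] | NDArray, grouping: SemanticGrouping
) -> NDArray[np.float64]:
    """Per-group restricted relevance R(fk, C_i) = max_{l in C_i} I(fk; l)."""
    cols = _label_list(labels)
    return np.array(
        [max(mutual_information(fk, cols[i]) for i in g) for g in grouping.groups]
    )


def _label_list(labels: list[ArrayLike] | NDArray) -> list[NDArray]:
    if isinstance(labels, np.ndarray) and labels.ndim == 2:
        return [labels[:, j] for j in range(labels.shape[1])]
    return [np.asarray(l) for l in labels]


class _Precomputed:
    """Shared per-run cache of information terms over one dataset.

    The (d, q) feature-label MI table is built once; pairwise feature terms
    (MI, summed interaction/conditional terms) are filled lazily as the
    greedy loop requests them.  Caching never changes values — every entry
    is the same plug-in estimate recomputed on demand.
    """

    def __init__(self, data: DiscreteDataset):
        self.data = data
        F, L = data.features, data.labels
        d, q = data.d, data.q
        self.rel = np.array(
            [[mutual_information(F[:, k], L[:, i]) for i in range(q)] for k in range(d)]
        )
        self.relsum = self.rel.sum(axis=1)
        self.mc = self.rel.max(axis=1)
        self.h_feature = np.array([entropy(F[:, k]) for k in range(d)])
        self._ff_mi: dict[tuple[int, int], float] = {}
        self._ii_sum: dict[tuple[int, int], float] = {}
        self._cmi_sum: dict[tuple[int, int], float] = {}
        self._label_rel: NDArray[np.float64] | None = None
        self._pair_interaction: dict[str, NDArray[np.float64]] = {}

    def ff_mi(self, k: int, j: int) -> float:
        key = (min(k, j), max(k, j))
        if key not in self._ff_mi:
            F = self.data.features
            self._ff_mi[key] = mutual_information(F[:, k], F[:, j])
        return self._ff_mi[key]

    def ii_sum(self, k: int, j: int) -> float:
        """sum_i I(f_k; f_j; l_i) over all labels (symmetric in k, j)."""
        key = (min(k, j), max(k, j))
        if key not in self._ii_sum:
            F, L = self.data.features, self.data.labels
            self._ii_sum[key] = sum(
                interaction_information(F[:, k], F[:, j], L[:, i])
                for i in range(self.data.q)
            )
        return self._ii_sum[key]

    def cmi_sum(self, k: int, j: int) -> float:
        """sum_i I(f_k; l_i | f_j) — conditional relevance given f_j."""
        if (k, j) not in self._cmi_sum:
            F, L = self.data.features, self.data.labels
            self._cmi_sum[(k, j)] = sum(
                conditional_mutual_information(F[:, k], L[:, i], F[:, j])
                for i in range(self.data.q)
            )
        return self._cmi_sum[(k, j)]

    def label_rel(self) -> NDArray[np.float64]:
        """Per-feature sum_i sum_{j != i} I(f_k; l_j | l_i)."""
        if self._label_rel is None:
            F, L = self.data.features, self.data.labels
            q = self.data.q
            self._label_rel = np.array(
                [
                    sum(
                        conditional_mutual_information(F[:, k], L[:, j], L[:, i])
                        for i in range(q)
                        for j in range(q)
                        if i != j
                    )
                    for k in range(self.data.d)
                ]
            )
        return self._label_rel

    def label_pair_interaction(self, convention: str) -> NDArray[np.float64]:
        """Per-feature sum over label pairs of I(f_k; l_i; l_j).

        ``unordered``: each distinct pair {l_i, l_j} counted once;
        ``ordered``: both (l_i, l_j) and (l_j, l_i), doubling the term.
        The diagonal i = j is always excluded (it degenerates to I(f;l)).
        """
        if convention not in self._pair_interaction:
            F, L = self.data.features, self.data.labels
            q = self.data.q
            base = np.array(
                [
                    sum(
                        interaction_information(F[:, k], L[:, i], L[:, j])
                        for i in range(q)
                        for j in range(i + 1, q)
                    )
                    for k in range(self.data.d)
                ]
            )
            self._pair_interaction["unordered"] = base
            self._pair_interaction["ordered"] = 2.0 * base
        return self._pair_interaction[convention]


def _greedy(
    data: DiscreteDataset,
    b: int,
    method: str,
    first_score: Callable[[_Precomputed, int], float],
    step_score: Callable[[_Precomputed, int, list[int]], float],
    pre: _Precomputed | None = None,
) -> SelectionResult:
    if not 1 <= b <= data.d:
        raise ValueError(f"b must be in [1, {data.d}], got {b}")
    if pre is None:
        pre = _Precomputed(data)
    selected: list[int] = []
    scores: list[float] = []
    remaining = list(range(data.d))
    while len(selected) < b:
        if selected:
            j_vals = [step_score(pre, k, selected) for k in remaining]
        else:
            j_vals = [first_score(pre, k) for k in remaining]
        best = int(np.argmax(j_vals))  # first max -> lowest-index tie-break
        selected.append(remaining.pop(best))
        scores.append(float(j_vals[best]))
    names = [data.feature_names[k] for k in selected]
    return SelectionResult(method, selected, names, scores, b)


def mcmfs_select(data: DiscreteDataset, b: int, **_: object) -> SelectionResult:
    """Max-correlation selection: max_l I(f;l) minus mean redundancy with S."""
    return _greedy(
        data,
        b,
        "mcmfs",
        lambda p, k: p.mc[k],
        lambda p, k, S: p.mc[k] - sum(p.ff_mi(k, j) for j in S) / len(S),
    )


def d2f_select(data: DiscreteDataset, b: int, **_: object) -> SelectionResult:
    """Summed relevance minus summed feature-feature-label interaction."""
    return _greedy(
        data,
        b,
        "d2f",
        lambda p, k: p.relsum[k],
        lambda p, k, S: p.relsum[k] - sum(p.ii_sum(k, j) for j in S),
    )


def scls_select(data: DiscreteDataset, b: int, **_: object) -> SelectionResult:
    """Scalable criterion: relevance scaled down by normalized redundancy."""

    def step(p: _Precomputed, k: int, S: list[int]) -> float:
        if p.h_feature[k] == 0.0:
            return 0.0
        red = sum(p.ff_mi(k, j) for j in S) / p.h_feature[k]
        return p.relsum[k] - red * p.relsum[k]

    return _greedy(data, b, "scls", lambda p, k: p.relsum[k], step)


def mdmr_select(data: DiscreteDataset, b: int, **_: object) -> SelectionResult:
    """Max-dependency min-redundancy: mean of I(f_k;f_j) - sum_i I(f_k;l_i|f_j)."""
    return _greedy(
        data,
        b,
        "mdmr",
        lambda p, k: p.relsum[k],
        lambda p, k, S: p.relsum[k]
        - sum(p.ff_mi(k, j) - p.cmi_sum(k, j) for j in S) / len(S),
    )


def pmu_select(
    data: DiscreteDataset, b: int, label_pairs: str = "unordered", **_: object
) -> SelectionResult:
    """Pairwise multi-label utility with a label-pair interaction penalty.

    ``label_pairs`` picks the convention for the sum over label pairs:
    ``unordered`` (default; each pair once) or ``ordered`` (both directions,
    doubling the term relative to the other criterion components).
    """
    if label_pairs not in ("unordered", "ordered"):
        raise ValueError("label_pairs must be 'unordered' or 'ordered'")

    def pair(p: _Precomputed, k: int) -> float:
        return p.label_pair_interaction(label_pairs)[k]

    return _greedy(
        data,
        b,
        "pmu",
        lambda p, k: p.relsum[k] - pair(p, k),
        lambda p, k, S: p.relsum[k] - sum(p.ii_sum(k, j) for j in S) - pair(p, k),
    )


def lrfs_select(data: DiscreteDataset, b: int, **_: object) -> SelectionResult:
    """Label-redundancy criterion, implemented in its printed per-label form.

    The redundancy term sits inside the outer label sum, so it is weighted
    by the number of labels q relative to the relevance term.
    """
    q = data.q
    return _greedy(
        data,
        b,
        "lrfs",
        lambda p, k: p.label_rel()[k],
        lambda p, k, S: p.label_rel()[k] - q * sum(p.ff_mi(k, j) for j in S) / len(S),
    )


def ppt_transform(
    labels: ArrayLike, min_count: int = 6
) -> tuple[NDArray[np.int64], NDArray[np.bool_]]:
    """Pruned label-powerset transform.

    Each distinct label combination becomes one class (codes assigned in
    order of first occurrence); instances whose combination occurs fewer
    than ``min_count`` times are dropped.  Returns (class codes over kept
    rows, boolean keep-mask over the original rows).
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    Y = np.asarray(labels, dtype=np.int64)
    if Y.ndim != 2:
        raise ValueError("labels must be an (n, q) matrix")
    keys = [tuple(row) for row in Y]
    counts: dict[tuple, int] = {}
    for key in keys:
        counts[key] = counts.get(key, 0) + 1
    mask = np.array([counts[key] >= min_count for key in keys])
    if not mask.any():
        raise ValueError(f"all instances pruned at min_count={min_count}")
    code_of: dict[tuple, int] = {}
    classes = np.empty(int(mask.sum()), dtype=np.int64)
    pos = 0
    for key, keep in zip(keys, mask):
        if not keep:
            continue
        if key not in code_of:
            code_of[key] = len(code_of)
        classes[pos] = code_of[key]
        pos += 1
    return classes, mask


def _univariate_rank(
    data: DiscreteDataset,
    method: str,
    stat: Callable[[NDArray, NDArray], float],
    min_count: int,
    b: int | None,
) -> SelectionResult:
    classes, mask = ppt_transform(data.labels, min_count)
    F = data.features[mask]
    scores = np.array([stat(F[:, k], classes) for k in range(data.d)])
    order = list(np.argsort(-scores, kind="stable"))  # descending, index tie-break
    b = data.d if b is None else b
    if not 1 <= b <= data.d:
        raise ValueError(f"b must be in [1, {data.d}], got {b}")
    order = [int(k) for k in order[:b]]
    return SelectionResult(
        method, order, [data.feature_names[k] for k in order],
        [float(scores[k]) for k in order], b,
    )


def _chi2_stat(x: NDArray, c: NDArray) -> float:
    table = np.zeros((int(x.max()) + 1, int(c.max()) + 1))
    np.add.at(table, (x, c), 1)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0
    return float(chi2_contingency(table, correction=False).statistic)


def ppt_mi_rank(
    data: DiscreteDataset, b: int | None = None, min_count: int = 6, **_: object
) -> SelectionResult:
    """Rank features by MI with the pruned label-powerset class."""
    return _univariate_rank(data, "ppt-mi", mutual_information, min_count, b)


def ppt_chi_rank(
    data: DiscreteDataset, b: int | None = None, min_count: int = 6, **_: object
) -> SelectionResult:
    """Rank features by Pearson chi-squared against the pruned powerset class."""
    return _univariate_rank(data, "ppt-chi", _chi2_stat, min_count, b)


SELECTORS: dict[str, Callable[..., SelectionResult]] = {
    "mcmfs": mcmfs_select,
    "d2f": d2f_select,
    "scls": scls_select,
    "mdmr": mdmr_select,
    "pmu": pmu_select,
    "lrfs": lrfs_select,
    "ppt-mi": ppt_mi_rank,
    "ppt-chi": ppt_chi_rank,
}


def select(data: DiscreteDataset, method: str, b: int, **config: object) -> SelectionResult:
    """Run a named selector; uniform entry point used by evaluation and the CLI."""
    try:
        fn = SELECTORS[method]
    except KeyError:
        raise ValueError(f"unknown selection method {method!r}; choose from {sorted(SELECTORS)}")
    return fn(data, b, **config)
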