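"""Dataset containers, equal-width discretization and multi-label I/O.

A :class:`DiscreteDataset` is the in-memory form every selector consumes:
an (n, d) integer-coded feature matrix plus an (n, q) binary label matrix,
both with names.  Continuous data is discretized with an equal-width
strategy (default three bins) before selection; already-integer columns
(e.g. binary indicator features) pass through unchanged.

Readers cover the two formats multi-label benchmarks typically come in:
Mulan-style ARFF with an XML label header, and plain CSV/TSV with labels
as named (or trailing) columns.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray
from scipy.io import arff as scipy_arff

__all__ = [
    "DiscreteDataset",
    "TrainTestPair",
    "EqualWidthDiscretizer",
    "equal_width_discretize",
    "read_mulan_arff",
    "read_csv_dataset",
    "write_csv",
]


@dataclass
class DiscreteDataset:
    """Integer-coded multi-label dataset: n instances, d features, q labels."""

    features: NDArray[np.int64]
    labels: NDArray[np.int64]
    feature_names: list[str] = field(default_factory=list)
    label_names: list[str] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.features.ndim != 2 or self.labels.ndim != 2:
            raise ValueError("features and labels must be 2-D matrices")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"row mismatch: {self.features.shape[0]} feature rows vs "
                f"{self.labels.shape[0]} label rows"
            )
        if min(self.features.shape) < 1 or self.labels.shape[1] < 1:
            raise ValueError("need at least one instance, one feature and one label")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        if self.features.min() < 0:
            raise ValueError("feature codes must be non-negative")
        if not self.feature_names:
            self.feature_names = [f"f{j + 1}" for j in range(self.d)]
        if not self.label_names:
            self.label_names = [f"l{j + 1}" for j in range(self.q)]
        if len(self.feature_names) != self.d or len(self.label_names) != self.q:
            raise ValueError("name lists do not match matrix dimensions")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    @property
    def q(self) -> int:
        return self.labels.shape[1]

    def feature(self, k: int) -> NDArray[np.int64]:
        return self.features[:, k]

    def label(self, i: int) -> NDArray[np.int64]:
        return self.labels[:, i]

    def label_columns(self) -> list[NDArray[np.int64]]:
        return [self.labels[:, i] for i in range(self.q)]

    def subset_features(self, indices: list[int]) -> "DiscreteDataset":
        return DiscreteDataset(
            self.features[:, indices],
            self.labels,
            [self.feature_names[k] for k in indices],
            list(self.label_names),
            provenance=self.provenance,
        )

    def subset_rows(self, mask_or_index: ArrayLike) -> "DiscreteDataset":
        idx = np.asarray(mask_or_index)
        return DiscreteDataset(
            self.features[idx],
            self.labels[idx],
            list(self.feature_names),
            list(self.label_names),
            provenance=self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.hstack([self.features, self.labels]),
            columns=self.feature_names + self.label_names,
        )


@dataclass
class TrainTestPair:
    """A pre-separated train/test split with identical schema."""

    train: DiscreteDataset
    test: DiscreteDataset

    def __post_init__(self) -> None:
        if self.train.feature_names != self.test.feature_names:
            raise ValueError("train and test feature names differ")
        if self.train.label_names != self.test.label_names:
            raise ValueError("train and test label names differ")


class EqualWidthDiscretizer:
    """Per-column equal-width binning of a real matrix into integer codes.

    For a column with observed range [a, b] the bin edges are
    ``a + i * (b - a) / bins`` for i = 0..bins; intervals are left-closed,
    right-open, except the last which is closed.  A constant column maps
    entirely to code 0.  When applied to unseen data, values outside the
    fitted range clamp to the outer bins.
    """

    def __init__(self, bins: int = 3):
        if bins < 2:
            raise ValueError("bins must be >= 2")
        self.bins = bins
        self.edges_: list[NDArray[np.float64]] | None = None

    def fit(self, matrix: ArrayLike, names: list[str] | None = None) -> "EqualWidthDiscretizer":
        X = np.asarray(matrix, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D matrix")
        self.edges_ = []
        for j in range(X.shape[1]):
            col = X[:, j]
            if np.isnan(col).any():
                name = names[j] if names else f"column {j}"
                raise ValueError(f"NaN values in feature {name!r}")
            lo, hi = col.min(), col.max()
            self.edges_.append(np.linspace(lo, hi, self.bins + 1))
        return self

    def transform(self, matrix: ArrayLike) -> NDArray[np.int64]:
        if self.edges_ is None:
            raise RuntimeError("discretizer is not fitted")
        X = np.asarray(matrix, dtype=float)
        out = np.zeros(X.shape, dtype=np.int64)
        for j, edges in enumerate(self.edges_):
            if edges[0] == edges[-1]:  # constant column at fit time
                continue
            codes = np.searchsorted(edges[1:-1], X[:, j], side="right")
            out[:, j] = np.clip(codes, 0, self.bins - 1)
        return out

    def fit_transform(self, matrix: ArrayLike, names: list[str] | None = None) -> NDArray[np.int64]:
        return self.fit(matrix, names).transform(matrix)


def equal_width_discretize(
    matrix: ArrayLike, bins: int = 3
) -> tuple[NDArray[np.int64], list[NDArray[np.float64]]]:
    """Equal-width discretize a real matrix; returns (codes, per-column edges)."""
    disc = EqualWidthDiscretizer(bins)
    codes = disc.fit_transform(matrix)
    assert disc.edges_ is not None
    return codes, disc.edges_


def _is_integral(col: NDArray) -> bool:
    return bool(np.all(col == np.floor(col)))


def _build_dataset(
    frame: pd.DataFrame,
    label_names: list[str],
    provenance: str,
    bins: int | None,
) -> DiscreteDataset:
    missing = [name for name in label_names if name not in frame.columns]
    if missing:
        raise ValueError(f"label attributes not found in data: {missing}")
    feature_names = [c for c in frame.columns if c not in set(label_names)]
    if not feature_names:
        raise ValueError("no feature columns remain after removing labels")
    labels = frame[label_names].to_numpy()
    try:
        labels = labels.astype(float).astype(np.int64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"labels are not numeric 0/1: {exc}") from None
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("label columns must be binary 0/1")

    raw = frame[feature_names].to_numpy(dtype=float)
    if np.isnan(raw).any():
        j = int(np.argwhere(np.isnan(raw).any(axis=0))[0, 0])
        raise ValueError(f"NaN values in feature {feature_names[j]!r}")
    continuous = [j for j in range(raw.shape[1]) if not _is_integral(raw[:, j])]
    if continuous and bins is None:
        raise ValueError(
            f"feature {feature_names[continuous[0]]!r} is continuous; "
            "pass bins= to discretize"
        )
    if bins is not None:
        codes = EqualWidthDiscretizer(bins).fit_transform(raw, feature_names)
        # already-discrete columns (e.g. binary indicators) pass through
        for j in range(raw.shape[1]):
            if j not in continuous and raw[:, j].min() >= 0 and raw[:, j].max() < bins:
                codes[:, j] = raw[:, j].astype(np.int64)
    else:
        codes = raw.astype(np.int64)
        if codes.min() < 0:
            raise ValueError("integer features must be non-negative codes")
    return DiscreteDataset(codes, labels, feature_names, label_names, provenance)


def _labels_from_xml(xml_path: str | Path) -> list[str]:
    root = ET.parse(xml_path).getroot()
    names = [el.attrib["name"] for el in root.iter() if el.tag.endswith("label")]
    if not names:
        raise ValueError(f"no <label> elements found in {xml_path}")
    return names


def read_mulan_arff(
    arff_path: str | Path,
    labels: str | Path | list[str],
    bins: int | None = None,
) -> DiscreteDataset:
    """Read a Mulan-style dense multi-label ARFF file.

    ``labels`` is either a list of label attribute names or the path to the
    accompanying XML label header.  Label attributes must be binary
    (nominal {0,1} or numeric 0/1); all other attributes are features.
    """
    if isinstance(labels, (str, Path)):
        label_names = _labels_from_xml(labels)
    else:
        label_names = list(labels)
    data, meta = scipy_arff.loadarff(str(arff_path))
    frame = pd.DataFrame(data)
    for col in frame.columns:  # nominal attributes arrive as bytes
        if frame[col].dtype == object:
            frame[col] = frame[col].str.decode("utf-8").astype(float)
    return _build_dataset(frame, label_names, f"arff:{arff_path}", bins)


def read_csv_dataset(
    path: str | Path,
    labels: int | list[str],
    sep: str = ",",
    bins: int | None = None,
) -> DiscreteDataset:
    """Read a CSV/TSV dataset; ``labels`` is a name list or a count of trailing columns."""
    frame = pd.read_csv(path, sep=sep)
    if isinstance(labels, int):
        if not 1 <= labels < frame.shape[1]:
            raise ValueError(f"label count {labels} out of range for {frame.shape[1]} columns")
        label_names = list(frame.columns[-labels:])
    else:
        label_names = list(labels)
    return _build_dataset(frame, label_names, f"csv:{path}", bins)


def write_csv(dataset: DiscreteDataset, path: str | Path, sep: str = ",") -> None:
    dataset.to_frame().to_csv(path, sep=sep, index=False)
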