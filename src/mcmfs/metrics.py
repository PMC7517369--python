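"""Multi-label evaluation metrics: Hamming loss, zero-one loss, macro/micro F1.

Hamming loss is the mean fraction of the q labels on which prediction and
truth disagree; zero-one loss is the fraction of instances whose single
most-confident predicted label is not in the true label set.  Macro-F1
averages per-label F1 scores; micro-F1 pools TP/FP/FN counts over labels
first.  Lower is better for the losses, higher for the F1 scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from sklearn.metrics import f1_score

__all__ = [
    "PredictionSet",
    "hamming_loss",
    "zero_one_loss",
    "macro_f1",
    "micro_f1",
    "METRIC_DIRECTIONS",
]

#: optimization direction per metric, used by reporting
METRIC_DIRECTIONS = {
    "hamming_loss": "lower",
    "zero_one_loss": "lower",
    "macro_f1": "higher",
    "micro_f1": "higher",
}


@dataclass
class PredictionSet:
    """True and predicted binary label matrices, plus optional confidences.

    ``confidences`` holds the classifier's real-valued score h(x_i, l) for
    each instance/label cell; it is required only for zero-one loss.
    """

    true_labels: NDArray[np.int64]
    predicted_labels: NDArray[np.int64]
    confidences: NDArray[np.float64] | None = None

    def __post_init__(self) -> None:
        self.true_labels = np.asarray(self.true_labels, dtype=np.int64)
        self.predicted_labels = np.asarray(self.predicted_labels, dtype=np.int64)
        if self.true_labels.shape != self.predicted_labels.shape:
            raise ValueError(
                f"shape mismatch: true {self.true_labels.shape} vs "
                f"predicted {self.predicted_labels.shape}"
            )
        if self.true_labels.ndim != 2:
            raise ValueError("label matrices must be 2-D (instances x labels)")
        if self.confidences is not None:
            self.confidences = np.asarray(self.confidences, dtype=float)
            if self.confidences.shape != self.true_labels.shape:
                raise ValueError("confidences shape does not match label matrices")


def hamming_loss(p: PredictionSet) -> float:
    """Mean per-instance symmetric-difference size divided by q; in [0, 1]."""
    return float(np.mean(p.true_labels != p.predicted_labels))


def zero_one_loss(p: PredictionSet) -> float:
    """Fraction of instances whose top-confidence label is not relevant.

    Argmax ties break to the lowest label index; an instance with an empty
    true label set counts as an error (its top label cannot be relevant).
    """
    if p.confidences is None:
        raise ValueError("zero-one loss requires confidence scores")
    top = np.argmax(p.confidences, axis=1)
    hits = p.true_labels[np.arange(len(top)), top]
    return float(np.mean(hits == 0))


def macro_f1(p: PredictionSet, skip_undefined: bool = False) -> float:
    """Arithmetic mean of per-label F1 scores.

    A label with no true and no predicted positives has an undefined F1;
    by default it contributes 0 (set ``skip_undefined`` to average only
    over labels where F1 is defined).
    """
    if skip_undefined:
        per_label = f1_score(
            p.true_labels, p.predicted_labels, average=None, zero_division=np.nan
        )
        per_label = np.asarray(per_label, dtype=float)
        defined = ~np.isnan(per_label)
        if not defined.any():
            return 0.0
        return float(per_label[defined].mean())
    return float(
        f1_score(p.true_labels, p.predicted_labels, average="macro", zero_division=0)
    )


def micro_f1(p: PredictionSet) -> float:
    """F1 from TP/FP/FN counts pooled over all labels."""
    return float(
        f1_score(p.true_labels, p.predicted_labels, average="micro", zero_division=0)
    )


def compute_all(p: PredictionSet) -> dict[str, float]:
    """All four metrics; zero-one loss only when confidences are present."""
    out = {
        "hamming_loss": hamming_loss(p),
        "macro_f1": macro_f1(p),
        "micro_f1": micro_f1(p),
    }
    if p.confidences is not None:
        out["zero_one_loss"] = zero_one_loss(p)
    return out
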