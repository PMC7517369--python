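"""Group-structured synthetic multi-label data, plus the worked artificial dataset.

Real multi-label data typically shows high-order label structure: several
labels are near-synonyms of one underlying concept ("Athletics",
"Gymnastics", "Swimming" all signal "Sports"), so the label set partitions
into semantic groups with strong within-group and weak between-group
dependence.  The generator here realises exactly that structure with the
simplest latent-factor model: each group g has a hidden binary factor z_g
drawn per instance, the group's labels are noisy copies of z_g, each
group's informative features are independent noisy copies of z_g, and
noise features are independent fair coins.  Group sizes can be made
imbalanced (e.g. 9 labels against 1) to probe whether a selector's
relevance term overweights large groups.

``table2_fixture`` returns the 10-instance, 8-feature, 5-label artificial
dataset used throughout the tests: its five labels form three semantic
groups ({l1,l2,l3}, {l4}, {l5}) visible in the label mutual-information
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocessing import DiscreteDataset
from .selectors import SemanticGrouping

__all__ = ["SyntheticSpec", "generate", "table2_fixture", "TABLE2_GROUPING"]


# 10 instances x (8 features | 5 labels)
_TABLE2 = np.array(
    [
        # f1 f2 f3 f4 f5 f6 f7 f8  l1 l2 l3 l4 l5
        [0, 1, 0, 0, 0, 1, 0, 0, 1, 1, 1, 0, 0],
        [1, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0, 0, 1],
        [1, 0, 1, 1, 0, 1, 1, 0, 0, 0, 0, 1, 0],
        [1, 1, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1],
        [0, 0, 1, 0, 1, 0, 1, 0, 0, 0, 0, 1, 0],
        [0, 1, 0, 0, 0, 0, 0, 0, 1, 1, 1, 0, 0],
        [0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 1],
        [0, 0, 0, 1, 0, 0, 0, 0, 1, 0, 0, 0, 0],
        [1, 0, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0, 0],
        [0, 0, 0, 0, 1, 0, 1, 0, 0, 0, 1, 0, 0],
    ],
    dtype=np.int64,
)

#: semantic grouping of the fixture's labels, evident from the label MI matrix
TABLE2_GROUPING = SemanticGrouping(groups=[[0, 1, 2], [3], [4]], q=5)


def table2_fixture() -> DiscreteDataset:
    """The embedded 10 x 8 x 5 artificial dataset (binary features and labels)."""
    return DiscreteDataset(
        _TABLE2[:, :8].copy(),
        _TABLE2[:, 8:].copy(),
        [f"f{j}" for j in range(1, 9)],
        [f"l{j}" for j in range(1, 6)],
        provenance="embedded artificial dataset",
    )


@dataclass
class SyntheticSpec:
    """Parameters of the latent-factor group-structured generator.

    Defaults model the imbalanced two-group scenario (a 9-label group vs a
    1-label group over q=10 labels) at n=2000 instances, with 3 informative
    features per group, 4 pure-noise features, a 10% feature flip rate and
    strong (0.8) within-group label coupling.
    """

    n: int = 2000
    group_sizes: tuple[int, ...] = (9, 1)
    features_per_group: int = 3
    noise_features: int = 4
    label_flip_prob: float = 0.1
    intra_group_coupling: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.group_sizes or any(g < 1 for g in self.group_sizes):
            raise ValueError("group sizes must be positive")
        if not 0.0 <= self.label_flip_prob < 0.5:
            raise ValueError("label_flip_prob must be in [0, 0.5)")
        if not 0.0 < self.intra_group_coupling <= 1.0:
            raise ValueError("intra_group_coupling must be in (0, 1]")
        if self.features_per_group < 1 or self.noise_features < 0:
            raise ValueError("need >= 1 informative feature per group, >= 0 noise features")

    @property
    def m(self) -> int:
        return len(self.group_sizes)

    @property
    def q(self) -> int:
        return int(sum(self.group_sizes))

    @property
    def d(self) -> int:
        return self.m * self.features_per_group + self.noise_features


def generate(spec: SyntheticSpec) -> tuple[DiscreteDataset, dict[str, int | str]]:
    """Draw a dataset from the group-structured model.

    Returns the dataset and a ground-truth map from feature name to the
    index of the group it is informative for, or ``"noise"``.

    Per instance and group g, a latent factor z_g ~ Bernoulli(1/2) is
    drawn.  Each of the group's labels copies z_g, flipped independently
    with probability ``label_flip_prob * (1 - intra_group_coupling)`` (at
    coupling 1 the group's labels are exact copies of each other).  Each
    of the group's informative features copies z_g flipped with
    probability ``label_flip_prob``; noise features are Bernoulli(1/2).
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n, spec.m
    z = rng.integers(0, 2, size=(n, m))

    label_flip = spec.label_flip_prob * (1.0 - spec.intra_group_coupling)
    label_cols, label_names, grouping = [], [], []
    for g, size in enumerate(spec.group_sizes):
        for j in range(size):
            flips = rng.random(n) < label_flip
            label_cols.append(np.where(flips, 1 - z[:, g], z[:, g]))
            label_names.append(f"g{g + 1}_l{j + 1}")
            grouping.append(g)

    feature_cols, feature_names = [], []
    truth: dict[str, int | str] = {}
    for g in range(m):
        for j in range(spec.features_per_group):
            flips = rng.random(n) < spec.label_flip_prob
            feature_cols.append(np.where(flips, 1 - z[:, g], z[:, g]))
            name = f"g{g + 1}_f{j + 1}"
            feature_names.append(name)
            truth[name] = g
    for j in range(spec.noise_features):
        feature_cols.append(rng.integers(0, 2, size=n))
        name = f"noise_f{j + 1}"
        feature_names.append(name)
        truth[name] = "noise"

    data = DiscreteDataset(
        np.column_stack(feature_cols),
        np.column_stack(label_cols),
        feature_names,
        label_names,
        provenance=f"synthetic group-structured (seed={spec.seed})",
    )
    return data, truth


def grouping_of(spec: SyntheticSpec) -> SemanticGrouping:
    """The label partition implied by a spec (labels are emitted group-by-group)."""
    groups, start = [], 0
    for size in spec.group_sizes:
        groups.append(list(range(start, start + size)))
        start += size
    return SemanticGrouping(groups=groups, q=spec.q)
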