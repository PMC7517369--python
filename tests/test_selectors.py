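import numpy as np
import pytest

from mcmfs import (
    DiscreteDataset,
    SemanticGrouping,
    d2f_select,
    entropy,
    max_correlation,
    mcmfs_select,
    mutual_information,
    ppt_chi_rank,
    ppt_mi_rank,
    ppt_transform,
    select,
)
from mcmfs.selectors import SELECTORS, correlation_vector
from mcmfs.synthetic_data import TABLE2_GROUPING, SyntheticSpec, generate

from . import oracles

GREEDY_METHODS = ["mcmfs", "d2f", "scls", "mdmr", "pmu", "lrfs"]

# published rankings on the embedded artificial dataset
EXPECTED_ORDERS = {
    "mcmfs": ["f2", "f8", "f3", "f7", "f4", "f5", "f6", "f1"],
    "d2f": ["f2", "f7", "f1", "f6", "f8", "f4", "f3", "f5"],
    "scls": ["f2", "f7", "f3", "f4", "f1", "f6", "f8", "f5"],
    "mdmr": ["f2", "f7", "f3", "f8", "f4", "f5", "f1", "f6"],
    "pmu": ["f8", "f7", "f1", "f6", "f2", "f4", "f5", "f3"],
    "lrfs": ["f2", "f7", "f8", "f3", "f1", "f4", "f5", "f6"],
}


class TestMaxCorrelation:
    def test_copy_of_a_label_scores_its_entropy(self, table2):
        assert max_correlation(table2.label(0), table2.labels) == pytest.approx(
            0.971, abs=5e-4
        )

    def test_f8_is_most_relevant_to_the_small_group_label(self, table2):
        # f8's best label is l5; it is also the best feature FOR l5
        mis = [mutual_information(table2.feature(7), table2.label(i)) for i in range(5)]
        assert int(np.argmax(mis)) == 4
        assert max_correlation(table2.feature(7), table2.labels) == pytest.approx(
            max(mis), abs=1e-12
        )
        per_feature_l5 = [
            mutual_information(table2.feature(k), table2.label(4)) for k in range(8)
        ]
        assert int(np.argmax(per_feature_l5)) == 7

    def test_single_label_reduces_to_plain_mi(self, table2):
        f = table2.feature(1)
        assert max_correlation(f, [table2.label(0)]) == pytest.approx(
            mutual_information(f, table2.label(0)), abs=1e-12
        )

    def test_empty_label_set_rejected(self, table2):
        with pytest.raises(ValueError, match="empty"):
            max_correlation(table2.feature(0), [])

    def test_grouped_correlation_vector(self, table2):
        vec = correlation_vector(table2.feature(1), table2.labels, TABLE2_GROUPING)
        assert vec.shape == (3,)
        assert vec.max() == pytest.approx(
            max_correlation(table2.feature(1), table2.labels), abs=1e-12
        )


class TestPublishedRankings:
    @pytest.mark.parametrize("method", GREEDY_METHODS)
    def test_fixture_order(self, table2, method):
        assert select(table2, method, 8).names == EXPECTED_ORDERS[method]

    def test_pmu_ordered_pair_convention_changes_midranks(self, table2):
        # doubling the label-pair term reshuffles the middle of the ranking
        ordered = select(table2, "pmu", 8, label_pairs="ordered").names
        assert ordered[0] == "f8"
        assert ordered != EXPECTED_ORDERS["pmu"]

    def test_mcmfs_first_step_is_argmax_of_max_correlation(self, table2):
        result = mcmfs_select(table2, 8)
        mcs = [max_correlation(table2.feature(k), table2.labels) for k in range(8)]
        assert result.order[0] == int(np.argmax(mcs))
        assert result.scores[0] == pytest.approx(max(mcs), abs=1e-12)

    def test_b_of_one_ranks_by_relevance(self, table2):
        assert mcmfs_select(table2, 1).names == ["f2"]

    @pytest.mark.parametrize("bad_b", [0, -1, 9])
    def test_invalid_budget_rejected(self, table2, bad_b):
        with pytest.raises(ValueError):
            mcmfs_select(table2, bad_b)


class TestGreedyInvariants:
    @pytest.mark.parametrize("method", GREEDY_METHODS)
    def test_prefix_property(self, table2, method):
        full = select(table2, method, 8)
        short = select(table2, method, 3)
        assert short.order == full.order[:3]
        assert short.scores == pytest.approx(full.scores[:3])

    @pytest.mark.parametrize("method", GREEDY_METHODS)
    def test_determinism(self, table2, method):
        a, b = select(table2, method, 8), select(table2, method, 8)
        assert a.order == b.order and a.scores == b.scores

    def test_duplicate_feature_penalized_by_own_entropy(self):
        f = np.tile([0, 1], 20)  # balanced, H = 1 bit
        weak = np.array([1] * 10 + [0] * 30)  # independent of f, H < 1 bit
        labels = np.column_stack([f, weak])
        data = DiscreteDataset(np.column_stack([f, f, weak]), labels)
        result = mcmfs_select(data, 3)
        assert result.order[0] == 0  # tie between the two copies -> lowest index
        # the duplicate's redundancy penalty is its own entropy: J = H(f) - H(f) = 0
        assert result.order[1] == 2
        step2_dup = max_correlation(f, labels) - mutual_information(f, f)
        assert step2_dup == pytest.approx(0.0, abs=1e-12)
        assert entropy(weak) - mutual_information(weak, f) > 0.5

    def test_independent_labels_give_zero_scores_and_index_order(self):
        n = 16
        features = np.column_stack([np.arange(n) % 2, (np.arange(n) // 2) % 2])
        labels = np.zeros((n, 1), dtype=int)
        labels[:1] = 1  # nearly-constant label, still valid
        res = d2f_select(DiscreteDataset(features, labels), 2)
        assert res.order == [0, 1]


class TestPerStepScoreOracles:
    """Each criterion's J at each step vs a naive from-scratch recomputation."""

    @staticmethod
    def _naive_scores(data, method, order):
        F, L = data.features, data.labels
        d, q = data.d, data.q
        mi = oracles.mutual_information
        cmi = oracles.conditional_mutual_information
        ii = oracles.interaction_information

        def rel(k):
            return sum(max(0.0, mi(F[:, k], L[:, i])) for i in range(q))

        def mc(k):
            return max(max(0.0, mi(F[:, k], L[:, i])) for i in range(q))

        scores = []
        S: list[int] = []
        for k in order:
            if method == "mcmfs":
                j = mc(k) if not S else mc(k) - np.mean(
                    [max(0.0, mi(F[:, k], F[:, s])) for s in S]
                )
            elif method == "d2f":
                j = rel(k) - sum(
                    ii(F[:, k], F[:, s], L[:, i]) for s in S for i in range(q)
                )
            elif method == "scls":
                h = oracles.entropy(F[:, k])
                if h == 0:
                    j = 0.0
                else:
                    red = sum(max(0.0, mi(F[:, k], F[:, s])) for s in S) / h
                    j = rel(k) - red * rel(k)
            elif method == "mdmr":
                j = rel(k)
                if S:
                    j -= np.mean(
                        [
                            max(0.0, mi(F[:, k], F[:, s]))
                            - sum(
                                max(0.0, cmi(F[:, k], L[:, i], F[:, s]))
                                for i in range(q)
                            )
                            for s in S
                        ]
                    )
            elif method == "pmu":
                pair = sum(
                    ii(F[:, k], L[:, i], L[:, j2])
                    for i in range(q)
                    for j2 in range(i + 1, q)
                )
                j = (
                    rel(k)
                    - sum(ii(F[:, k], F[:, s], L[:, i]) for s in S for i in range(q))
                    - pair
                )
            elif method == "lrfs":
                j = sum(
                    max(0.0, cmi(F[:, k], L[:, j2], L[:, i]))
                    for i in range(q)
                    for j2 in range(q)
                    if i != j2
                )
                if S:
                    j -= q * np.mean([max(0.0, mi(F[:, k], F[:, s])) for s in S])
            scores.append(float(j))
            S.append(k)
        return scores

    @pytest.mark.parametrize("method", GREEDY_METHODS)
    def test_scores_match_naive_recomputation(self, table2, method):
        result = select(table2, method, 8)
        naive = self._naive_scores(table2, method, result.order)
        assert result.scores == pytest.approx(naive, abs=1e-9)


class TestGroupCoverage:
    def test_top_features_cover_more_groups_than_cumulative_summation(self):
        """With one 9-label and one 1-label group, max-correlation selection
        picks features for both groups while summed relevance stays inside
        the large group."""
        mc_hits = d2f_hits = 0
        for seed in range(20):
            data, truth = generate(SyntheticSpec(n=1000, seed=seed))
            for counter, selector in ((0, mcmfs_select), (1, d2f_select)):
                top2 = selector(data, 2).order
                covered = {truth[data.feature_names[k]] for k in top2}
                if covered == {0, 1}:
                    if selector is mcmfs_select:
                        mc_hits += 1
                    else:
                        d2f_hits += 1
        assert mc_hits > d2f_hits


class TestPPT:
    def test_min_count_one_is_pure_label_powerset(self, table2):
        classes, mask = ppt_transform(table2.labels, min_count=1)
        assert mask.all()
        # distinct label rows of the fixture: 7 combinations
        assert classes.max() + 1 == 7
        assert len(np.unique(classes)) == 7

    def test_rare_combinations_are_pruned(self):
        labels = np.array([[1, 0]] * 5 + [[0, 1]])
        classes, mask = ppt_transform(labels, min_count=2)
        assert mask.sum() == 5
        assert (classes == 0).all()

    def test_all_pruned_rejected(self):
        labels = np.array([[1, 0], [0, 1]])
        with pytest.raises(ValueError, match="pruned"):
            ppt_transform(labels, min_count=3)

    def test_feature_identical_to_class_ranks_first(self, table2):
        classes, mask = ppt_transform(table2.labels, min_count=1)
        features = np.column_stack([table2.features[mask], classes])
        data = DiscreteDataset(features, table2.labels[mask])
        for rank in (ppt_mi_rank(data, min_count=1), ppt_chi_rank(data, min_count=1)):
            assert rank.order[0] == data.d - 1

    def test_constant_feature_scores_zero_and_ranks_last(self, table2):
        features = np.column_stack([table2.features, np.zeros(10, dtype=int)])
        data = DiscreteDataset(features, table2.labels)
        for rank in (ppt_mi_rank(data, min_count=1), ppt_chi_rank(data, min_count=1)):
            assert rank.order[-1] == 8
            assert rank.scores[-1] == pytest.approx(0.0, abs=1e-12)

    def test_chi2_of_perfect_two_by_two_association_equals_n(self):
        x = np.array([1] * 5 + [0] * 5)
        labels = np.column_stack([x, 1 - x])
        data = DiscreteDataset(x.reshape(-1, 1), labels)
        rank = ppt_chi_rank(data, min_count=1)
        assert rank.scores[0] == pytest.approx(10.0, abs=1e-9)


class TestSelectionResultAPI:
    def test_tsv_and_json_serialization(self, table2, tmp_path):
        result = mcmfs_select(table2, 3)
        tsv = result.to_tsv(tmp_path / "r.tsv")
        assert tsv.splitlines()[0] == "rank\tfeature\tscore"
        assert tsv.splitlines()[1].startswith("1\tf2")
        import json

        payload = json.loads(result.to_json())
        assert payload["names"] == ["f2", "f8", "f3"]

    def test_unknown_method_rejected(self, table2):
        with pytest.raises(ValueError, match="unknown"):
            select(table2, "bogus", 2)

    def test_registry_covers_all_methods(self):
        assert set(SELECTORS) == {
            "mcmfs", "d2f", "scls", "mdmr", "pmu", "lrfs", "ppt-mi", "ppt-chi",
        }


class TestSemanticGrouping:
    def test_partition_validated(self):
        with pytest.raises(ValueError, match="partition"):
            SemanticGrouping(groups=[[0, 1], [1, 2]], q=3)
        with pytest.raises(ValueError, match="nonempty"):
            SemanticGrouping(groups=[[0, 1, 2], []], q=3)
        g = SemanticGrouping(groups=[[0, 2], [1]], q=3)
        assert g.m == 2 and g.group_of(1) == 1
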