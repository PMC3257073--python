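import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tests.oracles import (
    cmi_oracle,
    criterion_oracle,
    fsncmi_oracle,
    joint_entropy_oracle,
    mi_oracle,
    mrmr_oracle,
)
from ubisite.fsncmi import (
    SelectorConfig,
    conditional_mutual_information,
    criterion_J,
    discretize,
    fsncmi_select,
    generate_subsets,
    joint_entropy,
    mrmr_select,
    mutual_information,
    read_subsets,
    write_subsets,
)

TOL = 1e-9


def random_discretized(rng, n=40, d=6, informative=True):
    """A small random code matrix with an optional class-linked feature."""
    y = rng.integers(0, 2, n)
    codes = rng.integers(0, 4, (n, d))
    if informative:
        noise = rng.random(n) < 0.15
        codes[:, 0] = np.where(noise, 1 - y, y)
    from ubisite.fsncmi import DiscretizedMatrix

    return DiscretizedMatrix(
        codes=codes, y=y, feature_ids=[f"f{j}" for j in range(d)], B=4
    )


class TestDiscretize:
    def test_equal_frequency_bins(self):
        X = np.arange(1, 101, dtype=float).reshape(-1, 1)
        y = np.zeros(100, dtype=int)
        data = discretize(X, y, ["f"], B=5)
        counts = np.bincount(data.codes[:, 0])
        assert np.array_equal(counts, [20] * 5)

    def test_constant_feature_single_bin(self):
        X = np.full((30, 1), 3.14)
        data = discretize(X, np.zeros(30, int), ["f"], B=5)
        assert np.all(data.codes == 0)

    def test_binary_feature_two_bins(self):
        X = np.array([0.0, 1.0] * 15).reshape(-1, 1)
        data = discretize(X, np.zeros(30, int), ["f"], B=5)
        np.testing.assert_array_equal(np.unique(data.codes), [0, 1])
        np.testing.assert_array_equal(data.codes[:, 0], X[:, 0].astype(int))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            discretize(np.empty((0, 0)), np.empty(0, int), [], B=5)


class TestEstimators:
    def test_independence_gives_zero_mi(self):
        # product table: every (x, y) cell equally likely
        x = np.repeat([0, 0, 1, 1], 25)
        y = np.tile([0, 1, 0, 1], 25)
        assert mutual_information(x, y) == pytest.approx(0.0, abs=TOL)

    def test_identical_fair_bits_give_one_bit(self):
        x = np.array([0, 1] * 20)
        assert mutual_information(x, x) == pytest.approx(1.0, abs=TOL)

    def test_printed_2x2_table(self):
        # joint counts [[2, 1], [1, 2]]
        x = np.array([0, 0, 0, 1, 1, 1])
        y = np.array([0, 0, 1, 0, 1, 1])
        expected = mi_oracle(list(x), list(y))
        assert mutual_information(x, y) == pytest.approx(expected, abs=1e-12)
        assert mutual_information(x, y) == pytest.approx(0.08170, abs=1e-4)

    def test_joint_entropy_identities(self):
        x = np.array([0, 1] * 10)
        y = np.array([0, 0, 1, 1] * 5)
        assert joint_entropy(x, x) == pytest.approx(1.0, abs=TOL)
        assert joint_entropy(x, y) == pytest.approx(2.0, abs=TOL)

    def test_cmi_conditioning_on_constant_equals_mi(self, rng):
        x = rng.integers(0, 3, 50)
        y = rng.integers(0, 3, 50)
        z = np.zeros(50, dtype=int)
        assert conditional_mutual_information(x, y, z) == pytest.approx(
            mutual_information(x, y), abs=TOL
        )

    def test_cmi_of_known_variable_is_zero(self, rng):
        x = rng.integers(0, 3, 50)
        y = rng.integers(0, 3, 50)
        assert conditional_mutual_information(x, y, y) == pytest.approx(0.0, abs=TOL)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            mutual_information(np.array([0, 1]), np.array([0, 1, 0]))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.integers(0, 2**31 - 1),
        st.integers(5, 50),
        st.integers(2, 4),
    )
    def test_estimators_match_brute_force(self, seed, n, levels):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, levels, n)
        y = rng.integers(0, levels, n)
        z = rng.integers(0, levels, n)
        assert mutual_information(x, y) == pytest.approx(
            mi_oracle(list(x), list(y)), abs=TOL
        )
        assert joint_entropy(x, y) == pytest.approx(
            joint_entropy_oracle(list(x), list(y)), abs=TOL
        )
        assert conditional_mutual_information(x, y, z) == pytest.approx(
            cmi_oracle(list(x), list(y), list(z)), abs=TOL
        )
        # Shannon identity I = H(X) + H(Y) - H(X,Y) vs. the direct estimate
        from ubisite.fsncmi import entropy

        assert mutual_information(x, y) == pytest.approx(
            entropy(x) + entropy(y) - joint_entropy(x, y), abs=TOL
        )
        assert mutual_information(x, y) >= -TOL
        assert conditional_mutual_information(x, y, z) >= -TOL


class TestCriterion:
    def test_candidate_equal_to_member_scores_zero(self, rng):
        f = rng.integers(0, 3, 40)
        C = rng.integers(0, 2, 40)
        assert criterion_J(f, [f], C) == pytest.approx(0.0, abs=TOL)

    def test_single_member_reduces_to_one_term(self, rng):
        f = rng.integers(0, 3, 40)
        g = rng.integers(0, 3, 40)
        C = rng.integers(0, 2, 40)
        expected = conditional_mutual_information(f, C, g) / joint_entropy(f, C)
        assert criterion_J(f, [g], C) == pytest.approx(expected, abs=TOL)

    def test_min_over_subset_matches_oracle(self, rng):
        cols = [rng.integers(0, 3, 40) for _ in range(4)]
        C = rng.integers(0, 2, 40)
        got = criterion_J(cols[0], cols[1:], C)
        want = criterion_oracle(list(cols[0]), [list(c) for c in cols[1:]], list(C))
        assert got == pytest.approx(want, abs=TOL)

    def test_empty_selected_set_rejected(self, rng):
        with pytest.raises(ValueError, match="non-empty"):
            criterion_J(rng.integers(0, 3, 10), [], rng.integers(0, 2, 10))


class TestFsncmiSelect:
    def test_class_copy_feature_is_seeded_first(self, rng):
        data = random_discretized(rng, informative=True)
        subset = fsncmi_select(data, t=0, config=SelectorConfig(k=3, P=1))
        assert subset.feature_ids[0] == "f0"

    def test_duplicated_feature_pruned_not_selected(self, rng):
        from ubisite.fsncmi import DiscretizedMatrix

        y = rng.integers(0, 2, 60)
        f0 = np.where(rng.random(60) < 0.1, 1 - y, y)
        codes = np.column_stack([f0, f0, rng.integers(0, 3, (60, 3))])
        data = DiscretizedMatrix(
            codes=codes, y=y, feature_ids=[f"f{j}" for j in range(5)], B=3
        )
        subset = fsncmi_select(data, t=0, config=SelectorConfig(k=4, P=1))
        assert subset.feature_ids[0] == "f0"
        assert "f1" not in subset.feature_ids  # exact duplicate -> pruned

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("t,k", [(0, 3), (1, 4), (2, 6)])
    def test_greedy_trace_matches_exhaustive_oracle(self, seed, t, k):
        rng = np.random.default_rng(seed)
        data = random_discretized(rng, n=35, d=7)
        subset = fsncmi_select(data, t=t, config=SelectorConfig(k=k, P=1))
        expected = fsncmi_oracle(
            [list(data.codes[:, j]) for j in range(7)], list(data.y), t=t, k=k
        )
        assert subset.indices == expected

    def test_tie_breaks_toward_smaller_index(self):
        from ubisite.fsncmi import DiscretizedMatrix

        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 50)
        f0 = np.where(rng.random(50) < 0.2, 1 - y, y)  # noisy class copy seeds FS
        g = rng.integers(0, 3, 50)
        # two identical candidate columns -> exact tie -> smaller index wins
        codes = np.column_stack([f0, g, g])
        data = DiscretizedMatrix(codes=codes, y=y, feature_ids=["a", "b", "c"], B=3)
        subset = fsncmi_select(data, t=0, config=SelectorConfig(k=2, P=1))
        assert subset.feature_ids == ["a", "b"]

    def test_threshold_stop_with_large_delta(self, rng):
        data = random_discretized(rng, n=50, d=8)
        subset = fsncmi_select(data, t=0, config=SelectorConfig(k=8, delta=10.0, P=1))
        # the first comparable pair of greedy values always differs by < 10
        assert subset.stopping_reason == "threshold"
        assert len(subset) <= 3

    def test_trajectory_aligned_and_duplicate_free(self, rng):
        data = random_discretized(rng)
        subset = fsncmi_select(data, t=0, config=SelectorConfig(k=5, P=1))
        assert len(subset.trajectory) == len(subset.feature_ids)
        assert len(set(subset.feature_ids)) == len(subset.feature_ids)

    def test_out_of_range_start_rejected(self, rng):
        data = random_discretized(rng)
        with pytest.raises(ValueError, match="out of range"):
            fsncmi_select(data, t=data.n_features)


class TestGenerateSubsets:
    def test_single_subset_starts_at_top_rank(self, rng):
        data = random_discretized(rng)
        subsets = generate_subsets(data, SelectorConfig(k=3, P=1))
        assert len(subsets) == 1
        assert subsets[0].start == 0
        assert subsets[0].feature_ids[0] == "f0"

    def test_distinct_starting_points_give_distinct_seeds(self, rng):
        data = random_discretized(rng)
        subsets = generate_subsets(data, SelectorConfig(k=3, P=2))
        assert subsets[0].feature_ids[0] != subsets[1].feature_ids[0]

    def test_deterministic(self, rng):
        data = random_discretized(rng)
        a = generate_subsets(data, SelectorConfig(k=3, P=3))
        b = generate_subsets(data, SelectorConfig(k=3, P=3))
        assert [s.feature_ids for s in a] == [s.feature_ids for s in b]

    def test_more_subsets_than_features_rejected(self, rng):
        data = random_discretized(rng, d=4)
        with pytest.raises(ValueError, match="subsets"):
            generate_subsets(data, SelectorConfig(k=2, P=5))

    def test_tsv_round_trip(self, rng, tmp_path):
        data = random_discretized(rng)
        subsets = generate_subsets(data, SelectorConfig(k=3, P=2))
        path = tmp_path / "subsets.tsv"
        write_subsets(subsets, path)
        back = read_subsets(path)
        assert [s.feature_ids for s in back] == [s.feature_ids for s in subsets]
        assert [s.stopping_reason for s in back] == [s.stopping_reason for s in subsets]


class TestMrmr:
    def test_informative_feature_selected_first(self, rng):
        data = random_discretized(rng)
        subset = mrmr_select(data, k=2)
        assert subset.feature_ids[0] == "f0"

    def test_duplicate_penalized_by_redundancy(self, rng):
        from ubisite.fsncmi import DiscretizedMatrix

        y = rng.integers(0, 2, 60)
        f0 = np.where(rng.random(60) < 0.2, 1 - y, y)
        codes = np.column_stack([f0, f0, rng.integers(0, 2, (60, 2))])
        data = DiscretizedMatrix(
            codes=codes, y=y, feature_ids=["a", "a2", "n1", "n2"], B=2
        )
        subset = mrmr_select(data, k=2)
        assert subset.feature_ids[0] == "a"
        assert subset.feature_ids[1] != "a2"

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        data = random_discretized(rng, n=30, d=6)
        subset = mrmr_select(data, k=4)
        expected = mrmr_oracle(
            [list(data.codes[:, j]) for j in range(6)], list(data.y), k=4
        )
        assert subset.indices == expected
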