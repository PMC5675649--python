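"""Discretization, plug-in MI, and the MaxRel / mRMR rankings."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tepsel
from conftest import brute_force_mrmr, random_discrete_dataset


def direct_mi(table):
    """Independent evaluation of the plug-in MI double sum, in bits."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    total = 0.0
    for i, j in itertools.product(range(table.shape[0]), range(table.shape[1])):
        p = table[i, j] / n
        if p > 0:
            px = table[i].sum() / n
            py = table[:, j].sum() / n
            total += p * math.log2(p / (px * py))
    return total


def vectors_from_table(table):
    xs, ys = [], []
    for i, row in enumerate(table):
        for j, count in enumerate(row):
            xs.extend([i] * count)
            ys.extend([j] * count)
    return np.array(xs), np.array(ys)


class TestDiscretize:
    def test_constant_gene_all_state_one(self):
        m = pd.DataFrame({"s1": [4.0], "s2": [4.0], "s3": [4.0]}, index=["g"])
        d = tepsel.discretize(m)
        assert d.states.loc["g"].tolist() == [1, 1, 1]

    def test_two_sigma_spread_hits_all_states(self):
        # values at mean-2sd, mean, mean+2sd under the +-1 sigma cut
        m = pd.DataFrame([[-2.0, 0.0, 2.0]], index=["g"], columns=["a", "b", "c"])
        d = tepsel.discretize(m)
        assert d.states.loc["g"].tolist() == [0, 1, 2]

    def test_single_outlier_hand_computed(self):
        # values [1,1,1,1,10]: mean 2.8, population sd 3.6 -> z = [-0.5 x4, 2.0]
        m = pd.DataFrame([[1, 1, 1, 1, 10]], index=["g"], dtype=float)
        d = tepsel.discretize(m)
        assert d.states.loc["g"].tolist() == [1, 1, 1, 1, 2]

    def test_equal_frequency_fallback(self):
        m = pd.DataFrame([np.arange(8.0)], index=["g"])
        d = tepsel.discretize(m, n_bins=4)
        states = d.states.loc["g"].to_numpy()
        assert set(states) == {0, 1, 2, 3}
        assert (np.bincount(states) == 2).all()

    def test_rejects_bad_inputs(self):
        m = pd.DataFrame([[1.0, 2.0]], index=["g"])
        with pytest.raises(ValueError):
            tepsel.discretize(m, n_bins=1)
        with pytest.raises(ValueError):
            tepsel.discretize(m.iloc[:, :1])


class TestMutualInformation:
    def test_constant_partner_gives_zero(self):
        x = np.array([0, 1, 2, 0, 1])
        y = np.zeros(5, dtype=int)
        assert tepsel.mutual_information(x, y) == 0.0

    def test_self_information_is_entropy(self):
        x = np.array([0, 1, 0, 1])
        assert tepsel.mutual_information(x, x) == pytest.approx(1.0)
        x = np.array([0, 0, 1, 2, 2, 2])
        assert tepsel.mutual_information(x, x) == pytest.approx(tepsel.entropy(x))

    def test_hand_computed_joint_table(self):
        # counts [[2,1],[1,2]] -> (2/3)log2(4/3) + (1/3)log2(2/3)
        x, y = vectors_from_table([[2, 1], [1, 2]])
        expected = 0.0817041659455104
        assert tepsel.mutual_information(x, y) == pytest.approx(expected, abs=1e-12)
        assert direct_mi([[2, 1], [1, 2]]) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "table",
        [
            [[5, 0], [0, 5]],
            [[3, 3], [3, 3]],
            [[1, 2, 3], [4, 0, 1]],
            [[7]],
            [[2, 0, 1], [0, 4, 0], [1, 1, 2]],
        ],
    )
    def test_matches_direct_formula_on_enumerated_tables(self, table):
        x, y = vectors_from_table(table)
        assert tepsel.mutual_information(x, y) == pytest.approx(
            direct_mi(table), abs=1e-12
        )

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            tepsel.mutual_information([0, 1], [0, 1, 2])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        st.lists(st.integers(0, 3), min_size=2, max_size=40),
        st.integers(0, 2**31 - 1),
    )
    def test_nonnegative_symmetric_and_bounded(self, xs, seed):
        """MI >= 0, symmetric, and obeys I(x,y) <= min(H(x), H(y))."""
        rng = np.random.default_rng(seed)
        x = np.array(xs)
        y = rng.integers(0, 3, len(x))
        ixy = tepsel.mutual_information(x, y)
        assert ixy >= 0
        assert ixy == pytest.approx(tepsel.mutual_information(y, x), abs=1e-12)
        assert ixy <= min(tepsel.entropy(x), tepsel.entropy(y)) + 1e-12


class TestMaxRelList:
    def test_singleton(self, processed_cohort):
        processed, labels, _ = processed_cohort
        d = tepsel.discretize(processed.iloc[:1])
        out = tepsel.max_rel_list(d, labels)
        assert len(out) == 1 and out.kind == "maxrel"

    def test_label_copy_ranks_first(self):
        rng = np.random.default_rng(0)
        labels = pd.Series(
            rng.integers(0, 3, 60).astype(str), index=[f"s{i}" for i in range(60)]
        )
        states = rng.integers(0, 3, size=(5, 60))
        states[2] = labels.astype(int).to_numpy()  # feature 2 mirrors the target
        d = tepsel.DiscreteMatrix(
            pd.DataFrame(states, index=[f"g{i}" for i in range(5)], columns=labels.index)
        )
        out = tepsel.max_rel_list(d, labels)
        assert out.features[0] == "g2"

    def test_scores_non_increasing_and_complete(self, processed_cohort):
        processed, labels, _ = processed_cohort
        out = tepsel.max_rel_list(tepsel.discretize(processed), labels)
        assert len(out) == len(processed)
        assert (np.diff(out.scores) <= 1e-12).all()


class TestMrmrList:
    def test_first_element_matches_maxrel(self, processed_cohort):
        processed, labels, _ = processed_cohort
        d = tepsel.discretize(processed.iloc[:40])
        maxrel = tepsel.max_rel_list(d, labels)
        ranked = tepsel.mrmr_list(d, labels)
        assert ranked.features[0] == maxrel.features[0]
        assert set(ranked.features) == set(maxrel.features)

    def test_duplicate_of_top_feature_pushed_down(self):
        rng = np.random.default_rng(3)
        n = 90
        labels = pd.Series(
            rng.integers(0, 2, n).astype(str), index=[f"s{i}" for i in range(n)]
        )
        top = labels.astype(int).to_numpy() ^ (rng.random(n) < 0.2)  # noisy label copy
        noise = rng.integers(0, 3, size=(4, n))
        states = np.vstack([top, top, noise])  # g1 duplicates g0 exactly
        d = tepsel.DiscreteMatrix(
            pd.DataFrame(states, index=[f"g{i}" for i in range(6)], columns=labels.index)
        )
        ranked = tepsel.mrmr_list(d, labels)
        assert ranked.features[0] == "g0"
        # redundancy penalty: the exact copy cannot be picked second
        assert ranked.features[1] != "g1"

    def test_matches_brute_force_reference(self):
        rng = np.random.default_rng(12)
        for _ in range(15):
            d, labels = random_discrete_dataset(rng)
            fast = tepsel.mrmr_list(d, labels)
            slow = brute_force_mrmr(d, labels)
            assert fast.features == slow.features
            np.testing.assert_allclose(fast.scores, slow.scores, atol=1e-12)

    def test_n_select_prefix_of_full_run(self, processed_cohort):
        processed, labels, _ = processed_cohort
        d = tepsel.discretize(processed.iloc[:30])
        full = tepsel.mrmr_list(d, labels)
        capped = tepsel.mrmr_list(d, labels, n_select=10)
        assert capped.features == full.features[:10]
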