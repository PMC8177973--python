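"""mRMR ranking: discretization rules, plug-in mutual information against
independent oracles, and greedy-search equivalence with brute force."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import mutual_info_score

from semgsel import discretize, mrmr_rank, mutual_information


def mi_oracle(a, b) -> float:
    """Independent MI estimate in bits (sklearn contingency-based)."""
    return mutual_info_score(a, b) / math.log(2)


def bruteforce_mrmr(states, labels, m, criterion="mid"):
    """Re-derives the greedy selection from scratch with full MI tables
    recomputed at every step via the independent oracle."""
    d = states.shape[0]
    rel = [mi_oracle(states[j], labels) for j in range(d)]
    S = [min(range(d), key=lambda j: (-rel[j], j))]
    while len(S) < m:
        best, best_score = None, None
        for j in range(d):
            if j in S:
                continue
            red = sum(mi_oracle(states[j], states[i]) for i in S) / len(S)
            score = rel[j] - red if criterion == "mid" \
                else rel[j] / max(red, 1e-12)
            if best_score is None or score > best_score:
                best, best_score = j, score
        S.append(best)
    return S


class TestDiscretize:
    def test_sd_thresholds_hand_example(self):
        disc = discretize(np.array([[-10.0, 0.0, 10.0, 0.0]]))
        assert disc.states.tolist() == [[-1, 0, 1, 0]]

    def test_constant_row_maps_to_zero(self):
        disc = discretize(np.array([[3.0, 3.0, 3.0]]))
        assert disc.states.tolist() == [[0, 0, 0]]

    def test_at_most_three_states(self, rng):
        disc = discretize(rng.standard_normal((5, 200)))
        assert disc.alphabet_sizes.max() <= 3

    def test_quantile_scheme(self, rng):
        disc = discretize(rng.standard_normal((2, 300)), scheme="quantile",
                          n_bins=4)
        assert disc.alphabet_sizes.max() <= 4
        assert disc.scheme["method"] == "quantile"


class TestMutualInformation:
    def test_identical_uniform_binary_is_one_bit(self):
        a = np.array([0, 1] * 10)
        assert mutual_information(a, a) == pytest.approx(1.0)

    def test_constructed_independence_is_zero(self):
        a = np.array([0, 0, 1, 1])
        b = np.array([0, 1, 0, 1])
        assert mutual_information(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_four_cell_arithmetic_oracle(self):
        # joint counts [[2,1],[1,2]] over n=6
        a = np.array([0, 0, 0, 1, 1, 1])
        b = np.array([0, 0, 1, 0, 1, 1])
        expected = (2 * (2 / 6) * math.log2((2 / 6) / 0.25)
                    + 2 * (1 / 6) * math.log2((1 / 6) / 0.25))
        assert mutual_information(a, b) == pytest.approx(expected,
                                                         abs=1e-12)

    def test_matches_independent_oracle(self, rng):
        for _ in range(10):
            a = rng.integers(0, 4, 100)
            b = rng.integers(0, 3, 100)
            assert mutual_information(a, b) == \
                pytest.approx(mi_oracle(a, b), abs=1e-10)

    def test_self_information_is_entropy(self, rng):
        a = rng.integers(0, 3, 200)
        _, counts = np.unique(a, return_counts=True)
        p = counts / counts.sum()
        assert mutual_information(a, a) == \
            pytest.approx(-np.sum(p * np.log2(p)))

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            mutual_information([0, 1], [0, 1, 0])

    @given(st.lists(st.integers(0, 3), min_size=2, max_size=60),
           st.lists(st.integers(0, 3), min_size=2, max_size=60))
    def test_symmetric_and_nonnegative(self, a, b):
        n = min(len(a), len(b))
        a, b = np.asarray(a[:n]), np.asarray(b[:n])
        iab = mutual_information(a, b)
        assert iab >= -1e-12
        assert abs(iab - mutual_information(b, a)) < 1e-12

    @given(st.lists(st.integers(0, 2), min_size=4, max_size=60))
    def test_relabeling_invariance(self, a):
        a = np.asarray(a)
        b = (a * 7 + 3) % 11          # bijective recoding on {0,1,2}
        c = np.roll(a, 1)
        assert mutual_information(a, c) == \
            pytest.approx(mutual_information(b, c), abs=1e-12)


class TestGreedyRanking:
    def make_instance(self, seed, d=6, n=40):
        r = np.random.default_rng(seed)
        labels = r.integers(0, 3, n)
        X = r.standard_normal((d, n))
        X[0] += 2.0 * labels          # strongly relevant variable
        X[1] = X[0] + 0.01 * r.standard_normal(n)   # near duplicate
        return discretize(X), labels

    def test_first_pick_is_max_relevance(self):
        disc, labels = self.make_instance(0)
        vs, state = mrmr_rank(disc, labels, 1,
                              row_index=[(1, f"f{i}") for i in range(6)])
        assert state.selected[0] == int(np.argmax(state.relevance))

    def test_duplicate_never_beats_nonredundant_equal(self):
        # x1 duplicates x0; x2 has identical relevance (same joint
        # distribution with the label) but zero redundancy with x0.
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        x0 = np.array([0, 0, 0, 1, 1, 1, 1, 0])
        x2 = np.array([0, 1, 0, 0, 1, 0, 1, 1])
        from semgsel.mrmr import DiscretizedMatrix

        disc = DiscretizedMatrix(states=np.vstack([x0, x0, x2]), scheme={})
        assert mutual_information(x0, labels) == \
            pytest.approx(mutual_information(x2, labels))
        assert mutual_information(x0, x2) == pytest.approx(0.0, abs=1e-12)
        _, state = mrmr_rank(disc, labels, 2)
        assert state.selected == [0, 2]        # tie -> lowest index; then
        # the non-redundant variable beats the duplicate

    @pytest.mark.parametrize("criterion", ["mid", "miq"])
    @pytest.mark.parametrize("seed", range(8))
    def test_equals_bruteforce_oracle(self, seed, criterion):
        disc, labels = self.make_instance(seed, d=(6 + seed % 3))
        d = disc.states.shape[0]
        m = min(4 + seed % 3, d)
        _, state = mrmr_rank(disc, labels, m, criterion=criterion)
        assert state.selected == bruteforce_mrmr(disc.states, labels, m,
                                                 criterion)

    def test_sample_order_invariance(self):
        disc, labels = self.make_instance(9)
        perm = np.random.default_rng(1).permutation(len(labels))
        from semgsel.mrmr import DiscretizedMatrix

        disc_p = DiscretizedMatrix(states=disc.states[:, perm], scheme={})
        _, s1 = mrmr_rank(disc, labels, 4)
        _, s2 = mrmr_rank(disc_p, labels[perm], 4)
        assert s1.selected == s2.selected

    def test_m_out_of_range_errors(self):
        disc, labels = self.make_instance(2)
        with pytest.raises(ValueError):
            mrmr_rank(disc, labels, 99)
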