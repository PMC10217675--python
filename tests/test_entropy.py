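"""Entropy scoring against direct evaluation, and selection behavior."""

import numpy as np
import pytest

from fundusfuse import (
    feature_entropy,
    iterative_entropy_selection,
    select_by_mean_threshold,
    select_top_k,
)
from fundusfuse.entropy import EntropyProfile

from conftest import make_planted_matrix


def direct_entropy_from_mass(o: np.ndarray) -> np.ndarray:
    """Loop-based reference: rf_ik = o_ik / sum_k o_ik; E = -sum rf log2 rf."""
    D, t = o.shape
    E = np.zeros(D)
    for i in range(D):
        total = o[i].sum()
        if total == 0:
            E[i] = np.log2(t)
            continue
        for k in range(t):
            rf = o[i, k] / total
            if rf > 0:
                E[i] -= rf * np.log2(rf)
    return E


def profile_with_scores(scores) -> EntropyProfile:
    scores = np.asarray(scores, dtype=float)
    t = 2
    return EntropyProfile(np.log2(t) - scores, scores, t, np.zeros((scores.size, t)), np.zeros((scores.size, t)))


class TestEntropy:
    def test_equal_mass_over_five_classes_is_maximally_entropic(self):
        y = np.repeat(np.arange(5), 4)
        x = np.ones((20, 3))
        x[:, 1] = np.tile([0.2, 0.4, 0.6, 0.8], 5)  # same profile in every class
        prof = feature_entropy(x, y)
        assert prof.entropy == pytest.approx([np.log2(5)] * 3)
        assert prof.score == pytest.approx([0.0] * 3)

    def test_single_class_mass_has_zero_entropy(self):
        y = np.repeat(np.arange(5), 4)
        x = np.zeros((20, 1))
        x[y == 2, 0] = 1.0
        prof = feature_entropy(x, y)
        assert prof.entropy[0] == pytest.approx(0.0)
        assert prof.score[0] == pytest.approx(np.log2(5))

    def test_two_equal_masses_give_one_bit(self):
        y = np.array([0, 0, 1, 1])
        x = np.array([[0.0], [1.0], [0.5], [0.5]])  # class masses (1, 1) after min-max
        prof = feature_entropy(x, y)
        assert prof.o[0].tolist() == [1.0, 1.0]
        assert prof.entropy[0] == pytest.approx(1.0)

    def test_matches_direct_evaluation_on_handbuilt_6x3_table(self):
        """Six features, three classes, masses chosen by hand."""
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1, 2], 10)
        x = rng.random((30, 6))
        prof = feature_entropy(x, y)
        assert np.max(np.abs(prof.entropy - direct_entropy_from_mass(prof.o))) < 1e-12
        # the mass table itself matches a direct group-by sum of normalized values
        xn = (x - x.min(0)) / (x.max(0) - x.min(0))
        for k, c in enumerate([0, 1, 2]):
            assert np.allclose(prof.o[:, k], xn[y == c].sum(0))

    @pytest.mark.parametrize("seed", range(4))
    def test_entropy_bounds_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        t = int(rng.integers(2, 6))
        y = rng.integers(0, t, 60)
        while np.unique(y).size < t:
            y = rng.integers(0, t, 60)
        x = rng.random((60, 15))
        prof = feature_entropy(x, y)
        assert (prof.entropy >= -1e-12).all() and (prof.entropy <= np.log2(t) + 1e-12).all()
        nz = prof.o.sum(1) > 0
        assert np.allclose(prof.rf[nz].sum(1), 1.0)

    def test_all_zero_column_scores_zero(self):
        y = np.array([0, 0, 1, 1])
        x = np.array([[3.0, 1.0], [3.0, 2.0], [3.0, 3.0], [3.0, 1.0]])  # col0 constant -> all-zero after min-max
        prof = feature_entropy(x, y)
        assert prof.entropy[0] == pytest.approx(1.0) and prof.score[0] == pytest.approx(0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            feature_entropy(np.random.default_rng(0).random((5, 2)), np.zeros(5, dtype=int))

    def test_binned_mode_runs_and_bounds_hold(self):
        x, y = make_planted_matrix(0, n=50)
        prof = feature_entropy(x, y, mode="binned", bins=10)
        assert (prof.entropy <= np.log2(5) + 1e-12).all()


class TestSelectors:
    def test_all_equal_scores_selects_everything(self):
        sel = select_by_mean_threshold(profile_with_scores([0.4, 0.4, 0.4]))
        assert sel.k == 3 and sel.mask.all()

    def test_mean_threshold_arithmetic(self):
        sel = select_by_mean_threshold(profile_with_scores([0, 0, 3]))
        assert sel.indices.tolist() == [2]

    def test_selection_invariant_to_score_shift(self):
        a = select_by_mean_threshold(profile_with_scores([0.1, 0.5, 0.9]))
        b = select_by_mean_threshold(profile_with_scores([0.2, 0.6, 1.0]))
        assert np.array_equal(a.mask, b.mask)

    def test_top_k_full_and_argmax(self):
        prof = profile_with_scores([0.2, 0.9, 0.5])
        assert select_top_k(prof, 3).mask.all()
        assert select_top_k(prof, 1).indices.tolist() == [1]

    def test_top_k_tie_breaks_to_lower_index(self):
        sel = select_top_k(profile_with_scores([5.0, 5.0, 1.0]), 1)
        assert sel.indices.tolist() == [0]

    def test_top_k_range_checked(self):
        prof = profile_with_scores([0.1, 0.2])
        for bad in (0, 3):
            with pytest.raises(ValueError):
                select_top_k(prof, bad)

    def test_popcount_equals_k(self):
        prof = profile_with_scores(np.random.default_rng(0).random(20))
        for k in (1, 7, 20):
            assert select_top_k(prof, k).mask.sum() == k


class TestIterative:
    def test_stops_immediately_when_error_below_target(self):
        x, y = make_planted_matrix(0, n=50)
        sel = iterative_entropy_selection(x, y, lambda m: 0.0, max_rounds=5)
        assert sel.rounds == 1 and not sel.warning and sel.error == 0.0

    def test_exhausts_rounds_with_warning_when_never_satisfied(self):
        x, y = make_planted_matrix(1, n=50)
        sel = iterative_entropy_selection(x, y, lambda m: 0.5, max_rounds=3)
        assert sel.rounds == 3 and sel.warning and sel.error == 0.5

    def test_recovers_planted_columns(self):
        x, y = make_planted_matrix(0)
        from fundusfuse import make_knn_evaluator

        sel = iterative_entropy_selection(x, y, make_knn_evaluator(x, y, seed=0))
        assert len(set(sel.indices) & set(range(5))) >= 4
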