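"""Whale-optimization wrapper selection: update rules, fitness, refinement."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dermfusion.hwoa import (
    FitnessConfig, HWOASelector, amd_refine, binarize_position, fitness,
    update_shrink, woa_minimize, woa_position_update,
)


class TestUpdateShrink:
    @pytest.mark.parametrize("t, max_it, expected", [
        (0, 10, 2.0), (10, 10, 0.0), (5, 10, 1.0)])
    def test_endpoints_and_midpoint(self, t, max_it, expected):
        assert update_shrink(t, max_it) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            update_shrink(0, 0)
        with pytest.raises(ValueError):
            update_shrink(11, 10)


class TestPositionUpdate:
    def test_spiral_at_best_returns_best(self, rng):
        best = rng.uniform(size=6)
        out = woa_position_update(best.copy(), best, rng.uniform(size=6),
                                  1.0, r=rng.uniform(size=6), h=0.3, ran=0.9)
        np.testing.assert_allclose(out, best)

    def test_zero_shrink_encircling_collapses_to_best(self, rng):
        best = rng.uniform(size=6)
        out = woa_position_update(rng.uniform(size=6), best,
                                  rng.uniform(size=6), 0.0,
                                  r=rng.uniform(size=6), h=0.0, ran=0.2)
        np.testing.assert_allclose(out, best)

    def test_spiral_with_fixed_draws_matches_hand_evaluation(self):
        # h = 0: e^0 * cos(0) = 1, so new = |d| + best, then clamped
        best = np.array([0.2, 0.4, 0.3])
        d = np.array([0.1, -0.2, 0.3])
        out = woa_position_update(best + d, best, np.zeros(3), 1.0,
                                  r=np.full(3, 0.5), h=0.0, ran=0.9)
        np.testing.assert_allclose(out, np.clip(np.abs(d) + best, 0, 1))

    @given(st.integers(0, 2**31 - 1))
    def test_output_always_in_unit_box(self, seed):
        g = np.random.default_rng(seed)
        out = woa_position_update(
            g.uniform(size=8), g.uniform(size=8), g.uniform(size=8),
            g.uniform(0, 2), r=g.uniform(size=8),
            h=g.uniform(-1, 1), ran=g.uniform())
        assert np.all(out >= 0.0) and np.all(out <= 1.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            woa_position_update(np.zeros(3), np.zeros(4), np.zeros(3),
                                1.0, np.zeros(3), 0.0, 0.1)


class TestFitness:
    @pytest.mark.parametrize("err, k, total, expected", [
        (0.2, 50, 100, 0.203),
        (0.0, 100, 100, 0.01),
        (1.0, 1, 100, 0.9901)])
    def test_values(self, err, k, total, expected):
        cfg = FitnessConfig(alpha_weight=0.99, beta_weight=0.01)
        assert fitness(err, k, total, cfg) == pytest.approx(expected)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty subset"):
            fitness(0.5, 0, 10, FitnessConfig())

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            FitnessConfig(alpha_weight=0.9, beta_weight=0.2)


class TestBinarize:
    def test_threshold_inclusive(self):
        np.testing.assert_array_equal(
            binarize_position(np.array([0.2, 0.7, 0.5]), 0.5),
            [False, True, True])
        np.testing.assert_array_equal(
            binarize_position(np.full(4, 0.5), 0.5), [True] * 4)

    def test_empty_mask_repaired_to_argmax(self):
        mask = binarize_position(np.array([0.1, 0.3, 0.2]), 0.5)
        np.testing.assert_array_equal(mask, [False, True, False])
        assert binarize_position(np.zeros(5), 0.5).sum() == 1


class TestAmdRefine:
    def test_zero_dispersion_keeps_all(self):
        assert amd_refine(np.ones(4)).sum() == 4

    def test_bimodal_keeps_high_group(self):
        mask = amd_refine(np.array([0.0, 0.0, 1.0, 1.0]))
        np.testing.assert_array_equal(mask, [False, False, True, True])

    def test_min_features_fallback_pads_by_score(self):
        # MD = 0.3: only the 0.9 clears it; floor of 2 pads with next best
        mask = amd_refine(np.array([0.1, 0.1, 0.1, 0.9]), min_features=2)
        assert mask.sum() == 2 and mask[3]


class TestWoaMinimize:
    def test_sphere_function_converges(self):
        _, best, trace = woa_minimize(lambda x: float(np.sum(x**2)), dim=10,
                                      n_agents=30, max_iterations=200, seed=1)
        assert best < 1e-2
        assert np.all(np.diff(trace) <= 0)

    def test_trace_non_increasing_across_seeds(self):
        for seed in range(3):
            _, _, trace = woa_minimize(lambda x: float(np.sum((x - 0.3)**2)),
                                       dim=5, n_agents=10, max_iterations=30,
                                       seed=seed)
            assert np.all(np.diff(trace) <= 0)


class TestSelector:
    def test_bit_reproducible_and_trace_monotone(self, benchmark_data):
        fm, _ = benchmark_data
        a = HWOASelector(max_iterations=10, n_eval_splits=1, random_state=3)
        b = HWOASelector(max_iterations=10, n_eval_splits=1, random_state=3)
        a.fit(fm.values, fm.labels)
        b.fit(fm.values, fm.labels)
        np.testing.assert_array_equal(a.support_, b.support_)
        np.testing.assert_array_equal(a.scores_, b.scores_)
        assert np.all(np.diff(a.fitness_trace_) <= 0)

    def test_recovers_informative_features(self, benchmark_data):
        fm, truth = benchmark_data
        sel = HWOASelector(random_state=0).fit(fm.values, fm.labels)
        hits = set(np.flatnonzero(sel.support_)) & set(truth["informative"])
        assert len(hits) / 8 >= 0.6
        assert sel.support_.sum() <= 0.6 * fm.n_features

    def test_beats_random_masks_of_equal_size(self, benchmark_data):
        """Permutation check: informative recall above chance level."""
        fm, truth = benchmark_data
        sel = HWOASelector(max_iterations=30, random_state=0).fit(
            fm.values, fm.labels)
        k = int(sel.support_.sum())
        observed = len(set(np.flatnonzero(sel.support_))
                       & set(truth["informative"]))
        g = np.random.default_rng(0)
        random_hits = [
            len(set(g.choice(fm.n_features, k, replace=False))
                & set(truth["informative"]))
            for _ in range(500)]
        # observed recall in the upper tail of the random-mask null
        assert observed > np.percentile(random_hits, 99)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 5))
        with pytest.raises(ValueError, match="single class"):
            HWOASelector().fit(X, np.zeros(20))
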