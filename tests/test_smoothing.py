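"""Smooth operators and the continuously differentiable episode runner."""

import math

import numpy as np
import pytest

from iblopt.agent import SimulationConfig, run_episode
from iblopt.memory import ActivationParams, N_CHUNKS
from iblopt.smoothing import (
    SmoothingParams,
    fold_max,
    run_episode_smoothed,
    smooth_absratio,
    smooth_argmax_select,
    smooth_clip,
    smooth_delta,
    smooth_heaviside,
    smooth_if_then,
    smooth_max,
    smooth_on_target,
)
from iblopt.streams import make_batch, make_streams


class TestPrimitives:
    def test_heaviside_values_and_limits(self):
        assert smooth_heaviside(0.0, 10.0) == pytest.approx(0.5)
        assert smooth_heaviside(0.1, 10.0) == pytest.approx(0.75)
        assert smooth_heaviside(1e9, 10.0) == pytest.approx(1.0, abs=1e-9)
        assert smooth_heaviside(-1e9, 10.0) == pytest.approx(0.0, abs=1e-9)
        xs = np.linspace(-3, 3, 101)
        assert np.all(np.diff(smooth_heaviside(xs, 10.0)) > 0)

    def test_delta_values_and_symmetry(self):
        assert smooth_delta(0.0, 0.01) == 1.0
        assert smooth_delta(0.01, 0.01) == pytest.approx(math.exp(-1))
        xs = np.linspace(-1, 1, 41)
        assert np.allclose(smooth_delta(xs, 0.3), smooth_delta(-xs, 0.3))

    def test_if_then(self):
        assert smooth_if_then(1e6, 3.0, 7.0, 10.0) == pytest.approx(3.0, rel=1e-6)
        assert smooth_if_then(0.0, 3.0, 7.0, 10.0) == pytest.approx(5.0)
        # integer-gap conditions agree with the discrete branch at h = 1e7
        for c in (-3, -2, -1, 1, 2, 3):
            expect = 3.0 if c >= 0 else 7.0
            assert smooth_if_then(c, 3.0, 7.0, 1e7) == pytest.approx(
                expect, abs=1e-6
            )

    def test_max_and_absratio(self):
        assert smooth_max(4.2, 4.2, 10.0) == pytest.approx(4.2)
        assert smooth_max(9.0, 6.0, 1e7) == pytest.approx(9.0, abs=1e-6)
        assert smooth_absratio(9.0, 6.0, 1e7) == pytest.approx(1 / 3, abs=1e-6)
        assert smooth_absratio(6.0, 9.0, 1e7) == pytest.approx(1 / 3, abs=1e-6)
        for a in (0.5, 1.0, 7.0):
            assert smooth_absratio(a, a, 10.0) == 0.0
        with pytest.raises(ValueError):
            smooth_absratio(0.0, 0.0, 10.0)

    def test_clip_interior_and_bounds(self):
        assert smooth_clip(6.0, 1.0, 12.0, 1e7) == pytest.approx(6.0, abs=1e-6)
        assert smooth_clip(15.0, 1.0, 12.0, 1e7) == pytest.approx(12.0, abs=1e-6)
        assert smooth_clip(-4.0, 1.0, 12.0, 1e7) == pytest.approx(1.0, abs=1e-6)

    def test_on_target_band(self):
        for p in range(1, 13):
            expect = 1.0 if 8 <= p <= 10 else 0.0
            assert smooth_on_target(float(p), 1e7) == pytest.approx(
                expect, abs=1e-6
            )


class TestConvergence:
    """Smoothed operators approach their discrete counterparts as h grows."""

    H_GRID = (10.0, 1e3, 1e5, 1e7)

    def test_pointwise_convergence_and_monotone_sharpening(self):
        xs = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])  # integer gaps
        discrete = (xs >= 0).astype(float)
        errs = [
            np.abs(smooth_heaviside(xs, h) - discrete).max() for h in self.H_GRID
        ]
        assert all(a >= b for a, b in zip(errs, errs[1:]))
        assert errs[-1] < 1e-6

        pairs = [(9.0, 6.0), (2.0, 5.0), (1.0, 12.0), (7.0, 7.0)]
        for f_s, f_d in (
            (smooth_max, max),
            (lambda x, y, h: smooth_absratio(x, y, h),
             lambda x, y: abs(x - y) / max(x, y)),
        ):
            errs = [
                max(abs(f_s(x, y, h) - f_d(x, y)) for x, y in pairs)
                for h in self.H_GRID
            ]
            assert all(a >= b + -1e-12 for a, b in zip(errs, errs[1:]))
            assert errs[-1] < 1e-6


class TestFoldMax:
    def test_singleton_and_equal_values(self):
        assert fold_max([3.3], 10.0) == 3.3
        assert fold_max([2.0, 2.0, 2.0], 10.0) == pytest.approx(2.0)

    def test_sharp_fold_approaches_max(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(-5, 5, 50)
        assert fold_max(vals, 1e7) == pytest.approx(vals.max(), abs=1e-4)

    def test_deflation_grows_as_h_shrinks(self):
        vals = np.full(1000, -100.0)
        vals[0] = 2.0
        gap_lo = 2.0 - fold_max(vals, 1e3)
        gap_hi = 2.0 - fold_max(vals, 1e7)
        assert gap_lo > 100 * gap_hi > 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fold_max([], 10.0)


class TestArgmaxSelect:
    def test_all_sentinel_falls_back(self):
        A = np.full(N_CHUNKS, -1000.0)
        b1 = np.arange(N_CHUNKS) % 12 + 1.0
        x = smooth_argmax_select(A, 0.0, b1, 7.0, 1e7)
        assert x == pytest.approx(7.0, abs=1e-4)

    def test_clear_winner_returns_its_content(self):
        b1 = np.arange(N_CHUNKS) % 12 + 1.0
        for idx in (0, 100, N_CHUNKS - 1):
            A = np.full(N_CHUNKS, -1000.0)
            A[idx] = 5.0
            x = smooth_argmax_select(A, 0.0, b1, 7.0, 1e7)
            assert x == pytest.approx(b1[idx], abs=1e-3)

    def test_below_threshold_falls_back(self):
        A = np.full(N_CHUNKS, -1000.0)
        A[50] = -5.0
        b1 = np.full(N_CHUNKS, 3.0)
        x = smooth_argmax_select(A, 0.0, b1, 9.0, 1e7)
        assert x == pytest.approx(9.0, abs=1e-3)

    def test_small_sharpness_blends_candidates(self):
        # three-chunk toy memory with nearly tied activations: the soft
        # selection lands strictly between the discrete candidates
        A = np.array([1.00, 0.99, 0.98])
        b1 = np.array([4.0, 8.0, 12.0])
        x = smooth_argmax_select(A, 0.0, b1, 2.0, 1e3)
        assert 4.05 < x < 12.0  # not the pure argmax content
        # with clearly separated activations the winner is returned exactly
        x_sharp = smooth_argmax_select(
            np.array([1.0, 0.9, 0.8]), 0.0, b1, 2.0, 1e7
        )
        assert x_sharp == pytest.approx(4.0, abs=1e-3)


@pytest.fixture()
def config():
    return SimulationConfig(params=ActivationParams(tau=-3.14, P=20.0))


class TestSmoothedEpisode:
    def test_score_bounded_and_deterministic(self, config):
        st = make_streams(3, 40)
        a = run_episode_smoothed(config, st)
        b = run_episode_smoothed(config, st)
        assert 0.0 <= a.score <= 40.0
        assert np.allclose(a.round_scores, b.round_scores)
        assert np.all((a.round_scores >= 0) & (a.round_scores <= 1))

    def test_sharp_regime_matches_discrete_trajectories(self, config):
        """With every part sharpened the smoothed loop reproduces the
        discrete workforce choices and scores."""
        sp = SmoothingParams(h_sim=1e5, h_env=1e5)
        diffs = []
        for seed in range(30):
            st = make_streams(seed, 40)
            d = run_episode(config, st)
            s = run_episode_smoothed(config, st, sp)
            diffs.append(abs(d.score - s.score))
        assert np.mean(diffs) < 0.5

    def test_default_regime_matches_batch_mean(self, config, batch100_seed1):
        """At h_sim = h_env = 10 individual trajectories may diverge, but
        the 100-replicate mean score tracks the discrete model."""
        d = np.mean([run_episode(config, st).score for st in batch100_seed1])
        s = np.mean(
            [
                run_episode_smoothed(config, st, SmoothingParams()).score
                for st in batch100_seed1
            ]
        )
        assert abs(d - s) < 0.5

    def test_soft_selection_collapses_learning(self, config):
        """Lowering the argmax sharpness to 1e3 reverts behavior to the
        exploration walk: the mean score drops by far more than the
        sharp-selection regime's."""
        batch = make_batch(1, 40)
        sharp = np.mean(
            [run_episode_smoothed(config, st).score for st in batch]
        )
        soft = np.mean(
            [
                run_episode_smoothed(
                    config, st, SmoothingParams(h_argmax=1e3)
                ).score
                for st in batch
            ]
        )
        assert sharp - soft > 8.0

    def test_retrieval_weights_recorded(self, config):
        res = run_episode_smoothed(config, make_streams(1, 40))
        assert res.retrieval_weights.shape == (40,)
        assert res.retrieval_weights[0] < 1e-3  # fresh memory: no retrieval
        assert res.retrieval_weights.max() > 0.99  # learning kicks in

    def test_frame_export(self, config):
        df = run_episode_smoothed(config, make_streams(1, 40)).to_frame()
        assert list(df.columns) == [
            "round",
            "x",
            "p_before",
            "p_after",
            "round_score",
            "retrieval_weight",
        ]
        assert len(df) == 40

    def test_option_variants_run(self, config):
        st = make_streams(2, 40)
        for kwargs in (
            {"walk_test": "window"},
            {"presentation_test": "delta"},
            {"presentation_test": "x_delta"},
            {"indicator": "band_env"},
            {"a_star_mode": "exact"},
            {"selection_weight": "heaviside"},
        ):
            res = run_episode_smoothed(config, st, SmoothingParams(**kwargs))
            assert 0.0 <= res.score <= 40.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SmoothingParams(h_sim=0.0)
        with pytest.raises(ValueError):
            SmoothingParams(walk_test="maybe")
        with pytest.raises(ValueError):
            SmoothingParams(indicator="confetti")
        with pytest.raises(ValueError):
            SmoothingParams(selection_weight="uniform")

    def test_retrieval_as_presentation_not_supported(self, config):
        cfg = SimulationConfig(
            params=config.params, count_retrieval_as_presentation=True
        )
        with pytest.raises(NotImplementedError):
            run_episode_smoothed(cfg, make_streams(0, 40))
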