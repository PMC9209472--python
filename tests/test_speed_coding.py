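"""Position regression, speed-cell classification, and GLM decoding."""

import numpy as np
import pytest
from scipy import stats

from placecode.behavior import analyze_behavior
from placecode.io_core import Session
from placecode.speed_coding import (
    alternating_blocks,
    classify_speed_cells,
    decode_speed,
    path_length_exclusions,
    regress_out_position,
    split_consistency,
)
from placecode.synthetic_data import (
    SimulationConfig,
    render_session,
    simulate_population,
    simulate_trajectory,
)


class TestRegressOutPosition:
    def test_pure_position_function_vanishes(self, small_behavior):
        xb = (small_behavior.x // 3.5).astype(int)
        trace = np.cos(xb).astype(float)
        resid = regress_out_position(trace, small_behavior.x, 70.0)
        np.testing.assert_allclose(resid, 0.0, atol=1e-8)

    def test_position_independent_trace_centered(self, rng, small_behavior):
        trace = rng.standard_normal(small_behavior.x.size)
        resid = regress_out_position(trace, small_behavior.x, 70.0)
        # per-bin means are near the global mean, so the residual is close
        # to the mean-centered trace
        assert np.corrcoef(resid, trace - trace.mean())[0, 1] > 0.99

    def test_constant_position_warns(self, rng):
        trace = rng.standard_normal(100)
        with pytest.warns(UserWarning):
            resid = regress_out_position(trace, np.full(100, 10.0), 70.0)
        np.testing.assert_allclose(resid, trace - trace.mean())

    def test_additive_speed_effect_survives(self, small_behavior):
        # trace = place effect + speed effect: the residual's speed
        # correlation matches the pure speed component's
        speed = small_behavior.speed
        xb = (small_behavior.x // 3.5).astype(int)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pure = 0.02 * speed + 0.5 * rng.standard_normal(speed.size)
            mixed = pure + 0.5 * np.sin(xb)
            r_pure = stats.spearmanr(pure, speed).statistic
            resid = regress_out_position(mixed, small_behavior.x, 70.0)
            r_resid = stats.spearmanr(resid, speed).statistic
            assert abs(r_resid - r_pure) < 0.05


class TestClassifySpeedCells:
    def _session_with_traces(self, small_session, traces):
        return Session(
            traces=np.atleast_2d(traces),
            pose=small_session.pose,
            sample_rate_hz=small_session.sample_rate_hz,
            meta=small_session.meta,
        )

    def test_speed_itself_is_positive(self, small_session, small_behavior):
        sess = self._session_with_traces(small_session, small_behavior.speed.copy())
        res = classify_speed_cells(sess, behavior=small_behavior)
        # position regression removes a little speed variance, but the
        # residual stays overwhelmingly speed-like
        assert res[0].speed_class == "positive"
        assert res[0].spearman_r > 0.8

    def test_negated_speed_is_negative(self, small_session, small_behavior):
        sess = self._session_with_traces(small_session, -small_behavior.speed)
        res = classify_speed_cells(sess, behavior=small_behavior)
        assert res[0].speed_class == "negative"

    def test_constructed_cells_recovered(self):
        cfg = SimulationConfig(
            duration_s=1200.0, n_cells=40, fraction_place_cells=0.0,
            fraction_speed_pos=0.5, fraction_speed_neg=0.5, rng_seed=21,
        )
        gt = simulate_population(cfg, 21)
        traj = simulate_trajectory(cfg, 22)
        sess = render_session(gt, traj, cfg, 23).session
        res = classify_speed_cells(sess)
        cls = np.array(
            [{"positive": 1, "negative": -1, "none": 0}[r.speed_class] for r in res]
        )
        assert (cls[gt.speed_class == 1] == 1).mean() >= 0.9
        assert (cls[gt.speed_class == -1] == -1).mean() >= 0.9

    def test_monotone_transform_invariance(self, small_session, small_behavior):
        # Spearman classification is invariant to monotone speed transforms
        sess = self._session_with_traces(small_session, small_behavior.speed.copy())
        r1 = classify_speed_cells(sess, behavior=small_behavior)[0].spearman_r
        beh2 = analyze_behavior(small_session)
        beh2.speeds["tail"] = np.exp(beh2.speeds["tail"] / 10.0)
        sess2 = self._session_with_traces(small_session, small_behavior.speed.copy())
        r2 = classify_speed_cells(sess2, behavior=beh2)[0].spearman_r
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestSplitConsistency:
    def test_stationary_tuning_is_consistent(self, small_session):
        # stationary tuned population: both split types give high consistency
        cfg = SimulationConfig(
            duration_s=1200.0, n_cells=30, fraction_place_cells=0.0,
            fraction_speed_pos=0.5, fraction_speed_neg=0.5, rng_seed=31,
        )
        gt = simulate_population(cfg, 31)
        traj = simulate_trajectory(cfg, 32)
        sess = render_session(gt, traj, cfg, 33).session
        r = split_consistency(sess, "half_half")
        assert r > 0.5
        r_lr = split_consistency(sess, "left_right")
        assert r_lr > 0.5

    def test_sign_flip_between_halves_negative(self):
        cfg = SimulationConfig(
            duration_s=1200.0, n_cells=30, fraction_place_cells=0.0,
            fraction_speed_pos=0.5, fraction_speed_neg=0.5, rng_seed=41,
        )
        gt = simulate_population(cfg, 41)
        traj = simulate_trajectory(cfg, 42)
        sess = render_session(gt, traj, cfg, 43).session
        flipped = gt.copy()
        flipped.speed_slope = -flipped.speed_slope
        half2 = render_session(flipped, traj, cfg, 44).session
        mid = sess.n_samples // 2
        sess.traces[:, mid:] = half2.traces[:, mid:]
        assert split_consistency(sess, "half_half") <= 0.0

    def test_unknown_split_rejected(self, small_session):
        with pytest.raises(ValueError, match="split"):
            split_consistency(small_session, "diagonal")


class TestDecoding:
    @staticmethod
    def _runs(idx):
        brk = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate([[0], brk + 1])
        stops = np.concatenate([brk, [idx.size - 1]])
        return [(int(idx[a]), int(idx[b])) for a, b in zip(starts, stops)]

    def test_blocks_disjoint_with_guard(self):
        train, test = alternating_blocks(9000, 7.5, 60.0, 10.0)
        assert np.intersect1d(train, test).size == 0
        guard = int(10.0 * 7.5)
        # every train run and test run are separated by at least the guard
        for a0, a1 in self._runs(train):
            for b0, b1 in self._runs(test):
                gap = b0 - a1 if b0 > a1 else a0 - b1
                assert gap >= guard

    def test_oracle_predictor_near_perfect(self, small_session, small_behavior):
        rng = np.random.default_rng(0)
        pred = np.vstack(
            [small_behavior.speed, rng.standard_normal((4, small_session.n_samples))]
        )
        res = decode_speed(
            small_session, 5, behavior=small_behavior,
            rng=np.random.default_rng(1), predictors=pred,
        )
        assert res.mean_r >= 0.99

    def test_noise_predictors_below_chance(self, small_session, small_behavior):
        below = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pred = rng.standard_normal((20, small_session.n_samples))
            res = decode_speed(
                small_session, 16, behavior=small_behavior, rng=rng, predictors=pred,
            )
            below += res.mean_r < res.chance_threshold
        assert below >= 4

    def test_more_tuned_cells_decode_better(self):
        cfg = SimulationConfig(
            duration_s=1200.0, n_cells=32, fraction_place_cells=0.0,
            fraction_speed_pos=0.5, fraction_speed_neg=0.5, rng_seed=51,
        )
        gt = simulate_population(cfg, 51)
        traj = simulate_trajectory(cfg, 52)
        sess = render_session(gt, traj, cfg, 53).session
        res32 = decode_speed(sess, 32, rng=np.random.default_rng(1))
        res8 = decode_speed(sess, 8, rng=np.random.default_rng(1))
        assert res32.mean_r > res8.mean_r
        assert res32.mean_r > res32.chance_threshold

    def test_subsample_larger_than_population_rejected(self, small_session):
        with pytest.raises(ValueError, match="n_subsample"):
            decode_speed(small_session, small_session.n_cells + 1)


def test_path_length_exclusion_rule():
    lengths = np.array([100.0, 105.0, 95.0, 98.0, 40.0])
    flags = path_length_exclusions(lengths)
    assert flags.tolist() == [False, False, False, False, True]
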