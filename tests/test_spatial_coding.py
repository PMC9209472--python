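"""Activity maps, mutual information and place-field geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from placecode.io_core import AnalysisConfig
from placecode.nulls import cyclic_offsets
from placecode.spatial_coding import (
    ActivityMap,
    classify_place_cells,
    compute_activity_map,
    detect_place_fields,
    mutual_information,
    mutual_information_from_joint,
    sturges_bins,
)


def brute_force_mi(joint: np.ndarray) -> float:
    """Independent double-sum oracle for I(X;Y) in bits."""
    p = np.asarray(joint, dtype=float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    total = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if p[i, j] > 0:
                total += p[i, j] * np.log2(p[i, j] / (px[i] * py[j]))
    return total


class TestSturges:
    @pytest.mark.parametrize("n,expected", [(256, 9), (1, 1), (1000, 11), (2, 2)])
    def test_values(self, n, expected):
        assert sturges_bins(n) == expected

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            sturges_bins(0)


class TestMutualInformation:
    def test_independent_joint_is_zero(self, rng):
        px = rng.dirichlet(np.ones(5))
        py = rng.dirichlet(np.ones(7))
        assert mutual_information_from_joint(np.outer(px, py)) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_binary_dependence_one_bit(self):
        joint = np.array([[0.5, 0.0], [0.0, 0.5]])
        assert mutual_information_from_joint(joint) == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 30, size=(4, 6)).astype(float)
            counts[0, 0] += 1  # nonempty
            joint = counts / counts.sum()
            assert mutual_information_from_joint(joint) == pytest.approx(
                brute_force_mi(joint), abs=1e-12
            )

    def test_nonnegative_and_bounded_by_entropy(self, rng):
        for _ in range(10):
            joint = rng.dirichlet(np.ones(24)).reshape(4, 6)
            mi = mutual_information_from_joint(joint)
            px = joint.sum(1)
            py = joint.sum(0)
            hx = -np.sum(px[px > 0] * np.log2(px[px > 0]))
            hy = -np.sum(py[py > 0] * np.log2(py[py > 0]))
            assert -1e-12 <= mi <= min(hx, hy) + 1e-12

    def test_relabeling_invariance(self, rng):
        counts = rng.integers(1, 20, size=(5, 5)).astype(float)
        joint = counts / counts.sum()
        perm = rng.permutation(5)
        assert mutual_information_from_joint(joint[perm]) == pytest.approx(
            mutual_information_from_joint(joint), abs=1e-12
        )

    def test_single_occupied_bin_warns_zero(self):
        x = np.full(200, 1.0)
        trace = np.random.default_rng(0).random(200)
        with pytest.warns(UserWarning):
            assert mutual_information(trace, x, np.ones(200, bool), 70.0) == 0.0


class TestActivityMap:
    def test_constant_trace_constant_map(self, small_behavior):
        amap = compute_activity_map(
            np.full(small_behavior.pose.shape[0], 2.5), small_behavior, 70.0, 9.0,
            smooth=False,
        )
        np.testing.assert_allclose(amap.values[amap.occupied], 2.5)
        smoothed = compute_activity_map(
            np.full(small_behavior.pose.shape[0], 2.5), small_behavior, 70.0, 9.0,
            smooth=True,
        )
        np.testing.assert_allclose(smoothed.values[smoothed.occupied], 2.5)

    def test_occupancy_conservation(self, small_session, small_behavior):
        mask = small_behavior.movement_mask
        for trace in small_session.traces[:5]:
            amap = compute_activity_map(trace, small_behavior, 70.0, 9.0, smooth=False)
            total = np.nansum(amap.values * amap.occupancy)
            assert total == pytest.approx(trace[mask].sum(), rel=1e-9)

    def test_argmax_near_true_center(self, small_render, small_behavior):
        gt, _, rr = small_render
        hits = 0
        idx = np.flatnonzero(gt.is_place)
        for i in idx:
            amap = compute_activity_map(rr.session.traces[i], small_behavior, 70.0, 9.0)
            prof = np.nanmax(np.where(amap.occupied, amap.values, np.nan), axis=0)
            best = (np.nanargmax(prof) + 0.5) * 3.5
            hits += abs(best - gt.field_center_cm[i]) <= 3.5
        assert hits / idx.size >= 0.8


class TestPlaceFields:
    def _map_from(self, values, occupied=None):
        values = np.asarray(values, dtype=float)
        occ = np.ones_like(values) if occupied is None else occupied
        return ActivityMap(values, occ, 3.5, values.shape[1] * 3.5, smoothed=True)

    def test_four_contiguous_bins_size(self):
        vals = np.zeros((3, 10))
        vals[1, 2:6] = 10.0
        fields = detect_place_fields(self._map_from(vals))
        assert len(fields) == 1
        assert fields[0].size_cm2 == pytest.approx(4 * 3.5 * 3.5)
        assert fields[0].width_cm == pytest.approx(4 * 3.5)

    def test_corner_touch_is_two_fields(self):
        vals = np.zeros((4, 6))
        vals[1, 2] = 10.0
        vals[2, 3] = 11.0
        fields = detect_place_fields(self._map_from(vals))
        assert len(fields) == 2
        assert fields[0].peak_value == pytest.approx(11.0)  # sorted by peak

    def test_no_bins_above_threshold(self):
        fields = detect_place_fields(self._map_from(np.ones((3, 8))))
        assert fields == []

    def test_width_monotone_in_generator_width(self):
        from placecode.synthetic_data import (
            SimulationConfig, render_session, simulate_population, simulate_trajectory,
        )
        from placecode.behavior import analyze_behavior

        mean_widths = []
        for w in (7.0, 14.0, 21.0):
            widths = []
            for seed in range(5):
                cfg = SimulationConfig(
                    duration_s=600.0, n_cells=8, fraction_place_cells=1.0,
                    field_width_cm_mean=w, field_width_cm_sd=0.0,
                    field_width_cm_min=w, fraction_speed_pos=0.0,
                    fraction_speed_neg=0.0, rng_seed=seed,
                )
                gt = simulate_population(cfg, seed)
                traj = simulate_trajectory(cfg, seed + 50)
                sess = render_session(gt, traj, cfg, seed + 90).session
                beh = analyze_behavior(sess)
                for trace in sess.traces:
                    amap = compute_activity_map(trace, beh, 70.0, 9.0)
                    fields = detect_place_fields(amap)
                    if fields:
                        widths.append(fields[0].width_cm)
            mean_widths.append(np.mean(widths))
        assert mean_widths[0] < mean_widths[1] < mean_widths[2]


class TestClassification:
    def test_deterministic_function_of_position_is_place_cell(self, small_session, small_behavior):
        from placecode.io_core import Session

        xb = (small_behavior.x // 3.5).astype(int)
        sess = Session(
            traces=(np.sin(xb) ** 2)[None, :],  # deterministic in position bin
            pose=small_session.pose,
            sample_rate_hz=small_session.sample_rate_hz,
            meta=small_session.meta,
        )
        res = classify_place_cells(sess, behavior=small_behavior, with_fields=False)
        assert res[0].is_place_cell
        assert res[0].mi > res[0].null_mi.max()

    def test_null_count_excludes_identity_shift(self, small_session, small_behavior):
        res = classify_place_cells(small_session, behavior=small_behavior, with_fields=False)
        assert res[0].null_mi.size == 99
        offsets = cyclic_offsets(small_session.n_samples, 100)
        assert offsets.size == 99
        assert 0 not in offsets

    def test_circular_shift_preserves_marginal(self, small_session):
        trace = small_session.traces[0]
        shifted = np.roll(trace, 137)
        assert sorted(trace) == sorted(shifted)

    def test_recovery_on_default_synthetic(self, small_render, small_behavior):
        gt, _, rr = small_render
        res = classify_place_cells(rr.session, behavior=small_behavior)
        detected = np.array([r.is_place_cell for r in res])
        assert detected[gt.is_place].mean() >= 0.9
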