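"""Sample extraction, ROI algebra and down-sampling bookkeeping."""

import numpy as np
import pytest

from hyperclass.data_model import (
    ACTIONS, DesignError, RoiMask, TrialTable, VolumeSeries,
    build_roi_from_statmap, combine_rois, downsample_volume, extract_samples,
)


def _run(n_scans=220, n_voxels=5, run_id=0, tr=2.0):
    # data[t, v] = t so sampled scan indices are directly readable
    data = np.tile(np.arange(n_scans, dtype=float)[:, None], (1, n_voxels))
    coords = np.array([(i, 0, 0) for i in range(n_voxels)])
    return VolumeSeries(data, tr, run_id, coords)


def _table(n_trials=24, run=0, spacing=8, start=2):
    labels = [ACTIONS[i % 4] for i in range(n_trials)]
    return TrialTable.from_records(
        [(run, start + i * spacing, lab, 3) for i, lab in enumerate(labels)]
    )


class TestExtractSamples:
    def test_canonical_run_yields_72_samples(self):
        s = extract_samples(_run(), _table(24), lag_seconds=6, scans_per_trial=3)
        assert s.n_samples == 72

    def test_empty_table_yields_empty_sampleset(self):
        s = extract_samples(_run(), _table(0))
        assert s.n_samples == 0
        assert s.x.shape == (0, 5)

    def test_lag_shift_selects_expected_scans(self):
        table = TrialTable.from_records([(0, 10, "slap", 3)])
        s = extract_samples(_run(), table, lag_seconds=6, scans_per_trial=3)
        # onset 10 + lag 6s / tr 2s = scans 13, 14, 15
        assert s.x[:, 0].tolist() == [13.0, 14.0, 15.0]
        assert list(s.y) == ["slap"] * 3

    def test_window_past_run_end_names_the_trial(self):
        table = TrialTable.from_records([(0, 218, "point", 3)])
        with pytest.raises(DesignError, match="onset_scan=218"):
            extract_samples(_run(220), table)

    def test_label_outside_action_set_rejected(self):
        with pytest.raises(DesignError, match="outside"):
            TrialTable.from_records([(0, 0, "wave", 3)])

    def test_non_integral_lag_rejected(self):
        with pytest.raises(DesignError, match="integer number of TRs"):
            extract_samples(_run(tr=2.0), _table(4), lag_seconds=5.0)

    def test_label_histogram_is_three_times_trial_histogram(self):
        table = _table(24)
        s = extract_samples(_run(), table, 6, 3)
        trial_counts = table.class_counts()
        assert s.class_counts() == {a: 3 * trial_counts[a] for a in ACTIONS}

    def test_sample_order_run_major_scan_innermost(self):
        runs = [_run(run_id=0), _run(run_id=1)]
        table = TrialTable(
            TrialTable.from_records(
                [(0, 2, "slap", 3), (0, 10, "point", 3),
                 (1, 2, "power_grip", 3)]
            ).frame
        )
        s = extract_samples(runs, table, 6, 3)
        assert s.run.tolist() == [0] * 6 + [1] * 3
        assert s.trial.tolist() == [0, 0, 0, 1, 1, 1, 2, 2, 2]
        assert s.x[:3, 0].tolist() == [5.0, 6.0, 7.0]


class TestCanonicalBookkeeping:
    def test_full_design_sample_and_fold_counts(self, default_samples):
        actor, _ = default_samples
        assert actor.n_samples == 360
        train, test = actor.split_run(0)
        assert (train.n_samples, test.n_samples) == (288, 72)
        target = (train.y == ACTIONS[0]).sum()
        assert (target, train.n_samples - target) == (72, 216)


class TestRoiOps:
    def test_statmap_threshold_strict(self):
        statmap = np.array([[[1.0, 2.5, 3.0]]])
        roi = build_roi_from_statmap(statmap, 2.0)
        assert roi.n_voxels == 2

    def test_all_subthreshold_warns_and_is_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            roi = build_roi_from_statmap(np.zeros((2, 2, 2)), 2.0)
        assert roi.n_voxels == 0

    def test_non_finite_statmap_rejected(self):
        bad = np.full((2, 2, 2), np.nan)
        with pytest.raises(DesignError):
            build_roi_from_statmap(bad, 2.0)

    def test_execution_observation_overlap_roi(self):
        rng = np.random.default_rng(0)
        exe = rng.normal(scale=2.0, size=(4, 4, 4))
        obs = rng.normal(scale=2.0, size=(4, 4, 4))
        overlap = combine_rois(
            [build_roi_from_statmap(exe, 2.0), build_roi_from_statmap(obs, 2.0)],
            "intersection",
        )
        assert np.array_equal(overlap.grid, (exe > 2) & (obs > 2))

    @pytest.mark.parametrize("mode", ["union", "intersection"])
    def test_idempotence(self, mode):
        grid = np.zeros((3, 3, 3), dtype=bool)
        grid[0, 0, :] = True
        a = RoiMask(grid)
        assert np.array_equal(combine_rois([a, a], mode).grid, grid)

    def test_union_with_empty_is_identity(self):
        grid = np.zeros((3, 3, 3), dtype=bool)
        grid[1] = True
        a, empty = RoiMask(grid), RoiMask(np.zeros((3, 3, 3), dtype=bool))
        assert np.array_equal(combine_rois([a, empty], "union").grid, grid)

    def test_intersection_of_disjoint_is_empty(self):
        g1 = np.zeros((3, 3, 3), dtype=bool); g1[0] = True
        g2 = np.zeros((3, 3, 3), dtype=bool); g2[2] = True
        assert combine_rois([RoiMask(g1), RoiMask(g2)], "intersection").n_voxels == 0

    def test_subtract_excludes_v1_voxels(self):
        rng = np.random.default_rng(1)
        meta = RoiMask(rng.random((4, 4, 4)) > 0.4)
        v1 = RoiMask(rng.random((4, 4, 4)) > 0.6)
        out = combine_rois([meta, v1], "subtract")
        assert not np.any(out.grid & v1.grid)
        again = combine_rois([out, v1], "subtract")
        assert np.array_equal(again.grid, out.grid)

    def test_geometry_mismatch_rejected(self):
        a = RoiMask(np.ones((2, 2, 2), dtype=bool))
        b = RoiMask(np.ones((3, 3, 3), dtype=bool))
        with pytest.raises(DesignError, match="geometry"):
            combine_rois([a, b], "union")


class TestDownsample:
    def _volume(self, side=4, n_scans=3):
        coords = np.array(
            [(x, y, z) for x in range(side) for y in range(side) for z in range(side)]
        )
        data = np.arange(n_scans * len(coords), dtype=float).reshape(n_scans, -1)
        return VolumeSeries(data, 2.0, 0, coords)

    def test_factor_one_is_identity(self):
        vs = self._volume()
        out = downsample_volume(vs, 1)
        assert np.array_equal(out.data, vs.data)
        assert np.array_equal(out.voxel_index, vs.voxel_index)

    def test_constant_volume_stays_constant(self):
        vs = self._volume()
        vs.data[:] = 7.0
        out = downsample_volume(vs, 2)
        assert np.allclose(out.data, 7.0)
        assert out.n_voxels == 8

    def test_block_mean_of_1_to_8(self):
        coords = np.array(
            [(x, y, z) for x in range(2) for y in range(2) for z in range(2)]
        )
        data = np.arange(1.0, 9.0)[None, :]
        out = downsample_volume(VolumeSeries(data, 2.0, 0, coords), 2)
        assert out.n_voxels == 1
        assert out.data[0, 0] == pytest.approx(4.5)

    def test_partial_edge_blocks_average_present_voxels(self):
        coords = np.array([(0, 0, 0), (1, 0, 0), (2, 0, 0)])  # 3 not divisible by 2
        data = np.array([[1.0, 3.0, 10.0]])
        out = downsample_volume(VolumeSeries(data, 2.0, 0, coords), 2)
        assert out.n_voxels == 2
        assert out.data[0].tolist() == [2.0, 10.0]

    def test_affine_scaled_by_factor(self):
        vs = self._volume()
        out = downsample_volume(vs, 2)
        assert np.allclose(out.affine[:3, :3], vs.affine[:3, :3] * 2)
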