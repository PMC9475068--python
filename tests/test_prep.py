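"""Preprocessing: FD, artifact handling, nuisance regression, filtering, QC."""

import numpy as np
import pytest

import isfc_predict as ip
from isfc_predict.core import SubjectRecord
from isfc_predict.prep import (PrepConfig, apply_qc, bandpass_detrend, compute_fd,
                               detect_artifacts, extract_roi_timeseries,
                               interpolate_artifacts, regress_nuisance_pcs,
                               _filter_regressors)


def _motion_with_steps(n_trs, steps):
    """Motion params with given (tr, column, delta) steps, radians for cols 3-5."""
    m = np.zeros((n_trs, 6))
    for tr, col, delta in steps:
        m[tr:, col] += delta
    return m


class TestFramewiseDisplacement:
    def test_zero_motion_gives_zero_fd(self):
        assert np.all(compute_fd(np.zeros((20, 6))) == 0)

    def test_translation_step_equals_its_magnitude(self):
        fd = compute_fd(_motion_with_steps(5, [(2, 0, 1.0)]))
        np.testing.assert_allclose(fd, [0, 0, 1.0, 0, 0])

    def test_rotation_converted_at_head_radius(self):
        fd = compute_fd(_motion_with_steps(4, [(1, 5, 0.02)]), rotation_radius_mm=50.0)
        np.testing.assert_allclose(fd, [0, 1.0, 0, 0])

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError, match="TR x 6"):
            compute_fd(np.zeros((10, 5)))


class TestArtifactDetection:
    def test_fd_above_2mm_is_flagged(self):
        ts = np.zeros((3, 4))
        flags = detect_artifacts(ts, np.array([0.1, 2.5, 0.1]))
        np.testing.assert_array_equal(flags, [1])

    def test_constant_global_signal_never_flags(self):
        ts = np.ones((30, 4)) * 7.0
        assert detect_artifacts(ts, np.zeros(30)).size == 0

    def test_global_signal_outlier_is_flagged(self):
        rng = np.random.default_rng(0)
        gs = np.sin(np.linspace(0, 6 * np.pi, 200)) + 0.1 * rng.standard_normal(200)
        gs[50] = gs.mean() + 10.0  # far beyond 3 SD of the global signal
        ts = np.repeat(gs[:, None], 3, axis=1)
        z = (gs - gs.mean()) / gs.std()
        assert abs(z[50]) > 3
        assert 50 in detect_artifacts(ts, np.zeros(200))


class TestInterpolation:
    def test_no_flags_is_identity(self):
        ts = np.arange(12.0).reshape(6, 2)
        np.testing.assert_array_equal(interpolate_artifacts(ts, []), ts)

    def test_interior_flag_takes_linear_midpoint(self):
        ts = np.array([[1.0], [99.0], [3.0], [3.0]])
        out = interpolate_artifacts(ts, [1])
        assert out[1, 0] == 2.0

    def test_boundary_flag_takes_nearest_clean_value(self):
        ts = np.array([[42.0], [5.0], [6.0]])
        out = interpolate_artifacts(ts, [0])
        assert out[0, 0] == 5.0

    def test_all_flagged_is_an_error(self):
        with pytest.raises(ValueError, match="all TRs flagged"):
            interpolate_artifacts(np.ones((4, 2)), [0, 1, 2, 3])


class TestNuisanceRegression:
    def test_self_regression_annihilates_the_series(self):
        rng = np.random.default_rng(1)
        ts = rng.standard_normal((50, 4))
        out = regress_nuisance_pcs(ts, ts, 4)
        assert np.abs(out).max() < 1e-10

    def test_orthogonal_nuisance_leaves_centered_input(self):
        t = np.arange(64)
        ts = np.column_stack([np.cos(2 * np.pi * 5 * t / 64),
                              np.cos(2 * np.pi * 9 * t / 64)])
        nuis = np.column_stack([np.sin(2 * np.pi * 3 * t / 64)])
        out = regress_nuisance_pcs(ts, nuis, 1)
        np.testing.assert_allclose(out, ts - ts.mean(axis=0), atol=1e-10)

    def test_projection_matches_explicit_oracle(self):
        rng = np.random.default_rng(2)
        pc = rng.standard_normal(80)
        ortho = rng.standard_normal(80)
        ortho -= ortho @ pc / (pc @ pc) * pc
        ortho -= ortho.mean()
        ts = (3.0 * pc + ortho)[:, None]
        out = regress_nuisance_pcs(ts, pc[:, None], 1)
        centered_pc = pc - pc.mean()
        expected = ortho - (ortho @ centered_pc) / (centered_pc @ centered_pc) * centered_pc
        np.testing.assert_allclose(out[:, 0], expected - expected.mean(), atol=1e-8)

    def test_npcs_beyond_rank_rejected(self):
        nuis = np.outer(np.arange(20.0), [1.0, 2.0])  # rank 1 after centering
        with pytest.raises(ValueError, match="rank"):
            regress_nuisance_pcs(np.zeros((20, 3)), nuis, 2)


class TestBandpassDetrend:
    TR = 2.0

    def _sinusoid(self, n, cycles):
        t = np.arange(n)
        return np.sin(2 * np.pi * cycles * t / n)

    def test_in_band_sinusoid_retained(self):
        n = 100
        x = self._sinusoid(n, 10)  # 10/(100*2s) = 0.05 Hz
        out = bandpass_detrend(x[:, None], self.TR)
        assert np.linalg.norm(out) >= 0.95 * np.linalg.norm(x)

    def test_out_of_band_sinusoid_removed(self):
        n = 100
        x = self._sinusoid(n, 40)  # 0.20 Hz > 0.15 Hz band edge
        out = bandpass_detrend(x[:, None], self.TR)
        assert np.linalg.norm(out) <= 0.05 * np.linalg.norm(x)

    def test_linear_ramp_removed(self):
        ramp = np.linspace(-1, 1, 90)
        out = bandpass_detrend(ramp[:, None], self.TR)[:, 0]
        assert abs(np.corrcoef(out + 1e-30 * ramp, ramp)[0, 1]) < 1e-6 or \
            np.abs(out).max() < 1e-10

    def test_projection_is_idempotent(self):
        rng = np.random.default_rng(3)
        ts = rng.standard_normal((120, 3))
        once = bandpass_detrend(ts, self.TR)
        twice = bandpass_detrend(once, self.TR)
        np.testing.assert_allclose(once, twice, atol=1e-8)

    def test_matches_full_least_squares_solve(self):
        rng = np.random.default_rng(4)
        ts = rng.standard_normal((64, 2))
        cfg = PrepConfig()
        reg = _filter_regressors(64, self.TR, cfg)
        coefs, *_ = np.linalg.lstsq(reg, ts, rcond=None)
        expected = ts - reg @ coefs
        np.testing.assert_allclose(bandpass_detrend(ts, self.TR, cfg), expected,
                                   atol=1e-8)

    def test_infeasible_band_lists_removable_frequencies(self):
        cfg = PrepConfig(band_low_hz=0.0001, band_high_hz=0.0002)
        with pytest.raises(ValueError, match="removable frequencies"):
            bandpass_detrend(np.zeros((20, 1)), self.TR, cfg)


def _make_subject(sid, n_trs, motion, group="child", score=0.5, rng_seed=0):
    rng = np.random.default_rng(rng_seed)
    return SubjectRecord(subject_id=sid, group=group,
                         timeseries=rng.standard_normal((n_trs, 4)),
                         motion_params=motion, age=8.0, score=score)


class TestApplyQC:
    def test_mean_fd_exclusion_rule(self):
        # steady 0.6 mm steps -> mean FD just under 0.6 -> excluded;
        # 0.4 mm steps -> retained
        n = 178
        high = _motion_with_steps(n, [(t, 0, 0.6 * (-1) ** t) for t in range(1, n)])
        low = _motion_with_steps(n, [(t, 0, 0.4 * (-1) ** t) for t in range(1, n)])
        cohort = ip.Cohort(
            subjects=[_make_subject("bad", n, high, rng_seed=1),
                      _make_subject("good", n, low, rng_seed=2)],
            roi_labels=list("abcd"))
        cleaned, report = apply_qc(cohort)
        assert report.subjects["bad"].excluded
        assert "mean FD" in report.subjects["bad"].reason
        assert not report.subjects["good"].excluded
        assert [s.subject_id for s in cleaned.subjects] == ["good"]

    def test_initial_tr_drop(self):
        n = 178
        cohort = ip.Cohort(subjects=[_make_subject("s", n, np.zeros((n, 6)))],
                           roi_labels=list("abcd"))
        cleaned, _ = apply_qc(cohort)
        assert cleaned.subjects[0].timeseries.shape[0] == 168

    def test_moderate_spike_is_scrubbed_not_interpolated(self):
        # A 1.2 mm FD spike exceeds the 1 mm scrub threshold but not the
        # 2 mm artifact threshold.
        n = 100
        motion = _motion_with_steps(n, [(50, 1, 1.2), (51, 1, -1.2)])
        cohort = ip.Cohort(subjects=[_make_subject("s", n, motion, rng_seed=3)],
                           roi_labels=list("abcd"))
        cleaned, report = apply_qc(cohort)
        qc = report.subjects["s"]
        assert 50 not in qc.artifact_tr_indices and 51 not in qc.artifact_tr_indices
        # scrub indices are relative to the series after the 10-TR drop
        assert 40 in qc.scrubbed_tr_indices and 41 in qc.scrubbed_tr_indices
        assert not cleaned.subjects[0].valid_tr_mask[40]

    def test_too_few_usable_trs_excludes_subject(self):
        n = 25  # 15 TRs after the initial drop; scrub 6 of them
        steps = []
        for t in range(15, 21):
            steps.append((t, 0, 1.2 * (-1) ** t))
        motion = _motion_with_steps(n, steps)
        cohort = ip.Cohort(subjects=[_make_subject("s", n, motion, rng_seed=4)],
                           roi_labels=list("abcd"))
        _, report = apply_qc(cohort)
        assert report.subjects["s"].excluded
        assert "usable TRs" in report.subjects["s"].reason

    def test_qc_is_deterministic(self, small_cohort):
        _, r1 = apply_qc(small_cohort)
        _, r2 = apply_qc(small_cohort)
        for sid in r1.subjects:
            np.testing.assert_array_equal(r1.subjects[sid].fd_series,
                                          r2.subjects[sid].fd_series)
            assert r1.subjects[sid].excluded == r2.subjects[sid].excluded


class TestROIExtraction:
    def _grids(self):
        atlas = np.zeros((8, 8, 8), dtype=int)
        mask = np.ones((8, 8, 8), dtype=bool)
        return atlas, mask

    def test_uniform_roi_yields_constant_series(self):
        atlas, mask = self._grids()
        atlas[2:4, 2:4, 2:4] = 1
        img = np.full((8, 8, 8, 5), 3.5)
        ts, kept, dropped = extract_roi_timeseries(img, atlas, mask)
        assert kept == [1] and dropped == []
        np.testing.assert_allclose(ts, 3.5)

    def test_small_roi_dropped_below_five_voxels(self):
        atlas, mask = self._grids()
        atlas[4, 4, 4] = 2  # dilates to 7 voxels...
        mask[:] = False
        mask[4, 4, 4] = True
        mask[5, 4, 4] = True
        mask[3, 4, 4] = True
        mask[4, 5, 4] = True  # ...but only 4 survive the group mask
        img = np.zeros((8, 8, 8, 3))
        ts, kept, dropped = extract_roi_timeseries(img, atlas, mask)
        assert dropped == [2] and kept == []

    def test_single_voxel_dilates_to_six_neighborhood(self):
        atlas, mask = self._grids()
        atlas[4, 4, 4] = 1
        img = np.zeros((8, 8, 8, 2))
        img[4, 4, 4, :] = 7.0  # center voxel only
        ts, kept, _ = extract_roi_timeseries(img, atlas, mask)
        assert kept == [1]
        np.testing.assert_allclose(ts[:, 0], 7.0 / 7.0)  # center + 6 face neighbors

    def test_overlap_assigned_to_nearer_roi(self):
        atlas, mask = self._grids()
        atlas[1, 4, 4] = 1
        atlas[4, 4, 4] = 2
        img = np.zeros((8, 8, 8, 2))
        ts, kept, dropped = extract_roi_timeseries(img, atlas, mask, min_voxels=1)
        assert kept == [1, 2] and dropped == []

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            extract_roi_timeseries(np.zeros((4, 4, 4, 2)), np.zeros((5, 4, 4), int),
                                   np.ones((4, 4, 4), bool))
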