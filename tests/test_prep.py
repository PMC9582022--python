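"""Framewise displacement, DVARS, scrubbing, QC, cosine basis, confound regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peersusc import prep


def _motion(n):
    return np.zeros((n, 6))


class TestFramewiseDisplacement:
    def test_constant_motion_gives_zero_fd(self):
        m = np.tile([1.0, -2.0, 0.5, 0.01, 0.0, -0.02], (10, 1))
        assert np.all(prep.compute_fd(m) == 0)

    def test_single_translation_step(self):
        m = _motion(5)
        m[3:, 0] += 0.1  # +0.1 mm in x from volume 3 on
        fd = prep.compute_fd(m)
        assert fd[3] == pytest.approx(0.1)
        assert fd[0] == 0 and fd[1] == fd[2] == fd[4] == 0

    def test_rotation_converted_on_50mm_sphere(self):
        m = _motion(4)
        m[2:, 4] += 0.002  # radians
        fd = prep.compute_fd(m, head_radius_mm=50.0)
        assert fd[2] == pytest.approx(0.002 * 50.0)

    @settings(deadline=None, max_examples=25)
    @given(shift=st.floats(-5, 5, allow_nan=False))
    def test_translation_invariance(self, shift):
        rng = np.random.default_rng(0)
        m = rng.normal(0, 0.05, (20, 6))
        np.testing.assert_allclose(
            prep.compute_fd(m), prep.compute_fd(m + shift), atol=1e-12
        )

    def test_rejects_short_or_bad_input(self):
        with pytest.raises(ValueError):
            prep.compute_fd(_motion(1))
        bad = _motion(5)
        bad[2, 1] = np.nan
        with pytest.raises(ValueError):
            prep.compute_fd(bad)


class TestDvars:
    def test_constant_timeseries(self):
        assert np.all(prep.compute_dvars(np.ones((8, 3))) == 0)

    def test_single_roi_step(self):
        ts = np.zeros((6, 1))
        ts[4:] = 2.0
        dvars = prep.compute_dvars(ts)
        assert dvars[4] == pytest.approx(2.0)
        assert dvars[[0, 1, 2, 3, 5]].sum() == 0

    def test_matches_loop_oracle(self, rng):
        ts = rng.normal(size=(10, 4))
        expected = np.zeros(10)
        for t in range(1, 10):  # independent brute-force definition
            expected[t] = np.sqrt(np.mean([(ts[t, j] - ts[t - 1, j]) ** 2 for j in range(4)]))
        np.testing.assert_allclose(prep.compute_dvars(ts), expected, atol=1e-12)


class TestScrubFlag:
    @pytest.mark.parametrize(
        "fd, expected",
        [
            ([0, 0.1, 0.35, 0.2], [False, False, True, False]),
            ([0, 0.05, 0.30, 0.1], [False, False, False, False]),  # boundary is strict
            ([0, 0.30], [False, False]),
        ],
    )
    def test_strictly_greater_than_threshold(self, fd, expected):
        np.testing.assert_array_equal(prep.flag_scrub(fd, 0.30), expected)


class TestQc:
    def test_under_ten_percent_high_fd_is_usable(self):
        fd = np.zeros(240)
        fd[10:33] = 0.5  # 23/240 = 9.6%
        qc = prep.qc_subject(fd, tr_seconds=2.0)
        assert qc.usable and qc.reasons == []
        assert qc.pct_high_fd_prescrub == pytest.approx(23 / 240)

    def test_over_ten_percent_high_fd_excluded(self):
        fd = np.zeros(240)
        fd[:25] = 0.5  # 25/240 = 10.4%
        qc = prep.qc_subject(fd, tr_seconds=2.0)
        assert not qc.usable and "high motion" in qc.reasons

    def test_short_scan_excluded(self):
        qc = prep.qc_subject(np.zeros(100), tr_seconds=2.0)  # 200 s < 240 s
        assert not qc.usable and qc.reasons == ["short scan"]

    def test_summary_statistics(self):
        fd = np.array([0, 0.1, 0.2, 0.3])
        qc = prep.qc_subject(fd, tr_seconds=2.0)
        assert qc.mean_fd == pytest.approx(0.2)
        assert qc.max_fd == pytest.approx(0.3)
        assert qc.mean_fd <= qc.max_fd


class TestDctBasis:
    def test_column_count_240_volumes_tr2_cutoff128(self):
        basis = prep.dct_basis(240, 2.0, 128.0)
        assert basis.shape == (240, 7)

    def test_columns_orthogonal(self):
        basis = prep.dct_basis(240, 2.0, 128.0)
        gram = basis.T @ basis
        np.testing.assert_allclose(gram, np.diag(np.diag(gram)), atol=1e-8)
        # and orthogonal to the constant regressor
        np.testing.assert_allclose(basis.sum(axis=0), 0, atol=1e-8)

    def test_no_columns_when_cutoff_exceeds_run_length(self):
        assert prep.dct_basis(100, 2.0, 2 * 100 * 2.0).shape[1] == 0

    def test_degenerate_cutoff_rejected(self):
        with pytest.raises(ValueError):
            prep.dct_basis(100, 2.0, 3.0)


class TestConfoundRegression:
    def test_intercept_only_demeans(self, rng):
        ts = rng.normal(5, 1, (50, 3))
        resid = prep.regress_confounds(ts, np.empty((50, 0)))
        np.testing.assert_allclose(resid, ts - ts.mean(axis=0), atol=1e-10)

    def test_residuals_orthogonal_to_confound(self, rng):
        conf = rng.normal(size=(100, 1))
        ts = 2.0 * conf + rng.normal(0, 0.1, (100, 1))
        resid = prep.regress_confounds(ts, conf)
        r = np.corrcoef(resid[:, 0], conf[:, 0])[0, 1]
        assert abs(r) < 1e-8

    def test_multiple_correlation_below_tolerance(self, rng):
        conf = rng.normal(size=(120, 5))
        ts = rng.normal(size=(120, 4)) + conf @ rng.normal(size=(5, 4))
        resid = prep.regress_confounds(ts, conf)
        design = np.column_stack([np.ones(120), conf])
        for j in range(4):
            # multiple R of the residual on the design
            beta, *_ = np.linalg.lstsq(design, resid[:, j], rcond=None)
            fitted = design @ beta
            assert np.std(fitted) / np.std(resid[:, j]) < 1e-6

    def test_regress_then_scrub_differs_from_scrub_then_regress(self, rng):
        """The two orderings are distinct projections; the pipeline logs its order."""
        conf = rng.normal(size=(60, 2))
        ts = rng.normal(size=(60, 3)) + conf @ rng.normal(size=(2, 3))
        mask = np.zeros(60, dtype=bool)
        mask[rng.choice(60, size=8, replace=False)] = True
        a = prep.scrub(prep.regress_confounds(ts, conf), mask)
        b = prep.regress_confounds(prep.scrub(ts, mask), prep.scrub(conf, mask))
        assert not np.allclose(a, b, atol=1e-10)

    def test_rank_deficient_design_rejected(self, rng):
        conf = rng.normal(size=(30, 1))
        with pytest.raises(np.linalg.LinAlgError):
            prep.regress_confounds(rng.normal(size=(30, 2)), np.hstack([conf, conf]))

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            prep.regress_confounds(rng.normal(size=(30, 2)), rng.normal(size=(29, 1)))


class TestScrub:
    def test_empty_censor_set_is_identity(self, rng):
        ts = rng.normal(size=(20, 3))
        np.testing.assert_array_equal(prep.scrub(ts, np.zeros(20, bool)), ts)

    def test_row_count_decreases_by_censored(self, rng):
        ts = rng.normal(size=(240, 4))
        mask = np.zeros(240, bool)
        mask[:17] = True
        assert prep.scrub(ts, mask).shape == (223, 4)

    def test_column_means_over_kept_volumes_only(self, rng):
        ts = rng.normal(size=(50, 2))
        mask = np.zeros(50, bool)
        mask[::5] = True
        kept = prep.scrub(ts, mask)
        np.testing.assert_allclose(kept.mean(axis=0), ts[~mask].mean(axis=0))

    def test_all_censored_rejected(self, rng):
        with pytest.raises(ValueError):
            prep.scrub(rng.normal(size=(5, 2)), np.ones(5, bool))


class TestSubjectPipeline:
    def test_missing_fd_column_recomputed(self, tmp_path, rng):
        motion = pd.DataFrame(
            np.cumsum(rng.normal(0, 0.02, (30, 6)), axis=0), columns=prep.MOTION_COLUMNS
        )
        motion["csf"] = rng.normal(size=30)
        path = tmp_path / "conf.tsv"
        motion.to_csv(path, sep="\t", index=False)
        conf = prep.read_confounds(path)
        np.testing.assert_allclose(
            conf["framewise_displacement"],
            prep.compute_fd(conf[prep.MOTION_COLUMNS]),
        )

    def test_rerun_is_bit_identical(self, imaging_cohort):
        sid = imaging_cohort.records["subject_id"].iloc[0]
        ts = imaging_cohort.timeseries[sid]
        conf = imaging_cohort.confounds[sid]
        a, qc_a, log_a = prep.prep_subject(ts, conf, 2.0)
        b, qc_b, log_b = prep.prep_subject(ts, conf, 2.0)
        pd.testing.assert_frame_equal(a, b)
        assert log_a == log_b and qc_a == qc_b
        assert log_a["order"] == ["fd", "qc", "regress", "scrub"]

    def test_residuals_orthogonal_to_design_after_pipeline(self, imaging_cohort):
        sid = imaging_cohort.records["subject_id"].iloc[0]
        ts = imaging_cohort.timeseries[sid]
        conf = imaging_cohort.confounds[sid]
        clean, _, log = prep.prep_subject(ts, conf, 2.0, censor_aware_regression=True)
        # censored-aware path: residuals orthogonal to the censored design
        fd = conf["framewise_displacement"].to_numpy()
        mask = prep.flag_scrub(fd)
        design = pd.concat(
            [
                conf[prep.DEFAULT_CONFOUNDS].reset_index(drop=True),
                pd.DataFrame(prep.dct_basis(len(ts), 2.0)),
            ],
            axis=1,
        ).to_numpy()[~mask]
        inner = design.T @ (clean.to_numpy() - clean.to_numpy().mean(0))
        scale = np.linalg.norm(design) * np.linalg.norm(clean.to_numpy())
        assert np.abs(inner).max() / scale < 1e-8


class TestAccounting:
    def test_volume_count_from_duration(self):
        assert prep.n_volumes_for(8 * 60, 2.0) == 240

    def test_usable_sample_subtracts_exclusions(self):
        assert prep.usable_sample(110, 19, 1, 3) == 87

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            prep.usable_sample(10, 10)
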