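"""Detection-limit statistics: thresholds, LoD rule, calibration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hidyce import (
    CalibrationCurve,
    DilutionStudy,
    compute_threshold,
    detection_limit,
    fit_calibration,
    measured_vaf,
    simulate_dilution_study,
    vaf_threshold_from_R_threshold,
)

GRID = (0.0, 0.001, 0.005, 0.01, 0.05)


def study_from_matrix(R, grid=GRID):
    R = np.asarray(R, float)
    return DilutionStudy(
        mutation="M", vaf_grid=grid, replicates=R.shape[1], R_matrix=R
    )


def exact_study(grid=GRID, replicates=4, scale=1.0):
    """R chosen so measured VAF == scale * prepared VAF exactly."""
    rows = []
    for v in grid:
        target = scale * v  # measured fraction
        rows.append([target / (1 - target)] * replicates)
    return study_from_matrix(rows, grid)


class TestMeasuredVaf:
    @pytest.mark.parametrize(
        "R, percent", [(1.0, 50.0), (0.0, 0.0), (0.0101, 1.0)]
    )
    def test_values(self, R, percent):
        assert measured_vaf(R) == pytest.approx(percent, abs=5e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            measured_vaf(-0.01)

    @given(r=st.floats(0, 100.0), dr=st.floats(1e-6, 10.0))
    def test_strictly_increasing_and_bounded(self, r, dr):
        assert 0 <= measured_vaf(r) < 100
        assert measured_vaf(r + dr) > measured_vaf(r)
        assert measured_vaf(1e9) < 100


class TestThreshold:
    def test_hand_computed_mean_plus_3sd(self):
        baseline = [0.001, 0.002, 0.003, 0.002]
        # mean 0.002, sample SD sqrt(2e-6/3) = 8.16497e-4
        assert compute_threshold(baseline) == pytest.approx(
            0.002 + 3 * 8.164966e-4, rel=1e-6
        )

    def test_all_zero_baseline(self):
        assert compute_threshold([0.0, 0.0, 0.0]) == 0.0

    def test_constant_baseline_gives_the_constant(self):
        assert compute_threshold([0.42] * 5) == pytest.approx(0.42)

    def test_fewer_than_two_replicates_rejected(self):
        with pytest.raises(ValueError):
            compute_threshold([0.1])

    @given(
        mean=st.floats(0, 1), sd=st.floats(0.001, 0.5),
        factor=st.floats(1.1, 5.0),
    )
    def test_monotone_in_baseline_sd_at_fixed_mean(self, mean, sd, factor):
        base = np.array([-1.0, 1.0, -1.0, 1.0])
        t1 = compute_threshold(mean + sd * base)
        t2 = compute_threshold(mean + sd * factor * base)
        assert t2 > t1


class TestDetectionLimit:
    def test_all_exceed_gives_smallest_positive_vaf(self):
        R = np.full((5, 8), 1.0)
        R[0] = 0.0
        res = detection_limit(study_from_matrix(R))
        assert res.detection_limit == 0.001

    def test_single_failure_at_lowest_vaf_moves_limit_up(self):
        R = np.full((5, 8), 1.0)
        R[0] = 0.0
        R[1, 3] = -1.0  # one replicate at 0.1% below threshold
        res = detection_limit(study_from_matrix(R))
        assert res.detection_limit == 0.005
        assert res.pass_pattern == (False, True, True, True)

    def test_failure_at_top_vaf_means_not_reached(self):
        R = np.full((5, 8), 1.0)
        R[0] = 0.0
        R[4, 0] = -1.0  # consistency clause: a 5% failure voids everything
        res = detection_limit(study_from_matrix(R))
        assert res.detection_limit is None
        assert res.detection_limit_percent is None

    def test_tie_at_threshold_fails(self):
        R = np.zeros((5, 2))
        res = detection_limit(study_from_matrix(R))  # T = 0, all R == 0
        assert res.detection_limit is None

    def test_missing_baseline_row_rejected(self):
        study = DilutionStudy(
            mutation="M", vaf_grid=(0.001, 0.01),
            replicates=2, R_matrix=np.ones((2, 2)),
        )
        with pytest.raises(ValueError, match="0%"):
            detection_limit(study)

    @given(bump=st.floats(0.0, 2.0), seed=st.integers(0, 1000))
    def test_raising_threshold_never_lowers_limit(self, bump, seed):
        study = simulate_dilution_study(noise_sd=0.002, seed=seed)
        t0 = detection_limit(study).threshold
        lo = detection_limit(study, threshold=t0)
        hi = detection_limit(study, threshold=t0 + bump)
        order = {v: i for i, v in enumerate(study.vaf_grid)}
        rank = lambda r: (
            len(order) if r.detection_limit is None else order[r.detection_limit]
        )
        assert rank(hi) >= rank(lo)


class TestCalibration:
    def test_identity_study_gives_unit_slope(self):
        curve = fit_calibration(exact_study())
        assert curve.slope == pytest.approx(1.0, abs=1e-9)
        assert curve.intercept == pytest.approx(0.0, abs=1e-9)
        assert curve.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_half_slope_study(self):
        curve = fit_calibration(exact_study(scale=0.5))
        assert curve.slope == pytest.approx(0.5, abs=1e-9)
        assert curve.intercept == pytest.approx(0.0, abs=1e-9)

    def test_noisy_slope_recovered_within_3_se(self):
        """Noisy studies recover the generating slope: the reference is
        the noise-free fit of the same generator (the ratio-to-VAF map is
        slightly concave over the 0-5% grid, so it is not exactly 1)."""
        reference = fit_calibration(
            simulate_dilution_study(noise_sd=0.0, seed=0)
        ).slope
        slopes = []
        for seed in range(20):
            study = simulate_dilution_study(noise_sd=0.001, seed=seed)
            slopes.append(fit_calibration(study).slope)
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - reference) < max(3 * se, 0.005)

    def test_degenerate_grid_rejected(self):
        study = DilutionStudy(
            mutation="M", vaf_grid=(0.0, 0.0),
            replicates=2, R_matrix=np.zeros((2, 2)),
        )
        with pytest.raises(ValueError, match="distinct"):
            fit_calibration(study)


class TestVafThreshold:
    def test_zero_threshold_zero_intercept(self):
        curve = CalibrationCurve(slope=1.0, intercept=0.0, residual_sd=0.0)
        assert vaf_threshold_from_R_threshold(0.0, curve) == 0.0

    def test_line_inversion(self):
        # measured_vaf(0.0101) = 1.0%; (1.0 - 0.2) / 0.8 = 1.0
        curve = CalibrationCurve(slope=0.8, intercept=0.2, residual_sd=0.0)
        assert vaf_threshold_from_R_threshold(
            0.0101, curve
        ) == pytest.approx(1.0, abs=2e-3)

    def test_noninvertible_curve_rejected(self):
        curve = CalibrationCurve(slope=0.0, intercept=0.0, residual_sd=0.0)
        with pytest.raises(ValueError, match="invertible"):
            vaf_threshold_from_R_threshold(0.1, curve)


class TestStudyGenerator:
    def test_grid_must_be_sorted(self):
        with pytest.raises(ValueError, match="sorted"):
            DilutionStudy(
                mutation="M", vaf_grid=(0.01, 0.0),
                replicates=1, R_matrix=np.zeros((2, 1)),
            )

    def test_deterministic_per_seed(self):
        a = simulate_dilution_study(seed=9).R_matrix
        b = simulate_dilution_study(seed=9).R_matrix
        np.testing.assert_array_equal(a, b)

    def test_mean_structure_matches_prepared_vaf(self):
        study = simulate_dilution_study(
            replicates=2000, noise_sd=0.001, seed=1
        )
        means = study.R_matrix.mean(axis=1)
        np.testing.assert_allclose(means, study.vaf_grid, atol=1e-4)
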