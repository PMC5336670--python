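"""Error-model calibration: OLS correctness, prediction, R² conventions."""

import io

import numpy as np
import pytest

from erlbd.errormodel import (
    CalibrationPoint,
    er_lbd_calibration,
    fit_error_model,
    loo_validate,
    predict,
    predict_rmsd,
    r_squared,
    read_calibration_csv,
    write_calibration_csv,
)
from erlbd.errors import (
    ConfigurationError,
    DegeneracyError,
    InsufficientDataError,
    ValidationError,
)
from erlbd.synth import make_calibration_table

# The packaged ER LBD series: human anchor, rat, oyster measured; rotifer
# prediction-only at 68 % similarity.
ER_POINTS = [
    CalibrationPoint("Human", 100.0, 0.0),
    CalibrationPoint("Rat", 94.0, 0.71),
    CalibrationPoint("Oyster", 72.0, 1.45),
    CalibrationPoint("Rotifer", 68.0, None),
]


def closed_form_ols(xs, ys):
    """Normal-equation OLS, independent of the fitting code path."""
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    A = np.column_stack([xs, np.ones_like(xs)])
    coef, *_ = np.linalg.lstsq(A, ys, rcond=None)
    return coef[0], coef[1]


class TestFit:
    def test_er_series_slope_and_intercept(self):
        m = fit_error_model(ER_POINTS)
        # closed-form OLS on (100, 0), (94, 0.71), (72, 1.45)
        assert m.slope == pytest.approx(-0.0469, abs=5e-4)
        assert m.intercept == pytest.approx(4.878, abs=5e-3)
        assert m.n_points == 3
        assert m.similarity_range == (72.0, 100.0)

    def test_matches_normal_equations_on_random_sets(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 12))
            xs = rng.uniform(0, 100, n)
            while len(np.unique(xs)) < 2:
                xs = rng.uniform(0, 100, n)
            ys = np.abs(rng.normal(1.0, 0.5, n))
            pts = [CalibrationPoint(f"p{i}", x, y) for i, (x, y) in enumerate(zip(xs, ys))]
            m = fit_error_model(pts)
            slope, intercept = closed_form_ols(xs, ys)
            assert m.slope == pytest.approx(slope, abs=1e-10)
            assert m.intercept == pytest.approx(intercept, abs=1e-10)

    def test_two_points_exact_line(self):
        m = fit_error_model(
            [CalibrationPoint("a", 90.0, 0.5), CalibrationPoint("b", 70.0, 1.5)]
        )
        assert predict_rmsd(m, 90.0) == pytest.approx(0.5)
        assert predict_rmsd(m, 70.0) == pytest.approx(1.5)
        assert m.r_squared == pytest.approx(1.0)

    def test_collinear_points_r2_is_1(self):
        pts = [CalibrationPoint(str(s), s, 5.0 - 0.04 * s) for s in (100, 90, 80)]
        m = fit_error_model(pts)
        assert m.r_squared == pytest.approx(1.0)

    def test_insufficient_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_error_model([CalibrationPoint("a", 90.0, 0.5)])

    def test_equal_similarities_degenerate(self):
        with pytest.raises(DegeneracyError):
            fit_error_model(
                [CalibrationPoint("a", 90.0, 0.5), CalibrationPoint("b", 90.0, 1.5)]
            )

    def test_prediction_only_points_ignored_by_fit(self):
        assert fit_error_model(ER_POINTS).n_points == 3


class TestPredict:
    def test_rotifer_prediction_from_er_series(self):
        m = fit_error_model(ER_POINTS)
        assert predict_rmsd(m, 68.0) == pytest.approx(1.69, abs=0.01)

    def test_prediction_below_range_is_flagged_extrapolation(self):
        m = fit_error_model(ER_POINTS)
        p = predict(m, 68.0)
        assert p.extrapolated  # 68 < min calibration similarity (72)
        assert not predict(m, 85.0).extrapolated

    def test_floor_at_zero_keeps_raw_value(self):
        m = fit_error_model(
            [CalibrationPoint("a", 0.0, 1.0), CalibrationPoint("b", 20.0, 0.0)]
        )
        p = predict(m, 30.0)  # raw -0.5
        assert p.rmsd_A == 0.0
        assert p.raw_rmsd_A == pytest.approx(-0.5)


class TestRSquared:
    def test_with_predictions_replicates_0_95(self):
        m = fit_error_model(ER_POINTS)
        assert r_squared(m, ER_POINTS, "with_predictions") == pytest.approx(0.95, abs=0.01)

    def test_calibration_only_is_0_91(self):
        m = fit_error_model(ER_POINTS)
        assert r_squared(m, ER_POINTS, "calibration_only") == pytest.approx(0.91, abs=0.01)

    def test_collinear_points_give_1(self):
        pts = [CalibrationPoint(str(s), s, 5.0 - 0.04 * s) for s in (100, 90, 80)]
        m = fit_error_model(pts)
        assert r_squared(m, pts, "calibration_only") == pytest.approx(1.0)

    def test_unknown_mode_rejected(self):
        m = fit_error_model(ER_POINTS)
        with pytest.raises(ConfigurationError):
            r_squared(m, ER_POINTS, "bogus")

    def test_prediction_points_only_raise_r2(self, rng):
        """On-line extra points can only pull R² up, never down."""
        for _ in range(20):
            xs = rng.uniform(40, 100, 5)
            while len(np.unique(xs)) < 2:
                xs = rng.uniform(40, 100, 5)
            ys = np.abs(2.5 - 0.02 * xs + rng.normal(0, 0.3, 5))
            pts = [CalibrationPoint(f"p{i}", x, y) for i, (x, y) in enumerate(zip(xs, ys))]
            m = fit_error_model(pts)
            base = r_squared(m, pts, "calibration_only")
            if base == pytest.approx(1.0):
                continue
            augmented = pts + [CalibrationPoint("extra", 50.0, None)]
            assert r_squared(m, augmented, "with_predictions") >= base - 1e-12


class TestLeaveOneOut:
    def test_collinear_points_have_zero_loo_error(self):
        pts = [CalibrationPoint(str(s), s, 5.0 - 0.04 * s) for s in (100, 90, 80, 70)]
        table = loo_validate(pts)
        assert np.allclose(table["abs_error"], 0.0, atol=1e-10)

    def test_er_series_oyster_loo_matches_two_point_line(self):
        table = loo_validate(ER_POINTS)
        # leaving oyster out: line through (100, 0) and (94, 0.71),
        # slope -0.71/6, evaluated at 72
        expected = 0.71 / 6.0 * (100.0 - 72.0)
        row = table[table["label"] == "Oyster"].iloc[0]
        assert row["predicted"] == pytest.approx(expected, abs=1e-10)

    def test_two_points_insufficient(self):
        with pytest.raises(InsufficientDataError):
            loo_validate(ER_POINTS[:2])


class TestParameterRecovery:
    def test_noiseless_table_recovers_truth_exactly(self):
        points, truth = make_calibration_table(-0.0469, 4.878, [100, 94, 72], sigma=0.0)
        m = fit_error_model(points)
        assert m.slope == pytest.approx(truth["slope"], abs=1e-10)
        assert m.intercept == pytest.approx(truth["intercept"], abs=1e-10)
        # line values at the ER similarities
        assert [p.rmsd_A for p in points] == pytest.approx([0.188, 0.469, 1.501], abs=1e-3)

    def test_estimates_unbiased_over_replicates(self):
        """Mean slope/intercept over 1,000 noisy tables within 3 SE of truth."""
        slope_t, int_t = -0.0469, 4.878
        slopes, intercepts = [], []
        for seed in range(1000):
            points, _ = make_calibration_table(
                slope_t, int_t, [100, 94, 72], sigma=0.1, seed=seed
            )
            m = fit_error_model(points)
            slopes.append(m.slope)
            intercepts.append(m.intercept)
        for est, truth in ((slopes, slope_t), (intercepts, int_t)):
            est = np.asarray(est)
            se = est.std(ddof=1) / np.sqrt(len(est))
            assert abs(est.mean() - truth) <= 3 * se


class TestCalibrationIO:
    def test_packaged_er_table_contents(self):
        pts = er_lbd_calibration()
        assert [p.label for p in pts] == ["Human", "Rat", "Oyster", "Rotifer"]
        assert [p.similarity_pct for p in pts] == [100.0, 94.0, 72.0, 68.0]
        assert [p.rmsd_A for p in pts] == [0.0, 0.71, 1.45, None]

    def test_csv_round_trip_preserves_blank_rmsd(self, tmp_path):
        path = tmp_path / "cal.csv"
        write_calibration_csv(ER_POINTS, path)
        again = read_calibration_csv(path)
        assert again == ER_POINTS

    def test_missing_columns_rejected(self):
        with pytest.raises(ValidationError):
            read_calibration_csv(io.StringIO("a,b\n1,2\n"))

    def test_invalid_similarity_rejected(self):
        with pytest.raises(ValidationError):
            CalibrationPoint("x", 150.0, 1.0)
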