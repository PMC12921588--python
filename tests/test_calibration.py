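"""FI totals, the polynomial calibration fit, model selection, and the two
pixel-to-concentration conversion modes."""

import logging

import numpy as np
import pytest

from haquant import (
    CalibrationModel,
    CalibrationPoint,
    PhantomSpec,
    RatioParams,
    ThicknessFactor,
    TissueMask,
    build_calibration_point,
    concentration_map,
    fi_concentration,
    fit_calibration,
    generate_phantom,
    pixel_to_concentration_ratio,
    select_model,
    total_fi,
)
from haquant.phantom import Misalignment
from haquant.pipeline import process_block

from conftest import make_image


def full_mask(shape):
    return TissueMask(mask=np.ones(shape, bool), threshold=0.0, pixel_size_um=1.0)


class TestTotalsAndConcentration:
    def test_constant_masked_sum(self):
        img = make_image(np.full((50, 50), 2.0))
        assert total_fi(img, full_mask((50, 50))) == 5000.0
        assert total_fi(make_image(np.zeros((5, 5))), full_mask((5, 5))) == 0.0

    def test_matches_enumeration_oracle(self, rng):
        data = rng.random((30, 30)) * 100
        mask = rng.random((30, 30)) > 0.4
        expected = sum(
            data[r, c] for r in range(30) for c in range(30) if mask[r, c]
        )
        tm = TissueMask(mask=mask, threshold=0.0, pixel_size_um=1.0)
        assert np.isclose(total_fi(make_image(data), tm), expected, rtol=1e-12)

    def test_empty_mask_rejected(self):
        empty = TissueMask(mask=np.zeros((5, 5), bool), threshold=0.0, pixel_size_um=1.0)
        with pytest.raises(ValueError, match="empty"):
            total_fi(make_image(np.ones((5, 5))), empty)

    def test_fi_concentration_linearity(self):
        assert fi_concentration(44_000, 44_000) == 1.0
        assert fi_concentration(0.0, 10.0) == 0.0
        assert fi_concentration(100.0, 20.0) == 2 * fi_concentration(100.0, 40.0)
        with pytest.raises(ValueError):
            fi_concentration(1.0, 0.0)


class TestBuildCalibrationPoint:
    def _block_with_flanks(self, level_before, level_after):
        # flanking FI images with uniform tissue plateaus on zero background
        def fi_img(level):
            img = np.zeros((40, 40))
            img[5:35, 5:35] = level
            return make_image(img)

        spec = PhantomSpec(
            seed=0, noise_sigma=0.0, elisa_cv=0.0, misalignment=Misalignment.identity()
        )
        block = generate_phantom(spec).block
        return block, fi_img(level_before), fi_img(level_after)

    def test_point_is_mean_of_flanks(self):
        block, fi_b, fi_a = self._block_with_flanks(5.0, 15.0)
        # each flank: total = level*900, volume = 900*5 → conc = level/5
        point = build_calibration_point(block, fi_b, fi_a)
        assert np.isclose(point.fi_concentration, (5.0 / 5 + 15.0 / 5) / 2)

    def test_identical_flanks(self):
        block, fi_b, fi_a = self._block_with_flanks(10.0, 10.0)
        point = build_calibration_point(block, fi_b, fi_a)
        assert np.isclose(point.fi_concentration, 2.0)

    def test_missing_flank_falls_back_with_warning(self, caplog):
        block, fi_b, _ = self._block_with_flanks(10.0, 10.0)
        with caplog.at_level(logging.WARNING):
            point = build_calibration_point(block, fi_b, None)
        assert np.isclose(point.fi_concentration, 2.0)
        assert any("missing flanking" in r.message for r in caplog.records)


def normal_equations_fit(x, y, degree):
    design = np.vander(x, degree + 1, increasing=True)
    return np.linalg.solve(design.T @ design, design.T @ y)


class TestFitCalibration:
    def test_exact_quadratic_interpolated(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = 2 * x**2 + 3 * x + 1
        model = fit_calibration(
            [CalibrationPoint(a, b) for a, b in zip(x, y)], degree=2
        )
        np.testing.assert_allclose(model.coefficients, [1, 3, 2], atol=1e-9)
        assert np.isclose(model.r_squared, 1.0)
        np.testing.assert_allclose(model.residuals, 0, atol=1e-9)

    def test_exact_linear(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        model = fit_calibration(
            [CalibrationPoint(a, 0.5 * a + 0.1) for a in x], degree=1
        )
        np.testing.assert_allclose(model.coefficients, [0.1, 0.5], atol=1e-12)
        np.testing.assert_allclose(model.residuals, 0, atol=1e-12)

    def test_noisy_fit_matches_oracle_and_recovers_truth(self):
        rng = np.random.default_rng(123)
        x = rng.uniform(0, 10, 50)
        true = np.array([1.0, 3.0, 2.0])
        y = true[0] + true[1] * x + true[2] * x**2
        sigma = 0.05 * np.ptp(y)
        y = y + rng.normal(0, sigma, 50)
        model = fit_calibration(
            [CalibrationPoint(a, max(b, 0)) for a, b in zip(x, y)], degree=2
        )
        y_used = np.clip(y, 0, None)
        oracle = normal_equations_fit(x, y_used, 2)
        np.testing.assert_allclose(model.coefficients, oracle, atol=1e-9)
        # standard errors from the oracle's covariance
        design = np.vander(x, 3, increasing=True)
        dof = 50 - 3
        s2 = float(model.residuals @ model.residuals) / dof
        se = np.sqrt(np.diag(s2 * np.linalg.inv(design.T @ design)))
        assert np.all(np.abs(model.coefficients - true) < 3 * se)

    def test_rank_deficient_rejected(self):
        pts = [CalibrationPoint(2.0, float(i)) for i in range(5)]
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_calibration(pts, degree=1)

    def test_too_few_points_rejected(self):
        pts = [CalibrationPoint(float(i), float(i)) for i in range(3)]
        with pytest.raises(ValueError, match="need >="):
            fit_calibration(pts, degree=2)


class TestSelectModel:
    def _points(self, quadratic, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 10, 50)
        y = 0.5 + 2 * x + (0.15 * x**2 if quadratic else 0.0)
        y = np.clip(y + rng.normal(0, 0.05 * np.ptp(y), x.size), 0, None)
        return [CalibrationPoint(a, b) for a, b in zip(x, y)]

    def test_quadratic_truth_selects_quadratic(self):
        pts = self._points(quadratic=True, seed=11)
        chosen, report = select_model(
            fit_calibration(pts, 1), fit_calibration(pts, 2)
        )
        assert chosen.degree == 2
        assert report["chosen_degree"] == 2
        assert set(report["linear"]) >= {"r_squared", "aic", "residuals"}

    def test_tie_prefers_linear(self):
        # exact linear data: both models interpolate, AICs tie at the floor
        x = np.linspace(0, 5, 8)
        pts = [CalibrationPoint(a, 2 * a + 1) for a in x]
        chosen, _ = select_model(fit_calibration(pts, 1), fit_calibration(pts, 2))
        assert chosen.degree == 1

    def test_mismatched_point_counts_rejected(self):
        pts = self._points(False, 1)
        with pytest.raises(ValueError, match="same points"):
            select_model(fit_calibration(pts[:-1], 1), fit_calibration(pts, 2))


class TestRatioConversion:
    def test_direct_evaluation(self):
        tk = ThicknessFactor.unity()
        assert np.isclose(
            pixel_to_concentration_ratio(10.0, 1000.0, 0.5, tk), 0.005
        )
        assert pixel_to_concentration_ratio(0.0, 1000.0, 0.5, tk) == 0.0

    def test_linear_in_tk(self):
        tk1 = ThicknessFactor(thin_thickness_um=5.0, reference_thickness_um=5.0)
        tk2 = ThicknessFactor(thin_thickness_um=5.0, reference_thickness_um=10.0)
        assert np.isclose(
            pixel_to_concentration_ratio(10.0, 1000.0, 0.5, tk2),
            2 * pixel_to_concentration_ratio(10.0, 1000.0, 0.5, tk1),
        )


class TestConcentrationMap:
    def test_constant_fi_ratio_mode(self):
        fi = make_image(np.full((10, 10), 50.0), thickness_um=5.0)
        mask = full_mask((10, 10))
        # normalize the section total by an arbitrary volume
        params = RatioParams(ha_total=0.8, fi_total_conc=total_fi(fi, mask) / 4000.0)
        cmap = concentration_map(fi, mask, params, mode="ratio")
        expected = (0.8 / params.fi_total_conc) * (50.0 / 5.0)
        np.testing.assert_allclose(cmap.values, expected, rtol=1e-12)
        assert cmap.mode == "ratio"

    def test_mass_conservation_identity(self, rng):
        fi = make_image(rng.random((30, 30)) * 200, thickness_um=5.0)
        mask = TissueMask(mask=rng.random((30, 30)) > 0.3, threshold=0.0, pixel_size_um=1.0)
        v_thick = 123_456.0
        params = RatioParams(
            ha_total=0.7, fi_total_conc=total_fi(fi, mask) / v_thick
        )
        cmap = concentration_map(fi, mask, params, mode="ratio")
        lhs = cmap.values[cmap.mask].sum() * 1.0 * fi.thickness_um
        rhs = 0.7 * v_thick
        assert abs(lhs - rhs) / rhs < 1e-10

    def test_curve_equals_ratio_for_proportional_fit_through_origin(self):
        fi = make_image(np.full((8, 8), 40.0), thickness_um=5.0)
        mask = full_mask((8, 8))
        fi_conc_total = 3.2
        ha_total = 0.6
        slope = ha_total / fi_conc_total
        model = CalibrationModel(
            degree=1,
            coefficients=[0.0, slope],
            r_squared=1.0,
            residuals=np.zeros(3),
            n_points=3,
            aic=0.0,
        )
        curve = concentration_map(fi, mask, model, mode="curve")
        ratio = concentration_map(
            fi, mask, RatioParams(ha_total=ha_total, fi_total_conc=fi_conc_total),
            mode="ratio",
        )
        np.testing.assert_allclose(curve.values, ratio.values, rtol=1e-12)

    def test_noiseless_phantom_curve_mode_recovers_truth(self):
        spec = PhantomSpec(seed=5, noise_sigma=0.0, elisa_cv=0.0)
        ds = generate_phantom(spec)
        res = process_block(ds.block, ds.landmarks, ds.landmarks)
        # generating law: fi_conc = (gain / h) * c  →  c = (h / gain) * fi_conc
        model = CalibrationModel(
            degree=1,
            coefficients=[0.0, spec.thin_thickness_um / spec.gain],
            r_squared=1.0,
            residuals=np.zeros(3),
            n_points=3,
            aic=0.0,
        )
        cmap = concentration_map(res.fi_before, res.mask_before, model, mode="curve")
        both = ds.truth_map.mask & cmap.mask
        rel = np.abs(cmap.values[both] - ds.truth_map.values[both]) / ds.truth_map.values[both]
        assert rel.max() < 0.01

    def test_negative_predictions_clamped(self):
        fi = make_image(np.full((4, 4), 1.0), thickness_um=5.0)
        model = CalibrationModel(
            degree=1,
            coefficients=[-10.0, 0.001],
            r_squared=0.5,
            residuals=np.zeros(3),
            n_points=3,
            aic=0.0,
        )
        cmap = concentration_map(fi, full_mask((4, 4)), model, mode="curve")
        assert cmap.values.min() == 0.0
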