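"""Calibration fitting, application, and geometry-cancellation invariants."""

import numpy as np
import pytest

from filmqa import (
    CalibrationPoint,
    apply_calibration,
    build_calibration,
    load_curve,
    read_calibration_csv,
    save_curve,
    write_calibration_csv,
)
from filmqa import synthetic as syn
from filmqa.model import FilmScan


def _rational_points(a=-171.2, b=770548.0, c=-600.0, pvs=(400, 750, 1475, 2237, 2879)):
    """Points sampled exactly from dose = a + b/(pv - c)."""
    return [
        CalibrationPoint(mu=float(i + 1), pixel_value=float(pv),
                         dose=float(a + b / (pv - c)))
        for i, pv in enumerate(pvs)
    ]


class TestBuildCalibration:
    def test_rational_fit_recovers_exact_parameters(self):
        pts = _rational_points()
        curve = build_calibration(pts, "rational")
        assert curve.params["a"] == pytest.approx(-171.2, rel=1e-6)
        assert curve.params["b"] == pytest.approx(770548.0, rel=1e-6)
        assert curve.params["c"] == pytest.approx(-600.0, rel=1e-6)
        assert np.max(np.abs(curve.residuals)) < 1e-6

    def test_rational_fit_with_pole_above_range(self):
        # opposite polarity: dose grows with pixel value, pole above data
        pts = [
            CalibrationPoint(mu=float(i + 1), pixel_value=float(pv),
                             dose=float(100.0 + 5e5 / (4500.0 - pv)))
            for i, pv in enumerate((500, 1200, 2200, 3100, 3800))
        ]
        curve = build_calibration(pts, "rational")
        assert curve.increasing
        assert np.max(np.abs(curve.residuals)) < 1e-6

    def test_pchip_reproduces_every_point(self, noisy_calibration):
        pts = noisy_calibration.points
        curve = build_calibration(pts, "pchip")
        for p in pts:
            assert curve(p.pixel_value) == pytest.approx(p.dose, abs=1e-9)

    def test_netod_poly_is_monotone_and_close(self):
        pts = _rational_points()
        curve = build_calibration(pts, "netod_poly", unexposed_pixel_value=3900.0)
        grid = np.linspace(curve.domain[0], curve.domain[1], 400)
        assert np.all(np.diff(curve(grid)) < 0) or np.all(np.diff(curve(grid)) > 0)

    def test_non_monotone_points_rejected_with_offenders_named(self):
        pts = _rational_points()
        bad = list(pts)
        bad[2] = CalibrationPoint(mu=3.0, pixel_value=pts[0].pixel_value,
                                  dose=pts[2].dose)
        with pytest.raises(ValueError, match="not monotone"):
            build_calibration(bad, "rational")

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            build_calibration(_rational_points()[:2], "rational")

    def test_fitted_model_monotone_on_dense_grid(self, noisy_calibration):
        lo, hi = noisy_calibration.domain
        grid = np.linspace(lo, hi, 2048)
        diffs = np.diff(noisy_calibration(grid))
        assert np.all(diffs < 0) or np.all(diffs > 0)


class TestApplyCalibration:
    def test_uniform_scan_at_200mu_patch_value_maps_to_its_dose(
        self, noiseless_calibration
    ):
        p200 = next(p for p in noiseless_calibration.points if p.mu == 200)
        px = np.full((30, 30), round(p200.pixel_value), dtype=np.uint16)
        scan = FilmScan(pixels=px)
        plane = apply_calibration(scan, noiseless_calibration)
        # within the dose step of one pixel-value quantum
        assert plane.values[0, 0] == pytest.approx(p200.dose, rel=2e-3)
        assert plane.sdd == 56.8
        assert plane.spacing[0] == pytest.approx(25.4 / 75)

    def test_unexposed_scan_maps_to_zero_dose(self, noiseless_calibration):
        pv0 = noiseless_calibration.unexposed_pixel_value
        px = np.full((20, 20), round(pv0), dtype=np.uint16)
        plane = apply_calibration(FilmScan(pixels=px), noiseless_calibration)
        assert np.all(plane.values >= 0)
        assert plane.values.max() < 1.0  # cGy

    def test_noiseless_simulation_roundtrip_within_quantization(
        self, noiseless_calibration, imrt_plan
    ):
        rng = np.random.default_rng(3)
        scan = syn.simulate_film_scan(imrt_plan, rng=rng, noise_sigma=0.0)
        plane = apply_calibration(scan, noiseless_calibration)
        # compare against the source plane sampled at the film's positions
        f = imrt_plan.sdd / scan.sdd
        ys, xs = plane.axis_coords()
        gy, gx = np.meshgrid(ys * f, xs * f, indexing="ij")
        truth = imrt_plan.values_at(np.stack([gy, gx], axis=-1))
        err = np.abs(plane.values - truth)
        assert err.max() < 1e-3 * imrt_plan.values.max()  # 0.1% of max dose

    def test_saturated_scan_refused(self, noiseless_calibration):
        # far beyond the high-dose (low pixel value) edge of the domain
        px = np.full((10, 10), 5, dtype=np.uint16)
        with pytest.raises(ValueError, match="high-dose"):
            apply_calibration(FilmScan(pixels=px), noiseless_calibration)

    def test_tray_transmission_cancels(self, imrt_plan):
        """Recovered dose is invariant to the tray factor when calibration
        and QA scans are regenerated with the same factor."""
        recovered = []
        for tray in (0.90, 0.942, 1.0):
            rng = np.random.default_rng(5)
            pts, pv0 = syn.generate_calibration(rng, noise_sigma=0.0,
                                                tray_transmission=tray)
            curve = build_calibration(pts, "rational", unexposed_pixel_value=pv0)
            scan = syn.simulate_film_scan(imrt_plan, rng=rng, noise_sigma=0.0,
                                          tray_transmission=tray)
            plane = apply_calibration(scan, curve)
            i, j = plane.shape[0] // 2, plane.shape[1] // 2
            recovered.append(plane.values[i, j])
        assert np.ptp(recovered) < 0.01 * np.mean(recovered)


class TestSerialization:
    def test_csv_roundtrip(self, tmp_path, noisy_calibration):
        path = tmp_path / "cal.csv"
        write_calibration_csv(path, noisy_calibration.points)
        back = read_calibration_csv(path)
        assert back == list(noisy_calibration.points)

    def test_curve_json_roundtrip(self, tmp_path, noisy_calibration):
        path = tmp_path / "curve.json"
        save_curve(path, noisy_calibration)
        back = load_curve(path)
        grid = np.linspace(*noisy_calibration.domain, 100)
        assert np.allclose(back(grid), noisy_calibration(grid), rtol=1e-9)
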