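"""Divergence projection, smoothing, resampling, and registration."""

import numpy as np
import pytest

from filmqa import (
    DosePlane,
    RegistrationTransform,
    apply_transform,
    coregister,
    gaussian_smooth,
    project_to_isocenter,
    resample_linear,
)
from filmqa import synthetic as syn


def field_width_50(plane, axis=1):
    """Width between the 50% points of the central profile, by linear
    interpolation of the crossing positions."""
    ys, xs = plane.axis_coords()
    i0 = np.argmin(np.abs(ys))
    prof = plane.values[i0, :] if axis == 1 else plane.values[:, i0]
    coords = xs if axis == 1 else ys
    half = prof.max() / 2
    above = prof >= half
    lo, hi = np.argmax(above), len(prof) - 1 - np.argmax(above[::-1])
    x_lo = np.interp(half, [prof[lo - 1], prof[lo]], [coords[lo - 1], coords[lo]])
    x_hi = np.interp(half, [prof[hi + 1], prof[hi]], [coords[hi + 1], coords[hi]])
    return x_hi - x_lo


class TestProjection:
    def test_field_edges_scale_by_similar_triangles(self):
        # 10x10 cm at isocenter seen at the tray: edges at +/-2.84 cm
        plane = syn.make_square_field(10.0, 200.0, spacing_mm=1.0, sdd=100.0)
        demag = project_to_isocenter(plane, target_sdd=56.8)
        assert field_width_50(demag) == pytest.approx(56.8, abs=0.15)
        back = project_to_isocenter(demag, target_sdd=100.0)
        assert field_width_50(back) == pytest.approx(100.0, abs=0.15)

    def test_doses_carried_unchanged(self, imrt_plan):
        proj = project_to_isocenter(imrt_plan.copy_with(sdd=56.8))
        assert np.array_equal(proj.values, imrt_plan.values)
        assert proj.sdd == 100.0

    def test_same_sdd_is_identity(self, imrt_plan):
        proj = project_to_isocenter(imrt_plan, target_sdd=imrt_plan.sdd)
        assert proj.spacing == imrt_plan.spacing
        assert proj.origin == imrt_plan.origin

    def test_spacing_scales_by_sdd_ratio(self):
        plane = DosePlane.centered(np.ones((5, 5)), 25.4 / 75, sdd=56.8)
        proj = project_to_isocenter(plane, 100.0)
        # 0.33867 mm x (100/56.8) = 0.59624 mm, by hand
        assert proj.spacing[0] == pytest.approx(0.596244, abs=1e-4)


class TestGaussianSmooth:
    def test_uniform_plane_unchanged(self):
        plane = DosePlane.centered(np.full((21, 21), 150.0), 0.5, sdd=100.0)
        out = gaussian_smooth(plane, 1.0)
        assert np.allclose(out.values, 150.0, atol=1e-9)

    def test_sigma_zero_is_bit_identical(self, imrt_plan):
        out = gaussian_smooth(imrt_plan, 0.0)
        assert np.array_equal(out.values, imrt_plan.values)

    def test_negative_sigma_rejected(self, imrt_plan):
        with pytest.raises(ValueError):
            gaussian_smooth(imrt_plan, -1.0)

    def test_noise_reduction_matches_kernel_l2_norm(self, rng):
        """White noise std is multiplied by the L2 norm of the discrete
        kernel; measure the norm numerically from an impulse response."""
        sigma_mm, spacing = 1.0, 0.5
        n = 401
        noise = rng.normal(0, 1, (n, n))
        plane = DosePlane.centered(noise - noise.min(), spacing, sdd=100.0)
        out = gaussian_smooth(plane, sigma_mm)
        impulse = np.zeros((81, 81))
        impulse[40, 40] = 1.0
        kernel = gaussian_smooth(
            DosePlane.centered(impulse, spacing, sdd=100.0), sigma_mm
        ).values
        expected_factor = np.sqrt((kernel**2).sum())
        measured = out.values[50:-50, 50:-50].std() / plane.values[50:-50, 50:-50].std()
        assert measured == pytest.approx(expected_factor, rel=0.05)


class TestResample:
    def test_2mm_to_half_mm_quadruples_point_density(self):
        plane = DosePlane.centered(np.ones((41, 41)), 2.0, sdd=100.0)
        out = resample_linear(plane, 0.5)
        # N nodes -> 4(N-1)+1 per axis over the same physical extent
        assert out.shape == (161, 161)
        assert out.extent() == pytest.approx(plane.extent())

    def test_affine_surface_exactly_reproduced(self):
        ys = np.arange(11) * 2.0
        xs = np.arange(13) * 2.0
        vals = 30.0 + 1.5 * xs[None, :] + 0.5 * ys[:, None]
        plane = DosePlane(vals, 2.0, (0.0, 0.0), sdd=100.0)
        out = resample_linear(plane, 0.5)
        oys, oxs = out.axis_coords()
        expected = 30.0 + 1.5 * oxs[None, :] + 0.5 * oys[:, None]
        assert np.allclose(out.values, expected, atol=1e-10)

    def test_identity_spacing_preserves_nodes(self, imrt_plan):
        out = resample_linear(imrt_plan, imrt_plan.spacing[0])
        assert np.allclose(out.values, imrt_plan.values, atol=1e-10)

    def test_absurd_spacing_capped(self, imrt_plan):
        with pytest.raises(ValueError, match="cap"):
            resample_linear(imrt_plan, 0.001)


class TestCoregister:
    def test_identical_planes_give_zero_shift(self, imrt_plan):
        t = coregister(imrt_plan, imrt_plan)
        assert abs(t.shift[0]) < 0.05 and abs(t.shift[1]) < 0.05

    def test_known_translation_recovered(self, imrt_plan):
        d = (2.0, -1.5)
        moved = DosePlane(
            imrt_plan.values,
            imrt_plan.spacing,
            (imrt_plan.origin[0] + d[0], imrt_plan.origin[1] + d[1]),
            imrt_plan.sdd,
        )
        t = coregister(imrt_plan, moved)
        # aligning back requires shifting by -d
        assert t.shift[0] == pytest.approx(-d[0], abs=0.25)
        assert t.shift[1] == pytest.approx(-d[1], abs=0.25)
        realigned = apply_transform(moved, t)
        # compare at common physical points well inside both grids
        pts = np.stack(np.meshgrid(np.linspace(-40, 40, 17),
                                   np.linspace(-40, 40, 17), indexing="ij"),
                       axis=-1)
        err = np.nanmax(np.abs(realigned.values_at(pts) - imrt_plan.values_at(pts)))
        assert err < 0.01 * imrt_plan.values.max()

    def test_manual_shift_returned_verbatim(self, imrt_plan):
        t = coregister(imrt_plan, imrt_plan, manual_shift=(1.25, -0.75))
        assert t.shift == (1.25, -0.75)

    def test_featureless_planes_flagged_low_confidence(self):
        flat = DosePlane.centered(np.full((31, 31), 100.0), 2.0, sdd=100.0)
        t = coregister(flat, flat)
        assert t.low_confidence
        assert t.shift == (0.0, 0.0)

    def test_mismatched_sdd_rejected(self, imrt_plan):
        tray = imrt_plan.copy_with(sdd=56.8)
        with pytest.raises(ValueError, match="SDD"):
            coregister(imrt_plan, tray)


class TestApplyTransform:
    def test_identity_is_bit_identical_interior(self, imrt_plan):
        out = apply_transform(imrt_plan, RegistrationTransform())
        assert np.allclose(out.values, imrt_plan.values, atol=1e-12)

    def test_integer_grid_shift_transports_values_exactly(self, imrt_plan):
        dy = imrt_plan.spacing[0]
        out = apply_transform(imrt_plan, RegistrationTransform(shift=(dy, 0)))
        assert np.allclose(out.values[1:, :], imrt_plan.values[:-1, :], atol=1e-12)
        assert np.all(np.isnan(out.values[0, :]))

    def test_shift_then_inverse_recovers_smooth_plane(self, imrt_plan):
        smooth = gaussian_smooth(imrt_plan, 2.0)
        t = RegistrationTransform(shift=(0.7, -0.3))
        there = apply_transform(smooth, t)
        back = apply_transform(there, t.inverse())
        core = np.s_[3:-3, 3:-3]
        err = np.nanmax(np.abs(back.values[core] - smooth.values[core]))
        # two bilinear resamplings each cost O(h^2 f'') in the penumbra
        assert err < 0.02 * smooth.values.max()


def test_full_chain_on_clean_aligned_pair(noiseless_calibration, imrt_plan):
    """Project -> register -> smooth -> resample on a noiseless, perfectly
    aligned synthetic pair must leave the comparison essentially exact."""
    from filmqa import PipelineConfig, run_qa

    rng = np.random.default_rng(9)
    scan = syn.simulate_film_scan(imrt_plan, rng=rng, noise_sigma=0.0)
    res = run_qa(scan, noiseless_calibration, imrt_plan,
                 config=PipelineConfig(smoothing_sigma_mm=0.0))
    assert abs(res.percent_diff) < 0.2
    assert res.gamma.pass_rate == 100.0
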