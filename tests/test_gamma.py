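"""Gamma index: closed-form cases, oracle equivalence, and invariants."""

import numpy as np
import pytest

from filmqa import DosePlane, GammaCriteria, gamma_map, gamma_oracle
from filmqa import synthetic as syn


def random_pair(seed, n=12, spacing=2.0, shift=True):
    """A noisy reference/evaluated plane pair on small grids."""
    rng = np.random.default_rng(seed)
    base = 150 + 60 * rng.random((n, n))
    ref = DosePlane.centered(base, spacing, sdd=100.0)
    ev_vals = np.clip(base + rng.normal(0, 4, (n, n)), 0, None)
    origin = ref.origin
    if shift:
        origin = (origin[0] + rng.uniform(-1, 1), origin[1] + rng.uniform(-1, 1))
    ev = DosePlane(ev_vals, spacing, origin, sdd=100.0)
    return ref, ev


class TestClosedForms:
    def test_identity_gives_zero_gamma_everywhere(self, imrt_plan):
        res = gamma_map(imrt_plan, imrt_plan)
        finite = res.gamma_map[np.isfinite(res.gamma_map)]
        assert res.pass_rate == 100.0
        assert np.max(finite) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "factor,expected_gamma,expected_pass",
        [(1.02, 2.0 / 3.0, 100.0), (1.04, 4.0 / 3.0, 0.0)],
    )
    def test_uniform_scaling_has_no_dta_escape(self, factor, expected_gamma,
                                               expected_pass):
        """On a gradient-free plane the DTA term cannot help, so gamma is
        exactly the dose difference over the 3% criterion."""
        ref = DosePlane.centered(np.full((15, 15), 200.0), 2.0, sdd=100.0)
        ev = DosePlane.centered(np.full((15, 15), 200.0 * factor), 2.0, sdd=100.0)
        res = gamma_map(ref, ev)
        finite = res.gamma_map[np.isfinite(res.gamma_map)]
        assert np.allclose(finite, expected_gamma, atol=1e-9)
        assert res.pass_rate == expected_pass

    def test_subcriterion_translation_absorbed_by_dta(self):
        """A pure 2 mm shift of a steep-gradient plane with 3 mm DTA gives
        gamma <= 2/3 plus sub-grid error."""
        plane = syn.make_square_field(6.0, 200.0, penumbra_sigma_mm=4.0,
                                      spacing_mm=2.0, margin_mm=20.0)
        shifted = DosePlane(plane.values, plane.spacing,
                            (plane.origin[0], plane.origin[1] + 2.0), plane.sdd)
        res = gamma_map(plane, shifted)
        finite = res.gamma_map[np.isfinite(res.gamma_map)]
        assert res.pass_rate == 100.0
        assert np.max(finite) <= 2.0 / 3.0 + 0.05

    def test_no_evaluable_points_is_error(self):
        """An evaluated plane with no data anywhere (all missing after
        registration) leaves an empty evaluable set."""
        ref = DosePlane.centered(np.full((8, 8), 100.0), 2.0, sdd=100.0)
        missing = ref.copy_with(values=np.full((8, 8), np.nan))
        with pytest.raises(ValueError, match="no evaluable"):
            gamma_map(ref, missing)


class TestOracleEquivalence:
    def test_single_noisy_pair_matches_oracle(self):
        ref, ev = random_pair(123)
        gm = gamma_map(ref, ev)
        go = gamma_oracle(ref, ev)
        assert np.nanmax(np.abs(gm.gamma_map - go.gamma_map)) < 1e-6
        assert gm.pass_rate == go.pass_rate
        assert gm.n_evaluated == go.n_evaluated

    @pytest.mark.parametrize("seed", range(20))
    def test_seeded_sweep_matches_oracle(self, seed):
        ref, ev = random_pair(seed)
        gm = gamma_map(ref, ev)
        go = gamma_oracle(ref, ev)
        assert np.nanmax(np.abs(gm.gamma_map - go.gamma_map)) < 1e-6

    def test_oracle_refuses_large_grids(self):
        big = DosePlane.centered(np.full((80, 80), 100.0), 2.0, sdd=100.0)
        with pytest.raises(ValueError, match="limited"):
            gamma_oracle(big, big)


class TestInvariants:
    def test_unit_relabeling_invariance(self):
        """Gy vs cGy: scaling both planes by the same factor leaves the
        relative dose-difference term, hence gamma, unchanged."""
        ref, ev = random_pair(7, shift=False)
        g1 = gamma_map(ref, ev)
        g2 = gamma_map(ref.copy_with(values=ref.values / 100),
                       ev.copy_with(values=ev.values / 100))
        assert np.allclose(g1.gamma_map, g2.gamma_map, atol=1e-9, equal_nan=True)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_loosening_criteria_never_lowers_pass_rate(self, seed):
        ref, ev = random_pair(seed)
        base = gamma_map(ref, ev, GammaCriteria(dose_tol=2.0, dta_tol=2.0))
        for crit in (GammaCriteria(dose_tol=3.0, dta_tol=2.0),
                     GammaCriteria(dose_tol=2.0, dta_tol=3.0),
                     GammaCriteria(dose_tol=4.0, dta_tol=4.0)):
            assert gamma_map(ref, ev, crit).pass_rate >= base.pass_rate

    def test_translation_bound(self):
        """Shifting the evaluated plane by t mm bounds every gamma by
        ~t/dta on a smooth plane (sub-grid discretization tolerance)."""
        plane = syn.make_square_field(8.0, 200.0, penumbra_sigma_mm=5.0,
                                      spacing_mm=2.0, margin_mm=20.0)
        for t_mm in (1.0, 2.0):
            shifted = DosePlane(plane.values, plane.spacing,
                                (plane.origin[0] + t_mm, plane.origin[1]),
                                plane.sdd)
            # fine lattice so the shift is representable to ~0.05 mm
            res = gamma_map(plane, shifted, max_step_mm=0.1)
            finite = res.gamma_map[np.isfinite(res.gamma_map)]
            assert np.max(finite) <= t_mm / 3.0 + 0.1

    def test_normalizations_agree_when_point_carries_max(self):
        # odd grid so the central axis (0,0) is a grid node
        ref, ev = random_pair(11, n=13, shift=False)
        i = ref.shape[0] // 2
        ref.values[i, i] = ref.values.max() + 1
        g_glob = gamma_map(ref, ev, GammaCriteria(normalization="global_max"))
        g_point = gamma_map(ref, ev, GammaCriteria(normalization="point_dose"))
        assert np.allclose(g_glob.gamma_map, g_point.gamma_map,
                           atol=1e-9, equal_nan=True)

    def test_subgrid_convergence_on_smooth_planes(self):
        """On smooth (clinically representative) planes, halving the
        fine-lattice step must not change the pass rate by more than 0.1
        percentage points — the lattice at dta/10 is already converged."""
        ref = syn.make_imrt_plane(syn.EXAMPLE_PLAN_SEGMENTS[1])
        ev = DosePlane(ref.values * 1.04, ref.spacing,
                       (ref.origin[0] + 0.7, ref.origin[1] - 0.4), ref.sdd)
        g_default = gamma_map(ref, ev, max_step_mm=0.3)
        g_half = gamma_map(ref, ev, max_step_mm=0.15)
        assert 0 < g_default.pass_rate < 100  # genuinely marginal case
        assert abs(g_default.pass_rate - g_half.pass_rate) <= 0.1

    def test_mismatched_sdd_rejected(self, imrt_plan):
        with pytest.raises(ValueError, match="SDD"):
            gamma_map(imrt_plan, imrt_plan.copy_with(sdd=56.8))
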