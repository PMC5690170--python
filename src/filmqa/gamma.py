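"""Gamma-index comparison of two dose planes.

For each reference point r above the low-dose threshold the gamma index is

    γ(r) = min over r' of sqrt( |r − r'|² / dta² + ΔD(r, r')² / δ² )

where r' ranges over evaluated-plane positions within the search radius,
ΔD is the dose difference in % of the normalization dose, δ the dose
criterion (%), and dta the distance-to-agreement criterion (mm).  A point
agrees when γ ≤ 1; the pass rate is the percentage of evaluated points
that agree.

Two implementations share this contract.  ``gamma_map`` is the production
path: the evaluated plane is bilinearly resampled onto a fine lattice
aligned with the reference grid (step ≤ dta/10) and the minimization is
vectorized over lattice offsets, visited in order of increasing distance
so the search can stop once the distance term alone exceeds every
remaining minimum — a pruning that cannot change any γ.  ``gamma_oracle``
is the correctness standard: an exhaustive per-point search over the same
lattice with no vectorization, pruning or early exit, kept on a separate
code path precisely so the two can be compared.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .model import DosePlane, GammaCriteria, GammaNormalization, GammaResult

__all__ = ["gamma_map", "gamma_oracle", "normalization_dose"]

ORACLE_MAX_NODES = 64  # per axis; the oracle is for small fixtures only


def normalization_dose(reference: DosePlane, criteria: GammaCriteria) -> float:
    """Normalization dose: the reference plane's global maximum, or its
    dose at the central axis for point-dose normalization."""
    if criteria.normalization is GammaNormalization.GLOBAL_MAX:
        finite = reference.values[np.isfinite(reference.values)]
        if finite.size == 0:
            raise ValueError("reference plane has no finite dose values")
        return float(finite.max())
    return reference.value_at((0.0, 0.0))


def _fine_lattice(reference: DosePlane, evaluated: DosePlane,
                  criteria: GammaCriteria, max_step_mm: float | None):
    """Fine sampling lattice aligned with the reference grid, extended by
    the search radius, with the evaluated plane resampled onto it."""
    radius = criteria.search_radius_factor * criteria.dta_tol
    target = max_step_mm if max_step_mm is not None else criteria.dta_tol / 10.0
    ky = max(1, math.ceil(reference.spacing[0] / target))
    kx = max(1, math.ceil(reference.spacing[1] / target))
    step_y = reference.spacing[0] / ky
    step_x = reference.spacing[1] / kx
    my = math.ceil(radius / step_y)
    mx = math.ceil(radius / step_x)

    ny, nx = reference.shape
    ys_f = reference.origin[0] + step_y * (np.arange((ny - 1) * ky + 2 * my + 1) - my)
    xs_f = reference.origin[1] + step_x * (np.arange((nx - 1) * kx + 2 * mx + 1) - mx)

    eys, exs = evaluated.axis_coords()
    interp = RegularGridInterpolator(
        (eys, exs), evaluated.values, method="linear",
        bounds_error=False, fill_value=np.nan,
    )
    gy, gx = np.meshgrid(ys_f, xs_f, indexing="ij")
    fine = interp(np.stack([gy, gx], axis=-1))
    return fine, (step_y, step_x), (ky, kx), (my, mx), radius


def _evaluation_mask(reference: DosePlane, norm: float,
                     criteria: GammaCriteria) -> np.ndarray:
    thr = criteria.threshold * norm
    return np.isfinite(reference.values) & (reference.values >= thr)


def _result(gmap: np.ndarray, criteria: GammaCriteria) -> GammaResult:
    finite = np.isfinite(gmap)
    n_eval = int(finite.sum())
    if n_eval == 0:
        raise ValueError("threshold excludes everything: no evaluable points")
    pass_rate = 100.0 * float((gmap[finite] <= 1.0).sum()) / n_eval
    return GammaResult(gamma_map=gmap, pass_rate=pass_rate,
                       n_evaluated=n_eval, criteria=criteria)


def gamma_map(reference: DosePlane, evaluated: DosePlane,
              criteria: GammaCriteria | None = None,
              *, max_step_mm: float | None = None) -> GammaResult:
    """Vectorized gamma computation (see module docstring).

    The reference plane (TPS) drives the evaluation: every reference node
    at or above the threshold gets a γ; below-threshold nodes — and nodes
    with no evaluated data anywhere in the search radius — carry NaN and
    are excluded from the pass-rate denominator.  ``max_step_mm``
    overrides the default fine-lattice step (dta/10), mainly so
    convergence in the step can be checked.
    """
    criteria = criteria or GammaCriteria()
    if abs(reference.sdd - evaluated.sdd) > 1e-6:
        raise ValueError("planes must live at the same SDD; project first")
    norm = normalization_dose(reference, criteria)
    if norm <= 0:
        raise ValueError("normalization dose must be positive")
    dd_abs = norm * criteria.dose_tol / 100.0

    fine, (sy, sx), (ky, kx), (my, mx), radius = _fine_lattice(
        reference, evaluated, criteria, max_step_mm
    )
    mask = _evaluation_mask(reference, norm, criteria)
    if not mask.any():
        raise ValueError("threshold excludes everything: no evaluable points")
    ny, nx = reference.shape
    ref = reference.values

    # offsets on the fine lattice, nearest first
    uu, vv = np.meshgrid(np.arange(-my, my + 1), np.arange(-mx, mx + 1),
                         indexing="ij")
    dist2 = (uu * sy) ** 2 + (vv * sx) ** 2
    inside = dist2 <= radius**2 + 1e-12
    order = np.argsort(dist2[inside], kind="stable")
    offs = np.stack([uu[inside][order], vv[inside][order]], axis=1)
    d2_sorted = dist2[inside][order]

    dta2 = criteria.dta_tol**2
    gmin2 = np.full((ny, nx), np.inf)
    for (u, v), d2 in zip(offs, d2_sorted):
        cur_max = gmin2[mask].max()
        if d2 / dta2 >= cur_max:
            break
        sub = fine[my + u: my + u + (ny - 1) * ky + 1: ky,
                   mx + v: mx + v + (nx - 1) * kx + 1: kx]
        cand = d2 / dta2 + ((sub - ref) / dd_abs) ** 2
        np.fmin(gmin2, cand, out=gmin2)  # fmin ignores NaN candidates

    gmap = np.sqrt(gmin2)
    gmap[~mask] = np.nan
    gmap[np.isinf(gmap)] = np.nan  # no evaluated data within the radius
    return _result(gmap, criteria)


def gamma_oracle(reference: DosePlane, evaluated: DosePlane,
                 criteria: GammaCriteria | None = None,
                 *, max_step_mm: float | None = None) -> GammaResult:
    """Exhaustive-search gamma on small grids: for every evaluable
    reference node, query every fine-lattice position within the search
    radius and take the minimum.  Same contract as :func:`gamma_map`;
    refuses reference grids above 64x64 nodes."""
    criteria = criteria or GammaCriteria()
    ny, nx = reference.shape
    if ny > ORACLE_MAX_NODES or nx > ORACLE_MAX_NODES:
        raise ValueError(
            f"gamma_oracle is limited to {ORACLE_MAX_NODES} nodes per axis "
            f"(got {ny}x{nx}); use gamma_map"
        )
    if abs(reference.sdd - evaluated.sdd) > 1e-6:
        raise ValueError("planes must live at the same SDD; project first")
    norm = normalization_dose(reference, criteria)
    dd_abs = norm * criteria.dose_tol / 100.0
    radius = criteria.search_radius_factor * criteria.dta_tol

    target = max_step_mm if max_step_mm is not None else criteria.dta_tol / 10.0
    ky = max(1, math.ceil(reference.spacing[0] / target))
    kx = max(1, math.ceil(reference.spacing[1] / target))
    sy, sx = reference.spacing[0] / ky, reference.spacing[1] / kx
    my, mx = math.ceil(radius / sy), math.ceil(radius / sx)
    dy = sy * np.arange(-my, my + 1)
    dx = sx * np.arange(-mx, mx + 1)

    eys, exs = evaluated.axis_coords()
    interp = RegularGridInterpolator(
        (eys, exs), evaluated.values, method="linear",
        bounds_error=False, fill_value=np.nan,
    )
    gdy, gdx = np.meshgrid(dy, dx, indexing="ij")
    d2 = gdy**2 + gdx**2
    in_radius = d2 <= radius**2 + 1e-12

    mask = _evaluation_mask(reference, norm, criteria)
    rys, rxs = reference.axis_coords()
    gmap = np.full((ny, nx), np.nan)
    for i in range(ny):
        for j in range(nx):
            if not mask[i, j]:
                continue
            pts = np.stack([rys[i] + gdy, rxs[j] + gdx], axis=-1)
            ev = interp(pts)
            g2 = np.where(
                in_radius & np.isfinite(ev),
                d2 / criteria.dta_tol**2
                + ((ev - reference.values[i, j]) / dd_abs) ** 2,
                np.inf,
            )
            best = g2.min()
            if np.isfinite(best):
                gmap[i, j] = math.sqrt(best)
    return _result(gmap, criteria)
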