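"""Geometric processing: divergence projection, smoothing, resampling,
and plane-to-plane registration.

The film is irradiated on the accessory-holder tray at SDD 56.8 cm while
the TPS computes its plane at the isocenter (100 cm).  Because the beam
diverges from a near-point source, the tray-plane dose pattern is a
demagnified copy of the isocenter pattern: projecting it forward is a pure
similarity scaling about the central axis by the SDD ratio (100/56.8 ≈
1.76), with point doses carried unchanged — the methodology's validated
assumption.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .model import DosePlane, RegistrationTransform

__all__ = [
    "project_to_isocenter",
    "gaussian_smooth",
    "resample_linear",
    "coregister",
    "apply_transform",
]

#: refuse resampling that would produce more nodes than this per axis
MAX_GRID_NODES = 4096


def project_to_isocenter(plane: DosePlane, target_sdd: float = 100.0) -> DosePlane:
    """Scale a dose plane from its SDD to ``target_sdd`` about the central
    axis.  Spacing and origin are multiplied by the SDD ratio; dose values
    are carried unchanged; the grid itself is untouched."""
    if target_sdd <= 0:
        raise ValueError("target_sdd must be positive")
    f = target_sdd / plane.sdd
    return DosePlane(
        plane.values.copy(),
        (plane.spacing[0] * f, plane.spacing[1] * f),
        (plane.origin[0] * f, plane.origin[1] * f),
        sdd=target_sdd,
        label=plane.label,
    )


def gaussian_smooth(plane: DosePlane, sigma_mm: float) -> DosePlane:
    """Separable Gaussian denoising with reflective boundaries.

    ``sigma_mm`` is in physical units and converted per axis to grid
    steps; 0 returns the plane unchanged (copy).  The kernel has unit sum,
    so constant planes are exactly preserved.
    """
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be non-negative")
    if sigma_mm == 0:
        return plane.copy_with(values=plane.values.copy())
    sigmas = (sigma_mm / plane.spacing[0], sigma_mm / plane.spacing[1])
    smoothed = ndimage.gaussian_filter(plane.values, sigma=sigmas, mode="reflect")
    return plane.copy_with(values=smoothed)


def resample_linear(plane: DosePlane, new_spacing) -> DosePlane:
    """Bilinearly resample onto a grid with the same physical extent.

    The new grid starts at the plane's origin and steps by ``new_spacing``
    up to the last node that fits inside the original extent (node-centred,
    inclusive).  Going from 2 mm to 0.5 mm therefore maps N nodes per axis
    to 4(N−1)+1, quadrupling the sampling density.  Nodes that coincide
    with original nodes keep their values exactly (bilinear identity).
    """
    sp = new_spacing if np.iterable(new_spacing) else (new_spacing, new_spacing)
    sp = (float(sp[0]), float(sp[1]))
    if sp[0] <= 0 or sp[1] <= 0:
        raise ValueError("new_spacing must be positive")
    ymin, ymax, xmin, xmax = plane.extent()
    eps = 1e-9
    n_y = int(np.floor((ymax - ymin) / sp[0] + eps)) + 1
    n_x = int(np.floor((xmax - xmin) / sp[1] + eps)) + 1
    if n_y > MAX_GRID_NODES or n_x > MAX_GRID_NODES:
        raise ValueError(
            f"resampling to {sp} mm would create a {n_y}x{n_x} grid "
            f"(cap {MAX_GRID_NODES} per axis)"
        )
    new_ys = ymin + sp[0] * np.arange(n_y)
    new_xs = xmin + sp[1] * np.arange(n_x)
    ys, xs = plane.axis_coords()
    interp = RegularGridInterpolator(
        (ys, xs), plane.values, method="linear", bounds_error=False, fill_value=np.nan
    )
    gy, gx = np.meshgrid(np.clip(new_ys, ymin, ymax), np.clip(new_xs, xmin, xmax),
                         indexing="ij")
    vals = interp(np.stack([gy, gx], axis=-1))
    return DosePlane(vals, sp, (float(new_ys[0]), float(new_xs[0])),
                     sdd=plane.sdd, label=plane.label)


# --------------------------------------------------------------------------
# Registration
# --------------------------------------------------------------------------

def _central_profile(plane: DosePlane, axis: str, coords: np.ndarray) -> np.ndarray:
    """Sample the plane along the central horizontal (axis='x') or
    vertical (axis='y') line at the given physical coordinates; outside
    samples are NaN."""
    ys, xs = plane.axis_coords()
    interp = RegularGridInterpolator(
        (ys, xs), plane.values, method="linear", bounds_error=False, fill_value=np.nan
    )
    if axis == "x":
        pts = np.stack([np.zeros_like(coords), coords], axis=-1)
    else:
        pts = np.stack([coords, np.zeros_like(coords)], axis=-1)
    return interp(pts)


def _profile_shift(ref: np.ndarray, mov_sampler, coords: np.ndarray,
                   search_mm: float, step: float) -> tuple[float, float]:
    """Per-axis shift of the moving profile that maximizes normalized
    cross-correlation with the reference profile; sub-step precision via
    parabolic interpolation of the correlation peak.  Returns (shift,
    peak_correlation)."""
    shifts = np.arange(-search_mm, search_mm + step / 2, step)
    scores = np.full(shifts.shape, -np.inf)
    for k, s in enumerate(shifts):
        mov = mov_sampler(coords - s)
        ok = np.isfinite(ref) & np.isfinite(mov)
        if ok.sum() < 8:
            continue
        r, m = ref[ok], mov[ok]
        r = r - r.mean()
        m = m - m.mean()
        denom = np.sqrt((r * r).sum() * (m * m).sum())
        if denom <= 0:
            continue
        scores[k] = float((r * m).sum() / denom)
    k = int(np.argmax(scores))
    if not np.isfinite(scores[k]):
        raise ValueError("featureless profiles: cross-correlation undefined")
    if k == 0 or k == len(shifts) - 1:
        raise ValueError(
            "correlation peak at the search-window boundary: insufficient "
            "overlap or window too small"
        )
    # parabolic refinement on the three points around the peak
    y0, y1, y2 = scores[k - 1], scores[k], scores[k + 1]
    denom = y0 - 2 * y1 + y2
    frac = 0.0 if abs(denom) < 1e-15 else 0.5 * (y0 - y2) / denom
    frac = float(np.clip(frac, -1.0, 1.0))
    return float(shifts[k] + frac * step), float(scores[k])


def coregister(
    reference: DosePlane,
    moving: DosePlane,
    *,
    search_mm: float = 10.0,
    step_mm: float | None = None,
    manual_shift: tuple[float, float] | None = None,
) -> RegistrationTransform:
    """Find the translation aligning ``moving`` onto ``reference``.

    If ``manual_shift`` (dy, dx) is given it is returned verbatim — the
    manual mode, where the operator aligns the two distributions by eye.
    Otherwise the central horizontal and vertical dose profiles of both
    planes are extracted and, per axis, the shift maximizing their
    normalized cross-correlation is found (sub-grid precision via
    parabolic peak interpolation).  Scale is fixed at 1 (the divergence
    projection is handled separately) and rotation at 0 (the film's axes
    are assumed aligned with the collimator axes).

    Near-featureless planes (correlation contrast below 1 % across the
    search window) return a zero shift flagged ``low_confidence``.
    """
    if manual_shift is not None:
        return RegistrationTransform(scale=1.0, shift=tuple(manual_shift))
    if abs(reference.sdd - moving.sdd) > 1e-6:
        raise ValueError(
            f"planes live at different SDDs ({reference.sdd} vs {moving.sdd} cm); "
            "project first"
        )
    if step_mm is None:
        step_mm = min(min(reference.spacing), min(moving.spacing)) / 2.0

    shifts = []
    low_conf = False
    for axis in ("y", "x"):
        ys, xs = reference.axis_coords()
        coords = ys if axis == "y" else xs
        ref_prof = _central_profile(reference, axis, coords)
        # degenerate-input guard: a flat reference profile carries no signal
        finite = ref_prof[np.isfinite(ref_prof)]
        if finite.size == 0 or np.ptp(finite) < 1e-6 * max(1.0, abs(finite).max()):
            shifts.append(0.0)
            low_conf = True
            continue
        sampler = lambda c, a=axis: _central_profile(moving, a, c)
        s, _ = _profile_shift(ref_prof, sampler, coords, search_mm, step_mm)
        shifts.append(s)
    # moving point p matches reference point p + shift ⇒ transform shift
    return RegistrationTransform(scale=1.0, shift=(shifts[0], shifts[1]),
                                 low_confidence=low_conf)


def apply_transform(plane: DosePlane, t: RegistrationTransform) -> DosePlane:
    """Resample ``plane`` under the transform, on its own grid.

    Each output node at reference position p takes the bilinearly
    interpolated value of the input at ``t.invert(p)``; positions mapping
    outside the input extent become NaN ("no film there") and are excluded
    downstream.
    """
    ys, xs = plane.axis_coords()
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    pts = t.invert(np.stack([gy, gx], axis=-1))
    interp = RegularGridInterpolator(
        (ys, xs), plane.values, method="linear", bounds_error=False, fill_value=np.nan
    )
    vals = interp(pts)
    return plane.copy_with(values=vals)
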