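"""Pixel-value → dose calibration for film irradiated on the tray.

The calibration ties the film response measured on the accessory-holder
tray (SDD 56.8 cm) directly to TPS doses computed at the isocenter plane
(SDD 100 cm) for the same monitor units.  Because calibration films and QA
films share the tray geometry, the inverse-square factor and the tray
transmission cancel identically: applying the curve to a QA scan yields
dose already on the TPS/100 cm scale.

Three monotone model forms are available:

``rational``
    dose = a + b/(pv − c), the standard radiochromic dose–response shape;
    extrapolates sanely and needs only three parameters.
``pchip``
    shape-preserving monotone cubic through the points; assumption-free,
    reproduces every calibration point exactly.
``netod_poly``
    quadratic in net optical density OD = log10(pv_unexposed / pv);
    requires the unexposed-film pixel value.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares

from .model import CalibrationCurve, CalibrationPoint, DosePlane, FilmScan

__all__ = [
    "build_calibration",
    "apply_calibration",
    "read_calibration_csv",
    "write_calibration_csv",
    "save_curve",
    "load_curve",
]

MODEL_KINDS = ("rational", "pchip", "netod_poly")

#: fraction of pixels allowed to fall outside the calibration domain
#: before apply_calibration refuses the scan (those inside the margin are
#: clamped to the domain edge and counted).
OUT_OF_DOMAIN_TOLERANCE = 0.01


def _check_monotone(points: Sequence[CalibrationPoint]) -> int:
    """Validate strict monotonicity of pixel value vs dose; return the
    sign of d(pixel)/d(dose) (+1 or −1)."""
    pts = sorted(points, key=lambda p: p.dose)
    pvs = [p.pixel_value for p in pts]
    diffs = np.diff(pvs)
    if np.all(diffs > 0):
        return 1
    if np.all(diffs < 0):
        return -1
    for i, d in enumerate(diffs):
        if d == 0 or np.sign(d) != np.sign(diffs[0]):
            raise ValueError(
                "calibration points are not monotone: doses "
                f"{pts[i].dose:g} and {pts[i+1].dose:g} cGy map to pixel values "
                f"{pts[i].pixel_value:g} and {pts[i+1].pixel_value:g}"
            )
    raise ValueError("calibration points are not monotone")


def build_calibration(
    points: Iterable[CalibrationPoint],
    model_kind: str = "rational",
    *,
    unexposed_pixel_value: float | None = None,
) -> CalibrationCurve:
    """Fit a monotone pixel-value → dose curve through calibration points.

    Requires at least three points whose pixel values are strictly
    monotone in dose (either polarity: transmission digitizers darken with
    dose, so higher dose usually means a lower pixel value, but the
    opposite convention is accepted).  If ``unexposed_pixel_value`` is
    given it is added as a zero-dose anchor (dose 1e-6 cGy to keep the
    models defined on positive doses).

    Returns a :class:`CalibrationCurve` whose residuals record the fit
    quality at each input point; a fit that is non-monotone over the data
    range is refused.
    """
    pts = tuple(points)
    if len(pts) < 3:
        raise ValueError(f"need at least 3 calibration points, got {len(pts)}")
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
    _check_monotone(pts)

    fit_pts = list(pts)
    if unexposed_pixel_value is not None:
        fit_pts.append(
            CalibrationPoint(mu=1e-6, pixel_value=unexposed_pixel_value, dose=1e-6)
        )
        _check_monotone(fit_pts)

    pv = np.array([p.pixel_value for p in fit_pts], dtype=float)
    dose = np.array([p.dose for p in fit_pts], dtype=float)
    order = np.argsort(pv)
    pv_s, dose_s = pv[order], dose[order]
    domain = (float(pv_s[0]), float(pv_s[-1]))

    if model_kind == "rational":
        model, params = _fit_rational(pv_s, dose_s)
    elif model_kind == "pchip":
        interp = PchipInterpolator(pv_s, dose_s, extrapolate=True)
        model, params = (lambda x: interp(x)), {"knots_pv": pv_s.tolist(),
                                                "knots_dose": dose_s.tolist()}
    else:  # netod_poly
        if unexposed_pixel_value is None:
            raise ValueError("netod_poly requires unexposed_pixel_value")
        model, params = _fit_netod_poly(pv, dose, unexposed_pixel_value)

    grid = np.linspace(domain[0], domain[1], 512)
    dgrid = np.diff(model(grid))
    if not (np.all(dgrid > 0) or np.all(dgrid < 0)):
        raise ValueError(
            f"fitted {model_kind} model is not strictly monotone over "
            f"pixel values [{domain[0]:g}, {domain[1]:g}]; try the 'pchip' "
            "interpolant instead"
        )

    residuals = np.asarray(model(np.array([p.pixel_value for p in pts]))) - np.array(
        [p.dose for p in pts]
    )
    return CalibrationCurve(
        points=pts,
        model=model,
        domain=domain,
        model_kind=model_kind,
        params=params,
        residuals=residuals,
        unexposed_pixel_value=unexposed_pixel_value,
    )


def _fit_rational(pv, dose):
    """Least-squares fit of dose = a + b/(pv − c) with the pole c kept
    outside the data range."""
    lo, hi = pv.min(), pv.max()
    span = hi - lo

    def make(a, b, c):
        return lambda x: a + b / (np.asarray(x, dtype=float) - c)

    def resid(theta):
        a, b, c = theta
        return make(a, b, c)(pv) - dose

    best = None
    # polarity of the pole is unknown a priori: try above and below range
    for c0 in (hi + 0.5 * span + 1.0, lo - 0.5 * span - 1.0):
        b0 = (dose[-1] - dose[0]) * (pv[-1] - c0) * (pv[0] - c0) / (pv[0] - pv[-1])
        a0 = dose[0] - b0 / (pv[0] - c0)
        if c0 > hi:
            bounds = ([-np.inf, -np.inf, hi + 1e-6], [np.inf, np.inf, np.inf])
        else:
            bounds = ([-np.inf, -np.inf, -np.inf], [np.inf, np.inf, lo - 1e-6])
        try:
            sol = least_squares(resid, [a0, b0, c0], bounds=bounds, xtol=1e-14,
                                ftol=1e-14, gtol=1e-14)
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise ValueError(
            "singular rational fit; try the 'pchip' interpolant instead"
        )
    a, b, c = (float(v) for v in best.x)
    return make(a, b, c), {"a": a, "b": b, "c": c}


def _fit_netod_poly(pv, dose, pv0, degree: int = 2):
    if np.any(pv <= 0):
        raise ValueError("netod_poly requires positive pixel values")
    od = np.log10(pv0 / pv)
    coeffs = np.polyfit(od, dose, deg=min(degree, len(pv) - 1))

    def model(x):
        x = np.asarray(x, dtype=float)
        return np.polyval(coeffs, np.log10(pv0 / np.maximum(x, 1e-9)))

    return model, {"pv_unexposed": float(pv0), "coeffs": coeffs.tolist()}


def apply_calibration(
    scan: FilmScan,
    curve: CalibrationCurve,
    *,
    center_origin: bool = True,
    log: list | None = None,
) -> DosePlane:
    """Convert a film scan to an absolute dose plane, element-wise.

    The result inherits its pixel spacing from the scan dpi and its SDD
    from the scan (56.8 cm for tray irradiations); doses are on the
    TPS/100 cm scale by construction of the calibration.

    Out-of-domain policy: the two domain edges are not equivalent.  The
    zero-dose edge (unexposed film) is routinely crossed by scanner noise
    on blank film — such pixels mean "no dose" and are clamped silently.
    The high-dose edge means saturation or gross mis-exposure: pixels
    beyond it are clamped only if they amount to no more than
    ``OUT_OF_DOMAIN_TOLERANCE`` of the scan, otherwise the scan is
    refused.  Negative doses produced by noise at the zero-dose end are
    clipped to 0.
    """
    lo, hi = curve.domain
    px = scan.pixels.astype(float)
    # which edge carries the high dose depends on the digitizer polarity
    hot_edge_is_low = not curve.increasing
    hot_outside = (px < lo) if hot_edge_is_low else (px > hi)
    n_out = int(hot_outside.sum())
    frac = n_out / px.size
    if frac > OUT_OF_DOMAIN_TOLERANCE:
        raise ValueError(
            f"{frac:.1%} of pixels fall beyond the high-dose edge of the "
            f"calibration domain [{lo:g}, {hi:g}] "
            f"(tolerance {OUT_OF_DOMAIN_TOLERANCE:.0%}): saturated film?"
        )
    px = np.clip(px, lo, hi)
    dose = np.asarray(curve(px), dtype=float)
    n_neg = int((dose < 0).sum())
    dose = np.maximum(dose, 0.0)

    spacing = scan.pixel_spacing_mm
    if center_origin:
        plane = DosePlane.centered(dose, spacing, sdd=scan.sdd, label=scan.label)
    else:
        plane = DosePlane(dose, spacing, (0.0, 0.0), sdd=scan.sdd, label=scan.label)
    if log is not None:
        log.append(
            {
                "op": "apply_calibration",
                "model_kind": curve.model_kind,
                "domain": list(curve.domain),
                "clamped_pixels": n_out,
                "clipped_negative": n_neg,
                "spacing_mm": spacing,
                "sdd_cm": scan.sdd,
            }
        )
    return plane


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

def read_calibration_csv(path) -> list[CalibrationPoint]:
    """Read a calibration table: columns mu, pixel_value, dose_cGy."""
    df = pd.read_csv(path)
    required = {"mu", "pixel_value", "dose_cGy"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: calibration CSV needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    return [
        CalibrationPoint(mu=float(r.mu), pixel_value=float(r.pixel_value),
                         dose=float(r.dose_cGy))
        for r in df.itertuples()
    ]


def write_calibration_csv(path, points: Iterable[CalibrationPoint]) -> None:
    pd.DataFrame(
        [{"mu": p.mu, "pixel_value": p.pixel_value, "dose_cGy": p.dose}
         for p in points]
    ).to_csv(path, index=False)


def save_curve(path, curve: CalibrationCurve) -> None:
    """Serialize a fitted curve (kind, parameters, domain, residuals)."""
    payload = {
        "format": "filmqa-calibration",
        "version": 1,
        "model_kind": curve.model_kind,
        "params": curve.params,
        "domain": list(curve.domain),
        "unexposed_pixel_value": curve.unexposed_pixel_value,
        "points": [
            {"mu": p.mu, "pixel_value": p.pixel_value, "dose_cGy": p.dose}
            for p in curve.points
        ],
        "residuals_cGy": None if curve.residuals is None else curve.residuals.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_curve(path) -> CalibrationCurve:
    """Rebuild a curve from its JSON serialization (refits from the stored
    points, which is exact for all supported model kinds)."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "filmqa-calibration":
        raise ValueError(f"{path}: not a filmqa calibration file")
    points = [
        CalibrationPoint(mu=p["mu"], pixel_value=p["pixel_value"], dose=p["dose_cGy"])
        for p in payload["points"]
    ]
    return build_calibration(
        points,
        model_kind=payload["model_kind"],
        unexposed_pixel_value=payload.get("unexposed_pixel_value"),
    )
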