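"""Shared domain types for transmission film QA.

Coordinate conventions
----------------------
All physical coordinates are in millimetres in the plane of the detector,
with the origin at the projection of the beam central axis.  ``x`` is the
crossplane (column) axis and ``y`` the inplane (row) axis.  A plane's grid
is stored row-major; grid element ``(i, j)`` sits at physical position
``(origin_y + i*spacing_y, origin_x + j*spacing_x)``.  Storing the origin
explicitly makes the source-to-detector (SDD) projection a pure scaling
about ``(0, 0)``.

Doses are in cGy throughout; distances along the beam axis (SDD) in cm.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "DosePlane",
    "FilmScan",
    "CalibrationPoint",
    "CalibrationCurve",
    "RegistrationTransform",
    "GammaCriteria",
    "GammaNormalization",
    "QAPolicy",
    "GammaResult",
    "Verdict",
    "QAResult",
]


def _as_pair(v) -> tuple[float, float]:
    """Broadcast a scalar to a (y, x) pair of floats."""
    if np.isscalar(v):
        return (float(v), float(v))
    a = tuple(float(x) for x in v)
    if len(a) != 2:
        raise ValueError(f"expected scalar or length-2 sequence, got {v!r}")
    return a  # type: ignore[return-value]


@dataclass
class DosePlane:
    """A 2D absolute-dose grid living at a stated source-to-detector distance.

    Parameters
    ----------
    values : ndarray, shape (ny, nx)
        Absorbed dose in cGy.  NaN marks points with no data (e.g. regions
        that fell outside the film after registration); they are excluded
        from downstream comparisons.
    spacing : float or (dy, dx)
        Grid step in mm per axis.
    origin : (y0, x0)
        Physical position (mm) of grid element (0, 0) relative to the beam
        central axis.
    sdd : float
        Source-to-detector distance in cm at which this plane lives.
    """

    values: np.ndarray
    spacing: tuple[float, float]
    origin: tuple[float, float]
    sdd: float
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("DosePlane values must be a 2D array")
        self.spacing = _as_pair(self.spacing)
        self.origin = _as_pair(self.origin)
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError("spacing must be positive on both axes")
        if self.sdd <= 0:
            raise ValueError("sdd must be positive")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < -1e-9:
            raise ValueError("doses must be non-negative")

    # -- geometry helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical node coordinates (ys, xs) in mm."""
        ny, nx = self.values.shape
        ys = self.origin[0] + self.spacing[0] * np.arange(ny)
        xs = self.origin[1] + self.spacing[1] * np.arange(nx)
        return ys, xs

    def extent(self) -> tuple[float, float, float, float]:
        """(ymin, ymax, xmin, xmax) of node positions, mm."""
        ys, xs = self.axis_coords()
        return ys[0], ys[-1], xs[0], xs[-1]

    @classmethod
    def centered(cls, values, spacing, sdd, label: str = "") -> "DosePlane":
        """Build a plane whose grid centre coincides with the central axis."""
        values = np.asarray(values, dtype=float)
        sp = _as_pair(spacing)
        ny, nx = values.shape
        origin = (-sp[0] * (ny - 1) / 2.0, -sp[1] * (nx - 1) / 2.0)
        return cls(values, sp, origin, sdd, label)

    def interpolator(self, *, nan_fill: bool = False) -> RegularGridInterpolator:
        ys, xs = self.axis_coords()
        vals = self.values
        if nan_fill:
            vals = np.where(np.isfinite(vals), vals, 0.0)
        return RegularGridInterpolator(
            (ys, xs), vals, method="linear", bounds_error=True
        )

    def value_at(self, point: Sequence[float]) -> float:
        """Bilinear dose lookup at a physical point (y, x) in mm.

        Exact grid nodes return the stored value; querying outside the
        plane's physical extent is an error, never an extrapolation.
        """
        y, x = float(point[0]), float(point[1])
        ymin, ymax, xmin, xmax = self.extent()
        eps = 1e-9
        if not (ymin - eps <= y <= ymax + eps and xmin - eps <= x <= xmax + eps):
            raise ValueError(
                f"point ({y:g}, {x:g}) mm outside plane extent "
                f"y[{ymin:g},{ymax:g}] x[{xmin:g},{xmax:g}]"
            )
        y = min(max(y, ymin), ymax)
        x = min(max(x, xmin), xmax)
        return float(self.interpolator()((y, x)))

    def values_at(self, points: np.ndarray) -> np.ndarray:
        """Vectorized bilinear lookup; points is (..., 2) as (y, x) mm."""
        return self.interpolator()(points)

    def copy_with(self, **kw) -> "DosePlane":
        return replace(self, **kw)


@dataclass
class FilmScan:
    """Raw scanned film: integer pixel values plus scanner metadata.

    The pixel grid is the un-calibrated measurement; dose conversion lives
    in :mod:`filmqa.calibration`.  ``roi`` is a rectangular crop in pixel
    indices ``(row0, row1, col0, col1)`` (half-open) already applied to
    ``pixels``; it is retained for provenance.
    """

    pixels: np.ndarray
    bit_depth: int = 12
    dpi: float = 75.0
    roi: tuple[int, int, int, int] | None = None
    sdd: float = 56.8
    label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("FilmScan pixels must be a 2D array")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValueError("FilmScan pixels must be integer-valued")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")
        if self.bit_depth <= 0:
            raise ValueError("bit_depth must be positive")
        lo, hi = int(self.pixels.min()), int(self.pixels.max())
        if lo < 0 or hi >= 2**self.bit_depth:
            raise ValueError(
                f"pixel values [{lo}, {hi}] exceed {self.bit_depth}-bit range"
            )
        if self.sdd <= 0:
            raise ValueError("sdd must be positive")

    @property
    def pixel_spacing_mm(self) -> float:
        """Pixel pitch implied by the scan resolution (25.4/dpi)."""
        return 25.4 / self.dpi


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration exposure: MU delivered on the tray, the ROI-mean
    pixel value it produced, and the TPS dose (cGy) computed for the same
    MU at the isocenter plane."""

    mu: float
    pixel_value: float
    dose: float

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if self.pixel_value < 0:
            raise ValueError("pixel_value must be non-negative")


@dataclass
class CalibrationCurve:
    """Monotone pixel-value → dose mapping tied to the tray geometry.

    ``model`` maps pixel value arrays to doses in cGy on the TPS/100 cm
    scale.  ``domain`` is the pixel-value interval covered by the fit;
    evaluation outside it is a policy decision made by
    :func:`filmqa.calibration.apply_calibration`, not by the curve.
    """

    points: tuple[CalibrationPoint, ...]
    model: Callable[[np.ndarray], np.ndarray]
    domain: tuple[float, float]
    model_kind: str
    params: dict = field(default_factory=dict)
    residuals: np.ndarray | None = None
    unexposed_pixel_value: float | None = None

    def __call__(self, pixel_values) -> np.ndarray:
        return np.asarray(self.model(np.asarray(pixel_values, dtype=float)))

    @property
    def increasing(self) -> bool:
        """True if dose increases with pixel value over the domain."""
        lo, hi = self.domain
        return bool(self(np.array([hi])) > self(np.array([lo])))


@dataclass
class RegistrationTransform:
    """Rigid in-plane mapping from the moving plane's frame to the
    reference frame: scale about the central axis, then rotate, then
    translate.  ``shift`` is (dy, dx) in mm."""

    scale: float = 1.0
    shift: tuple[float, float] = (0.0, 0.0)
    rotation_deg: float = 0.0
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        self.shift = _as_pair(self.shift)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (..., 2) moving-frame (y, x) points into the reference frame."""
        pts = np.asarray(points, dtype=float) * self.scale
        if self.rotation_deg:
            th = math.radians(self.rotation_deg)
            c, s = math.cos(th), math.sin(th)
            y, x = pts[..., 0].copy(), pts[..., 1].copy()
            pts = np.stack([c * y - s * x, s * y + c * x], axis=-1)
        return pts + np.asarray(self.shift)

    def invert(self, points: np.ndarray) -> np.ndarray:
        """Map reference-frame points back into the moving frame."""
        pts = np.asarray(points, dtype=float) - np.asarray(self.shift)
        if self.rotation_deg:
            th = math.radians(-self.rotation_deg)
            c, s = math.cos(th), math.sin(th)
            y, x = pts[..., 0].copy(), pts[..., 1].copy()
            pts = np.stack([c * y - s * x, s * y + c * x], axis=-1)
        return pts / self.scale

    def inverse(self) -> "RegistrationTransform":
        if self.rotation_deg:
            raise NotImplementedError("inverse with rotation not needed yet")
        return RegistrationTransform(
            scale=1.0 / self.scale,
            shift=(-self.shift[0] / self.scale, -self.shift[1] / self.scale),
        )


class GammaNormalization(str, enum.Enum):
    """How the dose-difference term is normalized."""

    GLOBAL_MAX = "global_max"
    POINT_DOSE = "point_dose"


@dataclass
class GammaCriteria:
    """Gamma-index acceptance criteria.

    dose_tol is the dose-difference criterion in % of the normalization
    dose; dta_tol the distance-to-agreement in mm; threshold the low-dose
    cutoff as a fraction of the normalization dose.  The spatial search is
    bounded at ``search_radius_factor * dta_tol`` — gamma contributions
    from farther away exceed the bound and can never change pass/fail.
    """

    dose_tol: float = 3.0
    dta_tol: float = 3.0
    threshold: float = 0.10
    normalization: GammaNormalization = GammaNormalization.GLOBAL_MAX
    search_radius_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.dose_tol <= 0:
            raise ValueError("dose_tol must be positive")
        if self.dta_tol <= 0:
            raise ValueError("dta_tol must be positive")
        if not 0 <= self.threshold < 1:
            raise ValueError("threshold must be in [0, 1)")
        if self.search_radius_factor <= 0:
            raise ValueError("search_radius_factor must be positive")
        self.normalization = GammaNormalization(self.normalization)


@dataclass
class QAPolicy:
    """Verdict thresholds for the transmission QA.

    A delivery passes only when |point-dose %diff| is strictly below
    ``max_point_diff`` AND the gamma pass rate strictly exceeds
    ``min_pass_rate`` — strict inequalities, so a result sitting exactly
    on a bound fails.  ``tray_transmission`` records the film-support
    attenuation (0.942 for the 6 MV beam on the acrylic tray); it cancels
    between calibration and measurement but matters for patient dose.
    """

    gamma: GammaCriteria = field(default_factory=GammaCriteria)
    max_point_diff: float = 5.0
    min_pass_rate: float = 95.0
    tray_transmission: float = 0.942

    def __post_init__(self) -> None:
        if not 0 < self.min_pass_rate <= 100:
            raise ValueError("min_pass_rate must be in (0, 100]")
        if self.max_point_diff <= 0:
            raise ValueError("max_point_diff must be positive")
        if not 0 < self.tray_transmission <= 1:
            raise ValueError("tray_transmission must be in (0, 1]")


@dataclass
class GammaResult:
    """Gamma map plus its pass rate.  Below-threshold points carry NaN
    ("not evaluated"), never 0, so the pass-rate denominator is always
    ``n_evaluated``."""

    gamma_map: np.ndarray
    pass_rate: float
    n_evaluated: int
    criteria: GammaCriteria

    def __post_init__(self) -> None:
        finite = self.gamma_map[np.isfinite(self.gamma_map)]
        if finite.size and finite.min() < 0:
            raise ValueError("gamma values must be non-negative")
        if not 0 <= self.pass_rate <= 100:
            raise ValueError("pass_rate must be in [0, 100]")


class Verdict(str, enum.Enum):
    PASS = "Pass"
    FAIL = "Fail"


@dataclass
class QAResult:
    """Full outcome of one transmission QA: the two normalization-point
    doses, their percent difference, the gamma result, the verdict, and a
    step-by-step provenance log sufficient to re-run the analysis."""

    dose_film: float
    dose_tps: float
    percent_diff: float
    gamma: GammaResult
    verdict: Verdict
    steps: list = field(default_factory=list)

    def log(self, op: str, **params) -> None:
        self.steps.append({"op": op, **params})
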