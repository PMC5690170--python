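"""Synthetic study generator: fabricate matched TPS dose planes and film
scans so every pipeline stage — and the end-to-end verdict — can be
exercised with no physical film.

The generator emulates the transmission-QA study conditions:

* TPS planes are computed at the isocenter (SDD 100 cm) on a 2 mm grid;
  fields are built from error-function-edged rectangles so the 50 %
  isodose falls exactly on the nominal field edge.
* Film scans live on the accessory-holder tray at SDD 56.8 cm, sampled at
  75 dpi and quantized to 12 bits.  The physical dose on the film is the
  isocenter dose boosted by the inverse-square factor (100/56.8)² and
  attenuated by the tray transmission (0.942); both factors also enter
  the synthetic calibration exposures, so they cancel in the recovered
  dose exactly as they do in reality.
* The film dose–response is a rational saturating curve (steep at low
  dose, flattening toward saturation) with the polarity of a transmission
  digitizer: more dose, lower pixel value.
* Delivery errors mirror the controlled-error study: per IMRT plan, a
  faithful delivery, a repeat with fresh noise, a delivery with a small
  random misalignment and output jitter (real-gantry surrogate), a
  delivery with uniformly reduced monitor units (10–37 % low), and a
  delivery with one segment removed.  The first three should pass QA,
  the last two should fail.

All randomness flows through one explicitly passed ``numpy.random
.Generator``; identical seeds give bit-identical scans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .model import (
    CalibrationPoint,
    DosePlane,
    FilmScan,
    RegistrationTransform,
    Verdict,
)

__all__ = [
    "FilmResponse",
    "default_response",
    "make_square_field",
    "make_imrt_plane",
    "example_imrt_plans",
    "generate_calibration",
    "simulate_film_scan",
    "Scenario",
    "make_error_scenarios",
    "TRAY_SDD_CM",
    "ISO_SDD_CM",
    "TRAY_TRANSMISSION",
]

TRAY_SDD_CM = 56.8
ISO_SDD_CM = 100.0
TRAY_TRANSMISSION = 0.942
#: TPS dose per monitor unit at the normalization point (cGy/MU)
CGY_PER_MU = 1.0
#: default scan noise: ~1 % of the 12-bit dynamic range, in pixel values
DEFAULT_NOISE_SIGMA = 40.0


def geometric_gain(sdd_film: float = TRAY_SDD_CM, sdd_iso: float = ISO_SDD_CM,
                   tray_transmission: float = TRAY_TRANSMISSION) -> float:
    """Physical film dose per unit isocenter dose: inverse-square boost
    at the tray distance times the tray transmission."""
    return tray_transmission * (sdd_iso / sdd_film) ** 2


@dataclass(frozen=True)
class FilmResponse:
    """Ground-truth film dose–response, rational in both directions:

        pixel(D) = c + b / (D + d)        (D = physical dose on film, cGy)
        dose(pv) = b / (pv - c) - d

    With the default parameters the response spans pixel values ~3900
    (unexposed) down to ~300 at 2000 cGy, darkest where the dose is
    highest, and is steepest at low dose — the qualitative shape of
    radiochromic film read in transmission.
    """

    b: float = 2.25e6
    c: float = -600.0
    d: float = 500.0

    def pixel_of_dose(self, dose_cgy):
        dose_cgy = np.asarray(dose_cgy, dtype=float)
        return self.c + self.b / (dose_cgy + self.d)

    def dose_of_pixel(self, pv):
        pv = np.asarray(pv, dtype=float)
        return self.b / (pv - self.c) - self.d

    @property
    def max_dose(self) -> float:
        """Largest physical dose with a representable (>0) pixel value."""
        return self.b / (1.0 - self.c) - self.d


def default_response() -> FilmResponse:
    return FilmResponse()


# --------------------------------------------------------------------------
# Dose-plane construction
# --------------------------------------------------------------------------

def _edge_profile(coords: np.ndarray, lo: float, hi: float,
                  sigma_mm: float) -> np.ndarray:
    """Error-function field edge: 1 well inside (lo, hi), 0 well outside,
    exactly 0.5 at the edges.  sigma 0 gives an ideal step."""
    if sigma_mm < 0:
        raise ValueError("penumbra sigma must be non-negative")
    if sigma_mm == 0:
        prof = ((coords > lo) & (coords < hi)).astype(float)
        prof[np.isclose(coords, lo) | np.isclose(coords, hi)] = 0.5
        return prof
    s = sigma_mm * math.sqrt(2.0)
    return 0.5 * (erf((coords - lo) / s) - erf((coords - hi) / s))


def make_square_field(
    size_cm: float,
    dose_cgy: float,
    penumbra_sigma_mm: float = 3.0,
    *,
    spacing_mm: float = 2.0,
    margin_mm: float = 30.0,
    sdd: float = ISO_SDD_CM,
) -> DosePlane:
    """Square open field of side ``size_cm`` (defined at the 50 % isodose)
    and central dose ``dose_cgy``, with error-function penumbrae."""
    if size_cm <= 0 or dose_cgy <= 0:
        raise ValueError("size and dose must be positive")
    half = size_cm * 10.0 / 2.0
    half_extent = half + margin_mm
    n = int(round(2 * half_extent / spacing_mm)) + 1
    coords = spacing_mm * (np.arange(n) - (n - 1) / 2)
    if half > coords[-1]:
        raise ValueError("field larger than grid extent; increase margin")
    sx = _edge_profile(coords, -half, half, penumbra_sigma_mm)
    values = dose_cgy * np.outer(sx, sx)
    return DosePlane.centered(values, spacing_mm, sdd=sdd,
                              label=f"square {size_cm:g}cm")


def make_imrt_plane(
    segments,
    dose_scale: float = 1.0,
    *,
    penumbra_sigma_mm: float = 3.0,
    spacing_mm: float = 2.0,
    half_extent_mm: float = 70.0,
    sdd: float = ISO_SDD_CM,
    label: str = "imrt",
) -> DosePlane:
    """Weighted superposition of error-function-edged rectangular segments.

    ``segments`` is a list of ``((y0, y1, x0, x1), weight_cGy)`` with the
    rectangle in mm at the isocenter plane.  The plane is deterministic
    for a given segment list; one segment reduces to a square/rect field.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("empty segment list")
    n = int(round(2 * half_extent_mm / spacing_mm)) + 1
    coords = spacing_mm * (np.arange(n) - (n - 1) / 2)
    values = np.zeros((n, n))
    for (y0, y1, x0, x1), w in segments:
        if y1 <= y0 or x1 <= x0:
            raise ValueError(f"degenerate segment rectangle {(y0, y1, x0, x1)}")
        py = _edge_profile(coords, y0, y1, penumbra_sigma_mm)
        px = _edge_profile(coords, x0, x1, penumbra_sigma_mm)
        values += w * np.outer(py, px)
    return DosePlane.centered(values * dose_scale, spacing_mm, sdd=sdd, label=label)


#: five fixed modulated plans: a base aperture plus partial-coverage
#: segments, every segment heavy enough that removing it is a clinically
#: meaningful delivery error.
EXAMPLE_PLAN_SEGMENTS: tuple[tuple[tuple[tuple[float, float, float, float], float], ...], ...] = (
    (((-55, 55, -55, 55), 120.0), ((-50, 0, -50, 50), 50.0),
     ((0, 50, -50, 50), 45.0), ((-30, 30, -30, 30), 40.0)),
    (((-50, 50, -50, 50), 110.0), ((-50, 50, -50, -10), 45.0),
     ((-50, 50, 10, 50), 45.0), ((-20, 20, -20, 20), 50.0)),
    (((-60, 60, -60, 60), 130.0), ((-60, 0, -60, 60), 55.0),
     ((-35, 35, 0, 60), 50.0), ((-15, 15, -15, 15), 45.0)),
    (((-45, 45, -45, 45), 125.0), ((-45, 45, -45, 5), 40.0),
     ((-10, 45, -45, 45), 45.0), ((-25, 25, -25, 25), 45.0)),
    (((-50, 50, -50, 50), 115.0), ((-50, -5, -50, 50), 50.0),
     ((5, 50, -50, 50), 50.0), ((-30, 30, -10, 30), 55.0)),
)


def example_imrt_plans(**kw) -> list[DosePlane]:
    """The five bundled modulated example plans (deterministic)."""
    return [
        make_imrt_plane(segs, label=f"imrt plan {i + 1}", **kw)
        for i, segs in enumerate(EXAMPLE_PLAN_SEGMENTS)
    ]


# --------------------------------------------------------------------------
# Film simulation
# --------------------------------------------------------------------------

def generate_calibration(
    rng: np.random.Generator,
    response: FilmResponse | None = None,
    *,
    mu_levels=(50, 100, 200, 400, 600),
    cgy_per_mu: float = CGY_PER_MU,
    tray_transmission: float = TRAY_TRANSMISSION,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    patch_pixels: int = 400,
    bit_depth: int = 12,
) -> tuple[list[CalibrationPoint], float]:
    """Simulate the calibration exposures on the tray.

    For each MU level the film patch receives the physical dose
    ``gain · MU · cgy_per_mu`` (gain = inverse-square boost × tray
    transmission); its ROI-mean pixel value is the mean of
    ``patch_pixels`` noisy quantized pixels.  The associated calibration
    dose is the TPS dose at the isocenter plane for the same MU — the
    pairing that makes the geometry cancel downstream.

    Returns the calibration points and the unexposed-film pixel value.
    """
    response = response or default_response()
    gain = geometric_gain(tray_transmission=tray_transmission)
    vmax = 2**bit_depth - 1
    points = []
    for mu in mu_levels:
        physical = gain * mu * cgy_per_mu
        pv = response.pixel_of_dose(physical)
        noisy = np.clip(np.rint(pv + rng.normal(0, noise_sigma, patch_pixels)),
                        0, vmax)
        points.append(
            CalibrationPoint(mu=float(mu), pixel_value=float(noisy.mean()),
                             dose=float(mu * cgy_per_mu))
        )
    pv0 = response.pixel_of_dose(0.0)
    unexposed = float(
        np.clip(np.rint(pv0 + rng.normal(0, noise_sigma, patch_pixels)),
                0, vmax).mean()
    )
    return points, unexposed


def simulate_film_scan(
    plane_at_iso: DosePlane,
    response: FilmResponse | None = None,
    *,
    rng: np.random.Generator,
    dpi: float = 75.0,
    bit_depth: int = 12,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    misalignment: RegistrationTransform | None = None,
    tray_transmission: float = TRAY_TRANSMISSION,
    film_sdd: float = TRAY_SDD_CM,
) -> FilmScan:
    """Fabricate the film scan a tray irradiation of ``plane_at_iso``
    would produce.

    The film grid is the demagnified image of the isocenter plane (pixel
    pitch 25.4/dpi mm at the tray distance).  Each pixel samples the
    isocenter plane at its projected position (optionally displaced by
    ``misalignment``, in tray-plane mm), converts the physical film dose
    through the response curve, adds Gaussian scanner noise, and
    quantizes to ``bit_depth`` bits.  Positions projecting outside the
    plane receive zero dose.
    """
    response = response or default_response()
    if misalignment is None:
        misalignment = RegistrationTransform()
    f = plane_at_iso.sdd / film_sdd  # film coords × f = iso coords
    spacing = 25.4 / dpi
    ymin, ymax, xmin, xmax = plane_at_iso.extent()
    half_y = min(-ymin, ymax) / f
    half_x = min(-xmin, xmax) / f
    n_y = 2 * int(math.floor(half_y / spacing)) + 1
    n_x = 2 * int(math.floor(half_x / spacing)) + 1
    ys = spacing * (np.arange(n_y) - (n_y - 1) / 2)
    xs = spacing * (np.arange(n_x) - (n_x - 1) / 2)
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    pts = np.stack([gy, gx], axis=-1)
    # a misaligned film sees the pattern displaced: sample at the
    # inverse-transformed position, then project to the isocenter plane
    pts = misalignment.invert(pts) * f
    interp = plane_at_iso.interpolator(nan_fill=True)
    ys_i, xs_i = plane_at_iso.axis_coords()
    inside = (
        (pts[..., 0] >= ys_i[0]) & (pts[..., 0] <= ys_i[-1])
        & (pts[..., 1] >= xs_i[0]) & (pts[..., 1] <= xs_i[-1])
    )
    dose_iso = np.zeros(pts.shape[:2])
    dose_iso[inside] = interp(pts[inside])
    physical = geometric_gain(film_sdd, plane_at_iso.sdd, tray_transmission) * dose_iso
    if physical.max() >= response.max_dose:
        raise ValueError(
            f"dose {physical.max():.0f} cGy exceeds the invertible range "
            f"of the response curve ({response.max_dose:.0f} cGy)"
        )
    pv = response.pixel_of_dose(physical)
    vmax = 2**bit_depth - 1
    pixels = np.clip(np.rint(pv + rng.normal(0, noise_sigma, pv.shape)),
                     0, vmax).astype(np.uint16)
    return FilmScan(pixels=pixels, bit_depth=bit_depth, dpi=dpi,
                    sdd=film_sdd, label=plane_at_iso.label + " film")


# --------------------------------------------------------------------------
# Delivery-error scenarios
# --------------------------------------------------------------------------

VARIANTS = ("faithful", "repeat", "gantry", "lower_mu", "field_removed")


@dataclass
class Scenario:
    """One controlled QA irradiation: the TPS plane the plan expects, the
    plane actually delivered (possibly wrong), the film misalignment, and
    the verdict the QA should reach."""

    name: str
    plan_index: int
    variant: str
    tps_plane: DosePlane
    delivered_plane: DosePlane
    misalignment: RegistrationTransform
    expected_verdict: Verdict
    seed: int
    mu_scale: float = 1.0
    removed_segment: int | None = None
    details: dict = field(default_factory=dict)


def make_error_scenarios(
    rng: np.random.Generator,
    *,
    plans=None,
    mu_scale_range: tuple[float, float] = (0.63, 0.90),
    gantry_shift_mm: float = 2.0,
    output_jitter: float = 0.008,
) -> list[Scenario]:
    """Build the 5 plans × 5 variants controlled-error study.

    Per plan: (1) faithful delivery, (2) repeat faithful delivery with
    fresh noise, (3) faithful delivery with a small random film
    misalignment and ~1 % output jitter (surrogate for irradiating at the
    real gantry angles), (4) monitor units uniformly reduced by 10–37 %,
    (5) one segment removed.  Variants 1–3 are expected to pass, 4–5 to
    fail.
    """
    if plans is None:
        plan_segments = EXAMPLE_PLAN_SEGMENTS
    else:
        plan_segments = tuple(plans)
    scenarios = []
    for ip, segs in enumerate(plan_segments):
        tps = make_imrt_plane(segs, label=f"imrt plan {ip + 1}")
        for variant in VARIANTS:
            seed = int(rng.integers(0, 2**31 - 1))
            mis = RegistrationTransform()
            delivered = tps
            mu_scale = 1.0
            removed = None
            if variant == "gantry":
                shift = tuple(rng.uniform(-gantry_shift_mm, gantry_shift_mm, 2))
                mis = RegistrationTransform(shift=shift)
                mu_scale = float(rng.normal(1.0, output_jitter))
                delivered = make_imrt_plane(segs, dose_scale=mu_scale,
                                            label=tps.label)
            elif variant == "lower_mu":
                mu_scale = float(rng.uniform(*mu_scale_range))
                delivered = make_imrt_plane(segs, dose_scale=mu_scale,
                                            label=tps.label)
            elif variant == "field_removed":
                removed = int(rng.integers(0, len(segs)))
                kept = [s for k, s in enumerate(segs) if k != removed]
                delivered = make_imrt_plane(kept, label=tps.label)
            expected = (
                Verdict.PASS if variant in ("faithful", "repeat", "gantry")
                else Verdict.FAIL
            )
            scenarios.append(
                Scenario(
                    name=f"plan{ip + 1}-{variant}",
                    plan_index=ip,
                    variant=variant,
                    tps_plane=tps,
                    delivered_plane=delivered,
                    misalignment=mis,
                    expected_verdict=expected,
                    seed=seed,
                    mu_scale=mu_scale,
                    removed_segment=removed,
                )
            )
    return scenarios
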