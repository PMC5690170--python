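"""End-to-end transmission QA: from raw film scan and TPS plane to verdict.

The processing chain mirrors the clinical workflow:

1. apply the calibration to the scan → absolute dose plane on the tray
   (SDD 56.8 cm), already on the TPS/100 cm dose scale;
2. project the film plane to the isocenter plane (pure similarity scaling
   by the SDD ratio, doses unchanged);
3. coregister film to TPS on the two central perpendicular profiles and
   resample the film under the recovered translation;
4. Gaussian-smooth the film plane to suppress scanner noise;
5. resample the TPS plane from its native grid (typically 2 mm) to a fine
   comparison grid (0.5 mm);
6. extract the normalization-point doses, compute their percent
   difference, run the gamma analysis, and apply the two-criterion
   Pass/Fail rule.

For the gamma step the film plane is rescaled so its dose at the
normalization point matches the TPS dose there (configurable).  This is
the standard relative-film convention: gamma then judges the *shape* of
the delivered distribution, while the absolute-dose criterion is carried
entirely by the point-dose difference.  A delivery with uniformly short
monitor units therefore keeps a high gamma pass rate but fails loudly on
the point dose — the signature that separates output errors from shape
errors.
"""

from __future__ import annotations

from dataclasses import dataclass

from .calibration import apply_calibration
from .gamma import gamma_map
from .model import CalibrationCurve, DosePlane, FilmScan, QAPolicy, QAResult
from .policy import evaluate_qa, extract_point_dose
from .register import (
    apply_transform,
    coregister,
    gaussian_smooth,
    project_to_isocenter,
    resample_linear,
)

__all__ = ["PipelineConfig", "run_qa"]


@dataclass
class PipelineConfig:
    """Tunable parameters of the comparison chain.

    smoothing_sigma_mm : Gaussian denoising width (mm); 0 disables.
    target_spacing_mm  : comparison-grid spacing the TPS plane is
                         resampled to (0.5 mm quadruples a 2 mm grid).
    search_mm          : half-width of the registration search window.
    manual_shift       : operator-supplied (dy, dx) mm; skips the
                         automatic profile registration when given.
    norm_point         : normalization point (y, x) mm at the isocenter.
    window_mm          : averaging window for point-dose extraction.
    renormalize_for_gamma : rescale the film plane to the TPS dose at the
                         normalization point before gamma (relative-film
                         convention, see module docstring).
    """

    smoothing_sigma_mm: float = 1.0
    target_spacing_mm: float = 0.5
    search_mm: float = 10.0
    manual_shift: tuple[float, float] | None = None
    norm_point: tuple[float, float] = (0.0, 0.0)
    window_mm: float = 2.0
    renormalize_for_gamma: bool = True


def run_qa(
    scan: FilmScan,
    curve: CalibrationCurve,
    tps_plane: DosePlane,
    policy: QAPolicy | None = None,
    config: PipelineConfig | None = None,
) -> QAResult:
    """Run the full transmission QA and return the verdict with full
    step-by-step provenance in ``QAResult.steps``."""
    policy = policy or QAPolicy()
    config = config or PipelineConfig()
    steps: list[dict] = []

    film_tray = apply_calibration(scan, curve, log=steps)

    film_iso = project_to_isocenter(film_tray, target_sdd=tps_plane.sdd)
    steps.append({
        "op": "project_to_isocenter",
        "from_sdd_cm": film_tray.sdd,
        "to_sdd_cm": tps_plane.sdd,
        "scale": tps_plane.sdd / film_tray.sdd,
    })

    t = coregister(
        tps_plane, film_iso,
        search_mm=config.search_mm,
        manual_shift=config.manual_shift,
    )
    film_reg = apply_transform(film_iso, t)
    steps.append({
        "op": "coregister",
        "mode": "manual" if config.manual_shift is not None else "auto-profile",
        "shift_mm": [round(v, 4) for v in t.shift],
        "low_confidence": t.low_confidence,
    })

    film_s = gaussian_smooth(film_reg, config.smoothing_sigma_mm)
    steps.append({"op": "gaussian_smooth", "sigma_mm": config.smoothing_sigma_mm})

    tps_fine = resample_linear(tps_plane, config.target_spacing_mm)
    steps.append({
        "op": "resample_linear",
        "plane": "tps",
        "from_spacing_mm": list(tps_plane.spacing),
        "to_spacing_mm": config.target_spacing_mm,
    })

    dose_film = extract_point_dose(film_s, config.norm_point, config.window_mm)
    dose_tps = extract_point_dose(tps_fine, config.norm_point, config.window_mm)
    steps.append({
        "op": "extract_point_dose",
        "point_mm": list(config.norm_point),
        "window_mm": config.window_mm,
        "dose_film_cGy": round(dose_film, 3),
        "dose_tps_cGy": round(dose_tps, 3),
    })

    film_for_gamma = film_s
    renormalized = False
    if config.renormalize_for_gamma and dose_film > 0:
        factor = dose_tps / dose_film
        film_for_gamma = film_s.copy_with(values=film_s.values * factor)
        renormalized = True
        steps.append({"op": "renormalize_for_gamma",
                      "factor": round(factor, 5)})
    if not renormalized:
        steps.append({"op": "renormalize_for_gamma", "factor": None,
                      "note": "disabled or film point dose non-positive"})

    gr = gamma_map(tps_fine, film_for_gamma, policy.gamma)
    steps.append({
        "op": "gamma_map",
        "dose_tol_pct": policy.gamma.dose_tol,
        "dta_mm": policy.gamma.dta_tol,
        "threshold": policy.gamma.threshold,
        "normalization": policy.gamma.normalization.value,
        "pass_rate_pct": round(gr.pass_rate, 3),
        "n_evaluated": gr.n_evaluated,
    })

    return evaluate_qa(dose_film, dose_tps, gr, policy, steps=steps)
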