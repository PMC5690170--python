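"""Point-dose extraction, percent difference, and the Pass/Fail rule.

A transmission QA is approved only when both criteria hold simultaneously:
the absolute point-dose difference at the normalization point is strictly
below 5 % and the gamma pass rate strictly exceeds 95 %.  The inequalities
are strict, so a delivery sitting exactly on a bound fails; verdicts are
computed on full-precision values, with one-decimal rounding applied only
for display.
"""

from __future__ import annotations

import numpy as np

from .model import DosePlane, GammaResult, QAPolicy, QAResult, Verdict

__all__ = ["percent_point_diff", "extract_point_dose", "evaluate_qa"]


def percent_point_diff(dose_film: float, dose_tps: float) -> float:
    """Percent difference of film vs TPS dose at the normalization point:
    100·(film − TPS)/TPS."""
    if dose_tps <= 0:
        raise ValueError("TPS dose must be positive")
    return 100.0 * (dose_film - dose_tps) / dose_tps


def extract_point_dose(
    plane: DosePlane, point=(0.0, 0.0), window_mm: float = 2.0
) -> float:
    """Dose at a point, averaged over a small square window.

    The window (side ``window_mm``, centred on the point) averages the
    grid nodes it covers, suppressing single-pixel noise at the
    normalization point; ``window_mm = 0`` degrades to a bilinear point
    lookup.
    """
    if window_mm < 0:
        raise ValueError("window_mm must be non-negative")
    if window_mm == 0:
        return plane.value_at(point)
    y, x = float(point[0]), float(point[1])
    half = window_mm / 2.0
    ymin, ymax, xmin, xmax = plane.extent()
    eps = 1e-9
    if y - half < ymin - eps or y + half > ymax + eps \
            or x - half < xmin - eps or x + half > xmax + eps:
        raise ValueError(
            f"window ±{half:g} mm around ({y:g}, {x:g}) extends outside the plane"
        )
    ys, xs = plane.axis_coords()
    sel_y = np.abs(ys - y) <= half + eps
    sel_x = np.abs(xs - x) <= half + eps
    block = plane.values[np.ix_(sel_y, sel_x)]
    block = block[np.isfinite(block)]
    if block.size == 0:
        raise ValueError("no finite dose values inside the window")
    return float(block.mean())


def evaluate_qa(
    dose_film: float,
    dose_tps: float,
    gamma: GammaResult,
    policy: QAPolicy | None = None,
    steps: list | None = None,
) -> QAResult:
    """Apply the two-criterion acceptance rule and assemble the QAResult.

    Pass ⇔ |percent_diff| < policy.max_point_diff AND
            gamma.pass_rate > policy.min_pass_rate  (both strict).
    """
    policy = policy or QAPolicy()
    if not (np.isfinite(dose_film) and np.isfinite(dose_tps)):
        raise ValueError("point doses must be finite")
    diff = percent_point_diff(dose_film, dose_tps)
    verdict = (
        Verdict.PASS
        if abs(diff) < policy.max_point_diff and gamma.pass_rate > policy.min_pass_rate
        else Verdict.FAIL
    )
    result = QAResult(
        dose_film=float(dose_film),
        dose_tps=float(dose_tps),
        percent_diff=diff,
        gamma=gamma,
        verdict=verdict,
        steps=list(steps) if steps else [],
    )
    result.log(
        "evaluate_qa",
        max_point_diff=policy.max_point_diff,
        min_pass_rate=policy.min_pass_rate,
        percent_diff=round(diff, 3),
        gamma_pass_rate=round(gamma.pass_rate, 3),
        verdict=verdict.value,
    )
    return result
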