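"""Full transmission QA of one simulated IMRT delivery.

A modulated plan is 'delivered' onto a film at the tray (demagnified,
attenuated, noisy, quantized scan), then pushed through the complete
pipeline against the TPS plane: calibrate, project to the isocenter,
register, smooth, resample, gamma, verdict.
"""

import numpy as np

from filmqa import build_calibration, run_qa
from filmqa import synthetic as syn

rng = np.random.default_rng(7)
points, pv0 = syn.generate_calibration(rng)
curve = build_calibration(points, "rational", unexposed_pixel_value=pv0)

plan = syn.example_imrt_plans()[0]
scan = syn.simulate_film_scan(plan, rng=rng)
print(f"film scan: {scan.pixels.shape} px at {scan.dpi:g} dpi, "
      f"SDD {scan.sdd} cm")

result = run_qa(scan, curve, plan)
print(f"\npoint dose: film {result.dose_film:.1f} cGy, "
      f"TPS {result.dose_tps:.1f} cGy -> {result.percent_diff:+.1f}%")
print(f"gamma 3%/3mm (10% threshold): {result.gamma.pass_rate:.1f}% of "
      f"{result.gamma.n_evaluated} points pass")
print(f"verdict: {result.verdict.value}")
print("\nprocessing provenance:")
for step in result.steps:
    print("  -", step["op"],
          {k: v for k, v in step.items() if k != "op"})
# Pass requires BOTH |point diff| < 5% and gamma pass rate > 95%.
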