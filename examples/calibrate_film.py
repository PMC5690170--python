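"""Build a pixel-value -> dose calibration from tray-geometry exposures.

Five film patches are irradiated on the accessory-holder tray (SDD
56.8 cm) at 50/100/200/400/600 MU and paired with the TPS doses computed
at the isocenter plane (SDD 100 cm) for the same MU.  Fitting a monotone
rational curve through (pixel value, TPS dose) makes the inverse-square
boost and the tray transmission cancel: applying the curve to any later
tray film yields dose directly on the TPS scale.
"""

import numpy as np

from filmqa import build_calibration
from filmqa import synthetic as syn

rng = np.random.default_rng(42)
points, unexposed_pv = syn.generate_calibration(rng)

print("MU    pixel value   TPS dose (cGy)")
for p in points:
    print(f"{p.mu:5.0f}  {p.pixel_value:10.1f}  {p.dose:12.1f}")
print(f"unexposed film pixel value: {unexposed_pv:.1f}")

curve = build_calibration(points, "rational", unexposed_pixel_value=unexposed_pv)
a, b, c = (curve.params[k] for k in "abc")
print(f"\nfitted: dose = {a:.1f} + {b:.3g}/(pv - ({c:.1f}))  over pixel "
      f"values [{curve.domain[0]:.0f}, {curve.domain[1]:.0f}]")
print("residuals at the calibration points (cGy):",
      ", ".join(f"{r:+.2f}" for r in curve.residuals))
# Residuals well under 1 cGy mean the five exposures are mutually
# consistent with a single monotone dose-response.
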