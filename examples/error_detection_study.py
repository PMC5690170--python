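"""Controlled delivery-error study: can the QA tell good deliveries from
bad ones?

Five modulated plans are each delivered five ways: twice faithfully, once
with a small film misalignment plus ~1% output jitter (a surrogate for
irradiating at the real gantry angles), once with monitor units reduced
by 10-37%, and once with one segment dropped.  The first three should
pass, the last two should fail.  Note the signature of the reduced-MU
error: the gamma pass rate stays high (the *shape* is right) while the
point-dose difference fails loudly — which is exactly why the QA needs
both criteria.
"""

import numpy as np

from filmqa import build_calibration, run_qa
from filmqa import synthetic as syn

rng = np.random.default_rng(2026)
points, pv0 = syn.generate_calibration(rng)
curve = build_calibration(points, "rational", unexposed_pixel_value=pv0)

print(f"{'scenario':24s} {'%diff':>7s} {'gamma%':>7s} verdict expected")
correct = 0
scenarios = syn.make_error_scenarios(rng)
for sc in scenarios:
    srng = np.random.default_rng(sc.seed)
    scan = syn.simulate_film_scan(sc.delivered_plane, rng=srng,
                                  misalignment=sc.misalignment)
    res = run_qa(scan, curve, sc.tps_plane)
    ok = res.verdict is sc.expected_verdict
    correct += ok
    print(f"{sc.name:24s} {res.percent_diff:+7.1f} {res.gamma.pass_rate:7.1f} "
          f"{res.verdict.value:7s} {sc.expected_verdict.value:8s}"
          f"{'' if ok else '  <-- misclassified'}")
print(f"\ncorrectly classified: {correct}/{len(scenarios)}")
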