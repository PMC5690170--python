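# filmqa

Transmission quality assurance for radiotherapy deliveries, using
radiochromic film mounted on the linac accessory holder.

## The problem

Pre-treatment QA of an IMRT plan does not guarantee that the *actual*
delivery to the patient is correct — output drifts, data-transfer
mistakes and missing fields all happen at treatment time.  A film placed
on an acrylic tray in the accessory holder rides along with every
fraction: it sits perpendicular to the beam at a source-to-detector
distance (SDD) of 56.8 cm, records the composite fluence of all delivered
fields, and costs nothing in treatment time.  The catch is that the
treatment planning system (TPS) computes its reference dose plane at the
isocenter, SDD 100 cm, on a phantom — so the film and the reference live
at different distances, different magnifications and different absolute
dose levels.

`filmqa` implements the methodology that bridges that gap:

1. **Calibration** ties the film's pixel values, measured *on the tray*,
   directly to TPS doses computed *at the isocenter* for the same monitor
   units.  Because calibration films and QA films share the tray
   geometry, the inverse-square factor ((100/56.8)² ≈ 3.10) and the tray
   transmission (0.942 for 6 MV) cancel identically: the calibrated film
   reads out on the TPS dose scale.  The default dose–response model is
   the rational form D(PV) = a + b/(PV − c), with a shape-preserving
   monotone interpolant and a net-optical-density polynomial as
   alternatives.
2. **Projection** magnifies the film plane to the isocenter by the SDD
   ratio 100/56.8 ≈ 1.761 about the beam central axis, carrying point
   doses unchanged (the beam does not change appreciably between the two
   distances for this geometry).
3. **Registration** aligns film to TPS by maximizing the normalized
   cross-correlation of the two central perpendicular dose profiles
   (sub-grid precision by parabolic peak interpolation); a manual shift
   can be supplied instead.
4. **Comparison**: Gaussian denoising of the film, resampling of the TPS
   plane from 2 mm to 0.5 mm, then
   * the point-dose difference at the normalization point,
     100·(D_film − D_TPS)/D_TPS, and
   * the gamma index γ(r) = min_{r′} √(|r−r′|²/δ_dta² + ΔD²/δ_D²) with
     3 % / 3 mm criteria and a 10 % low-dose threshold.
5. **Verdict**: Pass only if |point diff| < 5 % **and** gamma pass rate
   > 95 % (both strict).  The two criteria are deliberately complementary:
   a uniform monitor-unit error leaves the dose *shape* — and therefore
   gamma — intact and is caught only by the point dose, while a missing
   segment wrecks the shape and collapses gamma.

A synthetic-data module fabricates both sides of the comparison (TPS
planes, tray film scans with noise and quantization, and injected
delivery errors), so the whole pipeline is testable without physical
film.

## Worked example

`examples/analyze_delivery.py` simulates a faithful delivery of a
modulated plan and runs the full QA:

```
film scan: (235, 235) px at 75 dpi, SDD 56.8 cm

point dose: film 208.9 cGy, TPS 207.5 cGy -> +0.7%
gamma 3%/3mm (10% threshold): 100.0% of 53185 points pass
verdict: Pass
```

The +0.7 % point difference is scanner noise surviving the 2 mm
averaging window; 100 % of the 53 185 evaluated points (those above 10 %
of the maximum dose) have γ ≤ 1.  Both criteria clear their bounds, so
the delivery is approved.  `examples/error_detection_study.py` runs the
full 5-plans × 5-variants error study; a delivery at 74 % of the planned
monitor units prints the characteristic output-error signature —
`diff=-26.4% gamma=100.0% Fail` — while a delivery missing one segment
fails the other way (`diff=-7.4% gamma=42.2% Fail`).

The other examples cover calibration fitting (`calibrate_film.py`) and
closed-form gamma behaviour (`gamma_basics.py`).  The same workflow is
scriptable from a shell:

```
filmqa simulate --seed 303 --out-dir qa_fixtures
filmqa calibrate qa_fixtures/calibration.csv --out curve.json --unexposed-pv 3900
filmqa analyze qa_fixtures/plan1-faithful_film.tif qa_fixtures/plan1-faithful_tps.txt \
    --curve qa_fixtures/calibration_curve.json --out result.json
filmqa report result.json
```

`analyze` exits 0 on Pass, 1 on Fail, 2 on error, for clinical batch
scripting.

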