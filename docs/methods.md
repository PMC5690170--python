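# Methods

## Model and geometry

All dose planes are 2D grids of absorbed dose in cGy with explicit
per-axis spacing (mm), an origin giving the physical position of grid
element (0,0) relative to the beam central axis, and the
source-to-detector distance (SDD, cm) at which the plane lives.  Putting
the origin on the central axis makes the divergence projection a pure
similarity scaling about (0,0): moving a plane from SDD `s` to SDD `t`
multiplies spacing and origin by `t/s` and leaves the dose values
untouched.  The physical justification is that, for the tray geometry,
the beam's lateral shape at 56.8 cm is the demagnified image of its shape
at 100 cm and its spectrum changes negligibly between the two distances;
the package treats this as an assumption of the method, not something it
verifies.

Doses are cGy everywhere; the DICOM RT Dose reader converts Gy via
DoseGridScaling × 100.

## Calibration

Calibration exposures (50–600 MU, 10×10 cm field) are delivered to film
on the tray and paired with TPS doses computed at the isocenter plane for
the same MU.  Because both the inverse-square boost (100/56.8)² and the
tray transmission multiply the film-side dose identically for
calibration and QA films, they cancel: the fitted curve maps pixel value
directly to isocenter-scale dose.  A corollary, verified by a dedicated
test, is that the recovered dose is invariant to the transmission factor
as long as calibration and measurement share it.

Model forms:

* `rational` (default): D = a + b/(PV − c), fitted by bounded
  least-squares with the pole c constrained outside the data range (both
  polarities of the pole are tried and the better fit kept).  This is
  the standard saturating film-response shape and extrapolates sanely.
* `pchip`: shape-preserving monotone cubic through the points;
  assumption-free, exact at every calibration point.
* `netod_poly`: quadratic in net optical density log10(PV₀/PV);
  requires the unexposed-film pixel value PV₀.

All fits are refused if not strictly monotone on a 512-point grid over
the data range.  Either digitizer polarity (dose up = pixel value up or
down) is accepted; nothing is hard-coded.  The unexposed-film pixel
value is an optional zero-dose anchor (stored at 10⁻⁶ cGy so models
needing positive doses stay defined); without it the curve's domain does
not reach zero dose and blank-film regions cannot be converted.

Out-of-domain policy in `apply_calibration`: the two domain edges are
treated asymmetrically.  Pixels beyond the zero-dose edge are ordinary
scanner noise on blank film (on a noisy unexposed region, half of all
pixels land there) and are clamped silently, with negative doses clipped
to 0.  Pixels beyond the high-dose edge indicate saturation; more than
1 % of them refuses the scan.

## Processing chain and its order

`run_qa` applies: calibrate → project to isocenter → coregister →
smooth → resample → extract point doses → gamma → verdict.  Registration
runs before smoothing so it sees the least-processed data; smoothing
precedes the comparison to suppress scanner noise.  The order is a
package choice where several orders are defensible; it is logged
step-by-step in `QAResult.steps` together with every parameter, enough
to re-run the analysis bit-identically.

* **Smoothing**: separable Gaussian, σ = 1.0 mm by default (the film's
  0.34 mm pixels oversample the beam heavily, so 1 mm trades negligible
  penumbra blur for a ~4× noise-variance reduction).  σ = 0 disables.
* **Resampling**: bilinear onto a grid with the same physical extent,
  node-centred, inclusive of the last fitting node — N nodes at 2 mm
  become 4(N−1)+1 nodes at 0.5 mm.  Bilinear is exact for affine
  surfaces and for coincident nodes.
* **Registration**: translation only (the film's axes are mechanically
  aligned with the collimator axes; scale is already handled by the
  projection).  Per axis, the central profile of each plane is sampled
  on the reference coordinates, the normalized cross-correlation is
  scanned over a ±10 mm window at half-grid steps, and the peak is
  refined parabolically.  A correlation peak on the window boundary is
  an error; near-flat profiles (contrast < 10⁻⁶ of the dose scale)
  return zero shift flagged `low_confidence`.

## Gamma analysis

For each reference (TPS) node at or above the threshold,
γ = min over evaluated positions within 3×DTA of
√(d²/δ_dta² + ΔD²/δ_D²), with ΔD in % of the normalization dose
(global reference maximum by default; the reference dose at the central
axis in `point_dose` mode).  The search radius cap cannot change any
pass/fail status, since a candidate farther than 3×DTA contributes
γ > 3.  The evaluated plane is sampled on a fine lattice aligned with
the reference grid at step ≤ DTA/10 (convergence in this step is tested:
halving it moves the pass rate of a deliberately marginal smooth case by
< 0.1 points).  Below-threshold nodes, and nodes with no evaluated data
anywhere in the search radius (film edge after registration), carry NaN
and are excluded from the pass-rate denominator.

Two independent implementations share this contract.  `gamma_map`
vectorizes the minimization over lattice offsets visited nearest-first,
stopping once the distance term alone exceeds every current minimum.
`gamma_oracle` is an exhaustive per-node search with no pruning, kept on
a separate code path as the correctness standard; the suite and the
acceptance script compare the two across randomized plane pairs
(observed agreement ~10⁻¹⁴, asserted at 10⁻⁶).

**Relative gamma in the pipeline.**  Before the gamma step (and only
there), `run_qa` rescales the film plane so its dose at the
normalization point equals the TPS dose at that point.  This is the
standard relative-film convention: gamma then judges the distribution's
*shape*, while absolute dose is judged entirely by the point-dose
criterion.  The division of labour is what produces the characteristic
error signatures — a uniform MU deficit keeps gamma near 100 % but fails
the point dose by the deficit itself; a removed segment collapses gamma.
The flag `renormalize_for_gamma=False` restores fully absolute gamma.

## Verdict

Pass ⇔ |100·(D_film − D_TPS)/D_TPS| < 5 **and** gamma pass rate > 95,
both strict — a result sitting exactly on either bound fails.  Verdicts
use full-precision values; one-decimal rounding is display-only.  The
normalization point defaults to the central axis and is configurable;
its dose is the mean over a 2 mm window (25 sub-pixels at 0.5 mm) to
keep a single noisy pixel from deciding a verdict.

## Synthetic study conditions

The generator fabricates what the physical study measures:

* TPS planes on a 2 mm grid, 14 cm across, built from error-function-
  edged rectangles (50 % isodose exactly at the nominal edge, penumbra
  σ = 3 mm).  Five fixed modulated plans ship with the package; each is
  a base aperture of 110–130 cGy plus three partial segments of
  40–55 cGy, so every segment is individually consequential.
* Film scans at 75 dpi, 12-bit, SDD 56.8 cm.  The ground-truth response
  is rational in the same family as the default calibration model
  (pixel 3900 unexposed → ~300 at 2000 cGy, darkening with dose,
  steepest at low dose).  Scanner noise is additive Gaussian in pixel
  space, σ = 40 PV (~1 % of the dynamic range), followed by
  quantization; film-grain spatial correlation and scanner lateral
  response are deliberately not modelled.  All randomness flows through
  one explicit `numpy.random.Generator`; equal seeds give bit-identical
  scans.
* Delivery-error scenarios per plan: faithful; faithful repeat (fresh
  noise); small random misalignment within ±2 mm plus ~1 % output
  jitter (surrogate for delivering at the real gantry angles); monitor
  units uniformly reduced by a factor drawn from 0.63–0.90; one
  randomly chosen segment removed.  The first three are tagged
  expected-Pass, the last two expected-Fail; the classification test
  requires ≥ 24 of 25 correct, accepting that the misaligned/jittered
  variant can legitimately fail as marginal deliveries do.

What passing synthetic tests does **not** show: correctness of the
physical dose-response of any real film lot, scanner polarization and
lateral-response effects, film-grain noise correlation, or the validity
of the constant-shape assumption between 56.8 cm and 100 cm for beams
unlike the modelled one.  Those require measurements, not simulation.

## Numerical choices and limitations

* Bilinear interpolation throughout (`RegularGridInterpolator`); exact
  grid nodes reproduce stored values; queries outside a plane's extent
  are errors, never extrapolations, except where "outside" legitimately
  means "no film" (NaN, excluded downstream).
* Resampling refuses grids beyond 4096 nodes per axis; the gamma oracle
  refuses references beyond 64×64 nodes.
* The rational calibration fit uses xtol/ftol/gtol = 10⁻¹⁴ so that
  noise-free synthetic points are recovered to ~machine precision.
* 3D dose grids, time-resolved dose, deformable registration,
  multichannel film dosimetry, film-lot aging and patient-position
  verification are out of scope.
* Problem sizes in the shipped tests and the acceptance script (14 cm
  planes at 2 mm/0.5 mm, 50–100 oracle fixtures, 25 scenarios) were
  chosen so a full run completes in well under a minute each on one
  core while leaving every assertion statistically comfortable.
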