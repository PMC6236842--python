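# Methods

## Scope and model

The package treats a CBCT acquisition protocol as a small parameter
vector — tube potential (kVp), tube current (mA), pulse width (ms),
trajectory (half = 200 deg, full = 360 deg) and gantry speed (deg/s) —
from which two quantities follow arithmetically:

* projections = round(scan_angle / gantry_speed x frame_rate)
* mAs = current x pulse_width x projections

The frame rate is not printed on protocol sheets; it is fixed at 15
projections/s, the unique value consistent with every row of the
reference cohort (a 200 deg scan at 6 deg/s giving 500 projections), and
is overridable per protocol. Start/stop gantry angles, bowtie filter and
reconstruction settings are carried as opaque metadata: nothing computed
here depends on them.

Imaging dose is summarized by the weighted cone-beam dose index measured
with a 10 cm pencil chamber in a 16 cm CTDI head phantom:
wCBDI = (D_center + 2 D_periphery)/3, where D_periphery is the mean of
the four clock-position doses for half rotations and, by rotational
symmetry, the 12:00 reading alone for full rotations. If a full-rotation
set nevertheless carries all four peripherals, their mean is used
(strictly more information under the same symmetry) and the substitution
is logged. The normalized index nCBDI = wCBDI/mAs x 100 isolates the
potential dependence of the dose output. The internal dose unit is cGy
everywhere; mGy appears only at the reporting layer (a documented x10),
so the two conventions can never be mixed silently.

Two empirical scaling laws connect dose to the protocol parameters and to
image quality:

* nCBDI = c kVp^3 — dose output rises with the cube of the potential;
* noise = a wCBDI^(-1/2) — image noise falls with the inverse square
  root of dose.

Both are one-parameter fits with the exponent fixed by the model. The
least-squares coefficient has the closed form c = sum(x^p y)/sum(x^2p);
a brute-force grid search over c is used as the oracle in tests.
Agreement is summarized by the Pearson correlation between y and x^p
("normalized cross-correlation"; an uncentered cosine variant exists
behind a flag for sensitivity checks, and a log-space fit variant is
likewise exposed but not the default since the headline fits are quoted
in linear space). The residual SD uses denominator n (population form).
The 125-vs-100 kV comparison divides group means of nCBDI and propagates
the per-group sample SDs to first order; a matched-pairs variant is
provided because the grouping convention behind such ratios is not
standardized.

## Image-quality metrics

All ROI geometry is specified in phantom millimeters, never voxels. A
voxel belongs to a cylindrical ROI iff its center lies inside the
cylinder, with the z-interval half-open — deterministic and
resolution-consistent. ROIs must select at least 10 voxels.

* **Noise**: SD of HU in a central cylinder of the uniformity module with
  diameter 40% of the module diameter (length 10 mm by default).
* **Uniformity**: max |peripheral mean - central mean| over four
  peripheral cylinders. The exact peripheral geometry is not fixed by any
  standard, so it is explicit configuration: centers at 12/3/6/9 o'clock
  at 80% of the module radius, diameter 10% of the module diameter,
  length 10 mm.
* **HU constancy**: max |measured - expected| over the air (-1000 HU),
  LDPE (-100 HU) and acrylic (120 HU) inserts, measured over the central
  60% of each insert diameter to stay clear of the partial-volume rim.
* **Low-contrast detectability**: for each insert diameter d in
  {2..9, 15} mm, background circle ROIs of diameter d are placed in two
  rows bracketing the insert ring (ring radius -/+ (d + 2 mm)), 8 per row
  at angles midway between inserts, each kept >= 2 mm clear of every
  insert (violations raise rather than silently shifting). The SD of the
  per-ROI means is the noise competing with a 10 HU (1% contrast) object
  of that size; d is detected iff 4 x SD <= 10 HU. Scanning from the
  largest diameter down, the reported value is the smallest diameter of
  the contiguous detected run — an isolated pass below an undetected size
  is not trusted — and a failure at the largest size yields the ordered
  sentinel ">=15" (a value-plus-flag categorical, never a bare number).
  The ROI count and row placement are declared defaults, not inferences
  about any particular commercial analysis.
* **CNR**: |mean(ROI) - mean(BKG)| divided by a noise SD. The literal
  definition divides by the background SD; published patient tables are
  reproduced by dividing by the ROI SD instead (e.g. 35.4/37.3 -> 0.95,
  where the background SD would give exactly 1.00). Both conventions are
  implemented (`denominator="background"` is the default; `"roi"`
  reproduces those tables); the discrepancy is surfaced, not resolved.
* **MTF**: per bead, a 33 x 33-voxel in-plane window (9 slices) is
  extracted; the local background — the mean over the in-plane annulus
  beyond 80% of the window half-size, all slices — is subtracted; slices
  are summed to an in-plane PSF; the power spectrum of the zero-padded
  (256^2) FFT is radially averaged in bins of width Nyquist/64; the mean
  power in the band above 90% Nyquist is subtracted as a white-noise
  floor (skipped when that plateau exceeds 25% of the DC power, which
  indicates a genuinely unresolved PSF rather than noise); the square
  root is normalized to 1 at zero frequency; and the 0.5/0.1 crossings
  are located by linear interpolation, averaged over beads, and reported
  in lp/cm. A crossing not reached below Nyquist reports the Nyquist
  frequency with an at-limit flag. The annulus-mean background matters:
  a background error is amplified by the window voxel count when it
  enters the DC normalization, and the wide annulus keeps that error
  within the subtracted noise floor. Since the MTF is monotone
  decreasing, f10 > f50 necessarily; the packaged results table lists
  the two frequencies under labels consistent with that ordering.

A global HU offset leaves every metric unchanged except HU constancy,
which shifts by the offset; both directions are asserted in tests.

## Synthetic data generator

The generator produces the inputs the analysis assumes, with known ground
truth:

* **Digital Catphan**: air outside a 200 mm body cylinder; uniform
  background (20 HU, a plausible solid-phantom material value) inside;
  four 20 mm modules stacked along z; sensitometry inserts at their
  expected HU on a 50 mm ring; eight 1%-contrast inserts (2-9 mm) on a
  50 mm ring plus a central 15 mm insert (background + 10 HU); two beads
  rendered as impulses convolved with an in-plane Gaussian PSF. Insert
  edges are anti-aliased by a signed-distance partial-volume fraction on
  boundary voxels, which removes staircase bias from small-insert means
  (interior means are exact, so the noiseless phantom yields exactly zero
  noise/uniformity/HU-constancy and 2 mm detectability).
* **Head-like phantom**: a water tube (0 HU) and acrylic rod (120 HU) in
  a 160 mm soft-tissue cylinder (40 HU), with the three 10 mm x 25 mm
  analysis cylinders used for head CNR.
* **Chamber readings**: target wCBDI = c kVp^3 mAs/100, optionally
  scattered by (1 + eps), eps ~ N(0, 0.05^2); the center reads
  wCBDI(1 - h) and every peripheral wCBDI(1 + h/2) with heterogeneity
  h = 0.10, so the weighting formula recovers the target exactly.
* **Noise**: i.i.d. Gaussian HU noise with sigma = a/sqrt(wCBDI).

Defaults are the study conditions: a = 19.5 HU sqrt(cGy) (the observed
noise scale, ~34.5 HU at 0.32 cGy), c = 2.1e-7 cGy/100 mAs per kV^3
(nCBDI at 100 kV = 0.21 cGy/100 mAs), 5% dose jitter, 10% center-vs-
periphery heterogeneity. The default grid is 220 x 220 in-plane at 1 mm
with 40 slices at 2 mm — chosen so a full 26-protocol simulated study
runs in seconds; the 512 x 512 at 0.51 mm / 1 mm-slice reconstruction
grid of physical practice is available as the `paper_scale` preset, and
a compact uniformity-module-only preset (`noise_study`) serves the
dose-noise recovery loops. The default PSF sigma is 0.8 mm because the
1 mm default grid cannot resolve the 0.47 mm sigma that reproduces
published bead MTF values (f50 ~ 4.1, f10 ~ 7.0 lp/cm); the paper-scale
preset uses 0.47 mm. The bead amplitude (50 000 HU integrated) is set so
the bead spectrum dominates the noise floor of its analysis window even
at the lowest simulated dose.

What the generator does **not** emulate: real CBCT noise is spatially
correlated and streaky, not white; there is no scatter, beam hardening,
ring artifact, cupping, or anatomical realism. Passing tests therefore
demonstrate that the metric and fitting machinery is correct under the
assumed statistical structure — not that a physical scanner obeys it.
In particular the simulated detectability and CNR are systematically
more optimistic than physical Catphan readings at equal noise, because
white noise averages down faster inside an ROI than correlated noise.

## Numerical choices

* ROI voxel selection: center-inclusion, half-open in z; population SD
  (ddof 0) for voxel statistics; sample SD (ddof 1) across LCD ROI means.
* Detection rule boundary: 4 x SD <= 10 HU is inclusive (SD exactly 2.5
  HU detects).
* MTF: bin width Nyquist/64, padding to 256, crossings by linear
  interpolation between bin centers, curve anchored exactly at (0, 1).
* Protocol table parsing: UTF-8 CSV, header required, column names
  matched case-insensitively with units stripped; stated derived columns
  are validated against recomputation and mismatches warn with both
  values (the recomputed value wins).
* Determinism: every stochastic step draws from a generator seeded from
  the configuration; a fixed seed makes volumes, readings and all written
  study outputs byte-identical across runs.

## Problem sizes

The shipped test suite and analysis drivers use the test-scale grid
throughout (a full simulated 26-protocol study in ~15 s), 50 seeds for
the noise-coefficient recovery study and 200 synthetic cohorts for the
fit-recovery property. The acceptance report is computed entirely from
the packaged protocol/results tables and is deterministic.

## Known limitations

* The white-noise fidelity limit above: absolute detectability/CNR values
  from the simulator are not comparable with physical phantom readings.
* MTF from a noisy single bead remains a high-variance estimate; the
  noise-floor subtraction removes the bias but not the scatter. Physical
  practice averages repeated acquisitions.
* Automated phantom registration is out of scope: the layout is given in
  configuration, and ROI placement errors are reported as geometry
  errors, not corrected.
* Chamber physics (calibration, temperature/pressure correction) and
  narrow-beam CTDI are out of scope; readings are taken as given in cGy.
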