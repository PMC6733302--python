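# Methods

This note documents the measurement model, the synthetic-data
generator, the numerical choices and the known limitations of
`thzpowder`.

## Measurement principle and processing chain

A fixed terahertz reflection probe faces a rotating annular container
(HDPE, index $n_c = 1.54$ at terahertz frequencies; outer/inner
interior diameters 138/78 mm, interior height 45 mm) holding a powder
layer of nominal height 10 mm.  Each acquired waveform is reduced to
the signed peak amplitude of the pulse reflected at the
container/powder interface, inside a configurable delay gate.  Dividing
by the copper-foil reference amplitude (copper reflects with
coefficient −1) gives the per-measurement reflection coefficient
$r_{cp}$, with the sign fixed so that a powder with $n_p < n_c$ yields
$r_{cp} > 0$.

The chain then applies, in order:

1. **moving-average filter**, window 5, centred, shrinking at the
   sequence edges so output indices stay aligned with the registration;
   datum-flagged measurements are excluded from every window;
2. **datum detection** — contiguous runs with $|r| \ge$ threshold
   (default 0.5, far above any powder reflection and far below the
   copper return) mark datum passages; a complete rotation is the
   half-open sample interval between successive passage starts;
3. **angular binning** — within a rotation, the container angle of a
   measurement is its fractional position between the bounding passage
   starts (uniform rotation assumed); values are averaged in $N$
   half-open uniform bins (default 230) across the first 7 complete
   rotations.  Bin assignment uses integer arithmetic so samples on bin
   edges resolve deterministically to the lower bin.  Empty bins are
   reported as missing, never interpolated.  Profiles can be expressed
   in absolute container coordinates by passing the datum strip's
   angular position as the origin;
4. **Fresnel inversion** $n_p = n_c(1-r)/(1+r)$ per bin, and the
   per-material **linear calibration** $\bar\varrho_r = a_0 + a_1\bar
   n_p$ fitted by ordinary least squares on the pooled (run × stage)
   points.  $\bar n_p$ is the arithmetic mean over valid bins.

The reference (gravimetric) density is $\bar\varrho_r = m/(A\bar
h\varrho_t)$ with $A = \pi(D_o^2 - D_i^2)/4$; the fill height $\bar h$
is the mean of eight caliper readings minus the 73 mm compression-unit
stack (10 mm ring + 63 mm sensor block).  Lengths are stored in mm and
densities in g·cm⁻³; the single mm³↔cm³ conversion lives in the
geometry module (note 1 g·cm⁻³ = 1 mg·mm⁻³, which makes fill weights
in mg direct).

## Synthetic-data generator

The generator emulates the acquisition conditions of the rotating-
container study: 15 Hz acquisition over a 45 ps delay window, 2000
waveforms per stage, nominal rotation speed 4 rpm, container index
1.54, a copper datum strip (default width 8°), additive Gaussian noise
on the reflection coefficient with sd 0.0015, five compaction stages,
three runs per material, and eight dosing positions.

* **Index–density law**: $n_p = 1 + (n_s - 1)\varrho_r$ — the simplest
  effective-medium form that is linear in density and anchored at
  vacuum ($n_p = 1$) and the pore-free solid ($n_p = n_s$).  The solid
  terahertz index of α-lactose monohydrate is **an assumption,
  $n_s = 1.78$**, not a measured value; it sets the implied calibration
  slope $a_1 = 1/(n_s-1) \approx 1.282$ and scales every propagated
  density accuracy.
* **Waveforms** are scaled Ricker (single-cycle) pulses on the 45 ps
  axis; the analysis consumes only the gated peak amplitude, so no
  propagation optics, dispersion or multiple reflections are modelled.
* **Datum signature**: measurements whose container angle falls on the
  strip carry reflection −1 — equal in magnitude to the reference and
  opposite in sign to the powder reflection — guaranteeing unambiguous
  threshold detection.
* **Noise**: iid Gaussian on the reflection amplitude, sd
  0.0015 × reference amplitude, matching the single scalar accuracy
  figure the instrument achieves; verified in tests to within 10% over
  ≥10⁴ synthetic measurements.
* **Compaction** is a prescribed density increment, not mechanics: the
  stage-mean relative density relaxes exponentially in applied pressure
  from the bulk-density ratio towards the tapped-density ratio with a
  10 kPa pressure scale, stages at 0–8 kPa.  Bulk/tapped/true densities
  and container charges for Lactohale 100/200/220 are bundled as
  presets.
* **Bed heterogeneity**: a smooth low-order Fourier pattern (three
  harmonics, seeded random phases) with peak amplitude 0.01 absolute
  density units, drawn once per run and shared across its stages — the
  same imperfect bed observed through successive compressions.
* **Nominal-density error**: caliper readings carry Gaussian noise of
  sd 0.1 mm per position (8 positions), the physically plausible
  dominant error of the manual height measurement.  Propagated through
  $\bar\varrho_r \propto 1/\bar h$ this gives ≈0.0016 density units —
  the source of the ≈0.002 calibration RMSE the demo reproduces.
* **Dosing**: eight dip sites, default 45° apart; each hole's angular
  footprint is the geometric width of the 3.4 mm dosator at mid-annulus
  radius (≈3.6°), since the true refilled-hole width is not otherwise
  determined.  Refill is modelled as a *persistent* multiplicative
  density deficit; the pipeline's default deficit is "auto": refilled
  holes sit at the loose bulk-density ratio, so the deficit is
  $1 - \varrho_{r,\mathrm{bulk}}/\varrho_{r,\mathrm{stage}}$ (≈0.25 for
  Lactohale 200 after the last stage, ≈0.09 for the weakly compressible
  Lactohale 100 — whose dosing signature is correspondingly harder to
  detect, a faithful property of such powders).
* **Fill weights**: plug mass = local relative density × true density ×
  chamber volume (π/4 · 3.4² · 5 mm³) × efficiency + weighing noise
  (sd 0.8 mg).  The efficiency defaults to 1.5: the 1:2 pre-compression
  ratio draws more than one chamber volume of loose powder into the
  nozzle, so the naive chamber-volume mass *under*-estimates real fill
  weights; 1.5 places simulated weights in the tens-of-mg range of real
  capsule fills.  It is a config parameter, not a constant.

### Rotation speed: nominal vs effective

At exactly 15 Hz and 4 rpm a rotation is exactly 225 samples, so the
sampling grid is phase-locked to the container: the same 225 angles are
probed every rotation, with $N = 230$ bins at least five bins stay
permanently empty, and a dip site that falls between grid points is
never better resolved by averaging.  Real acquisitions are not locked —
2000 samples covering about 8.5 rotations corresponds to an effective
≈3.83 rpm — and the demo configuration uses that effective speed, which
de-locks the grid, fills all 230 bins and lets rotation averaging
resolve every hole.  `ScanConfig` itself defaults to the nominal
4.0 rpm; exactness tests exploit the locked case deliberately (integer
bin assignment makes noiseless field recovery exact to machine
precision there).

## What the generator does *not* emulate

No frequency-dependent (dispersive) index, absorption, oblique
incidence, or etalon effects; no scattering; no mechanical model of
compaction, friction or cohesion; no drift in rotation speed within a
scan; no probe misalignment.  Passing tests therefore demonstrate that
the *analysis chain* is correct and statistically well-behaved under
the stated noise model — not that a particular instrument will reach
the same accuracy on real powders, where baseline drift, speed jitter
and material-dependent optics enter.

## Numerical choices

* Half-open bins $[a, b)$; edge ties go to the lower bin.  Integer
  arithmetic for bin indices where the origin is 0.
* Moving-average edges shrink rather than truncate, preserving index
  alignment; fully masked windows yield NaN.
* Degenerate inputs raise: all-equal abscissa in the calibration,
  constant densities in the correlation, $|r| \ge 1$ in the inversion,
  nominal densities outside (0, 1), overlapping dosing holes.
* An all-zero trace returns peak amplitude 0 with a warning (a dead
  channel should not crash a 2000-waveform scan).
* Hole detection uses the profile **median** as baseline (robust while
  the depressed segments cover a minority of bins) and merges
  contiguous below-threshold bins across the 0°/360° wrap.  The
  pipeline's default depth threshold (0.015) sits above the 0.01
  heterogeneity amplitude so bed texture alone does not trigger
  segments.
* All randomness funnels through one seeded generator; child seeds stay
  below 2³¹.  Identical configuration + seed gives byte-identical
  output files.

## Problem sizes

The bundled demo and the acceptance script run the study at full
acquisition scale (2000 waveforms × 301 samples per stage, 3 runs × 5
stages per material, all three materials) — small enough to complete in
seconds on one CPU.  Monte-Carlo properties use 100–500 seeded
replicates at the same per-run scale.

## Known limitations

* The absolute calibration intercept/slope depend entirely on the
  assumed $n_s$; only their ratio structure ($a_0 = -a_1$) is a model
  property.  The propagated density accuracy (~0.5% per measurement at
  the default $n_s$) scales accordingly.
* Angle assignment assumes constant rotation speed between datum
  passages; slow drift within a rotation would smear bins.
* The fill-weight law is volumetric with a scalar efficiency; cohesive
  retention effects, which raise weight variability for fine powders,
  are represented only by the weighing-noise term.
* With phase-locked sampling (exact nominal rates) some angular bins
  are structurally empty; they are reported as missing rather than
  interpolated, and downstream statistics skip them.
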