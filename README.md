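# thzpowder

In-line monitoring of powder **bulk density** in a rotating annular
container from time-domain **terahertz reflection** measurements, and
prediction of capsule **fill weight** from the density estimates.

## The problem

Capsule filling is volumetric: a dosator nozzle dips into a powder bed
and retains a fixed-volume plug, so the delivered mass — a critical
quality attribute — tracks the local bulk density of the bed.  Bulk
density is hard to measure in-line.  A terahertz pulse sent through the
(THz-transparent) HDPE container wall is partially reflected at the
container/powder interface; the reflection amplitude encodes the
effective refractive index of the powder, which rises linearly with
packing density.  Scanning a fixed probe against a rotating container
therefore yields an angle-resolved, non-destructive map of relative
density, from which fill weights at the dosing positions can be
predicted.

This package is aimed at PAT (process analytical technology) method
developers: it implements the full analysis chain and a synthetic-data
generator that emulates the measurement physics, so every stage is
testable without instrument data.

## The model

For a powder of effective index $n_p$ behind a container wall of index
$n_c = 1.54$, the normal-incidence field reflection coefficient is

$$ r_{cp} = \frac{n_c - n_p}{n_c + n_p}
\qquad\Longleftrightarrow\qquad
n_p = n_c\,\frac{1 - r_{cp}}{1 + r_{cp}} . $$

$r_{cp}$ is measured as the gated peak amplitude of each reflected
pulse, normalised by a copper-foil reference reflection (a near-perfect
conductor, $r = -1$).  A copper datum strip on the container produces
one near-total reflection per revolution, which registers the rotation;
reflection coefficients are smoothed with a moving-average filter
(window 5), binned into $N = 230$ uniform angular bins, and averaged
over 7 complete rotations.

The nominal (gravimetric) relative density of the annular powder layer
is

$$ \bar\varrho_r = \frac{m}{A\,\bar h\,\varrho_t},
\qquad A = \frac{\pi}{4}\left(D_o^2 - D_i^2\right), $$

with powder mass $m$, fill height $\bar h$ (from eight caliper
readings), true density $\varrho_t$, and $D_o = 138$ mm,
$D_i = 78$ mm.  One linear calibration per material,

$$ \bar\varrho_r = a_0 + a_1\,\bar n_p , $$

is fitted by ordinary least squares over the compaction stages of all
runs; the fitted line converts mean index to predicted density, which
is correlated with off-line capsule fill weights stage by stage.

## Worked example

Run the bundled end-to-end demo — simulate three runs of a five-stage
compaction study on Lactohale 200, process and calibrate, predict
densities, synthesise off-line fill weights, correlate, then map a
post-dosing bed:

```python
from thzpowder import default_config, run_pipeline

res = run_pipeline(default_config(), out_dir="out", seed=1)
print(res.calibration.summary())
print(res.correlation.summary())
print("hole segments:", len(res.hole_segments))
```

prints

```
Density calibration (OLS)
============================================
material:        Lactohale 200
n points:        15
a0 (intercept):  -1.276747  (se 0.020799)
a1 (slope):      +1.278109  (se 0.015158)
R-squared:       0.9982
RMSE:            0.002017  (relative-density units)
index range:     [1.3143, 1.4187]
Density–fill-weight correlation
============================================
material:   Lactohale 200
n stages:   5
slope:      +105.41 mg per unit relative density
intercept:  -0.43 mg
R-squared:  0.9993
hole segments: 8
```

Reading the numbers: the calibration pools 15 points (3 runs × 5
stages).  The generator's index–density law implies
$a_1 = 1/(n_s - 1) \approx 1.282$ and $a_0 = -a_1$ for the assumed
solid index $n_s = 1.78$; the fit recovers both to within one standard
error, with an R² of 0.998 and a calibration residual of 0.002
relative-density units (dominated by the simulated caliper-reading
noise in the nominal density).  Predicted stage densities correlate
with the simulated capsule weights at R² = 0.999 — density is an
excellent fill-weight predictor under these conditions — and the
post-dosing density profile shows exactly the eight depressed segments
left by the dosator dips (sites M01–M08), which persist in every
rotation row of the density map.

The same workflow is scriptable from the shell:

```bash
thzpowder run-all --config examples/demo.yaml --seed 1 --out-dir out/
thzpowder holes out/density_profile.csv
```

and the individual stages (`simulate`, `process`, `calibrate`,
`predict`, `map`, `holes`, `correlate`) operate on the documented
HDF5/CSV/YAML files.

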