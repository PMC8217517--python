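# dbck — sperm waveform kinematics and neck morphometry

`dbck` is a Python toolkit for the quantitative analysis of single
mammalian sperm snapshots (e.g. snap-frozen swimming bovine sperm). It
answers three questions about each cell, and about populations of
cells:

1. **What is the tail doing?** An arclength-parametrized centerline
   r(s) = (x(s), y(s)) is traced from a grayscale image, expressed in
   the head-anchored frame (head long axis = x-axis, neck at the
   origin, +y = the sperm's right), and condensed into the
   sliding-filament tail variables: the mean beating amplitude ȳ, the
   mean interfilament sliding Δ̄ with Δ(s) = a·(θ(s) − θ₀) for a
   flagellar diameter a = 600 nm, and the mean signed curvature κ̄
   with κ(s) = dθ/ds. Left bends are negative in all three.

2. **Which way is it bending?** Centriole orientation-based sperm
   analysis (COSA): each cell's chirality is normalized using the
   conserved neck asymmetry (proximal centriole on the sperm's right,
   the larger distal-centriole rod on the left), after which the bend
   is classified as *sharp left*, *mild left*, *straight* or *slight
   right* (with Type 1/2 subtypes for left bends, by head–neck kink
   dominance).

3. **What is the neck doing, at nanometre scale?** Signed morphometrics
   from landmark tables and STORM-style localization clouds: rostral /
   caudal rod sliding d (positive when the right side sits higher than
   the left), rod length and width by the 50 %-of-intensity-peak rule,
   PC–neck angle and lateral shift, head–neck kink angle,
   segmented-column displacements and inter-segment angles,
   microtubule-to-PC-centerline distances, and circular-ROI photon
   sums.

A statistics layer ties the measurements together: Pearson
correlation + regression, unpaired two-tailed t-tests, and an
SPSS-style exploratory factor analysis (KMO, Bartlett's sphericity,
eigenvalue extraction, varimax rotation, |loading| > 0.40
significance rule) exposed as a model/results pair with a `summary()`
table.

Because the microscopy data such pipelines run on are rarely shared,
the package ships a first-class synthetic-specimen generator
(`dbck.synthgen`) with known ground truth: four bend classes with
left-biased frequencies (15/30/36/19 %, and *no* sharp right bends),
basal rod sliding coupled linearly to the bend phase (sharp-left minus
slight-right contrast of 300 nm), PC rocking (24°), PC lateral shift
(170 nm) and head kinking (45°) all driven by one latent phase, plus
Gaussian landmark/localization noise and TIFF rasterization. Every
parameter-recovery test in the suite runs against this generator.

## Worked example

Generate a 248-cell population with the default class mixture,
classify every cell, and correlate the measured rostral rod sliding
with the tail amplitude:

```python
import numpy as np
from dbck import synthgen, cosa, slidingmodel, neckmetrics, stats

params = synthgen.SynthParams(n_specimens=248, seed=1)
population = synthgen.make_population(params)

rows = []
for sp in population:
    oriented = cosa.normalize_orientation(sp)
    beat = cosa.classify_bend(oriented)
    tv = slidingmodel.tail_variables(oriented.waveform)
    m = neckmetrics.compute_neck_metrics(oriented.landmarks)
    rows.append((beat.category.value, tv.y_bar, m.d_rod_rostral))

dist = cosa.population_distribution([r[0] for r in rows])
for cat, frac in dist.fractions.items():
    print(f"{cat.value:>12s}: {dist.counts[cat]:3d}  ({100*frac:.1f} %)")

rep = stats.pearson_regression([r[1] for r in rows], [r[2] for r in rows])
print(f"rod sliding vs amplitude: R = {rep.r:.3f}, R2 = {rep.r2:.3f}, "
      f"slope = {rep.slope*1000:.1f} nm/um, p = {rep.p_two_tailed:.2e} {rep.stars}")
```

Output:

```
  sharp_left:  43  (17.3 %)
   mild_left:  78  (31.5 %)
    straight:  84  (33.9 %)
slight_right:  43  (17.3 %)
rod sliding vs amplitude: R = -0.987, R2 = 0.973, slope = -30.0 nm/um, p = 2.41e-195 ****
```

The class fractions scatter multinomially around the generator's
15/30/36/19 % mixture, no cell is called sharp-right, and the rod
sliding d is strongly *negatively* correlated with ȳ: cells bending
left (negative ȳ) carry a right rod displaced rostrally (positive d).
The slope says the right rod slides ~30 nm rostrally per µm of
leftward mean tail deflection.

## Command line

```bash
dbck simulate --out sim --seed 1 --n 50 --images   # population + TIFFs
dbck trace --image sim/images/sp00000.tif --pixel-size-nm 100 \
     --seed-x 210 --seed-y 180 --out wf.csv        # centerline from image
dbck run --out results --seed 1 --n 248            # full pipeline
dbck corr --table results/specimen_metrics.csv --x y_bar_nm --y d_rod_rostral
dbck efa --table results/specimen_metrics.csv      # factor analysis
```

All on-disk coordinates are nanometres; images are 16-bit TIFF;
configuration is YAML (`RunConfig`); localization tables use a
ThunderSTORM-compatible CSV dialect (`id, side, frame, x_nm, y_nm,
z_nm, intensity`).

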