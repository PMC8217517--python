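# Methods

## Coordinate and sign conventions

All lengths are nanometres internally and on disk; angles are stored
in radians and reported in degrees. The head-anchored frame places the
head long axis on the x-axis with the neck at the origin; +y is the
sperm's **right**, so leftward quantities are negative. "Rostral"
means toward the head tip, "caudal" toward the tail tip; the rostral
direction of the *neck midline* (not the head axis) is the reference
for the signed displacement d and for left/right side decisions, since
a kinked head tilts the whole neck relative to the head midline.

Signed metric conventions:

* d (rod, microtubule, segmented-column displacement): projection of
  (right-structure − left-structure) on the neck's rostral direction;
  positive when the right side sits higher (more rostral) than the
  left.
* PC lateral shift: signed perpendicular offset of the PC midpoint
  from the neck midline; right positive.
* Head–neck angle: signed angle **from the head long axis to the neck
  midline**. A head kinking to the sperm's left is, equivalently, a
  neck rotated toward the right of the head, so left-bent cells have
  positive head–neck angles under this definition.
* Every signed metric is odd under a mirror flip of the specimen; this
  is tested exhaustively.

## Sliding-filament tail variables

The flagellum is modelled as two inextensible filaments
r±(s) = r(s) ± (a/2) n̂(s) a distance a apart normal to the
centerline. Curvature forces an arclength mismatch between the two
rails,

    Δ(s) = a (θ(s) − θ₀),      κ(s) = dθ/ds,

with θ the tangent angle in the head frame and θ₀ its value at the
neck. The basal offset Δ₀ is fixed at zero: Δ(s) measures only the
curvature-induced mismatch, while basal sliding is measured
*independently* from neck landmarks and never inferred from the
waveform. The tail variables ȳ, Δ̄, κ̄ are signed arclength means
(trapezoidal) over the full traced length; absolute-value variants
exist but are not the default, because the left-biased beat is visible
precisely in the signed distributions. Defaults: a = 600 nm (bovine
flagellar diameter), grid spacing ds = 100 nm, both overridable.

Numerics: θ comes from central differences of (x, y) with
second-order one-sided stencils at the ends (`edge_order=2`; a
first-order end stencil would bias θ₀ by O(ds) and hence Δ by a
constant), followed by ±π unwrap before differentiation so curvature
never spikes at branch cuts. On circular arcs Δ(s) = a·s/R holds to
O(ds²).

## Centerline tracing

Tracing replaces a human-in-the-loop step with an automated one so it
can be tested: Otsu threshold → skeletonize → 8-connected pixel graph
(diagonal steps weighted √2) → prune side spurs shorter than 10 px →
longest geodesic path from the skeleton endpoint nearest a seed point
(the seed stands in for the human click) → centered moving-average
smoothing (default window 5 samples, a config parameter because
curvature is derivative-sensitive) → nm conversion by an explicit,
mandatory pixel size. When the head is in the image the traced path
runs head-tip → tail-tip; `crop_at_seed=True` keeps the portion from
the vertex nearest the seed (the neck) outward. Round-trip accuracy on
rasterized specimens at 100 nm pixels: path length within 2 % (<0.1 %
typical), tangent angles within 2° RMS on a 500 nm grid.

## The synthetic-specimen generator

The generator emulates snap-frozen populations of swimming bovine
sperm: static snapshots with a left-biased beat, nanometric neck
deformations coupled to the bend, and STORM-like rod localization
clouds. It is ground truth for every parameter-recovery test.

**Latent phase.** Each specimen carries one phase ψ ∈ [−1, 0.6], drawn
uniformly within its class interval: sharp-left [−1, −0.7], mild-left
[−0.7, −0.2], straight [−0.2, 0.2], slight-right [0.2, 0.6]. The
intervals create within-class variability while preserving class
order; nothing is ever generated beyond +0.6, so sharp right bends do
not exist by construction. Default class weights 0.15/0.30/0.36/0.19.

**Coupled deformations.** All neck deformations are affine in ψ:
metric = −ψ·(swing/1.25), where 1.25 = E[ψ|slight-right] −
E[ψ|sharp-left]. Each `swing` parameter therefore *is* the expected
sharp-left minus slight-right group contrast — the form in which such
deformations are reported for real populations. Defaults: rod sliding
300 nm, PC–neck angle 24°, PC lateral shift 170 nm, head–neck kink
45°. Consequences: d is positive (right rod rostral) in left-bent
cells; the truth d and truth head kink are perfectly correlated
(r = 1) before noise; the caudal rod distance carries a constant
+150 nm offset from the left/right rod length difference.

**Waveform.** The centerline integrates a tangent-angle profile

    θ(s) = θ_neck e^{−s/ℓ} + θ_bend(ψ) w(s) + A_θ sin(2πs/λ + π/2),

with ℓ = 2 µm (the kink relaxes over the neck region), w(s) the
smoothstep envelope 3t²−2t³, and a 4 µm-amplitude, 25 µm-wavelength
oscillation on a 50 µm flagellum. The quarter-period phase makes the
oscillation's contribution to the mean deflection zero to first
order, so class separation is carried by the bend term; the phase is
fixed rather than random so that within-class variability comes only
from ψ and noise-free classification is exact.

**Bend calibration.** The COSA thresholds T1 = 0.03 and T2 = 0.12
(fractions of flagellum length on D = ȳ/L) are conventions chosen to
align with the generator's ψ class boundaries. Because D(θ_bend) is
nonlinear (strong bends curl and their mean deflection saturates), a
single linear θ_bend(ψ) cannot hit both thresholds at both
boundaries. The generator therefore solves, by bracketing root-finds
(cached per geometry), a piecewise-linear θ_bend(ψ) through the class
boundaries such that D(±0.2) = ±T1 and D(−0.7) = −T2 exactly, with a
fixed −0.02 margin at ψ = −1 (linear extrapolation would demand a
deflection deeper than curled shapes can reach). Noise-free specimens
therefore classify back to their true class with zero error, which is
a designed property, not an empirical finding about real data.

**Neck geometry.** Fixed construction constants (nm): neck midline
800 long; rods ±100 lateral, left 500×120, right 350×90 (left longer
and thicker — the asymmetry chirality normalization falls back on);
microtubule edges ±130 lateral; PC 400 long at +150 lateral baseline;
9 SC segments at ±180 lateral, 100 apart, with the chain kinked
between segments 8 and 9 by up to 25° in left-bent cells; two central
bars that track the PC laterally. The DC central microtubule also
tracks the PC's lateral shift (the "rail" of the sliding system), so
its distance to the PC centerline is nearly constant across bend
classes while the left/right distances vary — mirroring the
differential-motion observation the metric exists for.

**Noise and randomness.** Landmark noise: i.i.d. isotropic Gaussian
per coordinate (default 10 nm); no noise model beyond isotropic
Gaussian is claimed. Localizations: uniform along the rod with a
uniform lateral spread of the rod width, isotropic Gaussian jitter
(default 15 nm ≈ STORM localization precision), gamma-distributed
intensities. One master seed; per-specimen streams derived by counter
(SeedSequence spawn keys), so specimen i is identical regardless of
population size. Identical parameters give byte-identical outputs.

**What the generator does not emulate.** Time-resolved beating, 3-D
rod geometry, cell rolling, optical PSF/background in rasterized
images, localization drift or multi-blinking, biological covariates
(sample, bull, buffer). Passing recovery tests therefore demonstrates
the *measurement machinery* is correct and unbiased at realistic noise
scales — not that real sperm obey the affine coupling laws.

## COSA classification

After chirality normalization (mirror iff the PC lies left of the neck
midline; rod-size asymmetry as fallback; error if both markers are
uninformative), D = ȳ/L is thresholded: sharp-left D ≤ −T2, mild-left
−T2 < D ≤ −T1, straight |D| < T1, slight-right D ≥ T1. A rightward
D ≥ T2 is reported as slight-right plus a `SharpRightWarning` rather
than an error or a fifth class — in the population the scheme was
built for, its absence is a finding, and a pipeline should count such
cells, not crash. Left bends get subtype Type 1 when
|head–neck angle| ≥ K = 30° (kink-dominated) and Type 2 otherwise
(kink plus mid-piece bend); the original distinction was qualitative,
so K is a convention and is reported in output metadata. The ȳ-based
statistic was chosen over tip-angle alternatives because ȳ is the
pipeline's own head-frame amplitude measure.

## Rod morphometry from localization clouds

Rod length/width use the 50 %-peak rule on a rendered line profile:
localizations are projected on the rod axis, binned (default 20 nm,
≈ localization precision) with intensity weighting, peaks are found
with a prominence gate of 25 % of the profile maximum (so shot-noise
bumps in the tails never count as the "first" peak), and the extent is
measured between the 50 %-of-first-peak and 50 %-of-last-peak
crossings, linearly interpolated between bin centers and clipped at
the terminal bin edge when the profile never drops below half within
the data. The measurement is exactly invariant to rescaling all
intensities. A raw-range variant (`method="range"`) exists; the
rendered-profile path is the default since line profiles are drawn on
rendered images in practice. 3-D localizations are projected to the
beat plane (the beat is planar); z is retained for extents along z on
request.

## Statistics layer

Implemented from first principles (only chi-square / Student-t tail
probabilities come from scipy): product-moment correlation with
least-squares line and two-tailed p (t, n−2 df); pooled-variance
Student t-test (Welch behind a flag — the pooled form is the common
default when only "unpaired, two-tailed t test" is specified);
Bartlett's sphericity χ² = −(n−1−(2p+5)/6)·ln det R with df
p(p−1)/2, returning +inf with a warning on singular matrices; KMO
from the inverse-correlation partials (exactly 0.5 for p = 2, an
identity used as a test anchor; undefined with an explicit error on an
identity correlation).

EFA uses principal-component extraction by default (the SPSS default,
since the extraction method is otherwise unspecified), with iterated
principal-axis factoring available via ``extraction="paf"``, the Kaiser
eigenvalue-greater-than-1 retention rule with the full scree vector
always reported for judgment overrides, and varimax rotation by
iterated pairwise planar rotations (closed-form optimal angle per
pair, tan 4φ formula) with Kaiser row normalization on by default and
undone after. The rotation matrix is accumulated and orthogonal to
1e−10; communalities are preserved to 1e−10; the criterion being
optimized (raw without normalization, row-normalized with it) never
decreases. Loadings with |value| > 0.40 are flagged significant. No
multiple-testing correction is applied anywhere; p-values carry the
conventional star thresholds 0.05/0.01/0.001/0.0001.

The 21-variable EFA fixture uses the pipeline's own metric set (tail
variables + neck metrics) and planted-factor synthetics; the original
21-variable list is not public, so recovery is demonstrated on known
structure instead.

## Pipeline and problem sizes

`run_pipeline` executes simulate → (optional rasterize + trace) →
tail variables → classify → neck metrics → correlation summary, writes
nm-unit CSVs plus a JSON summary stamped with the config hash and
seed, and is bit-identical under a fixed seed. The default path feeds
generator centerlines directly to the classifier; `trace_images=True`
re-traces every cell from its rasterized TIFF (identical categories on
test populations, ȳ differences below 50 nm). Standard problem sizes
used by the test suite and the acceptance script: 248-cell mixture
populations, 100 cells per class for group contrasts, n = 500 × 21
variables for EFA recovery, 10⁴ specimens for mixture-convergence
checks; these keep the full suite under a minute of compute while
leaving sampling errors far smaller than the tested tolerances.

## Known limitations

* Classification consistency (zero-error round-trip) is guaranteed
  only for the default threshold/geometry pairing; changing T1/T2
  without re-deriving the generator calibration breaks the exact
  alignment (the calibration recomputes automatically for geometry
  changes, but thresholds enter it as targets).
* The tracer assumes one specimen per image and a skeleton whose
  longest path is the flagellum; overlapping cells or tails crossing
  the head are out of scope.
* `profile_extent_50` assumes a profile with at least one
  prominence-significant peak; pathological multimodal profiles with
  sub-threshold peaks fall back to the global maximum.
* The EFA offers no oblique rotations and no maximum-likelihood
  extraction; PCA and iterated principal-axis factoring are the two
  implemented extractions.
* p-values assume approximate normality; the package performs no
  normality transformations.
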