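# Methods

## Coordinate conventions and input assumptions

All surfaces live in a right-handed RAS-like frame: +x toward the
subject's right, +y anterior, +z superior, units mm.  Inputs are pairs of
closed, triangulated *outer* hemisphere surfaces — sulci already filled by
a morphological closing, as produced by standard surface-reconstruction
pipelines — roughly normalized to MNI axes, with an optional per-subject
uniform scale factor mapping normalized back to native space.  Upstream
steps (skull stripping, bias correction, 7-dof normalization, surface
reconstruction) are out of scope; their output is this package's input.

## Measurement pipeline

### Vertex normals

Outward unit normals are the area-weighted average of incident face
normals.  Global orientation is determined from the signed volume, so
meshes wound inward are handled transparently; a zero-area face
contributes zero weight and an isolated vertex is an error.

### Medial-surface identification

A vertex belongs to the medial (inter-hemispheric) surface when its
outward normal points almost straight at the midline: the angle between
the normal and the *medial direction* is below `theta_max` (default 40°).
The medial direction is +x for a left hemisphere and −x for a right
hemisphere.  The sign matters: on a closed hemisphere the lateral pole cap
has normals anti-parallel to the medial direction, and an unsigned
|n·x̂| < cos(40°) criterion would flag it too, feeding the plane fit two
dense vertex clusters ~70 mm off the midline.  Empirically this flips the
smallest-variance direction of the pooled cloud away from x and destroys
the MSP estimate; the signed criterion excludes the caps by construction.
For a surface of unknown side (`side="whole"`), where no medial direction
exists, the unsigned criterion is used.

### Mid-sagittal plane and alignment

The MSP is the total-least-squares plane (centroid + smallest right
singular vector) through the pooled medial vertices of both hemispheres,
restricted to the central `central_fraction` (default 0.5) of the
whole-brain antero-posterior extent.  The restriction matters because
frontal/occipital bending curves the fissure away from a plane precisely
at the ends; the central band is where the planar model holds.  Fitted
normals are stored with a canonical sign (first nonzero component
positive) to remove the ±n ambiguity.

Alignment iterates: estimate the MSP, translate along its normal so the
plane contains the origin, and rotate about the axis n × x̂ by the
plane-to-x-axis angle.  Because the rotation changes which vertices pass
the medial criterion, the step repeats until the residual angle is below
`tol` (0.01°) or `max_iter` (5) is reached; non-convergence is a warning
and the last iterate is used.  On noisy surfaces the re-selection can
leave a residual of a few hundredths of a degree — negligible against the
metric tolerances.

Identifiability: the rotation is recoverable only when the medial surface
is approximately planar.  On a *round* medial cap (e.g. two full
ellipsoids) the angular selection window — defined about the fixed x-axis
— slides over the surface and pins the fitted plane near x̂ regardless of
object pose.  Real fissure walls and the synthetic hemispheres are flat
enough that tilts of several degrees are recovered to < 0.1°.  A rotation
*about* the x-axis leaves the midline plane invariant and is therefore
not identifiable from the MSP at all; it is assumed handled by the
upstream normalization (metrics are nevertheless insensitive to small
such rotations because pole z-differences are small).

### Poles, petalia, shift

The frontal/occipital pole is the raw vertex with extreme y-coordinate
(no interpolation or smoothing); exact coordinate ties resolve to the
lowest vertex index for determinism.  Petalia is the L−R difference of
the pole y-coordinates, shift the L−R difference of the *same* vertices'
z-coordinates, both multiplied by the subject scale factor.  Negative
frontal petalia means the right frontal pole leads; negative occipital
petalia means the left occipital pole trails — the human-typical RF/LO
pattern makes both negative.

A consequence of the definitions worth stating explicitly: the poles are
the y-extremes of each hemisphere, so the L−R length asymmetry satisfies
ΔL ≡ petalia_frontal − petalia_occipital *identically*.  Published human
cohort values respect this (−0.67 − (−1.58) = 0.91 ≈ 0.92), and the
synthetic generator enforces it in its stored ground truth.

### Bending

Per hemisphere, medial vertices in the first (frontal) and last
(occipital) `quarter_fraction` (default 0.25) of the whole-brain y-extent
are fitted with a TLS plane; bending is the angle between the plane
normal and the x-axis.  The sign is taken from the normal's y-component
such that a fissure deviating toward the subject's right at its
frontal/occipital extreme is positive in both regions (the y-sign rule is
opposite in the two regions because "toward the extreme" reverses).  The
two hemispheres' angles are averaged per region.  This makes the
human-typical rightward occipital bending positive; the convention is
enforced by the mirror anti-symmetry tests.

### Configuration labels and prevalence

For petalia and shift, the frontal letter is L when the left pole leads
(frontal value > 0) and R otherwise; the occipital letter is L when the
left pole trails/drops (occipital value < 0) and R otherwise.  For
bending the letters name the direction of the bend itself (rightward
positive ⇒ R).  Under all three rules the published human-typical values
land in the published modal quadrants (RF/LO petalia and shift, RF/RO
bending) and labels swap L↔R under mirroring.  Exact zeros are resolved
deterministically (frontal → R, occipital → L) and flagged as ties, so
prevalence denominators always equal the cohort size.

### Cohort statistics

One-sample two-tailed t tests (t = mean/(sd/√n), df = n−1) accept either
raw values or published (mean, sd, n) summaries.  Species prevalence
comparisons collapse each cohort to a quadrant-of-interest versus the
rest and apply the Pearson chi-squared statistic on the 2×2 table
*without* continuity correction — with correction the reconstructed
published statistics (14.85, 22.63) are not reproduced.  Published
configuration counts are reconstructed from prevalence percentages as
round(p·n), which lands on exact integers for the stored tables.
Pearson correlations use the exact t-based p-value on n−2 df.
p-values come from the exact t and chi-squared distributions (scipy).

## Synthetic data generator

Each hemisphere is a half-superellipsoid (|x/a|^p + |y/b|^p + |z/c|^p = 1,
default exponent 2.5, semi-axes 67 × 87 × 59 mm, matching human
whole-surface dimensions of roughly 136 × 174 × 118 mm), cut at the
midline, closed with a flat medial wall and offset laterally by a 1 mm
half-gap so the two walls are distinct, as the inter-hemispheric fissure
separates real outer surfaces.  There is no gyrification by design: the
pipeline consumes closed outer surfaces on which sulci are already
filled.

Deformations are composed so that a perfect measurement reads back the
requested parameters:

- **Petalia/shift**: per-hemisphere y/z displacement fields of ±p/2,
  ramping with a smooth cosine from zero at 40% of the y-extent from each
  pole to full at the pole.  Mid-brain — and with it the MSP band — stays
  undeformed, so torque injection and alignment do not confound.
- **Bending**: both hemispheres receive a lateral displacement
  tan(θ)·(distance past the quarter boundary), so the medial walls
  themselves tilt by exactly θ in the fitted region.  Because the bent
  wall crosses the midline (that is what bending *is*), it would widen
  the bent hemisphere's bounding box; the lateral 80% of that hemisphere
  is compressed back to its pre-bend width so the dimensional ground
  truth stays independent of the bend parameters.  The wall, poles and
  MSP are untouched by the compression.
- **Dimensional asymmetry**: anisotropic scaling of the left hemisphere —
  about its medial wall in x, about its centre in y and z.  The pole
  displacement this induces is folded into the petalia targets and the
  realized values are stored as ground truth (see the ΔL identity above);
  `delta_length` itself acts as an additional symmetric stretch and is
  not drawn independently in the cohort regimes.
- **MSP tilt**: a rigid rotation about z, emulating residual registration
  error; `global_scale` scales the whole geometry (brain size) while the
  injected asymmetries remain absolute mm/degrees.
- **Noise**: a spatially smooth Gaussian displacement field (sum of 24
  random plane waves, wavelengths 20–50 mm, pointwise SD = `noise_sd`).
  Independent per-vertex noise is *not* used: real segmentation error is
  spatially correlated, and white noise lets the pole argmax jump between
  near-tied vertices several mm apart in z on any practically sized mesh,
  producing shift outliers that no real surface exhibits.

Cohort regimes draw per-subject parameters from normal distributions
parameterised by the published cohort summaries: the *human-like* regime
uses the published human means; *chimp-like* is centred on zero (no
population-level torque) at 0.64 linear size; *null* keeps the human
spreads with zero means (for type-I calibration).  Where a summary SD was
not published it is recovered from the printed t statistic as
sd = |mean|·√n/|t|.  Defaults chosen once as realistic study conditions:
residual MSP tilt ~ N(0, 1.5°), surface noise SD 0.25 mm, mesh resolution
48 (azimuthal vertices; tests and the acceptance script use 32 to keep
run times in seconds — measurement error is already far below the metric
tolerances at that density).

### What passing tests do and do not show

The synthetic cohort demonstrates that the *measurement* pipeline is
unbiased (measured-vs-injected slopes ≈ 1, r > 0.95) and that alignment,
mirroring and size sweeps behave as the theory requires.  It does not
demonstrate robustness to features absent from the generator: real
fissures are curved surfaces rather than tilted planes, real hemispheres
differ in local shape (not just in the nine injected parameters), and
real noise includes segmentation topology errors.  Conclusions about real
cohorts rest on the published summary statistics, which the package
reproduces exactly from the printed tables.

## Numerical choices and degenerate inputs

- TLS plane fits use SVD; collinear/coincident points (second singular
  value ≈ 0) are an error, as is a medial selection below 50 vertices or
  an empty regional band.
- Watertightness is checked but only warned about: reconstructed outer
  surfaces are closed, but partial fixtures need not be.
- All internal values keep full precision; rounding (default 2 dp)
  happens only when serialising CSV reports, with a JSON sidecar
  retaining full precision and the producing configuration.
- Seeds: cohorts are deterministic given the spec seed; each subject's
  noise seed is derived from it (kept below 2³¹).

## Known limitations

- The MSP model is a plane; a curved midline surface is only approximated
  (mitigated by the central-band restriction, but a strongly S-shaped
  fissure would bias the fit).
- Poles are single raw vertices; on very coarse meshes the discrete pole
  can sit a vertex away from the continuous extremum.
- Rotation about the antero-posterior axis is not identifiable from the
  MSP (see above).
- The frontal bending sign rule mirrors the occipital one ("rightward =
  positive"); published data do not pin the frontal convention, so
  cross-study comparisons of frontal bending signs should check
  conventions first.
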