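# Methods

## Silhouette pipeline

The pipeline assumes a fixed camera viewing the walkway from below (or
above) with the walkway axis along image columns, a static background
image of the empty walkway, and 8-bit RGB frames (grayscale inputs are
promoted to three identical channels). Frame indices are 1-based, matching
the "first frame" convention of walkway paw logs.

**Analysis window.** The window runs from the first frame at which both
hind paws have been detected to the last frame at which both front paws
are still detected. This brackets the interval in which the whole animal
is on the recording area. An empty window (f_start > f_stop) and a paw
that never appears are hard errors.

**Foreground.** A pixel is foreground when its absolute difference from
the background exceeds the threshold (strictly) in at least one RGB
channel. The default threshold of 10 intensity counts avoids noise
oversensitivity at typical walkway contrast; it is a species-profile
parameter.

**Tail removal.** Morphological opening with a diamond structuring element
(all pixels within Manhattan distance r_d of the origin). The physical
radius is 9 mm for rats and 5 mm for mice, converted to pixels with
half-up rounding of r_d_mm / x_mm (minimum 1): 9 mm at 1 mm/px gives 9 px,
5 mm at 0.7 mm/px gives 7 px. Opening removes every structure narrower
than the element — the tail — while the diamond shape preserves the
rounded body outline well.

**Cleanup.** Holes are filled (background regions not 4-connected to the
image border) and the largest 8-connected component is kept; 4-connectivity
for holes and 8-connectivity for objects are the standard complementary
pair. Equal-size components are resolved toward the one whose first pixel
occurs earliest in row-major scan order — arbitrary but deterministic.

**Measurement.** The length is the Euclidean distance between the
rightmost and leftmost silhouette pixels along the walkway (column) axis,
with r_d subtracted from the column span before the distance is formed:
after opening, the silhouette typically protrudes about one element radius
into the tail-root area, because the tail root is about as wide as the
element (that is what r_d is matched to). In each extreme column the
endpoint row is the one nearest the silhouette centroid row (lower row on
ties) — the choice only matters for near-vertical edges and keeps the
measurement orientation-robust. A negative column span after the r_d
correction (degenerate, tiny silhouettes) clamps the length to zero. The
formula subtracts r_d from the column term only; for an animal walking
diagonally this under-corrects slightly, which is accepted as part of the
method.

Areas are pixel counts times the pixel area x_mm·y_mm. The without-tail
area uses the final opened mask; the with-tail area uses the hole-filled
largest component of the raw foreground (tail kept), so that stray noise
blobs do not inflate it.

**Run aggregation.** Per-frame lengths and areas are aggregated by taking
the maximum over the window — the animal is fully stretched in at least
some frames, and the maximum is insensitive to frames where it is curled.
Frames yielding no silhouette are skipped with a warning; only a window
with no usable frame at all is an error.

## Scaling

Eleven parameters are scaled: front/hind stride length (cm), front/hind
stand, swing and step-cycle times (s), body speed and front/hind swing
speed (cm/s). Left/right paw values are averaged first (body speed over
all four paws). Methods:

| method  | denominator          | note                                  |
|---------|----------------------|---------------------------------------|
| length  | silhouette length, cm| stride becomes dimensionless, speed 1/s |
| froude  | √(g·l_sil), cm/s     | speed parameters only; dimensionless  |
| area    | silhouette area, mm² |                                       |
| weight  | body weight, g       |                                       |
| age     | age, weeks           |                                       |

Gravity is expressed as 981 cm/s² so cm/s speeds and cm lengths stay
coherent in one place. Scaling is applied per run with that run's own
denominator, and the scaled values are then averaged per animal and age
point — not the other way round; with heterogeneous runs the two orders
differ and the per-run order is the contract. The weight–silhouette-length
index I_WSL = w / l_sil² (g/cm²) is computed from the animal-mean weight
and length. Body weights are treated as session metadata (no interpolation
between weighing and gait acquisition dates).

## Statistics

* **Correlation**: sample Pearson r with the exact two-sided p from the
  t transform on n−2 degrees of freedom (scipy); constant vectors and
  n < 3 are rejected rather than silently returning NaN.
* **Repeated-measures ANOVA** (one within-subject factor): classical
  sums-of-squares decomposition, F = MS_levels / MS_(levels×subject).
* **Mixed ANOVA** (genotype between, age within): split-plot decomposition;
  the genotype effect is tested against subject-within-group variation,
  age and interaction against the within-subject error. Implemented
  directly (about thirty lines of sums of squares) because the
  lower-bound sphericity adjustment reported here — ε = 1/(k−1), the most
  conservative correction, applied to both numerator and denominator
  degrees of freedom of within-subject effects — is not exposed by the
  usual packages; the unadjusted results are cross-checked against
  pingouin in the test suite. With k = 2 within levels the adjustment is
  the identity.
* **Complete cases**: all within-subject analyses use only animals
  measured at every age point.
* **Post hoc**: per age point, two-sided two-sample t tests of transgenic
  vs wild-type animal means with pooled variance (Welch is available via a
  flag), Bonferroni-corrected by the number of age points
  (p_adj = min(1, p·m)). Results are summarised as a parameter × age
  matrix of signed −log₁₀(p_adj), positive where the transgenic group is
  higher; cells with fewer than two animals in a group are NaN. p values
  below 1e-300 are floored for display only.

## Synthetic data

**Renderer.** The body is an ellipse with half-disk caps at nose and rear
(cap radius = half body width), drawn in physical millimetre coordinates
so anisotropic pixels are handled; the tail is a quadratic Bézier ribbon
leaving the rear cap along the body axis and curving away, tapering from
just under the structuring-element width at the root to a few pixels at
the tip, with one exact structuring-element footprint stamped at the tail
base. That stamp makes the geometry consistent with the measurement
model: opening retains exactly the footprint (the silhouette protrudes
into the tail by exactly r_d) and removes the rest of the ribbon, so the
r_d-corrected length equals the nose-to-tail-base ground truth up to
rasterisation (observed error ≤ 1.3 px across 80–260 mm bodies). A small
interior hole is carved (exercises hole filling) and a distractor blob
wide enough to survive opening is added (exercises largest-object
retention). Additive uniform pixel noise stays below half the foreground
threshold, so masks are deterministic given the geometry. Body contrast,
resolution, orientation jitter and motion per frame are configurable; the
paw log marks front paws on frames 1..n−1 and hind paws on 2..n so the
analysis window selects the interior frames.

What the renderer does **not** emulate: paw prints, limb motion, fur
texture, illumination gradients, reflections, motion blur, or foreground
contrast near the threshold. Passing the recovery suite therefore shows
the geometric correctness of the pipeline, not robustness to real-world
segmentation noise.

**Cohort generator.** A two-genotype longitudinal design patterned on a
rat aging study: five age points (10–42 weeks), 16 animals per genotype,
3 runs per animal and session. Each animal carries a persistent size
offset (sd 8 mm) around a growth trajectory (190→240 mm); per session a
small wobble (sd 3 mm) is added. Gait parameters follow dynamic
similarity: stride ∝ length, speeds ∝ √length (so Froude scaling, not
length scaling, fully flattens speeds), durations independent of length;
all with multiplicative log-normal noise split into a session-level
biological component (sd 0.08) and a run-level component (sd 0.05).
These defaults put the non-scaled animal-level stride-vs-length
correlation near 0.7, a rat-like regime. The couplings are expressed as
exponents (`stride_length_exp`, `speed_length_exp`), so a fully uncoupled
null cohort is expressible by setting them to zero. Genotype effects enter as a
length factor (size-driven differences) and/or direct per-parameter
factors. Weight follows a cube law in length (≈ 420 g at 22 cm, noise sd
0.05); silhouette readings add 1% multiplicative measurement noise. Left
and right paw columns are split symmetrically around each run value
(sd 0.02) so left/right averaging is exercised. The generator does not
enforce the kinematic identity swing speed = stride / swing time; the
parameters are generated marginally.

## Numerical choices and limitations

* Strict inequality at the foreground threshold (a difference equal to
  the threshold is background).
* Half-up rounding for the mm→px element radius; minimum radius 1 px.
* Morphology via scipy.ndimage with zero padding outside the frame; the
  test suite pins all three stages pixel-exactly to a brute-force
  set-arithmetic oracle.
* The method measures length along the walkway axis; animals turning
  around mid-run violate the assumption and will be under-measured in
  those frames (mitigated by the run-level maximum).
* Problem sizes in the validation suites (50 renders of 3–4 frames each,
  cohorts of 32–40 animals, 200-replicate ANOVA simulations) were chosen
  as the smallest designs at which the properties under test are stable.
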