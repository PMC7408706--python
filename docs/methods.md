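# Methods

## Problem

When a dental technician starts CAD modelling on an intraoral scan, the
scanned mesh (ME) of each implant scanbody is replaced by the
manufacturer's exact CAD model, the library file (LF), via a best-fit
superimposition.  Any dimensional incongruence between ME and LF turns
into a positional error of the implant in the virtual model, which
propagates into the fit of long-span prostheses.  This package quantifies
that congruence: it registers a scan mesh onto the library reference,
measures the signed point-to-surface deviation field in micrometres, and
analyses a full multi-scanner study of such measurements.  Because raw
scan meshes from the benchmark study are not public, the package ships a
synthetic-scan generator whose error signatures play the role of the five
scanners, plus the study's published cell-level summary table for the
parts of the analysis that are exact functions of it.

## Reference geometry and the synthetic scan model

The library file is a parametric solid: a cylinder of height 13 mm
(bounding-box height is exact by construction) and shaft radius 2.5 mm,
cut by one or more flat reference faces (default one face, 4 mm wide),
with a 45-degree chamfered top (0.6 mm).  The mesh is a structured
extrusion at a target edge length (0.35 mm by default, ~1.8k vertices;
0.1 mm gives ~20k vertices for registration benchmarks), closed and
outward-oriented; closedness is verified by the two-faces-per-edge
winding test.  Three named regions partition the faces: `flat_central`
(the middle third of the flat-face width), `flat_lateral` (the rest of
the flat face) and `back` (cylindrical shaft, chamfer and caps).  The
central band being the middle third is a package choice; the band width
is the natural parameter to change.

A simulated scan applies, in a fixed order:

1. **manufacturing tolerance** — one signed offset along the vertex
   normals, fixed per physical scanbody and bounded by ±20 µm; in a study
   the six offsets are drawn once (uniformly on ±20 µm) and shared across
   scanners and replicates, exactly as six physical posts would be;
2. **scanner signature** — a mean normal offset (positive = the scan
   grows outward and the library ends up inside it; negative = the scan
   shrinks inward), optionally region-dependent;
3. **Laplacian smoothing** — a surrogate for reconstruction
   post-processing (λ = 0.1 per iteration).  It rounds sharp rims by tens
   of micrometres and shrinks curved regions slightly, the mechanism that
   plausibly underlies inward-biased scanners.  Stronger smoothing
   (λ ≥ 0.5) deforms the rims by hundreds of micrometres and makes
   registration unstable, so the default is deliberately mild;
4. **observation noise** — i.i.d. Gaussian displacement along the vertex
   normals (per-scanner SD, 14–30 µm in the shipped profiles);
5. **rigid jitter** — a random pose (SD 1 degree, 200 µm in the shipped
   profiles), recorded in the mesh metadata so ground truth is always
   recoverable.

Random streams are split per (scanner, model, scanbody) from the master
seed, so adding replicates never perturbs existing ones.

The five shipped profiles — one outward (+24 µm), three inward (−22, −30,
−36 µm) and one mixed (0 µm mean, 30 µm noise) — reproduce the
qualitative signature classes reported for commercial intraoral scanners
and land per-cell mean absolute deviations mostly in the 20–50 µm band
(the full-study cells span ~13–53 µm once the ±20 µm manufacturing draw
is added).  What the generator does **not** emulate: stitching drift
across the arch, reflectance- and angle-dependent noise, partial
coverage/holes, and real reconstruction algorithms.  Passing tests
therefore show that the measurement and statistics chain is correct under
controlled error models, not that any physical scanner behaves this way.

## Registration

Superimposition follows the two-stage clinical workflow.  The coarse
stage is a three-point landmark alignment solved in closed form
(SVD-based orthogonal Procrustes with determinant correction); synthetic
landmark picks add 0.15 mm operator noise.  The fine stage is
point-to-plane ICP: area-weighted points sampled once from the moving
scan (seeded), exact nearest points on the reference surface, and a
weighted 6×6 small-angle linear solve per iteration with
re-orthonormalisation of the composed rotation.  The protocol runs at
least 100 iterations per superimposition (configurable), stopping after
that only when the RMS residual change falls below 1e-4 µm.

Nearest-point queries are exact: a KD-tree over face centroids proposes
candidates, per-face bounding radii turn centroid distances into rigorous
lower bounds, and unresolved points fall back to a certified ball search.
Oversized faces (radius > 2.5× the median, e.g. cap fans) are screened
separately with their individual radii so they cannot loosen the bound.
The accelerated result equals the brute-force all-triangles minimum, and
is tested as such.

**Robust weighting.**  Residuals are median-centred before weighting, so
a uniform offset — the very signal being measured — counts as consensus
rather than as outliers.  The default scheme is Huber with a widened
linear zone (c = 2.0) on a MAD scale floored at 5 µm.  Two failure modes
drove those choices, both observed empirically on this geometry: (i) a
hard-redescending weight (Tukey biweight) can reject the flat face — the
only constraint on rotation about the post axis — once the pose drifts
slightly, after which the near-symmetric cylinder slides freely
(millimetre-scale runaway); Huber's bounded but never-vanishing influence
anchors those weak modes while still capping the pull of gross outliers.
(ii) on a nearly noise-free offset surface the MAD collapses to numerical
curvature jitter and the inlier band becomes meaninglessly thin; the 5 µm
floor (well below any realistic scan noise) prevents that.  Tukey
(c = 4.685) remains available via configuration and is the right choice
when the geometry is well-constrained and outliers are gross; the test
suite exercises both.  If robust weighting ever concentrates on a planar
subset, the iteration falls back to unit weights before declaring the
problem degenerate.

Two intrinsic limits are worth knowing.  Offsetting vertices along
averaged vertex normals shortens true distances at sharp rims, so even
with no noise the least-squares pose optimum for a ±30 µm offset surface
sits ~3 µm from identity at the default tessellation; the registration
tests bound the pose error at 5 µm / 0.1 degree for that case, i.e. the
offset is not absorbed into the pose.  And a scan trimmed to the shaft
only (no caps, no chamfer) has no axial constraint at all; this is
detected and raised as an ill-conditioned registration.

## Deviation measurement and classification

After registration every scan vertex (or, optionally, a seeded surface
sample matching the ICP sampler) gets its exact distance to the reference
surface, signed positive on the outward-normal side of the nearest
reference triangle.  The headline congruence statistic is the mean of the
**absolute** deviations with its SD, median, quartiles (linear
interpolation), range, and a normal-approximation 95% CI; the signed mean
is retained for directionality.  The colorimetric classification uses a
±50 µm display scale with a ±1 µm green band: samples above +1 µm are
"outward", below −1 µm "inward", otherwise "none".  A region's direction
label is the majority class, ties resolving to "no deviation".  The
study-level qualitative table maps label fractions to predominance
symbols: 0 → blank, ≤ 0.25 → "+", ≤ 0.60 → "++", else "+++".

## Statistics

The study table is long-format: one row per (scanner, scanbody, model)
with the superimposition's mean absolute deviation in µm; the working
significance level is α = 0.01 throughout.

* **Descriptives** per cell: n, mean, SD, median, Q1–Q3; cells with fewer
  than two replicates are reported absent, never imputed.
* **Scanner estimates** use the balanced two-level identity: with a
  balanced design the scanner mean equals the unweighted average of its
  six cell means, which makes point estimates exact without a REML fit.
  The per-scanner CI uses the between-scanbody spread of the cell means
  (t, 5 df); the total observation-level SD (within + between cells) is
  reported alongside.
* **Scanner contrasts** are Tukey-adjusted via the studentized-range
  distribution.  The error term is the scanner × scanbody interaction
  mean square of the cell-mean layout (df = (k−1)(b−1)); since the six
  physical posts are shared by all scanners, scanbody main effects cancel
  in scanner differences and the interaction is the appropriate error.
  Under a shared-block null simulation this controls the significant-pair
  rate well below α.  Confidence limits are therefore not expected to
  match a mixed-model fit's exactly; point estimates are.
* **Scanbody contrasts** within each scanner are cell-mean differences
  (the balanced two-way-with-interaction estimates), Tukey-adjusted over
  the 15-pair family with the pooled within-cell mean square.
* **Friedman tests** compare model replicates within each scanner with
  the scanbody as block, computed in closed form (average ranks, standard
  tie correction, χ² approximation) so the two-treatment case works;
  SciPy's implementation is the independent oracle in the tests.  Holm
  adjustment runs across the scanner family.
* **Outlier flagging** defaults to a robust z-score (median/MAD,
  consistency constant 1.4826, threshold 3) within each cell, falling
  back to leave-one-out z when the MAD is zero.  A plain within-cell
  z-score is bounded by (n−1)/√n ≈ 2.85 at n = 10 and can never flag
  anything at threshold 3, which is why the robust form is the default.
  Flags are meant to exclude rows from parametric estimation only.
* **Biclustering** clusters rows and columns of the scanner × scanbody
  matrix independently (Euclidean distance, average linkage by default —
  the common heatmap convention; both configurable).  SciPy's
  deterministic merge order makes results reproducible.

## Problem sizes and runtimes

The package's reference experiments, as run by the analysis scripts, the
acceptance script and the test suite: the full-scale study uses 5
profiles × 10 models × 6 scanbodies = 300 superimpositions at the default
0.35 mm tessellation, 100 ICP iterations each at 600 sampled points
(≈ 6–7 minutes on one CPU); registration recovery uses the 0.1 mm
(~20k-vertex) tessellation with 4000 samples; the offset-recovery sweep
runs 6 offsets × 10 seeds with 30-iteration ICP at 400 samples; the null
calibration simulates 500 table-level studies of 3 scanners × 5 models.
Table-level simulation is used where mesh simulation would add nothing
(pure statistics calibration).

## Known limitations

* One-directional correspondence (scan → reference); whether a symmetric
  two-way distance would change results is testable via the sensitivity
  flag in `signed_deviation` (swap the roles) but is not the default.
* The CI on the congruence summary is a normal approximation; quantile
  bootstrap would be more faithful for skewed fields.
* The mixed-model contrasts are exact only for balanced designs; with
  missing cells the balanced identity no longer holds and the battery
  refuses rather than approximates.
* Scanner signatures are stylised (constant mean offset + noise +
  smoothing); real scanners show spatially structured error the generator
  does not model.
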