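# Methods

This note documents the models, conventions and numerical choices behind
the package, and what the synthetic testbed does and does not show.

## Label maps and boundary geometry

A grading of a B-scan is an H×W grid of compartment codes
(0 vitreous, 1 retina, 2 choroid, 3 sclera), or equivalently three ordered
per-column boundary rows (ILM, CCi, CSI). Conventions:

- 0-based indexing; row 0 is the image top (vitreous side), matching the
  raster order of exported B-scans.
- Half-open compartment intervals: a boundary row belongs to the
  compartment **below** the line, so the vitreous lies strictly above the
  ILM. Annotation tools draw one-pixel-wide lines without specifying which
  compartment owns the line pixels; this convention absorbs the line into
  the lower compartment and is stated explicitly because either choice is
  defensible.
- Boundaries may touch (zero-height compartments) in degenerate or
  synthetic inputs. Ensemble-level analysis emits a warning when a map
  lacks a compartment entirely, since studies of this kind include only
  scans showing all four compartments.
- Maps are analyzed at their stored size; no resizing or resampling of
  labels is performed (label interpolation is ill-defined and any choice
  would silently move boundaries).

PNG label files store the codes directly as 8-bit pixel values; a palette
mapping codes to display colors (vitreous orange, retina blue, choroid
yellow, sclera gray) is optional and purely cosmetic — readers decode by
palette index, never by color.

## Hamming distances

The overall distance is the fraction of pixels labeled differently; the
per-compartment distance is the Hamming distance of the binary membership
maps of one compartment with the **same** H·W denominator. This deliberately
ignores compartment size: a 5-row shift of the CSI costs the same number of
differing pixels whether the choroid is thick or thin. The identity
Σ_compartments d_c = 2·d_overall (each differing pixel flips exactly two
binary maps) is enforced as a property test. Distances are stored as
fractions; percent formatting (2 decimals) happens only in reporting.

With k graders and one model over N scans, per-scan distances for all pairs
form the distance table; pooled group means average all 3N values per group
directly (with a complete N-scan design this equals the mean of per-pair
means). The "fraction of scans where the model is closer" compares the mean
of the three grader–model distances with the mean of the three inter-grader
distances per scan, with strict inequality: ties count as not-closer.

## Metric MDS

Mean distances are embedded in 2D by Torgerson classical scaling (double
centering of squared distances, top-2 non-negative eigenpairs) followed by
SMACOF majorization on raw stress, iterated until the relative stress change
falls below 1e-9 or 300 iterations. Majorization is monotone, so stress
never increases; for matrices realizable in the plane the final Kruskal
stress-1 is below 1e-6, and for generic 4-point matrices a small positive
stress is the expected outcome — the contract is stress minimization, not
exact recovery. The procedure contains no randomness; the `seed` argument
is recorded for provenance only.

Because MDS is defined only up to rigid motions, coordinates are
canonicalized: centroid at the origin, first grading on the non-negative
x-axis, second grading with non-negative y. This makes outputs comparable
across runs and implementations.

## Permutation test

Group A pools all inter-grader distances, group B all grader–model
distances, for one scope at a time. The statistic is mean(A) − mean(B).
Each Monte-Carlo resample re-splits the pooled values into groups of the
original sizes uniformly at random (per-row Fisher–Yates shuffles of the
pooled index list, vectorized in chunks). One-sided p-values use the
add-one estimator (count + 1)/(B + 1); resampled statistics exactly equal
to the observed value count as exceedances; the two-sided p is twice the
smaller tail capped at 1. Consequently the smallest attainable two-sided p
is 2/(B + 1) — with the conventional B = 99,999, exactly 2e-5. The reported
99% interval for p is a Clopper–Pearson interval on the smaller-tail
exceedance proportion, doubled and clipped to [0, 1]; with zero exceedances
it evaluates to approximately (0, 1.06e-4). This is one reasonable
convention among several; it is implemented explicitly so it can be
audited.

An exhaustive variant enumerates all C(|A|+|B|, |A|) assignments (bounded
at 10^6) with the same tie rule and no add-one correction; it serves as the
correctness oracle for the Monte-Carlo estimator and for small worked
examples. Distances from the same scan are not independent; the test
permutes individual pooled values regardless, as is conventional for this
design, and the p-value should be read accordingly. No multiple-testing
correction is applied across the five scopes; results are reported per
scope. t-tests are deliberately not offered: the distance distributions are
strongly skewed.

Degenerate inputs (all distances equal, e.g. identical gradings) yield an
observed statistic of 0 that ties with every resample, so p = 1 — reported
as such rather than as an error.

## Boxplot summaries

Quartiles use linear interpolation. The upper whisker extends to the last
datum strictly less than Q3 + 1.5·IQR, the lower whisker to the first datum
strictly greater than Q1 − 1.5·IQR; data beyond the whiskers are outliers.
For constant data no datum is strictly inside the fence and the whiskers
fall back to the quartiles, giving whisker = constant and no outliers.

## Synthetic scene simulator

The simulator emulates the *geometry and ambiguity structure* of
multi-grader OCT compartment annotation, not OCT intensity images:

- **Truth**: each boundary of each scan is its centerline plus a smooth
  sinusoidal undulation (amplitude 12 rows, 1.5 periods per width, random
  phase per scan and boundary), rounded to integer rows. Default grid
  512×512 with centerlines at rows 160/250/310.
- **Graders**: truth + a constant per-boundary bias + stationary Gaussian
  noise smoothed by a circular moving average over `correlation_length`
  columns (so errors are spatially coherent like hand-drawn lines), rounded
  to integer rows (annotation lines are pixel-accurate), clipped to the
  grid, re-sorted per column to restore ordering.
- **Model**: a per-column weighted average of the graders' boundaries,
  rounded and re-ordered — the "robust average" behavior a network trained
  on multiple teachers exhibits.

Default profiles place almost all disagreement on the CSI (biases +5/0/−5
rows), small offsets on the CCi (0/+1/−1) and ILM (0/+0.5/−0.5), and noise
of 1.0–1.5 rows with correlation length 48. These were chosen once by
closed-form folded-normal arithmetic (E|Δ| of pairwise boundary offsets
divided by H) to land in the regime reported for real expert graders on
healthy retinas: overall inter-grader mean ≈ 2%, vitreous and retina pair
means < 0.7%, disagreement dominated by the choroid–sclera interface. The
consensus weights default to (0.4, 0.4, 0.2), reflecting two experienced
graders and one less-experienced one.

What passing tests on this testbed show: that the pipeline's measurements,
embeddings and tests recover known, planted structure (bias rankings,
consensus placement, significance at the floor) and obey their analytic
laws exactly (Σ|Δbias|/H for zero-noise flat scenes). What they do not
show: behavior under real OCT artifacts — speckle, signal loss in
pigmented eyes, pathology, grader fatigue or drift — none of which the
simulator models.

Sub-seeding is stable: per-scan, per-grader streams are derived from the
top-level seed, the scan index and a CRC of the grading id, so adding a
grader never perturbs existing gradings.

## Training-set augmentation

The augmentation utility triples a labeled set: originals + a mirrored copy
of each + one randomly rotated copy of each (angle uniform on [−8°, 8°]).
"Vertical mirroring" is interpreted as a left–right flip about the vertical
axis, which maps plausible retinal anatomy to plausible anatomy; the axis
convention is stated because "vertical mirror" is ambiguous. Label maps are
rotated with nearest-neighbor resampling and edge-clamp fill (there is no
background class to fill rotated-in corners), intensity images with
bilinear interpolation. 675 inputs yield 2025 outputs.

## Problem sizes and determinism

Test and acceptance runs use reduced problem sizes chosen to keep the suite
quick while preserving every counted or asserted structure: the parameter
recovery scenes use 128×128 grids with 24 scans, the 200-scan design checks
use 128×128 grids (group sizes depend only on the design, not the grid),
and full 512×512 scenes are exercised with up to 50 scans. All randomness
flows through explicit seeds; re-running any pipeline stage with the same
inputs and seed reproduces CSV/JSON outputs byte for byte.

## Known limitations

- Boundary-line inputs assume exactly three lines and four compartments;
  the metric layer itself is class-count agnostic but the I/O and synthetic
  layers are specific to this anatomy.
- The permutation test treats the 3N pooled values as exchangeable even
  though triplets share a scan (see above).
- MDS is fixed at 2 dimensions and metric (no non-metric variant).
- The simulator's graders have stationary behavior; real graders drift and
  disagree more on pathological scans.
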