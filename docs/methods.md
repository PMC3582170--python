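# Methods

## The measurement model

`cordstereo` implements design-based (assumption-free) estimation of
cross-sectional areas and volumes of a sectioned, multi-segment organ from
point counts on labeled images, together with the descriptive and
comparative statistics conventionally reported alongside such morphometry.

A segment of length L is cut into slabs of constant thickness T with one
uniformly random first cut u ~ U[0, T); for a sampling fraction 1/k every
k-th slab is kept (random phase), and one measurement section is taken near
the cranial face of each kept slab at a random choice among the first 30
microtome sections of 10 µm. Because the start is uniformly random and the
spacing constant, the section series is a systematic uniform random sample
and the Cavalieri sum V = t · ΣA(zᵢ) is unbiased for the volume, where t is
the *post-processing* distance between consecutive kept sections.

Area per section is estimated by point counting: a square lattice with
spacing √(a/p) and a uniformly random offset is overlaid on the image, and
a point hits a compartment when the pixel containing it carries one of the
compartment's labels (raster lookup, no sub-pixel geometry — this is how
counting is done on scanned section images). Each section is counted three
times with re-randomized offsets; the repeat mean ∑p (possibly fractional)
enters the formulas. Whether repeated counts in practice re-randomize the
grid or re-read one fixed grid is rarely stated; re-randomizing is the
default because it is the variant whose expectation is provably the pixel
area, and a caller can pin offsets for the other reading.

## Parameters and defaults

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| slab thickness T | 3.8 | mm | standard tissue-slicer blade interval for cord-sized organs |
| sampling fraction | 1, 1/2, 1/3 per segment | — | short end segments taken whole, long middle segments subsampled |
| t (post-processing) | 3.4 · k | mm | measured spacing after embedding; an input, never derived |
| a/p GS, WM | 6 | mm² | ~20–40 points on a 120–180 mm² section |
| a/p GM, DH, VH | 0.6 | mm² | ten-fold denser for the ten-fold smaller grey subfields |
| a/p CC | 3 | µm² | the canal is measured on µm-scale imagery |
| repeats | 3 | — | triplicate counting; ∑p is the mean |
| CE shape coefficient | 6 | — | b/√a for an oblong profile; exposed because published CE variants differ |
| CE smoothness divisor | 240 | — | the classical smoothness-class constant; exposed for the same reason |
| Duncan α | 0.05 | — | conventional |

The spacing ratio 3.4/3.8 implies 10.53% longitudinal shrinkage, while the
direct length comparison in the reference material gives 11.91%. These two
figures are deliberately left distinct: t is treated as a measured input to
the Cavalieri formula, and no shrinkage model is allowed to reconcile one
number into the other. The package carries both and flags the gap.

## The phantom

The synthetic organ is an ordered stack of segments whose gross section is
an ellipse with linearly tapering semi-axes; grey matter is four elliptical
horn lobes joined by a small rectangular isthmus, with an elliptical
central canal inside the isthmus. Lobes are placed flush against the
isthmus slab in x and stacked clear of each other in y, so the union area
is an exact sum and every compartment has a closed-form area and volume
(the GS taper integral is quadratic; everything else is area × length).
White matter is *defined* as GS minus grey matter minus canal; since the
measured tables list WM alongside GS and GM without saying how it was
counted, the estimator layer measures WM both ways (its own grid, and by
subtraction) and reports the gap.

The default eight-segment geometry rises in length to a C3 maximum and
falls to C8, widens toward the caudal enlargement, grows the ventral horns
caudally, and flattens the canal toward C7 — chosen so that post-shrinkage
areas and volumes land in the ranges of the published segment tables. It
is a validation harness, not an anatomical atlas: no claim of calibrated
horn shape, no histological texture, no nerve roots, and cross-sections
are axis-aligned ellipses rather than real cord outlines. Consequently,
passing tests demonstrate correctness of the estimators on known geometry,
not fidelity of any particular biological number.

Shrinkage is modeled as three independent linear factors (transverse,
vertical, longitudinal) scaling semi-axes and lengths; volumes scale by the
product of the three survivals. The default factors (0.1418, 0.1666,
0.1191) imply a 37.0% volumetric reduction — intentionally different from
the ~29% obtained by comparing summed pre-embedding volumes with summed
Cavalieri volumes, which demonstrates that anisotropic linear shrinkage
need not reproduce a directly measured volumetric figure.

## Numerical choices

- A section exactly on a segment boundary belongs to the caudal (later)
  segment, matching the convention of cutting in front of the roots.
- Rasterization labels a pixel by the innermost compartment containing its
  centre; pixel-count areas converge to the closed forms as O(pixel).
- The leading partial slab (u > 0) is kept as slab 0 for tissue
  accounting; for measurement it is treated as the clipped tail of a
  notional slab with face u − T, so all section positions lie on one
  uniform lattice. The partial yields a section only when the microtome
  offset falls inside its remaining material; drops happen only at the
  ends, preserving both the constant spacing the Cavalieri sum assumes and
  the uniform sampling density that makes it unbiased.
- `volume_cavalieri` refuses section series whose spacing varies by more
  than 1% of t.
- The CE formula keeps the residual end effect of a constant tally series
  (2P²/240 rather than exactly zero): the three lag sums have n, n−1 and
  n−2 terms, so the second-difference contraction does not vanish
  identically. A negative smoothness term is clipped to zero.
- Duncan critical points come from `scipy.stats.studentized_range` at the
  protection level 1 − (1 − α)^(p−1) (no hard-coded tables; cached per
  (p, df, α) since the quantile is expensive). With MSE = 0 the procedure
  degenerates gracefully: equal means share a letter, distinct means get
  distinct letters.
- Letters are assembled from the maximal homogeneous stretches of the
  descending-mean order (plus singletons), so sharing a letter is exactly
  pairwise non-significance; the step-down recursion and a full window
  enumeration provably mark the same maximal stretches, which the tests
  exploit as an independent oracle.
- Table reproduction rounds half-up at the printed precision, only at
  report time.
- Units are explicit throughout: GS/WM/GM/DH/VH in mm²/mm³; CC areas in
  10⁻³ mm² and volumes in 10⁻³ mm³ (converted explicitly from the µm-scale
  counts); grids and sections carry a length unit and refuse to mix.

## Statistics layer

Group descriptives are mean ± SE (sample SD/√n, n ≥ 2). Duncan's multiple
range test assumes a balanced one-way layout (df = k(n−1)); under the
global null the probability of reporting any separation equals the
protected level of the full-range test, 1 − (1 − α)^(k−1) ≈ 0.30 for eight
groups — the test suite monitors this rate with a ±0.10 band around the
nominal value (Monte-Carlo SE ≈ 0.023 at 400 simulations). Pearson
correlations use pairwise-complete observations with two-sided p-values
and 0.05/0.01/0.001 star coding; the observation unit for pooled
correlations (per animal-segment versus per-segment means) is a caller
choice, and neither pooling is claimed to reproduce any published r.

## Problem sizes

Validation experiments use 500 replicated designs (estimator bias and CE
calibration, ~10 sections each on a 38 mm tapered phantom at 0.05 mm
pixels), 500 random grid offsets (area unbiasedness), 400 null simulations
(Duncan), and 50 random fixtures for the letter-display oracle; the CLI
default renders five animals at 0.05 mm pixels (2 µm for the canal ROI).
These sizes hold Monte-Carlo error comfortably below the tolerances being
checked.

## Known limitations

- The Gundersen–Jensen CE underpredicts the replicate scatter of objects
  whose area profile is nearly constant but which end abruptly, because
  the variance is then dominated by the ±1-section end effect; on the
  smooth tapered phantom the empirical CV and mean predicted CE agree
  within a factor of two, which is the realistic expectation for this
  estimator class.
- Published per-segment CEs cannot be reproduced exactly without the raw
  counts; the package checks order of magnitude only.
- Diameters are axis-aligned caliper extents and assume dorsal-up input;
  principal-axis reorientation is available but is a measurement choice,
  not a registration step.
- The phantom's per-animal variation is a single isotropic size factor
  (CV 5%), far simpler than biological covariance structure; letter
  displays obtained on simulated animals validate the procedure, not any
  anatomical claim.
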