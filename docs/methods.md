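# Methods

This note documents the models, numerical choices and limitations behind
`morphodisp`, in the order the pipeline runs.

## Superimposition

Shapes are compared after removing position, scale and orientation. Each
configuration is centred and scaled to unit centroid size (the root summed
squared deviation from the centroid); GPA then alternates (i) rotating every
configuration to the current consensus by the orthogonal Procrustes solution
restricted to proper rotations and (ii) replacing the consensus by the
renormalized mean, until the consensus moves by less than `tol` (RMS
coordinate change, default 1e-8; `max_iter` 100, non-convergence returns a
flagged result rather than raising). Scale is not re-optimized during the
rotation step (partial Procrustes, unit sizes throughout), which matches the
tpsRelw-style convention of renormalizing the consensus each iteration.

Two deliberate choices:

- **Reflections are excluded** (rotation determinant forced to +1). A
  reflection would silently equate left- and right-facing lateral views and
  fake similarity; inputs are assumed pre-standardized to one facing.
- **The output frame is canonicalized**: the Procrustes fixed point is only
  defined up to a global rotation, so the final frame is rotated onto the
  consensus's principal axes, with the 180° ambiguity settled by the sign of
  the most eccentric landmark's x-coordinate. This makes GPA output
  invariant (to tolerance) under input translation, scaling, rotation and
  ordering — a property the tests assert.

## Semilandmark sliding

Semilandmarks carry curve information but not point identity, so each is
allowed to move along the unit chord between its two topological neighbours
(the tangent). Per specimen, the vector of tangent offsets minimizes the
thin-plate-spline bending energy of the specimen relative to the consensus:
with the bending-energy matrix M (upper-left k×k block of the inverse
bordered TPS system on the consensus, kernel U(r)=r² log r², affine part
annihilated), the offsets solve the restricted generalized-least-squares
system; an ill-conditioned system falls back to plain tangent projection
(logged). After all specimens slide, GPA reruns, and the cycle repeats
(default 10 cycles or consensus movement < 1e-6). The bending-energy
reference is the consensus *updated every cycle* by default; a fixed initial
reference is available (`reference="fixed"`).

Numerical safeguards:

- **Trust region.** The tangent is a linearization of the curve; the joint
  GLS step is scaled back by one scalar factor whenever it would carry any
  semilandmark further than 45% of its local chord. Scalar scaling of the
  step preserves the quadratic model's energy decrease; without it, sliders
  on sparsely sampled curves can run along the outline and the consensus
  degenerates (clustered semilandmarks make the TPS system stiffer each
  cycle and the procedure diverges — observed, and prevented by the limit).
- **Monotonicity.** Within every cycle the slide step cannot increase the
  total bending energy measured against that cycle's reference; the
  before/after totals are logged per cycle (`slide_log`) and asserted in the
  tests. Across cycles the reference itself changes, so a cross-cycle energy
  comparison is not well defined and is not claimed.

## Morphospaces

PCA is computed by SVD of the column-centred data matrix; `mode="correlation"`
additionally standardizes columns (an error for zero-variance columns).
Reported axes: min(n−1, p); eigenvalues below 1e-12 of the largest are
reported as exact zeros; every loading column is signed so its
largest-magnitude entry is positive, making outputs platform-stable. Both
landmark coordinates (shared units) and the five jaw ratios (commensurate
dimensionless quantities) default to covariance mode; correlation mode is a
flag, since for ratio data the choice is a genuine judgement call and the
variance split on the leading axes depends on it.

Shape reconstruction along an axis is linear: consensus + score × loading
(reshaped k×2); at score 0 it returns the consensus exactly.

## Jaw functional characters

Five ratios from seven raw lower-jaw measurements; a character is missing
iff any ingredient is missing; all present values must be positive.
Conspecific specimens are averaged per character over the specimens that
preserve it (pairwise-available mean), so a species loses a character only
when no specimen preserves it. The primary analysis path is complete-case:
on fossil trait tables, regularized-PCA imputation manufactures degenerate
morphospace axes rather than biological signal, so it is deliberately not
implemented.

## Time binning

The default scheme spans 27 Permian–Jurassic stages collapsed to 17 bins
(12 single-stage bins bracketing the two extinction boundaries; combined
early/middle/late Permian, Early Triassic and Middle Jurassic bins where
sampling is thin). Combined-bin membership follows ICS series boundaries;
midpoint ages follow the ICS chart. The scheme is data (`TimeBinScheme`,
YAML round-trip), so alternative schemes — e.g. series-level bins across the
Permo-Triassic boundary — are a config swap. Bins under `min_bin_n`
(default 3) are reported missing for disparity: a two-specimen bin supports
a mean but not a usable spread estimate.

## Disparity metrics and uncertainty

Sum of variances uses the n−1 denominator, which makes the Foote
partial-disparity identity Σ_g PD(g) = total exact (asserted to 1e-12) and
matches common disparity practice. MPD defaults to distances in the common
aligned frame (one joint superimposition, as when distances are read off a
single aligned dataset); per-pair re-superimposition is available
(`method="pairwise"`). Hull content uses qhull; a degenerate hull (too few
or affinely dependent points) is *missing*, not zero — zero would read as a
real collapse of morphospace — and missing bins are excluded from the
series-maximum normalization. Axis-subset presets {2, 5, 20, all} support
the sensitivity analysis over retained axes.

Confidence intervals are percentile bootstrap (1000 replicates over
specimens, same n, seeded): the simplest method consistent with an interval
"around the mean disparity value". Replicates where the metric is undefined
are skipped and counted; more than half skipped yields a missing interval
with a warning. Percentile intervals for a variance at moderate n run
slightly below nominal coverage (the acceptance suite measures coverage at
n=200 against the binomial band around 95%); BCa was considered out of
scope.

## Permutation tests

Both tests re-partition the pooled specimens of two bins into the observed
group sizes. The centroid-shift statistic is the Euclidean distance between
group means in full score space; the disparity-difference statistic is the
absolute metric difference (two-sided — no direction is privileged). Sampled
p-values use the add-one correction (#{null ≥ obs}+1)/(B+1), which cannot be
zero and is exactly valid at any B; when C(n_A+n_B, n_A) ≤ B the null is
enumerated and p is exact, the observed assignment included. Ties count as
≥ observed (tolerance 1e-12). Defaults: 9999 permutations (centroid), 1000
(disparity), α = 0.05, no multiple-testing correction.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
fish anatomy:

- **Landmarks.** A fusiform 28-point closed outline (14 fixed, 14
  semilandmarks on six curves). Each specimen adds six smooth deformation
  modes, Gram–Schmidt-orthonormalized against the translation, rotation and
  scaling directions of the base so planted variance survives the Procrustes
  projection up to a small leakage (the truth output records the planted
  values in pre-projection shape units; the pipeline recovers bin *ratios*
  and *ordering*, which is what the tests assert). Mode amplitudes are
  bin-specific (the planted disparity history), plus isotropic landmark
  noise, plus a random similarity transform for the superimposition to undo.
  Planted per-bin variance: Σ_m σ_m(bin)² + 2k·noise_sd².
- **Study-scale defaults.** 453 body specimens / 365 jaw specimens over the
  17 bins with minimum bin sizes 5 and 2 (both middle Permian), matching the
  sampling structure the binning rules are designed around.
- **Recovery design.** For ordering-recovery checks, amplitudes form a
  geometric ladder with adjacent planted-variance ratio 1.5 spread over six
  equal-weight modes. Rationale: a bin's estimated sum of variances then
  pools ~6(n−1) degrees of freedom, so at n=50 the log-ratio of adjacent
  estimates has SD ≈ √(4/(6·49)) ≈ 0.12 and a 1.5× gap is ≈3.5 SD — exact
  recovery of the 17-bin ordering is the expected single-sample outcome.
  The noise floor is kept below ~3% of the smallest bin's planted variance
  so the ladder is realized.
- **Traits.** Subgroup multivariate normals (a deep-jawed, high
  mechanical-advantage durophage-like cluster among them), cells masked
  missing completely at random at per-character rates (0.02, 0.35, 0.02,
  0.02, 0.45) whose overall expectation is 17.2%, concentrated in the
  posterior-MA and tooth-row characters as preservation dictates. MCAR is a
  simplification: real fossil missingness is preservational and correlated
  within specimens (which is why an empirical table can be 17% missing by
  cells yet retain ~60% complete rows, while MCAR at the same cell rate
  retains ~34%). The complete-case path is indifferent to the distinction,
  so MCAR suffices to test the plumbing — but passing tests say nothing
  about imputation behaviour under informative missingness, which is out of
  scope anyway.

What passing synthetic tests do **not** show: robustness to taphonomic
distortion, curve-resampling of semilandmarks, left/right standardization
errors, or non-MCAR missingness. Retrodeformation and imputation are
explicitly out of scope.

## Reproducibility

Every random stage draws from a generator spawned from one master seed
(`numpy` `SeedSequence` substreams per stage), so changing the replicate
count of one stage does not shift another's draws; reruns with the same seed
produce byte-identical CSV outputs. Problem sizes used by the acceptance
script — 453/365-specimen pipelines, 500 null pairs at n=20/20 with 999
permutations, 100 power repeats, 200 bootstrap-coverage bins, 50
ordering-recovery runs at n=50/bin — are the package's standard validation
sizes and complete in a few minutes on one CPU.
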