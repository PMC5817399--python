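# morphodisp

Landmark-based morphometrics and disparity-through-time analysis for fossil
assemblages, built for the kind of question palaeobiologists ask of
Permian–Jurassic ray-finned fishes: did morphological variety (disparity)
collapse at the Permo-Triassic and end-Triassic mass extinctions, or did the
clade pass through largely unscathed? The package turns digitized 2-D
landmark outlines and lower-jaw functional measurements into per-time-bin
disparity series with uncertainty, permutation tests across extinction
boundaries, and additive subgroup decompositions — and ships a synthetic-data
generator with planted structure so the whole pipeline is testable without
any fossil dataset.

## What it computes

**Superimposition.** Configurations of k landmarks are aligned by
generalized Procrustes analysis (GPA): each is centred, scaled to unit
centroid size, and rotated (proper rotations only) to the iteratively
re-estimated consensus. Semilandmarks — points along body curves whose exact
position carries no anatomical identity — are then slid along their local
tangent to minimize the thin-plate-spline bending energy

E(y) = yₓᵀ L⁻¹ₖ yₓ + y_yᵀ L⁻¹ₖ y_y,

where L⁻¹ₖ is the upper-left k×k block of the inverse bordered TPS system
built on the consensus with kernel U(r) = r² log r². The slide and the GPA
alternate until the consensus is stationary.

**Morphospaces.** PCA (covariance mode by default) of the aligned
coordinates gives the body-shape tangent space; PCA of five dimensionless
jaw ratios (anterior and posterior mechanical advantage, maximum and average
relative jaw depth, relative tooth-row length) gives the functional
morphospace. Missing jaw characters are handled by a complete-case filter —
imputation is deliberately not offered.

**Disparity per time bin.** With scores xᵢ of the n bin members,

- sum of variances: Σⱼ s²ⱼ over the chosen axes (sample variance, n−1);
- mean pairwise distance: mean of all C(n,2) Euclidean (Procrustes)
  distances;
- convex-hull content in the first 2–5 axes, each series normalized by its
  own maximum;

each with a 95% percentile-bootstrap confidence interval (1000 replicates
over specimens). Foote partial disparity attributes a bin's sum of variances
additively to subgroups g via PD(g) = Σ_{i∈g} ‖xᵢ − c‖²/(n−1), with c the
grand centroid of the bin.

**Inference.** Across any bin pair (presets: late Permian vs Early Triassic,
Rhaetian vs Hettangian) a centroid-shift permutation test (NPMANOVA-style,
9999 permutations, all axes) and a disparity-difference permutation test
(1000 permutations) with add-one-corrected p-values; small problems are
enumerated exhaustively for exact p.

## Worked example

Generate a synthetic dataset at study scale (453 specimens, 28 landmarks,
17 time bins), align, ordinate and measure disparity:

```sh
morphodisp simulate --kind body --seed 3 --outdir data
morphodisp align    --tps data/landmarks.tps --sliders data/sliders.csv --out aligned.csv
morphodisp ordinate --tps data/landmarks.tps --sliders data/sliders.csv --out scores.csv
morphodisp disparity --scores scores.csv --metadata data/metadata.csv \
    --bins data/bins.yaml --metric variance --bootstrap 100 --out var.csv
morphodisp test --scores scores.csv --metadata data/metadata.csv \
    --bins data/bins.yaml --bin-a "late Permian" --bin-b "Early Triassic"
```

which prints, among other lines:

```
aligned 453 configurations (3 GPA iterations, converged=True)
56 axes; first two carry 64.1% of variance
   Kimmeridgian variance 0.007786 0.006030 0.009233 32
      Tithonian variance 0.009894 0.008271 0.011432 44
centroid_shift: observed=0.00489768, p=0.986 (999 perms)
```

Reading this: 453 outlines superimpose exactly (the generator plants smooth
shape modes plus digitizing noise); the 56-axis tangent space concentrates
~64% of variance on two axes; per-bin rows give the variance disparity with
its bootstrap interval and sample size; and the boundary test finds no
centroid shift across the Permo-Triassic bins (p = 0.986 — this particular
synthetic history plants changing *spread*, not changing *position*, so a
non-significant centroid test is the correct answer).

The same flow drives the jaw arm (`morphodisp simulate --kind jaw`, then
`run-functional` with a YAML config), which reports, e.g.,
`missingness 17.2%; 128 complete cases` before ordinating the five ratios.

Everything the CLI does is a thin wrapper over library functions
(`morphodisp.gpa`, `slide_semilandmarks`, `pca`, `disparity_series`,
`centroid_shift_test`, `partial_disparity`, `run_body_shape`,
`run_functional`), which accept in-memory arrays and data frames.

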