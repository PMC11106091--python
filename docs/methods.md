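# Methods

This note documents the models, estimators and numerical conventions behind
`octafractal`: a pipeline that quantifies the macular capillary network on
en-face OCTA slabs with two fractal statistics — box-counting fractal
dimension (FD) and gliding-box lacunarity (LAC) — and relates them to the
extent of peripheral retinal non-perfusion in a diabetic-macular-edema (DME)
cohort. Because no patient images are distributed with this package, a
calibrated synthetic cohort stands in for them; its scope and limits are
described below.

## Per-slab pipeline

Each slab is an 8-bit grayscale en-face image of one capillary plexus
(superficial, SCP, or deep, DCP), nominally 3×3 mm. The stages are:

1. **Speckle suppression.** Median filter over a disk of radius 2 px
   (13-pixel footprint), borders by edge replication. "Radius" is read as a
   euclidean disk, not a square; the disk keeps the filter isotropic.
2. **Binarization.** Global Otsu threshold on the 256-bin histogram; the
   threshold `t` maximizes between-class variance, ties broken toward the
   smallest `t`, and vessel = strictly above `t`. By default the median
   filter runs before thresholding (`filter_order="pre"`), on the reading
   that filtering exists to stabilize the threshold; the reverse order is a
   config switch because both appear in the OCTA literature.
3. **Skeletonization.** Iterative morphological thinning (8-connected
   foreground) run to a fixed point, followed by simple-point pruning of
   residual fully-true 2×2 blocks (Hilditch crossing number = 1). The result
   is strictly one pixel wide, contained in the mask, and idempotent under
   re-skeletonization. At rare X-crossing junctions no simple deletion
   exists; there one strand is broken deterministically (a few pixels per
   256² image — negligible for the area statistics computed on it).

Both fractal statistics are computed on the skeleton, so vessel *caliber*
does not enter either measure; only network geometry does.

## Fractal dimension

FD is the slope of the ordinary least-squares fit of log N(ε) on log(1/ε),
where N(ε) is the number of ε×ε grid boxes containing at least one skeleton
pixel. Conventions:

- **Multiple origins.** For each ε the grid is evaluated at `n_origins = 4`
  deterministic offsets — the corners of a 2×2 lattice over [0, ε)², with
  (0, 0) always included — and the counts are averaged. Averaging suppresses
  grid-phase variance while keeping runs exactly reproducible. Partial boxes
  at the image edges participate.
- **Fit range.** The dyadic ladder runs 2, 4, …, floor(min(H, W)/4). The
  slope, however, is fitted on the **four coarsest** sizes (8–64 px at
  256 px): at ε below the mesh spacing the counts probe the one-pixel width
  of the strands (local slope → 1) rather than how the network fills the
  plane, and including those sizes caps the fitted FD near 1.75 for *any*
  dense mesh. Restricting the fit to the scaling regime is the standard
  box-counting practice; the full ladder remains one config option away
  (`box_sizes`).
- The slope is clamped to [0, 2] (the planar range); the raw slope and the
  fit R² are kept as diagnostics.

Validation anchors (all in the test suite): a filled square gives exactly
2.0 with R² = 1; a single pixel gives 0; a straight line gives 1.0 ± 0.05; a
level-5 Sierpinski carpet sampled at ε = 3^k gives exactly N = 8^(5−k) and
FD within 0.05 of log 8 / log 3 ≈ 1.8928; counts agree exactly with a
nested-loop brute-force counter on random images.

## Lacunarity

Gliding-box lacunarity: an r×r window visits every fully contained position
with unit step; with M the skeleton mass per window,

    Λ(r) = ⟨M²⟩ / ⟨M⟩²  =  1 + CV²(M) ≥ 1.

The per-slab summary is the mean over r of the normalized value
Λn(r) = 1 − 1/Λ(r) ∈ [0, 1), which maps the homogeneous limit to 0 and is
comparable across window sizes; raw Λ and CV² summaries are selectable
(`lac_normalization`). Window sizes default to the dyadic ladder above the
strand width (4–64 px at 256 px). Window sums use a summed-area table;
results match a nested-loop oracle exactly. Sizes whose windows carry no
mass are skipped.

## Synthetic cohort

The generator emulates what the pipeline consumes — not retinal biology:

- **Capillary mesh.** The near-zero level set of band-pass-filtered Gaussian
  noise (difference of Gaussians, σ = 0.8 / 2.0 px) forms a connected lace
  of ribbons; the fraction of pixels kept (`density`) is 0.50 for SCP and
  0.55 for DCP, the deep plexus being the denser mesh. A central disk of
  radius 0.10 × width (≈ 0.3 mm on a 3 mm scan) is cleared as the foveal
  avascular zone. Vessels render at gray level 185, background 45, additive
  noise SD 14, plus 0.2 % salt speckle for the median filter to remove.
- **Ischemic dropout.** Randomly placed ellipses (semi-axes 1–4 % of image
  width) clear vessel area until a target fraction `dropout` is removed.
  Per eye, `dropout = 0.24 × (NPA quadrant count) + N(0, 0.02)`, capped at
  0.95. Small patches were chosen deliberately: they erode space-filling
  (FD) faster than they create large-scale gaps (LAC), matching the
  published pattern of a large FD deficit with a modest LAC excess.
- **Cohort composition.** 50 eyes; 30 with non-perfusion in 1/2/3/4
  peripheral quadrants split 6/4/9/11; 20 well-perfused — the study's
  composition. Covariates (BCVA, CMT, age, sex) are drawn per group from
  normal distributions truncated to clinical ranges (0–100 letters,
  150–900 µm, 18–95 y), using the published group means and SDs. Beyond
  group membership all covariates are independent of the images; no
  joint FD–CMT or FD–BCVA structure is claimed.
- **Seeding.** A single cohort seed feeds a `numpy` `SeedSequence` tree: one
  child per eye (covariates + dropout jitter), two grandchildren per eye
  (SCP/DCP textures). No global random state is touched.

**Calibration.** `MESH_SIGMA_PX`, `BASE_DENSITY_*`, `DROPOUT_PER_QUADRANT`
and the patch-size range are fixed constants, chosen once by a grid search
that pushed generated cohorts through this pipeline and compared the
measured group statistics with the published targets (well-perfused SCP FD
1.92, NPA 1.21, cohort LAC 0.35). They are committed in
`synthetic_data.py` and are never re-tuned at test time. Measured values at
the defaults: well-perfused SCP FD ≈ 1.89, NPA ≈ 1.31, cohort SCP FD ≈ 1.54,
SCP LAC ≈ 0.38, FD–extent correlation ≈ −0.92. Two systematic offsets are
understood and accepted: (i) the radius-2 median filter erases mesh
structure finer than ~5 px, which caps the intact-mesh FD at ≈ 1.89 (vs the
printed 1.92 ± 0.03); (ii) the printed group means are mutually inconsistent
with the printed cohort mean (0.4·1.92 + 0.6·1.21 = 1.49 ≠ 1.6), so the NPA
mean is calibrated to ≈ 1.31, which keeps *both* the group and the cohort
targets inside their tolerances.

**What passing tests do not show.** The generator reproduces the
measured-statistic structure of the study groups, not OCTA physics: no
projection artifacts, no segmentation error, no vessel-caliber variation, no
eye motion, no device resampling. Agreement on synthetic cohorts validates
the *pipeline* (estimators, statistics, calibration machinery) — it is not
evidence about real DME eyes.

## Cohort statistics

Per-variable two-sided **Welch** t-tests compare NPA vs well-perfused eyes
(Welch because the published group SDs differ by an order of magnitude;
Student's pooled test is a flag). **Pearson** correlations relate each of
FD/LAC × SCP/DCP to non-perfusion extent, coded as the quadrant count 0–4
(a binary coding is a flag). p-values come from the t distribution with
n − 2 dof via t = r√((n−2)/(1−r²)). No multiple-testing correction is
applied by default (a Holm option exists); significance is reported at
0.05. A Shapiro–Wilk p per variable is recorded in the summary table as a
distributional diagnostic only. Both statistics are computed from their
formulas and are tested to 10 significant digits against independent
reference implementations.

## Problem sizes

Default slabs are 256×256 px — the scale at which all calibration constants
were fixed. Cohort-level checks aggregate 20 seeded cohorts (1,000 eyes per
plexus); trend properties (dropout monotonicity) use 128 px slabs and 10
seeds. The acceptance script regenerates 20 cohorts from scratch and reports
cohort-level means; it runs in a few minutes on one CPU.

## Known limitations

- FD and LAC depend on the chosen scale ranges; values are comparable only
  within a fixed configuration (the defaults are part of the method).
- The lacunarity normalization (mean of 1 − 1/Λ) is one documented
  convention among several; no bit-equivalence with any specific legacy
  tool is claimed.
- The thinness guarantee costs exact topology preservation at X-crossings
  (a few pixels per image).
- The generator leaves every joint distribution beyond group means/SDs at
  independence; correlations among covariates are not modeled.
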