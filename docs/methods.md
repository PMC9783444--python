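# Methods

## Box-counting fractal dimension

A region of interest is a 3D boolean voxel mask (the cortical ribbon of one
hemisphere, or a lobar subset of an aparc-style label volume). The estimator:

1. crops the mask to the tight bounding box of its foreground and anchors a
   single fixed grid of non-overlapping `r × r × r` boxes at the minimal
   corner;
2. counts the boxes containing at least one foreground voxel; partial boxes
   at the far boundary participate (every voxel must belong to some box);
3. increases `r` linearly, one voxel per step, over the fit window;
4. fits `log N(r)` on `log r` by unweighted ordinary least squares and
   reports FD = |slope|, the intercept, and R².

Fit windows are `r = 2…30` voxels for hemisphere masks and `r = 2…14` for
lobes. All integer `r` in the window enter the fit with equal weight, which
makes the abscissae *non*-equally spaced on the log scale; this is a
deliberate convention of the method, not an accident, and the curves are not
resampled to equal log spacing. Natural logarithms are used (the slope
magnitude is base-invariant). `r` is in voxel units; voxel size is metadata
only and anisotropic voxels trigger a logged warning.

**Grid anchoring.** Anchoring at the foreground bounding box makes counts
deterministic and exactly translation-invariant. No multi-offset averaging
is performed — one fixed grid per `r`.

**Degenerate inputs.** An empty mask (or fewer than 2 foreground voxels) is
an error. A fitted FD outside `(0, 3]` is returned with a quality flag
rather than raising, so cohort-level outlier screening can deal with
pathological masks; a flat curve tail (≥ 3 identical trailing counts,
meaning the window outgrew the structure) is likewise flagged.

**Finite-size bias.** Because `N(r)` is an integer cover, `N(r) =
ceil(L/r)^3` for a filled box of side `L`, which plateaus wherever
`ceil(L/r)` is constant. When the window extends to an appreciable fraction
of the object (r = 30 against a 64³ cube; r = 14 against an 81³ sponge),
these plateaus flatten the overall slope and the measured FD sits
systematically below the theoretical dimension: 2.710 for a filled 64³ cube,
1.807 for a 64×64×1 slab, 0.903 for a 64-voxel line (hemisphere window), and
2.549 for the level-4 Menger sponge against its theoretical
log 20/log 3 ≈ 2.727 (lobe window). These reference values were frozen from
a brute-force oracle run and are asserted in the test suite; restricting the
window to the scaling regime (`r = 2…8` on the same objects) recovers the
theoretical dimensions to within 0.1. The bias is deterministic and common
to all masks measured with the same window, so between-subject and
between-region comparisons are unaffected; absolute FD values should only be
compared across studies using the same window convention.

## Lobar parcellation

Volumetric DK labels code left cortical regions 1001–1035 and right regions
2001–2035. The lobe grouping (shipped as `data/dk_lobes.csv`) assigns 29
regions per hemisphere: frontal 11, temporal 9, parietal 5, occipital 4.
The insula (x035) and cingulate regions (x002, x010, x023, x026) belong to
no lobe and are excluded from lobar masks. Right-hemisphere sets are always
the left sets + 1000. Hemisphere FDs are measured on the ribbon masks when
supplied; on the label-only (synthetic) path the hemisphere mask is the
union of all of that side's cortical labels, and this substitution is
recorded in the run provenance.

## Statistical battery

Input is a subject table: `id, age` (years), `sex` (female = 0, male = 1),
`tbv` (total brain volume, mm³), and the 10 FD measures
(`fd_lh … fd_ro`).

* **Outlier screening** operates per measure, not per subject: values
  outside `[Q1 − 3·IQR, Q3 + 3·IQR]` (quartiles by linear interpolation)
  are set missing and logged; the subject's other measures are kept.
* **Main models**: OLS `FD ~ age + sex + TBV`, and `FD ~ age + age² + sex +
  TBV` with raw (uncentred) age; the resulting collinearity between age and
  age² is tolerated and the design condition number logged. Model
  preference is by minimum AIC (ties prefer linear); ΔAIC is exposed so a
  ≥ 2 materiality rule can be applied by the caller, since a small ΔAIC
  means the models are statistically indistinguishable.
* **AIC convention**: Gaussian likelihood with parameter count =
  coefficients (incl. intercept) + residual variance, i.e.
  `n·log(RSS/n) + n(log 2π + 1) + 2k`. Only AIC differences between models
  fitted to identical rows are meaningful; the comparison operation
  enforces row identity via a fingerprint of the complete-case index.
* **Sex-stratified** fits (`FD ~ age + TBV` per sex) and an **age × sex
  interaction** model (`FD ~ age + sex + age:sex + TBV`).
* **Asymmetry**: `AI = 2(L − R)/(L + R)` per region pair (positive =
  leftward). Main-effects model `AI ~ age + sex + TBV`; three-way model
  with one side's FD as response on `age + sex + AI + all two-way +
  age:sex:AI`, *excluding* TBV (both choices are overridable). Direction of
  asymmetry via the classical paired t-test; sex comparisons of raw
  measures via Welch's t.
* **Age subgroups**: seven 5-year bins, half-open `[45,50) … [70,75)` with
  the final bin `[75,80]` closed (a subject aged exactly 50 falls in the
  50–55 bin); per bin `FD ~ age + sex + TBV`; bins under 10 complete rows
  are flagged and skipped.
* **Thresholds**: plain Bonferroni — α = .05/10 = .005 for the FD models,
  .05/5 = .01 for asymmetry models, .05/20 = .0025 for the per-sex simple
  regressions. No FDR machinery.

Complete cases are used per model (only the columns the model involves).
Rank-deficient designs raise a singular-design error rather than silently
pseudo-inverting.

## Synthetic generators

**Phantoms.** Solid cubes, one-voxel slabs and lines anchor the integer
dimensions; the Menger sponge (subdivide 3×3×3, keep the 20 cells with at
most one middle coordinate) anchors log 20/log 3; Mandelbrot percolation
(recursive subdivision into m³ subcells, each kept independently with
probability p) has box dimension `3 + log p / log m` — continuously tunable,
which is why it, rather than deterministic sponges alone, encodes per-subject
effects at voxel level. Extinct percolation draws are regenerated up to a
retry cap. `p = 1` reproduces the full cube exactly.

**Cohort tables** draw each regional FD from the same generative form the
battery fits: `FD = b0 + β_age·age + β_age²·age² + β_sex·sex + β_tbv·TBV +
ε`, ε ~ N(0, σ²). Defaults are the conditions of a large mid-to-late-life
population cohort: n = 7010, truncated-normal ages (mean 62.5, SD 7.4,
range 45–79 years), 47.5% male, per-sex TBV (female 1,051,176 ± 79,038 mm³;
male 1,159,948 ± 92,742 mm³), region intercepts ≈ 2.24–2.38, age slopes
−1e−4 to −3e−4 FD/year, sex effects −6e−3 to +3.8e−3, residual SDs
0.011–0.023, with quadratic age terms (≈ 1e−5 FD/year²) only in the
bilateral frontal and right temporal regions. β_tbv defaults to 2e−8
FD/mm³, chosen to reproduce the reported positive FD–TBV correlation at the
cohort's TBV spread. Extreme outliers are injected at rate 0.005 per data
point as ±8σ offsets. Every generative coefficient and every injected
outlier position is returned in a ground-truth record.

**Subject volumes.** A 48³ grid (minimum; any size whose half factors into
2s and 3s works) splits into left/right halves along x; each half hosts four
cubic lobar compartments (2 × 2 in y/z) filled with mixed-subdivision
percolation (24 = 3·2·2·2 at the default size). Within a compartment the
lobe's DK label codes cycle across z-slices, so exactly the 58 lobar codes
appear; hemisphere ribbons are each side's compartment union. The target-FD
→ retention-p map inverts a *measured* calibration table (mean lobe-window
FD at each p over 30 seeds at the 24³ reference size, frozen from an oracle
run) rather than the asymptotic dimension formula, because lobe-window
measurement at 24³ carries the finite-size bias described above. Per-subject
randomness derives from `SeedSequence((master_seed, subject_index))`, so any
subject regenerates in isolation.

`validation_cohort_config` produces a deliberately *unrealistic* cohort
(between-subject FD spread 0.25) whose wide dynamic range makes
measured-vs-target rank agreement informative; it exists for end-to-end
validation of the measurement machinery, not as a population model.

## What the synthetic path does and does not show

Passing tests demonstrate that the box counter is exact (it matches
brute-force enumeration), that the estimator recovers known dimensions up to
the documented window bias, that the regression battery recovers generative
coefficients at the correct coverage, that the null calibration of the
interaction test is correct, and that the voxel pipeline preserves the
ordering of per-subject complexity targets. They do not show anything about
FreeSurfer segmentation quality, partial-volume effects, scanner noise, or
the anatomical realism of the compartment layout — the phantoms are
caricatures with controlled fractal statistics, not brains.

## Validation problem sizes

The shipped validation suite uses 64³/81³ phantoms, 50 random masks up to
16³ for oracle equivalence, n = 2000 cohorts (100 replicates for AIC
preference, 200 for null calibration), and a 30-subject voxel cohort on 48³
grids; these sizes were chosen so the full suite completes in minutes on one
core while keeping every statistical check adequately powered. With a true
quadratic effect of 1e−5 FD/year² and σ = 0.015 at n = 2000, the AIC
preference for the quadratic model has a per-replicate probability of
≈ 0.87 (the likelihood-ratio statistic is ≈ 2.6 ± 1, and preference requires
LR > 2), so preference rates in the mid-80s percent are the expected
behaviour at this sample size — not an estimator defect; at the full
cohort's n ≈ 7000 the preference is near-certain.

## Known limitations

* Absolute FD values depend on the fit window (see finite-size bias); only
  within-convention comparisons are meaningful.
* Voxel anisotropy is not corrected for — volumes should be resampled to
  isotropic grids (e.g. FreeSurfer conformed space) upstream.
* The cingulate and insula are deliberately absent from all lobar masks.
* Cross-sectional models only; no longitudinal or mixed-effects support.
* The outlier rule's quartile convention (linear interpolation) can differ
  slightly from other environments' defaults at small n.
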