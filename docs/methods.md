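# Methods

This note documents the models, conventions and numerical choices behind
`methvar`, in the order data flows through the package.

## 1. Data model

The lowest-level substrate is what a BeadChip scanner summarizes per
(sample, probe, colour channel): the mean fluorescence intensity (FI)
across beads, the bead-level FI standard deviation, and the bead count.
Infinium Type II probes read methylated signal in green and unmethylated
in red on one bead type; Type I probes have a single design channel, and
their read in the *other* channel ("out-of-band", OOB) carries no signal —
it is an empirical sample of the optical background.

**Type I simplification.** In this package Type I probes carry one in-band
record (design channel) and one OOB record, and betas are computed for
Type II probes only, as `beta = green / (green + red + offset)`. Type I
probes exist to supply the background sample that detection p-values and
background correction need. All intensity diagnostics are restricted to
Type II probes anyway, since only there are the two channels directly
comparable. Real Type I chemistry (two bead types in one channel) is not
modelled.

The beta offset defaults to 100, the conventional intensity stabilizer;
it is exposed everywhere it is used.

**Missingness rules.** `clean_matrix` drops probes whose NA fraction
strictly exceeds 10% (configurable) and median-imputes the remainder from
the probe's observed samples. For even observation counts the lower of the
two central order statistics is used by default (`median_convention=
"midpoint"` selects the average instead).

## 2. The replicate-plate simulator

The generator emulates a technical-replicate study: `n_subjects = 4`
subjects, each with 8 *pooled* replicates (aliquots of one pooled DNA
preparation) covering chamber numbers 1–8 exactly once across 4 slides in
a rotating pattern, plus 8 *independently prepared* replicates placed
pairwise on dedicated slides (two subjects per slide, four chambers each —
which is what makes a same-slide two-group comparison possible). Chamber
`c` maps to Sentrix position `R0cC01`.

Per probe and channel:

* baseline betas come from a bimodal mixture — Beta(0.5, 8) and
  Beta(8, 0.5) at 45% each plus a 10% mid-range Beta(2, 2) component —
  matching the characteristic two-peaked beta histogram of methylation
  arrays; per-subject deviations are N(0, `subject_effect_sd`), clipped to
  [0, 1];
* a latent probe brightness `B` is log-normal(meanlog 8, sdlog 0.5) — a
  probe property shared across samples;
* Type II signals are `B·beta·gain[chamber, green]` and
  `B·(1−beta)·gain[chamber, red]`;
* an additive optical background N(`background_mean`, `background_sd`) is
  drawn per record; OOB records are background-only draws, and the
  background does *not* scale with the chamber gain;
* bead counts are `1 + Poisson(bead_count_mean − 1)`, shared between the
  two channels of a probe (one physical bead type); the recorded bead-level
  SD is `cv_base · (signal + background_mean) · cv_inflation[chamber,
  channel]` with chi-distributed sampling noise, and the mean-FI error has
  standard deviation `sd_fi / sqrt(n_beads)` — so replicate noise falls as
  bead counts rise, which is what drives the negative bead-count /
  beta-SD correlation diagnostic;
* independently prepared replicates receive extra beta-scale noise
  (`prep_noise_sd`) before intensity synthesis;
* a list of planted outliers (probe, sample, bead count, FI shift,
  channel) is applied last.

### Default parameters and why

| parameter | default | rationale |
| --- | --- | --- |
| `subject_effect_sd` | 0.01 | blood methylomes of healthy adults differ modestly at most CpGs |
| `prep_noise_sd` | 0.005 | preparation adds noise on top of the array floor; no quantitative estimate of this gap exists for the emulated design, so the value is an assumption |
| `bead_count_mean` | 14 | typical per-probe bead redundancy of EPIC-class arrays |
| `cv_base` | 0.10 | bead-level CVs cluster around 0.1 in replicate data |
| `background_mean`, `background_sd` | 200, 30 | background a few percent of typical signal |
| `brightness_meanlog/sdlog` | 8.0, 0.5 | mean total intensity a few thousand FI units with a realistic dynamic range |

With these values the within-subject replicate beta SD is ≈ 0.01 and the
bundled biased scenario (`biased_plate.yaml`: chamber-1 gain 0.8 in both
channels, chamber-8 red CV × 1.5) reproduces the qualitative regime the
diagnostics were designed for: chamber structure visible in PCA and
clustering, a chamber-confounded null comparison that yields real false
positives, and full repair by the empirical-Bayes correction.

**What the simulator does not emulate.** Probe cross-hybridization,
SNP-affected probes, bisulfite-conversion chemistry, Infinium-I channel
switching, spatially smooth within-chamber gradients, probe-specific
background, and between-slide reagent drift. Positional bias enters only
as per-chamber multiplicative gain and noise inflation. Passing tests
therefore demonstrate that the *statistics* behave as designed under the
declared generative model — not that real arrays contain no other artifact
classes.

## 3. Preprocessing stand-ins

The preprocessing module is an explicitly simplified stand-in for a
production array pipeline. Quality-mask catalogues and channel-inference
stages are omitted because the synthetic manifest has no mislabelled
channels and no external mask list. Stages compose as
mask → dye-bias → background → betas, and the pipeline is deterministic.

* **Detection p-values** (`detect_poobah`): per sample,
  `p = 1 − F̂_oob(total in-band FI)` where `F̂_oob` is the empirical CDF
  (mid-rank convention) of the sample's OOB intensities, both channels
  pooled; probes with `p > alpha` (default 0.05) are masked and become NA
  in the beta matrix. Under a background-only null the p-values are
  uniform by construction. A Grubbs screen flags samples with abnormally
  low detection rates (p < 0.05).
* **Background correction** (`background_correct_normexp`): the
  normal-exponential convolution posterior mean, `E[S | X = x] = m +
  σ·φ(m/σ)/Φ(m/σ)` with `m = x − μ − σ²/α`, evaluated in log space for
  stability; outputs are strictly positive. Background location/scale are
  estimated per sample and channel by median/MAD of the OOB records
  (robustness), and the exponential signal mean `α` as the mean in-band
  excess over background, floored at σ. Masking does not gate background
  estimation — background comes from OOB records only, which sidesteps the
  ordering ambiguity entirely.
* **Dye-bias scaling** (`dye_bias_scale`): the red channel (means and
  bead-level SDs) is linearly rescaled per sample so the median Type II
  red intensity equals the median Type II green intensity.

## 4. Batch correction

`combat_adjust` implements the parametric empirical-Bayes location/scale
model from scratch: features are standardized by batch-structured fits
(size-weighted grand mean; pooled residual variance with denominator N),
per-batch locations γ̂ and scales δ̂² are shrunk toward a normal /
inverse-gamma prior fitted across features by method of moments, with
iterated posterior updates (convergence when the maximum relative change
of γ*, δ*² falls below 1e-4; at most 100 iterations; both configurable),
and the data are back-transformed with the shrunken estimates. The
nonparametric prior mode is out of scope. Correction runs on beta values —
the quantity the diagnostics are defined on — and outputs are clipped to
[0, 1], since the unconstrained back-transformation can leave the unit
interval. With a single feature there is no cross-feature information, so
the prior is flat and no shrinkage occurs. Batch is one factor per run
(chamber or slide); no covariates are modelled. The implementation agrees
with the Bioconductor reference to ~1e-15 on a toy matrix (cross-checked
in the test suite via Rscript).

`combat_counts_fi` is the count-style arm for intensities: per channel,
intensities are rounded to integers; per feature a negative binomial with
batch-specific means and method-of-moments dispersions (floored at 0.01)
is fitted, and each count is quantile-mapped (mid-CDF, which keeps the map
near the identity under equal batches) onto a batch-free target with the
geometric mean of batch means and a batch-size-weighted pooled dispersion.
Features with an all-zero batch pass through unadjusted. This is a
deliberate simplification of GLM-based count adjustment: method-of-moments
dispersions keep it dependency-light and exactly testable. Betas are
recomputed from the adjusted intensities afterwards.

## 5. Variability diagnostics

Sample (n−1) standard deviations are used throughout.

* **Within-subject z-scores**: per probe and subject, replicates are
  centered and scaled by the within-subject mean and SD; zero-SD probes
  become NaN and are omitted. Positional profiles average these z-scores
  per chamber or slide over subjects, after a >90% completeness filter.
* **SD ratio**: `mean_over_subjects(within-subject replicate SD) /
  (all-replicate SD + 1e-4)`; the offset guards CpGs with near-zero
  overall variability.
* **Bead CV**: `sd_fi / mean_fi` per record (Type II), aggregated per
  chamber by median and IQR; box-plot exports hide values beyond 1.96×IQR.
* **Intensity-binned bias**: Type II probes are ranked per subject by
  their median FI in the chosen channel and split into 100 percentile bins
  (stable ties); per bin and chamber the mean (signed FI, or absolute
  beta) deviation from the within-subject median is reported, averaged
  over subjects.
* **Variance decomposition**: per probe, a linear mixed model with chamber
  and slide as fixed effects and subject as a random effect. The single
  random effect is handled by one shared eigendecomposition of the
  subject-grouping matrix, so the REML criterion is evaluated for *all*
  probes jointly on a fixed grid of variance ratios (λ = 0 plus 80
  log-spaced points in [1e-4, 1e4]; λ = 0 floors σ²_subject at zero). The
  grid resolution limits the precision of σ²_subject but barely moves the
  fixed-effect F statistics, which are the reported quantity. Marginal
  (Type III-style) Wald F statistics use the GLS coefficient covariance at
  the selected λ with residual variance `RSS_w / (n − rank(X))` — chosen so
  the statistic reduces exactly to the classical ANOVA F when the random
  effect vanishes. This convention can differ from an lmer-style
  Satterthwaite F in the denominator degrees of freedom; it affects
  p-values, not the F ordering between factors. Rank-deficient fixed
  designs are refused.
* **PCA + clustering**: top 50 components (features centered, not scaled)
  of the samples × probes matrix; Ward-D2 agglomeration on the PC scores;
  subject purity is the fraction of samples matching their cluster's
  majority subject at a fixed cut of k = number of subjects (the source
  analyses report dendrograms visually; a fixed cut makes the endpoint a
  number).
* **Grubbs one-outlier test**: `G = max|x − x̄|/s` with the two-sided
  t-bound `p = min(1, 2n·P(T_{n−2} > t))`, `t² = n(n−2)G² / ((n−1)² −
  nG²)`.
* **Low-level correlations**: Pearson and Spearman of per-probe mean bead
  count, channel intensities and bead-level SDs against the per-probe
  replicate beta SD.

## 6. Differential-methylation audit

Per-probe testing is the pooled-variance two-sample t (the two-group
linear-model statistic); Welch's variant is behind a flag. Probes constant
in both groups have no valid statistic: they are flagged, excluded from
the Benjamini–Hochberg family, and counted. BH-adjusted p < 0.05 defines
significance.

The plate layout supports three constructed designs:

* **across-array arm**: two subjects, four pooled replicates each, every
  replicate on a different slide;
* **same-array arm**: the same two subjects, four independent replicates
  each, all on one shared slide;
* **balanced null**: two further subjects, each twice per side, with side
  A entirely in chamber 1 and side B entirely in chamber 8 — identical
  biological composition, maximal positional confounding, so every
  significant CpG is a false positive and the count measures positional
  bias leakage.

One subtlety is documented because it is easy to misread: the balanced
null is *conservative* at subject-variable CpGs. Subject effects cancel
exactly in the group-mean difference but still inflate the pooled variance
estimate, so its raw p-values are right-skewed even on bias-free data.
Calibration (KS uniformity) is therefore checked on a genuine global-null
comparison — one subject's pooled replicates split 4 vs 4 across chambers
— while false-positive counting uses the balanced null.

## 7. Clocks

A clock is `s = intercept + Σ coef_j · beta_j`, optionally passed through
the standard log-linear age anti-transform
`age = (1 + A)·exp(s) − 1` for `s < 0`, else `A + s·(1 + A)` (fixed point:
`s = 0 → age = A`, with `A` the "adult age", default 20). Missing clock
probes are governed by an explicit policy (`error` or cohort-mean
imputation); probes absent from the matrix entirely always raise.
Coefficient files are CSV (`probe_id,coefficient`) with one `# key=value`
metadata line; published coefficient sets are user-supplied inputs.

The stability report computes, per clock CpG and subject, the mean and
range of betas across technical replicates and an *influence* score
(range × |coefficient|), plus the SD of predicted ages across each
subject's replicates. CpGs whose influence exceeds a threshold (default
5× the median positive influence) are screened with the Grubbs test on
their low-level mean FI and bead-level SD in each channel across the
subject's replicates — the screen that pinpoints a single bad replicate
(low bead count, shifted FI) behind an erratic age prediction. The
planted-outlier protocol designates a high-coefficient clock CpG with
baseline beta away from 1 and injects a green-channel FI shift at 4 beads
in one replicate; recovery means topping the influence ranking *and* being
Grubbs-flagged in the injected channel.

## 8. Problem sizes and determinism

The standard protocols run at 4 subjects × 16 replicates × 20,000 probes
(single plates), 20 plates × 5,000 probes for the pipeline-ordering
median, and 100 repetitions × 400 probes for the planted-outlier rate —
sizes at which every recovery property is comfortably resolved while a
full run of the acceptance script stays around half a minute. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; a fixed seed yields byte-identical simulator
output.

## 9. Known limitations

* Chamber gain recovery is unbiased only after background correction; on
  raw intensities the additive background shrinks the estimate toward 1
  (by its share of total intensity), which is a property of the additive
  model, not of the estimator.
* The EB correction assumes an additive location/scale batch structure on
  the beta scale; strongly intensity-dependent biases are only partially
  captured (the intensity-binned diagnostic exists precisely to show
  what remains).
* The count-style intensity adjustment uses moment dispersions and a
  two-parameter NB target; it is not a reimplementation of GLM-based
  count batch correction and will differ from it numerically.
* Single-plate false-positive counts under the null design are bimodal
  across simulation seeds (a BH threshold cascade either fires or does
  not); multi-seed medians are the stable summary and are what the
  acceptance script reports.
* ICC-style reliability estimation and region-level (DMR) analysis are
  out of scope.
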