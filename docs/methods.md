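# Methods

`ebcpanel` re-creates, as a tested pipeline, the computational workflow
used to discover small miRNA biomarker panels in exhaled breath
condensate (EBC) microarray profiles: probe-level preprocessing,
abundance filtering, moderated differential expression, random-forest
feature elimination, leave-one-out panel evaluation, a binomial GLM
panel model with ROC analysis, and miRNA–target network degree
summaries.  Because no public probe-level EBC dataset is available, the
package ships a synthetic-data generator with planted ground truth; all
statistical claims the test suite makes are claims about this generator.

## Synthetic data generator

Each probe intensity is drawn as

    X = B + A · 2^(Δ + a_p + ε),   B ~ N(μ_bg, σ_bg²),  A ~ Exp(rate)

where `A` is the probe set's base abundance (drawn once per set, giving
heavy-tailed log-scale abundance heterogeneity), `Δ` is the planted
group shift in log2 units (zero unless an effect targets that miRNA and
the sample's group), `a_p ~ N(0, σ_aff²)` is a fixed per-probe affinity
offset (drawn once, so median polish has a probe structure to remove)
and `ε ~ N(0, σ_probe²)` is per-observation log-scale noise.  Marginally
each sample is therefore close to a normal background plus an
exponential signal — exactly the convolution the background-correction
step assumes, which makes parameter recovery a meaningful check.

Defaults: `μ_bg = 100`, `σ_bg = 20`, `rate = 1/200` (so roughly the top
few percent of probe sets are strongly above background, matching the
intent of the downstream top-5% abundance filter), `σ_aff = 0.5`,
`σ_probe = 0.25`.  The platform default is 30,424 probe sets with 2,578
human mature miRNAs and 4 replicate probes per set; all counts are
configurable and most tests run scaled-down platforms.  The default
study design is 21 patients vs 21 controls with clinical attributes
(histology AD/SCC, stage I–III/IV, invasion, vital status at 500 days
with 3 missing) assigned in the cohort proportions of the emulated
study.

What the generator does *not* emulate: spatial array artifacts,
cross-hybridization, mismatch probes, batch effects, correlated miRNA
co-regulation, and any real biological covariance structure.  Passing
tests therefore demonstrate the correctness and calibration of the
computation, not clinical performance on real EBC data.

## Preprocessing (RMA-style)

1. **Background correction.**  Per sample, the normal+exponential
   ("normexp") convolution parameters are estimated by maximum
   likelihood (Nelder–Mead on (μ, log σ, log rate)), started from the
   method-of-moments point in which the exponential mean is
   `(m₃/2)^(1/3)` of the third central moment.  Each intensity is then
   replaced by the posterior mean `E[S|X] = μ_sf + σ·φ(μ_sf/σ)/Φ(μ_sf/σ)`
   with `μ_sf = x − μ − σ²·rate`, which is strictly positive.  If the
   estimate degenerates (zero spread, non-finite optimum), the sample
   falls back to a shift-to-minimum correction and is flagged.
2. **Quantile normalization.**  Every column is mapped onto the
   across-sample mean of order statistics.  Ties within a column receive
   the mean of the reference values at the tied ranks, so tied inputs
   stay tied.
3. **Median-polish summarization.**  Probe intensities are log2
   transformed and each probe set is fitted with the additive model
   `log2 y ≈ overall + probe + sample` by Tukey's iterated median
   sweeps (row sweep, column sweep, re-centering each half-iteration).
   Convergence: change in residual L1 norm < 1e-6 of the initial scale,
   at most 20 sweeps (the brute-force comparisons in the tests run both
   sides at 1e-10 / 200 sweeps).  A probe set's expression is
   `overall + sample effect`; probe effects are discarded.  Balanced
   platforms use a vectorized polish over a (sets × probes × samples)
   stack, which follows the identical sweep schedule.

Order of operations is background → quantile → log2 → polish, the
standard RMA ordering; the alternative (normalizing after log) is not
implemented.

## Abundance filter and moderated t

Non-human probe sets are trimmed, per-miRNA medians are computed across
*all* arrays (both groups pooled), and exactly `floor(0.05 · n_human)`
features are kept — 128 when 2,578 human miRNAs are annotated.  Ties at
the cutoff break lexicographically by miRNA id.

Differential expression uses a per-feature two-group least-squares fit
with empirical-Bayes variance moderation.  Residual variances s²_g (on
d_g = n₁+n₂−2 df) are modelled as s²_g ~ s₀²·F(d_g, d₀); the prior
(d₀, s₀²) is estimated by matching the mean and variance of log s²_g
through the digamma/trigamma identities (trigamma inverted by Newton).
The moderated variance is the blend `s̃² = (d₀s₀² + d_g s²)/(d₀+d_g)`,
the moderated t is referred to a t distribution on d₀+d_g df, and a
feature is called regulated at two-sided p < 0.05 — deliberately with
no multiplicity correction, matching the discovery-oriented workflow
this pipeline reproduces; Benjamini–Hochberg q-values are reported as an
extra, clearly secondary, column.  `prior_df=0` switches to the ordinary
pooled t, `prior_df=inf` to complete shrinkage.  Sample standard
deviations use the n−1 denominator throughout.

Scaling for PCA/heatmaps is per-feature z-scoring (row mean 0, sd 1);
PCA is an SVD of the samples × features scaled matrix with no further
centering, with each component's sign fixed so its largest-magnitude
loading is positive.  Heatmap orderings use average-linkage
agglomeration on Euclidean distances.

## Panel selection and evaluation

- **mtry tuning**: stratified k-fold (default 5) CV accuracy over the
  candidate grid {1, ⌊√p⌋, ⌊p/3⌋, p} (capped at p); ties keep the
  smallest mtry.
- **Importance**: per tree, out-of-bag samples are identified by
  reconstructing the tree's bootstrap draw from its seed; a feature's
  importance is the mean over trees of (OOB accuracy − OOB accuracy
  after permuting that feature among the OOB samples) — the mean
  decrease in accuracy.  Constant features score exactly zero.
- **RFE**: tune mtry → grow a forest (default 500 trees) → importance →
  drop the least important feature, repeating until 3 remain.  Ties at
  the minimum drop the lexicographically last id.  Each iteration draws
  its seeds from the master seed plus a counter, so the full trace is
  reproducible.
- **LOOCV subset evaluation**: all 7 non-empty subsets of the trio are
  scored by leave-one-out cross-validation (forest retrained n times);
  accuracy is the raw fraction correct at probability threshold 0.5.
- **Panel model**: a binomial GLM (logit link) on the trio, fitted by
  IRLS.  Quasi-separation (non-convergence or any |coefficient| > 15)
  triggers a ridge-penalized refit (λ = 1e-4, intercept unpenalized)
  and sets a flag — small panels on 42 samples separate often, and the
  penalized fit keeps probabilities finite and usable for ROC.
- **ROC**: thresholds at the unique score values; AUC by trapezoid,
  which equals the tie-corrected rank statistic (checked exhaustively in
  tests); curves are auto-oriented so AUC ≥ 0.5 with a flip flag; the
  reported operating point maximizes Youden's J.  Individual miRNAs are
  scored by raw expression and the panel by its fitted (resubstitution)
  probabilities, with an LOOCV-probability panel ROC attached as a
  secondary output — resubstitution ROCs are optimistic, which is why
  the LOOCV accuracies are reported alongside.

## Target network

The proprietary interaction knowledge base behind the original analysis
is replaced by a user-supplied TSV (miRNA, gene, evidence level,
disease-association flag).  Edges are kept when the miRNA is in the
signature, the evidence is experimentally observed or high-confidence
predicted, and the disease flag is set; duplicate pairs collapse to the
strongest evidence.  Degree summaries are strict: "hub" miRNAs have
*more than* 10 retained targets and "hub" genes *more than* 5
regulators.  The bundled fixture is synthetic (invented edges over real
lung-cancer gene symbols) and exists to exercise the code.

## Problem sizes used by the test suite and acceptance script

Simulation-heavy checks run at sizes chosen to keep the full suite
comfortably reproducible on a single CPU while leaving the *conditions*
(21 vs 21 samples, effect sizes, thresholds, seed counts) untouched:

- null calibration: 20 seeds × 1,000 human miRNAs × 21 vs 21, full
  simulate→preprocess→moderated-t path; the p<0.05 rate must average
  0.05 ± 0.015 and a null trio's LOOCV accuracy 0.5 ± 0.15;
- recovery: 20 seeds with 3 planted features at Cohen's d = 2 among 14
  candidates entering elimination (a full-scale analysis enters a
  regulated subset of the 128 filtered miRNAs — typically around a
  dozen features — so 14 keeps the realistic order of magnitude),
  forests of 60 trees with 3-fold mtry tuning for RFE and 30-tree
  forests for LOOCV; RFE must recover all 3 planted features in ≥ 85%
  of seeds and the combined-panel pattern (trio LOOCV accuracy ≥ each
  individual's; panel AUC ≥ max individual AUC) must hold in ≥ 80%;
- the 2,578-miRNA filter check runs the genuine pipeline on a platform
  with 2,578 human + 22 other probe sets and 2 probes per set.

## Known limitations

- LOOCV accuracies for subsets chosen by RFE on the same samples are
  optimistically biased (no nested cross-validation); this mirrors the
  reproduced workflow and is stated rather than fixed.
- The normexp MLE can be slow for very large arrays (it is run once per
  sample on all probes); subsampling is not implemented.
- Median polish fits are the fixed-schedule iterative solution, which is
  the conventional estimator but not a unique minimizer of any global
  criterion.
- Real-data quantities reported for the emulated study (e.g. which
  miRNAs are significant, a panel AUC of 0.83, PC1 at 24.9% variance)
  depend on undeposited arrays and are out of reach of this package by
  construction; nothing in the tests targets them.
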