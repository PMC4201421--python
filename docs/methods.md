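# Methods

## The scientific question and the model ladder

Isogenic lines — populations made genetically (near-)identical by repeated
self-fertilization — should, under the usual assumptions, differ only in
their mean phenotype; variability *around* that mean is attributed to
uncontrolled noise and assumed equal across genotypes. The analysis this
package implements asks whether that assumption holds for lifetime
fecundity (LF, the total viable progeny of one hermaphrodite) in
*Caenorhabditis elegans*: do genotypes differ in their within-line variance,
is that variance related to the line's mean, and is a line's relative
variability preserved across food environments?

The question is answered by fitting a ladder of nested hierarchical
Gaussian models to individual LF observations from J lines in K
experimental blocks, one food environment at a time:

| Model | Likelihood | Line structure |
|---|---|---|
| 1 | LF_i ~ N(μ, σ²) | none |
| 2 | LF_i ~ N(μ_j, σ²) | μ_j ~ N(θ, σ²_among) |
| 3 | LF_i ~ N(μ_j, σ²_within_j) | μ_j ~ N(θ, σ²_among) |
| 4 | model 3 + α_k | block effect α_k ~ N(0, 1) |
| 5 | model 2 + α_k | block effect α_k ~ N(0, 1) |

Priors follow the diffuse-conjugate BUGS idiom: location parameters get
N(0, 1e10) — parameterized by **variance** here (the BUGS precision
1.0e−10) — and every precision τ = 1/σ² gets Gamma(0.001, 0.001) in
shape–rate form. Block effects get the informative N(0, 1) prior.

Model 2 improving on model 1 means lines differ in mean LF; model 3
improving on model 2 means lines differ in variance — the central claim;
models 4/5 test for block effects. In model 3 the hyper-prior variance of
the line means plays the role that σ²_among plays in model 2, and the trace
is labelled `sigma2_among` in both for consistency. The model-3 prior
statement in the source analysis is garbled; the reading adopted here
(μ_j ~ N(θ, σ²_among) with line-specific likelihood variances) is the one
consistent with its reported effective parameter count (pD ≈ 41 ≈ 21
shrunk means + 21 shrunk variances).

## Gibbs sampler

All full conditionals are conjugate (normal for μ, μ_j, θ, α_k; gamma for
every precision), so the sampler is a systematic-scan Gibbs sampler with
the fixed update order *line means → hyper-mean → precisions → block
effects* and no tuning. Deterministic initialization: means at line/grand
sample means, precisions at 1/sample-variance (variance floored at 1e−8),
block effects at 0. Observations are internally sorted into a canonical
order, so posterior summaries are exactly invariant to row order of the
input table. One chain is the default, matching the original protocol
(10,000 burn-in iterations + 10,000 updates, no thinning); multiple chains
are supported and add a split-chain R-hat to the diagnostics.

The deviance −2 Σ_i log N(LF_i; mean_i, var_i) is recorded at every kept
draw. DIC uses Dbar = mean deviance, Dhat = deviance at the plug-in state
built from posterior means — with variance parameters plugged in as
**posterior-mean precisions**, the convention of the BUGS family, against
which the published DIC tables were computed (`variance_plugin="variance"`
is available as a sensitivity check; it shifts Dhat because the variance
posterior is right-skewed). ΔDIC (simpler − complex) is read on the
conventional scale: < 2 substantial support for the simpler model, 4–7
considerably less, > 10 essentially none, with the unnamed gaps 2–4 and
7–10 labelled "intermediate".

Convergence is judged by the batch-means Monte Carlo error (50 batches)
relative to the posterior SD; a parameter whose ratio exceeds 5% is
flagged and the fit marked suspect. This is deliberately the criterion
that exposes the model-4 pathology: with per-line variances, free block
effects and a free intercept, the direction (μ_j + c, α_k − c) is
constrained only by the N(0, 1) block prior; when the data are precise the
conditional steps along that ridge are tiny, the chain mixes slowly, and
the affected parameters fail the MC-error criterion — a reproducible
stand-in for the non-identifiability reported for that model.

## Downstream summaries

* **Variance components** (from model 2): posterior summaries of σ_among
  and σ, plus the intraclass correlation on two scales. The variance-scale
  share σ²_among/(σ²_among + σ²) is the textbook quantity; the SD-scale
  share σ_among/(σ_among + σ) is what the published percentages (65%, 80%)
  actually correspond to — for the printed dispersions the variance-scale
  values are 78% and 94%. Both are reported, labelled.
* **Per-line summaries**: pooled-over-blocks mean, SD (n−1) and CV per
  line; the model-3 posterior of each within-line variance is attached on
  the **variance** scale (the only scale on which the published
  525.8–13180.0 range is plausible). `fold_range` is the max/min ratio of
  the per-line variances.
* **Rank correlations**: Spearman ρ with average ranks for ties; two-sided
  p by the t approximation for n ≥ 10 and by exact enumeration of the n!
  permutations below that. Degenerate (constant-rank) input returns ρ = 0
  with an explicit flag rather than NaN.

## Synthetic data

The generator emulates the assay design: J = 21 lines × K = 3 blocks ×
5 replicates = 315 observations per food, with

    μ_j ~ N(θ, σ²_among),
    log s_j = log-normal law + coupling · (μ_j − θ),
    LF ~ N(μ_j + α_k, s_j²).

`study_config` anchors every parameter to the published posterior
point estimates for the chosen food: θ = 98.76 / 244.9 and σ_among =
108.4 / 256.4; the within-line SD law is log-normal with the spread set so
the ±2σ_log span equals the published within-line variance fold range
(21.5× / 27.8×) and the median set so the RMS within-line SD equals the
published common-variance residual σ (57.5 / 65.8). The mean–CV coupling
defaults to a slope of −0.4/σ_among on log s_j, i.e. a line one
among-line-SD above the grand mean has its within-line SD shrunk by the
factor e^0.4 — a moderate version of the negative mean–variance relation
in the data. Cross-environment correlation of line-level parameters is
induced by a Gaussian copula on both the mean and log-SD innovations, with
the copula correlation 2·sin(πr_s/6) chosen so the latent Spearman
correlation equals the requested `cv_correlation`.

Zero-truncation is **off** by default so simulated data follow the
Gaussian working model exactly; datasets generated this way carry an
explicit `allow_negative` marker, because untruncated draws at the
published dispersion scales necessarily include negative values. Turning
truncation on gives more realistic count-like data for robustness checks
but breaks exact model correspondence.

What the generator does *not* emulate: fecundity is treated as continuous
Gaussian rather than an over-dispersed count, there are no reproduction
schedules, and lines are exchangeable (no pedigree or genetic structure).
Passing tests therefore demonstrate correctness of the inference machinery
under the stated model, not robustness to the skewness real brood counts
may have. One consequence of anchoring to the published dispersions is
worth stating plainly: σ_among = 108.4 (against θ = 98.76) and σ_among =
256.4 (against θ = 244.9) are large relative to the published line-mean
ranges, so some synthetic line means fall near or below zero and empirical
CV rank correlations in study-sized synthetic runs are attenuated relative
to the correlations reported for the real data. The correlation estimators
themselves are validated in controlled moderate-dispersion simulations.

## Numerical choices and problem sizes

* Percentiles use linear interpolation (NumPy default); credible intervals
  are the empirical 2.5/97.5 percentiles.
* MC error: 50 batches; if fewer than ~100 draws are available the batch
  count shrinks, and a lone draw reports 0.
* Gamma draws use shape–scale with scale = 1/rate; a line with fewer than
  2 observations under models 3/4 is allowed but noted in the diagnostics,
  since its variance posterior is essentially the prior.
* Seeds: every stochastic component takes an explicit seed;
  `numpy.random.SeedSequence.spawn` derives per-chain, per-food and
  per-model streams, so a single top-level seed makes an entire pipeline
  run byte-reproducible.
* Test/validation problem sizes were chosen to keep the statistics sharp
  at small cost: parameter-recovery uses 50 replicates of the full
  21 × 15 design with 1,500 + 3,000 iterations per fit; model-selection
  consistency uses 20 replicates per scenario with 1,000 + 3,000
  iterations; the acceptance script runs the full 10,000 + 10,000 protocol
  on both foods. At these sizes the MC-error criterion is met with a wide
  margin (ratios ≲ 0.015 at protocol length).

## Known limitations

* Exactly the five models are supported; there is no general BUGS-style
  model language, and no Poisson/negative-binomial likelihood (the
  per-observation variance bookkeeping would admit one).
* DIC is the only model-selection criterion, mirroring the original
  analysis; WAIC/LOO are out of scope.
* The published raw observations are not bundled; analyses of the real
  data require ingesting them as a normalized CSV via `dataio`
  (`column_map` handles renamed headers).
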