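# fecvar

Hierarchical Bayesian analysis of **genotype-specific variance in lifetime
fecundity**, built for quantitative geneticists and evolutionary
biologists working with isogenic lines.

Genetically identical individuals in a constant environment still vary —
and, strikingly, *how much* they vary can itself be a property of the
genotype. `fecvar` tests this for lifetime fecundity (LF, total viable
progeny per hermaphrodite) measured on inbred *C. elegans* lines: it fits
a ladder of nested Gaussian models by Gibbs sampling and asks, via DIC,
whether lines differ in mean LF, whether they differ in *variance* of LF,
and whether experimental blocks matter:

* **Model 1** — LF_i ~ N(μ, σ²)
* **Model 2** — LF_i ~ N(μ_j, σ²), line means μ_j ~ N(θ, σ²_among)
* **Model 3** — LF_i ~ N(μ_j, σ²_within j): each line also has its own variance
* **Models 4/5** — models 3/2 plus a block effect α_k ~ N(0, 1)

Location parameters take diffuse N(0, 1e10) priors and precisions take
Gamma(0.001, 0.001); all full conditionals are conjugate, so the sampler
is plain Gibbs. Downstream the package computes DIC tables and ΔDIC
decisions, among-line vs residual variance components with intraclass
correlations (on both the SD and the variance scale), per-line CVs with
fold ranges of the within-line variances, and Spearman correlations of
line CVs with line means and across food environments. A synthetic-data
generator reproduces the assay design (21 lines × 3 blocks × 5 replicates
= 315 observations per food) so every stage is testable end to end.

## Worked example

```python
import fecvar
from fecvar import MCMCSettings

# a study-sized synthetic food environment at the published parameter scales
data = fecvar.generate_dataset(fecvar.study_config("b_pumilus"), seed=1)
print("n_obs:", data.n_obs, "balanced:", fecvar.validate_dataset(data).balanced)

fits = {m: fecvar.fit(m, data, mcmc=MCMCSettings(seed=m)) for m in (1, 2, 3, 5)}
print(fecvar.dic_table(fits.values()).round(1))
res = fecvar.compare_models(fits[2], fits[3])
print(f"dDIC(Model 2 - Model 3) = {res.delta_dic:.1f}: {res.category}")

vc = fecvar.variance_components(fits[2])
print(f"sigma_among = {vc.sigma_among.mean:.1f} [{vc.sigma_among.ci_low:.1f}, {vc.sigma_among.ci_high:.1f}]")
print(f"sigma       = {vc.sigma_resid.mean:.1f} [{vc.sigma_resid.ci_low:.1f}, {vc.sigma_resid.ci_high:.1f}]")
print(f"ICC: {vc.icc_sd_pct}% (SD scale), {vc.icc_variance_pct}% (variance scale)")

lines = fecvar.line_summaries(data, fits[3])
print("within-line variance fold range:",
      round(fecvar.fold_range(lines["within_var_mean"]), 1))
```

prints

```
n_obs: 315 balanced: True
           Dbar    Dhat    pD     DIC
Model 1  3705.4  3703.4   2.0  3707.4
Model 2  3395.7  3374.4  21.3  3417.1
Model 3  3255.5  3212.4  43.1  3298.6
Model 5  3395.9  3374.3  21.6  3417.4
dDIC(Model 2 - Model 3) = 118.5: essentially no support for simpler
sigma_among = 72.8 [52.7, 102.0]
sigma       = 53.1 [49.0, 57.7]
ICC: 58% (SD scale), 66% (variance scale)
within-line variance fold range: 68.4
```

Reading the output: model 2 beats model 1 (lines differ in mean LF) and
model 3 beats model 2 by ΔDIC ≈ 118 (lines differ in their *variance* of
LF — the generator's heteroscedasticity is real and DIC finds it), while
model 5 adds nothing over model 2 (no block effect was simulated). The
effective parameter counts pD ≈ 2, 21 and 43 track the models' free
means/variances. About 58% of dispersion (SD scale) is among lines, and
the most variable line has ~68× the within-line variance of the least
variable one. Each fit also carries `convergence_`, which checks the
Monte-Carlo error of every parameter against 5% of its posterior SD.

The estimators are scikit-learn style: `GibbsFecundityModel(model=3,
seed=0).fit(data)` exposes `get_params`/`set_params` and trailing-underscore
fitted attributes (`trace_`, `summaries_`, `dic_`, `convergence_`);
`fecvar.fit(model, data, priors, mcmc)` is the thin functional wrapper.

## Command line

```bash
fecvar simulate --study both --seed 3 --out data.csv
fecvar compare --data data.csv --food b_pumilus --allow-negative --seed 1
fecvar run --config analysis.yaml --seed 1 --out report/
```

`run` drives the full pipeline (simulate/load → fit per food → DIC ladder →
variance components → line summaries → CV correlations) and writes CSV
tables, per-model traces and a JSON manifest that makes the run exactly
reproducible.

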