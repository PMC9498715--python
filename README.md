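# holopred

Holo-omics prediction of complex traits: does modelling the **interaction**
between a host's genome and its gut microbiome improve phenotype prediction
over using either alone?

`holopred` is a research pipeline for livestock-style holo-omics studies
(dairy-cattle milk/methane traits, pig feed-efficiency traits and the like).
It builds the standard sample × sample similarity kernels, fits multi-kernel
Bayesian linear mixed models by Gibbs sampling, and scores competing models by
repeated 10-fold cross-validated prediction accuracy — with a synthetic
holo-omics data generator so every stage is testable without animal data.

## Models

All models are linear mixed models of the form

```
y = Xβ + Wγ + Σ_k u_k + e,        u_k ~ N(0, K_k σ²_k),   e ~ N(0, I σ²_e)
```

with fixed effects β (e.g. farm, age, weight), class-effect blocks γ (diet,
slaughter day, pen) fitted under a BayesB mixture prior, and kernel random
effects `u_k` (RKHS terms) whose covariance kernels are:

| kernel | construction |
|---|---|
| **GRM** `G` | VanRaden: `G = (Z − 2Q)(Z − 2Q)' / Σ_m 2 p_m (1 − p_m)` from SNP dosages Z ∈ {0,1,2} |
| **MRM** `M` | `M = R R' / q` from log-transformed, per-OTU standardised relative abundances |
| **Hadamard** `G ∘ M` | entry-wise product — PSD interaction kernel (Schur product theorem) |
| **CORE** | `½ (L_G L_M' + L_M L_G')` from Cholesky factors — covariance between the two random effects |

Five model labels assemble these: `genomic` (G), `microbial` (M), `direct`
(G + M), `core` (G + M + CORE), `hadamard` (G + M + G∘M). Prediction accuracy
is the squared Pearson correlation r² between predicted and observed
phenotypes of held-out folds, averaged over folds and repeats; models are
compared by one-way ANOVA with Tukey HSD on the per-repeat r² values.

Upstream filters: SNPs at minor-allele frequency ≥ 0.01, OTUs present in
≥ 20% of samples (both configurable).

## Worked example

```python
import holopred as hp

# a synthetic herd-structured dataset with known variance decomposition
params = hp.SimulationParams(seed=7)          # n=400, fractions g/m/gm/e = 0.3/0.3/0.1/0.3
ds = hp.simulate_holoomics(params)

# fit the Hadamard interaction model
spec = hp.build_model("hadamard", ds.kernels, ds.phenotypes)
post = hp.fit(spec, ds.phenotypes, hp.McmcSettings(n_iter=3000, burn_in=800, thin=5, seed=1))
for term, frac in post.variance_fractions().items():
    print(f"  {term:9s} {frac:.3f}")

# cross-validated accuracy of four competing models
folds = hp.make_folds(params.n_samples, 10, repeats=3, seed=2)
st = hp.McmcSettings(n_iter=500, burn_in=150, thin=2, seed=3)
results = [hp.cross_validate(lbl, ds.phenotypes, ds.kernels, st, folds)
           for lbl in ("genomic", "microbial", "direct", "hadamard")]
for res in results:
    print(f"{res.model_label:9s} mean r2 = {res.mean_r2:.3f} +/- {res.sd_r2:.3f}")
comp = hp.compare_models(results)
print(f"ANOVA F = {comp.F_statistic:.2f}, p = {comp.p_value:.2e}")
```

prints

```
  GRM       0.356
  MRM       0.264
  HADAMARD  0.093
  residual  0.286
genomic   mean r2 = 0.204 +/- 0.018
microbial mean r2 = 0.237 +/- 0.006
direct    mean r2 = 0.284 +/- 0.012
hadamard  mean r2 = 0.271 +/- 0.003
ANOVA F = 28.92, p = 1.21e-04
```

The posterior variance fractions track the simulation truth (0.3/0.3/0.1/0.3),
and the holo-omics models clearly out-predict the single-kernel models; the
ANOVA confirms the differences are far beyond repeat-to-repeat noise.

The same pipeline runs from the shell:

```sh
holopred simulate --n-samples 400 --seed 7 --out data/
holopred cv --genotypes data/genotypes.tsv --otu-table data/otu_table.tsv \
    --phenotypes data/phenotypes.csv --class-columns diet \
    --model hadamard --k 10 --repeats 3 --out cv_hadamard.csv
holopred run config.yaml        # full filter -> kernels -> CV -> comparison run
```

## Layout

- `holopred.kernels` — filters and the four kernel constructors
- `holopred.model` — Gibbs sampler (BayesB blocks + RKHS kernel terms), prediction
- `holopred.evaluation` — folds, r², repeated CV, ANOVA/Tukey comparison
- `holopred.simulate` — synthetic holo-omics data with known variance structure
- `holopred.io`, `holopred.pipeline`, `holopred.cli` — file formats, YAML-configured end-to-end runs

See `docs/methods.md` for modelling details, priors, and known limitations.
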