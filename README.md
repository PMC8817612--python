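# trialkit

Linear mixed-model analysis of plant-breeding field trials: quality control,
REML-fitted single-trial models with spatial (AR1⊗AR1) plot error,
multi-environment trial (MET) analysis with factor-analytic
genotype-by-environment covariance, two-stage weighted analysis, genomic
BLUP, and a self-contained HTML report.

## Who it is for

Breeding programs phenotype the same set of genotypes across locations and
seasons, usually in resolvable incomplete-block (alpha-lattice) designs laid
out on a field grid. Turning those plot-level books into ranked genotype
predictions requires correcting for design factors and spatial field trend,
pooling information across environments, and — when marker data exist —
exploiting genomic relationships. `trialkit` packages that workflow as a
Python library plus a `trialkit` command-line tool.

## The models

**Single-trial.** Each environment is fitted with five candidate mixed
models sharing `y = μ + rep + genotype + block(rep) + ε` (genotype and block
random) and differing in the error structure: iid; iid plus random row and
column factors; separable first-order autoregressive error
`R = σ²_ε Σ_c(ρ_c) ⊗ Σ_r(ρ_r)` across field columns and rows; and the two
one-axis AR1 reductions. Models are compared by AIC (variance parameters
only; fixed parts are identical). From the best model the package extracts
genotype BLUPs, the generalized (Cullis) heritability

    H_c = 1 − V̄_BLUP / (2 σ²_g),

where `V̄_BLUP` is the mean variance of a difference of two genotype BLUPs
(from prediction-error variances and covariances), and a residual
semivariogram over row/column displacements for spatial diagnostics.

**Multi-environment.** Ten single-stage models place increasingly rich
covariances on the genotype-within-environment effects — compound symmetry,
heterogeneous/diagonal, uniform-correlation heterogeneous-variance (corh),
and factor-analytic `Σ = ΛΛ′ + Ψ` of order 1 or 2 — combined with iid,
per-environment, or spatial error. The fitted G-structure yields
environment correlation matrices, G×E BLUPs, per-genotype latent-regression
slopes on the first-factor loadings (stability), and an FA biplot. A
two-stage route computes per-environment genotype BLUEs (stage one, best
spatial model, genotype fixed) and fits the across-environment model on the
BLUEs weighted by 1/SE² with residual variance fixed at one.

**Genomic.** Marker dosages are centered and scaled (sample variance), the
genomic relationship matrix is `G = XX′/n`, and gBLUP replaces the iid
genotype covariance with `σ²_g G`, producing genomic estimated breeding
values (GEBVs).

All models are fitted by REML on the dense phenotypic covariance with an
L-BFGS optimizer on log-variance / atanh-correlation scale; see
`docs/methods.md` for the numerics.

## Worked example

```python
import numpy as np
from trialkit.synthdata import SimConfig, simulate_met
from trialkit import met, single_trial as st

cfg = SimConfig(n_geno=30, n_rep=2, n_block=3, rows=10, cols=6, n_env=4,
                fa_loadings=np.array([[1.2], [1.0], [0.8], [0.6]]),
                fa_psi=np.full(4, 0.2), rho_r=0.3, rho_c=0.3, seed=31)
book = simulate_met(cfg)

one = st.fit_models(book, "yield", env="E1", seed=0)
print(one.comparison[["model", "aic"]].head(3).to_string(index=False))
print(f"best: {one.best}  H_c = {one.heritability:.3f}")

res = met.fit_met_single_stage(book, "yield", model_ids=(1, 2, 7, 8), seed=0)
print(res.env_cor.round(2))
```

prints (numbers from this exact seed):

```
 model        aic
model3 178.741431
model2 185.556637
model5 192.039031
best: model3  H_c = 0.957
     E1   E2   E3   E4
E1  1.0  0.9  0.9  0.9
E2  0.9  1.0  0.9  0.9
E3  0.9  0.9  1.0  0.9
E4  0.9  0.9  0.9  1.0
```

The single-trial selection picks the separable spatial model (the generator
put AR1 correlation on both axes), H_c ≈ 0.96 is the repeatability of
genotype predictions in that trial (high here because the first
environment's genetic variance is large), and the environment correlation
matrix comes from the best-AIC G×E covariance structure — correlations
near 0.9 mean genotype rankings transfer well across these environments.

The same stages are available from the shell:

```bash
trialkit simulate --out book.csv --n-env 4 --n-geno 200 --seed 1
trialkit run --input book.csv --traits yield --out results --seed 1
```

`results/report.html` contains the QC decisions, model selection per trial,
MET results and stability plots as one self-contained document.

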