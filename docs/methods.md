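# Methods

## Model family

All analyses are linear mixed models

    y = Xβ + Σ_i Z_i u_i + ε,   u_i ~ N(0, G_i),   ε ~ N(0, R),

fitted by restricted maximum likelihood (REML). `X` carries the intercept
and design fixed effects with drop-first contrasts (or a one-hot cell-means
coding when genotype means are extracted as BLUEs); each `Z_i` is the
indicator expansion of a factor or factor interaction in a documented
sorted level order (interactions enumerate the full cartesian product of
the observed per-factor levels, outer factor slowest).

### Covariance structures

`trialkit.covstruct` implements: shared-variance identity, per-level
diagonal, compound symmetry (CS), uniform-correlation
heterogeneous-variance (corh), general correlation (corgh, validity
enforced by a Cholesky test rather than elementwise bounds), AR1,
separable Kronecker products of AR1/identity correlation factors,
factor-analytic FA(k) `ΛΛ′ + diag(Ψ)`, and a fixed-kernel form `σ²K` used
for genomic relationship matrices. Structures over environments apply to
genotype-within-environment effects as `Σ ⊗ I`.

FA identifiability: loadings above the diagonal are pinned to zero during
optimization; reported loadings are sign-fixed so each factor's
largest-magnitude loading is positive.

### Residual structures

Residuals are independent between environments (block diagonal). Within an
environment the error is iid, heterogeneous-by-environment iid, separable
AR1(column) × AR1(row), or AR1 along one axis only. Plot distance matrices
are computed directly from the 1-based field row/column coordinates, so
missing plots simply subset the implied covariance — correlations stay
distance-based, nothing is imputed. Spatial structures can be shared
across environments (one σ², ρ_c, ρ_r) or fitted per environment. Record
weights scale the iid residual diagonal by 1/w; the two-stage second step
fixes the residual variance at 1 so the stage-one standard errors carry
all the error information.

## REML numerics

The restricted log-likelihood is evaluated on the dense phenotypic
covariance `V = Σ_i Z_i G_i Z_i′ + R`:

    ℓ_R = −½ [ log|V| + log|X′V⁻¹X| + y′Py ] − ½ (n − p) log 2π,

where `P = V⁻¹ − V⁻¹X(X′V⁻¹X)⁻¹X′V⁻¹`. The `log|X′X|` compensation term
is omitted, matching the convention of common REML software, so values are
comparable across packages up to that data-independent constant. A
non-positive-definite `V` evaluates to −∞ (a large penalty inside the
optimizer).

Parameters are optimized unconstrained — log for variances, atanh for
correlations, identity for FA loadings — by L-BFGS-B within ±30 bounds
(guarding overflow). Gradients use the REML score
`∂ℓ/∂θ_i = −½[tr(P V̇_i) − y′P V̇_i P y]` with `V̇_i` formed by central
differences of only the covariance block that owns the parameter; for
shared-variance terms `V` is linear in `σ² = exp(θ)` and the derivative is
exact. Starting values split the OLS residual variance equally across
components (correlations start at 0); by default three starts are run, the
first from the heuristic and the rest jittered uniformly by ±0.7 on the
unconstrained scale, and the best restricted likelihood wins. A
line-search breakdown with a projected gradient below 1e−3 is treated as
converged (it occurs at flat boundary optima, e.g. a variance collapsing
to zero); otherwise non-convergence is flagged on the result, never
raised.

BLUEs are `(X′V⁻¹X)⁻¹X′V⁻¹y` with standard errors from the inverse
coefficient matrix; BLUPs are `G_i Z_i′Py`. Prediction-error variances and
pairwise covariances come from `G − G Z′PZ G`; PEC matrices are retained
for terms up to 600 levels (PEV always). AIC is `−2ℓ_R + 2k` with `k` the
number of free variance parameters only; model comparison refuses fits
whose fixed structures differ, since REML likelihoods are not comparable
across fixed parts, and breaks AIC ties toward fewer variance parameters.

## Generalized heritability and diagnostics

Cullis heritability is `H_c = 1 − V̄_BLUP/(2σ̂²_g)` with `V̄_BLUP` the mean
over genotype pairs of `PEV_i + PEV_j − 2 PEC_ij`, computed as
`2(m·tr C − 1′C1)/(m(m−1))`. A genotype variance below 1e−8 returns 0 by
convention; values escaping [0, 1] are clamped with a warning. In balanced
iid designs `H_c` reduces to `σ²_g/(σ²_g + σ²_ε/r)` (verified to 1e−6 in
the tests).

The semivariogram is `γ(d_r, d_c) =` half the mean squared difference of
conditional residuals at absolute row/column displacement `(d_r, d_c)`,
both diagonal directions pooled, each unordered pair counted once,
`γ(0,0) = 0`, cells with fewer than two pairs left empty. Note the surface
plateaus at the conditional-residual variance, which is smaller than
`σ²_ε` because BLUPs absorb part of the noise.

## The MET model set

Environment-and-replicate cell means are fixed in all single-stage MET
models. The design intent was a random environment main effect alongside
fixed replicates-within-environments; because the rep-within-env contrasts
span the environment means, a separate random environment effect is not
identifiable, so environment means live in the fixed part and the
G-structures below carry everything genetic. Blocks within (environment,
replicate) are always iid random.

1. genotype main + iid G×E, iid error — compound symmetry by the classic
   variance-component identity;
2. explicit CS on genotype-within-environment, iid error (must match
   model 1's likelihood — used as a built-in regression check);
3. CS + per-environment error variances;
4. CS + common AR1⊗AR1 error;
5. CS + per-environment best spatial error (imported from the
   single-trial selection);
6. diagonal G (heterogeneous variance, zero correlation);
7. corh G;
8. FA(1); 9. FA(2); 10. FA(1) + common AR1⊗AR1 error.

Models 6–9 use per-environment error variances. FA fits that fail to
converge are retried from three extra jittered starts.

Stability outputs: environment covariance is the realized fitted
G-structure (`ΛΛ′ + Ψ` for FA), correlation by standardization (zero-
variance environments get undefined rows); latent regression fits, per
genotype, OLS of its G×E BLUPs on the first-factor loadings, reporting
slope, intercept and a 95% t-interval (slopes equal factor scores exactly
as Ψ → 0); the biplot takes environment vectors from the principal-axis
rotation of Λ (first two factors; for FA(1) the second axis falls back to
√Ψ) and genotype scores from least-squares regression of the G×E BLUPs on
those vectors. The default selection flag marks the top decile by mean
predicted value.

### Two-stage analysis

Stage one fits each environment's best spatial model with genotype fixed
(cell means), yielding BLUEs and standard errors; degenerate SEs drop the
cell with a log entry. Stage two fits
`blue = μ + genotype + env + genotype:env + ε` with all three terms iid
random, diagonal weights `1/SE²`, and the residual variance fixed at one.
Under balanced iid data the stage-two genotype BLUPs correlate ≥ 0.99 with
the single-stage model-1 BLUPs (an acceptance check).

## Quality control

Order: missingness → outliers → reliability, deterministic given the
seed. A trial is dropped when its missing-response proportion strictly
exceeds 0.20 (proportions reported to 4 decimals). Descriptive statistics
use the sample (n−1) SD and `CV = 100·sd/mean` (undefined, not infinite,
at zero mean). Outliers: conditional residuals of the baseline
design-factor model (model 1, so flags do not depend on the later spatial
choice) are standardized by their sample SD, given two-sided normal
p-values, and screened by Holm step-down at α = 0.05; flagged responses
are masked, not deleted. This is conservative under the null — the
measured family-wise false-flag rate is far below α because conditional
residuals are shrunken — while an 8-SD spike in a 400-plot trial is still
detected essentially always. Trial reliability is the generalized
heritability of the trial's fit, thresholded at 0.2; the reliability of a
weakly heritable trial is estimated with sampling noise of order
`sd(σ̂²_g)/σ²_ε ≈ 0.07` at 200 genotypes × 2 reps, so borderline trials
(true H_c near 0.1–0.2) are misclassified at a nontrivial rate — the
filter is a screen, not a test.

## Genomic BLUP

Marker dosages (0/1/2, minor-allele counts) are validated; monomorphic
markers are dropped and missing entries imputed to the marker mean.
Columns are centered and scaled to unit sample (n−1) variance and
`G = XX′/n` over the `n` markers. G is individuals × individuals,
symmetric, PSD up to rounding, with zero row sums by construction; an
indefinite kernel (possible after subsetting or external input) is bent by
flooring eigenvalues at 1e−6 with a warning. The gBLUP fit places `σ²_g G`
on the genotype term, keeps replicates (within environments) fixed and
blocks plus non-genetic G×E iid random, and reports genotype BLUPs as
GEBVs with PEV.

## Synthetic data generator

The generator emulates the structure of a rainfed-rice screening book:
200 genotypes, 2 replicates, 6 incomplete blocks per replicate on a
20 × 20 grid by default, genotypes randomized to blocks within each
replicate and plots assigned serpentine-wise (field-realistic and
deterministic under the seed). Default variances: σ²_g = σ²_ε = 1,
σ²_block = 0.1, σ²_env = 0.25, σ²_ge = 0.25, ρ_r = ρ_c = 0.4, overall mean
10 — a heritability regime (plot-level h² ≈ 0.5) typical of yield trials.
Spatial error is drawn exactly from the separable AR1⊗AR1 process via the
Kronecker-factor Cholesky identity. MET books draw genotype-by-environment
genetic values with covariance `ΛΛ′ + Ψ` (or CS) plus iid environment
means; marker panels sample allele frequencies uniformly on [0.05, 0.5],
dosages Binomial(2, p), and additive effects rescaled so the realized
genetic-variance fraction equals the requested h².

What the generator does **not** emulate: non-Gaussian traits, outliers or
missingness beyond the explicit injection helpers, linkage disequilibrium
between markers, dominance/epistasis, and non-stationary field trend
(fertility gradients beyond AR1). Passing tests therefore demonstrate
correctness of the estimation machinery under the stated model, not
robustness to every field pathology.

## Problem sizes and determinism

The test battery runs the recovery studies at desk scale, chosen as the
smallest designs at which each statistical claim genuinely holds: spatial
recovery uses 200 replicates of the full 20 × 20 demo trial;
factor-analytic recovery uses 100 replicates of 4-environment, 40-genotype
METs and checks the Frobenius distance of the *mean* estimated environment
covariance (a bias property; a single 40-genotype replicate has ~35%
relative error); detection-rate studies use the 400-plot demo trial. The
acceptance script reruns the same blocks at reduced replicate counts and
records the replicate count beside every value. All randomness flows
through explicit integer seeds; identical seeds give byte-identical
generated tables and, modulo one timestamp line, byte-identical HTML
reports.

## Known limitations

Dense linear algebra bounds practical problem sizes to a few thousand
plots per fit; no average-information updates or sparse solvers; no
standard errors of variance components; Wald fixed-effect tests are
approximate (no denominator-df correction); the two-stage route uses
diagonal weights (not the full stage-one covariance); single-step
pedigree+genomic analysis and spline-based spatial models are out of
scope.
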