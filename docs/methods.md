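# Methods

## Outcome construction

The three two-week recall illness indicators (diarrhoea, fever, cough) are
collapsed into an 8-level categorical outcome by the fixed combination
table in `morbmap.outcomes` (all three → 1, diarrhoea+fever → 2,
diarrhoea+cough → 3, fever+cough → 4, singles 5–7, none → 0). The map is a
bijection on {0,1}³, so the synthetic generator can back-fill flags from a
sampled category and encoding round-trips exactly. Missing flags are never
imputed: the row is flagged for exclusion with a reason in the validation
report.

## Covariate recoding

* Child age: `[0,20)`, `[20,40)`, `[40,60]` months, half-open left-closed.
  The bin *names* are fixed by convention in this literature; boundary
  membership is not, so the half-open choice is documented here and
  recorded in every run manifest.
* Maternal age at first birth: split at 20 years, `<=20` closed on the
  left. Source material for this kind of analysis sometimes describes the
  variable as current maternal age; this package consistently uses age at
  first birth and the recode is labelled accordingly.
* BMI: binary split, default threshold **18.5** (the WHO underweight
  cut-point); 18.0 is supported because "BMI over 18" phrasing is common
  and ambiguous. Neither is presented as canonical; the choice is in the
  manifest.
* Wealth quintiles may optionally be collapsed to
  poorest/poorer — middle — richer/richest.

Recoding is idempotent and raises (with row ids) on out-of-domain values.

## The spatial prior and its fixture

Region effects use the intrinsic CAR prior: precision `(1/σ²_θ) Q` with
`Q = D − A` the graph Laplacian of the governorate adjacency graph. `Q` is
rank `R − c` (c connected components), so the prior is improper; the
sum-to-zero constraint per category restores identifiability, with the
intercept absorbing each recentring so the linear predictor is untouched.

The bundled 27-governorate adjacency list was curated for this package
from public administrative maps (desert borders are approximate, and the
standard four EDHS macro-regions are recorded in the id→name lookup). No
authoritative adjacency list exists for this analysis; any edge-list file
can be substituted, and every result records which graph was used.

## P-splines

Metrical covariates can enter as B-spline expansions (cubic, 20 interior
equidistant knots by default — the standard structured-additive-regression
convention) with penalty `K = D₂'D₂`, the Bayesian analogue of a
second-order random walk on adjacent coefficients; `rank(K) = m − 2`
(constants and linear trends unpenalised). Bases are column-centred for
identifiability against the intercept. The default model uses **linear
effects only**, mirroring the final specification this design follows;
splines are a configuration option.

## Sampler

Per non-reference category `k`, coefficient blocks (`β_k`, spline blocks,
`θ_k`, `φ_k`) are updated by Metropolis–Hastings with IWLS proposals: the
proposal is the Gaussian from one weighted-least-squares step at the
current state (precision `X'WX + P₀`, `W = diag(π_k(1−π_k))` floored at
1e-8), and the acceptance ratio uses the reverse proposal rebuilt at the
proposed state, so the chain is exact despite the asymmetric proposal.
Region blocks exploit that each child lies in one region (`X'WX` is
diagonal via bincounts), making sweeps O(n) per block. Variances use the
conjugate inverse-gamma update `IG(a + rank(P)/2, b + γ'Pγ/2)`.

Defaults (all configurable, conventions of the Bayesian structured
additive regression software family): 12,000 iterations, 2,000 burn-in,
thinning 10; fixed-effect prior precision 1e-6; `IG(0.001, 0.001)`
hyperpriors; initial values from a deterministic one-step ridge/prior
penalised IWLS fit, θ = φ = 0, variances 0.1. Linear predictors are
clipped at ±30 (numerical saturation). Acceptance rates are logged per
block; rates outside [0.05, 0.95] produce a warning, never silence — IWLS
proposals routinely accept above 0.95, which is benign but reported.
Identical seeds give identical chains; chains persist as one text file per
block plus a JSON manifest for exact reruns.

## Posterior summaries

"Posterior OR" = `exp(posterior mean of the coefficient)`; intervals are
exp of the 2.5%/97.5% equal-tailed empirical coefficient quantiles
(linear-interpolation quantiles). Both conventions in circulation —
summarise-then-exp vs exp-then-summarise — are implemented; the default is
the former and the results bundle records which was used. Highest-density
intervals are not implemented. Spatial tables summarise the structured
effect θ by default (`component="total"` adds φ), on both coefficient and
exp scales, with a sign-significance flag (interval excludes 0) and a risk
ranking.

## The synthetic world

`generate_survey` is the exact generative mirror of the fitted model:
independent covariates from stated marginals (a joint-sampler hook exists;
no covariate dependence structure is asserted), uniform region assignment,
ICAR θ (eigen-decomposition sampling with explicit null-space removal —
exact at these graph sizes — then centred), Gaussian φ, category sampled
from the multinomial-logit probabilities, flags back-filled.

Two stated worlds ship:

* `two_binary_truth` — two balanced binary covariates, per-category
  coefficients (incl. intercepts) uniform in [−1, 1], σ²_θ = 0.3,
  σ²_φ = 0.1, n = 4,000: the recovery/calibration testbed.
* `edhs_like_truth` — n = 10,872 with the full analysis covariate set at
  marginals chosen once to resemble a 2008 Egyptian DHS round (healthy
  majority, fever+cough the most common overlap, young-age and urban
  effects on the triple-illness state). It emulates *structure*, not the
  real data: no survey weights, clustering, stratification, covariate
  dependence or item missingness. A green test on synthetic data
  establishes the estimator and plumbing, not substantive epidemiology.

## What the tests do and do not establish

Unit and property tests pin exact structural identities (Laplacian ranks,
spline partition of unity, encoding bijection, likelihood closed forms
against brute-force oracles) and validate the sampler two independent
ways: posterior means match a maximum-likelihood multinomial logit from an
independent optimiser when spatial terms are off, and credible intervals
show near-nominal frequentist coverage under a null world.

One caveat is inherent to convolution spatial models: the likelihood
identifies only the **total** region effect θ + φ; the split between
structured and unstructured parts is prior-driven. On realistic data the
posterior-mean θ tracks the total effect closely (rank correlation ≥ 0.6
in every category in the recovery experiment) but its correlation with the
true θ alone can drop well below that in individual categories — an
information limit, not a sampler defect (the exact penalised-likelihood
mode with the true variances shows the same behaviour).

## Known limitations

* No survey design features (weights, clusters, strata) — deliberate.
* No multiple imputation; complete-case analysis with logged exclusions.
* The SAV reader's DHS code translations are best-effort and must be
  checked against the specific release's recode manual.
* Category-specific blocks are updated conditionally; very sparse
  categories (few dozen events) mix more slowly and widen honestly.
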