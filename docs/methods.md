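# Methods

## The prognostic model

Overall survival is modelled by Cox proportional hazards with an elastic-net
penalty. With features standardized to mean 0 and population variance 1, the
solver minimizes

    f(β) = -(1/n) ll(β) + λ [ α ‖β‖₁ + (1-α)/2 ‖β‖₂² ],    α ∈ (0,1], λ ≥ 0,

where `ll` is the **Breslow** partial log-likelihood. Breslow ties are used
throughout the package — the univariate scans, the stratified
likelihood-ratio models and the penalized solver all share one likelihood
implementation — so deviances computed in different stages are directly
comparable. The saturated log-likelihood under Breslow ties is
`-Σ_k d_k log d_k` over event times with multiplicity `d_k`, hence the
deviance `2(ll_sat − ll)` reduces to `-2 ll` when event times are distinct.

Coefficients are reported on the original feature scale and as *scaled
coefficients* (original β × feature SD, i.e. the standardized-scale values),
which express the contribution of one standard deviation of each feature to
the linear predictor. An all-zero coefficient vector ("empty selection") is
a valid model state: its risk scores are constant, and evaluation reports a
flagged concordance of 0.5 instead of failing, so feature-type combinations
with no prognostic signal complete the workflow.

### Hyperparameter selection

The (α, λ) pair is chosen by bootstrap out-of-bag deviance: B resamples of
size n with replacement; every grid point is fit on the in-bag subjects
(warm-started along each α's descending λ path) and scored by Breslow
deviance on the out-of-bag subjects; the pair with the lowest unweighted
mean OOB deviance wins. Defaults follow the standard design: nine α
(0.1–0.9 by 0.1), twenty λ (10² → 10⁻², log-spaced), B = 100. Resamples
whose in-bag or out-of-bag sets carry no events are redrawn (logged; hard
error after 1000 redraws). Ties in the mean deviance break toward the
largest λ, then the largest α — the most parsimonious model. An option
(`per_event`) normalizes each resample's OOB deviance by its event count
before averaging; the unnormalized mean is the default.

Single-feature inputs (the clinical-stage-only model) skip regularization
entirely and are fit by Newton–Raphson on the unpenalized likelihood.

### Numerical choices

* **Solver.** Proximal Newton: at each outer iteration the likelihood is
  replaced by its diagonal-Hessian weighted least-squares model and solved
  by cyclic coordinate descent with soft-thresholding (active-set cycling).
  A backtracking line search on the true penalized objective guarantees
  monotone descent; without it the outer loop can oscillate in the weakly
  penalized, p ≈ n regime. Per-subject Hessian weights are clamped below at
  1e-9.
* **Convergence.** A fit is converged when the largest coefficient change
  across an outer iteration falls below `tol` (final fits: 1e-7), or when
  the objective decrease stalls below 1e-13 (relative) on two consecutive
  iterations — at that point remaining coefficient drift lies in directions
  the objective cannot resolve. Bootstrap *tuning* fits use `tol = 1e-3`:
  the OOB deviance surface is flat far below that resolution (selected grid
  point and mean deviances agree with `tol = 1e-4` runs to three decimals)
  at roughly a third of the cost.
* **Optimality certificate.** `kkt_max_violation` checks the subgradient
  stationarity conditions on the standardized scale; random-instance tests
  hold it below 1e-5 (observed ~1e-7).
* **Standardization** uses the population (1/n) standard deviation;
  zero-variance columns must be removed before fitting (the training
  workflow's dedup step does this).

## Filters

* **Sparse filter:** features non-zero in ≤ 5% of training samples are
  removed; the boundary is inclusive (exactly 5% ⇒ removed).
* **Perfect-correlation dedup:** after removing zero-variance features,
  among any group with |Pearson r| = 1 on the training samples (tolerance
  1e-12) only the first feature in column order survives. Anti-correlated
  duplicates (r = −1) carry identical information for a linear model and
  are deduplicated too.
* **Copy-number calls:** segment score = mean of member-gene log2 scores;
  gain iff score > 0.3, loss iff score < −0.3, both strict (0.30 exactly is
  neutral).

## Subtyping

Samples are assigned the subtype whose reference centroid maximizes the
Spearman correlation with the sample profile over shared genes (≥ 3
required), after subtracting a subgroup-specific per-gene centering vector.
Exact ties go to the first subtype in declared column order and are
flagged; constant profiles are `unassignable`. Claudin-low status requires
both (a) correlation to the claudin-low centroid strictly exceeding every
other centroid and (b) membership in a majority-positive (> 50%) cluster of
a complete-linkage Euclidean dendrogram over an intrinsic gene list, cut at
k = number of subtypes + 1. The cut and majority rule are this package's
documented operationalization of "centroid positive and clustered
together"; singleton clusters satisfy the rule trivially and are flagged.
Centroids and centering vectors are always inputs — published centroid
files can be dropped in; the pipeline's simulate mode uses the generator's
own centroids and cohort-median centering.

## Association testing

Binomial GLMs (logistic; Wald inference; optional dataset fixed effect)
compare frequencies; complete separation is detected (|coef| > 15 or
SE > 100 or fit failure) and flagged with the estimate withheld. Univariate
and stratified Cox fits use the shared Breslow Newton solver. Wilcoxon
rank-sum p-values are exact by full enumeration over C(m+n, m) assignments
(midranks, hence valid under ties) when m + n ≤ 20, and use the
tie-corrected normal approximation otherwise. FDR control is
Benjamini–Hochberg, applied within each analysis family (each scan is its
own family; every result records its family id). Mutation features enter
association scans only when present in ≥ 5 training samples. The TP53
immune screen tests each signature, one-sided (greater), in each recurrent
(n ≥ 10) missense group and the pooled nonsense group against normal
samples, BH-adjusts the whole screen as one family, and selects signatures
significant in ≥ 1 missense group but not in the nonsense group.

## Evaluation

Harrell's C counts a pair comparable iff the shorter observed time is an
event (tied times are incomparable) and credits risk ties 0.5. The combined
test-set C is computed on pooled patients (per-set values are also
reported); pooling is the default because a single combined value is the
headline statistic, with per-set values alongside. Risk groups are cut at
each test set's own tertiles (median mode available via config).
Incremental value over stage comes from stratified Cox models — stage-only,
score-only, stage + score — reporting each model's likelihood-ratio
statistic versus the null and the percent LR increase in both addition
orders, plus Wald p-values of each joint-model coefficient. A score that
embeds stage renders the stage term redundant (non-significant) in the
joint model; that pattern is tested explicitly.

## The synthetic cohort generator

No public generative model exists for the target data, so the generator's
defaults define this package's study conditions:

| component | default | rationale |
|---|---|---|
| datasets | train 238, testA 224, testB 91, testC 133 (686 total) | multi-dataset structure with one discovery and three test sets |
| stage III fraction | 0.236 | pooled stage distribution of an early-stage TNBC cohort |
| mutation catalog | 700 genes; TP53-like gene at frequency 0.85; others log-uniform on [0.01, 0.15] | one dominant driver plus a low-frequency tail |
| TP53 variants | 134 protein changes; 7 hotspots (R175H, R273H, R213\*, Y220C, R273C, R306\*, R248Q) with elevated weights; classes ~60% missense / 15% nonsense / 15% frameshift / 5% splice / 5% in-frame | typed hotspot structure for the variant-level features |
| copy number | 534 segments × 3 genes; per-segment gain/loss probabilities log-uniform on [0.02, 0.40]; event magnitude ≈ 0.6; gene noise SD 0.15 | segment-structured gains/losses recoverable by the ±0.3 calls |
| signatures | 759 signatures × 5 member genes; member expression = latent N(0,1) score + N(0, 0.5) noise | median scoring recovers the latent score with mild attenuation |
| survival | Weibull baselines per dataset (shape 0.8–1.3, scale 10–25 y), hazard × exp(X·β_true); uniform administrative censoring on (0, 10 y] | simplest parametric family admitting proportional hazards; censoring independent of covariates |
| planted effects | stage +0.5, two signatures −0.5/−0.4, one segment loss +0.4 | small, mixed-platform truth for recovery tests |

One integer seed drives a named sub-stream per platform (clinical,
mutation, TP53, HRD, copy number, expression, subtype, survival, plus one
per bootstrap resample), so regenerating one platform or growing B never
perturbs other draws, and a fixed seed fixes every emitted byte.

What the generator does **not** emulate: tumor purity, allele fractions,
platform batch effects, linkage between platforms (mutations, copy number
and expression are independent given the planted effects), and real
signature correlation structure. Passing tests therefore demonstrate that
the machinery recovers truth under its stated model — not that the same
effect sizes or C-indexes would be observed in real cohorts.

## Reference experiment sizes

The scaled-down studies in `tnbcprog.benchmarks` (used by the test suite
and the acceptance script) run, per seed: a 600-patient training / 300-
patient test cohort with 10 planted signature effects (|β| ∈ [0.5, 0.8],
alternating sign) among 500 noise signatures; tuning over 3 α × 10 λ with
B = 25. The reduced grid keeps the full grid's ceiling (10²) but a floor of
10⁻¹: at these cohort sizes smaller penalties only explore the saturated-
fit regime, which never wins the OOB selection and dominates compute. The
end-to-end workflow study trains all seven feature-type combinations on a
238-patient training set with reduced catalogs (60 signatures, 80 genes,
20 TP53 variants, 40 segments) and survival effects planted on stage and
RNA only, so the DNA-only model exercises the empty-selection pathway.

## Known limitations

* Efron tie handling, time-varying covariates and interval censoring are
  out of scope; with heavy ties Breslow estimates are biased toward zero.
* The penalized solver's convergence rate degrades as λ → 0 with p ≳ n
  (near-flat likelihood); the objective-stall criterion makes such fits
  terminate with certified-stationary but direction-ambiguous coefficients.
* GLM separation detection is heuristic (threshold-based); exact logistic
  regression is not implemented.
* The immune screen's FDR family is the entire screen; per-group
  sub-families are not offered.
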