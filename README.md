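# tnbcprog

Multi-platform prognostic modelling of overall survival in stage II–III
triple-negative breast cancer (TNBC).

Early-stage TNBC lacks targeted therapies, and tumor stage is still the
main prognostic tool in the clinic. This package implements, as a tested
and reusable pipeline, the analysis needed to ask whether DNA features
(gene-level somatic mutations, variant-level *TP53* mutations, segment-level
copy-number gains/losses) and RNA features (expression-signature scores)
add prognostic information beyond stage:

* **feature assembly** — binarized somatic mutations (MAF input), ploidy-
  corrected copy number collapsed to segment means with gain/loss calls at
  ±0.3, upper-quartile–normalized expression scored against signature
  catalogs and median-centered;
* **intrinsic subtyping** — nearest-centroid (Spearman) calls after
  subgroup-specific gene centering, plus dual-criteria claudin-low calling;
* **univariate association testing** — binomial GLMs, (stratified) Cox
  models, exact/asymptotic Wilcoxon rank-sum tests, Benjamini–Hochberg FDR,
  Kaplan–Meier/log-rank, and a *TP53* recurrent-missense immune-signature
  screen;
* **prognostic modelling** — elastic-net Cox proportional hazards, with the
  penalty pair (α, λ) chosen by the lowest average out-of-bag Breslow
  deviance over bootstrap resamples of the training cohort;
* **evaluation** — Harrell's C on held-out test sets, tertile risk groups
  with log-rank tests, and nested likelihood-ratio comparisons against
  tumor stage.

Because the study data this pipeline targets are controlled-access, the
package ships a **synthetic cohort generator** with known ground truth
(planted coefficient vector, per-dataset Weibull baselines, planted
subtypes), so every stage is testable end to end.

## The model

For standardized features X the fitted model minimizes

```
-(1/n) · ll(β)  +  λ [ α ‖β‖₁ + (1-α)/2 ‖β‖₂² ]
```

where `ll` is the Breslow partial log-likelihood. A grid of nine α
(0.1–0.9) × twenty λ (10² → 10⁻², log-spaced) is scored by fitting every
point on each of B = 100 bootstrap in-bag sets and evaluating the Cox
deviance `2(ll_sat − ll)` on the out-of-bag subjects; the pair with the
lowest mean OOB deviance is refit on the full training set. Scaled
coefficients (β × feature SD) express each selected feature's contribution
per standard deviation. Single-feature (clinical-only) models are fit
unpenalized.

## Worked example

`examples/05_prognostic_model.py` trains an RNA-only model on a synthetic
cohort with three planted signature effects (−0.6, −0.5, +0.5):

```
chosen alpha=0.5, lambda=0.1
7 / 80 features selected
scaled coefficients (contribution per SD of the feature):
sig:SIG0002   -0.261
sig:SIG0001   -0.249
sig:SIG0030   -0.099
...
```

The two strongest protective signatures are the planted ones; the shrunken
extras are the usual elastic-net tail. `examples/06_incremental_value.py`
evaluates a signature-based risk score on two held-out test sets:

```
combined test-set C-index: 0.657
tertile-group log-rank p = 3.1e-06
LR(stage) = 1.71, LR(score) = 30.02, LR(joint) = 33.24
```

i.e. the score orders survival well (C ≈ 0.66), separates tertile risk
groups, and adds information far beyond stage (the joint-model score
coefficient stays significant).

The other examples cover simulation, feature assembly, subtyping and the
univariate scans. The same stages run from the shell:

```bash
tnbcprog run-all --config config.yaml --seed 1 --out out/
```

## Layout

```
src/tnbcprog/      synthetic, features, subtyping, stats, coxnet,
                   evaluate, pipeline, io, config, cli
examples/          one narrative script per capability
tests/             pytest suite (unit, property and acceptance tests)
docs/methods.md    modelling assumptions, defaults and numerical choices
```
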