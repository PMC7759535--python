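# Methods

`coxsig` builds and validates multigene prognostic signatures for overall
survival (OS) from gene-expression cohorts.  The pipeline has five stages,
each exposed as library functions and as a CLI subcommand; this note
records the statistical model behind each stage, the tunable parameters
and their defaults, the numerical choices, and the limits of what the
synthetic-data tests demonstrate.

## Pipeline model

**Stage 1 — consistent deregulation (`coxsig.deg`).**  For each
tumor/normal cohort, a per-gene Welch unequal-variance t-test is run on
log2 expression; p-values are Benjamini-Hochberg adjusted within the
cohort.  A gene is deregulated when |log2FC| strictly exceeds
log2(`fc_threshold`) (default 5, i.e. more-than-fivefold) and adjusted
p < `alpha` (default 0.05).  The cross-cohort filter keeps genes selected
in every cohort with the same direction everywhere.  Fold change is the
difference of class means on the log2 scale; with multiple probes per
gene, the probe with the highest mean expression represents the gene.
These three conventions (Welch test, log-scale FC, max-mean probe) are
package choices among the common options; each is a config point.

**Stage 2 — univariate OS screen (`coxsig.screen`).**  Each surviving
gene is tested in the discovery cohort two ways: a log-rank test of the
median-split high/low expression groups, and a single-covariate Cox fit
on continuous log2 expression (reported as HR).  The pass gate is the
log-rank p < `alpha` by default; gating on the Cox p instead is a flag.
Values tied with the median go to the "low" group, so "high" means
strictly above the median — a deterministic tie rule that makes the split
invariant under monotone transforms of expression.  No multiplicity
correction is applied at this stage; the screen is a filter, not an
inference.

**Stage 3 — resampling selection (`coxsig.resample`).**  The discovery
cohort of n patients is split `n_splits` = 100 times into a training set
of floor(2/3·n) patients and its complement (373 → 248/125).  Per split,
one joint multivariate Cox model of all candidate genes is fitted on the
training set; a gene is *selected* in that split when its Wald p < 0.05
in the joint model.  Genes are ranked by selection count (ties: higher
mean |coefficient| across splits, then gene id).  Then, for k = 1, 2, …,
the top-k genes are refitted per training set and Harrell's C of the
linear predictor is measured on the paired held-out set.  The signature
size k\* is the smallest k whose next `patience` = 3 prefixes improve the
mean held-out C by less than `tol` = 0.005.  The scan stops as soon as
the rule fires — later prefixes cannot change k\* and each one costs
`n_splits` Cox fits — and falls back to the argmax of the computed
profile if the rule never fires (an optional `max_k` caps the scan).
Finally the k\*-gene model is refitted on every training set; the
signature's coefficients are the arithmetic means of the per-split
coefficients, and its two cut points are the means of the per-split
33.33/66.67 percentiles of the training risk scores.  Tertiles are used
because a three-way good/intermediate/poor stratification of roughly
equal thirds is the intended clinical output; a KM-optimal cut search is
a possible alternative left as future config.

**Stages 4–5 — scoring and validation (`coxsig.scoring`).**  The risk
score of a sample is Σ coefficient_g · log2-expression_g.  Groups:
score ≤ cut_low → good, ≤ cut_high → intermediate, else poor (boundaries
to the lower-risk group).  Validation reports per-group Kaplan-Meier
curves, the k-group log-rank test, and intermediate-vs-good /
poor-vs-good hazard ratios with 95% CIs from a Cox fit on group
indicators.  `refit_in_cohort` transfers a fixed gene list to a new
cohort by re-running the resample-averaging locally; a calibration
subset, when given, restricts each split's cut-point estimation to the
training members of that subset (the full cohort reduces exactly to the
default).  `adjusted_cox` adds reference-coded clinical covariates
(reference level = first alphabetically unless configured) to the group
indicators in one joint fit.  `compare_signatures` refits two panels on
the same training halves and compares the medians of their held-out
poor-vs-good HRs; held-out evaluation is used throughout because the
pipeline's own concordance criterion is held-out.

## Survival primitives

All four primitives are implemented here (`coxsig.survival`) rather than
wrapped, because every stage needs low-level access (per-split warm
array paths, likelihood traces, deterministic tie rules); `lifelines`,
`scikit-survival` and R's `survival::coxph` are used as independent
cross-checks in the test suite only.

- **Cox fit**: Newton-Raphson on the Efron-corrected partial likelihood;
  at most 100 iterations, relative log-likelihood tolerance 1e-9,
  step-halving whenever a step would decrease the (penalized)
  likelihood, covariates mean-centered for exponent stability.  When all
  event times are distinct the Efron terms reduce to Breslow's and a
  fully vectorized O(n·p²) path is used; tied data take a per-unique-time
  sweep.  Standard errors come from the inverse of the observed
  (penalized, if ridge > 0) information; Wald p-values use the standard
  normal.  An optional ridge penalty (default 0 for ≤ 5 covariates,
  1e-4 above) keeps joint many-gene fits invertible — tens of genes on a
  few hundred samples are otherwise near-singular.  A singular
  information matrix (constant or collinear covariates) raises a typed
  error rather than returning noise; non-convergence returns
  `converged=False` with a warning.
- **Kaplan-Meier**: product-limit over distinct event times; censored
  subjects leave the risk set after their time.
- **Log-rank**: k-group observed-minus-expected with the per-event-time
  hypergeometric covariance, chi-square on k−1 df; groups with zero
  events stay in the bookkeeping, and only a cohort with zero events
  total is an error.
- **Harrell's C**: usable pairs are (i, j) with t_i < t_j and an event
  for i; score ties count 1/2; implemented as a vectorized pairwise
  comparison (the test oracle is an explicit O(n²) loop).

## Synthetic study (`coxsig.simulate`)

The generator emulates the data the pipeline is designed for: per-gene
log2 baselines ~ Normal(8, 2) shared across cohorts; planted DE genes
shift tumor samples by a signed log2 effect (default |log2FC| = 3,
sign-consistent across the default six 30v30 cohorts); residual noise
Normal(0, 0.5).  Survival for tumor samples follows a proportional-
hazards model: hazard = 0.02/month · exp(Σ β_g·(x_g − mean)), with five
planted prognostic genes at β = 0.8 by default, censoring by an
independent Exponential(0.01/month) truncated at 120 months.  Those rates
put the marginal event fraction near 0.6, keeping Cox fits well-posed.
The default discovery cohort has 373 patients (the size at which the
2/3 floor gives the 248/125 partition); the resampling-stage test design
(`candidate_stage_spec`) uses 50 candidate genes, 5 planted, n = 400.
`gen_study` additionally emits a clinical table with an independent
covariate (age, no hazard effect) and a confounded one (stage,
correlated with the genetic risk and adding 0.4 per level to the log
hazard).

What the generator does **not** emulate: probe/batch artifacts,
non-proportional hazards, gene-gene correlation beyond the planted
effects, and informative censoring.  Passing tests therefore demonstrate
the pipeline's statistical correctness under its own model assumptions,
not robustness to real microarray pathologies.

## Numerical and degenerate-input choices

- Boundary conventions are strict where the selection phrase is strict:
  fold change must exceed the threshold; median-tied samples are "low";
  boundary scores take the lower-risk group.
- Splits with zero training events are skipped with a warning; more than
  20% skipped aborts the stage.  Non-converged per-split refits are
  excluded from the signature averages.
- The whole resampling stage is a pure function of (data, plan): a fixed
  seed reproduces bit-identical selection counts, profiles and models,
  and the pipeline manifest records artifact hashes to make reruns
  checkable.

## Known limitations

- The per-split joint Wald selection is anticonservative when events per
  covariate are low: with 50 noise covariates and ~170 training events
  the per-gene null selection rate roughly doubles relative to the
  nominal 5% (verified against independent implementations — it is a
  property of the method, not of this code).  Selection counts from
  high-dimensional candidate sets should be read as rankings, not
  calibrated frequencies; null-calibration checks in the tests use
  events-per-variable ≥ 10.
- Wald p-values (not likelihood-ratio) are used throughout, matching the
  HR-centric reporting convention of the field.
- No time-varying covariates, competing risks, interval censoring or
  stratified baselines; only right-censored OS is modeled.
- Test problem sizes (n = 120–400 cohorts, 10–100 splits, 20
  meta-replicates) were chosen so the full suite runs in well under a
  minute per module while keeping Monte-Carlo error far from the
  asserted tolerances.
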