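# coxsig

Resampling-based construction and validation of multigene prognostic
signatures for overall survival (OS) from gene-expression cohorts.

Prognostic gene panels (Oncotype-DX-style) are usually built by chaining
several fragile steps: choosing deregulated genes, screening them against
survival, picking a panel size, and fixing weights and risk-group cut
points.  `coxsig` packages that whole strategy as one tested, seeded,
gene-agnostic pipeline aimed at biostatisticians and computational
biologists building or auditing such signatures:

1. **Consistency filter** — genes deregulated tumor-vs-normal (Welch test
   on log2 values, BH-adjusted p < α, |fold change| > threshold) with the
   same direction in *every* cohort.
2. **Univariate OS screen** — median-split Kaplan-Meier + log-rank and a
   continuous single-gene Cox HR in a discovery cohort.
3. **Resampling selection** — 100 seeded train/test splits (2/3 vs 1/3;
   373 patients → 248/125); per split one joint multivariate Cox fit of
   all candidates; genes ranked by how often they reach Wald p < 0.05.
4. **Concordance saturation** — top-k prefixes are refitted per training
   set and scored by Harrell's C on the held-out halves; the signature
   size k\* is where the mean held-out C stops improving.
5. **Signature & validation** — risk score = Σ β̄_g · log2-expression_g
   with β̄ the split-averaged Cox coefficients; averaged training-score
   tertiles define good/intermediate/poor groups; validation reports KM
   curves, k-group log-rank, HRs with CIs, clinically adjusted Cox
   tables, cohort-local recalibration and head-to-head panel comparison.

The survival core (Efron-tie Cox partial likelihood via Newton-Raphson
with step-halving and optional ridge, Kaplan-Meier, k-group log-rank,
Harrell's C) is implemented in-package and cross-checked in the test
suite against `lifelines`, `scikit-survival` and R's `survival`.

A `synthetic_data` generator (`coxsig.simulate`) produces multi-cohort
studies with planted deregulated and prognostic genes under a
proportional-hazards model, so the entire pipeline is testable without
any external download.  See `docs/methods.md` for the model, parameter
defaults and limitations.

## Worked example

Build a signature on a synthetic discovery cohort (50 candidate genes of
which 5 carry a planted hazard effect β = 0.8, n = 400) and validate it
on an independent cohort from the same generative model:

```python
import numpy as np
from coxsig import (ResamplePlan, build_signature, concordance_saturation,
                    gen_expression, gen_survival, select_frequency,
                    validate_cohort)
from coxsig.simulate import candidate_stage_spec

spec = candidate_stage_spec(seed=7)
expr = gen_expression(spec, 100, n_tumor=spec.n_discovery, n_normal=0)
surv = gen_survival(expr, spec, 100)

plan = ResamplePlan(n_splits=100, train_fraction=2/3, seed=7)
sel   = select_frequency(list(expr.gene_ids), expr, surv, plan)
prof  = concordance_saturation(sel.ranked_genes, expr, surv, plan)
model = build_signature(sel.ranked_genes[:prof.k_star], expr, surv, plan)

print("signature size k* =", prof.k_star)
print("genes:", model.genes)
print("coefficients:", np.round(model.coefficients, 3))

ve = gen_expression(spec, 200, n_tumor=200, n_normal=0, cohort_name="val")
vs = gen_survival(ve, spec, 200)
rep = validate_cohort(model, ve, vs)
print("log-rank p = %.3g" % rep.logrank_p)
print(rep.hr_table.round(3))
```

Output:

```
signature size k* = 7
genes: ['G0000', 'G0004', 'G0001', 'G0002', 'G0003', 'G0012', 'G0010']
coefficients: [1.033 0.93  0.868 0.855 0.923 0.51  0.408]
log-rank p = 2.2e-19
                         HR  HR_lo95  HR_hi95      p
intermediate_vs_good  2.200    1.352    3.579  0.002
poor_vs_good          7.356    4.568   11.846  0.000
```

All five planted genes rank on top (the two trailing genes are the noise
tail the saturation rule tolerated), their averaged coefficients are
near the generating β = 0.8, and the three risk groups separate sharply
in the held-out cohort: intermediate patients die at about twice the
rate of good-prognosis patients and poor patients at about seven times,
with the CIs excluding 1.

The same stages are available from a shell via the `coxsig` CLI
(`simulate`, `deg`, `screen`, `select`, `score`, `validate`, `compare`,
`run-all`); `coxsig run-all --out-dir out/` executes the full pipeline
from a YAML config and writes every intermediate table, the signature
JSON and a hash manifest.

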