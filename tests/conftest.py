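import numpy as np
import pandas as pd
import pytest

from coxsig import GenerativeSpec, SurvivalCohort, gen_expression, gen_survival
from coxsig.simulate import candidate_stage_spec


def make_cohort(time, event, covariates=None, prefix="p"):
    """Convenience constructor for small hand-built cohorts."""
    time = np.asarray(time, dtype=float)
    ids = np.array([f"{prefix}{i}" for i in range(time.size)], dtype=object)
    cov = pd.DataFrame(covariates) if covariates is not None else None
    return SurvivalCohort(ids, time, np.asarray(event, dtype=int), cov)


@pytest.fixture(scope="session")
def candidate_bundle():
    """Discovery cohort for the resampling stage: 50 candidate genes of
    which 5 are planted prognostic at beta=0.8, n=400."""
    spec = candidate_stage_spec(seed=11)
    expr = gen_expression(spec, 100, n_tumor=spec.n_discovery, n_normal=0,
                          cohort_name="discovery")
    surv = gen_survival(expr, spec, 100)
    return spec, expr, surv


@pytest.fixture(scope="session")
def ph_cohort():
    """Mid-size single-covariate proportional-hazards cohort (beta=0.8)."""
    rng = np.random.default_rng(5)
    n = 500
    x = rng.normal(0.0, 1.0, n)
    t = rng.exponential(1.0 / (0.05 * np.exp(0.8 * x)))
    c = rng.exponential(25.0, n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return make_cohort(time, event, {"x": x}), 0.8
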