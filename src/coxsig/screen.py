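"""Univariate overall-survival screen of candidate genes.

Stage 2: each consistency-filtered gene is tested for association with OS
in a discovery cohort, by (a) log-rank comparison of the median-split
high/low expression groups and (b) a single-covariate Cox fit on the
continuous log2 expression.  The pass/fail gate uses the log-rank p by
default (Cox p gating available via ``gate``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .deg import ExpressionCohort
from .exceptions import CoxsigError
from .survival import SurvivalCohort, _cox_newton, logrank_test

log = logging.getLogger(__name__)


def median_dichotomize(values) -> np.ndarray:
    """Split a vector at its median into 'low'/'high' labels.

    Values strictly above the median are 'high'; values at or below the
    median are 'low', so the high group is strictly-above-median.  A
    constant vector cannot be split.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2 or np.unique(v).size < 2:
        raise CoxsigError("cannot median-split a constant vector")
    med = np.median(v)
    return np.where(v > med, "high", "low")


@dataclass
class ScreenResult:
    """Per-gene screen table plus the genes skipped (absent from matrix)."""

    table: pd.DataFrame
    skipped: list

    @property
    def passed_genes(self) -> pd.Index:
        return self.table.index[self.table["passed"]]


def univariate_screen(
    expr: ExpressionCohort,
    surv: SurvivalCohort,
    genes,
    alpha: float = 0.05,
    gate: str = "logrank",
) -> ScreenResult:
    """Screen genes for OS association in a discovery cohort.

    Samples are matched by id between the expression matrix and the
    survival table.  Output is sorted by the gating p-value, ties broken
    by gene id; ``passed`` is p < alpha on the gating test.
    """
    if gate not in ("logrank", "cox"):
        raise CoxsigError("gate must be 'logrank' or 'cox'")
    shared = expr.sample_ids.intersection(pd.Index(surv.patient_id))
    if len(shared) == 0:
        raise CoxsigError("no shared samples between expression and survival")
    pos = {p: i for i, p in enumerate(surv.patient_id)}
    sub = surv.subset(np.array([pos[s] for s in shared]))

    genes = list(genes)
    skipped = [g for g in genes if g not in expr.gene_ids]
    if skipped:
        log.info("univariate_screen: skipped %d absent genes", len(skipped))
    present = [g for g in genes if g in expr.gene_ids]

    rows = []
    for g in present:
        x = expr.values.loc[g, shared].to_numpy(dtype=float)
        try:
            labels = median_dichotomize(x)
            _, lr_p = logrank_test(sub, labels)
        except CoxsigError:
            lr_p = np.nan
        try:
            beta, se, *_ = _cox_newton(sub.time, sub.event, x[:, None])
            hr = float(np.exp(beta[0]))
            # se can hit 0 on perfectly separating covariates
            z = np.inf if se[0] == 0 else beta[0] / se[0]
            cox_p = float(2 * norm.sf(abs(z)))
        except CoxsigError:
            hr, cox_p = np.nan, np.nan
        rows.append((g, lr_p, hr, cox_p))
    table = pd.DataFrame(
        rows, columns=["gene_id", "logrank_p", "cox_HR", "cox_p"]
    ).set_index("gene_id")
    gate_p = table["logrank_p"] if gate == "logrank" else table["cox_p"]
    table["passed"] = gate_p < alpha
    order = np.lexsort((table.index.to_numpy(), gate_p.fillna(np.inf).to_numpy()))
    table = table.iloc[order]
    return ScreenResult(table, skipped)
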