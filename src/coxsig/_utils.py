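"""Internal helpers shared across pipeline stages."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .deg import ExpressionCohort
from .exceptions import CoxsigError
from .survival import SurvivalCohort


def align_expression_survival(
    expr: ExpressionCohort, surv: SurvivalCohort, genes
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Match samples between an expression matrix and a survival table.

    Returns (time, event, X, sample_ids) with X an (n_samples, n_genes)
    float array in the order of ``genes``.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in expr.gene_ids]
    if missing:
        raise CoxsigError(f"genes absent from expression matrix: {missing}")
    shared = expr.sample_ids.intersection(pd.Index(surv.patient_id))
    if len(shared) == 0:
        raise CoxsigError("no shared samples between expression and survival")
    pos = {p: i for i, p in enumerate(surv.patient_id)}
    idx = np.array([pos[s] for s in shared])
    X = expr.values.loc[genes, shared].to_numpy(dtype=float).T
    return surv.time[idx], surv.event[idx], X, list(shared)
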