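"""Multi-cohort tumor-vs-normal deregulation screen.

Stage 1 of the signature pipeline: per-cohort differential expression on
log2 values (Welch t-test, BH adjustment, fold-change + FDR selection),
then intersection across cohorts requiring a consistent direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import CoxsigError

log = logging.getLogger(__name__)

TUMOR, NORMAL = "tumor", "normal"


@dataclass
class ExpressionCohort:
    """A gene-by-sample expression matrix on log2 scale.

    ``values`` has unique gene ids as the index and unique sample ids as
    columns.  ``sample_class`` labels each sample tumor/normal and may be
    absent for survival-only cohorts (all samples treated as tumor).
    """

    values: pd.DataFrame
    sample_class: pd.Series | None = None
    cohort_name: str = ""
    scale: str = "log2"

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()].unique().tolist()[:5]
            raise CoxsigError(f"duplicate gene ids, e.g. {dup}")
        if v.columns.duplicated().any():
            raise CoxsigError("duplicate sample ids")
        if v.isna().any().any():
            raise CoxsigError("missing expression values")
        if self.sample_class is not None:
            sc = self.sample_class.reindex(v.columns)
            if sc.isna().any():
                raise CoxsigError("sample_class missing for some samples")
            bad = set(sc.unique()) - {TUMOR, NORMAL}
            if bad:
                raise CoxsigError(f"unknown sample classes {sorted(bad)}")
            self.sample_class = sc

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def class_samples(self, cls: str) -> pd.Index:
        if self.sample_class is None:
            raise CoxsigError(f"cohort {self.cohort_name!r} has no class labels")
        return self.values.columns[self.sample_class.to_numpy() == cls]


@dataclass
class DegTable:
    """Per-gene deregulation statistics for one cohort.

    ``table`` columns: log2_fold_change (tumor mean - normal mean on log2
    scale), p_value, adj_p, direction (up/down), selected.
    """

    cohort_name: str
    table: pd.DataFrame
    fc_threshold: float
    alpha: float

    @property
    def selected_genes(self) -> pd.Index:
        return self.table.index[self.table["selected"]]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise CoxsigError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def collapse_probes(
    matrix: pd.DataFrame,
    mapping: pd.Series | dict,
    sample_class: pd.Series | None = None,
    cohort_name: str = "",
) -> ExpressionCohort:
    """Collapse a probe-by-sample matrix to gene level.

    For genes measured by several probes, the probe with the highest mean
    expression is retained.  Probes absent from the mapping are dropped
    (count logged).
    """
    if not isinstance(mapping, pd.Series):
        mapping = pd.Series(mapping)
    mapped = matrix.index.intersection(mapping.index)
    n_dropped = len(matrix.index) - len(mapped)
    if n_dropped:
        log.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    sub = matrix.loc[mapped]
    genes = mapping.loc[mapped]
    means = sub.mean(axis=1)
    # highest-mean probe wins within each gene
    keep = means.groupby(genes.to_numpy()).idxmax()
    collapsed = sub.loc[keep.to_numpy()]
    collapsed.index = pd.Index(keep.index, name="gene_id")
    collapsed = collapsed.sort_index()
    return ExpressionCohort(collapsed, sample_class, cohort_name)


def per_cohort_deg(
    cohort: ExpressionCohort, fc_threshold: float = 5.0, alpha: float = 0.05
) -> DegTable:
    """Tumor-vs-normal differential expression within one cohort.

    Welch's unequal-variance t-test per gene on log2 values; BH adjustment
    across all genes; a gene is selected when |log2FC| strictly exceeds
    log2(fc_threshold) and adjusted p < alpha.
    """
    tum = cohort.class_samples(TUMOR)
    nor = cohort.class_samples(NORMAL)
    if len(tum) < 2 or len(nor) < 2:
        raise CoxsigError(
            f"cohort {cohort.cohort_name!r} needs >=2 samples per class "
            f"(tumor={len(tum)}, normal={len(nor)})"
        )
    xt = cohort.values[tum].to_numpy(dtype=float)
    xn = cohort.values[nor].to_numpy(dtype=float)
    lfc = xt.mean(axis=1) - xn.mean(axis=1)
    res = stats.ttest_ind(xt, xn, axis=1, equal_var=False)
    p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)  # 0-variance genes
    adj = bh_adjust(p)
    selected = (np.abs(lfc) > np.log2(fc_threshold)) & (adj < alpha)
    table = pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "p_value": p,
            "adj_p": adj,
            "direction": np.where(lfc >= 0, "up", "down"),
            "selected": selected,
        },
        index=cohort.gene_ids.rename("gene_id"),
    )
    return DegTable(cohort.cohort_name, table, fc_threshold, alpha)


def consistent_deg(tables: list[DegTable], require_all: bool = True) -> pd.DataFrame:
    """Genes deregulated with the same direction across cohorts.

    With ``require_all`` (default) a gene must be selected in every cohort;
    otherwise in a strict majority.  In both modes the direction must agree
    in all cohorts where the gene is selected.

    Returns a DataFrame indexed by gene_id with columns ``direction`` and
    ``n_selected``.
    """
    if len(tables) < 2:
        raise CoxsigError("need at least 2 cohorts for a consistency filter")
    all_genes = tables[0].table.index
    sel = pd.DataFrame(
        {t.cohort_name or i: t.table["selected"].reindex(all_genes, fill_value=False)
         for i, t in enumerate(tables)}
    )
    direction = pd.DataFrame(
        {t.cohort_name or i: t.table["direction"].reindex(all_genes)
         for i, t in enumerate(tables)}
    )
    n_sel = sel.sum(axis=1)
    need = len(tables) if require_all else len(tables) // 2 + 1
    enough = n_sel >= need
    # same direction wherever selected
    up = (direction.eq("up") & sel).sum(axis=1)
    down = (direction.eq("down") & sel).sum(axis=1)
    consistent = (up == n_sel) | (down == n_sel)
    keep = enough & consistent & (n_sel > 0)
    out = pd.DataFrame(
        {
            "direction": np.where(up[keep] > 0, "up", "down"),
            "n_selected": n_sel[keep].astype(int),
        },
        index=all_genes[keep],
    )
    out.index.name = "gene_id"
    return out.sort_index()
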