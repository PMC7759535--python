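"""Apply a signature to a cohort: scores, groups, KM/log-rank, hazard ratios,
clinically adjusted Cox, cohort-local recalibration and head-to-head
signature comparison."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._utils import align_expression_survival
from .deg import ExpressionCohort
from .exceptions import CoxsigError
from .resample import ResamplePlan, SignatureModel, _default_ridge, build_signature, make_splits
from .survival import CoxFit, KMCurve, SurvivalCohort, _cox_newton, cox_fit, km_estimate, logrank_test

log = logging.getLogger(__name__)

GROUPS = ("good", "intermediate", "poor")


def prognostic_score(model: SignatureModel, expr: ExpressionCohort) -> pd.Series:
    """Per-sample risk score: sum of coefficient * log2 expression.

    Expression already on log2 scale is used as-is; linear-scale cohorts
    are log2-transformed here and must be strictly positive (use the
    loader's pseudocount option otherwise).
    """
    missing = [g for g in model.genes if g not in expr.gene_ids]
    if missing:
        raise CoxsigError(f"model genes missing from expression matrix: {missing}")
    vals = expr.values.loc[list(model.genes)].to_numpy(dtype=float)
    if expr.scale == "linear":
        if np.any(vals <= 0):
            raise CoxsigError(
                "non-positive linear-scale expression cannot be log-transformed; "
                "load with a pseudocount"
            )
        vals = np.log2(vals)
    scores = model.coefficients @ vals
    return pd.Series(scores, index=expr.sample_ids, name="score")


def assign_groups(scores: pd.Series, model: SignatureModel) -> pd.Series:
    """Three-group prognostic call from a score vector.

    score <= cut_low -> good; cut_low < score <= cut_high -> intermediate;
    score > cut_high -> poor (boundary scores go to the lower-risk group).
    """
    if model.cut_low >= model.cut_high:
        raise CoxsigError("cut_low must be < cut_high")
    s = np.asarray(scores, dtype=float)
    out = np.where(s <= model.cut_low, "good", np.where(s <= model.cut_high, "intermediate", "poor"))
    idx = scores.index if isinstance(scores, pd.Series) else None
    return pd.Series(out, index=idx, name="group")


@dataclass
class ValidationReport:
    """Stratified-validation summary for one cohort."""

    scores: pd.Series
    groups: pd.Series
    group_counts: dict
    km_curves: dict  # group -> KMCurve
    logrank_stat: float
    logrank_p: float
    hr_table: pd.DataFrame  # contrast x (HR, lo95, hi95, p) vs good
    notes: list

    def to_dict(self) -> dict:
        return {
            "group_counts": self.group_counts,
            "logrank_stat": self.logrank_stat,
            "logrank_p": self.logrank_p,
            "hazard_ratios": self.hr_table.replace({np.nan: None}).to_dict("index"),
            "notes": self.notes,
        }


def _indicator_hr(surv: SurvivalCohort, groups: pd.Series, contrasts=("intermediate", "poor")):
    """Cox fit on group indicator covariates with 'good' as reference."""
    present = [g for g in contrasts if (groups == g).any()]
    rows = {}
    notes = []
    if (groups == "good").sum() == 0:
        notes.append("no subjects in reference group 'good'; HRs undefined")
        present = []
    if present:
        X = np.column_stack([(groups == g).to_numpy(dtype=float) for g in present])
        try:
            beta, se, *_ = _cox_newton(surv.time, surv.event, X)
            for i, g in enumerate(present):
                z = beta[i] / se[i]
                rows[f"{g}_vs_good"] = {
                    "HR": float(np.exp(beta[i])),
                    "HR_lo95": float(np.exp(beta[i] - 1.96 * se[i])),
                    "HR_hi95": float(np.exp(beta[i] + 1.96 * se[i])),
                    "p": float(2 * norm.sf(abs(z))),
                }
        except CoxsigError as err:
            notes.append(f"HR fit failed: {err}")
    for g in contrasts:
        if f"{g}_vs_good" not in rows:
            rows[f"{g}_vs_good"] = {"HR": np.nan, "HR_lo95": np.nan, "HR_hi95": np.nan, "p": np.nan}
            if (groups == g).sum() == 0:
                notes.append(f"group '{g}' empty; HR undefined")
    table = pd.DataFrame.from_dict(rows, orient="index")
    return table, notes


def validate_cohort(
    model: SignatureModel, expr: ExpressionCohort, surv: SurvivalCohort
) -> ValidationReport:
    """Score a cohort, call groups, and test group survival separation.

    Produces per-group KM curves, the k-group log-rank test over the
    non-empty groups, and intermediate-vs-good / poor-vs-good hazard
    ratios with 95% CIs from a Cox fit on group indicators.
    """
    time, event, X, samples = align_expression_survival(expr, surv, model.genes)
    sub = SurvivalCohort(np.asarray(samples, dtype=object), time, event)
    scores = pd.Series(X @ model.coefficients, index=samples, name="score")
    groups = assign_groups(scores, model)

    counts = {g: int((groups == g).sum()) for g in GROUPS}
    km = {}
    for g in GROUPS:
        mask = (groups == g).to_numpy()
        if mask.any():
            km[g] = km_estimate(sub.subset(mask))
    nonempty = groups.to_numpy()
    labels_present = [g for g in GROUPS if counts[g] > 0]
    if len(labels_present) >= 2:
        stat, p = logrank_test(sub, nonempty)
    else:
        stat, p = np.nan, np.nan
    hr_table, notes = _indicator_hr(sub, groups)
    return ValidationReport(scores, groups, counts, km, stat, p, hr_table, notes)


def refit_in_cohort(
    genes,
    expr: ExpressionCohort,
    surv: SurvivalCohort,
    plan: ResamplePlan,
    calibration_ids=None,
) -> SignatureModel:
    """Re-estimate coefficients and cut points for a fixed gene list in a
    new cohort, using the same resample-averaging procedure that built the
    original signature.

    ``calibration_ids`` restricts the cut-point estimation to a subset of
    samples (e.g. a designated training subset of a hospital cohort): the
    averaged coefficients still come from the full cohort's resamples,
    while each split's tertile cut points are taken over the training
    members of the calibration subset only.  Passing the full cohort is
    identical to the default.
    """
    if calibration_ids is not None:
        calib = [s for s in calibration_ids if s in expr.sample_ids]
        if len(calib) < 30:
            warnings.warn(f"calibration subset has only {len(calib)} samples")
    return build_signature(genes, expr, surv, plan, cut_sample_ids=calibration_ids)


def adjusted_cox(
    groups: pd.Series,
    surv: SurvivalCohort,
    clinical_covariates: pd.DataFrame | None = None,
    reference_levels: dict | None = None,
) -> CoxFit:
    """Joint Cox fit of the signature groups plus clinical covariates.

    Categorical covariates are reference-coded (reference level = first
    alphabetically unless given in ``reference_levels``); numeric columns
    enter as-is.  Levels with no subjects are dropped with a warning.
    The returned fit's ``summary()`` is the familiar per-variable
    HR / 95% CI / p table.
    """
    reference_levels = reference_levels or {}
    cols = {}
    ref = reference_levels.get("signature", "good")
    for g in GROUPS:
        if g == ref:
            continue
        ind = (groups == g).astype(float)
        if ind.sum() == 0:
            warnings.warn(f"signature group '{g}' has no subjects; dropped")
            continue
        cols[f"signature[{g}]"] = ind.to_numpy()
    if clinical_covariates is not None:
        for name in clinical_covariates.columns:
            col = clinical_covariates[name]
            if pd.api.types.is_numeric_dtype(col):
                cols[name] = col.to_numpy(dtype=float)
            else:
                levels = sorted(col.astype(str).unique())
                ref_l = reference_levels.get(name, levels[0])
                for lv in levels:
                    if lv == ref_l:
                        continue
                    ind = (col.astype(str) == lv).to_numpy(dtype=float)
                    if ind.sum() == 0:
                        warnings.warn(f"{name} level '{lv}' has no subjects; dropped")
                        continue
                    cols[f"{name}[{lv}]"] = ind
    if not cols:
        raise CoxsigError("no covariates to fit")
    design = pd.DataFrame(cols)
    cohort = SurvivalCohort(surv.patient_id, surv.time, surv.event, design)
    return cox_fit(cohort, list(design.columns))


@dataclass
class SignatureComparison:
    median_hr_a: float
    median_hr_b: float
    fold_difference: float
    n_splits_a: int
    n_splits_b: int


def _split_hr(time, event, X, tr, te, ridge):
    """Poor-vs-good HR on the test half for one signature in one split."""
    beta, *_ = _cox_newton(time[tr], event[tr], X[tr], ridge=ridge)
    s_tr = X[tr] @ beta
    lo, hi = np.percentile(s_tr, [100.0 / 3.0, 200.0 / 3.0])
    s_te = X[te] @ beta
    good = s_te <= lo
    poor = s_te > hi
    keep = good | poor
    if good.sum() == 0 or poor.sum() == 0 or event[te][keep].sum() == 0:
        return None
    b, *_ = _cox_newton(time[te][keep], event[te][keep], poor[keep].astype(float)[:, None])
    return float(np.exp(b[0]))


def compare_signatures(
    genes_a,
    genes_b,
    expr: ExpressionCohort,
    surv: SurvivalCohort,
    plan: ResamplePlan,
) -> SignatureComparison:
    """Head-to-head comparison of two gene panels on shared resamples.

    Per split each panel is refitted on the training half, its tertile cut
    points taken from the training scores, and the poor-vs-good hazard
    ratio measured on the held-out half.  Splits where a panel yields an
    empty extreme group (HR undefined) are excluded from that panel's
    median.  Reported: per-panel median HR and the A/B fold difference.
    """
    ga, gb = list(genes_a), list(genes_b)
    time, event, Xa, samples = align_expression_survival(expr, surv, ga)
    _, _, Xb, _ = align_expression_survival(expr, surv, gb)
    splits = make_splits(len(samples), plan)

    hrs_a, hrs_b = [], []
    for tr, te in splits:
        if event[tr].sum() == 0:
            continue
        for X, genes, sink in ((Xa, ga, hrs_a), (Xb, gb, hrs_b)):
            try:
                hr = _split_hr(time, event, X, tr, te, _default_ridge(len(genes)))
            except CoxsigError:
                hr = None
            if hr is not None:
                sink.append(hr)
    if not hrs_a or not hrs_b:
        raise CoxsigError("one signature produced no defined split HRs")
    med_a = float(np.median(hrs_a))
    med_b = float(np.median(hrs_b))
    return SignatureComparison(med_a, med_b, med_a / med_b, len(hrs_a), len(hrs_b))
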