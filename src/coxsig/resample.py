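"""Resampling-based signature selection.

Stage 3, the engine of the pipeline: the discovery cohort is repeatedly
split into training and test sets (100 splits of roughly 2/3 vs 1/3 by
default, mirroring the 248/125 partition of a 373-patient cohort).  On
each training set a joint multivariate Cox model of all candidate genes is
fitted; genes are ranked by how often they reach Wald p < 0.05 across
splits.  Genes are then added in rank order until the mean held-out
concordance saturates, and the final signature's coefficients and tertile
cut points are averages over the per-split refits of the chosen genes.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._utils import align_expression_survival
from .deg import ExpressionCohort
from .exceptions import CoxsigError
from .survival import SurvivalCohort, _cox_newton

log = logging.getLogger(__name__)

#: ridge used for joint many-gene fits (near-singular information otherwise)
JOINT_RIDGE = 1e-4
#: number of covariates above which the joint-fit ridge kicks in by default
RIDGE_FREE_MAX = 5


def _default_ridge(n_covariates: int) -> float:
    return 0.0 if n_covariates <= RIDGE_FREE_MAX else JOINT_RIDGE


@dataclass(frozen=True)
class ResamplePlan:
    """Train/test resampling scheme: ``n_splits`` seeded random partitions
    with ``train_fraction`` of the cohort (floored) in training."""

    n_splits: int = 100
    train_fraction: float = 2.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_splits < 1:
            raise CoxsigError("n_splits must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise CoxsigError("train_fraction must be in (0, 1)")


@dataclass
class SelectionResult:
    """Per-gene selection frequencies over resampled multivariate fits."""

    counts: pd.Series  # gene -> number of splits with Wald p < alpha
    mean_abs_coef: pd.Series
    ranked_genes: list
    n_splits_used: int

    @property
    def ranks(self) -> pd.Series:
        return pd.Series(
            np.arange(1, len(self.ranked_genes) + 1), index=self.ranked_genes
        )


@dataclass
class ConcordanceProfile:
    """Mean held-out concordance for growing rank-ordered gene prefixes."""

    k: np.ndarray
    mean_c: np.ndarray
    k_star: int
    saturated: bool


@dataclass
class SignatureModel:
    """A fitted prognostic signature.

    The risk score of a sample is the linear combination of its log2
    expression of ``genes`` weighted by ``coefficients`` (per-split Cox
    coefficients averaged over training sets).  ``cut_low``/``cut_high``
    are the averaged training-score tertile boundaries defining the
    good / intermediate / poor groups.
    """

    genes: list
    coefficients: np.ndarray
    cut_low: float
    cut_high: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.genes) != self.coefficients.size:
            raise CoxsigError("genes and coefficients length mismatch")
        if not (np.isfinite(self.cut_low) and np.isfinite(self.cut_high)):
            raise CoxsigError("cut points must be finite")
        if self.cut_low >= self.cut_high:
            raise CoxsigError("cut_low must be < cut_high")

    def to_json(self, path) -> None:
        payload = {
            "genes": list(self.genes),
            "coefficients": self.coefficients.tolist(),
            "cut_low": self.cut_low,
            "cut_high": self.cut_high,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            d["genes"],
            np.asarray(d["coefficients"]),
            d["cut_low"],
            d["cut_high"],
            d.get("provenance", {}),
        )

    def to_tsv(self, coef_path, cuts_path=None) -> None:
        pd.Series(self.coefficients, index=self.genes, name="coefficient").to_csv(
            coef_path, sep="\t", index_label="gene"
        )
        if cuts_path is not None:
            with open(cuts_path, "w") as fh:
                fh.write(f"cut_low\t{self.cut_low}\ncut_high\t{self.cut_high}\n")


def make_splits(n: int, plan: ResamplePlan) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded list of (train, test) index partitions.

    |train| = floor(train_fraction * n); the test set is the complement.
    Sampling is without replacement and reproducible for a given plan.
    """
    if n < 4:
        raise CoxsigError("cohort too small to split (n < 4)")
    n_train = int(np.floor(plan.train_fraction * n))
    if n_train == 0 or n_train == n:
        raise CoxsigError("train_fraction yields an empty train or test set")
    rng = np.random.default_rng(plan.seed)
    out = []
    for _ in range(plan.n_splits):
        perm = rng.permutation(n)
        out.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return out


def _prepare(expr, surv, genes, plan):
    time, event, X, samples = align_expression_survival(expr, surv, genes)
    splits = make_splits(len(samples), plan)
    return time, event, X, splits


def _usable_splits(time, event, splits):
    """Drop splits whose training half has zero events; >20% dropped is an
    error (the resampling scheme is then mis-specified for the data)."""
    kept = []
    for tr, te in splits:
        if event[tr].sum() == 0:
            warnings.warn("skipping split with zero training events")
            continue
        kept.append((tr, te))
    if len(kept) < 0.8 * len(splits):
        raise CoxsigError(
            f"{len(splits) - len(kept)} of {len(splits)} splits had zero "
            "training events"
        )
    return kept


def select_frequency(
    candidates,
    expr: ExpressionCohort,
    surv: SurvivalCohort,
    plan: ResamplePlan,
    alpha: float = 0.05,
    ridge: float | None = None,
) -> SelectionResult:
    """Rank candidate genes by multivariate-Cox selection frequency.

    Per split, one joint Cox fit of all candidates on the training set; a
    gene counts as selected in that split when its Wald p < ``alpha``.
    Ranking is by descending count, ties broken by higher mean |coefficient|
    across splits, then gene id (deterministic).
    """
    genes = list(candidates)
    if not genes:
        raise CoxsigError("empty candidate set")
    if ridge is None:
        ridge = _default_ridge(len(genes))
    time, event, X, splits = _prepare(expr, surv, genes, plan)
    splits = _usable_splits(time, event, splits)

    counts = np.zeros(len(genes), dtype=int)
    abs_coef = np.zeros(len(genes))
    from scipy.stats import norm

    for tr, _ in splits:
        beta, se, *_ = _cox_newton(time[tr], event[tr], X[tr], ridge=ridge)
        p = 2 * norm.sf(np.abs(beta / se))
        counts += p < alpha
        abs_coef += np.abs(beta)
    abs_coef /= len(splits)

    counts_s = pd.Series(counts, index=genes, name="selection_count")
    mean_abs = pd.Series(abs_coef, index=genes, name="mean_abs_coef")
    order = sorted(
        genes, key=lambda g: (-counts_s[g], -mean_abs[g], g)
    )
    return SelectionResult(counts_s, mean_abs, order, len(splits))


def concordance_saturation(
    ranked_genes,
    expr: ExpressionCohort,
    surv: SurvivalCohort,
    plan: ResamplePlan,
    tol: float = 0.005,
    patience: int = 3,
    max_k: int | None = None,
    ridge: float | None = None,
) -> ConcordanceProfile:
    """Find the signature size at which held-out concordance saturates.

    For k = 1, 2, ... the top-k ranked genes are refitted on each training
    set and Harrell's C of the fitted score is measured on the paired test
    set; ``mean_c(k)`` averages over splits.  The chosen size ``k_star``
    is the smallest k whose next ``patience`` prefixes improve mean C by
    less than ``tol``.  The scan stops as soon as that rule fires (or at
    ``max_k``/the full list); if it never fires, k_star falls back to the
    argmax of the profile computed.
    """
    genes = list(ranked_genes)
    if not genes:
        raise CoxsigError("no ranked genes")
    k_max = len(genes) if max_k is None else min(max_k, len(genes))
    time, event, X, splits = _prepare(expr, surv, genes, plan)
    splits = _usable_splits(time, event, splits)

    # per-split usable-pair masks on the test half, reused for every k
    masks = []
    for _, te in splits:
        t, e = time[te], event[te]
        usable = (t[:, None] < t[None, :]) & (e[:, None] == 1)
        masks.append(usable)

    mean_c: list[float] = []
    k_star = None
    for k in range(1, k_max + 1):
        r = ridge if ridge is not None else _default_ridge(k)
        cs = []
        for (tr, te), usable in zip(splits, masks):
            beta, *_ = _cox_newton(time[tr], event[tr], X[tr, :k], ridge=r)
            s = X[te, :k] @ beta
            n_usable = usable.sum()
            if n_usable == 0:
                continue
            conc = (usable & (s[:, None] > s[None, :])).sum()
            ties = (usable & (s[:, None] == s[None, :])).sum()
            cs.append((conc + 0.5 * ties) / n_usable)
        mean_c.append(float(np.mean(cs)))
        # saturation check for the candidate k - patience steps back
        cand = k - patience
        if cand >= 1:
            gains = [mean_c[cand - 1 + j] - mean_c[cand - 1] for j in range(1, patience + 1)]
            if all(g < tol for g in gains):
                k_star = cand
                break
    saturated = k_star is not None
    if k_star is None:
        k_star = int(np.argmax(mean_c)) + 1
        log.info("concordance never saturated; falling back to argmax k=%d", k_star)
    return ConcordanceProfile(
        np.arange(1, len(mean_c) + 1), np.asarray(mean_c), k_star, saturated
    )


def build_signature(
    top_genes,
    expr: ExpressionCohort,
    surv: SurvivalCohort,
    plan: ResamplePlan,
    ridge: float | None = None,
    cohort_name: str | None = None,
    cut_sample_ids=None,
) -> SignatureModel:
    """Average per-split Cox refits of the chosen genes into a signature.

    Per split: refit the k-gene Cox model on the training set, compute the
    training-set risk scores, and record their 33.33/66.67 percentiles.
    The model's coefficients are the arithmetic mean of per-split
    coefficients; the cut points are the means of the per-split tertile
    boundaries.  Non-converged refits are excluded from both averages.

    ``cut_sample_ids`` restricts the per-split cut-point estimation to a
    calibration subset of samples (training members of that subset only);
    passing the full cohort is identical to the default.
    """
    genes = list(top_genes)
    if not genes:
        raise CoxsigError("empty gene list")
    if ridge is None:
        ridge = _default_ridge(len(genes))
    time, event, X, samples = align_expression_survival(expr, surv, genes)
    splits = _usable_splits(time, event, make_splits(len(samples), plan))
    cut_mask = np.ones(len(samples), dtype=bool)
    if cut_sample_ids is not None:
        wanted = set(cut_sample_ids)
        cut_mask = np.array([s in wanted for s in samples])
        if not cut_mask.any():
            raise CoxsigError("calibration subset shares no samples with cohort")

    betas, lows, highs = [], [], []
    n_dropped = 0
    for tr, _ in splits:
        beta, se, ll, conv, *_ = _cox_newton(time[tr], event[tr], X[tr], ridge=ridge)
        if not conv:
            n_dropped += 1
            continue
        betas.append(beta)
        cut_rows = tr[cut_mask[tr]]
        if cut_rows.size == 0:
            continue
        scores = X[cut_rows] @ beta
        lo, hi = np.percentile(scores, [100.0 / 3.0, 200.0 / 3.0])
        lows.append(lo)
        highs.append(hi)
    if not betas or not lows:
        raise CoxsigError("no converged refits; cannot build signature")
    if n_dropped:
        warnings.warn(f"excluded {n_dropped} non-converged refits from averages")
    coef = np.mean(betas, axis=0)
    prov = {
        "plan": asdict(plan),
        "discovery_cohort": cohort_name or expr.cohort_name,
        "n_splits_used": len(betas),
        "ridge": ridge,
    }
    return SignatureModel(genes, coef, float(np.mean(lows)), float(np.mean(highs)), prov)
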