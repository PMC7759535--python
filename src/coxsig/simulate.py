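"""Synthetic multi-cohort expression + survival data generator.

Emulates the statistical structure the pipeline assumes: several
tumor/normal microarray-style cohorts sharing a set of consistently
deregulated genes, a discovery cohort whose survival follows a
proportional-hazards model driven by a planted gene subset, and
independent (exponential + administrative) censoring.  All generators are
pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .deg import ExpressionCohort
from .exceptions import CoxsigError
from .survival import SurvivalCohort

__all__ = ["GenerativeSpec", "gen_expression", "gen_survival", "gen_study", "StudyBundle",
           "candidate_stage_spec"]


@dataclass(frozen=True)
class GenerativeSpec:
    """Parameters of the synthetic study.

    Defaults mirror the structure of the real study the pipeline targets:
    six tumor/normal deregulation cohorts of 30 samples per class, planted
    DE genes at |log2FC| = 3, residual log2-scale noise sd 0.5, a
    373-patient discovery survival cohort, and five prognostic genes with
    hazard coefficient 0.8 per log2 unit.  Baseline hazard, censoring rate
    and the administrative horizon are chosen so that roughly 60% of
    subjects have an observed event.
    """

    n_genes: int = 200
    n_cohorts: int = 6
    n_tumor: int = 30
    n_normal: int = 30
    n_de: int = 40
    de_effect: float = 3.0          # planted |log2FC|, sign alternates
    n_prognostic: int = 5
    prognostic_beta: float = 0.8    # log-hazard per log2 expression unit
    baseline_hazard: float = 0.02   # events per month
    censor_rate: float = 0.01      # exponential censoring, per month
    admin_censor: float = 120.0     # months
    noise_sd: float = 0.5           # log2-scale residual sd
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    n_discovery: int = 373
    n_validation: int = 200
    stage_beta: float = 0.4         # hazard effect of the confounded covariate
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_hazard", "censor_rate", "admin_censor", "noise_sd"):
            if getattr(self, name) <= 0:
                raise CoxsigError(f"{name} must be > 0")
        if self.n_de > self.n_genes or self.n_prognostic > self.n_genes:
            raise CoxsigError("planted gene counts exceed n_genes")

    @property
    def gene_ids(self) -> list:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    @property
    def de_effects(self) -> dict:
        """Planted signed log2 effects, sign-consistent across cohorts."""
        ids = self.gene_ids
        return {ids[i]: self.de_effect * (1 if i % 2 == 0 else -1) for i in range(self.n_de)}

    @property
    def prognostic_betas(self) -> dict:
        """Planted hazard coefficients; a subset of the DE genes when any
        DE genes are planted, otherwise the first genes."""
        ids = self.gene_ids
        return {ids[i]: self.prognostic_beta for i in range(self.n_prognostic)}


def candidate_stage_spec(seed: int = 0) -> GenerativeSpec:
    """Spec for exercising the resampling stage directly: 50 candidate
    genes of which 5 are prognostic at beta = 0.8, 400-patient cohort."""
    return GenerativeSpec(
        n_genes=50, n_de=0, n_prognostic=5, n_discovery=400, seed=seed
    )


def _baselines(spec: GenerativeSpec) -> np.ndarray:
    rng = np.random.default_rng([spec.seed % (2**31), 7])
    return rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_genes)


def gen_expression(
    spec: GenerativeSpec,
    cohort_index: int,
    n_tumor: int | None = None,
    n_normal: int | None = None,
    cohort_name: str | None = None,
) -> ExpressionCohort:
    """One cohort's log2 gene-by-sample matrix.

    Per-gene baselines are drawn once from the spec seed and shared by all
    cohorts; planted DE genes shift tumor samples by their signed log2
    effect (same direction in every cohort); iid Normal(0, noise_sd) is
    added on top.  ``n_normal=0`` yields a tumor-only (survival) cohort.
    """
    n_t = spec.n_tumor if n_tumor is None else n_tumor
    n_n = spec.n_normal if n_normal is None else n_normal
    name = cohort_name or f"cohort{cohort_index}"
    rng = np.random.default_rng([spec.seed % (2**31), 11, cohort_index])
    base = _baselines(spec)
    effects = spec.de_effects
    eff = np.array([effects.get(g, 0.0) for g in spec.gene_ids])

    tum = base[:, None] + eff[:, None] + rng.normal(0, spec.noise_sd, (spec.n_genes, n_t))
    cols = [f"{name}_T{i:03d}" for i in range(n_t)]
    classes = ["tumor"] * n_t
    mats = [tum]
    if n_n > 0:
        nor = base[:, None] + rng.normal(0, spec.noise_sd, (spec.n_genes, n_n))
        mats.append(nor)
        cols += [f"{name}_N{i:03d}" for i in range(n_n)]
        classes += ["normal"] * n_n
    values = pd.DataFrame(np.hstack(mats), index=pd.Index(spec.gene_ids, name="gene_id"), columns=cols)
    sc = pd.Series(classes, index=cols, name="sample_class")
    return ExpressionCohort(values, sc, name)


def gen_survival(
    expr: ExpressionCohort,
    spec: GenerativeSpec,
    cohort_index: int = 0,
    extra_eta: np.ndarray | None = None,
) -> SurvivalCohort:
    """Proportional-hazards survival for a cohort's tumor samples.

    hazard_i = baseline_hazard * exp(sum_g beta_g (x_gi - mean_g) + extra)
    with x the log2 expression centered within the cohort; event times are
    exponential given the hazard, censoring is the minimum of an
    independent exponential and the administrative horizon.
    """
    tum = expr.class_samples("tumor") if expr.sample_class is not None else expr.sample_ids
    if len(tum) < 2:
        raise CoxsigError("need at least 2 tumor samples")
    rng = np.random.default_rng([spec.seed % (2**31), 13, cohort_index])
    eta = np.zeros(len(tum))
    for g, b in spec.prognostic_betas.items():
        x = expr.values.loc[g, tum].to_numpy(dtype=float)
        eta += b * (x - x.mean())
    if extra_eta is not None:
        eta = eta + np.asarray(extra_eta, dtype=float)
    lam = spec.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / lam)
    t_cens = np.minimum(rng.exponential(1.0 / spec.censor_rate, len(tum)), spec.admin_censor)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    if event.sum() == 0:
        raise CoxsigError(
            "all subjects censored; baseline_hazard / censor_rate are "
            "mis-calibrated for this cohort size"
        )
    return SurvivalCohort(np.asarray(tum, dtype=object), time, event)


@dataclass
class StudyBundle:
    """Everything a full pipeline run needs, generated from one spec."""

    spec: GenerativeSpec
    de_cohorts: list
    discovery_expr: ExpressionCohort
    discovery_surv: SurvivalCohort
    clinical: pd.DataFrame  # confounded ('stage') + independent ('age') covariates
    validation: list  # (ExpressionCohort, SurvivalCohort) pairs

    def write(self, out_dir) -> None:
        from . import io as cio
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for c in self.de_cohorts:
            cio.write_expression(c, out / f"{c.cohort_name}_expr.tsv", out / f"{c.cohort_name}_class.tsv")
        cio.write_expression(
            self.discovery_expr, out / "discovery_expr.tsv", out / "discovery_class.tsv"
        )
        cio.write_clinical(self.discovery_surv, out / "discovery_clinical.tsv", extra=self.clinical)
        for i, (e, s) in enumerate(self.validation):
            cio.write_expression(e, out / f"validation{i}_expr.tsv", out / f"validation{i}_class.tsv")
            cio.write_clinical(s, out / f"validation{i}_clinical.tsv")


def gen_study(spec: GenerativeSpec) -> StudyBundle:
    """Generate the full synthetic study.

    Contents: ``n_cohorts`` tumor/normal DE cohorts; a tumor-only
    discovery cohort with PH survival; a clinical table holding an
    independent covariate (age, no hazard effect) and a confounded one
    (stage, correlated with the genetic risk and adding ``stage_beta``
    per level to the log hazard); and two validation cohorts drawn from
    the same generative model.
    """
    de_cohorts = [
        gen_expression(spec, i, cohort_name=f"deg{i + 1}") for i in range(spec.n_cohorts)
    ]
    disc = gen_expression(spec, 100, n_tumor=spec.n_discovery, n_normal=0, cohort_name="discovery")

    # stage: correlated with the genetic risk component (a confounder once
    # it also enters the hazard); age: independent, no effect
    rng = np.random.default_rng([spec.seed % (2**31), 17])
    tum = list(disc.sample_ids)
    eta_gene = np.zeros(len(tum))
    for g, b in spec.prognostic_betas.items():
        x = disc.values.loc[g, tum].to_numpy(dtype=float)
        eta_gene += b * (x - x.mean())
    noisy = eta_gene + rng.normal(0, np.std(eta_gene) + 1e-12, len(tum))
    stage_num = np.digitize(noisy, np.quantile(noisy, [1 / 3, 2 / 3]))  # 0,1,2
    stage = np.array(["II", "III", "IV"])[stage_num]
    age = rng.normal(60, 10, len(tum))
    clinical = pd.DataFrame({"age": age, "stage": stage}, index=tum)

    surv = gen_survival(
        disc, spec, cohort_index=100, extra_eta=spec.stage_beta * (stage_num - stage_num.mean())
    )
    validation = []
    for j in range(2):
        ve = gen_expression(
            spec, 200 + j, n_tumor=spec.n_validation, n_normal=0, cohort_name=f"validation{j}"
        )
        vs = gen_survival(ve, spec, cohort_index=200 + j)
        validation.append((ve, vs))
    return StudyBundle(spec, de_cohorts, disc, surv, clinical, validation)
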