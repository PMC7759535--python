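"""Tests for signature application: scores, groups, validation HRs,
recalibration, adjusted Cox and signature comparison."""

import numpy as np
import pandas as pd
import pytest

from coxsig import (
    CoxsigError,
    ResamplePlan,
    SignatureModel,
    adjusted_cox,
    assign_groups,
    build_signature,
    compare_signatures,
    prognostic_score,
    refit_in_cohort,
    validate_cohort,
)
from coxsig.deg import ExpressionCohort
from coxsig.survival import logrank_test

from conftest import make_cohort


def _expr(mat, samples, scale="log2"):
    vals = pd.DataFrame(mat, columns=samples)
    vals.index = [f"g{i}" for i in range(len(vals))]
    return ExpressionCohort(vals, None, "t", scale=scale)


def _model(coefs, cuts=(-0.5, 0.5)):
    return SignatureModel([f"g{i}" for i in range(len(coefs))], np.asarray(coefs, float),
                          cuts[0], cuts[1])


class TestPrognosticScore:
    def test_zero_coefficients_zero_scores(self):
        expr = _expr(np.random.default_rng(0).normal(8, 1, (3, 5)), list("abcde"))
        s = prognostic_score(_model([0.0, 0.0, 0.0]), expr)
        np.testing.assert_allclose(s, 0.0)

    def test_single_gene_arithmetic(self):
        expr = _expr([[3.0]], ["s1"])
        s = prognostic_score(_model([2.0]), expr)
        assert s["s1"] == 6.0

    def test_doubling_linear_expression_adds_beta(self):
        beta = 0.7
        expr1 = _expr([[10.0]], ["s1"], scale="linear")
        expr2 = _expr([[20.0]], ["s1"], scale="linear")
        s1 = prognostic_score(_model([beta]), expr1)
        s2 = prognostic_score(_model([beta]), expr2)
        assert s2["s1"] - s1["s1"] == pytest.approx(beta)

    def test_linear_in_coefficients(self):
        rng = np.random.default_rng(1)
        expr = _expr(rng.normal(8, 1, (4, 6)), list("abcdef"))
        b1, b2 = rng.normal(0, 1, 4), rng.normal(0, 1, 4)
        s = prognostic_score(_model(b1 + b2), expr)
        np.testing.assert_allclose(
            s, prognostic_score(_model(b1), expr) + prognostic_score(_model(b2), expr)
        )

    def test_missing_gene_and_nonpositive_linear_errors(self):
        expr = _expr([[1.0]], ["s1"])
        with pytest.raises(CoxsigError, match="missing"):
            prognostic_score(_model([1.0, 1.0]), expr)
        neg = _expr([[-2.0]], ["s1"], scale="linear")
        with pytest.raises(CoxsigError, match="pseudocount"):
            prognostic_score(_model([1.0]), neg)


class TestAssignGroups:
    def test_three_way_examples_and_boundaries(self):
        m = _model([1.0], cuts=(-0.5, 0.5))
        s = pd.Series([-1.0, 0.0, 1.0, -0.5, 0.5], index=list("abcde"))
        g = assign_groups(s, m)
        assert g.tolist() == ["good", "intermediate", "poor", "good", "intermediate"]

    def test_every_sample_gets_exactly_one_group(self):
        rng = np.random.default_rng(2)
        s = pd.Series(rng.normal(0, 2, 200))
        g = assign_groups(s, _model([1.0]))
        assert g.isin(["good", "intermediate", "poor"]).all()

    def test_tertile_cuts_give_thirds(self):
        rng = np.random.default_rng(3)
        s = pd.Series(rng.normal(0, 1, 900))
        lo, hi = np.percentile(s, [100 / 3, 200 / 3])
        g = assign_groups(s, _model([1.0], cuts=(lo, hi)))
        frac = g.value_counts(normalize=True)
        for grp in ("good", "intermediate", "poor"):
            assert frac[grp] == pytest.approx(1 / 3, abs=0.01)

    def test_bad_cuts_error(self):
        with pytest.raises(CoxsigError):
            SignatureModel(["g0"], np.array([1.0]), 0.5, -0.5)


def _three_group_cohort(rng, hazards=(0.02, 0.04, 0.08), n=150):
    """Expression is one gene taking values -1/0/1; survival hazards 1:2:4."""
    vals, times, events, ids = [], [], [], []
    for k, lam in enumerate(hazards):
        x = np.full(n, float(k - 1))
        t = rng.exponential(1 / lam, n)
        c = np.minimum(rng.exponential(1 / 0.01, n), 120)
        vals.append(x)
        times.append(np.minimum(t, c))
        events.append((t <= c).astype(int))
        ids += [f"s{k}_{i}" for i in range(n)]
    expr = ExpressionCohort(
        pd.DataFrame([np.concatenate(vals)], index=["g0"], columns=ids), None, "v"
    )
    surv = make_cohort(np.concatenate(times), np.concatenate(events), prefix="")
    surv = surv.__class__(np.array(ids, dtype=object), surv.time, surv.event)
    return expr, surv


class TestValidateCohort:
    def test_identical_survival_hr_near_one(self):
        rng = np.random.default_rng(4)
        expr, _ = _three_group_cohort(rng)
        t = rng.exponential(30, 450)
        surv = make_cohort(np.tile(t[:150], 3), np.ones(450), prefix="")
        surv = surv.__class__(expr.sample_ids.to_numpy(dtype=object), surv.time, surv.event)
        rep = validate_cohort(_model([1.0]), expr, surv)
        for contrast in ("intermediate_vs_good", "poor_vs_good"):
            assert rep.hr_table.loc[contrast, "HR"] == pytest.approx(1.0, abs=0.35)

    def test_1_2_4_hazard_recovery(self):
        rng = np.random.default_rng(5)
        expr, surv = _three_group_cohort(rng)
        rep = validate_cohort(_model([1.0]), expr, surv)
        for contrast, truth in [("intermediate_vs_good", 2.0), ("poor_vs_good", 4.0)]:
            row = rep.hr_table.loc[contrast]
            assert row["HR_lo95"] < truth < row["HR_hi95"]
        assert rep.logrank_p < 1e-6

    def test_logrank_matches_core_primitive_exactly(self):
        rng = np.random.default_rng(6)
        expr, surv = _three_group_cohort(rng, n=60)
        rep = validate_cohort(_model([1.0]), expr, surv)
        stat, p = logrank_test(surv, rep.groups.to_numpy())
        assert rep.logrank_stat == stat and rep.logrank_p == p

    def test_empty_group_reported_not_fatal(self):
        rng = np.random.default_rng(7)
        expr, surv = _three_group_cohort(rng, n=60)
        # cuts so high that nobody is 'poor'
        rep = validate_cohort(_model([1.0], cuts=(0.5, 99.0)), expr, surv)
        assert np.isnan(rep.hr_table.loc["poor_vs_good", "HR"])
        assert any("poor" in note for note in rep.notes)
        assert np.isfinite(rep.logrank_p)

    def test_hr_invariant_to_score_shift(self):
        rng = np.random.default_rng(8)
        expr, surv = _three_group_cohort(rng, n=80)
        rep1 = validate_cohort(_model([1.0], cuts=(-0.5, 0.5)), expr, surv)
        shifted = ExpressionCohort(expr.values + 10.0, None, "s")
        rep2 = validate_cohort(_model([1.0], cuts=(9.5, 10.5)), shifted, surv)
        np.testing.assert_allclose(
            rep1.hr_table["HR"].to_numpy(), rep2.hr_table["HR"].to_numpy()
        )


class TestRefitInCohort:
    def test_idempotent_on_discovery_cohort(self, candidate_bundle):
        spec, expr, surv = candidate_bundle
        genes = sorted(spec.prognostic_betas)
        plan = ResamplePlan(n_splits=10, seed=20)
        direct = build_signature(genes, expr, surv, plan)
        refit = refit_in_cohort(genes, expr, surv, plan)
        np.testing.assert_array_equal(direct.coefficients, refit.coefficients)
        assert direct.cut_low == refit.cut_low and direct.cut_high == refit.cut_high

    def test_full_cohort_calibration_matches_default(self, candidate_bundle):
        spec, expr, surv = candidate_bundle
        genes = sorted(spec.prognostic_betas)
        plan = ResamplePlan(n_splits=10, seed=21)
        default = refit_in_cohort(genes, expr, surv, plan)
        calibrated = refit_in_cohort(
            genes, expr, surv, plan, calibration_ids=list(expr.sample_ids)
        )
        assert default.cut_low == calibrated.cut_low
        assert default.cut_high == calibrated.cut_high

    def test_small_calibration_subset_warns(self, candidate_bundle):
        spec, expr, surv = candidate_bundle
        genes = sorted(spec.prognostic_betas)
        with pytest.warns(UserWarning, match="calibration"):
            refit_in_cohort(
                genes, expr, surv, ResamplePlan(n_splits=5, seed=22),
                calibration_ids=list(expr.sample_ids)[:20],
            )

    def test_sign_recovery_on_independent_cohort(self, candidate_bundle):
        spec, expr, surv = candidate_bundle
        from coxsig import gen_expression, gen_survival

        genes = sorted(spec.prognostic_betas)
        ve = gen_expression(spec, 300, n_tumor=250, n_normal=0, cohort_name="val")
        vs = gen_survival(ve, spec, 300)
        model = refit_in_cohort(genes, ve, vs, ResamplePlan(n_splits=20, seed=23))
        assert (model.coefficients > 0).all()  # generating betas all positive


class TestAdjustedCox:
    def test_sole_covariate_reproduces_validation_hrs(self):
        rng = np.random.default_rng(9)
        expr, surv = _three_group_cohort(rng)
        rep = validate_cohort(_model([1.0]), expr, surv)
        fit = adjusted_cox(rep.groups, surv)
        summ = fit.summary()
        assert summ.loc["signature[intermediate]", "HR"] == pytest.approx(
            rep.hr_table.loc["intermediate_vs_good", "HR"]
        )
        assert summ.loc["signature[poor]", "HR"] == pytest.approx(
            rep.hr_table.loc["poor_vs_good", "HR"]
        )

    def test_independent_covariate_leaves_hr_in_ci(self):
        rng = np.random.default_rng(10)
        expr, surv = _three_group_cohort(rng)
        groups = assign_groups(prognostic_score(_model([1.0]), expr), _model([1.0]))
        age = pd.Series(rng.normal(60, 10, surv.n), name="age")
        unadj = adjusted_cox(groups, surv)
        adj = adjusted_cox(groups, surv, pd.DataFrame({"age": age}))
        for term in ("signature[intermediate]", "signature[poor]"):
            lo = adj.summary().loc[term, "HR_lo95"]
            hi = adj.summary().loc[term, "HR_hi95"]
            assert lo < unadj.summary().loc[term, "HR"] < hi

    def test_confounded_design_adjustment_helps(self):
        # hazard = group effect (beta=0.6) + confounder effect (beta=0.8),
        # confounder correlated with group
        rng = np.random.default_rng(11)
        n = 900
        group = rng.integers(0, 2, n)  # poor vs good
        conf = group + rng.normal(0, 0.7, n)  # correlated covariate
        lam = 0.02 * np.exp(0.6 * group + 0.8 * conf)
        t = rng.exponential(1 / lam)
        c = np.minimum(rng.exponential(100, n), 120)
        surv = make_cohort(np.minimum(t, c), (t <= c).astype(int))
        groups = pd.Series(np.where(group == 1, "poor", "good"))
        unadj = adjusted_cox(groups, surv)
        adj = adjusted_cox(groups, surv, pd.DataFrame({"conf": conf}))
        truth = np.exp(0.6)
        hr_u = unadj.summary().loc["signature[poor]", "HR"]
        hr_a = adj.summary().loc["signature[poor]", "HR"]
        assert abs(hr_a - truth) < abs(hr_u - truth)

    def test_categorical_reference_coding(self):
        rng = np.random.default_rng(12)
        expr, surv = _three_group_cohort(rng, n=80)
        groups = assign_groups(prognostic_score(_model([1.0]), expr), _model([1.0]))
        stage = pd.Series(rng.choice(["II", "III", "IV"], surv.n))
        fit = adjusted_cox(groups, surv, pd.DataFrame({"stage": stage}))
        names = fit.summary().index
        assert "stage[III]" in names and "stage[IV]" in names
        assert "stage[II]" not in names  # first alphabetically = reference


class TestCompareSignatures:
    def test_identical_panels_fold_one(self, candidate_bundle):
        spec, expr, surv = candidate_bundle
        genes = sorted(spec.prognostic_betas)
        res = compare_signatures(genes, genes, expr, surv, ResamplePlan(n_splits=10, seed=30))
        assert res.fold_difference == pytest.approx(1.0)

    def test_symmetry_on_shared_splits(self, candidate_bundle):
        spec, expr, surv = candidate_bundle
        a = sorted(spec.prognostic_betas)
        b = [g for g in expr.gene_ids if g not in a][:5]
        plan = ResamplePlan(n_splits=10, seed=31)
        ab = compare_signatures(a, b, expr, surv, plan)
        ba = compare_signatures(b, a, expr, surv, plan)
        assert ab.fold_difference * ba.fold_difference == pytest.approx(1.0)

    def test_planted_panel_beats_noise_panel(self, candidate_bundle):
        spec, expr, surv = candidate_bundle
        a = sorted(spec.prognostic_betas)
        b = [g for g in expr.gene_ids if g not in a][:5]
        res = compare_signatures(a, b, expr, surv, ResamplePlan(n_splits=20, seed=32))
        assert res.fold_difference > 1.0
        assert res.median_hr_a > res.median_hr_b
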