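import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from addinter import (
    STATUS_NO_RESULT,
    STATUS_OK,
    STATUS_UNDEFINED_DENOM,
    classify_and_derive,
    generate_cohort,
    interaction_analysis,
    joint_indicator_coding,
    paper_default_config,
    reri_ap_from_ors,
    synergy_index_from_ors,
)


class TestJointCoding:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (0, 0, (0, 0, 0)),
            (1, 0, (1, 0, 0)),
            (0, 1, (0, 1, 0)),
            (1, 1, (0, 0, 1)),
        ],
    )
    def test_exhaustive_cells(self, a, b, expected):
        ind = joint_indicator_coding([a], [b])
        assert tuple(ind.iloc[0]) == expected

    def test_column_sums_are_cell_margins(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 2, 500)
        b = rng.integers(0, 2, 500)
        ind = joint_indicator_coding(a, b)
        assert ind["i10"].sum() == ((a == 1) & (b == 0)).sum()
        assert ind["i01"].sum() == ((a == 0) & (b == 1)).sum()
        assert ind["i11"].sum() == ((a == 1) & (b == 1)).sum()
        assert (ind.sum(axis=1) <= 1).all()


class TestSynergyFormula:
    @pytest.mark.parametrize(
        "ors, expected",
        [
            # (or11, or10, or01) -> S
            ((9.1, 3.4, 2.0), 8.1 / 3.4),
            ((5.9, 2.7, 2.5), 4.9 / 3.2),
            ((1.7, 0.9, 2.5), 0.7 / 1.4),
            ((3.0, 2.0, 2.0), 1.0),  # exact additivity
        ],
    )
    def test_values(self, ors, expected):
        s, status = synergy_index_from_ors(*ors)
        assert status == STATUS_OK
        assert s == pytest.approx(expected)

    def test_no_result_when_joint_or_at_most_one(self):
        s, status = synergy_index_from_ors(0.8, 2.3, 1.7)
        assert status == STATUS_NO_RESULT and np.isnan(s)
        s, status = synergy_index_from_ors(1.0, 1.0, 1.0)
        assert status == STATUS_NO_RESULT

    def test_undefined_denominator_flag(self):
        s, status = synergy_index_from_ors(1.5, 0.7, 0.9)
        assert status == STATUS_UNDEFINED_DENOM and np.isnan(s)

    def test_nonpositive_or_rejected(self):
        with pytest.raises(ValueError):
            synergy_index_from_ors(2.0, -1.0, 1.5)


class TestReriAp:
    def test_printed_or_arithmetic(self):
        reri, ap = reri_ap_from_ors(9.1, 3.4, 2.0)
        assert reri == pytest.approx(4.7)
        assert ap == pytest.approx(4.7 / 9.1)

    def test_additivity_is_zero(self):
        reri, ap = reri_ap_from_ors(3.0, 2.0, 2.0)
        assert reri == pytest.approx(0.0)
        assert ap == pytest.approx(0.0)

    def test_null_model(self):
        reri, ap = reri_ap_from_ors(1.0, 1.0, 1.0)
        assert reri == 0.0 and ap == 0.0


@pytest.fixture(scope="module")
def men_study():
    """One larger all-male cohort with the default interaction truth."""
    cfg = replace(paper_default_config(), n=30000, male_frac=1.0,
                  excluded_frac=0.0)
    return classify_and_derive(generate_cohort(cfg, seed=99)), cfg


class TestInteractionAnalysis:
    def test_consistency_with_formula(self, men_study):
        study, _ = men_study
        res = interaction_analysis(study, "bmi_gt30", "phd", sex="male")
        s, status = synergy_index_from_ors(
            res.or11.or_, res.or10.or_, res.or01.or_
        )
        assert res.status == status == STATUS_OK
        assert res.s == s  # identical floats, same code path inputs
        reri_direct = res.or11.or_ - res.or10.or_ - res.or01.or_ + 1.0
        assert res.reri == reri_direct
        assert res.ap == reri_direct / res.or11.or_

    def test_symmetry_in_exposure_order(self, men_study):
        study, _ = men_study
        r1 = interaction_analysis(study, "bmi_gt30", "phd", sex="male")
        r2 = interaction_analysis(study, "phd", "bmi_gt30", sex="male")
        assert r2.s == pytest.approx(r1.s, rel=1e-12)
        assert r2.reri == pytest.approx(r1.reri, rel=1e-12)
        assert r2.ap == pytest.approx(r1.ap, rel=1e-12)
        assert r2.s_ci == pytest.approx(r1.s_ci, rel=1e-10)
        assert r2.or10.or_ == pytest.approx(r1.or01.or_, rel=1e-12)

    def test_sign_coherence_reri_and_s(self, men_study):
        study, _ = men_study
        res = interaction_analysis(study, "bmi_gt30", "phd", sex="male")
        assert res.status == STATUS_OK
        assert (res.reri > 0) == (res.s > 1)

    def test_truth_recovery_single_seed(self, men_study):
        study, cfg = men_study
        from addinter import true_interaction

        truth = true_interaction(cfg)
        res = interaction_analysis(study, "bmi_gt30", "phd", sex="male")
        for est, tru in (
            (res.or10, truth.or10), (res.or01, truth.or01), (res.or11, truth.or11)
        ):
            assert abs(est.beta - np.log(tru)) < 3 * est.se

    def test_cell_case_counts_partition_cases(self, men_study):
        study, _ = men_study
        res = interaction_analysis(study, "bmi_gt30", "phd", sex="male")
        out = study.outcome.astype(str)
        male = study.df["sex"] == "male"
        complete = study.panel["bmi_gt30"].notna() & study.panel["phd"].notna()
        n_cases = int((male & complete & (out == "diabetes")).sum())
        assert sum(res.cell_cases.values()) == n_cases

    def test_bootstrap_brackets_delta_interval(self, men_study):
        """Percentile bootstrap roughly agrees with the delta interval
        when cells are well filled."""
        study, _ = men_study
        res = interaction_analysis(
            study, "bmi_gt30", "phd", sex="male", bootstrap=120, seed=2
        )
        lo_d, hi_d = res.s_ci
        lo_b, hi_b = res.s_ci_bootstrap
        assert hi_b > lo_b > 0
        # same order of magnitude, generous band: both are 95% intervals
        assert lo_b < res.s < hi_b
        assert hi_b / hi_d < 2.5 and lo_d / lo_b < 2.5

    def test_covariate_collapsibility_under_independence(self):
        """With covariates generated independently of the exposure pair
        and the outcome, adjusted and crude synergy agree within noise."""
        cfg = replace(paper_default_config(), n=40000, male_frac=1.0,
                      excluded_frac=0.0)
        study = classify_and_derive(generate_cohort(cfg, seed=17))
        crude = interaction_analysis(study, "bmi_gt30", "phd", sex="male")
        adj = interaction_analysis(
            study, "bmi_gt30", "phd", sex="male",
            covariates=("current_smoker", "ex_smoker", "leisure_inactive",
                        "work_inactive"),
        )
        assert adj.s == pytest.approx(crude.s, rel=0.15)

    def test_missing_exposures_dropped_and_counted(self, men_study):
        study, _ = men_study
        res = interaction_analysis(study, "current_smoker", "phd", sex="male")
        n_missing = int(study.panel["current_smoker"].isna().sum())
        assert res.n_dropped >= 1
        assert res.n_used + res.n_dropped >= n_missing
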