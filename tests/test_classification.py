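import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from addinter import (
    Cohort,
    OutcomeClass,
    classify_and_derive,
    classify_cohort,
    classify_outcome,
    derive_bmi,
    derive_exposures,
    percentile_cutoff,
)

from conftest import make_record


class TestOutcomeClassification:
    @pytest.mark.parametrize(
        "kw, expected",
        [
            # self-report alone suffices even with normal glucose
            (dict(selfreport_diabetes="yes", fasting_glucose=5.0), "diabetes"),
            # medication alone suffices
            (dict(antidiabetic_medication="yes", fasting_glucose=5.0), "diabetes"),
            # glucose threshold is inclusive at 7.0
            (dict(fasting_glucose=7.0), "diabetes"),
            (dict(fasting_glucose=6.9), "prediabetes"),
            (dict(fasting_glucose=6.1), "prediabetes"),
            (dict(fasting_glucose=6.0), "reference"),
            # unrounded values between 6.9 and 7.0 stay impaired-fasting-glucose
            (dict(fasting_glucose=6.95), "prediabetes"),
            # no glucose + blank question -> excluded
            (dict(fasting_glucose=None, selfreport_diabetes="blank"), "excluded"),
            # answered "no" without a measurement -> reference
            (dict(fasting_glucose=None, selfreport_diabetes="no"), "reference"),
        ],
    )
    def test_rule_boundaries(self, kw, expected):
        assert classify_outcome(make_record(**kw)).value == expected

    def test_vectorised_matches_scalar(self):
        recs = [
            make_record(id=f"p{i}", fasting_glucose=g, selfreport_diabetes=sr)
            for i, (g, sr) in enumerate(
                [(5.0, "no"), (6.1, "no"), (6.9, "blank"), (7.0, "no"),
                 (None, "blank"), (None, "no"), (5.0, "yes")]
            )
        ]
        cohort = Cohort.from_records(recs)
        vec = classify_cohort(cohort).astype(str).tolist()
        scal = [classify_outcome(r).value for r in recs]
        assert vec == scal

    def test_partition_on_synthetic_cohort(self, small_cohort):
        out = classify_cohort(small_cohort)
        counts = out.value_counts()
        assert counts.sum() == len(small_cohort)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        g=st.one_of(st.none(), st.floats(0.5, 25.0)),
        sr=st.sampled_from(["yes", "no", "blank"]),
        med=st.sampled_from(["yes", "no"]),
        delta=st.floats(0.0, 10.0),
    )
    def test_monotone_in_glucose(self, g, sr, med, delta):
        """Raising glucose never demotes the outcome class."""
        order = {"diabetes": 2, "prediabetes": 1, "reference": 0, "excluded": 0}
        r1 = make_record(fasting_glucose=g, selfreport_diabetes=sr,
                         antidiabetic_medication=med)
        c1 = classify_outcome(r1).value
        if g is None:
            return
        r2 = make_record(fasting_glucose=g + delta, selfreport_diabetes=sr,
                         antidiabetic_medication=med)
        c2 = classify_outcome(r2).value
        assert order[c2] >= order[c1]


class TestBMI:
    def test_exact_arithmetic(self):
        assert derive_bmi(180.0, 81.0) == pytest.approx(25.0)
        assert derive_bmi(100.0, 30.0) == pytest.approx(30.0)

    def test_missing_propagates(self):
        assert derive_bmi(None, 80.0) is None
        assert np.isnan(derive_bmi(float("nan"), 80.0))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            derive_bmi(-170.0, 80.0)


class TestPercentileCutoff:
    def test_linear_interpolation_oracle(self):
        """Brute-force order-statistic oracle: for sorted x of size n the
        q-quantile with linear interpolation sits between x[k] and x[k+1]
        at fraction h = q(n-1) - k."""
        vals = pd.Series(np.arange(1.0, 101.0))
        grp = pd.Series(["all"] * 100)
        got = percentile_cutoff(vals, grp, q=0.90)["all"]
        x = np.sort(vals.to_numpy())
        pos = 0.90 * (len(x) - 1)
        k = int(np.floor(pos))
        oracle = x[k] + (pos - k) * (x[k + 1] - x[k])
        assert got == pytest.approx(oracle) == pytest.approx(90.1)

    def test_constant_vector_flags_nobody(self):
        vals = pd.Series([5.0] * 30)
        grp = pd.Series(["g"] * 30)
        cut = percentile_cutoff(vals, grp, q=0.9)["g"]
        assert cut == 5.0
        assert not (vals > cut).any()  # "high" is strictly above

    def test_insufficient_group_named_in_error(self):
        vals = pd.Series([1.0] * 5 + [2.0] * 30)
        grp = pd.Series(["tiny"] * 5 + ["big"] * 30)
        with pytest.raises(ValueError, match="tiny"):
            percentile_cutoff(vals, grp, q=0.9)

    def test_invalid_q(self):
        with pytest.raises(ValueError):
            percentile_cutoff(pd.Series(np.arange(20.0)), pd.Series(["a"] * 20), q=1.5)


class TestExposurePanel:
    def test_parental_history_and_eligibility(self, small_study):
        """Mother-only: counts for the parental-history exposure and is
        ineligible for the paternal-history analysis (and vice versa)."""
        rec = make_record(mother_diabetes="yes", father_diabetes="no")
        panel = derive_exposures(
            Cohort.from_records([rec] * 1 + [make_record(id="p2")]),
            cutoffs=small_study.cutoffs,
        )
        row = panel.iloc[0]
        assert bool(row["phd"]) and bool(row["maternal_history"])
        assert bool(row["maternal_eligible"])
        assert not bool(row["paternal_eligible"])
        assert not bool(row["biparental"])

    def test_smoking_reference_includes_ex_smokers(self, small_study):
        rec = make_record(smoking="ex")
        panel = derive_exposures(
            Cohort.from_records([rec, make_record(id="p2")]),
            cutoffs=small_study.cutoffs,
        )
        assert panel["current_smoker"].iloc[0] == False  # noqa: E712
        assert panel["ex_smoker"].iloc[0] == True  # noqa: E712

    def test_bmi_cutoffs_are_strict(self, small_study):
        # height/weight chosen so BMI is exactly 30.0
        rec = make_record(height=100.0, weight=30.0)
        panel = derive_exposures(
            Cohort.from_records([rec, make_record(id="p2")]),
            cutoffs=small_study.cutoffs,
        )
        assert panel["bmi"].iloc[0] == pytest.approx(30.0)
        assert panel["bmi_gt25"].iloc[0] == True  # noqa: E712
        assert panel["bmi_gt30"].iloc[0] == False  # noqa: E712

    def test_missing_raw_fields_propagate(self, small_study):
        rec = make_record(smoking=None, leisure_pa=None, height=None,
                          waist=None)
        panel = derive_exposures(
            Cohort.from_records([rec, make_record(id="p2")]),
            cutoffs=small_study.cutoffs,
        )
        row = panel.iloc[0]
        for col in ("current_smoker", "leisure_inactive", "bmi_gt25",
                    "high_waist", "high_whr"):
            assert pd.isna(row[col])

    def test_obesity_implies_overweight_cohortwide(self, small_study):
        p = small_study.panel
        both = p["bmi_gt30"].fillna(False) & ~p["bmi_gt25"].fillna(True)
        assert not both.any()

    def test_biparental_implies_phd_cohortwide(self, small_study):
        p = small_study.panel
        assert not (p["biparental"] & ~p["phd"]).any()

    def test_family_history_superset_of_phd(self, small_study):
        p = small_study.panel
        assert not (p["phd"] & ~p["family_history"]).any()

    def test_determinism(self, small_cohort, small_study):
        again = derive_exposures(small_cohort, cutoffs=small_study.cutoffs)
        pd.testing.assert_frame_equal(again, small_study.panel)
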