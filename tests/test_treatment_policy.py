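import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import guidemark as gm
from guidemark.metabolic_states import ValidationError
from guidemark.treatment_policy import (
    BP_SEQUENCE,
    LIPID_SEQUENCE,
    GuidelineSpec,
    LipidRule,
    MedicationState,
    initial_medication_state,
)


def _factors(ldl=110.0, tc=200.0, hdl=45.0, sbp=135.0, dbp=82.0):
    return {"LDL": ldl, "TC": tc, "HDL": hdl, "SBP": sbp, "DBP": dbp}


class TestLipidRules:
    def test_us2_threshold_is_inclusive(self):
        spec = gm.packaged_guideline("us2")
        assert gm.lipid_rule_triggers(spec, _factors(ldl=100.0))
        assert not gm.lipid_rule_triggers(spec, _factors(ldl=99.9))

    def test_canada_ratio_rule_triggers_despite_low_ldl(self):
        spec = gm.packaged_guideline("canada")
        # LDL 90 mg/dL is below 2.5 mmol/L (96.7 mg/dL) but TC/HDL = 4.2
        assert gm.lipid_rule_triggers(spec, _factors(ldl=90.0, tc=189.0, hdl=45.0))
        assert not gm.lipid_rule_triggers(spec, _factors(ldl=90.0, tc=160.0, hdl=45.0))

    def test_australia_low_hdl_rule(self):
        spec = gm.packaged_guideline("australia")
        # HDL below 1 mmol/L (38.67 mg/dL) triggers regardless of LDL/TC
        assert gm.lipid_rule_triggers(spec, _factors(ldl=80.0, tc=140.0, hdl=35.0))

    def test_risk_stratified_threshold_selection(self):
        spec = gm.packaged_guideline("us3")
        f = _factors(ldl=110.0)
        assert gm.lipid_rule_triggers(spec, f, ten_year_chd_risk=0.25)  # high: >=100
        assert not gm.lipid_rule_triggers(spec, f, ten_year_chd_risk=0.15)  # mod: >=130
        assert not gm.lipid_rule_triggers(spec, f, ten_year_chd_risk=0.05)  # low: >=190
        assert gm.lipid_rule_triggers(
            spec, _factors(ldl=195.0), ten_year_chd_risk=0.05
        )

    def test_risk_stratified_requires_risk(self):
        spec = gm.packaged_guideline("us3")
        with pytest.raises(ValidationError):
            gm.lipid_rule_triggers(spec, _factors())

    def test_missing_quantity_rejected(self):
        spec = gm.packaged_guideline("us2")
        with pytest.raises(ValidationError):
            gm.lipid_rule_triggers(spec, {"TC": 200.0, "HDL": 45.0})

    def test_vectorized_evaluation(self):
        spec = gm.packaged_guideline("us2")
        out = gm.lipid_rule_triggers(spec, _factors(ldl=np.array([90.0, 100.0, 150.0])))
        np.testing.assert_array_equal(out, [False, True, True])


class TestBpRules:
    def test_thresholds_are_strict(self):
        spec = gm.packaged_guideline("us2")
        assert not gm.bp_rule_triggers(spec, _factors(sbp=130.0, dbp=80.0))
        assert gm.bp_rule_triggers(spec, _factors(sbp=131.0, dbp=80.0))
        assert gm.bp_rule_triggers(spec, _factors(sbp=130.0, dbp=81.0))

    def test_us1_uses_higher_dbp_threshold(self):
        spec = gm.packaged_guideline("us1")
        assert not gm.bp_rule_triggers(spec, _factors(sbp=130.0, dbp=85.0))
        assert gm.bp_rule_triggers(spec, _factors(sbp=130.0, dbp=86.0))

    def test_accord_intensive_systolic_target(self):
        spec = gm.packaged_guideline("accord")
        assert gm.bp_rule_triggers(spec, _factors(sbp=121.0, dbp=75.0))
        assert not gm.bp_rule_triggers(spec, _factors(sbp=120.0, dbp=75.0))


class TestAnnualDecision:
    def test_untreated_patient_starts_statin_and_thiazide(self):
        spec = gm.packaged_guideline("us2")
        meds = MedicationState()
        new = gm.annual_decision(spec, meds, _factors(ldl=120.0, sbp=140.0, dbp=85.0))
        assert new.active_classes == ("statin", "thiazide")

    def test_exhausted_lipid_sequence_is_unchanged(self):
        spec = gm.packaged_guideline("us2")
        meds = MedicationState(n_lipid=2, n_bp=0)
        new = gm.annual_decision(spec, meds, _factors(ldl=150.0, sbp=120.0, dbp=75.0))
        assert new.n_lipid == 2 and new.n_bp == 0

    def test_initiate_at_diagnosis_never_intensifies(self):
        spec = gm.packaged_guideline("initiate_at_diagnosis")
        meds = initial_medication_state(spec)
        assert set(meds.active_classes) == {"statin", "ace_arb"}
        new = gm.annual_decision(spec, meds, _factors(ldl=250.0, sbp=190.0, dbp=110.0))
        assert new == meds

    def test_at_most_one_new_class_per_domain_per_cycle(self):
        spec = gm.packaged_guideline("us2")
        meds = MedicationState()
        new = gm.annual_decision(spec, meds, _factors(ldl=250.0, sbp=190.0, dbp=110.0))
        assert new.n_lipid == 1 and new.n_bp == 1

    def test_ace_first_sequence_for_diagnosis_variants(self):
        spec = gm.packaged_guideline("us4")
        meds = initial_medication_state(spec)
        assert meds.active_classes == ("statin", "ace_arb")
        new = gm.annual_decision(
            spec, meds, _factors(ldl=120.0, sbp=140.0, dbp=85.0)
        )
        assert new.active_classes == ("statin", "fibrate", "ace_arb", "thiazide")

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=50, max_value=250),
                st.floats(min_value=100, max_value=200),
                st.floats(min_value=60, max_value=110),
            ),
            min_size=1,
            max_size=20,
        )
    )
    def test_medication_sets_monotone_over_any_factor_path(self, path):
        spec = gm.packaged_guideline("us2")
        meds = MedicationState()
        for ldl, sbp, dbp in path:
            new = gm.annual_decision(spec, meds, _factors(ldl=ldl, sbp=sbp, dbp=dbp))
            assert set(meds.active_classes) <= set(new.active_classes)
            meds = new


class TestTreatedFactors:
    def test_statin_lowers_tc_by_14_percent(self, effects):
        out = gm.treated_factors({"TC": 200.0}, ["statin"], effects)
        assert out["TC"] == pytest.approx(172.0)

    def test_statin_plus_fibrate_effects_add(self, effects):
        out = gm.treated_factors({"TC": 200.0}, ["statin", "fibrate"], effects)
        assert out["TC"] == pytest.approx(200.0 * (1 - 0.179))

    def test_no_medication_is_identity(self, effects):
        out = gm.treated_factors({"TC": 200.0, "SBP": 140.0}, [], effects)
        assert out == {"TC": 200.0, "SBP": 140.0}

    def test_hdl_increases_under_lipid_treatment(self, effects):
        out = gm.treated_factors({"HDL": 45.0}, ["statin"], effects)
        assert out["HDL"] == pytest.approx(45.0 * 1.073)

    def test_total_reduction_beyond_100_percent_rejected(self):
        table = gm.EffectTable(effects={"statin": {"TC": -60.0}, "fibrate": {"TC": -50.0}})
        with pytest.raises(ValidationError):
            gm.treated_factors({"TC": 200.0}, ["statin", "fibrate"], table)


class TestCostsAndDiscounting:
    def test_single_class_cost(self, costs):
        assert gm.annual_cost(["statin"], costs) == 212.0

    def test_costs_add_across_classes(self, costs):
        assert gm.annual_cost(["statin", "ace_arb"], costs) == 260.0

    def test_empty_set_costs_nothing(self, costs):
        assert gm.annual_cost([], costs) == 0.0

    def test_missing_class_rejected(self):
        table = gm.CostTable(costs={"statin": 212.0})
        with pytest.raises(ValidationError):
            gm.annual_cost(["fibrate"], table)

    def test_upper_bound_variant_is_more_expensive(self):
        base = gm.default_cost_table("base")
        upper = gm.default_cost_table("upper")
        assert all(upper.costs[c] >= base.costs[c] for c in base.costs)

    @pytest.mark.parametrize(
        "amount,years,rate,expected",
        [(212.0, 0, 0.03, 212.0), (212.0, 1, 0.03, 212.0 / 1.03), (500.0, 7, 0.0, 500.0)],
    )
    def test_discount_examples(self, amount, years, rate, expected):
        assert gm.discount(amount, years, rate) == pytest.approx(expected)

    @given(st.floats(min_value=0, max_value=1e6), st.integers(min_value=0, max_value=40))
    def test_discounting_never_increases_value(self, amount, years):
        assert gm.discount(amount, years, 0.03) <= amount + 1e-9


class TestGuidelineSpecs:
    def test_all_packaged_guidelines_load(self):
        names = gm.packaged_guideline_names()
        assert {"us1", "us2", "us3", "us4", "canada", "european", "british",
                "australia", "accord", "initiate_at_diagnosis",
                "no_treatment"} <= set(names)
        for key in names:
            spec = gm.packaged_guideline(key)
            assert isinstance(spec, GuidelineSpec)

    def test_unknown_guideline_rejected(self):
        with pytest.raises(ValidationError):
            gm.packaged_guideline("mars")

    def test_misordered_risk_strata_rejected(self):
        with pytest.raises(ValidationError):
            GuidelineSpec(
                name="bad",
                risk_stratified=True,
                ldl_thresholds_by_risk={"high": 190, "moderate": 130, "low": 100},
            )

    def test_rule_with_unknown_quantity_rejected(self):
        with pytest.raises(ValidationError):
            LipidRule(quantity="ApoB", comparator=">=", threshold=1.0)
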