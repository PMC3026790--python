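import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import guidemark as gm
from guidemark.metabolic_states import (
    Cutpoints,
    ValidationError,
    annual_state_sequences,
)


class TestConvertUnits:
    @pytest.mark.parametrize(
        "value,from_u,to_u,analyte,expected",
        [
            (2.5, "mmol/L", "mg/dL", "cholesterol", 96.675),
            (100.0, "mg/dL", "mmol/L", "cholesterol", 100.0 / 38.67),
            (1.0, "mmol/L", "mg/dL", "triglyceride", 88.57),
            (150.0, "mg/dL", "mg/dL", "cholesterol", 150.0),
        ],
    )
    def test_known_conversions(self, value, from_u, to_u, analyte, expected):
        assert gm.convert_units(value, from_u, to_u, analyte) == pytest.approx(expected)

    @given(st.floats(min_value=0.1, max_value=1000))
    def test_round_trip_is_identity(self, value):
        back = gm.convert_units(
            gm.convert_units(value, "mg/dL", "mmol/L", "cholesterol"),
            "mmol/L",
            "mg/dL",
            "cholesterol",
        )
        assert back == pytest.approx(value, abs=1e-9)

    def test_unknown_analyte_or_unit_rejected(self):
        with pytest.raises(ValidationError):
            gm.convert_units(1.0, "mg/dL", "mmol/L", "glucose")
        with pytest.raises(ValidationError):
            gm.convert_units(1.0, "mg/dL", "g/L", "cholesterol")


class TestFriedewald:
    @pytest.mark.parametrize(
        "tc,hdl,tg,expected",
        [(200, 50, 150, 120.0), (180, 40, 0, 140.0), (160, 40, 100, 100.0)],
    )
    def test_formula(self, tc, hdl, tg, expected):
        assert gm.friedewald_ldl(tc, hdl, tg) == pytest.approx(expected)

    def test_high_triglycerides_out_of_domain(self):
        with pytest.raises(ValidationError):
            gm.friedewald_ldl(160, 40, 500)

    def test_negative_ldl_rejected(self):
        with pytest.raises(ValidationError):
            gm.friedewald_ldl(100, 90, 100)

    @given(
        st.floats(min_value=120, max_value=300),
        st.floats(min_value=20, max_value=90),
        st.floats(min_value=10, max_value=390),
    )
    def test_monotone_in_each_argument(self, tc, hdl, tg):
        try:
            base = gm.friedewald_ldl(tc, hdl, tg)
        except ValidationError:
            return
        assert gm.friedewald_ldl(tc + 1, hdl, tg) > base
        try:
            lower_hdl = gm.friedewald_ldl(tc, hdl + 1, tg)
        except ValidationError:
            return
        assert lower_hdl < base


class TestBinValue:
    def test_interior_edge_goes_to_higher_bin(self):
        assert gm.bin_value(200.0, [160, 200, 240]) == 2

    def test_below_all_edges_is_bin_zero(self):
        assert gm.bin_value(10.0, [160, 200, 240]) == 0

    def test_at_or_above_last_edge_is_last_bin(self):
        assert gm.bin_value(240.0, [160, 200, 240]) == 3
        assert gm.bin_value(1e6, [160, 200, 240]) == 3

    @given(
        st.floats(min_value=0, max_value=400),
        st.floats(min_value=0, max_value=400),
    )
    def test_monotone(self, v1, v2):
        edges = [160, 200, 240]
        lo, hi = sorted([v1, v2])
        assert gm.bin_value(lo, edges) <= gm.bin_value(hi, edges)

    def test_bad_edges_rejected(self):
        with pytest.raises(ValidationError):
            gm.bin_value(1.0, [200, 160])


class TestCutpoints:
    def test_representative_outside_bin_rejected(self):
        with pytest.raises(ValidationError):
            Cutpoints(
                edges={"TC": (160, 200), "HDL": (45,), "SBP": (130,), "DBP": (85,)},
                representatives={
                    "TC": (140, 210, 220),  # 210 not inside [160, 200)
                    "HDL": (40, 50),
                    "SBP": (120, 140),
                    "DBP": (80, 90),
                },
            )

    def test_default_cutpoints_cover_bp_guideline_thresholds(self):
        cp = gm.default_cutpoints()
        assert {120, 130, 140, 160} <= set(cp.edges["SBP"])
        assert {80, 85, 90} <= set(cp.edges["DBP"])


class TestTransitionMatrixEstimation:
    def test_hand_counted_sequence(self):
        # transitions: 0->0, 0->1, 1->1
        m = gm.estimate_transition_matrix([[0, 0, 1, 1]], 2, smoothing=0.0)
        np.testing.assert_allclose(m, [[0.5, 0.5], [0.0, 1.0]])

    def test_no_data_with_smoothing_is_uniform(self):
        m = gm.estimate_transition_matrix([], 3, smoothing=1.0)
        np.testing.assert_allclose(m, np.full((3, 3), 1.0 / 3.0))

    def test_no_data_no_smoothing_is_uniform(self):
        m = gm.estimate_transition_matrix([], 2, smoothing=0.0)
        np.testing.assert_allclose(m, np.full((2, 2), 0.5))

    def test_single_state_space_rejected(self):
        with pytest.raises(ValidationError):
            gm.estimate_transition_matrix([[0, 0]], 1)

    def test_recovers_generating_matrix(self):
        truth = np.array(
            [
                [0.7, 0.2, 0.1],
                [0.15, 0.7, 0.15],
                [0.05, 0.25, 0.7],
            ]
        )
        rng = np.random.default_rng(42)
        seq = [0]
        for _ in range(10_000):
            seq.append(rng.choice(3, p=truth[seq[-1]]))
        est = gm.estimate_transition_matrix([seq], 3, smoothing=0.0)
        assert np.max(np.abs(est - truth)) < 0.02

    @given(
        st.lists(
            st.lists(st.integers(min_value=0, max_value=3), min_size=0, max_size=10),
            min_size=0,
            max_size=5,
        ),
        st.floats(min_value=0, max_value=2),
    )
    def test_always_row_stochastic(self, seqs, smoothing):
        m = gm.estimate_transition_matrix(seqs, 4, smoothing=smoothing)
        assert np.all(m >= 0)
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-9)


def _panel_from_arrays(ages, values, factor="TG", patient_id=0):
    col = gm.metabolic_states.FACTOR_COLUMNS[factor]
    n = len(ages)
    df = pd.DataFrame(
        {
            "patient_id": patient_id,
            "sex": "male",
            "age": ages,
            "visit_year": np.arange(n),
            "tc_mgdl": 200.0,
            "hdl_mgdl": 45.0,
            "tg_mgdl": 150.0,
            "sbp_mmhg": 130.0,
            "dbp_mmhg": 80.0,
            "hba1c_pct": 7.0,
            "meds": "",
            "died": 0,
        }
    )
    df[col] = values
    return df


class TestAgeTrend:
    def test_exact_line_recovered(self):
        ages = np.array([40.0, 50.0, 60.0, 70.0])
        panel = _panel_from_arrays(ages, 100 + 2 * (ages - 40))
        trend = gm.fit_age_trend(panel, "TG")
        assert trend.slope == pytest.approx(2.0)
        assert trend.predict(40) == pytest.approx(100.0)

    def test_constant_factor_has_zero_slope(self):
        panel = _panel_from_arrays(np.array([45.0, 55.0, 65.0]), 120.0)
        assert gm.fit_age_trend(panel, "TG").slope == pytest.approx(0.0, abs=1e-12)

    def test_single_age_rejected(self):
        panel = _panel_from_arrays(np.array([50.0, 50.0]), [100.0, 110.0])
        with pytest.raises(ValidationError):
            gm.fit_age_trend(panel, "TG")

    def test_prediction_clamps_to_fitted_range(self):
        ages = np.array([45.0, 50.0, 55.0])
        panel = _panel_from_arrays(ages, 100 + 2 * (ages - 40))
        trend = gm.fit_age_trend(panel, "TG")
        assert trend.predict(30) == trend.predict(45)
        assert trend.predict(90) == trend.predict(55)

    def test_noisy_slope_recovered_within_two_se(self):
        rng = np.random.default_rng(7)
        ages = rng.uniform(40, 80, size=2000)
        y = 100 + 1.5 * (ages - 40) + rng.normal(0, 20, size=2000)
        panel = _panel_from_arrays(ages, y)
        trend = gm.fit_age_trend(panel, "TG")
        # SE of the OLS slope
        se = 20.0 / np.sqrt(np.sum((ages - ages.mean()) ** 2))
        assert abs(trend.slope - 1.5) < 2 * se


class TestTreatmentEffectEstimator:
    def _episode_panel(self, pre, post, med="statin"):
        df = _panel_from_arrays(np.array([50.0, 51.0]), [pre, post], factor="TC")
        df["meds"] = ["", med]
        return df

    def test_single_episode_percent_change(self):
        panel = self._episode_panel(200.0, 172.0)
        assert gm.estimate_treatment_effect(panel, "statin", "TC") == pytest.approx(-14.0)

    def test_no_change_is_zero(self):
        panel = self._episode_panel(180.0, 180.0)
        assert gm.estimate_treatment_effect(panel, "statin", "TC") == pytest.approx(0.0)

    def test_no_episodes_is_error(self):
        panel = _panel_from_arrays(np.array([50.0, 51.0]), [200.0, 200.0])
        with pytest.raises(ValidationError):
            gm.estimate_treatment_effect(panel, "statin", "TC")

    def test_confounded_episode_excluded(self):
        # statin and fibrate both start in the same interval: no clean episode
        panel = self._episode_panel(200.0, 160.0, med="statin;fibrate")
        with pytest.raises(ValidationError):
            gm.estimate_treatment_effect(panel, "statin", "TC")

    def test_unknown_class_rejected(self):
        panel = self._episode_panel(200.0, 172.0)
        with pytest.raises(ValidationError):
            gm.estimate_treatment_effect(panel, "aspirin", "TC")


class TestEffectTable:
    def test_lipid_class_cannot_touch_blood_pressure(self):
        with pytest.raises(ValidationError):
            gm.EffectTable(effects={"statin": {"SBP": -5.0}})

    def test_default_table_covers_all_classes(self):
        table = gm.default_effect_table()
        assert set(table.effects) == set(gm.metabolic_states.MEDICATION_CLASSES)


class TestFittedModel:
    def test_fitted_matrices_are_row_stochastic(self, fitted_model):
        for f, m in fitted_model.matrices.items():
            assert np.all(np.asarray(m) >= 0)
            np.testing.assert_allclose(np.asarray(m).sum(axis=1), 1.0, atol=1e-9)

    def test_json_round_trip(self, fitted_model, tmp_path):
        path = tmp_path / "model.json"
        fitted_model.to_json(path)
        loaded = gm.TransitionModel.from_json(path)
        for f in fitted_model.matrices:
            np.testing.assert_allclose(loaded.matrices[f], fitted_model.matrices[f])
        assert loaded.trends["TG"].slope == pytest.approx(
            fitted_model.trends["TG"].slope
        )

    def test_binned_panel_sequences_are_approximately_first_order_markov(
        self, default_panel, cutpoints
    ):
        """Conditioning on the state two steps back should barely change the
        next-state distribution (weighted total-variation distance small)."""
        for factor in ("TC", "SBP"):
            seqs = annual_state_sequences(default_panel, cutpoints, factor)
            n = cutpoints.n_bins(factor)
            c2 = np.zeros((n, n, n))
            for s in seqs:
                s = np.asarray(s)
                for i in range(len(s) - 2):
                    c2[s[i], s[i + 1], s[i + 2]] += 1
            c1 = c2.sum(axis=0)
            p1 = c1 / np.maximum(c1.sum(axis=1, keepdims=True), 1)
            tvs, weights = [], []
            for prev in range(n):
                for cur in range(n):
                    tot = c2[prev, cur].sum()
                    if tot >= 30:
                        p2 = c2[prev, cur] / tot
                        tvs.append(0.5 * np.abs(p2 - p1[cur]).sum())
                        weights.append(tot)
            assert len(tvs) > 0
            mean_tv = float(np.average(tvs, weights=weights))
            assert mean_tv < 0.15
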