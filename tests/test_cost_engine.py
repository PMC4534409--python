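"""Cost accounting: adverse events, first-line phases, disease events and second line."""

import numpy as np
import pytest

from aplbim.cost_engine import (
    CostBreakdown,
    cohort_costs,
    course_cost,
    event_and_second_line_costs,
    expected_ae_cost,
    first_line_costs,
    per_patient_costs,
    round_eur100,
)
from aplbim.markov_engine import run_cohort
from aplbim.synthetic_data import perturbed_config


class TestExpectedAECost:
    def test_ato_induction_hand_sum(self, base_config):
        value = expected_ae_cost("induction", base_config.regimens.ato_atra, base_config.ae_unit_costs)
        assert value == pytest.approx(0.46 * 206 + 0.59 * 331 + 0.025 * 222 + 0.011 * 202)
        assert value == pytest.approx(297.822)

    def test_atra_second_consolidation_cycle_hand_sum(self, base_config):
        value = expected_ae_cost("consolidation_2", base_config.regimens.atra_chemo, base_config.ae_unit_costs)
        assert value == pytest.approx(0.76 * 66 + 0.65 * 62 + 0.004 * 61 + 0.098 * 62)
        assert value == pytest.approx(96.78)

    def test_zero_probabilities_cost_nothing(self, base_config):
        raw = base_config.model_dump(mode="json")
        for phase in raw["regimens"]["ato_atra"]["ae_probabilities"].values():
            for k in phase:
                phase[k] = 0.0
        from aplbim.inputs import validate_config

        config = validate_config(raw)
        assert expected_ae_cost("induction", config.regimens.ato_atra, config.ae_unit_costs) == 0.0


class TestFirstLineCosts:
    def test_zero_occupancy_trace_costs_nothing(self, base_config):
        trace = run_cohort(base_config.regimens.ato_atra, cohort_size=0.0, entry_month=7)
        costs = first_line_costs(trace, base_config.regimens.ato_atra, base_config.ae_unit_costs)
        assert costs.grand_total() == 0.0

    def test_completing_patient_accrues_exact_pharmacy_total(self, base_config, no_transition_probs):
        """No leakage from the phase allocation: full course inside the horizon -> Table total."""
        for key, expected in (("ato_atra", 46_814.0), ("atra_chemo", 6_832.0)):
            regimen = base_config.regimens[key]
            trace = run_cohort(regimen, cohort_size=1.0, entry_month=7, probs=no_transition_probs)
            costs = first_line_costs(trace, regimen, base_config.ae_unit_costs)
            assert costs.cumulative("pharmacy") == pytest.approx(expected, abs=1e-9)

    def test_no_transition_ato_medical_hand_sum(self, base_config, no_transition_probs):
        """1 induction + 7 consolidation + 22 post-treatment months from a July-1 entry."""
        regimen = base_config.regimens.ato_atra
        trace = run_cohort(regimen, cohort_size=1.0, entry_month=7, probs=no_transition_probs)
        costs = first_line_costs(trace, regimen, base_config.ae_unit_costs)
        assert costs.cumulative("medical") == pytest.approx(7585 + 7 * 398 + 22 * 94)

    def test_ae_costs_confined_to_induction_and_first_three_consolidation_cycles(
        self, base_config, no_transition_probs
    ):
        regimen = base_config.regimens.ato_atra
        trace = run_cohort(regimen, cohort_size=1.0, entry_month=7, probs=no_transition_probs)
        costs = first_line_costs(trace, regimen, base_config.ae_unit_costs)
        ae = costs.monthly["adverse_event"]
        assert np.all(ae[11:] == 0.0)  # consolidation cycles 4+ and beyond carry no AE profile
        assert ae[7] == pytest.approx(297.822)
        assert ae[8] == ae[9] == pytest.approx(0.06 * 66 + 0.06 * 62 + 0.025 * 61 + 0.011 * 62)


class TestSecondLineAndEvents:
    def test_derived_course_totals_match_published_second_line_sums(self, base_config):
        assert course_cost(base_config.regimens.ato_atra) == pytest.approx(57_185.0)
        # published 37,472; component-derived course differs by 6 euros
        assert course_cost(base_config.regimens.atra_chemo) == pytest.approx(37_466.0)

    def test_no_events_no_costs(self, base_config, no_transition_probs):
        trace = run_cohort(base_config.regimens.atra_chemo, 1.0, 7, probs=no_transition_probs)
        costs = event_and_second_line_costs(
            trace, base_config.regimens.atra_chemo, base_config.regimens.ato_atra
        )
        assert costs.grand_total() == 0.0

    def test_full_second_line_course_accrues_for_early_event(self, base_config):
        """A unit event flow in month 7 accrues the whole opposite-regimen course by month 36."""
        regimen = base_config.regimens.atra_chemo
        trace = run_cohort(regimen, 1.0, 7)
        trace.incident_events[:] = 0.0
        trace.incident_events[7] = 1.0
        costs = event_and_second_line_costs(trace, regimen, base_config.regimens.ato_atra)
        assert costs.cumulative("second_line") == pytest.approx(57_185.0)
        assert costs.cumulative("disease_event") == pytest.approx(430.0)
        # course occupies the 8 months following the event
        assert costs.monthly["second_line"][7] == 0.0
        assert costs.monthly["second_line"][8] == pytest.approx(57_185.0 / 8)
        assert costs.monthly["second_line"][16] == 0.0

    def test_late_event_truncated_at_horizon(self, base_config):
        regimen = base_config.regimens.atra_chemo
        trace = run_cohort(regimen, 1.0, 7)
        trace.incident_events[:] = 0.0
        trace.incident_events[35] = 1.0
        costs = event_and_second_line_costs(trace, regimen, base_config.regimens.ato_atra)
        # second line starts the month after the event; one month fits before the horizon
        assert costs.cumulative("second_line") == pytest.approx(57_185.0 / 8)

    def test_explicit_second_line_total_override(self, base_config):
        raw = base_config.model_dump(mode="json")
        raw["regimens"]["ato_atra"]["second_line_total"] = 60_000.0
        from aplbim.inputs import validate_config

        config = validate_config(raw)
        assert course_cost(config.regimens.ato_atra) == 60_000.0


class TestPerPatientCosts:
    def test_cumulative_displays_match_published_per_patient_costs(self, base_config):
        """Three-year cumulative pharmacy/medical per patient, display-rounded to EUR 100."""
        ato = per_patient_costs(base_config, "ato_atra")
        atra = per_patient_costs(base_config, "atra_chemo")
        assert round_eur100(ato.cumulative("pharmacy")) == 46_600.0  # published 46,700
        assert round_eur100(atra.cumulative("pharmacy")) == 6_500.0
        assert round_eur100(ato.cumulative("medical")) == 12_400.0  # published 12,300
        assert round_eur100(atra.cumulative("medical")) == 30_200.0
        assert round_eur100(ato.cumulative("adverse_event")) == 300.0
        assert round_eur100(atra.cumulative("adverse_event")) == 600.0

    def test_yearly_pharmacy_split_matches_published_table(self, base_config):
        ato = per_patient_costs(base_config, "ato_atra")
        assert [round_eur100(v) for v in ato.yearly("pharmacy")] == [36_800.0, 9_900.0, 0.0]
        atra = per_patient_costs(base_config, "atra_chemo")
        assert [round_eur100(v) for v in atra.yearly("pharmacy")] == [3_700.0, 1_600.0, 1_200.0]

    def test_component_additivity(self, base_config):
        costs = per_patient_costs(base_config, "atra_chemo")
        frame = costs.to_frame()
        for col in frame.columns:
            assert frame.loc["total", col] == pytest.approx(frame.drop("total")[col].sum())
        np.testing.assert_allclose(
            frame["cumulative"], frame[["year_1", "year_2", "year_3"]].sum(axis=1), rtol=1e-12
        )

    def test_zero_probability_zero_cost_config_all_zero(self, base_config, no_transition_probs):
        raw = base_config.model_dump(mode="json")
        for reg in raw["regimens"].values():
            reg["transition_probabilities"] = {
                "stable_to_event": 0.0, "stable_to_death": 0.0, "event_to_death": 0.0,
            }
            reg["pharmacy"] = {
                "first_line_total": 0, "induction_total": 0, "consolidation_total": 0, "maintenance_monthly": 0,
            }
            for k in reg["medical"]:
                reg["medical"][k] = 0
            reg["disease_event_cost"] = 0
            for phase in reg["ae_probabilities"].values():
                for k in phase:
                    phase[k] = 0.0
        from aplbim.inputs import validate_config

        config = validate_config(raw)
        assert per_patient_costs(config, "ato_atra").grand_total() == 0.0


class TestInvariants:
    def test_zero_horizon_zero_cost(self, base_config):
        trace = run_cohort(base_config.regimens.ato_atra, 1.0, 7)
        empty = CostBreakdown(horizon=36)
        assert empty.grand_total() == 0.0
        assert np.all(trace.stable_start[:7] == 0.0)  # nothing accrues before entry

    @pytest.mark.parametrize(
        "parameter",
        [
            "regimens.ato_atra.pharmacy.consolidation_total",
            "regimens.atra_chemo.medical.maintenance_per_cycle",
            "ae_unit_costs.induction.thrombocytopenia",
            "regimens.atra_chemo.disease_event_cost",
        ],
    )
    def test_increasing_a_unit_cost_never_decreases_any_component(self, base_config, parameter):
        bumped = perturbed_config(base_config, parameter, 1.5)
        for key in ("ato_atra", "atra_chemo"):
            base = per_patient_costs(base_config, key)
            up = per_patient_costs(bumped, key)
            for comp in base.monthly:
                assert up.cumulative(comp) >= base.cumulative(comp) - 1e-9
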