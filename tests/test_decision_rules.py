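"""Action map, outcome rules, ledger validation and serialization."""

import dataclasses

import pytest

from triage_cim import (
    ClinicalAction,
    ClinicalParams,
    CostParams,
    GroundTruth,
    LedgerError,
    PredictionCombo,
    action_for,
    action_map_from_csv,
    action_map_to_csv,
    default_ledger,
    enumerate_cells,
    enumerate_combos,
    enumerate_truths,
    outcome_for,
    validate_ledger,
)
from triage_cim.decision_rules import OutcomeRecord, OutcomeRule

CL = ClinicalParams()
COSTS = CostParams()
LEDGER = default_ledger()


def combo(bb, vb, mb):
    return PredictionCombo(bb, vb, mb)


def cell_cost(c, t):
    return COSTS.price(outcome_for(c, t, LEDGER, CL).cost_events)


class TestEnumeration:
    def test_cell_count_and_distinctness(self):
        cells = enumerate_cells()
        assert len(cells) == 144
        assert len(set(cells)) == 144
        assert len(enumerate_combos()) == 18
        assert len(enumerate_truths()) == 8

    def test_order_is_stable(self):
        assert enumerate_cells() == enumerate_cells()

    def test_band_level_validation(self):
        with pytest.raises(ValueError):
            PredictionCombo("very_high", "low", "low")
        with pytest.raises(ValueError):
            PredictionCombo("low", "moderate", "low")  # viral has no moderate


class TestActionInvariants:
    def test_icu_antibiotics_require_icu(self):
        with pytest.raises(ValueError, match="iv_icu"):
            ClinicalAction("ward_admit", "iv_icu", False, False, False)

    def test_oseltamivir_requires_pcr(self):
        with pytest.raises(ValueError, match="PCR"):
            ClinicalAction("discharge_home", "none", False, True, False)


class TestDefaultActionMap:
    def test_all_low_discharges_without_treatment_or_tests(self):
        a = action_for(combo("low", "low", "low"), LEDGER)
        assert a.disposition == "discharge_home"
        assert a.antibiotic_regimen == "none"
        assert not a.viral_pcr_ordered
        assert not a.blood_culture_ordered

    def test_bacterial_and_mortality_high_goes_to_icu_on_iv(self):
        a = action_for(combo("high", "low", "high"), LEDGER)
        assert a.disposition == "icu_admit"
        assert a.antibiotic_regimen == "iv_icu"

    def test_viral_high_discharge_gets_pcr_and_oseltamivir(self):
        a = action_for(combo("low", "high", "low"), LEDGER)
        assert a.disposition == "discharge_home"
        assert a.viral_pcr_ordered and a.oseltamivir_given
        assert a.antibiotic_regimen == "none"

    def test_high_mortality_without_infection_signal_goes_to_ward(self):
        # an isolated high severity score admits for monitoring, not ICU
        a = action_for(combo("low", "low", "high"), LEDGER)
        assert a.disposition == "ward_admit"

    def test_high_bacterial_low_mortality_is_observed_on_orals(self):
        a = action_for(combo("high", "low", "low"), LEDGER)
        assert a.disposition == "ed_observation"
        assert a.antibiotic_regimen == "oral_outpatient"

    def test_missing_combo_raises_configuration_error(self):
        broken = dict(LEDGER.action_map)
        del broken[combo("low", "low", "low")]
        lg = LEDGER.with_action_map(broken)
        with pytest.raises(LedgerError, match="does not cover"):
            action_for(combo("low", "low", "low"), lg)


class TestOutcomes:
    def test_healthy_concordant_discharge_has_no_utilization(self):
        rec = outcome_for(
            combo("low", "low", "low"),
            GroundTruth(False, False, False),
            LEDGER,
            CL,
        )
        assert rec.hospital_ward_days == 0.0
        assert rec.icu_days == 0.0
        assert rec.antibiotic_days == 0.0
        assert not rec.readmission
        # baseline cohort mortality applies to every suspected-ARTI patient
        assert rec.death_probability == CL.mortality_arti

    def test_missed_severe_bacterial_triggers_readmission_composite(self):
        rec = outcome_for(
            combo("low", "low", "low"),
            GroundTruth(True, False, True),
            LEDGER,
            CL,
        )
        assert rec.readmission
        assert ("missed_bact_with_mort", 1.0) in rec.cost_events
        # rehospitalization: survivors in ICU, nonsurvivors' long stay
        p = rec.death_probability
        assert p == CL.mortality_septic_icu_viral  # no timely-admit benefit
        assert rec.icu_days == pytest.approx((1 - p) * CL.rehosp_icu_los)
        assert rec.hospital_ward_days == pytest.approx(p * CL.nonsurvivor_los)

    def test_missed_severe_nonbacterial_uses_other_composite(self):
        rec = outcome_for(
            combo("low", "low", "low"),
            GroundTruth(False, True, True),
            LEDGER,
            CL,
        )
        keys = [k for k, _ in rec.cost_events]
        assert "missed_mort_no_bact" in keys
        assert "missed_bact_with_mort" not in keys

    def test_timely_icu_admission_reduces_severe_mortality(self):
        rec = outcome_for(
            combo("high", "low", "high"),
            GroundTruth(True, False, True),
            LEDGER,
            CL,
        )
        expected = CL.mortality_septic_icu_viral * (
            1 - CL.mortality_reduction_timely
        )
        assert rec.death_probability == pytest.approx(expected)

    def test_missed_bacterial_nonsevere_adds_one_day_and_composite(self):
        rec = outcome_for(
            combo("low", "low", "low"),
            GroundTruth(True, False, False),
            LEDGER,
            CL,
        )
        assert rec.readmission
        assert rec.hospital_ward_days == 1.0
        assert ("missed_bact_no_mort", 1.0) in rec.cost_events

    def test_oseltamivir_lowers_treated_viral_mortality(self):
        treated = outcome_for(
            combo("low", "high", "low"),
            GroundTruth(False, True, False),
            LEDGER,
            CL,
        )
        untreated = outcome_for(
            combo("low", "low", "low"),
            GroundTruth(False, True, False),
            LEDGER,
            CL,
        )
        assert treated.death_probability == CL.mortality_viral
        assert untreated.death_probability == CL.mortality_arti

    def test_true_severity_extends_ward_stay_with_escalation(self):
        rec = outcome_for(
            combo("low", "low", "moderate"),
            GroundTruth(False, False, True),
            LEDGER,
            CL,
        )
        assert rec.hospital_ward_days == CL.rehosp_icu_los
        assert rec.antibiotic_days == pytest.approx(
            CL.antibiotic_days_ward + CL.antibiotic_days_icu
        )

    def test_outcomes_are_deterministic(self):
        c, t = combo("moderate", "high", "moderate"), GroundTruth(True, True, False)
        assert outcome_for(c, t, LEDGER, CL) == outcome_for(c, t, LEDGER, CL)

    def test_death_probability_non_increasing_in_mortality_band(self):
        # timely-care benefit: a truly severe patient never does worse when
        # the predicted mortality band is higher
        for bb in ("low", "moderate", "high"):
            for vb in ("low", "high"):
                for truth in (
                    GroundTruth(True, False, True),
                    GroundTruth(False, True, True),
                    GroundTruth(True, True, True),
                    GroundTruth(False, False, True),
                ):
                    ps = [
                        outcome_for(combo(bb, vb, mb), truth, LEDGER, CL)
                        .death_probability
                        for mb in ("low", "moderate", "high")
                    ]
                    assert ps[0] >= ps[1] >= ps[2]


class TestCostStructure:
    @staticmethod
    def concordant_combo(truth):
        return combo(
            "high" if truth.bacterial else "low",
            "high" if truth.viral else "low",
            "high" if truth.mortality_risk else "low",
        )

    def test_missed_care_penalty_cells_cost_more_than_concordant_care(self):
        # under-treatment that triggers a missed-diagnosis composite is
        # always costlier than the concordant action for the same truth
        for truth in enumerate_truths():
            base = cell_cost(self.concordant_combo(truth), truth)
            for c in enumerate_combos():
                rec = outcome_for(c, truth, LEDGER, CL)
                if rec.readmission:
                    assert cell_cost(c, truth) > base

    def test_all_low_prediction_is_cheapest_for_healthy_truth(self):
        healthy = GroundTruth(False, False, False)
        base = cell_cost(combo("low", "low", "low"), healthy)
        costs = [cell_cost(c, healthy) for c in enumerate_combos()]
        assert base == min(costs)

    def test_cost_events_price_against_catalog(self):
        rec = outcome_for(
            combo("low", "low", "moderate"),
            GroundTruth(False, False, False),
            LEDGER,
            CL,
        )
        expected = (
            COSTS.ed_visit_incl_pct
            + CL.los_short_ward * COSTS.ward_day
            + COSTS.abx_oral_iv_ward
        )
        assert COSTS.price(rec.cost_events) == pytest.approx(expected)


class TestValidation:
    def test_default_ledger_covers_everything(self):
        report = validate_ledger(LEDGER)
        assert report.ok
        assert report.n_cells_covered == 144
        assert report.unreachable_rules == []

    def test_deleted_action_is_reported(self):
        broken = dict(LEDGER.action_map)
        missing = combo("high", "high", "high")
        del broken[missing]
        report = validate_ledger(LEDGER.with_action_map(broken))
        assert not report.ok
        assert missing in report.missing_combos

    def test_rule_producing_negative_los_is_named(self):
        bad_rule = OutcomeRule(
            name="negative_los",
            applies=lambda c, a, t: True,
            build=lambda c, a, t, cl: OutcomeRecord(
                hospital_ward_days=-1.0,
                icu_days=0.0,
                antibiotic_days=0.0,
                death_probability=0.0,
                readmission=False,
                cost_events=(),
            ),
        )
        lg = dataclasses.replace(LEDGER, outcome_rules=(bad_rule,))
        report = validate_ledger(lg)
        assert not report.ok
        assert all("negative_los" in msg for _, _, msg in report.invalid_cells)

    def test_shadowed_rule_is_flagged_unreachable(self):
        catch_all = LEDGER.outcome_rules[-1]
        shadowed = OutcomeRule(
            name="never_reached",
            applies=lambda c, a, t: t.bacterial,
            build=catch_all.build,
        )
        lg = dataclasses.replace(
            LEDGER, outcome_rules=(catch_all, shadowed)
        )
        report = validate_ledger(lg)
        assert "never_reached" in report.unreachable_rules


class TestSerialization:
    def test_action_map_round_trips(self):
        text = action_map_to_csv(LEDGER)
        lg = action_map_from_csv(text)
        assert lg.action_map == LEDGER.action_map

    def test_unknown_column_is_an_error(self):
        text = action_map_to_csv(LEDGER)
        header, rest = text.split("\n", 1)
        mangled = header + ",surprise\n" + "\n".join(
            line + "," for line in rest.splitlines()
        )
        with pytest.raises(LedgerError, match="unknown"):
            action_map_from_csv(mangled)

    def test_missing_row_is_an_error(self):
        text = action_map_to_csv(LEDGER)
        lines = text.splitlines()
        with pytest.raises(LedgerError, match="missing"):
            action_map_from_csv("\n".join(lines[:-1]))

    def test_wrong_schema_tag_is_an_error(self):
        text = action_map_to_csv(LEDGER).replace(
            "triage-cim-action-map-v1", "triage-cim-action-map-v999"
        )
        with pytest.raises(LedgerError, match="schema"):
            action_map_from_csv(text)
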