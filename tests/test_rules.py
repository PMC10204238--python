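"""Criteria engine: group evaluation, probable logic, precedence, and the
declarative rule format."""

import numpy as np
import pytest
import yaml

from headdx.cohort import generate_patient
from headdx.records import DiagnosisLabel as L
from headdx.rules import (Ambiguous, RuleSchemaError, default_rules,
                          diagnose_rules, dump_rules, evaluate_criteria,
                          load_rules, resolve_priority)
from headdx.vignettes import (borderline_pm_ptth, make_record,
                              vignette_suite)


def evals_by_label(record, rules=None):
    return {ev.diagnosis: ev for ev in evaluate_criteria(record, rules)}


class TestEvaluateCriteria:
    def test_textbook_mo_meets_all_groups_and_fails_tth(self, mo_record):
        by = evals_by_label(mo_record)
        assert by[L.MO].fully_met
        # tension-type must miss the quality and associated-symptom groups
        assert {"C", "D"} <= by[L.fETTH].groups_failed

    def test_two_hour_attacks_miss_exactly_the_duration_group(self, mo_record):
        record = mo_record.model_copy(deep=True)
        record.attack.duration_minutes_untreated = 120
        ev = evals_by_label(record)[L.MO]
        assert ev.groups_failed == frozenset({"B"})

    def test_featureless_record_fails_every_diagnosis(self):
        blank = make_record(attacks=0, duration=10, vas=1, days=0.1,
                            qualities={"other"}, laterality="variable",
                            locations={"vertex"})
        for ev in evaluate_criteria(blank):
            assert ev.n_failed >= 1

    def test_missing_field_counts_as_failed_and_not_assessable(self):
        record = make_record(days=20, migraine_days=None, attacks=8,
                             duration=5000, nausea=True, aggravated=True)
        ev = evals_by_label(record)[L.CM]
        assert "C" in ev.groups_failed and "C" in ev.not_assessable

    def test_deterministic_pure_function(self, mo_record):
        first = diagnose_rules(mo_record)
        second = diagnose_rules(mo_record)
        assert first.label == second.label
        assert [e.groups_failed for e in first.trace] == \
            [e.groups_failed for e in second.trace]


class TestDiagnoseRules:
    def test_full_mo_diagnosed_by_rules(self, mo_record):
        result = diagnose_rules(mo_record)
        assert (result.label, result.method) == (L.MO, "rule")

    def test_cm_plus_medication_overuse_resolves_to_moh(self):
        record = make_record(attacks=9, duration=5000, days=20,
                             migraine_days=9, months=6, vas=8, nausea=True,
                             aggravated=True, medication=[{
                                 "drug_class": "triptan",
                                 "intake_days_per_month": 12,
                                 "months_of_regular_use": 4}])
        by = evals_by_label(record)
        assert by[L.CM].fully_met and by[L.MOH].fully_met
        assert diagnose_rules(record).label == L.MOH

    def test_borderline_record_is_ambiguous_between_pm_and_ptth(self):
        outcome = diagnose_rules(borderline_pm_ptth())
        assert isinstance(outcome, Ambiguous)
        assert outcome.candidates == {L.PM, L.PTTH}

    def test_one_migraine_group_short_gives_probable_migraine(self):
        record = make_record(attacks=4, duration=1440, vas=7, nausea=True,
                             aggravated=True, days=2)
        assert diagnose_rules(record).label == L.PM

    def test_unclassifiable_record_lands_in_others(self):
        record = make_record(attacks=3, duration=10, vas=2, days=0.5,
                             qualities={"other"}, laterality="variable")
        assert diagnose_rules(record).label == L.OTHERS


class TestPriority:
    def test_moh_outranks_chronic_migraine(self):
        assert resolve_priority({L.CM, L.MOH}) == L.MOH

    def test_singleton(self):
        assert resolve_priority({L.MO}) == L.MO

    def test_chronic_outranks_episodic_tth(self):
        assert resolve_priority({L.iETTH, L.fETTH}) == L.fETTH
        assert resolve_priority({L.iETTH, L.fETTH, L.CTTH}) == L.CTTH

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            resolve_priority(set())

    def test_tth_frequency_bands_are_mutually_exclusive(self):
        """No frequency/duration combination fully satisfies two TTH
        subtypes at once, so the episodic/chronic precedence is exercised
        only via hand-injected candidate sets."""
        base = make_record(attacks=30, duration=240, months=24,
                           laterality="bilateral",
                           qualities={"pressing_tightening"}, vas=4,
                           migraine_days=0)
        tth = (L.iETTH, L.fETTH, L.CTTH)
        for days in np.arange(0.2, 31.0, 0.6):
            record = base.model_copy(deep=True)
            record.course.headache_days_per_month = float(days)
            by = evals_by_label(record)
            assert sum(by[lbl].fully_met for lbl in tth) <= 1


class TestMohDominance:
    def test_moh_label_regardless_of_cooccurring_candidates(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            record = generate_patient(L.MOH, 1.0, rng)
            assert diagnose_rules(record).label == L.MOH


class TestRuleFormat:
    def test_dump_load_round_trip(self, tmp_path, rules):
        path = tmp_path / "rules.yaml"
        dump_rules(rules, path)
        again = load_rules(path)
        assert again.priority == rules.priority
        assert [(r.rule_id, r.predicate) for r in again.rules] == \
            [(r.rule_id, r.predicate) for r in rules.rules]

    def test_undeclared_field_rejected_with_rule_id(self, tmp_path, rules):
        path = tmp_path / "rules.yaml"
        dump_rules(rules, path)
        doc = yaml.safe_load(path.read_text())
        doc["diagnoses"]["MO"]["B"]["expr"] = "aura_color == 'red'"
        path.write_text(yaml.safe_dump(doc))
        with pytest.raises(RuleSchemaError, match="MO.B.*aura_color"):
            load_rules(path)

    def test_single_group_diagnosis_rejected(self, tmp_path, rules):
        path = tmp_path / "rules.yaml"
        dump_rules(rules, path)
        doc = yaml.safe_load(path.read_text())
        doc["diagnoses"]["NDPH"].pop("B")
        path.write_text(yaml.safe_dump(doc))
        with pytest.raises(RuleSchemaError, match="NDPH"):
            load_rules(path)

    def test_unknown_top_level_key_rejected(self, tmp_path, rules):
        path = tmp_path / "rules.yaml"
        dump_rules(rules, path)
        doc = yaml.safe_load(path.read_text())
        doc["extras"] = 1
        path.write_text(yaml.safe_dump(doc))
        with pytest.raises(RuleSchemaError, match="extras"):
            load_rules(path)

    def test_editing_a_threshold_changes_the_diagnosis(self, tmp_path, rules):
        # lowering the migraine attack-count floor turns a four-attack
        # probable-migraine presentation into definite migraine
        path = tmp_path / "rules.yaml"
        dump_rules(rules, path)
        doc = yaml.safe_load(path.read_text())
        doc["diagnoses"]["MO"]["A"]["expr"] = "attack_count >= 3"
        path.write_text(yaml.safe_dump(doc))
        edited = load_rules(path)
        record = make_record(attacks=4, duration=1440, vas=7, nausea=True,
                             aggravated=True, days=2)
        assert diagnose_rules(record).label == L.PM
        assert diagnose_rules(record, edited).label == L.MO

    def test_dangerous_constructs_rejected(self, tmp_path, rules):
        path = tmp_path / "rules.yaml"
        dump_rules(rules, path)
        doc = yaml.safe_load(path.read_text())
        doc["diagnoses"]["MO"]["B"]["expr"] = "__import__('os').getcwd()"
        path.write_text(yaml.safe_dump(doc))
        with pytest.raises(RuleSchemaError):
            load_rules(path)


def test_vignette_oracle_suite_matches_hand_applied_criteria(pm_ptth_casebase):
    """Hand-labelled presentations (two or more per category, including the
    CM+MOH overlap and the PM/PTTH borderline) must all be recovered."""
    from headdx.cbr import hybrid_diagnose
    for name, record, expected in vignette_suite():
        result = hybrid_diagnose(record, casebase=pm_ptth_casebase)
        assert result.label == expected, name
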