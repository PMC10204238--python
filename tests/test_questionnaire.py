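"""Interview engine: branching, validation, inconsistency handling,
instrument scoring, and compilation."""

import itertools

import pytest

from headdx.cohort import generate_patient, simulate_session
from headdx.questionnaire import (
    ConfigurationError, ContradictorySessionError, IncompleteSessionError,
    Quantity, QuestionnaireItem, Session, ShowIfClause, ValidationError,
    compile_record, detect_inconsistencies, next_item, record_answer,
    score_gad7, score_phq9, write_transcript, replay_transcript,
    _parse_bank,
)
from headdx.records import DiagnosisLabel


def toy_item(iid, kind="yes_no", show_if=(), options=()):
    return QuestionnaireItem(item_id=iid, theme="characteristics",
                             prompt=iid, answer_kind=kind,
                             options=tuple(options), show_if=tuple(show_if))


TOY_BANK = [
    toy_item("age", kind="number"),
    toy_item("aura_present"),
    toy_item("aura_duration", kind="number",
             show_if=[ShowIfClause("aura_present", "eq", True)]),
    toy_item("nausea"),
    toy_item("severe", show_if=[ShowIfClause("nausea", "eq", True)]),
]


class TestNextItem:
    def test_first_item_of_plain_bank(self):
        assert next_item(Session.start(), TOY_BANK).item_id == "age"

    def test_gated_item_never_shown_on_any_answer_path(self):
        # exhaustive walk over every yes/no combination of the toy bank
        for aura, nausea in itertools.product([True, False], repeat=2):
            answers = {"age": 30.0, "aura_present": aura, "nausea": nausea}
            session = Session.start()
            seen = []
            while (item := next_item(session, TOY_BANK)) is not None:
                seen.append(item.item_id)
                assert item.eligible(session.answers)
                record_answer(session, item, answers.get(item.item_id, True),
                              TOY_BANK)
            assert ("aura_duration" in seen) == aura
            assert ("severe" in seen) == nausea

    def test_reask_queue_takes_precedence_even_when_answered(self):
        session = Session.start()
        for item in TOY_BANK[:2]:
            record_answer(session, item, 5 if item.answer_kind == "number" else False,
                          TOY_BANK)
        session.reask_queue.append("age")
        assert next_item(session, TOY_BANK).item_id == "age"

    def test_loop_terminates_and_progress_reaches_one(self):
        session = Session.start()
        steps = 0
        while (item := next_item(session, TOY_BANK)) is not None:
            steps += 1
            assert steps <= 2 * len(TOY_BANK)
            record_answer(session, item,
                          1 if item.answer_kind == "number" else False, TOY_BANK)
        assert session.progress == 1.0

    def test_cyclic_show_if_is_a_configuration_error_naming_the_cycle(self):
        doc = [
            {"item_id": "a", "theme": "characteristics", "prompt": "a",
             "answer_kind": "yes_no",
             "show_if": [{"item": "b", "op": "eq", "value": True}]},
            {"item_id": "b", "theme": "characteristics", "prompt": "b",
             "answer_kind": "yes_no",
             "show_if": [{"item": "a", "op": "eq", "value": True}]},
        ]
        with pytest.raises(ConfigurationError, match="a|b"):
            _parse_bank(doc, "toy")


class TestRecordAnswer:
    @pytest.mark.parametrize("kind,raw,expected", [
        ("vas_1_10", "7", 7),
        ("vas_1_10", 3, 3),
        ("number", "12.5", 12.5),
        ("yes_no", "yes", True),
        ("yes_no", "no", False),
    ])
    def test_parses_scalar_kinds(self, kind, raw, expected):
        session = Session.start()
        item = toy_item("x", kind=kind)
        record_answer(session, item, raw, [item])
        assert session.answers["x"].value == expected

    @pytest.mark.parametrize("raw,minutes", [
        ("45 minutes", 45), ("2 hours", 120), ("1 day", 1440),
        ("3 wk", 3 * 10080), ("1.5 h", 90),
    ])
    def test_free_number_unit_entry_normalizes_units(self, raw, minutes):
        session = Session.start()
        item = toy_item("dur", kind="number_with_unit")
        record_answer(session, item, raw, [item])
        assert session.answers["dur"].value.to_minutes() == pytest.approx(minutes)

    @pytest.mark.parametrize("kind,raw", [
        ("vas_1_10", "11"),            # above scale maximum
        ("vas_1_10", "0"),
        ("number_with_unit", "45 fortnights"),  # unknown unit is rejected
        ("number_with_unit", "soon"),
        ("number", "-3"),
    ])
    def test_invalid_answers_leave_session_unchanged(self, kind, raw):
        session = Session.start()
        item = toy_item("x", kind=kind)
        with pytest.raises(ValidationError, match="x"):
            record_answer(session, item, raw, [item])
        assert not session.answers and not session.asked

    def test_choice_token_outside_options_rejected(self):
        session = Session.start()
        item = toy_item("q", kind="single_choice", options=["a", "b"])
        with pytest.raises(ValidationError, match="q"):
            record_answer(session, item, "c", [item])
        record_answer(session, item, "b", [item])
        assert session.answers["q"].value == "b"

    def test_progress_can_drop_when_branch_opens(self):
        session = Session.start()
        record_answer(session, TOY_BANK[0], 30, TOY_BANK)
        record_answer(session, TOY_BANK[1], False, TOY_BANK)
        record_answer(session, TOY_BANK[3], False, TOY_BANK)
        assert session.progress == 1.0
        # re-answering aura to "yes" opens a new item: progress drops
        record_answer(session, TOY_BANK[1], True, TOY_BANK)
        assert session.progress < 1.0


class TestConsistency:
    def _answered(self, bank):
        session = Session.start()
        by_id = {i.item_id: i for i in bank}
        return session, by_id

    def test_attack_history_longer_than_disease_duration_fires(self, bank):
        session, by_id = self._answered(bank)
        record_answer(session, by_id["disease_duration"], "1 month", bank)
        record_answer(session, by_id["years_with_attacks"], "10 years", bank)
        fired = detect_inconsistencies(session)
        assert [f[0] for f in fired] == ["onset_vs_attack_history"]
        assert set(session.reask_queue) == {"disease_duration",
                                            "years_with_attacks"}

    def test_calendar_bound_on_headache_days(self, bank):
        session, by_id = self._answered(bank)
        record_answer(session, by_id["headache_days_per_month"], 40, bank)
        assert [f[0] for f in detect_inconsistencies(session)] == \
            ["headache_days_calendar_bound"]

    def test_attack_time_budget_check(self, bank):
        session, by_id = self._answered(bank)
        record_answer(session, by_id["attack_duration"], "20 hours", bank)
        record_answer(session, by_id["attacks_per_day"], 3, bank)
        assert [f[0] for f in detect_inconsistencies(session)] == \
            ["attack_duration_vs_frequency"]

    def test_consistent_simulated_interview_has_no_findings(self, rng):
        record = generate_patient(DiagnosisLabel.MO, 1.0, rng)
        session = simulate_session(record)
        assert detect_inconsistencies(session) == []

    def test_second_violation_of_same_check_marks_contradictory(self, bank):
        session, by_id = self._answered(bank)
        record_answer(session, by_id["headache_days_per_month"], 40, bank)
        detect_inconsistencies(session)
        assert not session.contradictory
        # patient re-answers with another impossible value
        record_answer(session, by_id["headache_days_per_month"], 45, bank)
        detect_inconsistencies(session)
        assert session.contradictory
        with pytest.raises(ContradictorySessionError):
            compile_record(session, bank)


class TestInstruments:
    @pytest.mark.parametrize("items,total,band", [
        ([0] * 9, 0, "minimal"),
        ([3] * 9, 27, "severe"),
        ([1, 1, 1, 1, 1, 0, 0, 0, 0], 5, "mild"),
        ([2] * 5 + [0] * 4, 10, "moderate"),
    ])
    def test_phq9_sum_and_band(self, items, total, band):
        assert score_phq9(items) == (total, band)

    @pytest.mark.parametrize("items,total,band", [
        ([0] * 7, 0, "minimal"),
        ([3] * 7, 21, "severe"),
        ([1, 1, 1, 1, 1, 0, 0], 5, "mild"),
    ])
    def test_gad7_sum_and_band(self, items, total, band):
        assert score_gad7(items) == (total, band)

    def test_out_of_range_item_rejected(self):
        with pytest.raises(ValidationError):
            score_phq9([0, 0, 0, 0, 0, 0, 0, 0, 4])
        with pytest.raises(ValidationError):
            score_gad7([1, 2, 3, -1, 0, 0, 0])


class TestCompile:
    def test_day_durations_normalized_to_minutes(self, bank, rng):
        record = generate_patient(DiagnosisLabel.MO, 1.0, rng)
        session = simulate_session(record)
        by_id = {i.item_id: i for i in bank}
        record_answer(session, by_id["attack_duration"], "1 day", bank)
        compiled = compile_record(session, bank)
        assert compiled.attack.duration_minutes_untreated == 1440

    def test_missing_mandatory_theme_is_incomplete(self, bank, rng):
        record = generate_patient(DiagnosisLabel.MO, 1.0, rng)
        session = simulate_session(record)
        for iid in [i.item_id for i in bank if i.theme == "red_flags"]:
            del session.answers[iid]
        with pytest.raises(IncompleteSessionError, match="rf_"):
            compile_record(session, bank)

    def test_skipped_mood_section_maps_to_absent_not_no(self, rng):
        record = generate_patient(DiagnosisLabel.fETTH, 1.0, rng)
        compiled = compile_record(simulate_session(record))
        assert compiled.psych.answered is False
        assert compiled.psych.phq9_total is None

    def test_transcript_replay_reproduces_the_record(self, tmp_path, rng):
        record = generate_patient(DiagnosisLabel.CH, 1.0, rng)
        session = simulate_session(record)
        path = tmp_path / "transcript.jsonl"
        write_transcript(session, path)
        replayed = replay_transcript(path)
        assert compile_record(replayed) == record


def test_quantity_rejects_nonpositive_and_unknown_units():
    with pytest.raises(ValueError):
        Quantity(0, "minute")
    with pytest.raises(ValueError):
        Quantity(5, "parsec")
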