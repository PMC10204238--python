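"""Conversational intake engine.

Models the patient-computer interview: an item bank with answer-dependent
branching, free number+unit entry for durations, answer validation,
automatic inconsistency detection with re-asking, progress tracking, and
compilation of a finished session into a :class:`~headdx.records.PatientRecord`.

The flow is a simple loop::

    session = Session.start()
    while (item := next_item(session, bank)) is not None:
        record_answer(session, item, raw_answer_for(item))
        detect_inconsistencies(session)
    record = compile_record(session, bank)

Inconsistent answer pairs (e.g. an attack history longer than the disease
duration) put the offending items back on a re-ask queue; a *second*
violation of the same check after re-asking marks the whole session
contradictory, and contradictory sessions cannot be compiled.
"""

from __future__ import annotations

import json
import re
import time
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence, Union

import yaml

from .records import (
    Associated, Attack, Aura, Autonomic, Course, Demographics, MedicationUse,
    Pain, PatientRecord, Psych, RedFlagProfile,
)

__all__ = [
    "Quantity", "Answer", "QuestionnaireItem", "Session", "ConsistencyCheck",
    "ValidationError", "ConfigurationError", "IncompleteSessionError",
    "ContradictorySessionError", "load_item_bank", "default_bank",
    "next_item", "record_answer", "detect_inconsistencies", "DEFAULT_CHECKS",
    "score_phq9", "score_gad7", "compile_record", "write_transcript",
    "replay_transcript",
]

THEMES = ("demographics", "characteristics", "red_flags", "triggers",
          "family_history", "comorbidities", "medical_history",
          "psych_optional")
ANSWER_KINDS = ("single_choice", "multi_choice", "number", "number_with_unit",
                "vas_1_10", "body_map_regions", "yes_no", "free_text")
_CHOICE_KINDS = ("single_choice", "multi_choice", "body_map_regions")

MINUTES_PER_UNIT = {"minute": 1.0, "hour": 60.0, "day": 1440.0,
                    "week": 10080.0, "month": 43200.0, "year": 525600.0}


class ValidationError(ValueError):
    def __init__(self, item_id: str, message: str):
        super().__init__(f"{item_id}: {message}")
        self.item_id = item_id


class ConfigurationError(ValueError):
    pass


class IncompleteSessionError(ValueError):
    def __init__(self, message: str, items: Sequence[str] = ()):
        super().__init__(message)
        self.items = list(items)


class ContradictorySessionError(IncompleteSessionError):
    pass


@dataclass(frozen=True)
class Quantity:
    magnitude: float
    unit: str

    def __post_init__(self):
        if self.magnitude <= 0:
            raise ValueError("quantity magnitude must be positive")
        if self.unit not in MINUTES_PER_UNIT:
            raise ValueError(f"unknown unit {self.unit!r}")

    def to_minutes(self) -> float:
        return self.magnitude * MINUTES_PER_UNIT[self.unit]


@dataclass(frozen=True)
class Answer:
    item_id: str
    value: object  # token | frozenset | Quantity | int | float | bool | str


@dataclass(frozen=True)
class ShowIfClause:
    item: str
    op: str  # eq | ne | in | ge | le
    value: object

    def holds(self, answers: Mapping[str, Answer]) -> bool:
        ans = answers.get(self.item)
        if ans is None:
            return False
        val = ans.value
        if isinstance(val, Quantity):
            val = val.to_minutes()
        if self.op == "eq":
            return val == self.value
        if self.op == "ne":
            return val != self.value
        if self.op == "in":
            return val in self.value
        if self.op == "ge":
            return float(val) >= float(self.value)
        if self.op == "le":
            return float(val) <= float(self.value)
        raise ConfigurationError(f"unknown show_if op {self.op!r}")


@dataclass(frozen=True)
class QuestionnaireItem:
    item_id: str
    theme: str
    prompt: str
    answer_kind: str
    options: tuple[str, ...] = ()
    show_if: tuple[ShowIfClause, ...] = ()

    def eligible(self, answers: Mapping[str, Answer]) -> bool:
        return all(clause.holds(answers) for clause in self.show_if)


@dataclass
class Session:
    answers: dict[str, Answer] = dc_field(default_factory=dict)
    asked: list[str] = dc_field(default_factory=list)
    reask_queue: list[str] = dc_field(default_factory=list)
    started_at: float = 0.0
    finished_at: Optional[float] = None
    progress: float = 0.0
    check_strikes: dict[str, int] = dc_field(default_factory=dict)
    open_violations: dict[str, tuple[str, ...]] = dc_field(default_factory=dict)
    contradictory: bool = False
    transcript: list[dict] = dc_field(default_factory=list)

    @classmethod
    def start(cls, now: Optional[float] = None) -> "Session":
        return cls(started_at=time.time() if now is None else now)

    @property
    def completion_seconds(self) -> Optional[float]:
        if self.finished_at is None:
            return None
        return self.finished_at - self.started_at


# ---------------------------------------------------------------------------
# item bank
# ---------------------------------------------------------------------------

def _parse_bank(items: list, origin: str) -> list[QuestionnaireItem]:
    if not isinstance(items, list):
        raise ConfigurationError(f"{origin}: item bank must be a list")
    bank: list[QuestionnaireItem] = []
    seen: set[str] = set()
    for raw in items:
        extra = set(raw) - {"item_id", "theme", "prompt", "answer_kind",
                            "options", "show_if"}
        if extra:
            raise ConfigurationError(
                f"{origin}: item {raw.get('item_id')}: unknown keys {sorted(extra)}")
        iid = raw["item_id"]
        if iid in seen:
            raise ConfigurationError(f"{origin}: duplicate item_id {iid!r}")
        seen.add(iid)
        if raw["theme"] not in THEMES:
            raise ConfigurationError(f"{origin}: {iid}: unknown theme {raw['theme']!r}")
        kind = raw["answer_kind"]
        if kind not in ANSWER_KINDS:
            raise ConfigurationError(f"{origin}: {iid}: unknown answer_kind {kind!r}")
        options = tuple(raw.get("options", ()))
        if (kind in _CHOICE_KINDS) != bool(options):
            raise ConfigurationError(
                f"{origin}: {iid}: options required exactly for choice kinds")
        clauses = tuple(
            ShowIfClause(c["item"], c["op"], c["value"])
            for c in raw.get("show_if", ()))
        bank.append(QuestionnaireItem(
            item_id=iid, theme=raw["theme"], prompt=raw["prompt"],
            answer_kind=kind, options=options, show_if=clauses))
    _check_dependencies(bank, origin)
    return bank


def _check_dependencies(bank: list[QuestionnaireItem], origin: str) -> None:
    """show_if references must resolve and must be topologically orderable."""
    ids = {item.item_id for item in bank}
    deps = {item.item_id: {c.item for c in item.show_if} for item in bank}
    for iid, parents in deps.items():
        missing = parents - ids
        if missing:
            raise ConfigurationError(
                f"{origin}: {iid}: show_if references unknown items {sorted(missing)}")
    # cycle detection by iterative DFS
    WHITE, GREY, BLACK = 0, 1, 2
    color = {iid: WHITE for iid in deps}

    def visit(start: str) -> None:
        stack = [(start, iter(deps[start]))]
        color[start] = GREY
        path = [start]
        while stack:
            node, it = stack[-1]
            for parent in it:
                if color[parent] == GREY:
                    cycle = path[path.index(parent):] + [parent]
                    raise ConfigurationError(
                        f"{origin}: cyclic show_if dependency: "
                        + " -> ".join(cycle))
                if color[parent] == WHITE:
                    color[parent] = GREY
                    stack.append((parent, iter(deps[parent])))
                    path.append(parent)
                    break
            else:
                color[node] = BLACK
                stack.pop()
                path.pop()

    for iid in deps:
        if color[iid] == WHITE:
            visit(iid)


def load_item_bank(path: Union[str, Path]) -> list[QuestionnaireItem]:
    with open(path) as fh:
        return _parse_bank(yaml.safe_load(fh), str(path))


_BANK_CACHE: list[QuestionnaireItem] | None = None


def default_bank() -> list[QuestionnaireItem]:
    global _BANK_CACHE
    if _BANK_CACHE is None:
        text = resources.files("headdx.data").joinpath("item_bank.yaml").read_text()
        _BANK_CACHE = _parse_bank(yaml.safe_load(text), "item_bank.yaml")
    return _BANK_CACHE


_UNIT_LOOKUP: dict[str, str] | None = None


def _unit_lookup() -> dict[str, str]:
    global _UNIT_LOOKUP
    if _UNIT_LOOKUP is None:
        text = resources.files("headdx.data").joinpath("units.yaml").read_text()
        table = yaml.safe_load(text)
        _UNIT_LOOKUP = {syn.lower(): unit
                        for unit, syns in table.items() for syn in syns}
    return _UNIT_LOOKUP


# ---------------------------------------------------------------------------
# the ask/answer loop
# ---------------------------------------------------------------------------

def next_item(session: Session,
              bank: Sequence[QuestionnaireItem] | None = None,
              ) -> Optional[QuestionnaireItem]:
    """The next question to put to the patient, or ``None`` when done.

    Items queued for confirmation (re-ask) come first; otherwise the first
    unanswered item whose show_if holds over the current answers. An item
    whose show_if is false is never returned.
    """
    bank = bank if bank is not None else default_bank()
    by_id = {item.item_id: item for item in bank}
    if session.reask_queue:
        return by_id[session.reask_queue[0]]
    for item in bank:
        if item.item_id not in session.answers and item.eligible(session.answers):
            return item
    if session.finished_at is None:
        session.finished_at = time.time()
    return None


_NUMBER_UNIT_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*([A-Za-z]+)\s*$")


def _parse_value(item: QuestionnaireItem, raw: object) -> object:
    kind = item.answer_kind
    if kind == "yes_no":
        if isinstance(raw, bool):
            return raw
        token = str(raw).strip().lower()
        if token in ("yes", "true", "y", "1"):
            return True
        if token in ("no", "false", "n", "0"):
            return False
        raise ValidationError(item.item_id, f"expected yes/no, got {raw!r}")
    if kind == "vas_1_10":
        try:
            value = int(str(raw).strip())
        except ValueError:
            raise ValidationError(item.item_id, f"VAS must be an integer, got {raw!r}") from None
        if not 1 <= value <= 10:
            raise ValidationError(item.item_id, f"VAS must lie in 1-10, got {value}")
        return value
    if kind == "number":
        try:
            value = float(raw)
        except (TypeError, ValueError):
            raise ValidationError(item.item_id, f"expected a number, got {raw!r}") from None
        if value < 0:
            raise ValidationError(item.item_id, f"negative value {value}")
        return value
    if kind == "number_with_unit":
        if isinstance(raw, Quantity):
            return raw
        match = _NUMBER_UNIT_RE.match(str(raw))
        if not match:
            raise ValidationError(
                item.item_id, f"expected '<number> <unit>', got {raw!r}")
        magnitude = float(match.group(1))
        unit = _unit_lookup().get(match.group(2).lower())
        if unit is None:
            raise ValidationError(item.item_id, f"unknown time unit {match.group(2)!r}")
        if magnitude <= 0:
            raise ValidationError(item.item_id, "quantity must be positive")
        return Quantity(magnitude, unit)
    if kind == "single_choice":
        token = str(raw).strip()
        if token not in item.options:
            raise ValidationError(
                item.item_id, f"option {token!r} not among {list(item.options)}")
        return token
    if kind in ("multi_choice", "body_map_regions"):
        if isinstance(raw, str):
            tokens = [t.strip() for t in raw.split(",") if t.strip()]
        else:
            tokens = [str(t) for t in raw]
        bad = [t for t in tokens if t not in item.options]
        if bad:
            raise ValidationError(item.item_id, f"unknown options {bad}")
        return frozenset(tokens)
    return str(raw)  # free_text


def _update_progress(session: Session, bank: Sequence[QuestionnaireItem]) -> None:
    eligible = [it.item_id for it in bank if it.eligible(session.answers)]
    answered = sum(1 for iid in eligible if iid in session.answers)
    session.progress = answered / len(eligible) if eligible else 0.0


def record_answer(session: Session, item: QuestionnaireItem, raw: object,
                  bank: Sequence[QuestionnaireItem] | None = None,
                  now: Optional[float] = None) -> Session:
    """Validate and store one answer; on a validation error the session is
    left untouched. Re-answered items replace the previous answer
    (last-write-wins) and clear their pending violations."""
    bank = bank if bank is not None else default_bank()
    value = _parse_value(item, raw)  # may raise; session untouched then
    replaced = item.item_id in session.answers
    session.answers[item.item_id] = Answer(item.item_id, value)
    if item.item_id not in session.asked:
        session.asked.append(item.item_id)
    if item.item_id in session.reask_queue:
        session.reask_queue.remove(item.item_id)
    if replaced:
        for check_id, items in list(session.open_violations.items()):
            if item.item_id in items:
                del session.open_violations[check_id]
    session.transcript.append({
        "item_id": item.item_id,
        "raw": raw if isinstance(raw, (str, int, float, bool)) else str(raw),
        "timestamp": time.time() if now is None else now,
    })
    _update_progress(session, bank)
    return session


# ---------------------------------------------------------------------------
# consistency checks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsistencyCheck:
    check_id: str
    item_ids: tuple[str, ...]
    violated: Callable[[Mapping[str, Answer]], bool]
    description: str = ""


def _val(answers: Mapping[str, Answer], iid: str):
    ans = answers.get(iid)
    return None if ans is None else ans.value


def _onset_vs_history(answers) -> bool:
    dd, yw = _val(answers, "disease_duration"), _val(answers, "years_with_attacks")
    if dd is None or yw is None:
        return False
    return yw.to_minutes() > dd.to_minutes() * 1.0001


def _days_bound(answers) -> bool:
    days = _val(answers, "headache_days_per_month")
    return days is not None and days > 31


def _attack_time_budget(answers) -> bool:
    dur, freq = _val(answers, "attack_duration"), _val(answers, "attacks_per_day")
    if dur is None or freq is None:
        return False
    # more attack-time per day than a day holds implies >31 headache
    # days/month, which is impossible
    return dur.to_minutes() * freq > 1440.0


DEFAULT_CHECKS: tuple[ConsistencyCheck, ...] = (
    ConsistencyCheck(
        "onset_vs_attack_history",
        ("disease_duration", "years_with_attacks"),
        _onset_vs_history,
        "attack history cannot be longer than the disease duration"),
    ConsistencyCheck(
        "headache_days_calendar_bound",
        ("headache_days_per_month",),
        _days_bound,
        "headache days per month cannot exceed 31"),
    ConsistencyCheck(
        "attack_duration_vs_frequency",
        ("attack_duration", "attacks_per_day"),
        _attack_time_budget,
        "per-attack duration times frequency cannot exceed 24 h/day"),
)


def detect_inconsistencies(session: Session,
                           checks: Sequence[ConsistencyCheck] = DEFAULT_CHECKS,
                           ) -> list[tuple[str, list[str]]]:
    """Return every violated check and queue its items for confirmation.

    Each named item is enqueued at most once. A check that fires again after
    its items were re-answered marks the session contradictory (two-strike
    rule, mirroring exclusion of irreconcilable records).
    """
    fired: list[tuple[str, list[str]]] = []
    for check in checks:
        if not check.violated(session.answers):
            session.open_violations.pop(check.check_id, None)
            continue
        fired.append((check.check_id, list(check.item_ids)))
        for iid in check.item_ids:
            if iid in session.answers and iid not in session.reask_queue:
                session.reask_queue.append(iid)
        if check.check_id not in session.open_violations:
            session.open_violations[check.check_id] = check.item_ids
            session.check_strikes[check.check_id] = \
                session.check_strikes.get(check.check_id, 0) + 1
            if session.check_strikes[check.check_id] >= 2:
                session.contradictory = True
    return fired


# ---------------------------------------------------------------------------
# mood instruments
# ---------------------------------------------------------------------------

_PHQ9_BANDS = ((4, "minimal"), (9, "mild"), (14, "moderate"),
               (19, "moderately_severe"), (27, "severe"))
_GAD7_BANDS = ((4, "minimal"), (9, "mild"), (14, "moderate"), (21, "severe"))


def _score(items: Sequence[int], n: int, bands) -> tuple[int, str]:
    if len(items) != n:
        raise ValidationError("psych", f"expected {n} item scores, got {len(items)}")
    for value in items:
        if not (isinstance(value, int) and 0 <= value <= 3):
            raise ValidationError("psych", f"item scores must be integers 0-3, got {value!r}")
    total = sum(items)
    for upper, band in bands:
        if total <= upper:
            return total, band
    raise AssertionError


def score_phq9(items: Sequence[int]) -> tuple[int, str]:
    """Sum-score the nine depression items (0-27) and band the total."""
    return _score(items, 9, _PHQ9_BANDS)


def score_gad7(items: Sequence[int]) -> tuple[int, str]:
    """Sum-score the seven anxiety items (0-21) and band the total."""
    return _score(items, 7, _GAD7_BANDS)


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------

def _minutes(q: Quantity | None) -> float | None:
    return None if q is None else q.to_minutes()


def _months(q: Quantity) -> float:
    # answers given directly in months avoid a lossy round trip via minutes
    return q.magnitude if q.unit == "month" else q.to_minutes() / MINUTES_PER_UNIT["month"]


def compile_record(session: Session,
                   bank: Sequence[QuestionnaireItem] | None = None,
                   checks: Sequence[ConsistencyCheck] = DEFAULT_CHECKS,
                   ) -> PatientRecord:
    """Deterministically map a finished, consistent session to a record.

    Durations are normalized to minutes (months for the disease course);
    the optional mood theme maps to absent-with-flag when skipped, never
    silently to "no".
    """
    bank = bank if bank is not None else default_bank()
    if session.contradictory:
        raise ContradictorySessionError(
            "session marked contradictory by repeated consistency violations",
            [iid for items in session.open_violations.values() for iid in items])
    open_checks = [c for c in checks if c.violated(session.answers)]
    if open_checks:
        raise IncompleteSessionError(
            "unresolved inconsistencies: "
            + ", ".join(c.check_id for c in open_checks),
            [iid for c in open_checks for iid in c.item_ids])
    missing = [item.item_id for item in bank
               if item.eligible(session.answers)
               and item.item_id not in session.answers]
    if missing or session.reask_queue:
        raise IncompleteSessionError(
            "session incomplete; missing items: " + ", ".join(missing),
            missing + list(session.reask_queue))

    def a(iid: str):
        return _val(session.answers, iid)

    days = float(a("headache_days_per_month"))
    migraine_days = a("migraine_like_days_per_month")
    medication: list[MedicationUse] = []
    if a("painkiller_use"):
        medication.append(MedicationUse(
            drug_class=a("painkiller_class"),
            intake_days_per_month=float(a("painkiller_days_per_month")),
            months_of_regular_use=float(a("painkiller_months")),
        ))
    overuse = any(m.intake_days_per_month >= 10 for m in medication)
    autonomic_features = a("autonomic_features") or frozenset()
    if a("psych_optin"):
        phq = [int(a(f"phq9_q{i}")) for i in range(1, 10)]
        gad = [int(a(f"gad7_q{i}")) for i in range(1, 8)]
        psych = Psych(phq9_total=score_phq9(phq)[0],
                      gad7_total=score_gad7(gad)[0], answered=True)
    else:
        psych = Psych(answered=False)
    return PatientRecord(
        demographics=Demographics(
            age=float(a("age")), sex=a("sex"), education=a("education"),
            occupation=a("occupation"), height_cm=float(a("height")),
            weight_kg=float(a("weight"))),
        course=Course(
            disease_duration_months=_months(a("disease_duration")),
            onset_abrupt=bool(a("onset_abrupt")),
            daily_from_onset=bool(a("daily_from_onset")),
            onset_clearly_remembered=bool(a("onset_clearly_remembered")),
            headache_days_per_month=days,
            migraine_like_days_per_month=(
                None if migraine_days is None else float(migraine_days)),
            lifetime_attack_count=int(a("lifetime_attack_count"))),
        pain=Pain(
            locations=a("head_locations"), laterality=a("laterality"),
            qualities=a("pain_qualities"), vas=int(a("vas"))),
        attack=Attack(
            duration_minutes_untreated=_minutes(a("attack_duration")),
            frequency_per_day=float(a("attacks_per_day")),
            trigger_evoked=bool(a("trigger_evoked"))),
        associated=Associated(
            nausea=bool(a("nausea")), vomiting=bool(a("vomiting")),
            mild_nausea_only=bool(a("mild_nausea_only")),
            photophobia=bool(a("photophobia")),
            phonophobia=bool(a("phonophobia")),
            aggravated_by_routine_activity=bool(a("aggravated_by_activity")),
            restlessness_agitation=bool(a("restlessness"))),
        autonomic=Autonomic(
            ipsilateral=bool(a("autonomic_ipsilateral")),
            **{name: name in autonomic_features
               for name in ("conjunctival_injection", "lacrimation",
                            "nasal_congestion", "rhinorrhoea", "eyelid_oedema",
                            "ptosis_miosis", "forehead_face_sweating")}),
        aura=Aura(
            present=bool(a("aura_present")),
            symptoms=a("aura_symptoms") or frozenset(),
            each_symptom_5_to_60_min=bool(a("aura_each_5_60")),
            gradual_spread_ge_5_min=bool(a("aura_gradual_spread")),
            headache_within_60_min=bool(a("aura_headache_within_60"))),
        medication=medication,
        red_flags=RedFlagProfile(
            systemic_symptoms_fever=bool(a("rf_fever")),
            neoplasm_history=bool(a("rf_neoplasm")),
            neurologic_deficit=bool(a("rf_neuro_deficit")),
            sudden_abrupt_onset=bool(a("rf_thunderclap")),
            onset_after_50=bool(a("rf_onset_after_50")),
            pattern_change_or_new_headache=bool(a("rf_pattern_change")),
            positional_headache=bool(a("rf_positional")),
            precipitated_by_cough_sneeze_exercise=bool(a("rf_cough_exercise")),
            progressive_headache=bool(a("rf_progressive")),
            eye_pain_autonomic_features=bool(a("rf_eye_pain_autonomic")),
            posttraumatic_onset=bool(a("rf_posttraumatic")),
            painkiller_overuse_flag=overuse),
        psych=psych,
    )


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

def write_transcript(session: Session, path: Union[str, Path]) -> None:
    """One record_answer event per JSON line."""
    with open(path, "w") as fh:
        for event in session.transcript:
            fh.write(json.dumps(event) + "\n")


def replay_transcript(path: Union[str, Path],
                      bank: Sequence[QuestionnaireItem] | None = None,
                      ) -> Session:
    """Re-run a recorded interview through the validation pipeline."""
    bank = bank if bank is not None else default_bank()
    by_id = {item.item_id: item for item in bank}
    session = Session.start()
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            event = json.loads(line)
            item = by_id.get(event["item_id"])
            if item is None:
                raise ValidationError(event["item_id"], "unknown item in transcript")
            record_answer(session, item, event["raw"], bank,
                          now=event.get("timestamp"))
            detect_inconsistencies(session)
    return session
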