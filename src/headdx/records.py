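"""Structured patient records and diagnosis results.

A :class:`PatientRecord` is the unit that flows through the whole pipeline:
the questionnaire engine compiles one from a session, the red-flag screener
and the rule engine read it, and the synthetic-cohort generator produces
them directly. Validation is strict: quantities must be positive, monthly
day counts are capped at the calendar bound of 31, and the migraine-like day
count can never exceed the total headache day count.
"""

from __future__ import annotations

import enum
import warnings
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


class DiagnosisLabel(str, enum.Enum):
    """The 12 output categories plus a residual OTHERS bucket."""

    MO = "MO"                  # migraine without aura
    MA = "MA"                  # migraine with aura
    PM = "PM"                  # probable migraine
    CM = "CM"                  # chronic migraine
    iETTH = "iETTH"            # infrequent episodic tension-type headache
    fETTH = "fETTH"            # frequent episodic tension-type headache
    PTTH = "PTTH"              # probable tension-type headache
    CTTH = "CTTH"              # chronic tension-type headache
    CH = "CH"                  # cluster headache
    NDPH = "NDPH"              # new daily persistent headache
    MOH = "MOH"                # medication-overuse headache
    NEURALGIA = "NEURALGIA"
    OTHERS = "OTHERS"


#: labels for which full diagnostic criteria are encoded (everything except
#: the probable categories and the residual bucket, which are derived)
DEFINITE_LABELS = (
    DiagnosisLabel.MO, DiagnosisLabel.MA, DiagnosisLabel.CM,
    DiagnosisLabel.iETTH, DiagnosisLabel.fETTH, DiagnosisLabel.CTTH,
    DiagnosisLabel.CH, DiagnosisLabel.NDPH, DiagnosisLabel.MOH,
    DiagnosisLabel.NEURALGIA,
)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class Demographics(_Strict):
    age: float = Field(ge=0, le=120)
    sex: str  # "female" | "male"
    education: str = "secondary"
    occupation: str = "other"
    height_cm: Optional[float] = Field(default=None, gt=0)
    weight_kg: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _age_window(self):
        # the engine was validated on ages 11-85; outside that window records
        # are accepted with a warning, never rejected
        if not (11 <= self.age <= 85):
            warnings.warn(
                f"age {self.age} outside the validated 11-85 range",
                stacklevel=2,
            )
        return self


class Course(_Strict):
    disease_duration_months: float = Field(gt=0)
    onset_abrupt: bool = False
    daily_from_onset: bool = False
    onset_clearly_remembered: bool = False
    headache_days_per_month: float = Field(ge=0, le=31)  # 3-month average
    #: None = not elicited (the questionnaire asks it only for frequent headache)
    migraine_like_days_per_month: Optional[float] = Field(default=None, ge=0, le=31)
    lifetime_attack_count: int = Field(ge=0)

    @model_validator(mode="after")
    def _day_counts(self):
        if (self.migraine_like_days_per_month is not None
                and self.migraine_like_days_per_month > self.headache_days_per_month):
            raise ValueError(
                "migraine_like_days_per_month cannot exceed headache_days_per_month"
            )
        return self


#: tokens the body-map location answer may carry
BODY_MAP_REGIONS = frozenset({
    "frontal", "temporal", "orbital", "supraorbital", "occipital",
    "parietal", "vertex", "face", "neck", "whole_head",
})

PAIN_QUALITIES = frozenset({
    "pulsating", "pressing_tightening", "stabbing", "electric_shock", "other",
})


class Pain(_Strict):
    locations: frozenset[str] = frozenset()
    laterality: str = "bilateral"  # unilateral | bilateral | variable
    qualities: frozenset[str] = frozenset()
    vas: int = Field(ge=1, le=10)

    @model_validator(mode="after")
    def _tokens(self):
        bad = self.locations - BODY_MAP_REGIONS
        if bad:
            raise ValueError(f"unknown body-map regions: {sorted(bad)}")
        bad = self.qualities - PAIN_QUALITIES
        if bad:
            raise ValueError(f"unknown pain qualities: {sorted(bad)}")
        if self.laterality not in {"unilateral", "bilateral", "variable"}:
            raise ValueError(f"unknown laterality {self.laterality!r}")
        return self


class Attack(_Strict):
    duration_minutes_untreated: float = Field(gt=0)
    frequency_per_day: float = Field(ge=0)
    trigger_evoked: bool = False  # innocuous-stimulus triggered (neuralgia screen)


class Associated(_Strict):
    nausea: bool = False
    vomiting: bool = False
    mild_nausea_only: bool = False
    photophobia: bool = False
    phonophobia: bool = False
    aggravated_by_routine_activity: bool = False
    restlessness_agitation: bool = False


class Autonomic(_Strict):
    conjunctival_injection: bool = False
    lacrimation: bool = False
    nasal_congestion: bool = False
    rhinorrhoea: bool = False
    eyelid_oedema: bool = False
    ptosis_miosis: bool = False
    forehead_face_sweating: bool = False
    ipsilateral: bool = False

    @property
    def any_feature(self) -> bool:
        return any([
            self.conjunctival_injection, self.lacrimation,
            self.nasal_congestion, self.rhinorrhoea, self.eyelid_oedema,
            self.ptosis_miosis, self.forehead_face_sweating,
        ])


AURA_SYMPTOMS = frozenset({"visual", "sensory", "speech"})


class Aura(_Strict):
    present: bool = False
    symptoms: frozenset[str] = frozenset()
    each_symptom_5_to_60_min: bool = False
    gradual_spread_ge_5_min: bool = False
    headache_within_60_min: bool = False

    @model_validator(mode="after")
    def _symbols(self):
        bad = self.symptoms - AURA_SYMPTOMS
        if bad:
            raise ValueError(f"unknown aura symptoms: {sorted(bad)}")
        return self


DRUG_CLASSES = ("triptan", "ergot", "opioid", "combination_analgesic",
                "simple_analgesic", "nsaid")
#: acute-medication classes for which overuse means >=10 intake days/month
SHORT_ACTING_CLASSES = frozenset(
    {"triptan", "ergot", "opioid", "combination_analgesic"})


class MedicationUse(_Strict):
    drug_class: str
    intake_days_per_month: float = Field(ge=0, le=31)
    months_of_regular_use: float = Field(ge=0)

    @model_validator(mode="after")
    def _cls(self):
        if self.drug_class not in DRUG_CLASSES:
            raise ValueError(f"unknown drug class {self.drug_class!r}")
        return self


class RedFlagProfile(_Strict):
    """SNNOOP10-style secondary-headache alarm features.

    Every field must be explicitly answered; the screener refuses to run on a
    record whose red-flag theme is missing (``None``), so screening can never
    silently pass.
    """

    systemic_symptoms_fever: bool = False
    neoplasm_history: bool = False
    neurologic_deficit: bool = False
    sudden_abrupt_onset: bool = False
    onset_after_50: bool = False
    pattern_change_or_new_headache: bool = False
    positional_headache: bool = False
    precipitated_by_cough_sneeze_exercise: bool = False
    progressive_headache: bool = False
    eye_pain_autonomic_features: bool = False
    posttraumatic_onset: bool = False
    painkiller_overuse_flag: bool = False
    other_flags: dict[str, bool] = Field(default_factory=dict)


class Psych(_Strict):
    phq9_total: Optional[int] = Field(default=None, ge=0, le=27)
    gad7_total: Optional[int] = Field(default=None, ge=0, le=21)
    answered: bool = False  # optional theme taken at all?


class PatientRecord(_Strict):
    demographics: Demographics
    course: Course
    pain: Pain
    attack: Attack
    associated: Associated
    autonomic: Autonomic
    aura: Aura
    medication: list[MedicationUse] = Field(default_factory=list)
    red_flags: Optional[RedFlagProfile] = None
    psych: Psych = Field(default_factory=Psych)


class FlagWarning(_Strict):
    """A single secondary-headache warning attached to a diagnosis."""

    flag_id: str
    message: str
    severity: str  # advisory | urgent


class CriteriaEvaluation(_Strict):
    diagnosis: DiagnosisLabel
    groups_met: frozenset[str]
    groups_failed: frozenset[str]
    not_assessable: frozenset[str] = frozenset()

    @property
    def n_failed(self) -> int:
        return len(self.groups_failed)

    @property
    def fully_met(self) -> bool:
        return not self.groups_failed


class DiagnosisResult(_Strict):
    label: DiagnosisLabel
    method: str  # "rule" | "cbr"
    trace: list[CriteriaEvaluation] = Field(default_factory=list)
    warnings: list[FlagWarning] = Field(default_factory=list)
    notes: list[str] = Field(default_factory=list)

    @property
    def pending_secondary_exclusion(self) -> bool:
        """True when red-flag warnings mean the primary-headache label should
        be treated as provisional until secondary causes are excluded."""
        return bool(self.warnings)

    def to_json_dict(self) -> dict:
        return {
            "label": self.label.value,
            "method": self.method,
            "pending_secondary_exclusion": self.pending_secondary_exclusion,
            "warnings": [w.model_dump() for w in self.warnings],
            "trace": [
                {
                    "diagnosis": ev.diagnosis.value,
                    "groups_met": sorted(ev.groups_met),
                    "groups_failed": sorted(ev.groups_failed),
                    "not_assessable": sorted(ev.not_assessable),
                    "n_failed": ev.n_failed,
                }
                for ev in self.trace
            ],
            "notes": list(self.notes),
        }
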