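"""Synthetic outpatient headache cohorts.

Generates structured patient records per target diagnosis so that every
other module is testable without clinical data. Each label has a generative
template whose field distributions sit centrally inside that diagnosis'
criterion windows; at ``typicality=1`` a record fully satisfies its own
label's criterion groups and misses at least one group of every other
definite label (the single documented exception: medication-overuse
records also satisfy the chronic-migraine groups, which is exactly the
overlap the precedence rule resolves). With probability ``1 - typicality``
exactly one criterion group is nudged just outside its threshold, producing
the borderline "probable" presentations that drive the case-based stage.

The probable categories are generated constructively: a probable-migraine
record is a migraine template with one group deliberately missed, a
probable-TTH record an episodic/chronic tension-type template treated the
same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .cbr import CaseBase, Feature, FeatureSchema, default_schema, featurize
from .questionnaire import (
    QuestionnaireItem, Session, detect_inconsistencies, next_item,
    record_answer, default_bank,
)
from .records import (
    Associated, Attack, Aura, Autonomic, Course, Demographics, DiagnosisLabel,
    MedicationUse, Pain, PatientRecord, Psych, RedFlagProfile,
)

__all__ = ["GeneratorConfig", "DEFAULT_LABEL_MIX", "generate_patient",
           "generate_cohort", "generate_casebase", "planted_casebase",
           "simulate_session"]

#: cohort composition used by default: the expert reference distribution of
#: the 531-patient validation cohort, with the non-generable residual
#: category removed and the remainder renormalized.
DEFAULT_LABEL_MIX: dict[DiagnosisLabel, float] = {
    lbl: count / 495.0 for lbl, count in {
        DiagnosisLabel.MO: 129, DiagnosisLabel.MA: 32, DiagnosisLabel.PM: 95,
        DiagnosisLabel.CM: 10, DiagnosisLabel.iETTH: 11,
        DiagnosisLabel.fETTH: 45, DiagnosisLabel.PTTH: 60,
        DiagnosisLabel.CTTH: 25, DiagnosisLabel.CH: 9,
        DiagnosisLabel.NDPH: 5, DiagnosisLabel.MOH: 29,
        DiagnosisLabel.NEURALGIA: 45,
    }.items()
}

_INJECTABLE_FLAGS = (
    "systemic_symptoms_fever", "neoplasm_history", "neurologic_deficit",
    "sudden_abrupt_onset", "onset_after_50", "pattern_change_or_new_headache",
    "positional_headache", "precipitated_by_cough_sneeze_exercise",
    "progressive_headache", "eye_pain_autonomic_features",
    "posttraumatic_onset",
)


@dataclass(frozen=True)
class GeneratorConfig:
    n: int = 100
    seed: int = 0
    typicality: float = 1.0
    red_flag_rate: float = 0.0
    label_mix: dict[DiagnosisLabel, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_LABEL_MIX))

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n >= 1 required")
        if not (0 <= self.typicality <= 1 and 0 <= self.red_flag_rate <= 1):
            raise ValueError("typicality and red_flag_rate must lie in [0, 1]")
        total = sum(self.label_mix.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"label mix proportions sum to {total}, not 1")
        if DiagnosisLabel.OTHERS in self.label_mix:
            raise ValueError("OTHERS has no generative template")


# ---------------------------------------------------------------------------
# internal: mutable draft of a record
# ---------------------------------------------------------------------------

class _Draft:
    """Plain attribute bag later frozen into a validated PatientRecord."""

    def __init__(self, rng: np.random.Generator):
        self.age = int(rng.integers(18, 65))
        self.sex = "female" if rng.random() < 0.62 else "male"
        self.education = str(rng.choice(
            ["primary_or_below", "secondary", "university_or_above"]))
        self.height = float(rng.integers(150, 190))
        self.weight = float(rng.integers(45, 95))
        self.disease_months = float(rng.uniform(6, 240))
        self.onset_abrupt = False
        self.daily_from_onset = False
        self.onset_remembered = False
        self.days = 2.0
        self.migraine_days: float | None = None
        self.attacks = 10
        self.duration = 60.0
        self.frequency = 0.1
        self.trigger_evoked = False
        self.locations: set[str] = {"frontal"}
        self.laterality = "bilateral"
        self.qualities: set[str] = {"pressing_tightening"}
        self.vas = 5
        self.aggravated = False
        self.nausea = False
        self.vomiting = False
        self.mild_nausea_only = False
        self.photophobia = False
        self.phonophobia = False
        self.restlessness = False
        self.autonomic: set[str] = set()
        self.autonomic_ipsilateral = False
        self.aura = False
        self.aura_symptoms: set[str] = set()
        self.aura_5_60 = False
        self.aura_gradual = False
        self.aura_within_60 = False
        self.medication: list[MedicationUse] = []
        self.flags: set[str] = set()

    def cap_frequency(self):
        """attacks/day bounded so total attack time stays well under 24 h/day"""
        self.frequency = float(min(self.frequency, 720.0 / self.duration))

    def freeze(self) -> PatientRecord:
        overuse = any(m.intake_days_per_month >= 10 for m in self.medication)
        return PatientRecord(
            demographics=Demographics(
                age=self.age, sex=self.sex, education=self.education,
                occupation="other", height_cm=self.height,
                weight_kg=self.weight),
            course=Course(
                disease_duration_months=self.disease_months,
                onset_abrupt=self.onset_abrupt,
                daily_from_onset=self.daily_from_onset,
                onset_clearly_remembered=self.onset_remembered,
                headache_days_per_month=self.days,
                migraine_like_days_per_month=self.migraine_days,
                lifetime_attack_count=self.attacks),
            pain=Pain(locations=frozenset(self.locations),
                      laterality=self.laterality,
                      qualities=frozenset(self.qualities), vas=self.vas),
            attack=Attack(duration_minutes_untreated=self.duration,
                          frequency_per_day=self.frequency,
                          trigger_evoked=self.trigger_evoked),
            associated=Associated(
                nausea=self.nausea, vomiting=self.vomiting,
                mild_nausea_only=self.mild_nausea_only,
                photophobia=self.photophobia, phonophobia=self.phonophobia,
                aggravated_by_routine_activity=self.aggravated,
                restlessness_agitation=self.restlessness),
            autonomic=Autonomic(
                ipsilateral=self.autonomic_ipsilateral,
                **{name: name in self.autonomic for name in (
                    "conjunctival_injection", "lacrimation",
                    "nasal_congestion", "rhinorrhoea", "eyelid_oedema",
                    "ptosis_miosis", "forehead_face_sweating")}),
            aura=Aura(present=self.aura,
                      symptoms=frozenset(self.aura_symptoms),
                      each_symptom_5_to_60_min=self.aura_5_60,
                      gradual_spread_ge_5_min=self.aura_gradual,
                      headache_within_60_min=self.aura_within_60),
            medication=list(self.medication),
            red_flags=RedFlagProfile(
                painkiller_overuse_flag=overuse,
                **{name: name in self.flags for name in _INJECTABLE_FLAGS}),
            psych=Psych(answered=False),
        )


# ---------------------------------------------------------------------------
# label templates
# ---------------------------------------------------------------------------

def _migraine_core(d: _Draft, rng) -> None:
    d.duration = float(rng.uniform(300, 4000))       # 5-67 h untreated
    d.laterality = "unilateral" if rng.random() < 0.7 else "bilateral"
    d.qualities = {"pulsating"}
    d.locations = {str(rng.choice(["temporal", "frontal", "orbital"]))}
    d.vas = int(rng.integers(4, 11))                 # moderate to severe
    d.aggravated = rng.random() < 0.8
    d.nausea = rng.random() < 0.8
    if d.nausea:
        d.photophobia = rng.random() < 0.6
        d.phonophobia = rng.random() < 0.6
    else:  # keep the associated-symptom group satisfied
        d.photophobia = d.phonophobia = True
    d.days = float(rng.uniform(1.5, 12))
    d.frequency = d.days / 30.0
    d.cap_frequency()


def _mo(d: _Draft, rng) -> None:
    d.attacks = int(rng.integers(6, 10))
    _migraine_core(d, rng)


def _mo_perturb(d: _Draft, rng, choice: str | None = None) -> None:
    choice = choice or str(rng.choice(["attacks", "duration", "associated"]))
    if choice == "attacks":
        d.attacks = int(rng.integers(3, 5))          # just below five attacks
    elif choice == "duration":
        d.duration = float(rng.uniform(150, 230))    # just under 4 h
        d.cap_frequency()
    else:  # drop every associated symptom
        d.nausea = d.vomiting = False
        d.photophobia = d.phonophobia = False
        d.mild_nausea_only = False
        # keep pain characteristics unambiguously migrainous so the record
        # stays one group short of migraine only
        d.laterality = "unilateral"
        d.aggravated = True


def _ma(d: _Draft, rng) -> None:
    d.attacks = int(rng.integers(2, 5))  # below the no-aura attack threshold
    _migraine_core(d, rng)
    d.aura = True
    d.aura_symptoms = {"visual"} | ({"sensory"} if rng.random() < 0.3 else set())
    d.aura_5_60 = d.aura_gradual = d.aura_within_60 = True


def _ma_perturb(d: _Draft, rng) -> None:
    if rng.random() < 0.5:
        d.aura_5_60 = d.aura_gradual = d.aura_within_60 = False
    else:
        d.attacks = 1


def _cm(d: _Draft, rng) -> None:
    d.attacks = int(rng.integers(6, 10))
    _migraine_core(d, rng)
    d.nausea = True
    d.days = float(rng.uniform(16, 26))
    d.migraine_days = float(rng.uniform(8.5, min(d.days - 0.5, 15)))
    d.disease_months = float(rng.uniform(6, 120))
    d.duration = float(rng.uniform(4500, 5760))      # beyond the 72 h window
    d.frequency = 0.2
    d.cap_frequency()


def _cm_perturb(d: _Draft, rng) -> None:
    if rng.random() < 0.5:
        d.migraine_days = float(rng.uniform(5, 7.5))
    else:
        d.days = float(rng.uniform(12, 14))
        d.migraine_days = None                       # below the asking threshold


def _tth_core(d: _Draft, rng) -> None:
    d.attacks = int(rng.integers(12, 40))
    d.duration = float(rng.uniform(60, 480))
    d.laterality = "bilateral" if rng.random() < 0.85 else "unilateral"
    d.qualities = {"pressing_tightening"}
    d.locations = {"frontal", "occipital"} if rng.random() < 0.5 else {"whole_head"}
    d.vas = int(rng.integers(2, 7))                  # mild to moderate
    d.aggravated = False
    d.nausea = d.vomiting = False
    if rng.random() < 0.25:
        d.photophobia = True
    elif rng.random() < 0.25:
        d.phonophobia = True
    d.disease_months = float(rng.uniform(6, 120))
    d.frequency = d.days / 30.0
    d.cap_frequency()


def _ietth(d: _Draft, rng) -> None:
    d.days = float(rng.uniform(0.3, 0.9))
    _tth_core(d, rng)


def _fetth(d: _Draft, rng) -> None:
    d.days = float(rng.uniform(2, 12))
    _tth_core(d, rng)


def _ctth(d: _Draft, rng) -> None:
    d.days = float(rng.uniform(16, 28))
    _tth_core(d, rng)
    d.attacks = int(rng.integers(50, 200))
    d.laterality = "bilateral"
    d.duration = float(rng.uniform(120, 720))
    d.migraine_days = 0.0
    if rng.random() < 0.4:                           # mild nausea is permitted
        d.nausea = True
        d.mild_nausea_only = True
        d.photophobia = d.phonophobia = False
    d.frequency = 0.5
    d.cap_frequency()


def _tth_perturb(d: _Draft, rng, allow_attacks: bool = True) -> None:
    if allow_attacks and rng.random() < 0.5:
        d.attacks = int(rng.integers(6, 10))         # just below ten episodes
    else:
        d.duration = float(rng.uniform(10, 25))      # just under 30 minutes
        d.cap_frequency()


def _ch(d: _Draft, rng) -> None:
    d.attacks = int(rng.integers(20, 200))
    d.days = float(rng.uniform(8, 14))
    d.disease_months = float(rng.uniform(12, 120))
    d.duration = float(rng.uniform(15, 29))
    d.frequency = float(rng.uniform(1, 6))
    d.laterality = "unilateral"
    d.locations = {"orbital"} | ({"temporal"} if rng.random() < 0.5 else set())
    d.qualities = {"other"}
    d.vas = int(rng.integers(8, 11))
    d.autonomic = {"lacrimation", "conjunctival_injection"}
    d.autonomic_ipsilateral = True
    d.restlessness = rng.random() < 0.7
    d.cap_frequency()


def _ch_perturb(d: _Draft, rng) -> None:
    if rng.random() < 0.5:
        d.frequency = 0.3                            # below one every other day
    else:
        d.autonomic = set()
        d.autonomic_ipsilateral = False
        d.restlessness = False


def _ndph(d: _Draft, rng) -> None:
    d.daily_from_onset = True
    d.onset_remembered = True
    d.disease_months = float(rng.uniform(4, 36))
    d.days = float(rng.uniform(28, 31))
    d.migraine_days = 0.0
    d.attacks = int(30 * d.disease_months)
    d.duration = float(rng.uniform(10100, 20000))    # unremitting for days
    d.frequency = 0.03
    d.laterality = "unilateral"
    d.qualities = {"pulsating"}
    d.locations = {"whole_head"}
    d.vas = int(rng.integers(7, 10))
    d.aggravated = True
    d.photophobia = True
    d.cap_frequency()


def _ndph_perturb(d: _Draft, rng) -> None:
    if rng.random() < 0.5:
        d.onset_remembered = False
    else:
        d.disease_months = float(rng.uniform(1.5, 2.9))
        d.attacks = int(30 * d.disease_months)


def _moh(d: _Draft, rng) -> None:
    _cm(d, rng)  # chronic migraine-like background, by design
    cls = str(rng.choice(["triptan", "combination_analgesic", "nsaid",
                          "simple_analgesic"], p=[0.4, 0.3, 0.2, 0.1]))
    intake = (float(rng.uniform(10.5, 20))
              if cls in ("triptan", "combination_analgesic")
              else float(rng.uniform(15.5, 25)))
    d.medication = [MedicationUse(
        drug_class=cls, intake_days_per_month=intake,
        months_of_regular_use=float(rng.uniform(4, 48)))]


def _moh_perturb(d: _Draft, rng) -> None:
    if rng.random() < 0.5:
        med = d.medication[0]
        d.medication = [MedicationUse(
            drug_class=med.drug_class,
            intake_days_per_month=float(rng.uniform(5, 9)),
            months_of_regular_use=med.months_of_regular_use)]
    else:
        d.days = float(rng.uniform(12, 14))
        d.migraine_days = None


def _neuralgia(d: _Draft, rng) -> None:
    d.attacks = int(rng.integers(50, 500))
    d.days = float(rng.uniform(5, 14))
    d.duration = float(rng.uniform(0.2, 5))
    d.frequency = float(rng.uniform(3, 30))
    d.trigger_evoked = True
    d.laterality = "unilateral"
    d.locations = {"face"} | ({"temporal"} if rng.random() < 0.3 else set())
    d.qualities = {"stabbing"} | ({"electric_shock"} if rng.random() < 0.4 else set())
    d.vas = int(rng.integers(7, 10))
    d.cap_frequency()


def _neuralgia_perturb(d: _Draft, rng) -> None:
    if rng.random() < 0.5:
        d.trigger_evoked = False
    else:
        d.duration = float(rng.uniform(12, 25))
        d.cap_frequency()


def _pm(d: _Draft, rng) -> None:
    """Probable migraine: a migraine template with exactly one group missed."""
    _mo(d, rng)
    _mo_perturb(d, rng)


def _ptth(d: _Draft, rng) -> None:
    base = str(rng.choice(["iETTH", "fETTH", "CTTH"]))
    if base == "iETTH":
        _ietth(d, rng)
        _tth_perturb(d, rng)
    elif base == "fETTH":
        _fetth(d, rng)
        _tth_perturb(d, rng)
    else:
        _ctth(d, rng)
        _tth_perturb(d, rng, allow_attacks=False)
    # a one-sided presentation can leave the record one group short of
    # migraine as well; keep the tension-type side unambiguous
    d.laterality = "bilateral"


_TEMPLATES = {
    DiagnosisLabel.MO: (_mo, _mo_perturb),
    DiagnosisLabel.MA: (_ma, _ma_perturb),
    DiagnosisLabel.CM: (_cm, _cm_perturb),
    DiagnosisLabel.iETTH: (_ietth, _tth_perturb),
    DiagnosisLabel.fETTH: (_fetth, _tth_perturb),
    DiagnosisLabel.CTTH: (_ctth, lambda d, rng: _tth_perturb(d, rng, False)),
    DiagnosisLabel.CH: (_ch, _ch_perturb),
    DiagnosisLabel.NDPH: (_ndph, _ndph_perturb),
    DiagnosisLabel.MOH: (_moh, _moh_perturb),
    DiagnosisLabel.NEURALGIA: (_neuralgia, _neuralgia_perturb),
    DiagnosisLabel.PM: (_pm, None),
    DiagnosisLabel.PTTH: (_ptth, None),
}


def generate_patient(label: DiagnosisLabel, typicality: float = 1.0,
                     rng: np.random.Generator | None = None,
                     red_flag: bool = False) -> PatientRecord:
    """One synthetic record presenting as ``label``.

    At ``typicality=1`` the record is a textbook presentation recovered by
    the rule engine; at lower typicality one criterion group is perturbed
    with probability ``1 - typicality``. The probable categories are always
    borderline by construction. OTHERS has no template.
    """
    if label == DiagnosisLabel.OTHERS:
        raise ValueError("OTHERS has no generative template")
    rng = rng if rng is not None else np.random.default_rng(0)
    build, perturb = _TEMPLATES[label]
    d = _Draft(rng)
    build(d, rng)
    if perturb is not None and rng.random() > typicality:
        perturb(d, rng)
    if red_flag:
        flag = str(rng.choice(_INJECTABLE_FLAGS))
        d.flags.add(flag)
        if flag == "onset_after_50":
            d.age = int(rng.integers(52, 80))
            d.disease_months = float(min(d.disease_months, 24))
    return d.freeze()


def generate_cohort(cfg: GeneratorConfig,
                    ) -> tuple[list[PatientRecord], list[DiagnosisLabel]]:
    """n records with ground-truth labels drawn from the configured mix."""
    rng = np.random.default_rng(cfg.seed)
    labels_pool = list(cfg.label_mix)
    probs = np.array([cfg.label_mix[lbl] for lbl in labels_pool], dtype=float)
    probs /= probs.sum()
    idx = rng.choice(len(labels_pool), size=cfg.n, p=probs)
    records, truth = [], []
    for i in idx:
        label = labels_pool[int(i)]
        red = bool(rng.random() < cfg.red_flag_rate)
        records.append(generate_patient(label, cfg.typicality, rng, red_flag=red))
        truth.append(label)
    return records, truth


def generate_casebase(labels: set[DiagnosisLabel] | None = None,
                      n_per_label: int = 20,
                      schema: FeatureSchema | None = None,
                      seed: int = 0) -> CaseBase:
    """A labelled reference case base of borderline presentations."""
    labels = labels or {DiagnosisLabel.PM, DiagnosisLabel.PTTH}
    if DiagnosisLabel.OTHERS in labels:
        raise ValueError("OTHERS has no generative template")
    schema = schema or default_schema()
    rng = np.random.default_rng(seed)
    vectors, case_labels = [], []
    for label in sorted(labels, key=lambda lbl: lbl.value):
        for _ in range(n_per_label):
            record = generate_patient(label, typicality=0.3, rng=rng)
            vectors.append(featurize(record, schema))
            case_labels.append(label)
    return CaseBase(schema, vectors, case_labels)


def planted_casebase(n_cases: int = 100, n_noise: int = 19,
                     seed: int = 0) -> tuple[CaseBase, int]:
    """A case base whose first feature alone determines the label while the
    remaining features are label-independent binary noise; used to probe
    whether weight optimization concentrates mass on the informative
    feature. Under uniform weights the noise drowns the signal and
    leave-one-out accuracy sits well below one; a weight vector loaded onto
    the informative feature classifies perfectly.
    Returns (case base, index of the informative feature)."""
    rng = np.random.default_rng(seed)
    feats = [Feature(name="informative", kind="binary")]
    feats += [Feature(name=f"noise_{i}", kind="binary") for i in range(n_noise)]
    schema = FeatureSchema(tuple(feats))
    vectors, labels = [], []
    for i in range(n_cases):
        label = DiagnosisLabel.PM if i % 2 == 0 else DiagnosisLabel.PTTH
        vec = [1.0 if label == DiagnosisLabel.PM else 0.0]
        vec += [float(b) for b in rng.integers(0, 2, n_noise)]
        vectors.append(vec)
        labels.append(label)
    return CaseBase(schema, vectors, labels), 0


# ---------------------------------------------------------------------------
# questionnaire simulation
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return repr(float(x))


def _answer_map(record: PatientRecord) -> dict[str, object]:
    course, pain, attack = record.course, record.pain, record.attack
    assoc, aura, auto = record.associated, record.aura, record.autonomic
    rf = record.red_flags
    med = record.medication[0] if record.medication else None
    auto_features = [name for name in (
        "conjunctival_injection", "lacrimation", "nasal_congestion",
        "rhinorrhoea", "eyelid_oedema", "ptosis_miosis",
        "forehead_face_sweating") if getattr(auto, name)]
    answers: dict[str, object] = {
        "age": record.demographics.age,
        "sex": record.demographics.sex,
        "education": record.demographics.education,
        "occupation": record.demographics.occupation,
        "height": record.demographics.height_cm,
        "weight": record.demographics.weight_kg,
        "disease_duration": f"{_fmt(course.disease_duration_months)} months",
        "years_with_attacks": f"{_fmt(course.disease_duration_months)} months",
        "daily_from_onset": course.daily_from_onset,
        "onset_clearly_remembered": course.onset_clearly_remembered,
        "onset_abrupt": course.onset_abrupt,
        "headache_days_per_month": course.headache_days_per_month,
        "migraine_like_days_per_month": course.migraine_like_days_per_month,
        "lifetime_attack_count": course.lifetime_attack_count,
        "attack_duration": f"{_fmt(attack.duration_minutes_untreated)} minutes",
        "attacks_per_day": attack.frequency_per_day,
        "head_locations": ",".join(sorted(pain.locations)),
        "laterality": pain.laterality,
        "pain_qualities": ",".join(sorted(pain.qualities)),
        "vas": pain.vas,
        "aggravated_by_activity": assoc.aggravated_by_routine_activity,
        "nausea": assoc.nausea,
        "mild_nausea_only": assoc.mild_nausea_only,
        "vomiting": assoc.vomiting,
        "photophobia": assoc.photophobia,
        "phonophobia": assoc.phonophobia,
        "restlessness": assoc.restlessness_agitation,
        "aura_present": aura.present,
        "aura_symptoms": ",".join(sorted(aura.symptoms)),
        "aura_each_5_60": aura.each_symptom_5_to_60_min,
        "aura_gradual_spread": aura.gradual_spread_ge_5_min,
        "aura_headache_within_60": aura.headache_within_60_min,
        "autonomic_any": auto.any_feature,
        "autonomic_features": ",".join(auto_features),
        "autonomic_ipsilateral": auto.ipsilateral,
        "rf_fever": rf.systemic_symptoms_fever,
        "rf_neoplasm": rf.neoplasm_history,
        "rf_neuro_deficit": rf.neurologic_deficit,
        "rf_thunderclap": rf.sudden_abrupt_onset,
        "rf_onset_after_50": rf.onset_after_50,
        "rf_pattern_change": rf.pattern_change_or_new_headache,
        "rf_positional": rf.positional_headache,
        "rf_cough_exercise": rf.precipitated_by_cough_sneeze_exercise,
        "rf_progressive": rf.progressive_headache,
        "rf_eye_pain_autonomic": rf.eye_pain_autonomic_features,
        "rf_posttraumatic": rf.posttraumatic_onset,
        "trigger_evoked": attack.trigger_evoked,
        "common_triggers": "none",
        "family_history_headache": False,
        "comorbidity_present": False,
        "painkiller_use": med is not None,
        "painkiller_class": med.drug_class if med else None,
        "painkiller_days_per_month": med.intake_days_per_month if med else None,
        "painkiller_months": med.months_of_regular_use if med else None,
        "prior_imaging": "none",
        "psych_optin": record.psych.answered,
    }
    return answers


def simulate_session(record: PatientRecord,
                     bank: list[QuestionnaireItem] | None = None) -> Session:
    """Answer the questionnaire exactly as the record dictates.

    Compiling the resulting session reproduces the record on every field the
    questionnaire covers (round-trip identity). Raises when the interview
    reaches an item the record cannot answer.
    """
    bank = bank if bank is not None else default_bank()
    answers = _answer_map(record)
    session = Session.start()
    guard = 0
    while (item := next_item(session, bank)) is not None:
        guard += 1
        if guard > 10 * len(bank):
            raise RuntimeError("interview did not terminate")
        if item.item_id not in answers or answers[item.item_id] is None:
            raise ValueError(
                f"record does not cover questionnaire item {item.item_id!r}")
        record_answer(session, item, answers[item.item_id], bank)
        detect_inconsistencies(session)
    return session
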