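"""Hand-constructed clinical vignettes with hand-applied criterion labels.

Each vignette was labelled by walking the diagnostic criteria by hand,
independently of the rule engine; the suite doubles as the engine's oracle.
It covers at least two presentations per output category, the documented
chronic-migraine/medication-overuse overlap (which must resolve to MOH),
and one borderline presentation that is one criterion group short of both
migraine and tension-type headache and therefore goes to the case-based
differential.
"""

from __future__ import annotations

from .cbr import CaseBase, Feature, FeatureSchema
from .records import (
    Associated, Attack, Aura, Autonomic, Course, Demographics, DiagnosisLabel,
    MedicationUse, Pain, PatientRecord, Psych, RedFlagProfile,
)

__all__ = ["vignette_suite", "borderline_pm_ptth", "handcrafted_pm_ptth_casebase"]


def make_record(**kw) -> PatientRecord:
    """A complete record from flat keyword overrides (test/vignette helper)."""
    med = kw.get("medication", [])
    return PatientRecord(
        demographics=Demographics(
            age=kw.get("age", 35), sex=kw.get("sex", "female"),
            height_cm=165, weight_kg=60),
        course=Course(
            disease_duration_months=kw.get("months", 24),
            onset_abrupt=kw.get("onset_abrupt", False),
            daily_from_onset=kw.get("daily", False),
            onset_clearly_remembered=kw.get("remembered", False),
            headache_days_per_month=kw.get("days", 3),
            migraine_like_days_per_month=kw.get("migraine_days", None),
            lifetime_attack_count=kw.get("attacks", 10)),
        pain=Pain(
            locations=frozenset(kw.get("locations", {"temporal"})),
            laterality=kw.get("laterality", "unilateral"),
            qualities=frozenset(kw.get("qualities", {"pulsating"})),
            vas=kw.get("vas", 7)),
        attack=Attack(
            duration_minutes_untreated=kw.get("duration", 1440),
            frequency_per_day=kw.get("frequency", 0.1),
            trigger_evoked=kw.get("trigger_evoked", False)),
        associated=Associated(
            nausea=kw.get("nausea", False),
            vomiting=kw.get("vomiting", False),
            mild_nausea_only=kw.get("mild_nausea_only", False),
            photophobia=kw.get("photophobia", False),
            phonophobia=kw.get("phonophobia", False),
            aggravated_by_routine_activity=kw.get("aggravated", False),
            restlessness_agitation=kw.get("restlessness", False)),
        autonomic=Autonomic(
            lacrimation=kw.get("lacrimation", False),
            conjunctival_injection=kw.get("conjunctival", False),
            ipsilateral=kw.get("ipsilateral", False)),
        aura=Aura(
            present=kw.get("aura", False),
            symptoms=frozenset(kw.get("aura_symptoms", set())),
            each_symptom_5_to_60_min=kw.get("aura_5_60", False),
            gradual_spread_ge_5_min=kw.get("aura_gradual", False),
            headache_within_60_min=kw.get("aura_within_60", False)),
        medication=med,
        red_flags=RedFlagProfile(**kw.get("flags", {})),
        psych=Psych(answered=False),
    )


def borderline_pm_ptth() -> PatientRecord:
    """Severe 3-hour bilateral pulsating attacks with nausea: one group short
    of migraine (duration) and one short of frequent-episodic TTH
    (associated symptoms) -- the case-based differential."""
    return make_record(attacks=12, duration=180, vas=8, laterality="bilateral",
                       qualities={"pulsating"}, nausea=True, aggravated=False,
                       days=3, months=24)


def vignette_suite() -> list[tuple[str, PatientRecord, DiagnosisLabel]]:
    L = DiagnosisLabel
    suite: list[tuple[str, PatientRecord, DiagnosisLabel]] = []

    # --- migraine without aura ---------------------------------------------
    suite.append(("mo_textbook", make_record(
        attacks=10, duration=1440, laterality="unilateral",
        qualities={"pulsating"}, vas=7, nausea=True, aggravated=True,
        days=2), L.MO))
    suite.append(("mo_photophobic", make_record(
        attacks=8, duration=600, laterality="bilateral",
        qualities={"pulsating"}, vas=8, aggravated=True,
        photophobia=True, phonophobia=True, days=4), L.MO))

    # --- migraine with aura ------------------------------------------------
    suite.append(("ma_visual", make_record(
        attacks=4, duration=720, vas=6, nausea=True, aggravated=True,
        aura=True, aura_symptoms={"visual"}, aura_5_60=True,
        aura_gradual=True, aura_within_60=True, days=2), L.MA))
    suite.append(("ma_sensory", make_record(
        attacks=3, duration=300, vas=5, photophobia=True, phonophobia=True,
        aura=True, aura_symptoms={"visual", "sensory"}, aura_within_60=True,
        days=1), L.MA))

    # --- probable migraine (exactly one migraine group missed) -------------
    suite.append(("pm_short_attacks", make_record(
        attacks=10, duration=120, laterality="unilateral",
        qualities={"pulsating"}, vas=7, nausea=True, aggravated=True,
        days=2), L.PM))
    suite.append(("pm_few_attacks", make_record(
        attacks=4, duration=1440, laterality="unilateral",
        qualities={"pulsating"}, vas=7, nausea=True, aggravated=True,
        days=2), L.PM))

    # --- chronic migraine ---------------------------------------------------
    suite.append(("cm_textbook", make_record(
        attacks=8, duration=5000, days=20, migraine_days=10, months=12,
        vas=8, nausea=True, aggravated=True), L.CM))
    suite.append(("cm_borderline_days", make_record(
        attacks=9, duration=4800, days=15, migraine_days=8, months=4,
        vas=7, nausea=True, aggravated=True), L.CM))

    # --- episodic/chronic tension-type -------------------------------------
    suite.append(("ietth_textbook", make_record(
        attacks=15, duration=240, days=0.5, laterality="bilateral",
        qualities={"pressing_tightening"}, vas=4), L.iETTH))
    suite.append(("ietth_photophobic", make_record(
        attacks=12, duration=120, days=0.8, laterality="bilateral",
        qualities={"pressing_tightening"}, vas=3, photophobia=True), L.iETTH))
    suite.append(("fetth_textbook", make_record(
        attacks=30, duration=300, days=6, months=24, laterality="bilateral",
        qualities={"pressing_tightening"}, vas=5), L.fETTH))
    suite.append(("fetth_unilateral", make_record(
        attacks=20, duration=480, days=10, months=12,
        laterality="unilateral", qualities={"pressing_tightening"},
        vas=3), L.fETTH))
    suite.append(("ctth_textbook", make_record(
        attacks=100, duration=600, days=22, migraine_days=0, months=36,
        laterality="bilateral", qualities={"pressing_tightening"},
        vas=4), L.CTTH))
    suite.append(("ctth_mild_nausea", make_record(
        attacks=80, duration=480, days=18, migraine_days=0, months=12,
        laterality="bilateral", qualities={"pressing_tightening"}, vas=5,
        nausea=True, mild_nausea_only=True), L.CTTH))

    # --- probable tension-type (one TTH group missed) ----------------------
    suite.append(("ptth_too_short", make_record(
        attacks=30, duration=20, days=6, months=24, laterality="bilateral",
        qualities={"pressing_tightening"}, vas=4), L.PTTH))
    suite.append(("ptth_few_episodes", make_record(
        attacks=8, duration=240, days=6, months=24, laterality="bilateral",
        qualities={"pressing_tightening"}, vas=4), L.PTTH))

    # --- cluster headache ---------------------------------------------------
    suite.append(("ch_textbook", make_record(
        attacks=40, duration=45, frequency=2, days=10, months=24,
        laterality="unilateral", locations={"orbital"}, qualities={"other"},
        vas=9, lacrimation=True, conjunctival=True, ipsilateral=True,
        restlessness=True), L.CH))
    suite.append(("ch_restless_only", make_record(
        attacks=20, duration=90, frequency=1, days=8, months=12,
        laterality="unilateral", locations={"supraorbital", "temporal"},
        qualities={"other"}, vas=8, restlessness=True), L.CH))

    # --- new daily persistent headache --------------------------------------
    suite.append(("ndph_textbook", make_record(
        daily=True, remembered=True, months=6, days=30, migraine_days=0,
        duration=20000, frequency=0.03, laterality="unilateral",
        qualities={"pulsating"}, vas=7, aggravated=True,
        photophobia=True, attacks=180), L.NDPH))
    suite.append(("ndph_pressing", make_record(
        daily=True, remembered=True, months=5, days=29, migraine_days=0,
        duration=15000, frequency=0.03, laterality="unilateral",
        qualities={"pulsating"}, vas=8, aggravated=True, attacks=150), L.NDPH))

    # --- medication-overuse headache (also meets chronic migraine) ---------
    suite.append(("moh_triptan_over_cm", make_record(
        attacks=9, duration=5000, days=20, migraine_days=9, months=6,
        vas=8, nausea=True, aggravated=True,
        medication=[MedicationUse(drug_class="triptan",
                                  intake_days_per_month=12,
                                  months_of_regular_use=4)]), L.MOH))
    suite.append(("moh_simple_analgesic", make_record(
        attacks=8, duration=4800, days=25, migraine_days=10, months=24,
        vas=7, nausea=True, aggravated=True,
        medication=[MedicationUse(drug_class="simple_analgesic",
                                  intake_days_per_month=20,
                                  months_of_regular_use=12)]), L.MOH))

    # --- neuralgia (screen-level) -------------------------------------------
    suite.append(("neuralgia_trigeminal", make_record(
        attacks=200, duration=0.5, frequency=10, days=10, months=12,
        laterality="unilateral", locations={"face"}, qualities={"stabbing"},
        vas=9, trigger_evoked=True), L.NEURALGIA))
    suite.append(("neuralgia_electric", make_record(
        attacks=100, duration=2, frequency=5, days=8, months=6,
        laterality="unilateral", locations={"face", "temporal"},
        qualities={"electric_shock"}, vas=8, trigger_evoked=True), L.NEURALGIA))

    # --- unclassifiable -----------------------------------------------------
    suite.append(("others_untriggered_stabs", make_record(
        attacks=100, duration=3, frequency=5, days=8, months=6,
        laterality="unilateral", locations={"face"}, qualities={"stabbing"},
        vas=8, trigger_evoked=False), L.OTHERS))
    suite.append(("others_vomiting_brief", make_record(
        attacks=5, duration=45, days=2, months=12, laterality="bilateral",
        qualities={"other"}, vas=5, vomiting=True, nausea=True), L.OTHERS))

    # --- the borderline differential (settled by CBR as probable migraine
    # --- against the handcrafted case base below) ---------------------------
    suite.append(("borderline_pm_vs_ptth", borderline_pm_ptth(), L.PM))
    return suite


def handcrafted_pm_ptth_casebase() -> CaseBase:
    """Six hand-placed reference cases on a three-feature schema; similarity
    tables are small enough to verify by hand. The borderline vignette's
    nearest case is probable migraine."""
    schema = FeatureSchema((
        Feature(name="vas", kind="numeric", range=(1, 10)),
        Feature(name="pulsating", kind="binary"),
        Feature(name="nausea", kind="binary"),
    ))
    pm, ptth = DiagnosisLabel.PM, DiagnosisLabel.PTTH
    cases = [
        ([7 / 9, 1.0, 1.0], pm),    # severe pulsating with nausea
        ([8 / 9, 1.0, 0.0], pm),
        ([6 / 9, 0.0, 1.0], pm),
        ([2 / 9, 0.0, 0.0], ptth),  # mild pressing, no nausea
        ([3 / 9, 0.0, 0.0], ptth),
        ([4 / 9, 1.0, 0.0], ptth),
    ]
    return CaseBase(schema, [c[0] for c in cases], [c[1] for c in cases])
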