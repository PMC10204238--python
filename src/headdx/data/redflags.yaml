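# Warning text and severity per red-flag item. Severity is either
# "urgent" (immediate secondary work-up) or "advisory".
systemic_symptoms_fever:
  severity: urgent
  message: Fever or other systemic symptoms accompany the headache.
neoplasm_history:
  severity: advisory
  message: History of neoplasm; metastatic or paraneoplastic causes should be excluded.
neurologic_deficit:
  severity: urgent
  message: Neurological deficit or altered consciousness reported.
sudden_abrupt_onset:
  severity: urgent
  message: Sudden or abrupt (thunderclap) onset.
onset_after_50:
  severity: advisory
  message: New headache beginning after age 50.
pattern_change_or_new_headache:
  severity: advisory
  message: Change of the established pattern, or a recent new headache.
positional_headache:
  severity: advisory
  message: Headache changes with posture.
precipitated_by_cough_sneeze_exercise:
  severity: advisory
  message: Headache precipitated by coughing, sneezing or exercise.
progressive_headache:
  severity: advisory
  message: Progressively worsening headache.
eye_pain_autonomic_features:
  severity: advisory
  message: Eye pain with autonomic features.
posttraumatic_onset:
  severity: advisory
  message: Onset after head trauma.
painkiller_overuse_flag:
  severity: advisory
  message: Frequent acute-painkiller use; medication overuse possible.
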