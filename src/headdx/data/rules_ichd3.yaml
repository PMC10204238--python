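# Diagnostic criteria for the encoded headache categories, one document for
# the whole rule set. Criterion-group predicates use the expression grammar
# documented in headdx.rules (comparisons, and/or/not, set membership,
# count(...) of truthy clauses) over the flattened patient-record context.
#
# Severity convention on the 1-10 pain scale: mild 1-3, moderate 4-6,
# severe 7-10; "moderate or severe" is vas >= 4, "mild or moderate" vas <= 6.
#
# The precedence list resolves co-occurring fully-met diagnoses: medication-
# overuse headache first (it outranks chronic migraine by design), then
# chronic before episodic forms, definite before probable.
priority: [MOH, CM, CTTH, MO, MA, CH, NDPH, fETTH, iETTH, NEURALGIA, PM, PTTH, OTHERS]

diagnoses:
  MO:
    A:
      expr: attack_count >= 5
      description: at least five attacks fulfilling the remaining groups
    B:
      expr: 240 <= duration_minutes <= 4320
      description: attacks last 4-72 h untreated
    C:
      expr: count(unilateral, pulsating, vas >= 4, aggravated) >= 2
      description: >-
        at least two of: unilateral, pulsating, moderate-severe intensity,
        aggravated by routine physical activity
    D:
      expr: nausea or vomiting or (photophobia and phonophobia)
      description: nausea and/or vomiting, or photophobia and phonophobia

  MA:
    A:
      expr: attack_count >= 2 and aura_present
      description: at least two attacks with aura
    B:
      expr: aura_symptom_count >= 1
      description: fully reversible visual, sensory and/or speech aura symptoms
    C:
      expr: count(aura_gradual_spread, aura_duration_5_60, aura_headache_within_60) >= 1
      description: >-
        at least one of: gradual spread over >=5 min, symptom duration
        5-60 min, headache within 60 min of the aura
        (simplified characteristic set)

  CM:
    A:
      expr: headache_days_per_month >= 15
      description: headache on at least 15 days/month
    B:
      expr: disease_duration_months > 3
      description: for more than 3 months
    C:
      expr: migraine_like_days_per_month >= 8
      description: migraine-like features on at least 8 days/month

  iETTH:
    A:
      expr: attack_count >= 10 and headache_days_per_month < 1
      description: at least 10 episodes, on average <1 day/month
    B:
      expr: 30 <= duration_minutes <= 10080
      description: lasting 30 minutes to 7 days
    C:
      expr: count(bilateral, pressing_tightening, vas <= 6, not aggravated) >= 2
      description: >-
        at least two of: bilateral, pressing/tightening, mild-moderate
        intensity, not aggravated by routine activity
    D:
      expr: not nausea and not vomiting and count(photophobia, phonophobia) <= 1
      description: no nausea or vomiting, at most one of photo-/phonophobia

  fETTH:
    A:
      expr: attack_count >= 10 and 1 <= headache_days_per_month <= 14 and disease_duration_months > 3
      description: at least 10 episodes on 1-14 days/month for >3 months
    B:
      expr: 30 <= duration_minutes <= 10080
      description: lasting 30 minutes to 7 days
    C:
      expr: count(bilateral, pressing_tightening, vas <= 6, not aggravated) >= 2
      description: >-
        at least two of: bilateral, pressing/tightening, mild-moderate
        intensity, not aggravated by routine activity
    D:
      expr: not nausea and not vomiting and count(photophobia, phonophobia) <= 1
      description: no nausea or vomiting, at most one of photo-/phonophobia

  CTTH:
    A:
      expr: headache_days_per_month >= 15 and disease_duration_months > 3
      description: headache on >=15 days/month for more than 3 months
    B:
      expr: duration_minutes >= 30
      description: lasting hours to days, or unremitting
    C:
      expr: count(bilateral, pressing_tightening, vas <= 6, not aggravated) >= 2
      description: >-
        at least two of: bilateral, pressing/tightening, mild-moderate
        intensity, not aggravated by routine activity
    D:
      expr: not vomiting and (not nausea or mild_nausea_only) and count(photophobia, phonophobia, mild_nausea_only) <= 1
      description: >-
        no more than one of photophobia, phonophobia or mild nausea;
        neither moderate/severe nausea nor vomiting

  CH:
    A:
      expr: attack_count >= 5
      description: at least five attacks
    B:
      expr: unilateral and vas >= 7 and orbital_temporal_pain and 15 <= duration_minutes <= 180
      description: >-
        severe unilateral orbital, supraorbital and/or temporal pain lasting
        15-180 minutes untreated
    C:
      expr: (autonomic_any and autonomic_ipsilateral) or restlessness
      description: >-
        ipsilateral cranial autonomic features and/or restlessness or
        agitation
    D:
      expr: 0.5 <= frequency_per_day <= 8
      description: frequency between one every other day and eight per day

  NDPH:
    A:
      expr: daily_from_onset and onset_clearly_remembered
      description: daily and unremitting from a distinctly remembered onset
    B:
      expr: disease_duration_months > 3
      description: present for more than 3 months

  MOH:
    A:
      expr: headache_days_per_month >= 15
      description: headache on at least 15 days/month
    B:
      expr: overuse_short_acting or overuse_simple
      description: >-
        regular overuse for >3 months of acute medication (>=10 days/month
        for triptans/ergots/opioids/combination analgesics, >=15 days/month
        for simple analgesics/NSAIDs)

  NEURALGIA:
    A:
      expr: stabbing_or_electric
      description: stabbing or electric-shock-like pain (screen-level rule)
    B:
      expr: duration_minutes <= 10
      description: paroxysms lasting seconds to a few minutes
    C:
      expr: trigger_evoked
      description: attacks precipitated by innocuous stimuli
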