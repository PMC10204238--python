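# Methods

This note documents the models, defaults, and numerical choices behind
`headdx`, and what its synthetic tests do and do not establish about real
clinical data.

## Diagnostic model

The engine assigns exactly one label per record from
{MO, MA, PM, CM, iETTH, fETTH, PTTH, CTTH, CH, NDPH, MOH, NEURALGIA,
OTHERS}. Diagnosis is two-staged:

1. **Rules.** Each definite category carries named criterion groups
   (A, B, C, …) expressed in a restricted boolean grammar (comparisons,
   and/or/not, set membership, `count(...)` of truthy clauses) over a
   flattened record context. The shipped rule file is a transcription of
   the standard classification criteria with three documented
   simplifications:
   * the migraine-with-aura C-group is reduced to "≥1 of {gradual spread
     ≥5 min, symptom duration 5–60 min, headache within 60 min}" because
     the questionnaire does not elicit all six canonical aura
     characteristics;
   * neuralgia is a screen-level rule (stabbing/electric quality,
     paroxysms ≤10 min, innocuous-stimulus triggering) — its clinical role
     here is flagging, not subtype diagnosis;
   * chronic TTH accepts mild nausea within its at-most-one-of group.
   Pain intensity on the 1–10 scale is banded mild 1–3 / moderate 4–6 /
   severe 7–10, so "moderate or severe" is VAS ≥ 4. "More than 3 months"
   is `disease_duration_months > 3`, strictly.
2. **Probable logic and CBR.** With no fully-met diagnosis, a migraine
   category missing exactly one group yields PM, a tension-type subtype
   missing exactly one yields PTTH. When both hold, the record is the
   classic borderline presentation (e.g. severe 3-hour bilateral pulsating
   attacks with nausea) and is classified by 1-nearest-neighbour over a
   labelled case base restricted to PM/PTTH cases. Similarity is a
   weighted Gower mean: numeric features are min–max scaled to [0, 1] and
   compared as `1 − |x−y|`, binary likewise, categorical by equality.

**Precedence.** Fully-met candidates are collapsed with the configurable
order `MOH > CM > CTTH > MO > MA > CH > NDPH > fETTH > iETTH > NEURALGIA >
PM > PTTH > OTHERS` — medication overuse first (its management differs and
it co-occurs with chronic migraine by construction), then chronic before
episodic, definite before probable. Only the MOH > CM edge is clinically
mandated; the rest of the order is a design choice isolated in the rule
file so it can be edited without code changes.

**Missing data.** A criterion group whose predicate touches an unanswered
field is *not assessable* and counts as failed. Incomplete records can
therefore reach at most a probable label or OTHERS, never a definite
diagnosis — the conservative direction.

## Red-flag screening

One warning per positive profile field, in fixed field order; severities
(three urgent: thunderclap onset, neurologic deficit, fever/systemic
symptoms; the rest advisory) live in an editable YAML map. Screening
errors out on an absent profile rather than passing silently, and warnings
annotate rather than veto: the secondary-headache decision belongs to the
physician.

## Questionnaire engine

Branching is a conjunction of clauses over prior answers; the shipped bank
(72 items) covers every field the rule set consumes, with the default
branches: aura details only after reported aura, medication-overuse
details only after reported painkiller use, cranial autonomic details only
for short (≤180 min) unilateral attacks, migraine-like day counts only for
frequent (≥15 days/month) headache, and an optional mood section (PHQ-9,
GAD-7; sum-scored with the standard cut points). Durations accept free
number+unit entry against a synonym table; unknown units are rejected,
never guessed. The exact wording and branching graph of the original
instrument are unpublished; this bank is a reconstruction and is flagged
as such in its header.

Consistency checks shipped by default: attack history longer than disease
duration; >31 headache days/month; per-attack duration × attacks/day
exceeding 24 h/day (which would imply more than a full month of headache
days). Violated checks re-ask their items (last-write-wins); a second
violation of the same check marks the session contradictory, mirroring the
exclusion of irreconcilable records from a validation cohort. Completion
time is recorded but never used in logic.

## GA feature weighting

Chromosomes are non-negative weight vectors renormalized to sum 1 after
every operator. Defaults: population 50, 100 generations, tournament size
3, uniform crossover at rate 0.8, Gaussian mutation (per-gene rate 0.05,
σ = 0.1, clipped at 0), elitism 1, mandatory seed. Fitness is leave-one-out
1-NN accuracy on the case base. Because many weight vectors can classify a
small base perfectly, equal-accuracy chromosomes are ranked by the mean
leave-one-out similarity margin (nearest same-label minus nearest
other-label case); the margin enters tournament selection only as a bonus
of 10⁻³ × margin, below one accuracy quantum, so accuracy always
dominates. This makes the returned optimum well-defined and concentrates
weight on genuinely informative features instead of halting on the first
perfect-but-diffuse chromosome.

The weight-recovery probe (`planted_casebase`) uses 100 cases with one
label-determining binary feature and 19 binary noise features — sized so
that uniform weights sit in the noise-dominated regime (leave-one-out
accuracy ≈ 0.75–0.8) and recovering the planted feature is informative.

## Synthetic cohorts

Each label has a generative template whose field distributions sit
centrally inside that label's criterion windows (e.g. migraine: untreated
duration uniform on ~5–67 h, VAS 4–10, unilateral with probability 0.7,
nausea 0.8). Two structural choices matter:

* At typicality 1, a record fully satisfies its own label and misses ≥1
  group of every other definite label, with the single documented
  exception that MOH records also satisfy the CM groups (that overlap is
  what the precedence rule exists for). The closure property — rule
  diagnosis recovers the generating label for 100% of textbook records —
  is asserted over 3 × 500-record seeded cohorts.
* Migraine-template attack counts are drawn in 6–9: episodic TTH requires
  ≥10 episodes, so every single-group perturbation of a migraine record
  stays strictly on the probable-migraine side instead of drifting into an
  ambiguous PM/PTTH overlap. Perturbations move exactly one group just
  outside its threshold (attacks → 3–4, duration → 2.5–3.8 h, or all
  associated symptoms off), and analogous menus exist per label.

The default cohort mix follows the expert reference distribution of a
531-patient outpatient validation cohort with the residual category
removed and renormalized. Red-flag injection sets one random alarm flag
per selected record (and raises age past 50 when the late-onset flag is
drawn).

What the generator does **not** model: covariate structure (age/education
effects on completion time), inter-site heterogeneity, free-text noise,
patient misunderstanding of questions, and secondary-headache phenotypes
beyond the alarm flags. Passing closure and round-trip tests therefore
demonstrates internal consistency of the pipeline, not field accuracy on
real patients.

## Evaluation layer

Per-class indices come from the one-vs-rest collapse of the 13-class
agreement table (rows = system, columns = reference): sensitivity
tp/(tp+fn), specificity tn/(tn+fp), PPV, NPV, Youden = sens + spec − 1,
and binary Cohen's κ with p_o = (tp+tn)/n and
p_e = ((tp+fn)(tp+fp) + (fn+tn)(fp+tn))/n². Two rate conventions are
emitted side by side: `fnr_paper = 1 − NPV` and `fpr_paper = 1 − PPV`
reproduce the convention used in the published accuracy tables this
package re-derives, while `fnr_standard = 1 − sensitivity` and
`fpr_standard = 1 − specificity` are the textbook complements. Proportion
intervals are Clopper–Pearson by default (Wilson available); the κ
interval is the asymptotic normal one, `se = sqrt(p_o(1−p_o)/n)/(1−p_e)`.
Empty-denominator cells are reported as undefined-with-reason, never NaN.

The two packaged agreement matrices have exact row/column marginals and
diagonal cells (verified on every load against embedded integrity
constants); their off-diagonal cells are a constrained reconstruction —
the published grids are typographically damaged — and are flagged as such
in the fixture metadata. Every published per-class index is a function of
marginals and diagonals only, so the reconstruction cannot affect any
reported statistic; cell-level tests are restricted to diagonals and
marginals accordingly.

## Problem sizes and determinism

Default verification sizes: 27 hand-labelled vignettes; 3 × 500 synthetic
records for closure; 100 records for red-flag coverage; 20 seeded planted
case bases for the GA properties. Every stochastic entry point takes an
explicit seed and is reproducible bit-for-bit; `scripts/acceptance.py`
derives all internal seeds from its single `--seed` argument.

## Known limitations

* The rule file is a faithful criteria transcription, not a byte-level
  clone of any deployed system; thresholds live in YAML precisely so they
  can be audited and edited.
* CBR triggers only for the PM/PTTH differential by default; the shipped
  case bases are synthetic stand-ins (no clinical case base is published).
* Secondary headaches are flagged, never differentially diagnosed; imaging
  and examination findings are out of scope.
* Only two raters are supported in the agreement statistics; κ is
  per-class one-vs-rest, not multi-class weighted κ.
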