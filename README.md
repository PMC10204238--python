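# headdx

Decision support for diagnosing headache disorders from a structured,
patient-answered history. The package is aimed at clinical-informatics
researchers who want a transparent, fully inspectable reference
implementation of a guideline-plus-case-based headache diagnosis pipeline,
together with the biostatistics needed to evaluate it against expert
diagnoses.

## What it does

1. **Conversational intake** (`headdx.questionnaire`): an editable YAML item
   bank over seven themes (demographics, headache characteristics, red
   flags, triggers, family history, comorbidities, medical history, plus an
   optional mood section) with answer-dependent branching, free
   number-plus-unit duration entry ("45 minutes", "2 h"), a 1–10 visual
   analog pain scale, and body-map locations. Inconsistent answer pairs
   (e.g. an attack history longer than the disease itself, or more than 31
   headache days in a month) are detected automatically and re-asked; a
   second violation of the same check marks the interview contradictory and
   it is rejected.
2. **Red-flag screening** (`headdx.redflags`): an SNNOOP10-style alarm
   profile (fever/systemic symptoms, neoplasm history, neurologic deficit,
   thunderclap onset, onset after 50, pattern change, positional or
   cough/exercise-provoked headache, progressive course, eye pain with
   autonomic features, post-traumatic onset, analgesic overuse) emits one
   warning per positive flag. Warnings annotate the diagnosis as *pending
   secondary exclusion*; they never suppress it.
3. **Rule-based diagnosis** (`headdx.rules`): declarative criterion groups
   for 10 definite categories — migraine without/with aura (MO/MA), chronic
   migraine (CM), infrequent/frequent episodic and chronic tension-type
   headache (iETTH/fETTH/CTTH), cluster headache (CH), new daily persistent
   headache (NDPH), medication-overuse headache (MOH), and a screen-level
   neuralgia rule — written in a small audited expression grammar over the
   patient record. A record fully meeting one set of criteria gets that
   label; co-occurring candidates are resolved by a configurable precedence
   in which **MOH outranks CM**. A record one criterion group short of
   migraine (or of a tension-type subtype) becomes *probable migraine* (PM)
   or *probable TTH* (PTTH).
4. **Case-based reasoning** (`headdx.cbr`): when a record is one group short
   of *both* sides, the PM-vs-PTTH differential is settled by the nearest
   case in a labelled case base under weighted Gower similarity
   `sim(x,y) = Σᵢ wᵢ sᵢ(xᵢ,yᵢ)`, with the weights fitted by a genetic
   algorithm whose fitness is leave-one-out 1-NN accuracy.
5. **Evaluation** (`headdx.evaluation`): multi-class agreement tables,
   one-vs-rest sensitivity, specificity, PPV, NPV, Youden index, exact
   binomial confidence intervals, and per-class Cohen's κ
   `(p_o − p_e)/(1 − p_e)`. Two published 531-patient agreement matrices
   (system vs two expert references) ship as fixtures with exact marginals
   and diagonals.
6. **Synthetic cohorts** (`headdx.cohort`): label-conditional generators for
   every category, with a typicality dial that nudges single criterion
   groups just outside their windows to produce borderline "probable"
   presentations, red-flag injection, and a questionnaire simulator whose
   sessions compile back to the generating record exactly.

## Worked example

```python
import numpy as np
from headdx import DiagnosisLabel, generate_patient, hybrid_diagnose

rng = np.random.default_rng(42)
record = generate_patient(DiagnosisLabel.MOH, typicality=1.0, rng=rng)
result = hybrid_diagnose(record)

print("label:", result.label.value, "| method:", result.method,
      "| pending secondary exclusion:", result.pending_secondary_exclusion)
print("warnings:", [w.flag_id for w in result.warnings])
by = {e.diagnosis.value: sorted(e.groups_failed) for e in result.trace}
print("CM groups failed:", by["CM"], "| MOH groups failed:", by["MOH"])
```

prints

```
label: MOH | method: rule | pending secondary exclusion: True
warnings: ['painkiller_overuse_flag']
CM groups failed: [] | MOH groups failed: []
```

The synthetic patient has ≥15 headache days/month with ≥8 migraine-like
days (all chronic-migraine groups met, `CM` fails nothing) *and* has been
taking a triptan on ≥10 days/month for more than 3 months (all `MOH`
groups met). Both diagnoses apply; the precedence rule gives the final
single label MOH, and the analgesic-overuse red flag annotates the result
as pending exclusion of a secondary cause.

On the command line the same pipeline looks like:

```bash
headdx simulate --n 100 --seed 1 --out-dir cohort/   # records + truth labels
headdx diagnose record.json --out result.json
headdx evaluate --fixture table2_comparisonA          # per-class indices
headdx reproduce-tables                               # both comparisons at once
```

`headdx evaluate --fixture table2_comparisonA` prints, among others,
MO sensitivity 0.8915, specificity 0.9975, κ 0.920, and the grouped
recognition rates `migraine group: 234/266 (87.97%)` and
`tension_type group: 123/141 (87.23%)`.

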