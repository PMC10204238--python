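# Default feature schema for the case-based reasoning stage. Feature names
# resolve against the flattened record context of headdx.rules (plus
# "laterality", kept categorical). Numeric ranges are the min-max scaling
# bounds; values outside are clipped.
features:
  - name: vas
    kind: numeric
    range: [1, 10]
  - name: duration_minutes
    kind: numeric
    range: [5, 10080]
  - name: headache_days_per_month
    kind: numeric
    range: [0, 31]
  - name: attack_count
    kind: numeric
    range: [0, 200]
  - name: laterality
    kind: categorical
    categories: [unilateral, bilateral, variable]
  - name: pulsating
    kind: binary
  - name: pressing_tightening
    kind: binary
  - name: aggravated
    kind: binary
  - name: nausea
    kind: binary
  - name: vomiting
    kind: binary
  - name: photophobia
    kind: binary
  - name: phonophobia
    kind: binary
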