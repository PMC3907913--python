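# Default evidence-combination table for variant classification.
#
# Ordered, first match wins; the final empty-when rule is the required
# catch-all. Classes: Neutral < UV1 < UV2 < UV3 < UV4 < Pathogenic.
#
# Numeric thresholds (configurable by editing a copy of this file):
#   control_af > 0.01        -> "common" in controls/public databases
#   missense_score >= 0.8    -> damaging in silico missense prediction
#   splice_delta >= 0.8      -> strong predicted splice-site disruption
#   scores in [0.5, 0.8)     -> mildly suggestive single line of evidence
rules:
  - name: ptc
    when:
      ptc: {eq: true}
    class: Pathogenic

  - name: minigene-deleterious
    when:
      minigene_result: {eq: deleterious}
    class: UV4

  - name: strong-splice-disruption
    when:
      splice_delta: {ge: 0.8}
      control_af: {le: 0.01, allow_unknown: true}
    class: UV4

  - name: common-with-benign-predictions
    when:
      control_af: {gt: 0.01}
      missense_score: {lt: 0.5, allow_unknown: true}
      splice_delta: {lt: 0.5, allow_unknown: true}
    class: Neutral

  - name: rare-damaging-missense
    when:
      missense_score: {ge: 0.8}
      control_af: {le: 0.01, allow_unknown: true}
    class: UV3

  - name: moderate-missense
    when:
      missense_score: {ge: 0.5}
    class: UV2

  - name: moderate-splice
    when:
      splice_delta: {ge: 0.5}
    class: UV2

  - name: rare-benign-predictions
    when:
      control_af: {le: 0.01, allow_unknown: true}
      missense_score: {lt: 0.5, allow_unknown: true}
      splice_delta: {lt: 0.5, allow_unknown: true}
    class: UV1

  - name: default
    when: {}
    class: UV2
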