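# DEMONSTRATION wear-stage map.
#
# This is NOT a published eruption/wear scoring scheme: it is a compact
# fixture alphabet whose admissible runs exercise every code path
# (single-class stages, two-class spans for every class, one three-class
# span).  Replace it with a transcription of the real scoring table when
# analysing archaeological material.
#
# Schema: one entry per (tooth, stage); `classes` is the contiguous run
# of admissible age-class labels, in scheme order.
entries:
  - {tooth: dP4, stage: A,  classes: ["0-6m"]}
  - {tooth: dP4, stage: B,  classes: ["6-15m"]}
  - {tooth: dP4, stage: AB, classes: ["0-6m", "6-15m"]}
  - {tooth: dP4, stage: BC, classes: ["6-15m", "15-26m"]}
  - {tooth: M1,  stage: C,  classes: ["15-26m"]}
  - {tooth: M1,  stage: D,  classes: ["26-36m"]}
  - {tooth: M1,  stage: CD, classes: ["15-26m", "26-36m"]}
  - {tooth: M2,  stage: E,  classes: ["3-6y"]}
  - {tooth: M2,  stage: DE, classes: ["26-36m", "3-6y"]}
  - {tooth: M2,  stage: EF, classes: ["3-6y", "6-8y"]}
  - {tooth: M2,  stage: DEF, classes: ["26-36m", "3-6y", "6-8y"]}
  - {tooth: M3,  stage: F,  classes: ["6-8y"]}
  - {tooth: M3,  stage: G,  classes: [">8y"]}
  - {tooth: M3,  stage: FG, classes: ["6-8y", ">8y"]}
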