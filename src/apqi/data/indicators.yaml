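# Default disease-specific antibiotic prescribing quality indicator (APQI)
# configuration: nine indications, each with its eligibility window, the
# guideline-recommended antibiotic set (ATC prefixes, Belgian first-choice
# guidance) and acceptable ranges in percent for
#   a = % of eligible patients prescribed an antibiotic
#   b = % of antibiotic-treated patients receiving a recommended antibiotic
#   c = % of antibiotic-treated patients receiving a quinolone
# Age bounds are inclusive completed years ("older than two years" -> min_age 2).
# Every field here is data: copy this file and edit to use local guidance.
indicators:
  - icpc: H71
    label: Acute otitis media
    min_age: 2
    recommended: [J01CA04]        # amoxicillin
    range_a: [0, 20]
    range_b: [80, 100]
    range_c: [0, 5]
  - icpc: R74
    label: Acute upper respiratory tract infection
    min_age: 1
    recommended: [J01CE]          # narrow-spectrum (phenoxymethyl)penicillin
    range_a: [0, 20]
    range_b: [80, 100]
    range_c: [0, 5]
  - icpc: R75
    label: Acute/chronic sinusitis
    min_age: 18
    recommended: [J01CA04]
    range_a: [0, 20]
    range_b: [80, 100]
    range_c: [0, 5]
  - icpc: R76
    label: Acute tonsillitis
    min_age: 1
    recommended: [J01CE]
    range_a: [0, 20]
    range_b: [80, 100]
    range_c: [0, 5]
  - icpc: R78
    label: Acute bronchitis/bronchiolitis
    min_age: 18
    max_age: 75
    recommended: [J01CA04]
    range_a: [0, 30]
    range_b: [80, 100]
    range_c: [0, 5]
  - icpc: R81
    label: Pneumonia
    min_age: 18
    max_age: 65
    recommended: [J01CA04]
    range_a: [80, 100]
    range_b: [80, 100]
    range_c: [0, 5]
  - icpc: U71
    label: Cystitis/other urinary infection
    min_age: 18
    sex: F
    recommended: [J01XE]          # nitrofurantoin derivatives
    range_a: [80, 100]
    range_b: [80, 100]
    range_c: [0, 5]
  - icpc: S76
    label: Erysipelas
    min_age: 1
    recommended: [J01CF]          # isoxazolyl penicillins (flucloxacillin)
    range_a: [80, 100]
    range_b: [80, 100]
    range_c: [0, 5]
    proposed: true
  - icpc: D82
    label: Teeth/gum disease
    min_age: 18
    recommended: [J01CA04]
    range_a: [0, 30]
    range_b: [80, 100]
    range_c: [0, 5]
    proposed: true
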