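# Default clinical-scale definitions: score ranges, severity breakpoints,
# labels and sentence templates.  Breakpoints follow conventional clinical
# bands and are user-overridable; bins are half-open [lo, hi) with the final
# bin closed at the range maximum.  `invert: true` means a LOWER score is MORE
# severe (clock drawing test convention).
scales:
  - scale_id: MDS-UPDRS
    score_range: [0, 132]
    breakpoints: [15, 33, 59]
    labels: [Mild, Moderate, Significant, Serious]
    template: "The subject showed {label} (MDS-UPDRS) motor impairment on examination."
    invert: false
  - scale_id: STAI
    score_range: [20, 80]
    breakpoints: [38, 45, 55]
    labels: [Mild, Moderate, Significant, Serious]
    template: "The subject reported {label} (STAI) anxiety levels."
    invert: false
  - scale_id: ESS
    score_range: [0, 24]
    breakpoints: [6, 11, 16]
    labels: [Mild, Moderate, Significant, Serious]
    template: "The subject noted {label} (ESS) drowsiness during the day."
    invert: false
  - scale_id: CDT
    score_range: [0, 5]
    breakpoints: [2, 3, 4]
    labels: [Mild, Moderate, Significant, Serious]
    template: "The subject displayed {label} (CDT) impairment in the clock drawing task."
    invert: true
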