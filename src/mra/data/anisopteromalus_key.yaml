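# Quantitative identification key and diagnosis ranges for females of the
# six Anisopteromalus species, encoded from the published key couplets and
# species diagnoses.  Ratios are named "numerator:denominator" over the
# character abbreviations of the measurement registry.
#
# Each couplet has two branches; quantitative conditions decide, optional
# qualitative traits (observer-supplied booleans) only resolve cases where
# the quantitative conditions are ambiguous (both fail or both hold).
# "within" bounds are [low, high] inclusive.  The point thresholds of
# A. ceylonensis (known from a single measured specimen) are encoded as
# +/- 0.05 bands around the printed values.

ratios:
  - "hea.b:tb3.l"
  - "eye.h:sct.l"
  - "mss.l:ool.l"
  - "hea.b:eye.d"
  - "pdl.flg:eye.h"
  - "hea.h:eye.b"
  - "tb3.l:mv.l"
  - "sct.l:stv.l"
  - "gst.l:ool.l"
  - "eye.b:ool.l"
  - "mss.l:eye.d"
  - "tb3.l:eye.d"

couplets:
  1:
    a:
      combine: and
      conditions:
        - {ratio: "hea.b:tb3.l", op: ">=", bound: 1.53}
        - {ratio: "eye.h:sct.l", op: "<=", bound: 1.10}
      traits: {speculum_setae_patch: true, scutellum_projecting: true}
      outcome: "A. apiovorus"
    b:
      combine: or
      conditions:
        - {ratio: "hea.b:tb3.l", op: "<", bound: 1.53}
        - {ratio: "eye.h:sct.l", op: ">", bound: 1.10}
      traits: {speculum_setae_patch: false, scutellum_projecting: false}
      outcome: 2
  2:
    a:
      combine: and
      conditions:
        - {ratio: "mss.l:ool.l", op: "<=", bound: 8.14}
        - {ratio: "hea.b:eye.d", op: "<=", bound: 1.52}
      traits: {tergite1_margin_produced: true}
      outcome: 3
    b:
      combine: or
      conditions:
        - {ratio: "mss.l:ool.l", op: ">", bound: 8.14}
        - {ratio: "hea.b:eye.d", op: ">", bound: 1.52}
      traits: {tergite1_margin_produced: false}
      outcome: 4
  3:
    a:
      combine: and
      conditions:
        - {ratio: "pdl.flg:eye.h", op: "within", bounds: [1.77, 2.25]}
      traits: {flagellum_clavate: true, setae_conspicuous: false}
      outcome: "A. calandrae"
    b:
      combine: and
      conditions:
        - {ratio: "pdl.flg:eye.h", op: "within", bounds: [2.43, 2.69]}
      traits: {flagellum_clavate: false, setae_conspicuous: true}
      outcome: "A. cornis"
  4:
    a:
      combine: and
      conditions:
        - {ratio: "hea.h:eye.b", op: "within", bounds: [1.97, 2.07]}
        - {ratio: "tb3.l:mv.l", op: "within", bounds: [1.51, 1.61]}
      traits: {scutellum_strongly_curved: true}
      outcome: "A. ceylonensis"
    b:
      combine: and
      conditions:
        - {ratio: "hea.h:eye.b", op: "within", bounds: [2.24, 2.74]}
        - {ratio: "tb3.l:mv.l", op: "within", bounds: [1.67, 2.25]}
      traits: {scutellum_strongly_curved: false}
      outcome: 5
  5:
    a:
      combine: and
      conditions:
        - {ratio: "sct.l:stv.l", op: "<=", bound: 2.00}
        - {ratio: "gst.l:ool.l", op: ">=", bound: 11.38}
      traits: {gena_carinate: true, propodeum_costula_distinct: false}
      outcome: "A. quinarius"
    b:
      combine: or
      conditions:
        - {ratio: "sct.l:stv.l", op: ">", bound: 2.00}
        - {ratio: "gst.l:ool.l", op: "<", bound: 11.38}
      traits: {gena_carinate: false, propodeum_costula_distinct: true}
      outcome: "A. caryedophagus"

diagnoses:
  "A. calandrae":
    "hea.b:tb3.l": [1.24, 1.51]
    "hea.b:eye.d": [1.38, 1.52]
    "hea.h:eye.b": [2.46, 3.39]
    "eye.h:sct.l": [1.09, 1.30]
    "pdl.flg:eye.h": [1.77, 2.25]
    "mss.l:ool.l": [5.96, 8.14]
    "sct.l:stv.l": [1.48, 1.96]
    "tb3.l:mv.l": [1.66, 2.21]
    "gst.l:ool.l": [7.78, 12.02]
  "A. cornis":
    "hea.b:tb3.l": [1.15, 1.26]
    "hea.b:eye.d": [1.37, 1.40]
    "hea.h:eye.b": [3.15, 3.59]
    "eye.h:sct.l": [1.05, 1.09]
    "pdl.flg:eye.h": [2.43, 2.69]
    "mss.l:ool.l": [6.19, 7.96]
    "sct.l:stv.l": [1.64, 1.74]
    "tb3.l:mv.l": [1.90, 2.29]
    "gst.l:ool.l": [7.98, 11.94]
  "A. quinarius":
    "hea.b:tb3.l": [1.24, 1.51]
    "hea.b:eye.d": [1.48, 1.69]
    "hea.h:eye.b": [2.34, 2.74]
    "eye.h:sct.l": [1.09, 1.32]
    "pdl.flg:eye.h": [1.63, 1.97]
    "mss.l:ool.l": [8.11, 11.87]
    "sct.l:stv.l": [1.38, 2.00]
    "tb3.l:mv.l": [1.67, 2.25]
    "gst.l:ool.l": [11.38, 16.43]
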