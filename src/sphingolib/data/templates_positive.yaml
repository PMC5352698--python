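# Positive-mode templates.  Restricted to the protonated precursor's
# dehydration series (up to two water losses); full positive-mode fragment
# sets are out of scope.
polarity: positive

shared:
  cer_pos:
    - {label: "precursor - H2O", formula: "species - H2O", rules: [P2],
       intensity: 999, origin: precursor, dehydration: false}
    - {label: "precursor - 2H2O", formula: "species - H2O - H2O", rules: [P2],
       intensity: 400, origin: precursor, dehydration: false}

_pos_adducts: &pos ["[M+H]+"]

classes:
  Cer[NS]: {adducts: *pos, extends: cer_pos}
  Cer[NDS]: {adducts: *pos, extends: cer_pos}
  Cer[NP]: {adducts: *pos, extends: cer_pos}
  Cer[AS]: {adducts: *pos, extends: cer_pos}
  Cer[ADS]: {adducts: *pos, extends: cer_pos}
  Cer[AP]: {adducts: *pos, extends: cer_pos}
  Cer[BS]: {adducts: *pos, extends: cer_pos}
  Cer[BDS]: {adducts: *pos, extends: cer_pos}
  Cer[EOS]: {adducts: *pos, extends: cer_pos}
  Cer[EODS]: {adducts: *pos, extends: cer_pos}
  HexCer[NS]: {adducts: *pos, extends: cer_pos}
  HexCer[NDS]: {adducts: *pos, extends: cer_pos}
  HexCer[NP]: {adducts: *pos, extends: cer_pos}
  HexCer[AS]: {adducts: *pos, extends: cer_pos}
  HexCer[ADS]: {adducts: *pos, extends: cer_pos}
  HexCer[AP]: {adducts: *pos, extends: cer_pos}
  HexCer[BS]: {adducts: *pos, extends: cer_pos}
  HexCer[BDS]: {adducts: *pos, extends: cer_pos}
  HexCer[EOS]: {adducts: *pos, extends: cer_pos}
  HexCer[EODS]: {adducts: *pos, extends: cer_pos}
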