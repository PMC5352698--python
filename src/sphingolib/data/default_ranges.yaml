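# Default enumeration ranges for the 21 sphingolipid classes.
#
# Fatty-acid chains span 12-36 carbons with 0-3 double bonds; sphingoid
# chains span 14-30 carbons.  Sphingosine (S) bases take 0-7 double bonds,
# dihydrosphingosine (DS) and phytosphingosine (P) bases are saturated.
# Esterified omega-hydroxy (EO) classes enumerate the esterified chain over
# the same range as the amide-linked fatty acid.  Negative-mode adducts:
# proton loss, formate and acetate (SM: formate and acetate only).

_s_ranges: &s
  fa_carbons: [12, 36]
  fa_double_bonds: [0, 3]
  base_carbons: [14, 30]
  base_double_bonds: [0, 7]
  adducts: ["[M-H]-", "[M+HCOO]-", "[M+CH3COO]-"]

_ds_ranges: &ds
  fa_carbons: [12, 36]
  fa_double_bonds: [0, 3]
  base_carbons: [14, 30]
  base_double_bonds: [0, 0]
  adducts: ["[M-H]-", "[M+HCOO]-", "[M+CH3COO]-"]

_p_ranges: &p
  fa_carbons: [12, 36]
  fa_double_bonds: [0, 3]
  base_carbons: [14, 30]
  base_double_bonds: [0, 0]
  adducts: ["[M-H]-", "[M+HCOO]-", "[M+CH3COO]-"]

_eos_ranges: &eos
  fa_carbons: [12, 36]
  fa_double_bonds: [0, 3]
  base_carbons: [14, 30]
  base_double_bonds: [0, 7]
  ester_carbons: [12, 36]
  ester_double_bonds: [0, 3]
  adducts: ["[M-H]-", "[M+HCOO]-", "[M+CH3COO]-"]

_eods_ranges: &eods
  fa_carbons: [12, 36]
  fa_double_bonds: [0, 3]
  base_carbons: [14, 30]
  base_double_bonds: [0, 0]
  ester_carbons: [12, 36]
  ester_double_bonds: [0, 3]
  adducts: ["[M-H]-", "[M+HCOO]-", "[M+CH3COO]-"]

classes:
  Cer[NS]: *s
  Cer[NDS]: *ds
  Cer[NP]: *p
  Cer[AS]: *s
  Cer[ADS]: *ds
  Cer[AP]: *p
  Cer[BS]: *s
  Cer[BDS]: *ds
  Cer[EOS]: *eos
  Cer[EODS]: *eods
  HexCer[NS]: *s
  HexCer[NDS]: *ds
  HexCer[NP]: *p
  HexCer[AS]: *s
  HexCer[ADS]: *ds
  HexCer[AP]: *p
  HexCer[BS]: *s
  HexCer[BDS]: *ds
  HexCer[EOS]: *eos
  HexCer[EODS]: *eods
  SM:
    fa_carbons: [12, 36]
    fa_double_bonds: [0, 3]
    base_carbons: [14, 30]
    base_double_bonds: [0, 7]
    adducts: ["[M+HCOO]-", "[M+CH3COO]-"]
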