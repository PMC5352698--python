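# Negative-mode diagnostic-ion templates, one set per lipid class.
#
# Each entry maps a neutral substructure (an expression over the species'
# building blocks) to a product ion through hydrogen-rearrangement rules.
# Available blocks: species, base (sphingoid), fa_acid (free fatty acid,
# combined with the esterified chain for EO classes), fa_amide (fatty acid
# with the carboxyl OH replaced by NH2), est_acid (esterified chain, EO
# only).  Literal formulas (C2H2, H2O, ...) may be added or subtracted.
# ``dehydration: true`` declares a -H2O satellite ion at intensity 150.
# Intensities are relative, 0-999; the base peak per class carries 999.
polarity: negative

shared:
  # non-hydroxy acyl ceramide backbone: three fatty-acid ions (b, c, d),
  # two sphingoid ions (e, f), each with a dehydration satellite -> 10 ions.
  ns:
    - {label: "fatty acid amide (b)", formula: "fa_amide", rules: [N2],
       intensity: 400, origin: fatty-acid, dehydration: true}
    - {label: "fatty acid carboxylate (c)", formula: "fa_acid", rules: [N1],
       intensity: 400, origin: fatty-acid, dehydration: true}
    - {label: "fatty acid + C2H2 (d)", formula: "fa_acid + C2H2", rules: [N2],
       intensity: 400, origin: fatty-acid, dehydration: true}
    - {label: "sphingoid base, double cleavage (e)", formula: "base", rules: [N2, N5],
       intensity: 400, origin: sphingoid, dehydration: true}
    - {label: "sphingoid base (f)", formula: "base", rules: [N2],
       intensity: 999, origin: sphingoid, dehydration: true}

  # alpha-hydroxy acyl ceramides: the deprotonated hydroxy fatty acid from
  # nucleophilic substitution is the class-defining base peak -> 14 ions.
  "as":
    - {label: "alpha-hydroxy fatty acid carboxylate (nucleophilic substitution)",
       formula: "fa_acid", rules: [N1],
       intensity: 999, origin: fatty-acid, dehydration: false}
    - {label: "fatty acid amide (b)", formula: "fa_amide", rules: [N2],
       intensity: 400, origin: fatty-acid, dehydration: true}
    - {label: "fatty acid, new double bond (c)", formula: "fa_acid", rules: [N2],
       intensity: 400, origin: fatty-acid, dehydration: true}
    - {label: "fatty acid + C2H2 (d)", formula: "fa_acid + C2H2", rules: [N2],
       intensity: 400, origin: fatty-acid, dehydration: true}
    - {label: "fatty acid - CH2O (g)", formula: "fa_acid - CH2O", rules: [N2],
       intensity: 400, origin: fatty-acid, dehydration: true}
    - {label: "sphingoid base, double cleavage (e)", formula: "base", rules: [N2, N5],
       intensity: 400, origin: sphingoid, dehydration: true}
    - {label: "sphingoid base (f)", formula: "base", rules: [N2],
       intensity: 400, origin: sphingoid, dehydration: true}
    - {label: "sphingoid - CH2O, double cleavage (h)", formula: "base - CH2O",
       rules: [N1, N3],
       intensity: 400, origin: sphingoid, dehydration: false}

  # beta-hydroxy acyl ceramides: retro-aldol (alpha-elimination) product,
  # the N-acetyl sphingoid enolate, is the class-defining base peak.
  bs:
    - {label: "N-acetyl sphingoid enolate (retro-aldol)", formula: "base + C2H2O",
       rules: [N1],
       intensity: 999, origin: rearrangement, dehydration: false}
    - {label: "fatty acid amide (b)", formula: "fa_amide", rules: [N2],
       intensity: 400, origin: fatty-acid, dehydration: true}
    - {label: "fatty acid carboxylate (c)", formula: "fa_acid", rules: [N1],
       intensity: 400, origin: fatty-acid, dehydration: true}
    - {label: "fatty acid + C2H2 (d)", formula: "fa_acid + C2H2", rules: [N2],
       intensity: 400, origin: fatty-acid, dehydration: true}
    - {label: "sphingoid base, double cleavage (e)", formula: "base", rules: [N2, N5],
       intensity: 400, origin: sphingoid, dehydration: true}
    - {label: "sphingoid base (f)", formula: "base", rules: [N2],
       intensity: 400, origin: sphingoid, dehydration: true}

  hex_extra:
    - {label: "hexose loss (ceramide anion)", formula: "species - C6H10O5", rules: [N1],
       intensity: 400, origin: head, dehydration: true}

  eo_extra:
    - {label: "esterified fatty acid carboxylate", formula: "est_acid", rules: [N1],
       intensity: 400, origin: fatty-acid, dehydration: false}
    - {label: "omega-hydroxy fatty acid carboxylate",
       formula: "fa_acid - est_acid + H2O", rules: [N1],
       intensity: 400, origin: fatty-acid, dehydration: false}

  sm:
    - {label: "demethylated precursor", formula: "species - CH2", rules: [N1],
       intensity: 999, origin: head, dehydration: false}
    - {label: "demethylated phosphocholine", formula: "C4H12NO4P", rules: [N1],
       intensity: 400, origin: head, dehydration: false}

_neg_adducts: &neg ["[M-H]-", "[M+HCOO]-", "[M+CH3COO]-"]

classes:
  Cer[NS]: {adducts: *neg, extends: ns}
  Cer[NDS]: {adducts: *neg, extends: ns}
  Cer[NP]: {adducts: *neg, extends: ns}
  Cer[AS]: {adducts: *neg, extends: "as"}
  Cer[ADS]: {adducts: *neg, extends: "as"}
  Cer[AP]: {adducts: *neg, extends: "as"}
  Cer[BS]: {adducts: *neg, extends: bs}
  Cer[BDS]: {adducts: *neg, extends: bs}
  Cer[EOS]: {adducts: *neg, extends: ns, plus: [eo_extra]}
  Cer[EODS]: {adducts: *neg, extends: ns, plus: [eo_extra]}
  HexCer[NS]: {adducts: *neg, extends: ns, plus: [hex_extra]}
  HexCer[NDS]: {adducts: *neg, extends: ns, plus: [hex_extra]}
  HexCer[NP]: {adducts: *neg, extends: ns, plus: [hex_extra]}
  HexCer[AS]: {adducts: *neg, extends: "as", plus: [hex_extra]}
  HexCer[ADS]: {adducts: *neg, extends: "as", plus: [hex_extra]}
  HexCer[AP]: {adducts: *neg, extends: "as", plus: [hex_extra]}
  HexCer[BS]: {adducts: *neg, extends: bs, plus: [hex_extra]}
  HexCer[BDS]: {adducts: *neg, extends: bs, plus: [hex_extra]}
  HexCer[EOS]: {adducts: *neg, extends: ns, plus: [eo_extra, hex_extra]}
  HexCer[EODS]: {adducts: *neg, extends: ns, plus: [eo_extra, hex_extra]}
  SM: {adducts: ["[M+HCOO]-", "[M+CH3COO]-"], extends: sm}
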