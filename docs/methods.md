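# Methods

## Scope and data model

`sphingolib` models sphingolipids as three building blocks: a sphingoid
base (dihydroxy `d` or trihydroxy `t`; kinds DS = dihydrosphingosine,
S = sphingosine, P = phytosphingosine), one N-acyl fatty acid (types
N = non-hydroxy, A = α-hydroxy, B = β-hydroxy, EO = esterified ω-hydroxy,
the latter carrying a second, ester-linked fatty acid) and a head group
(H for ceramide, one hexose for HexCer, phosphocholine for SM).  The 21
supported classes are the cross-product that occurs in human and mouse
tissue; 6-hydroxy-sphingosine classes and gangliosides are out of scope.
Molecular formulas follow from block condensation (one H2O removed per
bond formed), e.g. Cer[AS](d18:1/16:0) = C18H37NO2 + C16H32O3 − H2O =
C34H67NO4.

## Mass arithmetic

All m/z values are computed from one frozen table of IUPAC monoisotopic
masses (≥ 6 decimals; H 1.0078250319, C 12, N 14.0030740052,
O 15.9949146221, P 30.97376151, …).  Ion m/z is
`(mass(M) + dH·m_H − z·m_e)/|z|`; the electron mass (0.00054858 Da) is
included by default and switchable per call.  The convention reproduces
the deprotonated α-hydroxy-palmitic acid at 271.2279, within 1 mDa of the
commonly printed 271.227 (TOF accuracy does not discriminate between the
two electron conventions).  Adducts are singly charged formula deltas:
[M−H]⁻ −1.007276, [M+HCOO]⁻ +44.998201, [M+CH3COO]⁻ +59.013851,
[M+H]⁺ +1.007276, plus ammonium and sodium.

## Structure enumeration

Default ranges: fatty acid 12–36 carbons × 0–3 double bonds, sphingoid
14–30 carbons × 0–7 double bonds (S classes; DS and P bases are kept
saturated — DS by definition, P as the representative convention for the
shipped library).  EO classes enumerate the esterified chain over the same
range as the amide-linked fatty acid, since no EO-specific ranges are
established; their shorthand is `CLASS dNN:M/KK:J/LL:I`
(base / ω-hydroxy FA / ester FA), an artifact convention.  Enumeration
order is lexicographic (FA carbons, FA double bonds, base carbons, base
double bonds, ester chain) for reproducible diffs.  An optional even-only
parity filter applies to fatty-acid carbons.

The shipped per-class reference manifest (structure counts such as 3,360
for Cer[NS] and 3,384 for SM, 109,448 structures over all 21 classes, with
spectra = structures × adducts) reflects curation filters applied to the
published library that are **not** derivable from the stated ranges alone
(the raw Cer[NS] product is 25 × 4 × 17 × 8 = 13,600).  It is therefore
treated as manifest data, not as a generation target; generation itself is
fully configuration-driven.

One representative SMILES is emitted per composition: fatty-acid double
bonds are written cis and anchored at the methyl end (Δn−9, n−6, n−3 — the
oleic/linoleic/linolenic pattern), sphingoid double bonds trans from Δ4
with methylene-interrupted spacing (phytosphingoid bases from Δ6, after the
C4 hydroxyl).  The series shifts upward if it would collide with a
substituted carbon and raises an error when it cannot fit.  Strings are
template concatenations — valence-valid and formula-exact (enforced in the
test suite with RDKit) but not canonicalized and without stereocentres.

## Fragmentation engine

Fragments are neutralised substructures M′ observed as [M′ ± bH]⁻ (or
[M′ ± aH]⁺).  The hydrogen deltas are fixed by the HR rule table:
P1 −1, P2 +1, P3 0, P4 −2 (positive); N1 −1, N2 −3, N3 −2, N4 0, N5 −2
(negative).  Consecutive cleavages combine additively (N2+N5 = −5,
N1+N3 = −3); template depth is two cleavages.

Templates are data, not code: YAML files map each class to entries of
(label, formula expression over the species' blocks, rule ids, intensity,
origin).  The engine only evaluates formula arithmetic.  Key choices:

- **Cer[NS]-type backbone** — three fatty-acid ions (amide b under N2,
  carboxylate c under N1, acid+C2H2 d under N2) and two sphingoid ions
  (double-cleavage e under N2+N5, base f under N2), each with a declared
  −H2O satellite: 10 product ions.
- **Cer[AS]-type** — additionally the class-defining deprotonated
  α-hydroxy fatty acid (nucleophilic substitution of the sphingoid C1
  hydroxyl anion at the amide carbonyl; rule N1) as base peak, plus an
  acid−CH2O ion and a two-cleavage sphingoid ion (N1+N3): 14 product ions.
- **Cer[BS]-type** — the retro-aldol (α-elimination) product, an N-acetyl
  sphingoid enolate under N1, as base peak (theoretical 340.2857 for
  d18:1/26:0; the instrument-observed 340.2797 differs by a few mDa and is
  deliberately not asserted bit-exact).
- **HexCer** classes add the hexose-loss ceramide anion (+ satellite);
  EO classes add the ester- and ω-hydroxy-fatty-acid carboxylates.
- **SM** carries head-group diagnostics only (demethylated precursor and
  demethylated phosphocholine at 168.0431); acyl-chain assignment for SM
  is documented as unreliable because sphingoid fragments are rarely
  observed for this class.
- **Positive mode** is restricted to the protonated precursor's dehydration
  series (−H2O, −2H2O).

Relative intensities are empirical conventions shared across each class:
base peak 999, other diagnostics 400, dehydration satellites 150
(arbitrary-but-fixed).  Product ions closer than 0.001 Th merge, keeping
the larger intensity — genuinely isobaric fragments (e.g. the fatty-acid
amide vs. the dehydrated base when chain compositions coincide) thus
collapse into one peak, exactly as an instrument would show them, so some
compositions carry fewer peaks than the nominal class count.  Acetate and
formate adduct spectra root at the adduct ion while fragments are computed
from the neutral molecule M (the in-source-deprotonation alternative would
change only the precursor annotation, not the product ions).

## Retention-time model

A two-segment linear QSRR for a step-formed reverse-phase gradient.
Routing is by XLogP: the early segment (intercept −14; XLogP 0.55,
SssCH2 0.17, C2SP3 0.048, BIC0 71, ATSC2m −0.0022, ATSC2v 0.00081) applies
at XLogP ≤ 15.9; the late segment (intercept 9.5; XLogP 0.16,
LipoaffinityIndex 0.076, SpMAD_Dzi −0.14, C2SP3 0.085) at XLogP ≥ 16.6;
inside the open interval the prediction is the unweighted arithmetic mean
of both (not an interpolation — the blend is a step-edge smoother, and the
prediction is guaranteed to lie between the two segment values).
Predictions are in minutes and not clamped.  These coefficients ship as
the immutable `paper-2017` builtin; refits are separate JSON models.

Refitting: constant and exact-duplicate descriptor columns are dropped,
descriptors with |Pearson r| ≥ 0.85 against RT are kept (absolute value,
because hydrophilicity descriptors anticorrelate with reverse-phase RT),
the training set is split by overlapping XLogP windows (default 5.0–16.6
and 15.9–32.1, outer edges open-ended; overlap rows enter both segments,
and narrowing the windows switches to exclusive assignment), and each
segment is fitted by forward stepwise OLS under AIC = n·log(RSS/n) + 2p
(the R `step` convention; selection is insensitive to the constant
offset).  Ties break deterministically by descriptor name; the accepted
AIC trace is strictly decreasing.  Descriptor names are matched
case-insensitively with whitespace stripped and a small synonym map
("ATSC2 m" ≡ "ATSC2m").

The shipped model's training/validation residual SDs (0.14/0.31 min) stem
from instrument data that is not redistributable; the test suite instead
verifies noiseless-refit exactness and coefficient recovery within 3
standard errors on synthetic data at 0.14 min Gaussian noise, with
descriptor scales chosen so every true effect is detectable
(unit-variance descriptors would bury the 10⁻³-magnitude autocorrelation
coefficients below the noise floor).

## Identification

Candidates must match polarity, precursor m/z within 0.01 Da, and — only
when both query and record carry an RT — retention time within 2 min.
Peaks are paired greedily by nearest m/z within 0.05 Da, each peak used
once, ties toward lower m/z with a symmetric tie-break.  Scores (all
0–100): forward dot product (cosine over paired plus unpaired positions),
reverse dot product (query peaks unmatched by the library are ignored) and
matched-diagnostic-ion fraction.  The exact blend used by established
profiling software is not published, so the total score is their
unweighted mean, with every component exposed so a cutoff can be applied
to the raw dot product alone.  Acceptance threshold: total ≥ 80.  No
intensity or m/z weighting is applied inside the cosine; weighted variants
would be configuration, not default.

## Synthetic fixtures

Query fixtures perturb library spectra with Gaussian m/z jitter (default
σ = 2 mDa; precursor σ/2), multiplicative log-normal intensity noise
(CV 20%, mean-one parameterisation) and Bernoulli dropout (default 0,
resampled so ≥ 1 peak survives).  Decoys reassign intensities among a
record's m/z positions by a uniform random cyclic permutation (Sattolo),
guaranteeing no fixed point.  The RT generator emits standard-normal
descriptors with a known linear combination plus Gaussian noise.  These
fixtures emulate centroided, deisotoped peak lists with well-calibrated
masses; they do not emulate chromatographic peak shape, co-elution,
in-source fragmentation, isotopologue interference or data-dependent
sampling gaps, so passing recovery tests demonstrates correctness of the
matching machinery, not instrument-level identification rates (the
published FDR/TPR figures depend on manually curated biological data and
are not reproducible at desk scale).

Recovery simulations in the tests use a 630-record two-class library
(Cer[NS]/Cer[AS], FA 14–20 × 0–2, base 16–20 × 0–2, acetate adduct) and
200 seeded queries — sizes chosen to exercise isobaric competition among
chain compositions while keeping the suite fast.

## Numerical conventions and edge cases

- Formula subtraction is checked element-wise; negative counts raise.
- Peak-merge tolerance 0.001 Th; annotation tolerance default 10 mDa,
  tie to lower m/z.
- MSP output: m/z with 4 decimals, RT with 2, intensities as integers;
  byte-identical across runs; round-trip lossless at emitted precision.
- Empty enumeration ranges yield empty lists (not errors); inverted ranges
  fail at configuration load.
- Charge 0, empty neutral formulas, sub-minimum chain lengths (< 2
  carbons), unsaturated DS bases and unknown classes/adducts/elements all
  raise immediately with the offending name in the message.

## Known limitations

- Diagnostic-ion sets beyond the anchored Cer[NS]/Cer[AS]/Cer[BS]/SM ions
  are template conventions; satellite compositions are partially inferred
  rather than instrument-verified.
- Positive-mode coverage is deliberately minimal.
- SMILES are representative single isomers; no stereochemistry, no
  canonicalization, no InChIKey.
- The RT model abstracts the gradient to two segments; other LC programs
  require refitting.
- SM acyl-chain composition cannot be confirmed from negative-mode
  head-group diagnostics alone.
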