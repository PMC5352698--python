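# sphingolib

In silico MS/MS spectral libraries, retention-time (RT) prediction and
library-based spectral identification for sphingolipids.

Untargeted LC–ESI–MS/MS lipidomics identifies compounds by matching
retention time, precursor *m/z* and MS/MS spectrum against references — but
authentic standards cover only a sliver of sphingolipid chemical space.
`sphingolib` closes that gap computationally for 21 sphingolipid classes
(ceramides with non-, α-, β- and esterified ω-hydroxy fatty acids on
sphingosine, dihydrosphingosine and phytosphingosine backbones, their
monohexosides, and sphingomyelin):

1. **Enumeration** — species are assembled combinatorially from building
   blocks (sphingoid base × N-acyl fatty acid × head group) over
   configurable chain-length and double-bond ranges, with one
   representative SMILES per composition.
2. **Fragmentation** — negative-mode product-ion spectra are generated from
   per-class diagnostic-ion templates.  Each fragment is a neutralised
   substructure M′ observed as [M′ ± *b*H]⁻, where the allowed hydrogen
   rearrangements are fixed by the low-energy-CID HR rules
   (N1: M → [M′−H]⁻, N2: M → [M′−3H]⁻, N3: M → [M′−2H]⁻, N4: M⁻ → M′⁻,
   N5: M⁻ → [M′−2H]⁻, and their positive-mode counterparts P1–P4).
   Intensities use the 0–999 convention.
3. **RT prediction** — a segmented QSRR model on 2-D molecular descriptors:
   RT = −14 + 0.55·XLogP + 0.17·SssCH2 + 0.048·C2SP3 + 71·BIC0 −
   0.0022·ATSC2m + 0.00081·ATSC2v for XLogP ≤ 15.9, RT = 9.5 + 0.16·XLogP +
   0.076·LipoaffinityIndex − 0.14·SpMAD_Dzi + 0.085·C2SP3 for XLogP ≥ 16.6,
   and the mean of both in between.  A refitting pipeline (correlation
   prefilter + forward stepwise AIC regression) supports new LC conditions.
4. **Identification** — query features are gated by precursor tolerance
   (0.01 Da), optional RT tolerance (2 min) and scored with the dot-product
   (cosine) similarity; matches at a total score ≥ 80 are accepted.

## Worked example

```python
import sphingolib as sl

species = sl.parse_name("Cer[AS] d18:1/16:0")
record = sl.generate_spectrum(species, "[M+CH3COO]-")
print(record.name, record.adduct, f"precursor m/z {record.precursor_mz:.4f}")
for p in record.peaks:
    print(f"  {p.mz:9.4f}  {p.intensity:4d}  {p.annotation.label}")
```

```
Cer[AS] d18:1/16:0 [M+CH3COO]- precursor m/z 612.5209
   221.1911   150  fatty acid - CH2O (g) - H2O
   239.2017   400  fatty acid - CH2O (g)
   250.2176   150  fatty acid amide (b) - H2O
   251.2017   150  fatty acid, new double bond (c) - H2O
   266.2489   400  sphingoid - CH2O, double cleavage (h)
   268.2282   400  fatty acid amide (b)
   269.2122   400  fatty acid, new double bond (c)
   271.2279   999  alpha-hydroxy fatty acid carboxylate (nucleophilic substitution)
   276.2333   150  sphingoid base, double cleavage (e) - H2O
   277.2173   150  fatty acid + C2H2 (d) - H2O
   278.2489   150  sphingoid base (f) - H2O
   294.2439   400  sphingoid base, double cleavage (e)
   295.2279   400  fatty acid + C2H2 (d)
   296.2595   400  sphingoid base (f)
```

The 14 diagnostic ions of the α-hydroxy ceramide class include its
signature peak: the deprotonated α-hydroxy-palmitic acid released by
nucleophilic substitution, at *m/z* 271.2279 (C16H32O3 − H⁻).  Retention
times come from descriptor rows (PaDEL-style CSV):

```python
rt = sl.predict_rt({"XLogP": 13.04, "SssCH2": 26.90, "C2SP3": 2.0,
                    "BIC0": 0.215, "ATSC2m": -310.2, "ATSC2v": 1210.4,
                    "LipoaffinityIndex": 0.0, "SpMAD_Dzi": 0.0})
print(f"predicted RT: {rt:.2f} min")   # -> predicted RT: 14.77 min
```

The same workflows are scriptable from the shell:

```sh
sphingolib build-library --out library.msp --manifest manifest.tsv
sphingolib predict-rt --descriptors padel.csv --out rt.csv
sphingolib identify --query queries.mgf --library library.msp --out hits.tsv
sphingolib make-fixtures --library library.msp --n 200 --seed 1 \
    --out queries.msp --truth truth.tsv
```

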