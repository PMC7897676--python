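# isoformid

Computational identification of new psychoactive substances (NPS) and their
metabolites from high-resolution accurate-mass (HRAM) MS and solid-deposition
GC-FTIR data.

Clinical and forensic laboratories frequently face seized powders and
intoxication biosamples containing NPS for which no reference standard is at
hand — and positional isomers (2-/3-/4-MMC, 2-/3-/4-MeO-PCP) that LC-MS
cannot tell apart because they share retention behavior, MH⁺ mass and
fragmentation. This package implements the computational workflow that
resolves such cases by combining two orthogonal measurements:

1. **Accurate-mass identification.** From an accurate MH⁺ m/z, candidate
   elemental compositions are enumerated over a count lattice, filtered by
   mass window (Δm = (m_acc − m_exact)/m_exact × 10⁶ ppm) and
   ring-and-double-bond equivalents (RDBE = C − H/2 + N/2 + 1), and checked
   against the calculated MH⁺ isotopic pattern (M+0…M+3) via the relative
   isotopic abundance RIA = I(M+1)/I(M+0).
2. **Metabolite screening in biofluids.** Phase I/II biotransformation rules
   (O-demethylation −CH₂, hydroxylation +O, oxidation to oxo +O−H₂,
   dehydrogenation −H₂, carboxylation +O₂, terminal glucuronidation +C₆H₈O₆)
   generate candidate metabolite formulas from the parent compound; observed
   MS1 features are annotated against five criteria (retention behavior,
   MH⁺ mass accuracy, isotopic-pattern agreement, product-ion matches,
   literature concordance) and the most abundant identified analytes form a
   targeted screening panel.
3. **Positional-isomer discrimination by IR.** Solid-phase IR spectra are
   searched against a library with a quality match factor
   QMF = 100·max(r, 0), where r is the Pearson correlation of
   Savitzky–Golay first derivatives (window 9, order 2) on a common
   650–4000 cm⁻¹ / 4 cm⁻¹ grid. Co-addition of consecutive GC depositions
   models the limit of identification (LOI) for weak analytes.

Because raw casework data of this kind is withheld for legal reasons, the
package ships a first-class synthetic-data module that generates
ground-truth-tagged peak tables and IR libraries emulating the structure of
the real measurements.

## Worked example

```sh
$ isoformid mass --formula C18H28NO --charge 1
274.2165

$ isoformid isotopes --formula C18H28NO
label   mz        abundance
M+0     274.2165  1.00000
M+1     275.2199  0.20194
M+2     276.2233  0.02138
M+3     277.2266  0.00158

$ isoformid searchformula --mz 178.1226 --ppm 3 --elements C0-20,H0-40,N0-2,O0-4
rank    neutral   mh_mz     delta_ppm  rdbe
1       C11H15NO  178.1226  -0.23      5.0
```

The first command is the theoretical m/z of protonated 3-MeO-PCP (electron
mass subtracted for the cation). The second is its calculated isotopic
ladder: M+1 and M+2 are the ¹³C substitutions and the abundances are
relative to M+0 (RIA ≈ 0.202 for an 18-carbon ion). The third shows that a
single CHNO composition — C11H15NO, the methylmethcathinone formula, RDBE 5
— is compatible with the observed powder mass at ±3 ppm.

The full case-study workflow lives in `analysis/` as numbered drivers that
write their tables under `results/`:

```sh
python analysis/01_powder_identification.py   # formula assignment, both powders
python analysis/02_metabolite_screening.py    # urine annotation + top-7 panel
python analysis/03_ir_isomer_discrimination.py
python analysis/04_deposition_loi.py
```

`02_metabolite_screening.py`, for example, plants the published metabolite
panel into a synthetic urine peak table (1 ppm mass jitter, 30 decoys),
annotates 70 rule-derived candidates, and prints the selected panel — the
parent plus the O-demethyl (M1a), O-demethyl-piperidine-OH (M1b),
O-demethyl-piperidine-di-OH (M1g), piperidine-di-OH (M1h) phase I
metabolites and the M2a/M2c glucuronides, matching the reported seven-analyte
screening layout.

## Layout

- `src/isoformid/` — the library: `formula`, `isotopes`, `powder_id`,
  `metabolites`, `ir`, `jcampdx`, `simulate`, `io`, `cli`, plus
  `reference` (the published 3-MeO-PCP metabolite table used as regression
  targets and planting list).
- `analysis/` — numbered narrative drivers reproducing the case study.
- `tests/` — pytest suite with independent brute-force oracles.
- `docs/methods.md` — models, parameter choices, and limitations.
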