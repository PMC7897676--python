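# Methods

## Exact masses and ions

All masses derive from a bundled, versioned constants table
(`data/atomic_masses.tsv`: AME2020 isotope masses, CIAAW 2021 representative
abundances, CODATA 2018 electron mass), so results never depend on an
external library's tables. The monoisotopic (exact) mass of a formula is the
sum of lightest-isotope masses; for an ion of charge z,
m/z = (Σmᵢ − z·mₑ)/|z|. The electron-mass correction is **on by default**
for cations: protonated 3-MeO-PCP computes to 274.2165 with the correction
and 274.2171 without, and only the corrected value reproduces the reported
four-decimal ladders, which settles a convention the source data leaves
implicit. Display rounding is round-half-even at 4 decimals (masses) and 2
decimals (ppm, RIA error); internal computation is full precision.

Formula text follows a Hill-order grammar (counts optional = 1). The element
vocabulary defaults to CHNO — every species in the case data — and is
extensible per call; the restriction exists to catch symbol typos, not as a
physical limit.

## Isotopic patterns

An ion's pattern is computed exactly (within truncation at M+3) by
enumerating, per element, all isotopic compositions with nominal shift ≤ 3
with their multinomial probabilities, convolving across elements, and
binning by total nominal shift. Each bin reports

- its total probability relative to the monoisotopic bin, and
- the m/z of its **single most abundant isotopologue** (not the
  abundance-weighted centroid).

The dominant-isotopologue convention is what a centroiding high-resolution
instrument reports and is observable in the reference ladders: for CHNO ions
M+1 and M+2 are always the pure ¹³C substitutions, while at M+3 the
¹⁸O+¹³C species overtakes 3×¹³C once the ion carries ~3 or more oxygens
(e.g. the C17H26NO3⁺ ladder ends at M+0 + 3.0076, not + 3.0101). The
implementation is verified against two independent oracles: exhaustive
per-atom enumeration (≤ 10 atoms, 1e-9) and polynomial convolution of
single-atom shift distributions (case-size ions, 1e-6).

Pattern agreement is scored per label as Δm in ppm against tolerances of
5/5/5/7.5 ppm for M+0..M+3 — enveloping the sub-ppm to ~4 ppm accuracies
observed on a 100k-resolution Orbitrap, wider at M+3 where centroids sit on
weak signals — plus a relative RIA tolerance of ±20%. Labels missing from a
truncated experimental pattern are reported absent, not failed.

## Composition search

Search is over **neutral** formulas with MH⁺ m/z = mass(neutral + H, +1),
matching how assignments are reported (neutral composition for the
compound, MH⁺ composition for the ion). Enumeration is exhaustive over the
per-element count lattice with branch-and-bound mass pruning; tests check
exact agreement with a naive full-lattice scan. RDBE (general valence form,
default bounds 0–25, half-integers allowed) prunes chemically impossible
compositions while keeping the case assignments (RDBE 5 and 6). Ranking is
by |Δm|, then |RIA error| when an experimental pattern is supplied, then
Hill text — fully deterministic.

The element bounds and ppm tolerance of the original vendor software are
not documented anywhere; the defaults (C≤30, H≤60, N≤3, O≤6, ±3 ppm) are
engineering choices shown by the tests to leave each powder with a unique
candidate.

## Metabolite annotation

`enumerate_candidates(parent, rules, depth)` applies phase I rules as
multisets (order does not change the formula; all generating paths are kept
on the merged candidate) with per-rule application caps
(hydroxylation ≤ 3, oxo ≤ 2, others ≤ 1), then at most **one phase II
conjugation as the terminal step** — glucuronides of transformed aglycones
exist, glucuronide-then-oxidation paths are implausible. `depth` bounds the
phase I path length only; the terminal conjugation rides on top. With depth
3 this covers every distinct MH⁺ composition of the reference table,
including the tri-transformed aglycones that are then conjugated. Depth 0
returns the parent alone.

The five identification criteria are scored per candidate against the
matched feature:

1. **Retention**: pass iff the matched tR is below the parent's minus a
   0.1 min guard band (metabolites are more hydrophilic and elute earlier;
   the direction is the documented fact, the guard band is ours).
2. **MH⁺ mass**: nearest monoisotopic peak within ±5 ppm (envelopes the
   observed |Δm| ≤ 1.37 ppm with margin for jitter). Multiple peaks in the
   window are isomer matches: the evidence uses the smallest-|Δm| match
   (ties to the more intense), the most abundant match carries a star, and
   an ambiguity flag is raised.
3. **Isotopic pattern**: `compare_patterns` on the feature's envelope.
4. **Product ions**: count of observed fragments within 10 ppm of a
   user-supplied reference list (fragment m/z are configuration input, not
   predicted — published fragment lists carry no formulas).
5. **Literature**: membership of the neutral formula in a supplied list.

Status is *identified* iff 2 and 3 pass plus at least one of 1/4/5,
*tentative* otherwise, *rejected* with no mass match. Note that criteria
operate at the formula level: an artifact that shares its composition with a
genuine metabolite (the carboxy-methyl ester artifact vs the tri-oxygenated
metabolite) cannot be separated by mass alone; artifact-only compositions
are flagged and excluded from panel selection by default.

The screening panel is the parent plus the k−1 most intense identified
metabolite features (isomer features count separately; ties break by label
then feature id).

## Synthetic data

**MS generator.** Study conditions mirror the urine case: parent at
7.74 min; every reference metabolite planted at its reported retention
time(s) with the non-starred isomer features at 0.4× abundance; mass jitter
σ = 1 ppm (the observed accuracies), envelope noise 2% relative per label,
30 uniform decoy peaks; metabolite abundances follow the reported
ion-chromatogram ordering, in which the parent and the six panel
metabolites dominate and all others are minor. The rule-based generator
variant draws retention times uniformly in (0.40, 0.98)·parent tR and
abundances log-normally. Everything is reproducible bit-for-bit from the
recorded seed.

What the generator does **not** emulate: chromatographic peak shapes,
co-eluting matrix, detector saturation, or correlated mass error within a
scan — so 100% recovery at zero jitter demonstrates bookkeeping
correctness, not real-matrix performance.

**IR generator.** Compounds are sums of Gaussian bands on the
650–4000 cm⁻¹ / 4 cm⁻¹ acquisition grid with widths σ = 2.5–6 cm⁻¹
(solid-deposition bands are sharp, FWHM ≈ 6–14 cm⁻¹) and 15–30 bands each.
Isomer family members share 80% of their bands, but positional isomerism
perturbs even the common modes: shared band centers shift uniformly within
±12 cm⁻¹ between members, and the member-specific bands are placed in the
fingerprint region below 1500 cm⁻¹. These two choices are what make
first-derivative correlation discriminate: a shift comparable to the band
width decorrelates the derivative almost completely. Queries add white
noise (0.005) and slow sinusoidal baseline drift (0.02). Even so, synthetic
wrong-isomer QMFs (~35–55) stay well above the ~14% seen on real spectra —
real isomer spectra differ more than this model's — so the benchmark
asserts rank order and a >30-point gap, never absolute QMF values.

## QMF and the deposition ladder

The vendor's "first derivative correlation" algorithm is unpublished. Here:
both spectra are interpolated to the common grid, min-max normalized,
differentiated with a Savitzky–Golay filter (9 points, order 2), and scored
as 100·max(Pearson r, 0). Anti-correlation clamps to zero; a zero-variance
derivative scores 0 with a degenerate flag. QMF is symmetric and invariant
to affine rescaling of either spectrum.

`coadd` is a pointwise **sum** — deposition physically accumulates analyte
on the disc, so signal grows ∝ n while independent per-scan noise grows
∝ √n. For the limit-of-identification simulation the measurement model adds
one further term: after the n-th deposition the acquisition integrates
proportionally longer, so the per-point noise of the measured spectrum
scales as 1/√n of a single scan. Pure √n co-addition gain cannot take a
derivative correlation from r ≈ 0.13 to r ≥ 0.8 within five steps (the
correlation of a signal at derivative-SNR s is r = s/√(1+s²), and
r(1) < 0.2 caps r(5) below 0.72); the integration term is the minimal
physically sensible mechanism that reproduces the reported trajectory of a
weak urinary analyte — unsearchable at one deposition (QMF ≈ 13–15),
crossing QMF 80 around five depositions and 90 within a few more. The
per-deposition amplitude default (0.008 of the normalized reference, noise
0.02/scan) was calibrated once to that starting point and then frozen. LOI
is the smallest n whose median QMF over 30 seeded replicates reaches the
threshold; a ladder that never crosses returns the sentinel `"not reached"`.

## Numerical and interface choices

- All randomness flows through `numpy.random.default_rng` seeded from the
  config; seeds are recorded in generated truth tables.
- Peak-table CSV round trips use `float_precision="round_trip"`; malformed
  rows are reported with row numbers, never coerced.
- JCAMP-DX support covers the XYDATA (X++(Y..Y)) AFFN subset this package
  writes; descending-wavenumber files are re-sorted ascending with a log
  note. Compressed ordinate forms (SQZ/DIF/DUP) are out of scope.
- CLI exit codes: 0 success, 2 validation error, 3 empty result.

## Known limitations

- Annotation is formula-level: positional isomers and artifacts sharing a
  composition are distinguished only by retention time and, ultimately, by
  the IR stage.
- Adducts other than protonation, negative mode, and |z| > 1 validation are
  out of scope (multiply charged ions are supported by contract only).
- Isotope patterns are truncated at M+3 and binned at unit nominal mass; no
  fine-structure resolution within a bin.
- Quantitation is deliberately absent — the workflow identifies, it does
  not measure concentrations.
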