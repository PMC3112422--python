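# Methods

## Forward model

A monitored SIM cluster is modeled on an integer mass-shift grid 0..K
relative to the monoisotopic base m/z (unit-resolution quadrupole data;
fractional-mass fine structure is out of scope). The observed molar
fractions are the discrete convolution of two distributions:

* the **natural envelope** of the fragment, obtained by convolving
  single-atom isotope-shift distributions over every atom of the
  fragment's elemental composition (binary exponentiation of the atom
  polynomial, truncated at K, renormalized — exact for shifts ≤ K);
* the **tracer MID**: for deuterium labeling, a mixture
  (1−f)·δ(m0) + f·Binomial(N, p) where f is the fraction of the pool made
  during labeling, p the body-water deuterium enrichment and N the number
  of water-derived hydrogen positions; for [1,2-¹³C]acetyl labeling, mass
  2k carries (1−f)·[k=0] + f·Binomial(n, g) with n acetyl units and g the
  doubly labeled acetyl-CoA fraction (odd shifts empty).

Natural-abundance correction inverts this by solving the lower-triangular
system M·x = observed, where column j of M is the natural envelope shifted
by j. The matrix uses the same K-truncated, renormalized envelope as the
forward convolution, so the noiseless round trip is exact to solver
precision (verified to 1e-9 over random tracer distributions). Negative
solution components (counting noise) are clipped to zero and the result
renormalized — deterministic, no sequential peak stripping.

## Estimators

* **p (body water):** from r = m2/m1 of the corrected MID,
  p = 2r / ((N−1) + 2r). The ratio involves only labeled molecules, so the
  estimate is invariant to the unlabeled pool size. By default p is
  estimated per sample from palmitate (the strongest cluster) and applied
  to the sample's other analytes; a global p can be supplied instead.
* **FNS (deuterium):** FNS = ME/(p·N) with ME = Σ i·mᵢ. Unbiased for the
  mixture model because new molecules average p·N deuterium atoms. Values
  marginally outside [0, 1] from noise are clipped, with the unclipped
  value kept in diagnostics.
* **g (acetyl-CoA):** from a consecutive even-peak ratio
  R = m₂₍ₖ₊₁₎/m₂ₖ, g = (k+1)·R / ((n−k) + (k+1)·R); k = 1 for M+4/M+2
  (palmitate, oleate), k = 2 for M+6/M+4 (stearate). The two ratios agree
  identically on noiseless data — this is tested. The medium's glucose
  enrichment is never converted to g analytically; g is always estimated
  from spectra, since unlabeled-carbon dilution makes the culture value
  (~0.12–0.13) much lower than the nominal medium enrichment.
* **FNS (MIDA):** Σ_{k∈{1,2,3}} m₂ₖ divided by Σ_{k∈{1,2,3}}
  C(n,k)gᵏ(1−g)ⁿ⁻ᵏ — the observed light labeled fraction over its
  expectation at full turnover. Odd shifts (stray single-¹³C signal) are
  ignored after correction, matching the two-carbon-unit model. An
  optional precursor-sharing flag lets oleate reuse stearate's g when its
  own signal is weak; it is off by default.

Both ratio inversions are checked in the test suite against independent
least-squares grid fits of the binomial forward model.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| N (palmitate / stearate / oleate) | 21 / 24 / 24 | water-derived H positions per molecule; the palmitate value is the established constant, the other two ship as editable assumptions in the definitions table |
| n acetyl units | 8 / 9 / 9 | chain length / 2 |
| fragment compositions | C17H34O2 (m/z 270), C19H38O2 (m/z 298), C18H32O (m/z 264) | methyl-ester molecular ions; oleate uses the methanol-loss fragment. Only the m/z values are fixed by the acquisition method, so compositions live in the editable definitions CSV |
| isotope abundances | ¹³C 0.0107, ²H 0.000115, ¹⁷O 0.00038, ¹⁸O 0.00205 | IUPAC values, user-editable CSV; oxygen and hydrogen natural abundance are included in the correction by default |
| cluster window K | 5 (deuterium), ≥8 (¹³C) | monitored shifts above base m/z; ¹³C acquisition must reach m8 so the m2/m4/m6 light peaks survive correction |
| labeling window | 14 days | nursing-period labeling |
| response factors | 1.0 per FAME | internal-standard quantification; configurable per analyte |
| qPCR efficiency | exactly 2 | 2^(−ΔΔCt) without efficiency correction |
| t-test | pooled variance | Welch by flag; no multiplicity correction by default, BH by flag |

A note on K: the ratio estimators for p and g are invariant to window
truncation (the triangular solve recovers tracer components 0..K exactly,
up to a common renormalization), but the sum-based quantities — ME and the
MIDA light-peak sum — are biased low/high by the envelope mass outside the
window. At the default operating points (p ≈ 0.03, g ≈ 0.12) this bias is
below 10⁻³ in FNS, negligible against between-animal SE; the exact
noiseless recovery tests therefore use windows spanning the full binomial
envelope (K = N, or 2n for ¹³C).

## Synthetic-data generator

The generator emulates the two study arms end to end with per-animal
ground truth recorded alongside the outputs:

* **Between-animal variation**: FNS ~ Normal(group mean, SE·√n) truncated
  to [0, 1]; composition log-normal around the group mean (default CV
  0.15); precursor enrichment Normal with SD 0.0015. Published group
  dispersion is mean ± SE, so SE·√n is the only dispersion information
  available to translate into a per-animal SD.
* **Measurement noise**: Poisson counting noise on cluster intensities at
  a configurable depth (default 10⁶ total counts; `None` = noiseless
  expected fractions), log-normal multiplicative noise (CV 5%) on peak
  areas, a shared per-run detector scale that cancels under
  internal-standard normalization, and Gaussian Ct noise (SD 0.05 cycles).
* **Default designs**: `nursing_pup_design()` (deuterium, SC fat + liver
  expression, Control FNS 0.400/0.225/0.178 vs FR 0.435/0.241/0.176 for
  palmitate/stearate/oleate, compositions chosen so palmitate synthesis is
  ~3.2 µg/mg/day and Control indices are 0.041/3.23/0.29/0.27, SCD1 folds
  1.65 and 0.28) and `adipocyte_c13_design()` (g 0.118 vs 0.133, FNS
  0.254/0.079/0.015 vs 0.310/0.092/0.017).

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: chromatographic artifacts (co-elution,
baseline drift, peak-integration error), deuterium uptake kinetics and
tracer recycling (steady-state enrichment is assumed), correlated
between-animal composition (analyte amounts vary independently, so index
dispersion is somewhat pessimistic), litter structure, and detector
response differences between FAMEs.

## Numerical and design choices

* Exact triangular solve (`scipy.linalg.solve_triangular`) rather than
  iterative peak stripping; the system is guarded against a vanishing
  monoisotopic component although valid envelopes cannot produce one.
* Convolution truncates then renormalizes; all returned MIDs are
  non-negative and sum to 1 within 1e-9.
* Zero-variance group pairs in the t-test return the degenerate limits
  (t = 0, p = 1 for identical constants) instead of NaN.
* A degenerate group (n < 2) yields a summary without a test, flagged.
* Desaturation indices use raw integrated areas, not isotope-corrected
  abundances, matching how such indices are defined from chromatogram
  peak areas; a zero denominator gives NaN with a warning rather than an
  error.
* Report tables are formatted from stage outputs only; nothing is
  recomputed at formatting time, so reruns are byte-identical.
* Problem sizes in the acceptance script (20 replicate studies of
  n = 6/group per design; 500 null replicates) keep group-mean estimates
  within a fraction of one between-animal SE while the whole script runs
  in well under a minute.

## Known limitations

Stearate FNS mixes true de novo synthesis with elongation of pre-existing
palmitate; the estimator reports the combined fraction (no
elongation-source partitioning). Oleate's deuterium N is an assumption,
not a measured constant. The generator's group means are point
parameterizations — recovering them validates the estimators, not the
biology. Litter-level aggregation is left to a manifest column; rows are
otherwise treated as independent statistical units.
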