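# lipotrace

Stable-isotope tracing of fatty-acid de novo synthesis from GC/MS
selected-ion-monitoring (SIM) data, built for programming-of-obesity style
studies: two groups of animals (or primary adipocyte cultures) labeled with
deuterated water or [U-¹³C]glucose, with palmitate, stearate and oleate ion
clusters monitored as methyl esters (m/z 270, 298, 264).

`lipotrace` implements the complete analysis chain:

1. **Natural-abundance correction.** An observed ion cluster is the
   convolution of the tracer mass-isotopomer distribution (MID) with the
   fragment's natural isotopologue envelope (¹³C, ²H, ¹⁷O, ¹⁸O over all
   atoms, derivatizing agent included). The envelope is computed from the
   fragment's elemental composition, assembled into a lower-triangular
   mixing matrix, and the observed intensities are deconvolved by solving
   the triangular system, leaving molar fractions m0, m1, m2, … that
   reflect tracer only.
2. **Deuterium-water fractional synthesis.** Newly made molecules carry
   Binomial(N, p) deuterium atoms (N = 21 exchangeable positions for
   palmitate; p ≈ 0.03 body-water enrichment). Body-water enrichment is
   estimated from the m2/m1 consecutive isotopomer ratio,
   r = ((N−1)/2)·p/(1−p); the molar enrichment ME = Σᵢ i·mᵢ then gives the
   fraction of new synthesis **FNS = ME / (p·N)**, and absolute synthesis
   as FNS · (µg analyte / mg tissue) / labeling days.
3. **¹³C mass-isotopomer distribution analysis (MIDA).** [U-¹³C]glucose
   yields [1,2-¹³C]acetyl-CoA, so a chain of n acetyl units (8 for
   palmitate, 9 for stearate/oleate) carries k doubly labeled units with
   probability Binomial(n, g) at mass shift 2k. Precursor enrichment g is
   inverted from the M+4/M+2 (or M+6/M+4) consecutive even-peak ratio, and
   FNS is the observed "light" labeled fraction (m2 + m4 + m6) over its
   binomial expectation for a fully turned-over pool.
4. **Lipid profiling.** Percent-of-palmitate profiles, desaturation indices
   (16:1/16:0, 18:1n-9/18:0, 18:1n-7/18:0) and the stearate/palmitate
   ratio from integrated peak areas; absolute µg/mg via a d3-heptadecanoate
   internal standard; SCD1 expression folds by 2^(−ΔΔCt).
5. **Group statistics.** Mean ± SE per group with a pooled-variance
   unpaired t-test (Welch and Benjamini–Hochberg available by flag) and
   paper-style significance markers.
6. **Synthetic studies.** A seeded generator produces complete study
   bundles (raw clusters, peak areas, manifest, Ct values, per-animal
   ground truth) so every stage is testable with known answers.

## Worked example

Simulate a deuterium nursing-pup study (Control vs food-restricted "FR"
offspring, n = 6/group, 14 labeling days at ~3% body-water enrichment) and
run the full pipeline:

```bash
lipotrace all --design nursing-pup-deuterium --out demo --seed 7
```

Selected rows of `demo/results/summary.csv` (mean ± SE per group, pooled
t-test):

```
tissue                           metric   mean_1     se_1   mean_2     se_2        p significance
sc_fat                    fns_palmitate 0.416733 0.009015 0.446336 0.007272 0.028579            *
sc_fat                     fns_stearate 0.227248 0.007641 0.253438 0.009994 0.063998            ¥
sc_fat rate_ug_per_mg_per_day_palmitate 3.560447 0.264803 4.015803 0.229020 0.222554
sc_fat         relative_expression_SCD1 0.000949 0.000016 0.001625 0.000046 6.8e-08            **
```

Reading this: SC-fat palmitate FNS is ~0.42 in Controls vs ~0.45 in FR
(the generator's configured truths are 0.400 and 0.435; each replicate
scatters around them with SE ≈ 0.01), the FR excess is significant at
p < 0.05, palmitate synthesis is ~3.6 vs ~4.0 µg per mg fat per day, and
SCD1 expression is ~1.7-fold higher in FR SC fat (0.001625/0.000949). The
same pipeline runs on the ¹³C culture design with
`--design adipocyte-c13`, where `precursor_enrichment_palmitate` is the
acetyl-CoA enrichment (~0.118 Control vs ~0.133 FR).

The equivalent library calls:

```python
import lipotrace as lt

bundle = lt.simulate_study(lt.nursing_pup_design(), seed=7)
results = lt.run_pipeline(bundle, out_dir="demo/results")
print(results["summary"].head())
```

CSV-level subcommands (`simulate`, `correct`, `fns-d2o`, `fns-c13`,
`profile`, `report`) expose the individual stages on bundle directories;
custom studies are described in a YAML design file (see
`StudyDesign.from_yaml`), and custom analytes/isotope tables in CSV
(`lipotrace.definitions`, `lipotrace.isotopes.IsotopeTable`).

## Limitations

Inputs are integrated SIM intensities and peak areas; chromatographic peak
detection, retention-time calibration and high-resolution isotopologue
fine structure are out of scope. Steady-state precursor enrichment is
assumed over the labeling window. See `docs/methods.md` for the model
details, parameter defaults and numerical choices.
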