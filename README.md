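# qmsp

Simulation and analysis of relative methylation quantification of the
repetitive elements *LINE-1* and *Alu* by bisulfite quantitative
methylation-specific PCR (qMSP).

## The problem

Global DNA methylation is commonly proxied by the methylation level of
the high-copy retrotransposons *LINE-1* and *Alu*, measured by qMSP on
bisulfite-converted DNA: a methylation-specific primer set (MSP)
amplifies only the converted, originally-methylated template, and a
methylation-independent primer set (MIP) amplifies all converted
templates as the normalizing reference. The level is reported relative
to a fully methylated calibrator that defines 100%.

Two technical artifacts can silently corrupt this workflow:

- **PCR amplification bias** — a MIP reference that amplifies one
  template class (originally-methylated vs originally-unmethylated)
  faster than the other distorts recovered methylation, most strongly at
  low methylation, and can flip a cohort's apparent hypo/hypermethylation.
- **Incomplete bisulfite conversion** at excess DNA input, which lets
  unmethylated cytosines read as methylated.

This package implements the full desk-side workflow for detecting and
avoiding these artifacts — standard-curve calibration, formula
selection, calibrator-normalized quantification with CT-cutoff
exclusion, mixture-panel bias assessment, and cohort statistics —
together with a mechanistic bisulfite-qPCR simulator that makes every
stage testable without wet-lab data.

## The model

Each qPCR well holds two template pools: `N_m` copies reading as
methylated and `N_u` reading as unmethylated, amplified per cycle at
fractional efficiencies `e_m` and `e_u` in (0, 1]. The threshold cycle
CT is the unique `t` with

    N_m (1 + e_m)^t + N_u (1 + e_u)^t = Q

for instrument threshold `Q` (closed form when one pool is empty or the
efficiencies coincide; bracketed root-finding otherwise). A standard
curve is the OLS fit of CT on log10(input mass) over a dilution series
of fully methylated DNA; its slope yields the amplification efficiency
`E = 10^(-1/slope) - 1` and anchors the CT cutoff at the assay's limit
of detection. Relative methylation of a sample *s* against calibrator
*cal* is either the Livak ratio

    level = 100 x 2^-[(CT_me,s - CT_ref,s) - (CT_me,cal - CT_ref,cal)]

or the efficiency-corrected Pfaffl ratio

    level = 100 x (1+E_me)^(CT_me,cal - CT_me,s) / (1+E_ref)^(CT_ref,cal - CT_ref,s)

selected per element by the dilution-design rule: regress
dCT = CT(MIP) - CT(MSP) on log10(mass); Livak iff |slope| < 0.1 cycles
per log10(pg) and the slope's two-sided p > 0.05, Pfaffl otherwise.
Samples whose reference replicates all exceed the reference's CT cutoff
are excluded; levels above 100% are legal and never capped.

Bias assessment quantifies a mixture panel of fully methylated and
fully unmethylated DNA (0–100%), regresses recovered on input
methylation, and calls the MSP+MIP pair UNBIASED iff the slope lies in
1 ± 0.1 and |intercept| ≤ 5 percentage points.

## Worked example

`python examples/bias_assessment.py` simulates two mixture panels
(200 pg input, duplicates, CT noise 0.1 cycles) and prints:

```
unbiased reference (L1-Ref):
  input   0.0% -> recovered   0.00%
  input  12.5% -> recovered  12.55%
  input  25.0% -> recovered  27.99%
  input  50.0% -> recovered  52.77%
  input  75.0% -> recovered  80.87%
  input 100.0% -> recovered 100.00%
  regression slope 1.019, intercept +1.10 points, R^2 0.997 -> UNBIASED
biased reference (L1-Ref1):
  input   0.0% -> recovered   0.00%
  input  12.5% -> recovered  59.53%
  input  25.0% -> recovered  70.12%
  input  50.0% -> recovered  83.81%
  input  75.0% -> recovered 107.29%
  input 100.0% -> recovered 100.00%
  regression slope 0.852, intercept +32.83 points, R^2 0.720 -> BIASED
```

The unbiased pair tracks the identity line within noise. The biased
reference (allele efficiencies 0.95 vs 0.80) amplifies the calibrator's
methylated template faster than a sample's unmethylated one, so every
interior level is inflated — a 12.5%-methylated control reads as ~60% —
and the pair is flagged BIASED. The other examples cover standard-curve
calibration and formula choice (`standard_curves_and_formula_choice.py`),
a paired tumour/adjacent cohort (`cohort_comparison.py`), and the
excess-input conversion-failure artifact
(`excess_input_conversion_failure.py`).

A thin CLI mirrors the workflow for shell use:

```sh
qmsp simulate dilution --config scenario.yaml --out dilution.csv
qmsp curve --ct-table dilution.csv --assay L1-Ref --out fit.json
qmsp select-formula --ct-table dilution.csv --msp L1-Me --mip L1-Ref
qmsp quantify --ct-table cohort.csv --config run.yaml --dilution-table dilution.csv --out results.tsv
qmsp bias --ct-table mix.csv --truth mix.truth.csv --config run.yaml --out verdict.json
qmsp cohort --results results.tsv --element LINE1 --reference L1-Ref --design paired --out stats.json
```

CT tables are plain CSV (`sample_id,assay_id,replicate,ct,input_mass_pg,group`,
undetermined CTs as `NA`); configuration is YAML.

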