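# Methods

## The two-pool amplification model

A bisulfite-converted qPCR reaction is modelled as two template pools:
molecules that were methylated before conversion (count `N_m`) and
molecules that were not (`N_u`). Each pool grows exponentially at its
own per-cycle fractional efficiency, so after `t` cycles the amplicon
count is `N_m (1+e_m)^t + N_u (1+e_u)^t`. The threshold cycle (CT) is
the continuous `t` at which this sum reaches the instrument threshold
`Q`. The sum is strictly increasing in `t`, so the root is unique; it
is found with Brent's method bracketed between 0 and the earlier of the
two single-pool crossing times, to well below 1e-9 cycles
(`xtol=1e-12`). When one pool is empty or the efficiencies coincide the
closed form `t = log(Q/N0) / log(1+e)` is used directly.

This primitive is deliberately minimal: no fluorescence baselines, no
plateau chemistry, no per-cycle efficiency decay. CT is the only
observable, because every statistic in the downstream pipeline consumes
CTs alone. Amplification bias is exactly the case `e_m != e_u` on a
methylation-independent (MIP) primer set; a methylation-specific (MSP)
primer set sees the unmethylated pool only through its
`cross_reactivity` weight (default 0).

Initial pool sizes for a sample with methylated fraction `m` are

    total = input_mass_pg x copies_per_pg x bisulfite_recovery x template_fraction
    N_m   = total x (m + (1 - m) x conversion_failure)
    N_u   = total - N_m

`conversion_failure` is the fraction of unmethylated molecules whose
cytosines escape deamination and therefore read as methylated. It can
be a constant or an increasing function of input mass; the bundled
saturating curve `f(mass) = f_max x mass / (mass + K)` (defaults
`f_max = 0.15`, `K = 5000 pg`) emulates the degradation of conversion
quality at excess DNA input. Note the mechanism only acts on
unmethylated molecules: a fully methylated control is insensitive to it
by construction, so the input-mass artifact is demonstrated on
partially methylated samples (see `examples/excess_input_conversion_failure.py`).

## Default parameters and why

| parameter | default | rationale |
|---|---|---|
| copies_per_pg | 0.303 genomes/pg x 1.5e5 (LINE-1 5'UTR) or 1.1e6 (Alu) copies/haploid genome | repeat-family copy numbers of the human genome; only shifts CT intercepts, no pipeline statistic depends on them |
| threshold `Q` | 1e13 copies | places CTs for picogram-scale repeat-element inputs in the instrument-typical 15–35 cycle range (a 12.5 pg LINE-1 input crosses near CT 30, matching realistic cutoff magnitudes) and exceeds any realistic initial copy number, including multi-nanogram Alu inputs |
| max_cycles | 40 | standard real-time PCR run length; CTs beyond it are UNDETERMINED |
| ct_noise_sd | 0.1 cycles | typical instrument replicate repeatability |
| n_replicates | 2 | duplicate wells, the usual clinical-assay design |
| template_fraction | 2/20 | 2 µL of a 20 µL bisulfite eluate per reaction |
| bisulfite_recovery | 1.0 | recovery losses rescale all CTs equally and cancel in calibrator-normalized ratios |
| dilution masses | 1000, 250, 62.5, 15.625, 3.125 pg | the standard-curve design |
| mixture grid | 0, 12.5, 25, 50, 75, 100 % | defined-methylation controls spanning the full range |
| mixture / cohort input | 200 pg | the low-input regime in which conversion is complete |

Random numbers: every simulated well draws its Gaussian CT noise from a
substream keyed on (seed, sample index, CRC32 of the assay id). This
makes seeded runs bit-reproducible, keeps noise independent of plate
layout order, and — importantly — keeps two assays' series independent
even when simulated in separate calls under one seed. (With plain
per-sample streams, an MSP and a MIP dilution series simulated
separately would share identical noise draws and their dCT regression
would be artificially exact.)

## Standard curves, efficiency, formula selection

The standard curve is an ordinary least-squares fit of CT on
log10(mass) over the dilution series of fully methylated DNA
(scipy.stats.linregress); undetermined wells are excluded from the fit
but counted, and a mass with any undetermined replicate cannot anchor
the limit of detection. Efficiency is reported as
`100 x (10^(-1/slope) - 1)` percent; a non-negative slope flags the fit
and leaves efficiency undefined.

The CT cutoff is the fitted line's predicted CT at the
limit-of-detection mass (default: the smallest mass at which every
replicate amplified, overridable within the fitted mass range). The
fitted prediction is used rather than the observed mean at that mass
because it is less noise-sensitive; both are reported.

Formula selection regresses per-mass dCT = mean CT(MIP) − mean CT(MSP)
on log10(mass). Livak is chosen iff |slope| < 0.1 cycles per log10(pg)
and the slope's two-sided p-value exceeds 0.05; otherwise Pfaffl. Both
thresholds are configurable. Replicate CTs are averaged per mass before
the regression, so one dCT enters per input amount. When the per-mass
dCTs are exactly collinear the slope t-statistic is 0/0; the p-value is
then taken as 1 (a zero slope with zero residual is maximal evidence of
flatness). Note the rule's operating characteristic: with a truly
shared efficiency the dCT slope is null, so the p-condition trips at
exactly its alpha = 0.05 false-positive rate and Livak is selected in
~95% of noisy replications — not more.

A modelling consequence worth stating: the Livak ratio is exact only at
perfect doubling (E = 1). Two assays sharing E = 0.9 pass the
flat-dCT rule, yet Livak then recovers `m^(ln2/ln1.9)` rather than `m`
for interior methylation fractions; the efficiency-corrected Pfaffl
ratio with the fitted efficiencies is exact for any allele-equal
efficiencies. The noise-free identity tests therefore exercise Livak at
E = 1 and Pfaffl elsewhere.

## Quantification and exclusion

Replicates aggregate by the mean of determined CTs at or below the
assay's cutoff. A sample x assay aggregate is excluded only when *no*
replicate passes — one passing replicate is used alone and flagged
(`partial_*`) for audit. Exclusion of a result row is driven by the
reference assay (the printed rule); a sample whose MSP signal is absent
while its reference is detected reports 0% with status ZERO_SIGNAL,
the limit of the ratio as methylated copies go to zero. A missing or
undetermined calibrator aborts the run. Cross-normalization (LINE-1 by
the Alu reference and vice versa) produces one result row per declared
MIP reference. Levels are never capped at 100%.

## Bias assessment

The mixture panel's fully methylated control *is* the calibrator — the
same material in the same wells — so the panel is emitted with a single
100% sample named `calibrator`, and its self-referenced recovered level
is exactly 100. This matters quantitatively: quantifying the panel
against a separate noisy calibrator would multiply every recovered
level by a shared run-scale factor with ~10% sd (CT noise 0.1,
duplicates), and the recovered-vs-input regression slope would inherit
that factor, destroying the verdict's specificity. With
self-calibration the verdict (slope in 1 ± 0.1, |intercept| ≤ 5 points)
is both specific (0/200 false positives at allele-efficiency gap 0) and
sensitive (200/200 detections at gap 0.10) under duplicate wells and
CT noise sd 0.1.

Sign law, verified against the accumulation oracle: under a fully
methylated calibrator, recovered exceeds input at every interior level
iff the reference amplifies the calibrator's (methylated-origin)
template faster than the sample's unmethylated one (`e_meth > e_unmeth`
on the MIP). The *relative* inflation `recovered/input` grows
monotonically as input methylation falls; the absolute gap does not —
it peaks at intermediate levels, because it is the product of a growing
ratio and a shrinking level. The 0% point enters the regression as
recovered 0 via the ZERO_SIGNAL convention (configurable to drop).

## Cohort simulation and statistics

A cohort group is `n` subjects with methylation
`clip(mean + sd x z, 0, 1)`, `z` standard normal. In paired designs the
subject effect `z` is shared across arms (common random numbers), so
arm means differ while subject `i` is the same individual in both arms;
with zero noise and equal means the paired comparison is exactly null.
Each sample is run with all declared assays (four reactions in the
standard two-element design) in duplicate.

Group comparisons gate on Shapiro–Wilk normality at alpha = 0.05
(applied to the paired differences for paired designs): normal →
t-test (paired/unpaired), non-normal → Wilcoxon signed-rank /
Mann-Whitney U. More than two groups use Kruskal–Wallis; age
association uses Spearman's rank correlation. All p-values are
two-sided; no multiple-testing correction is applied. Constant paired
differences of zero are reported as a degenerate comparison with p = 1.
The gate's realized type-I error under a normal null at n = 30 stays
within 0.06 at nominal 0.05 (property-tested over 2000 replications).

## Error propagation under replicate noise

With CT noise sd 0.1 and duplicates, the ddCT of a quantified sample
carries sd `sqrt(4 x 0.1^2 / 2) ~ 0.141` cycles, i.e. ~9% relative
error on the level at E = 0.9. Two consequences shape the tests: the
error in percentage points scales with the level itself (a ±5-point
band is a 2-sigma statement at 25% methylation but only ~0.5 sigma at
100%), and the in-run calibrator contributes a scale error shared by
all samples of a run, which averages out only across independent runs.
Recovery claims are therefore asserted as means over seeded runs, and
coverage claims per methylation level.

## Problem sizes

The test suite and acceptance script run entirely from simulation at
desk scale: dilution series of 5 masses x 2–3 replicates, mixture
panels of 6 levels x 2 assays x 2 replicates (200 seeded panels per
verdict operating characteristic), cohorts of up to 100 pairs x 50
seeded replications, and 100–1000 random instances for the solver
oracle and property fuzzing. The full suite completes in well under a
minute on one core.

## Known limitations

- No fluorescence-trace simulation; CT is the atomic observable, so
  baseline/threshold-setting artifacts of real instruments are out of
  scope.
- No sequence-level model of primers or bisulfite chemistry: bias is a
  two-number efficiency differential, not a primer-annealing model.
- Efficiencies are constant across cycles (no plateau); realistic
  late-cycle saturation would compress high CTs slightly.
- The cohort generator draws Gaussian subject heterogeneity; real
  cohorts are skewed and heavy-tailed, which the normality gate will
  route to rank tests, but effect-size calibration against real cfDNA
  distributions is not attempted.
- Passing tests demonstrate internal consistency of the workflow under
  the stated noise model, not the behaviour of any particular primer
  set on real samples.
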