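# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions that were genuinely open.

## Genome binning

Copy-number analysis operates on fixed-width genomic bins (default 1 Mb,
the standard resolution for shallow single-cell whole-genome sequencing).
Two stock genomes are provided: a 5-chromosome, 500 Mb toy genome used
throughout the tests and analyses (small enough that a 50-cell cohort
simulates, calls and scores in well under a minute), and an hg38-like
table with GRCh38 chromosome lengths for realistic-scale runs. The genome
length in Mb, `L`, computed from the bin extents, is the denominator of
the structural score.

## Karyotype simulation

A cohort is a mixture of clones. Each clone has a base ploidy and a list
of copy-number events drawn from a six-kind grammar: whole-chromosome
gain/loss, arm-level gain/loss, and focal amplification/deletion with an
explicit span. The grammar expresses the four archetypes recurrently seen
in patient-derived ovarian cancer karyotypes: whole-chromosome
aneuploidies, heavily rearranged chromosomes (many within-chromosome
transitions), monosomies (whole-chromosome loss to a single copy) and
tetrasomies (whole-chromosome gain to four copies). Arm boundaries are
taken at the chromosome midpoint — the toy genome carries no centromere
annotation, and nothing downstream depends on the split point.

Cell-to-cell variability is modelled as *mis-segregation*: per cell and
per chromosome, with a configurable probability, the whole chromosome
gains or loses one copy with equal sign probability. This is the simplest
generative mechanism producing single-cell scatter around a clonal
karyotype; real CIN also produces segmental changes, chromothripsis and
selection effects that this generator deliberately does not model. No
quantitative per-division mis-segregation rate is established for these
cultures; preset rates (0.02 per chromosome per cell for the noisy
presets, 0 for the clonally pure whole-chromosome preset) were chosen once
to give visible but subordinate cell-to-cell scatter.

The **tetrasomy preset is a single tetrasomic chromosome** (chr1 at four
copies, mean ploidy 2.48). This is an identifiability constraint, not an
aesthetic one: read counts constrain copy number only up to a scale, so a
profile is only recoverable if its mean ploidy is closer to the caller's
default than the mean of any harmonic (see below). On the 500 Mb toy
genome, tetrasomic profiles with more than ~165 Mb at four copies have a
halved harmonic closer to diploid and are unrecoverable in principle by
any ratio-based caller with a diploid prior.

## Read-count emission

Counts per bin are negative-binomial with mean `state × reads_per_copy`
(a small `background` mean, default 1, where the state is zero) and
variance `mean·(1 + dispersion·mean)`; dispersion 0 reduces to Poisson.
Negative-binomial overdispersion is the standard model for shallow
sequencing counts. GC and mappability bias are deliberately not simulated
(and the caller correspondingly applies no bias correction). A
`deterministic` flag emits the rounded means exactly, which gives the
caller a noiseless oracle case.

## Copy-number state calling

The published analyses used an HMM-based caller; reimplementing it is out
of scope here. The substitute preserves the same output contract (integer
cells-by-bins state matrix) with transparent, testable behaviour:

1. per cell, bin counts are normalised to mean 1;
2. a scale (the cell's mean copy number) is chosen by grid search over
   [1, max_state] in steps of 0.05, minimising the mean squared distance
   of the scaled values to their nearest integers; scales whose implied
   states exceed `max_state` are excluded (otherwise a harmonic multiple
   of the true scale can win with clipped states); exact ties break toward
   the scale whose implied mean ploidy is closest to `default_ploidy`;
3. states are the nearest integers, clipped to [0, max_state];
4. the *harmonic family* of the called profile — the profile times any
   integer, or divided by any common factor of its states, all of which
   fit ratio-only data equally well — is resolved toward the member whose
   mean ploidy is closest to `default_ploidy`. This generalises the tie
   rule in step 2 to noisy data, where the lower harmonic otherwise
   always wins the residual comparison (its noise amplitude is smaller);
   a uniformly tetraploid (genome-doubled) cell therefore calls as
   diploid unless `assume_ploidy` overrides the search;
5. a median filter (default window 3) smooths within each chromosome,
   never across a chromosome boundary. A median over an odd window can
   only output a value present in that window, so smoothing introduces no
   foreign states.

Cells below a total-read threshold are excluded from the state matrix but
always appear, flagged, in the per-cell QC report together with the fitted
scale and residual. No automated analogue of manual curation is attempted.

On the archetype presets at 100 Poisson reads per copy per bin, bin-level
accuracy is ≥ 99% for all four presets (50 cells); accuracy averaged over
the presets rises monotonically over 10/50/100 reads per copy. At 50 cells
the per-preset curves are dominated by the 2–3 cells whose mis-segregated
profiles are scale-confounded, so monotonicity is a property of the
aggregate, not of each preset individually.

## Karyotype scores

* **Aneuploidy** `A = mean_{cells,bins} |s − p|`: mean absolute deviation
  from the euploid ploidy `p` (default 2). Zero iff perfectly euploid.
* **Heterogeneity** `H = mean_bins (1 − Σ_s f_s²)`: mean per-bin
  Gini–Simpson diversity across cells — the probability that two cells
  drawn with replacement differ at a random bin. Bounded in [0, 1]; zero
  iff all cells are identical; requires ≥ 2 cells.
* **Structural** `S = T/(L·N)`: `T` counts adjacent-bin state differences
  within chromosomes over all cells (chromosome boundaries never counted),
  `L` is the genome length in Mb, `N` the number of cells. Adding one
  transition to one cell raises `S` by exactly `1/(L·N)`, and "per Mb" is
  per Mb of total genome covered by the binning, not per chromosome.

The aneuploidy and heterogeneity formulas are this package's fixed
definitions: the upstream literature delegates them to a tool without
restating them, so the simplest statistics matching the verbal semantics
were chosen; exact numerical parity with that tool is not claimed. All
three scores are invariant to permuting cells or chromosomes and to
duplicating every cell.

## Mitotic cohorts and fate profiling

A fate table has one row per filmed cell: duration in minutes from
nuclear envelope breakdown to anaphase onset or mitotic exit, a set of
mitotic-error annotations (anaphase bridge, lagging chromosome,
multipolar, cohesion fatigue, premature anaphase, unaligned anaphase,
cytokinesis failure, chromosome ejection — the last used by 3D cultures,
sharing one schema with 2D), and a terminal fate (division, slippage,
death in mitosis, death in interphase, never entering mitosis, fusion).

The simulator draws a category per cell from a categorical mixture — the
category is "normal", one error annotation (fate: division), or a
terminal fate — and a duration from that category's log-normal.
Log-normals were chosen because observed mitotic-duration distributions
are right-skewed; no particular family is established. Real annotation
data has correlated multi-error cells and condition-dependent censoring
that the generator does not emulate, so passing tests demonstrate correct
bookkeeping and statistics, not biological realism of the mixtures.

Summaries report the sample mean, unbiased variance, adjusted
Fisher–Pearson skewness (an all-equal sample reports skewness 0 with a
`degenerate` flag), median, interquartile range and 10–90% range, with a
warning (not an error) below the recommended 100-cell minimum. The
skewness field stands in for regression-based skew diagnostics reported
by commercial statistics packages, which are not computable from the
duration data alone; the difference is intentional and documented here.
The frequency-distribution regression fits relative frequency against bin
midpoint (default 10 min bins) over occupied bins by ordinary least
squares. Fate compositions report terminal-fate percentages over all
records and error percentages over mitotic records (those that entered
mitosis — slippage and death-in-mitosis cells count in this denominator);
the pie triple is normal / anaphase-bridges-only (annotation set exactly
{anaphase_bridge}) / all other defects combined, and sums to 100 exactly.

## Growth curves, doubling time and IC50

The growth model is exponential `N(t) = N0·2^(t/Td)` or, with a carrying
capacity, logistic with the same early doubling time. A drug at
concentration `c` retains the fraction
`f(c) = bottom + (top − bottom)/(1 + (c/EC50)^hill)` of growth, applied to
the **net growth increment**: `N_c(t) = N0 + f(c)·(N_vehicle(t) − N0)`.
This keeps `N_c(0) = N0` (a drug cannot change the seeding density) and
makes the curve AUC exactly affine in `f(c)`, so the AUC-versus-
concentration relation is itself a four-parameter logistic with the same
EC50 and hill slope — the concentration at the half-maximal suppression
of AUC *is* the programmed EC50, which is what makes programmed-truth
recovery a well-posed test. Scaling the growth *rate* instead would break
that correspondence (the AUC of an exponential is convex in the rate).
Measurement noise is multiplicative log-normal with unit mean and the
stated CV.

Doubling time: values are normalised to the first timepoint (the
reference the readout is normalised to is not otherwise determined) and
log2-transformed; in automatic mode every contiguous window of at least
`min_window` (default 5) points with positive slope is fitted by OLS and
the window maximising r² (the widest on ties, with r² compared at 12
decimals) is selected; doubling time is the inverse slope. A curve with
no positive-slope window raises a "no log phase" error. Manual log-phase
selection by eye is replaced by this max-r² rule.

Dose response: AUCs (trapezoidal) are normalised to percent of the
vehicle AUC — the vehicle is used only for normalisation, never as a fit
point — and fitted with a four-parameter logistic in log10 concentration
by nonlinear least squares (initialisation: top = max, bottom = min,
|hill| = 1 falling, log IC50 at the concentration nearest the half-range
response; bounds: top, bottom ≥ 0, hill sign free). A response spanning
less than 10% of vehicle raises "no dose effect"; non-convergence returns
a flagged fit with no IC50. Whether AUC normalisation happens before or
after plotting against concentration is immaterial to the IC50 (the fit
is invariant to jointly rescaling AUCs and vehicle), and the
normalise-first order is fixed here.

## Variant classification

With stromal cells as the germline baseline, each locus with tumour and
stromal ref/alt read depths is classified in this fixed order:
insufficient depth (either compartment < 20×) → ambiguous; variant absent
in both → reference; stroma heterozygous (allele fraction 0.25–0.75) and
tumour homozygous alt (≥ 0.90) → LOH; stroma matching the reference,
tumour carrying the variant (allele fraction ≥ 0.10 and ≥ 4 alt reads)
with a one-sided Fisher exact test on the 2×2 allele-count table
significant at α = 0.05 → somatic; variant present in both with matching
genotype class → germline; anything else → ambiguous. The Fisher p-value
is reported for every locus, and somatic is never returned at p ≥ α.

All thresholds are conventional values fixed by this package — the
upstream description defers to its calling tool's internals. Discordant
or low-depth sites are deliberately left ambiguous rather than guessed.
The paired simulator draws depths Poisson around the target and alt
counts binomially: germline at a shared fraction of 0.5 or 1.0, LOH at
stroma 0.5 / tumour 1.0, somatic at stroma 0 with tumour fraction uniform
in [0.25, 0.75] (clearly present at the default thresholds while spanning
sub-clonal to clonal). At 10,000× depth classification recovers all
labels; at 30× per-class recall exceeds 90%. Database (e.g. COSMIC)
annotation of calls is out of scope.

## Cohort rates

The establishment rate is reported per sample (established / attempted
culture attempts) and per patient (patients with ≥ 1 established model /
patients with ≥ 1 attempted sample). The bundled manifest encodes the
programme's bookkeeping — 312 collected samples from 135 patients, 290
attempts, 76 established models across 44 patients, with every patient
having at least one attempt, so the patient denominator is all 135 —
yielding 26.2% and 32.6%. Sample-to-patient assignments in the manifest
are synthetic placeholders; only the marginal counts carry meaning, and
both rates depend on the counts alone.

## Problem sizes and determinism

Simulated cohorts default to 50 cells on the 500 Mb toy genome, 2000-cell
mitosis cohorts, 3-replicate growth plates at 9 half-log concentrations,
and a few hundred variant loci: sizes at which every statistic under test
is stable at the stated tolerances while the whole suite runs in seconds.
Every generator is a pure function of its parameters and an integer seed
(NumPy `default_rng`); rerunning any scenario with the same seed
reproduces outputs byte-for-byte.

## Known limitations

* The state caller is a quantizer, not an HMM: it has no positional prior,
  no breakpoint refinement below bin resolution and no subclone
  reconstruction, and genome-doubled cells are fundamentally
  scale-confounded with diploid ones (resolved by the default-ploidy
  preference or the `assume_ploidy` override).
* Read-count simulation starts at binned counts: no FASTQ/BAM emission,
  no GC/mappability structure, so the caller's accuracy figures do not
  speak to alignment- or bias-driven errors in real libraries.
* The aneuploidy/heterogeneity definitions match the verbal semantics of
  the published scores but are not guaranteed numerically identical to
  the original tool's output.
* Fate and duration mixtures are independent per cell; lineage structure
  (daughter-cell correlations) is not modelled.
* The dose-response machinery assumes a monotone response; biphasic
  responses will fit poorly (flagged by residual, not detected
  specially).
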