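# Methods

This note records the modelling assumptions behind `mesasim`, the defaults
and why they were chosen, the numerical choices that affect results, and
what the synthetic testbed does and does not establish about real data.

## The physical model

**Fragments.** Input DNA is modelled as per-copy random tilings of the
genome: each genome copy is cut into abutting fragments whose lengths are
either fixed or truncated-normal (default 52,400 ± 5,706 bp, a
high-molecular-weight gel-plug prep; minimum 100 bp). The fragmentation
phase is random by default — sheared DNA has no genome-aligned phase — which
is what makes the fragment covering any given point uniformly positioned
over it and hence produces the triangular coverage kernel. An `aligned`
phase option tiles from coordinate zero (exactly G/L fragments), useful for
exact-conservation checks. Chromosome ends truncate their terminal
fragments, so the realised mean length is ~L·(1 − L/G) — at desk scale a
~1% effect.

**Encapsulation.** The number of fragments per droplet is
Poisson(λ_t + λ_b) with multinomial type labels, equivalent to independent
Poisson target/background streams — the standard digital-PCR assumption.
Target fragments are, by definition, those that fully contain a probe
amplicon: a fragment missing a primer site cannot amplify, so
boundary-touching fragments are negative. At large droplet counts over
desk-scale fragment pools, sampling is with replacement (flagged in the
output); expectations are unchanged.

**Detection and sorting.** A droplet fluoresces if it contains a target
fragment and its PCR did not drop out (`pcr_failure_rate`). Amplitudes are
class-conditional normals; failed positives draw from the negative class.
Emulsion instability merges a fraction of droplets pairwise before
screening: a merged droplet has the union of contents, the maximum of the
two amplitudes and the summed width. Each droplet is selected for merging
with probability `merge_rate/(1+merge_rate)`, so the merged share of final
droplets is ≈`merge_rate`. Merging a positive with a background-only
droplet carries that background through the sort — one of the two
mechanisms (with false sorts) by which collected purity falls below 100%.
The sorter collects droplets passing an amplitude threshold and width gate,
plus gate-negative droplets at `false_sort_rate`. The false-sort rate that
yields a given collected droplet purity is available in closed form
(`solve_false_sort_rate`); a 2.3%-positive emulsion reaches 87.6% collected
purity at a false-sort rate of 0.33%.

**Post-sort chemistry.** TaqMan amplicons produced in detected droplets
(default 200 molecules each; only the product with `residual_amplicon`
is observable) are removed by the UDG step — `residual_amplicon = 0` by
default. Skipping removal puts a hard coverage spike exactly over the
amplicon; the Monte-Carlo cross-checks of the analytic fold formulas
include the removal step, as the workflow does. WGA is modelled abstractly
as per-fragment copy numbers `max(1, round(X))` with X lognormal rescaled
to mean 1; `sigma_wga` (default 0.8) controls dispersion and is the main
driver of duplicate reads.

**Sequencing.** Single-end 50 bp reads with truth coordinates — no aligner
is involved, so alignment-rate statistics of real libraries are out of
scope by design, and an optional FASTQ export exists for users who want to
run a real aligner. Source molecules are chosen proportional to
copy_number × eligible start positions. (A pure copy-number weighting was
considered; it is indistinguishable for equal-length fragments — the regime
the model targets — but breaks per-base uniformity for a whole-genome
reference pool of unequal-length molecules, so the position-weighted form
is used.) Hom variants are written onto both haplotypes, het variants onto
haplotype 1 (a fragment's haplotype is its genome-copy id mod 2);
sequencing errors are i.i.d. substitutions (default 10⁻³). Paired ends and
position-dependent quality are not modelled.

## Coverage statistics

Windows follow the 20 kb / 2 kb-step sliding convention; tail windows
shorter than the window are dropped, not rescaled, and the background
threshold is the mean + 3 × sample SD (ddof = 1) of window means after
excluding given intervals. The differential scan reports maximal runs of
consecutive windows at or above a threshold in one track and below it in
the other. Two threshold roles are deliberately distinct:

* the **mean+3SD ceiling** answers "is this window significantly above
  background?" — by construction ~0.1% of background windows graze it;
* the **differential-scan threshold** answers "which regions are
  enriched?", and defaults to **2× the reference ceiling**: a level no
  background fluctuation plausibly reaches while enriched loci clear it
  several-fold, mirroring the practice of scanning at a round number far
  above the background ceiling.

Fold enrichment is the mean depth of the probe-centred window over the
genome-wide mean, which **includes** the target regions — this biases folds
conservatively downward and keeps the denominator independent of any locus
annotation. Uniformity counts bases *at or above* each depth by default
(an `at_or_above=False` toggle gives the strict reading).

**FWHM.** The fragment-size proxy is the full width at half maximum of the
coverage peak after subtracting the genome-wide mean, computed by default
on the 20 kb moving-average profile with linear interpolation at the
crossings. A box filter of width w widens a triangular peak's FWHM by
exactly w/4 (the profile is locally linear at the half-max crossings, but
the peak itself is flattened), so that amount is subtracted by default;
the correction is exact for triangles with L > w and approximate
otherwise, and a raw-profile mode avoids it entirely. The genome-mean
background subtraction assumes the peak is a small fraction of total
coverage; when targets dominate the genome (tiny test chromosomes) the
estimate biases low by roughly L·(background/peak)/2.

## Analytic formulas

The closed forms assume single-locus, fixed-length fragments and treat the
amplicon as a point (100 bp ≪ 52 kb, error O(amplicon/L)). The fold
formula is implemented with the finite-loading factor
T = λ_t/(1−e^(−λ_t)) and an `n_targets` divisor for multiplexed panels
(target molecules split evenly across loci); with T = 1 and one target it
reduces to the forms quoted in the README. Purity is defined over molecule
counts and fold enrichment over base coverage; the conversion factor L
cancels when all molecules share one length, which is why the two scales
can be compared directly in the fixed-L cross-checks. These formulas are
ideal-workflow upper bounds: WGA dispersion, merging and false sorts all
pull measured enrichment below them, so no claim is made that any
particular measured fold should equal the formula at full experimental
scale.

The λ defaults are back-calculated from observable positive fractions
(λ = −ln(1−f); e.g. f = 1.3% → λ = 0.013085) because the dilution itself
(genome equivalents per droplet) is not a directly printed quantity.
When `lambda_b` is not given, it is derived from whole-genome input DNA at
fixed molar composition: λ_b = λ_t·(G/L − n_targets)/n_targets.

## Variant calling

Candidate sites need ≥ 2 non-reference bases; quality is
−10·log₁₀ P(X ≥ alt_count) with X ~ Binomial(depth, ε) — the chance the
alternate support is sequencing error alone — capped at 3000; a call PASSes
only with depth ≥ 10 and quality ≥ 10, with sub-threshold sites labelled
LowDepth/LowQual. Genotypes use the common heuristics (het for alt
fraction in [0.2, 0.8), hom-alt ≥ 0.8). Duplicates are removed before
counting by default (toggleable); the coverage figures use raw reads by
default since duplicate handling there is a reporting choice, not a filter.
This is deliberately not a full Bayesian caller, and no numeric agreement
with bcftools' quality model is claimed — the object of study is the
filter thresholds and the effect of enrichment on sensitivity.

## Study conditions and scale

The default synthetic system is a 5 Mb + 1 Mb two-chromosome genome with
five 100 bp probe amplicons on the larger chromosome (windows 50–200 kb,
spacing ≥ the largest window), planted SNPs at 10⁻³/bp with 50% het, i.i.d.
uniform base composition (the enrichment math is
sequence-composition-independent). Presets: `test` (2.5 Mb genome, 10⁵
droplets, 1.5×10⁵ reads; full pipeline in a few seconds) and `desk` (6 Mb,
10⁶ droplets, 3×10⁵ reads). The desk read count gives a genome-wide mean
depth of ~2.5×, chosen so the reference sample sits near the depth floor
while enriched loci reach tens-fold coverage — the regime in which targeted
enrichment is scientifically interesting. Every stochastic stage draws
from a named substream of one global seed, so any stage re-run reproduces
bit-identically.

What passing tests show — and don't. The simulator's agreement with the
closed forms (within 3 SE over ≥ 20 seeds) validates the Poisson loading,
sorting and kernel logic, and the qualitative reproductions (folds
decreasing with window size, only planted loci in the differential scan,
far more in-window PASS calls after enrichment) show the analysis stack
measures what it should on data whose truth is known. They do not
establish performance on real libraries: transposase insertion bias,
PCR/optical duplicate structure, alignment and mappability artifacts,
indels and structural variation, and reference-database concordance are
all outside the model.

## Known limitations

* Background droplet occupancy is independent of target occupancy; true
  co-encapsulation correlations from DNA clumping are not modelled.
* WGA is a per-fragment copy-number draw, not a branching-process MDA
  model; chimeric amplification artifacts are absent.
* The FWHM smoothing correction assumes a triangular peak; heavy-tailed
  fragment-length mixtures will bias the corrected estimate slightly.
* Sorter width gating is modelled but droplet-size/fluorescence
  correlations are not.
* Multi-allelic sites and indels are not called.
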