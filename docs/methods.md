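# Methods

This note records the models, parameter choices and numerical conventions
behind `msh3rep`, and what the synthetic-data experiments do and do not
establish about real data.

## The locus model

The amplicon is modelled as `left_flank + units + right_flank` on the MSH3
coding strand, 1-based inclusive coordinates. The rendering of the six-unit
allele (6a) with all flanking variants in the reference state is the locus
reference frame; variant offsets are stated in that frame and shifted by
9·(k − 6) for a k-unit allele when they lie 3′ of the repeat. Variants inside
the repeat are rejected by construction.

The default locus is a synthetic stand-in. The real unit DNA sequences and
variant offsets are not published as machine-readable sequence, so the
package ships five 9-bp units built from Pro/Ala codons
({CCA,CCT,CCG,GCA,GCT,GCG}), pairwise distinguishable at ≥ 1 position, with
U1 as the reference unit (6a = 6 × U1); 250-bp seeded random flanks (fixed
seed 58314 — the default locus is one object, not a random family); and
seven flanking variants (six SNPs, one 1-bp deletion), three of them 5′ of
the repeat. Variant positions are snapped to sites whose base differs from
both neighbours so that a 1-bp indel has an unambiguous alignment placement.
The 16-allele catalogue spans 3–9 units with 3a, 6a, 7a and 8a present; 3a is
[U1, U2, U1] where U2 differs from U1 at one base, which is exactly what
makes the 3a-vs-6a misalignment produce a single fully-supported apparent
substitution inside the repeat rather than only a length artefact. Real
locus descriptions load from the same JSON schema.

## Alignment

Reads are aligned glocally (read end-to-end, reference ends free) rather
than locally, so repeat-length evidence cannot be soft-clipped away. The
aligner is Gotoh's three-state affine-gap DP with integer scores; a gap of
length L costs `gap_open + L·gap_extend`. Defaults: match +2, mismatch −3,
gap_open −12, gap_extend −1. Two presets exist because the misalignment
artefact manifests differently under each: `SUBSTITUTION_FAVORING`
(gap_open −100000) forces phantom substitutions, `INDEL_FAVORING`
(mismatch −6, gap_open −4) forces a unit-multiple phantom deletion.

Traceback is deterministic: at co-optimal cells the aligned (diagonal) move
is preferred over an insertion (up), then a deletion (left); among
co-optimal end columns the leftmost is taken; when closing a gap run,
re-entry into the aligned state is preferred. Scores are int64; the DP is
numba-compiled. An optional band restricts diagonals to a corridor around
the read/reference length difference (default half-width 25 in the
genotyper); this is exact for substitution-only reads with ≤ 25 bp of
unexpected indel drift and is what makes 16-reference classification of
~550-bp reads affordable. Correctness is checked against an independent
top-down enumeration oracle on random small instances.

## Read merging and QC

Pairs are merged by the best ungapped overlap (≥ 10 nt): lowest mismatch
fraction wins, ties to the longer overlap; overlap disagreements resolve to
the higher-quality base (ties to the forward base). Pairs whose best overlap
exceeds a 10% mismatch fraction stay unmerged and are excluded from
genotyping. QC reports the fraction of bases at or above Q30 per file and
pooled, passing above 80% — the acceptance rule for this assay.

## Genotyping and phasing

Each merged read is scored against every allele rendering in the bank; the
best-scoring allele wins, and co-optimal ties are never resolved silently —
such reads are flagged ambiguous and excluded from support counts. The
diploid repeat genotype is the top one or two allele classes with support
≥ `min_hap_frac` (default 0.2) of unambiguous reads; fewer than `min_depth`
(default 30) unambiguous reads is a no-call, and three classes above
threshold raises a contamination flag. Flanking variants are phased
read-backed: one merged read spans the whole amplicon, so each read
contributes a full variant-allele vector tied to its repeat allele. For
repeat heterozygotes each haplotype takes the per-variant majority over its
read class; for repeat homozygotes reads are partitioned on their complete
variant vectors and the top two vectors (second ≥ `min_hap_frac`) become the
haplotypes. Per-subject SAM against the best allele reference is emitted so
homozygote haplotypes can be confirmed in any viewer.

`artefact_scan` is the phantom-variant demonstrator: it aligns reads to a
single chosen reference and piles up substitutions/indels supported by
≥ 50% of covering reads. Same-allele scans are empty; cross-length scans
reproduce the apparent SNP (or 27-bp deletion) inside the repeat; bank-based
classification resolves the artefact. The exact phantom coordinate is a
property of the unit sequences and is therefore locus-dependent; on the
default locus it is position 266 (substitution-favoring) / 293 (default
scoring).

## Synthetic data

Read geometry follows the assay: 600 cycles split 400 nt forward / 200 nt
reverse over a ~530–580 bp amplicon, so merged reads span the amplicon.
Errors are i.i.d. substitutions (default 0.5%); indel sequencing errors are
deliberately not simulated — the artefact under study is an alignment
phenomenon, and substitution-only errors keep the truth recoverable.
Qualities follow a two-piece model (plateau Q38, 3′ decay to Q28/Q30,
per-base Gaussian sd 3) and are independent of the error process.

The instability process draws per-read gains ~ Poisson(rate · age ·
progenitor/100), i.e. expansion-biased, increasing in age, rate and
inherited length. The functional form is a declared modelling choice, not an
empirical claim. Default base rate 0.05 per year (at progenitor length 100)
keeps the progenitor peak populated across the simulated age range so the
HD ratio index stays defined; 300 reads per distribution.

Cohorts draw two haplotypes i.i.d. from a frequency table (Hardy–Weinberg;
an inbreeding knob exists, default 0). The default table has 12 haplotypes:
6a most common, 3a second (allele frequency ≈ 0.15), the three 5′ SNPs alt
on all and only 3a haplotypes (complete LD by construction), and the 3a
background split into two haplotypes differing only at one 3′ SNP —
mirroring the observed Hap1/Hap2 pair. `build_haplotype_table` constructs
tables for arbitrary allele/variant frequencies and r² targets, raising an
error that names the D′-max bound when a target is infeasible. Phenotypes
are linear-additive with Gaussian noise: onset +1.05 y per 3a copy (the
headline scenario), progression −0.52 units per copy (HD), expansion rate
−0.02 per copy, expression effects on *MSH3*/*DHFR*; DM1 adds CCG-like
interruptions (prevalence 0.08) that delay onset and slow expansion. The HD
expansion index is never injected: per-subject distributions are simulated
and scored by the instability module, so index code is exercised end to end.

What passing these simulations does **not** show: robustness to PCR stutter
or chimeras, indel sequencing errors, off-target reads, allele-length PCR
bias, non-Gaussian phenotype noise, population structure, or genotyping
error propagating into association — none of which are simulated.

## Instability measures

HD: the sentence defining the measure names an explicit denominator, so it
is implemented as the ratio N(length > progenitor)/N(length = progenitor); a
fraction-of-total variant sits behind `mode="fraction"`. Zero progenitor
reads is an error, not a zero. DM1: modal length − progenitor, with modal
ties resolved to the smaller length (conservative toward less expansion).
Relative rate: OLS residual of the index on age + inherited length, linear
main effects by default (interaction and log-transform available as
switches); residuals are exactly orthogonal to the covariates and sum to
zero.

## Association and meta-analysis

Dosages are 0/1/2 under the additive model; multi-allelic repeats are
analysed per allele (target vs rest), not by a global multi-allelic test.
Covariate convention: onset adjusts for inherited length (plus interruptions
in DM1); progression for inherited length; relative rate and expression are
analysed unadjusted (the rate is already residualised). Non-estimable
designs (zero dosage variance, rank deficiency) return a flagged result
naming the collinear columns — this is the expected outcome for the three
SNPs in complete LD with 3a in conditional fits. Bonferroni across the
phenotypes tested per marker is reported alongside raw p.

Meta-analysis defaults to the sample-size-weighted scheme
Z = Σ√Nᵢ·Zᵢ/√ΣNᵢ with Zᵢ signed by effect direction (protective effects
carry negative Z; per-study orientation flips supported); inverse-variance
pooling is available. HWE: χ² 1-df goodness of fit, or the Levene–Haldane
exact test by full enumeration of heterozygote counts (mid-p off). LD is
computed from phased haplotypes only (read-backed phasing upstream); no EM
for unphased data. D′ and r² are clamped to their bounds with boundary
snapping at 1e-9 to absorb float roundoff.

The haplotype network is a minimum spanning network over Hamming distances
(repeat-allele column plus variant columns): Kruskal in equal-weight
batches keeping every co-minimal edge (ε = 0), with lexicographic
tie-breaking so the result is input-order invariant. An optional single
median-vector pass inserts the column-majority vector of an observed triple
when it strictly reduces total edge weight — a documented single-pass
simplification of full median joining.

## Determinism and problem sizes

Every generator is a pure function of (config, seed); per-subject streams
derive from `numpy.random.SeedSequence.spawn`. Pipeline runs write a config
snapshot, version stamp and a log with seed, config hash and per-stage
record counts; the config hash excludes the output path, so identical
configurations reproduce every table byte for byte in any directory, and
completed stages are skipped on re-entry under the same hash.

Standard evaluation sizes, chosen to exercise the estimators at meaningful
precision while staying desk-scale: 200 subjects at 100× coverage for
genotype recovery; 50 replicates for artefact reproduction; 500 random
instances for the alignment oracle; 1000 cohorts of 200 for null
calibration; n = 2000 for effect recovery; full enumeration to n = 50 for
exact HWE. The demo pipeline defaults to 200 subjects at 50×.

## Known limitations

- The default locus is a structural stand-in; phantom-variant coordinates
  and unit-composition details differ from the real locus.
- Genotype calling is count-based, not likelihood-based: no base-quality
  weighting, no statistical phasing, no off-target handling.
- The instability model has a single rate parameter and no contraction
  process beyond the expansion bias.
- The median-joining pass is single-round; deep reticulations of the full
  algorithm are out of scope.
- Expression values are rpkm-like draws, not RNA-Seq processing.
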