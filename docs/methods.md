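# Methods

This note documents the models behind `coatmap`, the choices made where the
design was genuinely open, and the limits of what the synthetic data can show.

## Phenotype and QTL model

The trait is a bounded ordinal score: darkness of hair coat on a 0–3 scale,
recorded as the mean of `n_raters` (default 6) independent ratings. The
generative latent value for an individual with dosage *g* ∈ {0,1,2} of the
counted allele is

    latent = baseline + G(g) + u + e,

with `G(0,1,2) = (−a, d, +a)`, a polygenic deviate *u* with covariance
proportional to the GRM, and residual `e ~ N(0, resid_var)`. The
single-locus decomposition gives the allele-substitution effect
`α = a + (q−p)d`, additive variance `V_A = 2pqα²` and dominance variance
`V_D = (2pq·d)²`.

Defaults mirror the mapped DHC locus: p = 0.481, α = 0.702, d = −0.467
(score units). The residual variance default 0.344 is derived, not free: no
phenotype variance or rater reliability is reported for the original study,
so it is calibrated once so that the QTL explains
`V_G/(V_G+V_E) = 0.300/0.644 = 46.6 %` of the latent variance, the share the
top marker's regression R² is expected to recover. With d < 0 the
heterozygote median skews toward the low-score homozygote — the reference
allele pulls carriers toward lighter coats.

Each rater observes the latent value plus `N(0, rater_sd²)` noise and
converts it to {0,1,2,3} via fixed cut points; the reported score is the
rater mean clamped to [0,3]. Cut points default to (0.9, 1.6, 2.3) around a
baseline of 1.5, chosen to make the score distribution right-skewed (mostly
light animals), qualitatively matching the described cohort. `rater =
None` returns the raw latent value — the mode used for analytic variance
checks, where clamping and discretization would bias the bookkeeping.

## Genotypes, GRM and the mixed-model scan

Markers are simulated as two independent Bernoulli(p) haplotypes per
individual — Hardy–Weinberg by construction, no linkage disequilibrium.
Because block analyses need LD, `plant_haplotype_block` rewrites a marker
window with two founder haplotypes that cosegregate with the anchor (QTL)
alleles plus a tail of rare mutated copies; anchor dosages are preserved
exactly. This is a deliberate caricature of LD: two deep clades and
singletons, no recombination gradient, no distance decay.

The GRM is the frequency-standardized form `G = ZZ'/m` with
`Z_ij = (x_ij − 2p_j)/√(2p_j q_j)` and per-marker mean imputation of missing
dosages (the source tooling is named in the field but its exact formula is
not printed; the VanRaden/GCTA-style standardization is the natural
reading). QC removes markers with call rate **strictly below** 0.90 or MAF
strictly below 0.02 — the thresholds are exclusive because the underlying
rule is worded as "lower than".

REML works in the GRM eigenbasis, profiling the restricted likelihood down
to a one-dimensional search over the variance ratio λ = σ²g/σ²e (bounded
log-scale golden search, λ ∈ [1e−6, 1e6]); boundary estimates are allowed
and flagged, and a GRM numerically proportional to the identity is flagged
as unidentifiable. The association scan is MLMA-LOCO: for each chromosome,
variance components are estimated **once** on the GRM built from all other
chromosomes (not re-estimated per marker — the standard default, and the
desk-scale economical choice), then every marker on that chromosome is
tested by GLS with covariance σ²g·G_loco + σ²e·I and a 1-df chi-square.
Covariates default to an intercept only (the original model's covariates are
not stated). Monomorphic markers yield NaN rows; markers collinear with the
covariates (e.g. perfect LD with a conditioned marker) are skipped with a
warning.

The inflation factor is the **through-origin** regression slope of sorted
observed statistics on 1-df chi-square quantiles ("slope" is specified
without an intercept; through-origin makes λ scale-equivariant: λ of c·χ² is
exactly c). Note that at desk scale (hundreds of markers) a genuine QTL
inflates λ well above 1 because one extreme quantile carries weight that
half a million null markers would otherwise dilute; null scans sit in
[0.9, 1.1].

## Additive/dominance decomposition

Dosages are re-coded as `m = g − 2p` and `w = (−2p², 2pq, −2q²)` for
g = 0, 1, 2, and `y` is regressed on `[1, m, w]` by OLS with classical
standard errors. Under exact HWE counts cov(m, w) = 0, so α̂ is unchanged by
dropping w; on finite samples orthogonality is only approximate and is not
enforced. `p` defaults to the sample frequency of the counted allele (the
alternative allele by default, matching the convention that the alternative
allele is associated with darker coat). With fewer than three genotype
classes d is not estimable and is reported NaN, the model degrading to the
additive regression.

## Haplotype blocks

Block alleles are strings of ref/alt base characters over the markers of a
closed genomic interval, one per phased chromosome copy, so published block
strings are representable verbatim. Grouping keeps alleles with frequency
**strictly above** the threshold (default 5 %), labels them H1, H2, … by
descending count, and pools the rest into "HN"; counts are kept exactly
(rational frequencies sum to 1) and the grouping is invertible. Phase
inference is out of scope: synthetic data is phased by construction and a
phased VCF is accepted as-is.

## Structural-variant engine

**Coordinates** are 1-based closed throughout: `length = end − start + 1`
(63,600,957 − 63,599,803 + 1 = 1155).

**Edits.** A rearrangement is an ordered list of deletions (closed
intervals), insertions (before a position) and inverted-duplication
insertions (the reverse complement of a source interval inserted at a
target, source untouched). The CoordinateMap records every base's provenance
and maps retained bases bijectively.

**Mapper.** The internal mapper indexes exact k-mers (default k = 31) and
extends anchors without gaps, allowing isolated mismatches (budget 6, never
two consecutive); trailing mismatches are trimmed so alignments end on
matches, and unaligned tails become soft clips. A second diagonal covering
≥ k read bases outside the primary alignment is emitted as a supplementary
(chimeric) record. Ties go to the leftmost position; ambiguous best
placements are kept with MAPQ 0. It is deliberately a *toy*: ungapped, exact
anchors, no affine gaps — sufficient for substitution-error short reads on
unique synthetic sequence (100 % placement accuracy on error-free reads, by
test), and SAM ingestion exists for externally aligned real data. The repo
never shells out to an aligner.

**Orientation nomenclature** (conventions vary; fixed here): RL = inward
proper pair (leftmost mate forward), RR = both forward, LL = both reverse,
RF = outward, cross = mate unaligned/other contig. An inverted duplication
whose copy maps ~316 kb away turns junction-straddling pairs into RR/LL
pairs with inserts near the breakpoint-to-source distance.

**Signature and distance.** A region signature holds pair-class counts and
insert summaries, clip clusters (window 10 bp, min support 3 for reporting),
chimeric anchors, raw clip/anchor event lists, and a median-normalized depth
profile. The distance between two signatures averages four components,
each in [0, 1] with equal default weights (config-exposed; the original
comparison criterion was visual, so the weighting is a package choice):

1. pair-class divergence — the largest per-class normalized contrast
   |f_obs − f_sim|/(f_obs + f_sim) over classes with ≥ 3 reads combined;
   the maximum keeps rare but diagnostic RR/LL classes from being drowned
   out by the RL bulk;
2. clip-coordinate set distance — support-weighted symmetric nearest-match
   distance (capped at 1 kb) over clusters built from raw events, so a
   six-read junction pileup outweighs stray single clips without a hard
   threshold cliff;
3. the same for chimeric anchors;
4. depth-profile L1 gap with a 0.3 deadzone per window (counting noise at
   ~10×; genuine copy-number differences are 0.5–1.0).

`rank_hypotheses` applies each candidate edit, simulates reads from the
mutant with the same seed (so the ranking is invariant to candidate order
and duplicate candidates tie exactly), maps them to the unedited reference
and sorts by distance; invalid candidates score infinity with a reason.

**Breakpoint localization.** The windowed depth scan (window 200 bp) flags
runs of windows below a depth ratio; runs touching the contig edges are
discarded as coverage fall-off. Clip clusters then refine the flagged
interval: the 5′ breakpoint is the modal coordinate of the best-supported
right-side clip cluster near the interval start, the 3′ breakpoint the best
left-side cluster near the end. Because the search is confined to a
depth-supported neighbourhood, the localizer accepts clusters down to
support 1 (stray single clips essentially never out-support a junction
pileup there). Supplementary alignments contribute their clip coordinates
too — for a read whose larger part maps to the duplication source, the split
flank piece is the only record carrying the breakpoint clip. Reported
junctions can shift by a few bases of chance micro-homology between novel
and reference sequence, the usual ambiguity of alignment-based breakpoints.

**Long-read junction sizing** aligns long reads to a *deletion-applied*
reference (insertion sizing is much better conditioned there than against
the full wild type): unique exact k-mer anchors (k = 21) nearest the
junction on each side extrapolate the read coordinates where the flanks end
and begin, and the gap is the per-read insertion estimate. Error-free mutant
reads measure the insert exactly (150 bp); with ONT-like errors (3 %
mismatch, 3 % insertion, 5 % deletion — indel-dominant, net −2 % length
bias) estimates scatter by tens of bp around a slightly deflated centre;
wild-type reads measure the full deleted segment (> 1.1 kb). Reads must be
anchored ≥ 200 bp into both flanks.

**Genotyping** combines the depth ratio over the SV interval with
discordant-pair and breakpoint-clip support: hom-alt below 0.25 with
support, het in [0.25, 0.75) with support, hom-ref at normal depth without
support; too few pairs in the window (default 50) or conflicting evidence
yields no-call. At ~6× long-read-era coverages the no-call rate rises, as
expected.

## Read simulators

Paired-end reads follow the wgsim recipe: uniform fragment starts,
N(insert_mean, insert_sd) fragment lengths, read 1 forward from the 5′ end,
read 2 reverse-complemented from the 3′ end (inward/RL by construction),
substitution errors at a flat rate (default 0.001 in SV simulations — error
handling in the original simulations is unstated, so a typical Illumina
substitution rate is assumed). An optional GC-dependent thinning flag
(default off) emulates PCR amplification bias of legacy library preparations.
Long reads draw exponential-ish lengths around the mean (default 5.7 kb,
coverage ~8.7× in the ONT-style scenarios) with indel-dominant errors.

Not emulated: base-quality profiles, GC-dependent error rates, chimeric
library artifacts, reference repeats (fragments are i.i.d. uniform, so
k-mers are effectively unique). Passing tests therefore demonstrate the
*logic* of signature extraction and ranking under clean mapping conditions,
not robustness to repeat-rich real genomes.

## Problem sizes

Defaults are chosen so every stage runs in seconds on one CPU: cohorts of
432 × ~600 markers for the GWAS stages, 200 replicates for estimator
recovery, a 330-kb fragment at 10× (≈ 33 k reads) for the full-geometry SV
reconstruction, and 40-kb fragments with a nearby source segment for unit
scale. The acceptance script uses the full 330-kb geometry with the printed
coordinates; its reference fragment is seeded internally, since the genome
is a fixed condition of the study, while read sampling follows the
user-supplied seed.

## Known limitations

- The mapper has no gapped alignment; indel-rich short reads would clip
  rather than align through.
- Breakpoint coordinates inherit micro-homology ambiguity (± a few bp).
- `plant_haplotype_block` produces two-clade LD, not a realistic decay.
- The inflation factor is informative only at null or genome scale; with few
  markers and a strong QTL it is dominated by the signal itself.
- REML assumes a dense positive semi-definite GRM; pedigree or sparse
  relationship structures are untested.
- The simulated rater model is a guess at an unreported instrument; only the
  latent-scale variance bookkeeping is anchored.
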