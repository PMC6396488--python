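# Methods

This note documents the statistical machinery behind `gdparent`, the
choices made where the design was genuinely open, and what the simulated
validations do and do not establish.

## Genotype model

Genotypes at a bi-allelic SNP are collapsed to three states per locus —
primary homozygote, heterozygote, secondary homozygote — plus missing.
The two alleles of a locus are taken from all tokens observed at that
column and ordered lexicographically; the Gower dissimilarity is invariant
to which allele is called primary, so the ordering only serves
determinism.  Loci with more than two observed alleles or with no
non-missing call are dropped with a logged count.  Monomorphic loci are
retained by default (they are homozygous in every parent and always match,
so they dilute but can never flip a comparison); `drop_monomorphic=True`
removes them.

The collapse is deliberately ploidy-agnostic: any heterozygous dosage maps
to the single heterozygous state and no dosage model is attempted.
Tetraploid data, for example, enter the analysis exactly as their
three-state calls.

## Gower dissimilarity

For state vectors x, y over L loci,

    GD = 1 - (sum_l s_l w_l) / (sum_l w_l)

with s_l = 1 if x_l = y_l, 0.5 if the states differ by one allele
(heterozygote vs either homozygote), 0 for opposite homozygotes, and
w_l = 1 iff both calls are non-missing.  GD ranges over [0, 1]; a pair
with no comparable locus has an *undefined* GD, propagated as NaN and
excluded from ranking with a warning — never silently reported as 0.
Internally all-pairs GDs are computed through one-hot indicator matrix
products (six BLAS calls per block), which the tests verify against a
per-locus loop.

## Triad analysis

Mother candidates are the classes {Mo, Pa, All}, fathers {Fa, Pa, All},
offspring {Off, All}.  Parent pairs are unordered, deduplicated, with
mother ≠ father; every offspring candidate is paired with every parent
pair, including the parents themselves, so the fully unguided space for n
individuals is exactly n · n(n−1)/2 triads.  Triads whose "offspring" is
one of its own parents are scored and reported in the full table (the
count above is the contract) but are never declared — an individual cannot
be its own parent.

The expected progeny of a pair is defined only at loci where both parents
are homozygous and called; elsewhere it is missing and carries zero weight.
It is computed once per pair and reused across all offspring; the tests
assert bit-identical results to per-triad recomputation.

**Gap detection.** Only GD values below `MaxIdent` (default 0.1) are
scanned; values above it can never be declared and are excluded from
significance testing, though they remain in the sorted output table.  The
threshold is the midpoint of the largest difference between adjacent
ordered values; an exact tie resolves to the lower-GD gap (the smaller,
more conservative declared set).  Fewer than three values below the
ceiling make the gap undeterminable and nothing is declared.

**Significance.** The size of the gap is tested as an upper outlier among
all adjacent-gap lengths in the scanned region with a Dixon ratio test.
If the gap is significant at α, each triad below the threshold is tested
as a lower outlier against a comparison sample of the
`comparison_sample_size` (default 30) smallest GDs above the gap, and
declared iff its p-value ≤ α.  Thirty keeps the Dixon statistic in its
classical operating range while sampling the near-gap neighbourhood; if
fewer above-gap values exist, all are used with a warning.  α defaults to
0.01 (99% confidence).

**Dixon p-values.** The ratio variant follows sample size (r10 for n ≤ 7,
r11 for 8–10, r21 for 11–13, r22 for n ≥ 14).  Published critical-value
tables stop near n = 30 and interpolating them is itself a guess, so
p-values come from a seeded Monte-Carlo simulation of the null (10,000
standard-normal samples of the same size; the statistic is location- and
scale-free).  The null distribution is cached per sample size, p-values
use the (1 + #{null ≥ observed})/(N + 1) estimator, and the tests verify
both uniformity of null p-values and agreement with the classical
one-sided critical values (e.g. r10 at n = 5: 0.642 at 5% risk).  A
constant sample returns p = 1.  Consequences of the Monte-Carlo floor:
p-values are never below ~1e-4, so declarations at α much below 0.001 are
not meaningful at the default replicate count.

## Dyad analysis

For offspring k and candidate parent i, with co-parents j ranging over the
remaining parent candidates (excluding i and k):

    GDM_i|k   = mean_j GD_ij|k
    sigma_i|k = sd_j GD_ij|k          (sample sd, divisor j-1)
    GDCV_i|k  = sigma_i|k / GD_i|k

Stage 1 treats each offspring's set of GDM values as a normal sample and
flags candidates whose normal score falls below the lower confidence
bound; stage 2 z-scores the GDCV values over *all* candidates (a stable
null) and reports flagged pairs whose score exceeds the upper bound.  The
bounds are one-sided normal quantiles at the configured confidence
(default 0.99 → ±2.326); as confidence → 0 the stage-1 bound rises to +∞
and every pair is flagged, which is the intended degenerate limit.  The
reported cumulative p-value is the product of the stage-1 lower-tail and
stage-2 upper-tail normal probabilities — the simplest composition of the
two stages' evidence; it is a ranking device, not a calibrated joint
p-value.

**The GDCV denominator.**  GD_i|k is the Gower dissimilarity between
parent i and offspring k restricted to loci *homozygous in both* — the
same pairwise-homozygous principle the triad stage rests on.  This choice
is load-bearing.  A true parent and its offspring can disagree at a
mutually homozygous locus only through genotyping error, so the
denominator is near zero for real parents and near the population's
homozygous-mismatch rate (~0.17 under the default simulation) for
everyone else; dividing sigma by it turns the true parent into an extreme
upper outlier (z ≈ +7 in the labeled validation runs) while full siblings
— whose mutual homozygous loci disagree whenever opposite alleles
segregate — stay near the bulk.  The plain all-loci dissimilarity was
evaluated and rejected: its parent-vs-background ratio (~1.6×) is almost
exactly cancelled by the parent's smaller sigma, leaving stage 2 with no
power at all in this setting.  When no mismatching pairwise-homozygous
locus is observed the denominator is floored at half a mismatch
(0.5/n_usable), the resolution limit of the panel; candidates at zero
*plain* dissimilarity from the offspring are excluded as duplicate
samples.

Stage-1 normal scores use the plain mean/sd of the full candidate set
(including the candidate being tested); with ~60 candidates a single true
parent deflates its own z-score only modestly (it still reaches z ≈ −6)
and the simpler rule is kept.  Offspring need at least three candidate
parents for the scores to mean anything; degenerate (zero-sd) sets flag
nothing, with a warning.

By default the dyad stage runs only for offspring without a declared
triad, since it exists as the fallback for exactly that case; a flag
forces it for all offspring or suppresses it entirely.

## Pedigree simulator

The generator emulates the validation design of the reference population:
62 unrelated founders, five families of three full siblings (parents drawn
*without replacement* from the founders, so full-sib confounders exist by
construction), 1000 bi-allelic SNPs.  Per-locus allele frequencies are
uniform on [0.05, 0.95], giving an expected heterozygosity of
2(E[p] − E[p²]) = 0.365 under Hardy–Weinberg — matching the reference
population's observed 36.6% — with 11.8% missing data and a 1% per-call
error rate.  Offspring are produced by call-level Mendelian transmission:
homozygous parents transmit their allele deterministically (so with error
and missingness off, every true trio has GD exactly 0 — a tested
invariant), heterozygous parents transmit either allele with probability
1/2.  Genotyping error moves a call to an adjacent state
(homozygote ↔ heterozygote, symmetric; opposite homozygotes require two
perturbations), the simplest model consistent with reduced-representation
sequencing miscalls, and missingness is applied independently.  The same
seed reproduces tables bit for bit.

What the simulation does *not* model: linkage and LD (loci are
independent), population structure or relatedness among founders,
locus-specific error and coverage (error and missingness are i.i.d.), and
true polyploid segregation (transmission is diploid at the call level).
Passing validations therefore show that the statistics behave as designed
under idealized marker panels of realistic size and noise, not that any
particular real collection will separate as cleanly; real data with
related founders, clones, or structured missingness can narrow the gap and
inflate dyad backgrounds.

## Validation setup and observed behaviour

The end-to-end checks simulate the design above.  At these settings each
parent pair leaves ~370–400 usable (pairwise-homozygous) loci, true-trio
GDs land at 0.003–0.02 (exactly 0 without error), and the nearest
non-declarable triads — parent+sib and sib+sib combinations of the same
family — start near 0.05, so the gap analysis separates them cleanly.
Triad recovery is exact (0 Type I, 0 Type II) in ≈96% of seeds; the rare
exceptions are single-triad tail events (a true trio drawn to GD ≈ 0.023
whose Dixon p lands just above 0.01, or a parent+sib triad drifting under
the threshold).  The labeled dyad scenario (one parent per family removed,
adults Pa / progeny Off) recovers the remaining parent of all 15 offspring
with no spurious pairs in every tested seed; the unguided variant
reproduces the intended confounder behaviour — full sibs flagged at stage
1, rejected at stage 2.  `scripts/acceptance.py` reports the modal
accuracies over 20 seeded replicates; the test suite uses 30 (triad) and
20 (dyad) fixed seeds, sized to keep the default run inside a few minutes
on one CPU.

## Numerical and degenerate-case conventions

- Undefined GDs (no comparable loci) are NaN throughout; affected triads
  or dyad pairs are excluded with warnings, never coerced to 0.
- GD and p-values are written with six significant digits, matching the
  magnitude of meaningful GDs (~0.0016) without false precision.
- Loci are named `L0001…` by column order since the input has no header.
- Equal maximal gaps resolve to the lower-GD gap; argmax order makes this
  deterministic.
- The run log records locus drop counts, usable-loci statistics, gap
  location/size/p, declaration counts, and QC warnings for individuals
  whose mean GD or mean usable-locus count falls more than 3 sd below the
  population mean (likely duplicated or badly genotyped samples).
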