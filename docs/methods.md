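# Methods

This note documents the models implemented in divscan, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions and known limitations a user
should be aware of before trusting a result.

## The analysis model

The pipeline assumes a single panmictic population sampled as `N` diploid
individuals (default 18) plus, optionally, one haploid male — the typical
design for a haplodiploid insect, where the male's genome doubles as a
genotyping-error detector: any site called heterozygous in a haploid is
an artifact.

All downstream statistics consume only biallelic genotype dosages and
site/genotype quality annotations; nothing in the package depends on how
the calls were produced.

### Filter cascade

Order: site hard filters → haploid consistency → genotype DP/GQ masking →
cohort filters. Conventions that matter:

- All thresholds are strict inequalities on the *failing* side
  (`QD < 2.0` fails, `QD = 2.0` survives), matching the usual
  variant-filtration semantics.
- A missing INFO annotation passes its predicate (it cannot be shown
  bad); the event is counted in the report.
- `max_missing_count` counts missing genotypes, not alleles, and MAF is
  computed from post-masking called dosages — the order of operations a
  one-pass vcftools invocation applies.
- Cohort filters operate on the diploid cohort only; the haploid column
  is consulted solely by the consistency stage. Presets `round1`
  (no missing genotypes, no genotype-level filters), `round2_gatk`
  (≤ 8 missing) and `round2_final` (the full stringent set) reproduce a
  two-round calling design.

### Windowed diversity

Windows are non-overlapping tiles anchored at position 0 of each
scaffold; trailing partial windows are kept. Per site,
π = 2j(n−j)/(n(n−1)) with `n` the *called* alleles at that site. Window
π divides the summed site values by either the window length or, in
coverage-corrected mode, by the **count** of sites with depth ≥ 5
(covered fraction × window length). Dividing by a count, not a
proportion, keeps the result a per-bp rate; with complete coverage the
two modes coincide (tested).

Tajima's D uses the standard constants; because missingness makes the
per-site sample size vary, the `n` for a window's constants is the
rounded median per-site called-allele count over its segregating sites.
D is *undefined* (NaN, serialized as `nan`) when S = 0 — never 0. Note
the variance coefficients vanish exactly at n ≤ 3, so D needs at least
two diploids and in practice many more.

### Heterozygosity, HWE, relatedness

Per-individual F = (O − E)/(M − E) with E the sum over called
polymorphic sites of 1 − 2pq·C/(C−1). The HWE test is the exact
conditional test (sum of genotype-configuration probabilities no larger
than the observed one). Relatedness is the unadjusted moment estimator
Ajk from dosages and sample allele frequencies.

**Known bias, by design:** with frequencies estimated from the same
individuals, unrelated pairs have expectation ≈ −1/N, not 0 (the shared
sample-mean covariance). At N = 18 that is ≈ −0.057; simulation
reproduces it to three decimals. The implementation follows the standard
estimator definition rather than re-centring, because the raw statistic
is what the field's tools report; interpret small negative values at
small N as "unrelated". The same effect shrinks a duplicated
individual's pairwise value to ≈ ((N−2)/N)² + (N−2)/N².

### Selection scan

Rank-based throughout: per-gene mean π and mean D (windows overlapping
the gene by ≥ 1 bp; undefined-D windows dropped from the D mean only) are
mapped through their own empirical CDFs (weak inequality, range (0, 1]),
multiplied, and the product is re-percentiled; `joint_pct ≤ tail`
(default 0.05) selects. Invariances that follow and are tested: any
monotone transform of all π (or all D) values leaves the output
unchanged; permuting gene labels permutes the output; selected fraction
≤ tail plus boundary-tie mass. Genes overlapping no window with defined
statistics are excluded, not imputed. With fewer than 20 genes the 5%
tail is empty and nothing is selected.

A structural consequence worth stating explicitly: the call budget is
~`tail × n_genes`, so if a fraction f > tail of genes truly carries the
signal, sensitivity cannot exceed tail/f no matter how strong the signal
— e.g. 0.25 when f = 20% and tail = 5%. Recovery experiments in the
validation suite therefore use the default planted fraction of 5%, where
measured sensitivity and precision are both ≈ 0.9.

### Motif scoring

The window scorer is a two-state (background/motif) partition-function
HMM with mononucleotide background: before each emission the chain stays
in background with probability 1 − t or emits a full w-mer from the PWM
with probability t (split evenly across strands), t = 0.0025 fixed. The
reported score is the log partition function relative to the
background-only model; it tends to 0 as t → 0 and equals the
log-sum over all non-overlapping placement configurations (verified
against an enumeration oracle to 1e−9). The forward recursion runs in a
background-normalised domain with periodic rescaling, so 500 bp windows
cannot underflow. Masked bases emit probability 1 in both numerator and
denominator and zero out any motif placement covering them; windows more
than half masked are not scored. Limitations: no dinucleotide
background, no per-window re-estimation of t — the fixed-t
forward score is the scale on which the rank normalizations operate, and
only ranks are consumed downstream.

The background distribution is learned from non-genic regions ≥ 5 kb on
scaffolds ≥ 22 kb (falling back to whole-genome frequencies with a
warning), floored at 0.001 per base.

GC normalization sorts scored windows by GC into 20 equal-count bins
(remainder spread over the first bins) and rank-normalizes within each
bin. Equal counts rather than equal GC spans keep every bin's rank scale
comparable. A score that is a pure function of GC becomes ~uniform after
binning (tested), which is precisely the confound the normalization
removes.

Regulatory regions are strand-oriented and clipped to scaffold bounds;
NearStartSite assigns windows by midpoint to the nearest TSS (boundary
ties go to both genes); GeneTerr spans between the nearest
non-overlapping neighbours' boundaries and is extended (never shrunk) to
at least 5 kb upstream of the TSS. `Pgm = 1 − (1 − Ngm)^Wg` is a
Šidák-style correction of the best (minimum) normalized score over the
region's `Wg` windows: it rewards a single excellent window but accounts
for how many chances the region had. Target sets order genes by
ascending Pgm with gene-id tie-breaks.

### Enrichment

One-sided Fisher tests are upper-tail hypergeometric probabilities; the
universe is the set of genes scored for the relevant combination
(supplied explicitly by the caller), and BH correction runs across the
entire battery jointly — correcting per motif would change m and is not
what a genome-wide screen reports. The default significance threshold
6e-4 is the adjusted-P level appropriate to a ~1,800-test battery.
Odds ratios use a 0.5 Haldane correction on zero cells for reporting
only; p-values are always exact. BH is not idempotent as an operator
(reapplying it to adjusted values can only increase them); only the
one-pass guarantees are asserted.

## The synthetic-data generator

The generator produces the study *conditions*, not reads: 18 diploids +
1 haploid male, θ = 0.0015/bp (the diversity scale of a low-diversity
bee population), low-pass coverage (mean 20×, so the depth ≥ 5
correction and DP/GQ masks are exercised), 200 genes of 5 kb on 1.8 Mb
of 40%-GC sequence, 5% of genes inside sweep regions by default
(mirroring the ~4–5% of genes such scans call), a 5% failing-annotation
site fraction and a 1% haploid-heterozygote error rate.

Sites are placed by a Bernoulli process with per-bp rate θ·a₁
(a₁ = Σ 1/i over 2N−1), the derived-allele count j of a segregating site
is drawn with P(j) ∝ 1/j, and the j derived alleles are assigned to the
2N chromosomes uniformly at random (random union of gametes =
Hardy–Weinberg genotypes). This makes E[π] = θ exactly and the *sample*
SFS exactly neutral, hence windowed Tajima's D centred on zero — the
calibration the validation suite checks. Sweeps multiply the site
density by `reduction` (default 0.2) and skew the spectrum to
P(j) ∝ 1/j^skew (default 2), producing the joint low-π/negative-D
signature. Annotation and DP/GQ values are drawn from labelled
passing/failing distributions; the filter module tests predicates, not a
caller's internals.

What the generator does **not** emulate — and what passing tests
therefore do not demonstrate about real data: linkage disequilibrium
(sites are unlinked), recombination structure, coalescent variance in
the SFS, demography (the neutral spectrum is the equilibrium one),
indels and genotyping error beyond the two labelled mechanisms, mapping
artifacts correlated with repeats, and real TF-binding sequence
composition (planted sites are independent PWM draws). Sweep emulation
by thinning + skew creates the *signature* the scan targets without
claiming coalescent realism.

Determinism: every stage derives its RNG stream from (seed, stage), so
identical configs give byte-identical FASTA/VCF/GFF3/BED/MEME outputs
(tested), and stages can be re-run independently.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use desk-scale sizes
chosen to keep each experiment well-conditioned: 200 kb / 223 motifs for
the target-set battery; the 1.8 Mb default study (≥ 1,700 windows,
≥ 10,000 polymorphic sites) for neutral calibration; five seeds × 200
genes for sweep recovery; five seeds × 400 genes × 20 motifs with a
deterministic (2 bits/column) planted PWM for motif recovery. Planted
recovery uses the deterministic PWM because sampled sites from a softer
matrix legitimately carry mismatches and need not outrank background
maxima — strong-site capture is the property the pipeline guarantees.

## Numerical conventions

- Coordinates 0-based half-open internally; GFF3 written 1-based
  inclusive; VCF positions converted on read/write.
- Undefined statistics are NaN end to end and serialize as `nan`.
- Exact tests (HWE, Fisher) match integer-enumeration oracles to 1e−12;
  diversity and HMM scores match brute-force oracles to 1e−9.
- The HWE test includes configurations with probability equal to the
  observed one using a 1 + 1e−12 relative slack, so exact ties (which
  occur with integer-weight distributions) are counted in.
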