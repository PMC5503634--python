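# Methods

This note records the statistical models the package implements, the
choices made where conventions diverge, and what the synthetic-data
generator does and does not emulate.

## Data model

Genotypes are stored as insertion dosage — the count of DIP+ alleles,
0/1/2 — with NaN for missing; the "+/−" string notation is a reader
dialect only. Missing genotypes are excluded locus-wise (and
pairwise-complete for LD): standard casework practice, and the packaged
reference sample has no missingness.

### Count reconstruction

A published panel row prints the DIP− frequency and Ho to 4 decimal
places at a known n. The heterozygote count is recovered as
round(Ho·n) and the deletion-allele count as round(p·2n), both with
half-away-from-zero rounding (the rounding used to print the tables;
Python's default half-to-even would mis-round exact halves such as
TPI = 0.78125). At n = 125 the 4-dp precision makes the integer counts
unique — verified in tests against an exhaustive-search oracle — and a
parity/negativity check rejects rows that cannot come from integer
counts.

## Per-locus forensic parameters

- **He** defaults to the uncorrected 2pq form. The corrected
  2N/(2N−1) variant is exposed behind a flag: published DIPplex panel
  tables cite the corrected formula but print uncorrected values, and
  only the uncorrected form reproduces the packaged reference cells.
- **DP** uses observed genotype frequencies, not HWE-expected ones;
  only the observed form reproduces the reference DP column (e.g.
  0.3100 rather than 0.3297 at the least-diverse locus). At exact HWE
  proportions it coincides with 1 − (p⁴ + 4p²q² + q⁴), a property the
  tests assert.
- **PE** is the PowerStats/Brenner form h²(1 − 2h(1−h)²) computed from
  observed heterozygosity; it reproduces the reference PE column
  bit-for-bit at 4 dp.
- **CPE/CDP** accumulate Π(1 − vᵢ) in log space (log1p/expm1) so the
  13 significant decimals of CDP survive 30 multiplications.

## Hardy–Weinberg testing

The default test is the exact conditional test: given the allele
counts, every heterozygote count of matching parity is enumerated with
weight N!/(n₀!n₁!n₂!)·2^{n₁}, and the p-value sums the probabilities of
all configurations no more probable than the observed one. Equality of
probabilities is detected with a 1e−12 relative slack so tied
configurations are always included. A 1-df chi-square variant (no
continuity correction) is available behind a flag. The exact test was
chosen as the default because it is well-defined at n = 125 for
biallelic data and conservative under the null (rejection ≤ α, which
the calibration test checks at 10,000 simulated loci). The published
per-locus p column was produced by an unnamed calculator and two
different programs disagreed on which loci fell below 0.05, so that
column is treated as a diagnostic, not a reproduction target; the
panel-level conclusion — no locus significant after Bonferroni
correction at α/30 ≈ 0.0017 — is reproduced. Bonferroni m is the full
panel size (30), including any monomorphic loci in synthetic data.

## Linkage disequilibrium

Haplotype frequencies for an unphased pair come from the standard EM
iteration over the double-heterozygote phase ambiguity: initialised at
linkage equilibrium, tolerance 1e−10 on the log-likelihood, at most
1000 iterations (convergence is typically < 50). r² = D²/(p_A q_A p_B q_B)
with D measured on the insertion alleles; the statistic is invariant to
allele relabelling and locus order. Pairs involving a locus that is
monomorphic (globally or within the pairwise-complete subset) are
reported as missing, never 0, to keep "untestable" distinct from "no
signal". The default screen threshold is r² ≥ 0.8, the conventional
cutoff for declaring forensic loci non-independent.

## Differentiation and distances

Fst is the Weir–Cockerham (1984) θ for two populations, computed from
genotype counts so the within-individual component (observed
heterozygosity) enters the a/b/c variance components; the multilocus
estimate is Σa/Σ(a+b+c). Loci monomorphic in the pooled sample carry
no information and are dropped from the sums with a warning. Negative
estimates are reported as computed — truncation would bias means across
replicates. The implementation is checked against exact-rational-
arithmetic evaluations of the component formulas frozen into the tests.

Significance uses an individual-level permutation test (both alleles of
an individual move together, matching how genotypic permutation tests
are conventionally run): individuals are pooled, reassigned to the two
original sample sizes, and p = (1 + #{θ* ≥ θ_obs})/(n_perm + 1), which
can never be 0. The default is 10,000 permutations; a seed is
mandatory.

Nei's D_A = 1 − (1/L)ΣΣ√(x·y) operates on frequency tables (each
biallelic locus expanding to (p, 1−p)), because inter-population
comparisons are typically made against published frequencies rather
than raw genotypes. D_A is symmetric and in [0, 1] but not a metric; no
triangle inequality is asserted.

## Neighbor joining

Saitou–Nei agglomeration with the Studier–Keppler Q-criterion. Ties in
Q (compared after rounding to 12 decimals, so floating-point noise does
not break exact ties) resolve to the lexicographically smallest
row-major index pair, making the output deterministic. Negative branch
lengths are retained — they preserve additivity, and clamping is a
display decision left to the consumer. The result is unrooted,
represented with a trifurcating top node; on additive matrices the
input distances are reproduced entry-wise (tests assert 1e−9). Newick
output quotes labels containing reserved characters and round-trips
through dendropy.

## PCA of frequency tables

Populations are observations, one feature per locus (the DIP−
frequency). Columns are mean-centered, not scaled — the features share
the [0, 1] frequency scale, and no scaling is conventional for
allele-frequency PCA. The decomposition is a thin SVD of the centered
matrix (equivalently an eigendecomposition of the covariance across
populations, which the tests verify independently); eigenvector signs
are fixed by making each component's largest-magnitude loading
positive. Using both complementary columns per locus would leave the
explained-variance fractions unchanged and scale scores by √2 — a
tested property that bounds the impact of the one-column choice.

## Synthetic data

The generator emulates the study design the pipeline targets: N
unrelated diploid individuals (default 125, the reference sample size)
typed at 30 independent biallelic loci whose ancestral frequencies
default to the packaged reference panel. Within a population,
genotypes follow inbreeding-adjusted proportions
p² + Fpq : 2pq(1−F) : q² + Fpq, so F_IS = 0 gives exact HWE and F_IS > 0
provides power checks for the HWE tests. Across populations, locus
frequencies follow the Balding–Nichols model,
Beta(p(1−Fst)/Fst, (1−p)(1−Fst)/Fst), the standard Fst-parameterised
frequency prior; ancestrally fixed loci stay fixed, and fst = 0
degenerates to shared frequencies (used for null calibrations). A
single seeded generator is consumed population-major, then locus, then
individual, so tables are bit-reproducible.

What the generator does **not** emulate: genotyping error and allelic
dropout, missing data, linkage between loci (loci are simulated
independently — the LD screen's negative result on synthetic data shows
calibration, not that real panels are linkage-free), mutation, and
admixture structure. Passing tests therefore demonstrate estimator
correctness and calibration under the stated models, not robustness to
artefacts of real capillary-electrophoresis data.

## Problem sizes in the test and acceptance suites

Chosen to make sampling error negligible relative to the asserted
tolerances while keeping the default suite quick: 10,000 loci for HWE
calibration; 100 panel replicates for the LD screen; 200 replicate
population pairs per Fst level (0.01/0.05/0.1, 20% relative tolerance
on the mean); 50 replicates × 399 permutations for the permutation-test
null (rejection in [0.03, 0.07] at α = 0.05).

## Known limitations

- Two populations only for θ; no hierarchical AMOVA or >2-group
  designs.
- The exact HWE p-values need not match published columns produced by
  other calculators (mid-p or ordering conventions differ between
  programs).
- D_A on frequencies ignores sampling error in the frequencies
  themselves; no bias correction is applied.
- NJ provides no bootstrap support values.
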