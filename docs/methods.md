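# Methods

`strpop` implements the statistical pipeline of a forensic STR population
study: per-locus forensic parameters, exact tests of Hardy–Weinberg
equilibrium (HWE) and pairwise linkage disequilibrium (LD), inter-population
differentiation (Weir–Cockerham Fst, Nei's DA distance), distance-based
trees with bootstrap-over-loci support, PCA of population allele
frequencies, and a synthetic-study generator that gives every estimator a
recoverable ground truth.

## Data model

Genotypes are unordered diploid allele pairs; alleles are repeat counts with
an optional microvariant suffix ("13.2" = 13 repeats + 2 bases), ordered by
(repeat, partial). Missing data is handled by per-locus deletion: each locus
carries its own typed count `n_l`, and a partial profile never drops an
individual from the other loci. Allele frequencies are gene-copy fractions
`p_i = c_i / (2 n_l)`; only observed alleles are stored, so every stored
frequency is a positive multiple of `1/(2 n_l)`.

For GenePop interchange, allele `R.P` is encoded as the 3-digit integer
`10·R + P` (so `13.2 → 132`, `14 → 140`); the mapping and the population ids
are declared in the file's free-text title line because the format itself has
neither microvariant nor population-name support. Code 0 is reserved for the
missing sentinel, so allele "0" is not encodable (it does not occur on real
STR ladders).

## Forensic parameters

With `p` the allele-frequency vector, `h` the observed heterozygote fraction
and `H = 1 − h`:

* `HE = 1 − Σ p_i²`, with **no** `2n/(2n−1)` small-sample correction by
  default — the uncorrected form is what standard forensic report software
  (Powerstats) prints, and it is the form that reproduces the bundled
  published table at 4 decimals where the corrected form does not. An
  unbiased mode is available via `unbiased_n`.
* `PIC = 1 − Σ p_i² − (Σ p_i²)² + Σ p_i⁴` (Botstein's form).
* `PD = 1 − Σ_j G_j²` over **observed** genotype proportions, so PD is only
  computable from genotypes, never from a frequency table; the API enforces
  this by taking genotype lists.
* `PE = h²(1 − 2hH²)` (Brenner convention, from observed heterozygosity
  only); allele-frequency-based PE variants are out of scope.
* `TPI = 1/(2(1 − h))`, an error at `h = 1` (infinite index).
* Cumulative powers `1 − Π(1 − v_l)` are accumulated in log-space; the
  residual product `Π(1 − v_l)` and its log10 are returned because the
  combined value saturates to 1.0 in double precision for any panel of ~20
  informative loci — the residual is the quantity that stays meaningful.

Report rendering rounds half-up to 4 decimals (the convention of published
frequency tables); all internal computation is full precision.

## HWE exact test

The test conditions on the allele counts. Under random mating the
probability of a genotype table `{a_ij}` with copy counts `{m_i}` and `h`
heterozygotes among `n` individuals is Levene's distribution

    P(table) = n! · Π_i m_i! · 2^h / ((2n)! · Π_{i≤j} a_ij!)

and the probability-test p-value sums `P` over all tables no more probable
than the observed one (tolerance 1e-9 on log-probability for ties).

* **Enumeration** walks the heterozygote-count cells recursively, pruning on
  copy-count parity; it is used automatically when the table space holds
  fewer than 50,000 tables (covers 2–3 allele loci at study sample sizes).
* **Markov chain**: the state is the arrangement of the `2n` gene copies
  into `n` pairs; each step proposes transposing two uniformly chosen copies
  and always accepts. The stationary law is uniform over arrangements, which
  induces exactly the Levene distribution on tables, so the long-run
  fraction of states no more probable than the observed table estimates the
  same p-value. This pairing-shuffle chain is a deliberate simplification of
  the classical genotype-switch sampler with the identical stationary
  distribution and no acceptance-ratio bookkeeping; log-probabilities are
  updated incrementally (two genotypes change per accepted move).
  The schedule is (dememorization, batches, iterations) with defaults
  (10,000, 100, 5,000) — the defaults of the standard population-genetics
  web service for this test — and the Monte-Carlo standard error is the
  batch-means estimate. p is the raw proportion (no +1 correction), so 0.0
  and 1.0 are representable. Results are bit-reproducible given (seed,
  schedule).

A monomorphic locus has a single possible table: p = 1 exactly.

## LD test and locus exclusion

Gametic phase is unknown, so association is tested on the genotypic
contingency table (distinct one-locus genotypes × distinct other-locus
genotypes, cells counting individuals typed at both). The statistic is the
log-likelihood ratio G; the null distribution permutes one locus's genotypes
across individuals, preserving both margins. p is again a raw proportion
with binomial standard error. A pair involving a monomorphic locus carries
no information (p = 1).

Bonferroni control over all `C(L,2)` pairs uses the strict inequality
`p < α/m` (for 21 loci: thresholds 0.05/21 ≈ 0.00238 and 0.05/210 ≈ 0.00024).
The exclusion rule removes every locus appearing in at least one significant
pair and returns the retained set sorted by name — the standard pre-filter
before building allele-sharing distances and trees.

## Fst and DA

Fst between two samples is Weir & Cockerham's (1984) θ: per allele, the
variance components a (among populations), b (among individuals within) and
c (within individuals) are computed from sample frequencies and
heterozygote-carrier proportions, summed over alleles (and over loci for the
overall value), and θ = Σa / Σ(a+b+c). The multi-locus value is this
ratio-of-sums, not a mean of per-locus ratios. Negative estimates are
reported as-is (they are the estimator's behaviour near zero
differentiation); a locus monomorphic across both samples contributes zero
components and is flagged. Permutation p-values shuffle individuals between
the samples (default 10,000 permutations, per-locus child seeds derived from
one seed) and report the raw proportion of permuted θ ≥ observed.

Nei's DA is `1 − (1/L) Σ_l Σ_i √(x_il · y_il)` over the union of alleles at
each locus (an allele absent from one table contributes zero, never an
error). The value is clamped to [0, 1] against floating-point residue.

## Trees and PCA

UPGMA performs weighted-by-size average-linkage agglomeration with merge
heights halved into an ultrametric rooted tree. NJ is the Saitou–Nei
Q-criterion agglomeration, returned unrooted (trifurcating root); negative
branch-length estimates are clipped to zero with the deficit moved to the
sister branch, preserving path lengths. Both agglomerations break ties on
the lexicographically smallest pair of cluster labels (a cluster's label is
its smallest leaf name), so trees are identical across platforms. Trees are
`skbio.TreeNode` objects; Newick round-trips preserve topology, lengths and
support values.

Bootstrap-over-loci resamples loci with replacement, rebuilds the DA matrix
and tree per replicate, and annotates each internal edge of the full-locus
reference tree with the fraction of replicates containing the same leaf
bipartition (bipartitions canonicalized to the side not containing the
alphabetically first population).

PCA treats each population as a point in (locus, allele) frequency space
over the union of observed alleles (absent → 0), mean-centers columns only
(the covariance convention of the era's numerical environments; a
unit-variance mode is behind a flag) and takes scores and explained-variance
fractions from the SVD, with `min(populations − 1, features)` components.

## Synthetic studies

The generator's defaults are the conditions of the study design it
emulates: 11 populations × 21 loci, 100 individuals per sample, 4–25 alleles
per locus with a 10% microvariant rate, Dirichlet concentration 1.0 (giving
the skewed frequency spectra typical of STR panels), Fst = 0.02 (within the
0–0.09 range such studies report), no inbreeding, no LD. Per locus, a
symmetric-Dirichlet ancestral vector is drawn over a ladder of repeat counts
7–24; each population's vector is a Balding–Nichols divergence — a Dirichlet
draw with parameter `p(1 − Fst)/Fst`, whose mean is the ancestral vector and
whose dispersion is exactly Fst — making the Fst parameter recoverable by
the Weir–Cockerham estimator. Genotypes are drawn under HWE with optional
inbreeding f (mixture construction: with probability f the two copies are
identical by descent).

LD injection is restricted to designated biallelic pairs: those loci get
balanced (0.5/0.5) ancestral frequencies so the feasible range of the
gametic coefficient D stays wide, and the requested D is clamped into 95% of
each population's feasible range (the realized value is recorded in the
ground truth). Multi-allelic LD is out of scope. Features of real data the
generator does not emulate: stepwise mutation dynamics, null alleles,
genotyping dropout and allelic ladder artefacts — so passing tests validate
the estimators, not robustness to those artefacts.

## Validation design and problem sizes

* The deterministic layer is validated against a bundled published 21-locus
  frequency table (n = 275): gene-copy counts reconstructed as
  `round(f·550)` reproduce every printed HE, PIC, PE and TPI value at 4
  decimals, the 166-allele count, and the cumulative powers (combined PE to
  9 decimals; combined PD via its residual product ≈ 6.19e-20, which only
  log-space accumulation can represent).
* Fst recovery: 200 two-population replicates at Fst = 0.05, n = 200, 10
  loci; the mean overall θ must land within 0.01 of the generator value.
* HWE calibration: 1,000 null replicates at n = 100 with 8-allele loci (the
  bundled panel's mean allele count), Markov-chain p with a (1,000, 20, 250)
  schedule; Kolmogorov–Smirnov uniformity at the 1% level. The exact test is
  discretely conservative, so very small tables would bias this check; the
  8-allele design keeps the conditional table space fine-grained.
* Chain-vs-enumeration agreement within 3 Monte-Carlo standard errors on 2-
  and 3-allele samples; NJ must exactly recover random additive trees (≤10
  taxa); UPGMA must return ultrametric inputs' cophenetic structure exactly;
  the LD exclusion rule must remove exactly the generator's injected-LD loci
  in a 21-locus study (4,000 permutations, so only a permutation p of 0 can
  cross the 0.00024 Bonferroni threshold); PCA explained fractions must
  match an independent eigendecomposition within 1e-9.

These sizes were chosen as the smallest at which each property is sharply
testable; all stochastic checks run under fixed seeds.

## Known limitations

* The HWE probability test (not the U-score variant) is the only exact test
  offered; published p rows produced with unknown software settings are not
  expected to reproduce number-for-number.
* Pairwise Fst covers two samples (the pairwise-comparison workflow);
  hierarchical AMOVA with more levels is out of scope.
* DA on 4-decimal published frequencies inherits print-rounding noise of
  order 1e-4.
* The LD permutation test measures genotypic association; it does not
  estimate D′ or r², and the generator's LD ground truth is biallelic.
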