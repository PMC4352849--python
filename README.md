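# strpop

Population-genetic analysis of forensic STR (short tandem repeat) panels.

Forensic genetics labs characterize a new STR multiplex by typing it in a
population sample and reporting, per locus, the statistics that determine
its usefulness for identification and kinship casework — and by comparing
the sample against reference populations to place it genetically. `strpop`
implements that entire analysis as one tested Python library (plus a thin
`strpop` command-line tool) for:

* **per-locus forensic parameters** — observed/expected heterozygosity
  (`HO`, `HE = 1 − Σp²`), polymorphism information content
  (`PIC = 1 − Σp² − (Σp²)² + Σp⁴`), power of discrimination
  (`PD = 1 − ΣG²` over observed genotype proportions), probability of
  exclusion (`PE = h²(1 − 2hH²)`), typical paternity index
  (`TPI = 1/(2(1−h))`), and cumulative PD/PE across a panel computed in
  log-space;
* **exact tests** — Hardy–Weinberg equilibrium by the conditional
  probability test (complete enumeration or a seeded Markov chain with
  batch-means errors), genotypic linkage-disequilibrium permutation tests,
  Bonferroni correction, and the rule that excludes LD-involved loci from
  downstream distance analyses;
* **population differentiation** — Weir–Cockerham θ (locus-by-locus and
  overall, with permutation p-values) and Nei's DA distance
  (`DA = 1 − (1/L) Σ_l Σ_i √(x_i y_i)`);
* **trees and PCA** — UPGMA and neighbor-joining from distance matrices,
  bootstrap-over-loci support values, Newick I/O, and PCA of population
  allele-frequency vectors;
* **synthetic studies** — a Balding–Nichols multi-population generator
  with controlled Fst, inbreeding and linkage disequilibrium, so every
  estimator can be validated against known ground truth.

Genotype tables read from CSV or GenePop files (microvariant alleles such
as "13.2" handled throughout); frequency tables read from the row-per-allele
CSV layout used by published population reports. See `docs/methods.md` for
the statistical conventions and their rationale.

## Worked example

The package bundles a published 21-locus frequency table from a Han
population sample (n = 275, Guanzhong region, China) used as its reference
validation dataset:

```python
import strpop as sp

freqs  = sp.datasets.load_han_guanzhong_frequencies(count_reconstructed=True)
params = sp.datasets.load_han_guanzhong_parameters()

p = freqs.frequency_vector("D19S433")          # most polymorphic locus
print(sp.round_half_up(sp.expected_heterozygosity(p)))   # 0.8147
print(sp.round_half_up(sp.pic(p)))                       # 0.7916

ho = round(float(params.loc["HO", "D19S433"]) * 275) / 275
print(sp.round_half_up(sp.probability_of_exclusion(ho))) # 0.5856
print(sp.round_half_up(sp.typical_paternity_index(ho)))  # 2.4123

print(freqs.count_observed_alleles())                    # 166
print(round(sp.combined_power(params.loc["PE"]).combined, 9))  # 0.999998184
print(sp.combined_power(params.loc["PD"]).residual)      # 6.180237957167568e-20
```

The locus is 81% heterozygous in expectation, excludes a random non-father
59% of the time on its own, and the full 21-locus panel excludes 99.9998% of
non-fathers; the chance that two random individuals share a full profile is
the PD residual, about 6.2 × 10⁻²⁰.

A synthetic end-to-end run:

```python
fx = sp.make_study_fixture(sp.SimConfig(seed=1))   # 11 pops x 21 loci x 100
table = sp.summary_frame(sp.locus_summary_table(fx.populations[0], hwe=False))
pops = [sp.AlleleFrequencyTable.from_genotypes(p) for p in fx.populations]
tree = sp.bootstrap_over_loci(pops, n_replicates=100, method="upgma", seed=1)
print(sp.to_newick(tree))
```

The same operations are exposed on the command line:
`strpop summary`, `strpop hwe`, `strpop ld`, `strpop fst`, `strpop da`,
`strpop tree`, `strpop pca`, `strpop simulate` (see `strpop --help`).

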