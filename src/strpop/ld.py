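"""Pairwise linkage-disequilibrium tests and the locus-exclusion rule.

Gametic phase is unknown in population STR data, so association between
two loci is tested on the genotypic contingency table: rows are the
distinct genotypes at one locus, columns at the other, cells count
individuals typed at both.  The statistic is the log-likelihood ratio
(G); the null distribution comes from permuting one locus's genotypes
across individuals, which preserves both margins' genotype compositions.

Family-wise error over all C(L,2) pairs is controlled by Bonferroni, and
the exclusion rule drops every locus involved in at least one
significant pair (the standard pre-filter before building allele-sharing
distances and trees from multi-locus frequency data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Hashable, Mapping, Sequence

import numpy as np

from .hwe import ExactTestResult
from .tables import GenotypeTable

__all__ = [
    "ld_exact_test",
    "pairwise_ld_tests",
    "bonferroni",
    "MultipleTestReport",
    "ld_locus_exclusion",
]


def _g_statistic(table: np.ndarray) -> float:
    """Log-likelihood-ratio statistic of a contingency table."""
    n = table.sum()
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows * cols / n
    mask = table > 0
    return float(2.0 * (table[mask] * np.log(table[mask] / expected[mask])).sum())


def ld_exact_test(
    genotypes_a: Sequence,
    genotypes_b: Sequence,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> ExactTestResult:
    """Monte-Carlo test of genotypic association between two loci.

    ``genotypes_a`` and ``genotypes_b`` are the aligned genotype lists of
    the individuals typed at both loci.  p is the raw proportion of
    permutations whose G statistic reaches the observed one.
    """
    if len(genotypes_a) != len(genotypes_b):
        raise ValueError("genotype lists are not aligned")
    if len(genotypes_a) < 2:
        raise ValueError("need at least two individuals typed at both loci")
    if n_permutations < 1:
        raise ValueError("n_permutations must be positive")
    cats_a = {g: i for i, g in enumerate(sorted(set(genotypes_a)))}
    cats_b = {g: i for i, g in enumerate(sorted(set(genotypes_b)))}
    if len(cats_a) == 1 or len(cats_b) == 1:
        return ExactTestResult(1.0, 0.0, "enumeration", "log-likelihood-ratio", seed=seed)
    ka, kb = len(cats_a), len(cats_b)
    a = np.array([cats_a[g] for g in genotypes_a])
    b = np.array([cats_b[g] for g in genotypes_b])
    n = len(a)

    def table(bvec: np.ndarray) -> np.ndarray:
        return np.bincount(a * kb + bvec, minlength=ka * kb).reshape(ka, kb)

    g_obs = _g_statistic(table(b))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if _g_statistic(table(rng.permutation(b))) >= g_obs - 1e-9:
            hits += 1
    p = hits / n_permutations
    se = float(np.sqrt(p * (1.0 - p) / n_permutations))
    return ExactTestResult(
        p, se, "mcmc", "log-likelihood-ratio", n_steps=n_permutations, seed=seed
    )


def pairwise_ld_tests(
    table: GenotypeTable,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> dict[tuple[str, str], ExactTestResult]:
    """Run the LD test on every pair of loci of one population sample.

    Returns a mapping over all C(L,2) pairs (sorted locus-name order);
    each pair gets an independent child seed derived from ``seed``.
    """
    pairs = list(combinations(sorted(table.loci), 2))
    seeds = np.random.SeedSequence(seed).spawn(len(pairs))
    results: dict[tuple[str, str], ExactTestResult] = {}
    for (l1, l2), ss in zip(pairs, seeds):
        ga, gb = [], []
        for sample in table.individuals:
            g1 = table.genotype(sample, l1)
            g2 = table.genotype(sample, l2)
            if g1 is not None and g2 is not None:
                ga.append(g1)
                gb.append(g2)
        results[(l1, l2)] = ld_exact_test(
            ga, gb, n_permutations=n_permutations,
            seed=int(ss.generate_state(1)[0] % (2**31)),
        )
    return results


@dataclass
class MultipleTestReport:
    """Bonferroni family-wise report over a set of tests."""

    m: int
    alpha: float
    threshold: float
    p_values: dict[Hashable, float] = field(default_factory=dict)
    significant: list[Hashable] = field(default_factory=list)


def bonferroni(p_values: Mapping[Hashable, float], alpha: float = 0.05) -> MultipleTestReport:
    """Bonferroni correction: significant iff p < alpha/m (strict)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha out of (0,1): {alpha}")
    m = len(p_values)
    if m < 1:
        raise ValueError("no tests")
    threshold = alpha / m
    significant = sorted(k for k, p in p_values.items() if p < threshold)
    return MultipleTestReport(m, alpha, threshold, dict(p_values), significant)


def ld_locus_exclusion(
    report: MultipleTestReport, loci: Sequence[str] | None = None
) -> list[str]:
    """Loci retained after removing every member of a significant LD pair.

    ``report`` must be a Bonferroni report whose keys are locus pairs; if
    ``loci`` is omitted, the locus universe is the union of all pair
    members.
    """
    if loci is None:
        universe = {locus for pair in report.p_values for locus in pair}
    else:
        universe = set(loci)
    excluded = {locus for pair in report.significant for locus in pair}
    return sorted(universe - excluded)
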