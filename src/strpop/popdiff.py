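"""Inter-population differentiation: Fst and Nei's DA distance.

Fst is estimated by Weir & Cockerham's (1984) theta: for each allele the
observed variance in sample allele frequency is decomposed into
among-population (a), among-individual-within-population (b) and
within-individual (c) components, alleles are treated as unordered
states, and theta is the ratio of summed a components to summed
(a + b + c) — over alleles for one locus, and over loci for a
multi-locus overall value.  Negative estimates (sampling noise around
zero differentiation) are reported as-is, never clipped.  Permutation
p-values shuffle individuals between the two samples.

Nei's DA distance (Nei, Tajima & Tateno 1983) between allele-frequency
tables is ``1 - (1/L) * sum_l sum_i sqrt(x_il * y_il)``, summed over the
union of alleles at each locus (an allele absent from one population
contributes zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix

from .tables import AlleleFrequencyTable, GenotypeTable

__all__ = [
    "pairwise_fst",
    "overall_fst",
    "fst_permutation_p",
    "fst_report",
    "FstResult",
    "nei_da",
    "da_matrix",
    "PopulationDistances",
]


def _encode_locus(pops: Sequence[list]) -> tuple[list[np.ndarray], int]:
    """Genotype pair lists -> integer arrays (n_i x 2) over a shared allele index."""
    alleles = sorted({a for pop in pops for g in pop for a in g})
    index = {a: i for i, a in enumerate(alleles)}
    out = []
    for pop in pops:
        arr = np.array([[index[a], index[b]] for a, b in pop], dtype=np.intp)
        out.append(arr.reshape(-1, 2))
    return out, len(alleles)


def _wc_components(genos: Sequence[np.ndarray], k: int) -> tuple[float, float, float]:
    """Summed Weir-Cockerham (a, b, c) variance components over k alleles."""
    r = len(genos)
    n = np.array([len(g) for g in genos], dtype=float)
    if np.any(n < 1) or r < 2:
        raise ValueError("need >=2 populations with typed individuals")
    nbar = n.mean()
    if nbar <= 1:
        raise ValueError("Weir-Cockerham components need more than one individual")
    n_c = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)

    # per-population allele frequencies and heterozygote-carrier proportions
    p = np.empty((r, k))
    h = np.empty((r, k))
    for i, g in enumerate(genos):
        counts = np.bincount(g.ravel(), minlength=k)
        p[i] = counts / (2 * len(g))
        het_rows = g[g[:, 0] != g[:, 1]]
        h[i] = np.bincount(het_rows.ravel(), minlength=k) / len(g)

    w = n / (r * nbar)
    pbar = w @ p
    s2 = ((n[:, None] * (p - pbar) ** 2).sum(axis=0)) / ((r - 1) * nbar)
    hbar = w @ h

    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = nbar / n_c * (s2 - (inner - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return float(a.sum()), float(b.sum()), float(c.sum())


def _locus_components(
    pop_a: GenotypeTable, pop_b: GenotypeTable, locus: str
) -> tuple[float, float, float, bool]:
    genos_raw = [pop_a.locus_genotypes(locus), pop_b.locus_genotypes(locus)]
    genos, k = _encode_locus(genos_raw)
    if k <= 1:
        return 0.0, 0.0, 0.0, True  # monomorphic across both: no information
    a, b, c = _wc_components(genos, k)
    return a, b, c, False


def pairwise_fst(pop_a: GenotypeTable, pop_b: GenotypeTable, locus: str) -> float:
    """Weir-Cockerham theta between two samples at one locus.

    A locus monomorphic across both samples carries no information and
    is reported as 0.0 (see :func:`fst_report` for the flag).
    """
    a, b, c, mono = _locus_components(pop_a, pop_b, locus)
    if mono:
        return 0.0
    total = a + b + c
    if total == 0.0:
        return 0.0
    return a / total


def overall_fst(
    pop_a: GenotypeTable, pop_b: GenotypeTable, loci: Sequence[str] | None = None
) -> float:
    """Multi-locus theta: summed a components over summed (a+b+c).

    This ratio-of-sums form is the standard multi-locus estimator; it is
    not the mean of per-locus theta, and monomorphic loci contribute
    nothing.
    """
    loci = list(loci) if loci is not None else [
        l for l in pop_a.loci if l in set(pop_b.loci)
    ]
    if not loci:
        raise ValueError("no shared loci")
    a_sum = b_sum = c_sum = 0.0
    informative = 0
    for locus in loci:
        a, b, c, mono = _locus_components(pop_a, pop_b, locus)
        if not mono:
            informative += 1
        a_sum += a
        b_sum += b
        c_sum += c
    if informative == 0 or (a_sum + b_sum + c_sum) == 0.0:
        raise ValueError("no informative locus")
    return a_sum / (a_sum + b_sum + c_sum)


def fst_permutation_p(
    pop_a: GenotypeTable,
    pop_b: GenotypeTable,
    locus: str,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> float:
    """Permutation p for one locus: individuals shuffled between samples.

    p is the raw proportion of permuted theta values >= the observed
    one, so 0.0 and 1.0 are attainable.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    genos, k = _encode_locus(
        [pop_a.locus_genotypes(locus), pop_b.locus_genotypes(locus)]
    )
    if k <= 1:
        return 1.0
    n_a = len(genos[0])

    def theta(ga: np.ndarray, gb: np.ndarray) -> float:
        a, b, c = _wc_components([ga, gb], k)
        t = a + b + c
        return 0.0 if t == 0.0 else a / t

    observed = theta(genos[0], genos[1])
    pooled = np.concatenate(genos, axis=0)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(pooled))
        if theta(pooled[perm[:n_a]], pooled[perm[n_a:]]) >= observed - 1e-12:
            hits += 1
    return hits / n_permutations


@dataclass
class FstResult:
    """Locus-by-locus and overall differentiation between two samples."""

    population_pair: tuple[str, str]
    per_locus: dict[str, tuple[float, float]]  # locus -> (theta, p)
    overall: float
    monomorphic: list[str] = field(default_factory=list)
    n_permutations: int = 0
    seed: int | None = None


def fst_report(
    pop_a: GenotypeTable,
    pop_b: GenotypeTable,
    loci: Sequence[str] | None = None,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> FstResult:
    """Full pairwise differentiation report (the Table-2 row shape)."""
    loci = list(loci) if loci is not None else [
        l for l in pop_a.loci if l in set(pop_b.loci)
    ]
    seeds = np.random.SeedSequence(seed).spawn(len(loci))
    per_locus: dict[str, tuple[float, float]] = {}
    mono: list[str] = []
    for locus, ss in zip(loci, seeds):
        theta = pairwise_fst(pop_a, pop_b, locus)
        _, _, _, is_mono = _locus_components(pop_a, pop_b, locus)
        if is_mono:
            mono.append(locus)
            per_locus[locus] = (0.0, 1.0)
            continue
        p = fst_permutation_p(
            pop_a, pop_b, locus, n_permutations=n_permutations,
            seed=int(ss.generate_state(1)[0] % (2**31)),
        )
        per_locus[locus] = (theta, p)
    if len(mono) == len(loci):
        overall = math.nan  # no informative locus at all
    else:
        overall = overall_fst(pop_a, pop_b, loci)
    return FstResult(
        (pop_a.population_id, pop_b.population_id),
        per_locus,
        overall,
        mono,
        n_permutations,
        seed,
    )


def nei_da(
    freq_a: AlleleFrequencyTable,
    freq_b: AlleleFrequencyTable,
    loci: Sequence[str] | None = None,
) -> float:
    """Nei's DA distance between two allele-frequency tables."""
    loci = list(loci) if loci is not None else freq_a.loci
    total = 0.0
    for locus in loci:
        if locus not in freq_a.frequencies or locus not in freq_b.frequencies:
            raise KeyError(f"locus {locus!r} absent from a frequency table")
        xa = freq_a.frequencies[locus]
        xb = freq_b.frequencies[locus]
        shared = 0.0
        for allele in set(xa) | set(xb):
            shared += math.sqrt(xa.get(allele, 0.0) * xb.get(allele, 0.0))
        total += shared
    return min(1.0, max(0.0, 1.0 - total / len(loci)))


@dataclass
class PopulationDistances:
    """A symmetric population distance matrix with the loci it used."""

    matrix: DistanceMatrix
    loci_used: tuple[str, ...]


def da_matrix(
    populations: Sequence[AlleleFrequencyTable],
    loci: Sequence[str] | None = None,
) -> PopulationDistances:
    """Pairwise DA distances over a set of populations."""
    if len(populations) < 2:
        raise ValueError("need at least two populations")
    loci = list(loci) if loci is not None else populations[0].loci
    ids = [p.population_id for p in populations]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = nei_da(populations[i], populations[j], loci)
    return PopulationDistances(DistanceMatrix(d, ids), tuple(loci))
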