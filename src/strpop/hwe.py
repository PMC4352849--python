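"""Exact test of Hardy-Weinberg equilibrium for multi-allelic loci.

The test conditions on the observed allele counts: under random mating,
the probability of a genotype-count table ``{a_ij}`` with allele copy
counts ``{m_i}`` and ``h`` heterozygotes among ``n`` individuals is the
Levene (1949) distribution

    P(table) = n! * prod_i m_i! * 2^h / ((2n)! * prod_{i<=j} a_ij!)

and the probability-test p-value sums P over all tables (same allele
counts) no more probable than the observed one.

Two engines are provided:

* complete enumeration of the conditional table space, exact, used
  automatically when the space is small enough;
* a Markov chain over the pairings of the ``2n`` gene copies: a random
  transposition of two copies is proposed each step and always accepted.
  The chain's stationary law is uniform over arrangements, which induces
  exactly the Levene distribution on genotype tables, so the long-run
  fraction of states no more probable than the observed table estimates
  the same p-value.  Monte-Carlo error is reported via batch means.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from math import lgamma, log

import numpy as np

from .alleles import AlleleLabel

__all__ = ["ExactTestResult", "hwe_exact_test", "count_hwe_tables"]

_LOG2 = math.log(2.0)
_TOL = 1e-9


@dataclass
class ExactTestResult:
    """Outcome of an exact (or Monte-Carlo exact) test."""

    p_value: float
    se: float
    method: str  # "enumeration" | "mcmc"
    statistic_kind: str = "probability"
    n_steps: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


def _encode(genotypes) -> tuple[dict[tuple[int, int], int], list[int], int]:
    """Map genotypes to integer allele indices; return table, copy counts, n."""
    alleles = sorted({a for g in genotypes for a in g})
    index = {a: i for i, a in enumerate(alleles)}
    table: Counter[tuple[int, int]] = Counter()
    m = [0] * len(alleles)
    for a, b in genotypes:
        i, j = sorted((index[a], index[b]))
        table[(i, j)] += 1
        m[i] += 1
        m[j] += 1
    return dict(table), m, len(genotypes)


def _log_variable(table: dict[tuple[int, int], int]) -> float:
    """h*log2 - sum(log a_ij!) — the part of log P that varies over tables."""
    h = sum(c for (i, j), c in table.items() if i != j)
    return h * _LOG2 - sum(lgamma(c + 1) for c in table.values())


def _enumerate_log_variable(m: list[int]):
    """Yield the variable log-probability part of every table with copy counts m."""
    k = len(m)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]

    def rec(idx: int, rem: list[int], het: int, sumlg: float):
        if idx == len(pairs):
            # all heterozygote cells fixed; remaining copies are homozygotes
            total = sumlg
            ok = True
            for r in rem:
                if r % 2:
                    ok = False
                    break
                total += lgamma(r // 2 + 1)
            if ok:
                yield het * _LOG2 - total
            return
        i, j = pairs[idx]
        # once row i is complete, rem[i] must be even (homozygote pairs)
        last_of_row = idx + 1 == len(pairs) or pairs[idx + 1][0] != i
        hi = min(rem[i], rem[j])
        for a in range(hi + 1):
            rem[i] -= a
            rem[j] -= a
            if not last_of_row or rem[i] % 2 == 0:
                yield from rec(idx + 1, rem, het + a, sumlg + lgamma(a + 1))
            rem[i] += a
            rem[j] += a

    yield from rec(0, list(m), 0, 0.0)


def count_hwe_tables(m: list[int], cap: int = 1_000_000) -> int:
    """Number of genotype tables consistent with copy counts, up to ``cap``."""
    count = 0
    for _ in _enumerate_log_variable(m):
        count += 1
        if count >= cap:
            return cap
    return count


def _p_enumeration(table: dict[tuple[int, int], int], m: list[int]) -> float:
    obs = _log_variable(table)
    logs = np.fromiter(_enumerate_log_variable(m), dtype=float)
    w = np.exp(logs - logs.max())
    return float(w[logs <= obs + _TOL].sum() / w.sum())


def _p_mcmc(
    table: dict[tuple[int, int], int],
    m: list[int],
    chain: tuple[int, int, int],
    seed: int | None,
) -> tuple[float, float, int]:
    demem, batches, iterations = chain
    if demem < 0 or batches < 2 or iterations < 1:
        raise ValueError(f"invalid chain parameters {chain}")
    rng = np.random.default_rng(seed)
    obs = _log_variable(table) + _TOL

    # state: arrangement of the 2n gene copies; consecutive pairs = genotypes
    x: list[int] = []
    counts: dict[tuple[int, int], int] = dict(table)
    het = sum(c for (i, j), c in table.items() if i != j)
    sumlg = sum(lgamma(c + 1) for c in counts.values())
    for (i, j), c in sorted(table.items()):
        x.extend([i, j] * c)
    two_n = len(x)

    logv = het * _LOG2 - sumlg
    inside = logv <= obs

    def steps(n_steps: int, record: list | None) -> None:
        nonlocal het, sumlg, logv, inside
        draws = rng.integers(0, two_n, size=2 * n_steps).tolist()
        for t in range(n_steps):
            u = draws[2 * t]
            v = draws[2 * t + 1]
            if u // 2 != v // 2 and x[u] != x[v]:
                for base in (u // 2 * 2, v // 2 * 2):
                    a, b = x[base], x[base + 1]
                    g = (a, b) if a <= b else (b, a)
                    c = counts[g]
                    sumlg -= log(c)
                    if c == 1:
                        del counts[g]
                    else:
                        counts[g] = c - 1
                    if a != b:
                        het -= 1
                x[u], x[v] = x[v], x[u]
                for base in (u // 2 * 2, v // 2 * 2):
                    a, b = x[base], x[base + 1]
                    g = (a, b) if a <= b else (b, a)
                    c = counts.get(g, 0)
                    sumlg += log(c + 1)
                    counts[g] = c + 1
                    if a != b:
                        het += 1
                logv = het * _LOG2 - sumlg
                inside = logv <= obs
            if record is not None:
                record.append(inside)

    steps(demem, None)
    batch_means = []
    for _ in range(batches):
        rec: list[bool] = []
        steps(iterations, rec)
        batch_means.append(sum(rec) / iterations)
    bm = np.asarray(batch_means)
    p = float(bm.mean())
    se = float(bm.std(ddof=1) / math.sqrt(batches))
    return p, se, demem + batches * iterations


def hwe_exact_test(
    genotypes,
    method: str = "auto",
    chain: tuple[int, int, int] = (10_000, 100, 5_000),
    seed: int | None = None,
    enumeration_limit: int = 50_000,
) -> ExactTestResult:
    """Exact HWE probability test on the typed genotypes of one locus.

    Parameters
    ----------
    genotypes : sequence of allele pairs
        Typed diploid genotypes (unordered pairs of :class:`AlleleLabel`
        or any sortable allele identifiers).
    method : {"auto", "enumeration", "mcmc"}
        "auto" enumerates when the conditional table space has at most
        ``enumeration_limit`` tables, otherwise runs the Markov chain.
    chain : (dememorization, batches, iterations)
        Markov-chain schedule; the Monte-Carlo standard error comes from
        the spread of the per-batch means.
    seed : int, optional
        Chain seed; results are bit-reproducible given (seed, chain).
    """
    if len(genotypes) < 1:
        raise ValueError("no typed individuals")
    table, m, _n = _encode(genotypes)
    if len(m) == 1:  # monomorphic: single possible table
        return ExactTestResult(1.0, 0.0, "enumeration", seed=seed)
    if method not in ("auto", "enumeration", "mcmc"):
        raise ValueError(f"unknown method {method!r}")
    if method == "auto":
        n_tables = count_hwe_tables(m, cap=enumeration_limit)
        method = "enumeration" if n_tables < enumeration_limit else "mcmc"
    if method == "enumeration":
        return ExactTestResult(_p_enumeration(table, m), 0.0, "enumeration", seed=seed)
    p, se, n_steps = _p_mcmc(table, m, chain, seed)
    return ExactTestResult(p, se, "mcmc", n_steps=n_steps, seed=seed)
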