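"""Per-locus forensic parameters and their cumulative combinations.

The statistics of a forensic STR population report, in the Powerstats
conventions:

* ``HO`` — observed heterozygosity, the fraction of typed individuals
  carrying two distinct alleles;
* ``HE`` — expected heterozygosity under random mating, ``1 - sum(p_i^2)``
  (no small-sample correction by default; an unbiased mode is available);
* ``PIC`` — Botstein's polymorphism information content,
  ``1 - sum(p^2) - (sum(p^2))^2 + sum(p^4)``;
* ``PD`` — power of discrimination, one minus the sum of squared
  *observed* genotype proportions (hence computable only from genotypes);
* ``PE`` — probability of exclusion in the Brenner form
  ``h^2 (1 - 2 h H^2)`` with ``h = HO`` and ``H = 1 - h``;
* ``TPI`` — typical paternity index ``1 / (2 (1 - HO))``;
* cumulative PD/PE over a panel, ``1 - prod(1 - v_l)``, accumulated in
  log-space because the residual product underflows the printed digits.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .alleles import AlleleLabel
from .tables import AlleleFrequencyTable, GenotypeTable

__all__ = [
    "observed_heterozygosity",
    "expected_heterozygosity",
    "pic",
    "power_of_discrimination",
    "probability_of_exclusion",
    "typical_paternity_index",
    "combined_power",
    "CombinedPower",
    "LocusSummary",
    "locus_summary_table",
    "summary_frame",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 4) -> float:
    """Decimal half-up rounding, the convention of forensic report tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def observed_heterozygosity(genotypes: Sequence[tuple[AlleleLabel, AlleleLabel]]) -> float:
    """Fraction of typed individuals with two distinct alleles."""
    if not genotypes:
        raise ValueError("no typed individuals")
    het = sum(1 for a, b in genotypes if a != b)
    return het / len(genotypes)


def expected_heterozygosity(p: Iterable[float], *, unbiased_n: int | None = None) -> float:
    """``1 - sum(p_i^2)``; with ``unbiased_n`` applies the 2n/(2n-1) factor."""
    arr = np.asarray(list(p), dtype=float)
    he = 1.0 - float(np.sum(arr**2))
    if unbiased_n is not None:
        he *= 2 * unbiased_n / (2 * unbiased_n - 1)
    return he


def pic(p: Iterable[float]) -> float:
    """Botstein polymorphism information content of a frequency vector."""
    arr = np.asarray(list(p), dtype=float)
    s2 = float(np.sum(arr**2))
    s4 = float(np.sum(arr**4))
    return 1.0 - s2 - s2 * s2 + s4


def power_of_discrimination(genotypes: Sequence[tuple[AlleleLabel, AlleleLabel]]) -> float:
    """One minus the sum of squared observed genotype proportions."""
    if not genotypes:
        raise ValueError("no typed individuals")
    counts = Counter(genotypes)
    n = len(genotypes)
    return 1.0 - sum((c / n) ** 2 for c in counts.values())


def probability_of_exclusion(ho: float) -> float:
    """Brenner-form PE from observed heterozygosity."""
    if not 0.0 <= ho <= 1.0:
        raise ValueError(f"heterozygosity out of [0,1]: {ho}")
    h, hom = ho, 1.0 - ho
    return h * h * (1.0 - 2.0 * h * hom * hom)


def typical_paternity_index(ho: float) -> float:
    """``1 / (2 (1 - HO))``; undefined when every individual is heterozygous."""
    if not 0.0 <= ho <= 1.0:
        raise ValueError(f"heterozygosity out of [0,1]: {ho}")
    if ho == 1.0:
        raise ValueError("TPI infinite at HO = 1")
    return 1.0 / (2.0 * (1.0 - ho))


class CombinedPower(NamedTuple):
    """Cumulative power over a panel: ``combined = 1 - residual``."""

    combined: float
    residual: float  #: prod(1 - v_l), the quantity that stays meaningful
    log10_residual: float


def combined_power(values: Iterable[float]) -> CombinedPower:
    """Combine per-locus PD or PE values across a panel in log-space.

    The combined power ``1 - prod(1 - v_l)`` saturates to 1.0 in double
    precision for a multi-locus panel, so the residual product and its
    log10 are returned alongside it.
    """
    log_residual = 0.0
    for v in values:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"power value out of [0,1]: {v}")
        if v == 1.0:
            return CombinedPower(1.0, 0.0, -math.inf)
        log_residual += math.log1p(-v)
    residual = math.exp(log_residual)
    return CombinedPower(1.0 - residual, residual, log_residual / math.log(10))


@dataclass
class LocusSummary:
    """One row of a Table-1-style forensic parameter report."""

    locus: str
    n: int
    HO: float
    HE: float
    PIC: float
    PD: float
    PE: float
    TPI: float
    hwe_p: float | None = None


def locus_summary_table(
    table: GenotypeTable,
    *,
    hwe: bool = True,
    seed: int | None = 0,
    hwe_kwargs: dict | None = None,
) -> list[LocusSummary]:
    """Assemble the full per-locus forensic parameter set for a sample.

    HWE exact-test p-values are included unless ``hwe=False``; they are
    the only stochastic column, controlled by ``seed``.
    """
    from .hwe import hwe_exact_test  # deferred: hwe depends on tables only

    freqs = AlleleFrequencyTable.from_genotypes(table)
    out = []
    for i, locus in enumerate(table.loci):
        genotypes = table.locus_genotypes(locus)
        p = freqs.frequency_vector(locus)
        ho = observed_heterozygosity(genotypes)
        monomorphic = len(p) == 1
        if hwe:
            hwe_p = hwe_exact_test(
                genotypes,
                seed=None if seed is None else seed + i,
                **(hwe_kwargs or {}),
            ).p_value
        else:
            hwe_p = None
        out.append(
            LocusSummary(
                locus=locus,
                n=len(genotypes),
                HO=ho,
                HE=expected_heterozygosity(p),
                PIC=pic(p),
                PD=power_of_discrimination(genotypes),
                PE=probability_of_exclusion(ho),
                TPI=math.inf if ho == 1.0 else typical_paternity_index(ho),
                hwe_p=1.0 if monomorphic else hwe_p,
            )
        )
    return out


def summary_frame(summaries: Sequence[LocusSummary], ndigits: int = 4) -> pd.DataFrame:
    """Render locus summaries as a statistics-by-loci report table.

    Values are rounded half-up to ``ndigits`` decimals, the display
    convention of published STR frequency tables; pass ``ndigits=None``
    for full precision.
    """
    rows = ["PD", "PIC", "PE", "TPI", "HO", "HE", "hwe_p", "n"]
    data = {}
    for s in summaries:
        col = [s.PD, s.PIC, s.PE, s.TPI, s.HO, s.HE, s.hwe_p, s.n]
        if ndigits is not None:
            col = [
                round_half_up(v, ndigits)
                if isinstance(v, float) and math.isfinite(v)
                else v
                for v in col
            ]
        data[s.locus] = col
    return pd.DataFrame(data, index=rows)
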