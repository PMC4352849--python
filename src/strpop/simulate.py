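"""Synthetic multi-population STR study generator.

The generator emulates the design of a multi-population forensic STR
study — one set of autosomal STR loci typed in several population
samples — with every relevant parameter controlled and recorded, so the
whole analysis pipeline is testable with known ground truth:

* ancestral allele frequencies per locus are symmetric-Dirichlet draws
  over a realistic STR allele ladder (repeat units 7-24, optional
  microvariants);
* each population's frequencies diverge from the ancestral vector under
  the Balding-Nichols model — a Dirichlet draw with parameter
  ``p * (1 - Fst) / Fst`` — which makes Fst an explicit, recoverable
  parameter;
* genotypes are sampled under Hardy-Weinberg equilibrium, with optional
  inbreeding ``f`` (``P(ii) = p_i^2 + f p_i (1 - p_i)``,
  ``P(ij) = 2 p_i p_j (1 - f)``);
* optional two-locus linkage disequilibrium is injected on designated
  locus pairs, which are made biallelic so the feasible range of the
  gametic coefficient D is exact.

Defaults mirror a typical study of this kind: 11 populations x 21 loci,
around 100 individuals per sample, 4-25 alleles per locus with a 10%
microvariant rate, and mild differentiation (Fst = 0.02).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alleles import AlleleLabel
from .tables import GenotypeTable

__all__ = [
    "SimConfig",
    "StudyFixture",
    "str_allele_ladder",
    "sample_ancestral_frequencies",
    "diverge_balding_nichols",
    "sample_genotypes",
    "sample_linked_pair",
    "make_study_fixture",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameterization of one synthetic study; identical configs give
    byte-identical datasets."""

    n_populations: int = 11
    n_individuals: int | tuple[int, ...] = 100
    n_loci: int = 21
    alleles_per_locus: tuple[int, int] = (4, 25)
    dirichlet_concentration: float = 1.0
    fst: float | tuple[float, ...] = 0.02
    inbreeding_f: float | tuple[float, ...] = 0.0
    ld_pairs: tuple[tuple[int, int, float], ...] = ()  # (locus_idx, locus_idx, D)
    microvariant_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 1 or self.n_loci < 1:
            raise ValueError("need at least one population and one locus")
        lo, hi = self.alleles_per_locus
        if not 1 <= lo <= hi:
            raise ValueError(f"bad allele range {self.alleles_per_locus}")
        if self.dirichlet_concentration <= 0:
            raise ValueError("Dirichlet concentration must be positive")
        for fst in self._per_pop(self.fst):
            if not 0.0 <= fst < 1.0:
                raise ValueError(f"fst out of [0,1): {fst}")
        for f in self._per_pop(self.inbreeding_f):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"inbreeding out of [0,1]: {f}")
        if not 0.0 <= self.microvariant_rate <= 1.0:
            raise ValueError("microvariant rate out of [0,1]")
        seen: set[int] = set()
        for i, j, _d in self.ld_pairs:
            if i == j or not (0 <= i < self.n_loci and 0 <= j < self.n_loci):
                raise ValueError(f"bad LD pair ({i}, {j})")
            if i in seen or j in seen:
                raise ValueError("LD pairs must be disjoint")
            seen.update((i, j))

    def _per_pop(self, value) -> tuple:
        if isinstance(value, (int, float)):
            return (value,) * self.n_populations
        if len(value) != self.n_populations:
            raise ValueError("per-population parameter has wrong length")
        return tuple(value)

    @property
    def pop_sizes(self) -> tuple[int, ...]:
        return tuple(int(v) for v in self._per_pop(self.n_individuals))

    @property
    def pop_fst(self) -> tuple[float, ...]:
        return tuple(float(v) for v in self._per_pop(self.fst))

    @property
    def pop_inbreeding(self) -> tuple[float, ...]:
        return tuple(float(v) for v in self._per_pop(self.inbreeding_f))


def str_allele_ladder(
    k: int, microvariant_rate: float, rng: np.random.Generator
) -> list[AlleleLabel]:
    """Draw ``k`` distinct allele labels from a realistic STR ladder.

    Full-repeat alleles run over a contiguous window inside 7-24; each
    rung may additionally carry a microvariant (".1"/".2"/".3") with the
    given rate.  If ``k`` exceeds what full repeats alone can offer,
    microvariants fill the gap.
    """
    if k < 1:
        raise ValueError("need at least one allele")
    base_lo, base_hi = 7, 24
    pool: list[AlleleLabel] = []
    # start low enough that full repeats alone could cover k when possible
    start = int(rng.integers(base_lo, max(base_lo + 1, base_hi - k + 2)))
    repeat = start
    while len(pool) < k:
        if repeat > base_hi and not pool:
            raise ValueError(f"cannot build a ladder of {k} alleles")
        if repeat > base_hi:
            # ladder exhausted: force microvariants onto existing rungs
            for r in range(start, base_hi + 1):
                for p in (1, 2, 3):
                    lab = AlleleLabel(r, p)
                    if lab not in pool:
                        pool.append(lab)
                    if len(pool) >= k:
                        break
                if len(pool) >= k:
                    break
            break
        pool.append(AlleleLabel(repeat, 0))
        if len(pool) < k and rng.random() < microvariant_rate:
            pool.append(AlleleLabel(repeat, int(rng.integers(1, 4))))
        repeat += 1
    return sorted(pool[:k])


def sample_ancestral_frequencies(
    k: int,
    concentration: float = 1.0,
    rng: np.random.Generator | int | None = None,
    microvariant_rate: float = 0.1,
) -> tuple[list[AlleleLabel], np.ndarray]:
    """Symmetric-Dirichlet ancestral frequencies over a fresh allele ladder."""
    if k < 1:
        raise ValueError("need at least one allele")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    labels = str_allele_ladder(k, microvariant_rate, rng)
    if k == 1:
        return labels, np.array([1.0])
    freqs = rng.dirichlet(np.full(k, concentration))
    return labels, freqs


def diverge_balding_nichols(
    p: np.ndarray, fst: float, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Descendant frequencies under the Balding-Nichols model.

    A Dirichlet draw with parameter ``p (1 - Fst) / Fst``; the mean is
    the ancestral vector and the dispersion around it is exactly Fst.
    ``fst = 0`` returns the ancestral vector unchanged.
    """
    p = np.asarray(p, dtype=float)
    if not 0.0 <= fst < 1.0:
        raise ValueError(f"fst out of [0,1): {fst}")
    if fst == 0.0 or len(p) == 1:
        return p.copy()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return rng.dirichlet(p * (1.0 - fst) / fst)


def sample_genotypes(
    labels: Sequence[AlleleLabel],
    p: np.ndarray,
    n: int,
    inbreeding_f: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> list[tuple[AlleleLabel, AlleleLabel]]:
    """Sample ``n`` diploid genotypes, HWE with optional inbreeding.

    With probability ``f`` an individual's two gene copies are identical
    by descent (one draw, homozygote), otherwise two independent draws —
    giving ``P(ii) = p_i^2 + f p_i (1 - p_i)`` and
    ``P(ij) = 2 p_i p_j (1 - f)``.  ``f = 0`` is exact HWE sampling.
    """
    if n < 1:
        raise ValueError("need at least one individual")
    if not 0.0 <= inbreeding_f <= 1.0:
        raise ValueError(f"inbreeding out of [0,1]: {inbreeding_f}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = np.asarray(p, dtype=float)
    first = rng.choice(len(p), size=n, p=p)
    second = rng.choice(len(p), size=n, p=p)
    if inbreeding_f > 0.0:
        ibd = rng.random(n) < inbreeding_f
        second = np.where(ibd, first, second)
    return [(labels[i], labels[j]) for i, j in zip(first, second)]


def feasible_d_range(pa: float, pb: float) -> tuple[float, float]:
    """Feasible gametic D for biallelic loci with major-allele freqs pa, pb."""
    qa, qb = 1.0 - pa, 1.0 - pb
    return (-min(pa * pb, qa * qb), min(pa * qb, qa * pb))


def sample_linked_pair(
    labels_a: Sequence[AlleleLabel],
    labels_b: Sequence[AlleleLabel],
    pa: float,
    pb: float,
    d: float,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> tuple[list, list]:
    """Sample two biallelic genotype columns with gametic disequilibrium D.

    Haplotype frequencies are ``p(AB) = pa*pb + D`` and so on with the
    usual sign pattern; individuals are formed from two independent
    haplotypes.  ``d = 0`` gives independent loci.
    """
    if len(labels_a) != 2 or len(labels_b) != 2:
        raise ValueError("linked-pair sampling is biallelic by construction")
    lo, hi = feasible_d_range(pa, pb)
    if not lo <= d <= hi:
        raise ValueError(f"infeasible D={d}; feasible range [{lo:.4f}, {hi:.4f}]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    qa, qb = 1.0 - pa, 1.0 - pb
    hap_p = np.array([pa * pb + d, pa * qb - d, qa * pb - d, qa * qb + d])
    hap_p = np.clip(hap_p, 0.0, None)
    hap_p /= hap_p.sum()
    haps = rng.choice(4, size=2 * n, p=hap_p)
    a_idx = haps // 2  # 0 -> major allele A, 1 -> minor
    b_idx = haps % 2
    col_a = [
        (labels_a[a_idx[2 * t]], labels_a[a_idx[2 * t + 1]]) for t in range(n)
    ]
    col_b = [
        (labels_b[b_idx[2 * t]], labels_b[b_idx[2 * t + 1]]) for t in range(n)
    ]
    return col_a, col_b


@dataclass
class StudyFixture:
    """A generated study plus the ground truth behind it."""

    config: SimConfig
    populations: list[GenotypeTable]
    loci: list[str]
    ancestral: dict[str, tuple[list[AlleleLabel], np.ndarray]]
    population_frequencies: dict[str, dict[str, np.ndarray]]  # pop -> locus -> p
    realized_ld: dict[tuple[str, str, str], float] = field(default_factory=dict)
    #: keys are (population_id, locusA, locusB); D may be clamped per population

    @property
    def ld_locus_names(self) -> set[str]:
        return {
            self.loci[i] for pair in self.config.ld_pairs for i in pair[:2]
        }


def make_study_fixture(config: SimConfig) -> StudyFixture:
    """Generate the full multi-population study a config describes."""
    rng = np.random.default_rng(config.seed)
    loci = [f"L{idx + 1:02d}" for idx in range(config.n_loci)]
    ld_loci = {i for pair in config.ld_pairs for i in pair[:2]}

    ancestral: dict[str, tuple[list[AlleleLabel], np.ndarray]] = {}
    for idx, locus in enumerate(loci):
        if idx in ld_loci:
            # LD pairs are biallelic with balanced ancestral frequencies so
            # the feasible range of the gametic coefficient D stays wide
            labels = str_allele_ladder(2, config.microvariant_rate, rng)
            ancestral[locus] = (labels, np.array([0.5, 0.5]))
        else:
            lo, hi = config.alleles_per_locus
            k = int(rng.integers(lo, hi + 1))
            ancestral[locus] = sample_ancestral_frequencies(
                k, config.dirichlet_concentration, rng, config.microvariant_rate
            )

    pop_ids = [f"POP{i + 1:02d}" for i in range(config.n_populations)]
    sizes = config.pop_sizes
    fsts = config.pop_fst
    fs = config.pop_inbreeding

    populations: list[GenotypeTable] = []
    pop_freqs: dict[str, dict[str, np.ndarray]] = {}
    realized_ld: dict[tuple[str, str, str], float] = {}

    for p_idx, pop_id in enumerate(pop_ids):
        n = sizes[p_idx]
        samples = [f"{pop_id}_I{t + 1:03d}" for t in range(n)]
        freqs: dict[str, np.ndarray] = {}
        columns: dict[str, list] = {}
        for locus in loci:
            labels, anc = ancestral[locus]
            p = diverge_balding_nichols(anc, fsts[p_idx], rng)
            freqs[locus] = p
            columns[locus] = sample_genotypes(labels, p, n, fs[p_idx], rng)
        for i, j, d_req in config.ld_pairs:
            la, lb = loci[i], loci[j]
            labels_a, labels_b = ancestral[la][0], ancestral[lb][0]
            pa, pb = float(freqs[la][0]), float(freqs[lb][0])
            lo, hi = feasible_d_range(pa, pb)
            d = min(max(d_req, 0.95 * lo), 0.95 * hi)  # keep strictly feasible
            columns[la], columns[lb] = sample_linked_pair(
                labels_a, labels_b, pa, pb, d, n, rng
            )
            realized_ld[(pop_id, la, lb)] = d
        genotypes = {
            (sample, locus): columns[locus][t]
            for locus in loci
            for t, sample in enumerate(samples)
        }
        populations.append(GenotypeTable(pop_id, samples, loci, genotypes))
        pop_freqs[pop_id] = freqs

    return StudyFixture(config, populations, loci, ancestral, pop_freqs, realized_ld)
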