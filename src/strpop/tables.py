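"""In-memory containers for STR genotype and allele-frequency data.

A :class:`GenotypeTable` holds the diploid genotypes of one population
sample (individuals x loci, unordered allele pairs, missing allowed).
An :class:`AlleleFrequencyTable` holds per-locus allele frequencies with
the per-locus typed sample size, which is all most downstream statistics
need.  Missing genotypes are handled by per-locus deletion: each locus
has its own typed count ``n_l`` and partial profiles never drop an
individual entirely.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .alleles import AlleleLabel, Genotype, sort_genotype

__all__ = ["GenotypeTable", "AlleleFrequencyTable"]


class GenotypeTable:
    """Diploid STR genotypes for one population sample.

    Parameters
    ----------
    population_id : str
        Name of the population sample.
    individuals : sequence of str
        Sample identifiers, unique.
    loci : sequence of str
        Locus names, unique.
    genotypes : mapping
        ``(sample, locus) -> (AlleleLabel, AlleleLabel)``; absent keys are
        missing genotypes.  Pairs are stored order-free.
    """

    def __init__(
        self,
        population_id: str,
        individuals: Sequence[str],
        loci: Sequence[str],
        genotypes: Mapping[tuple[str, str], tuple[AlleleLabel, AlleleLabel]],
    ) -> None:
        if len(set(individuals)) != len(individuals):
            dupes = [s for s, c in Counter(individuals).items() if c > 1]
            raise ValueError(f"duplicate sample id(s): {dupes}")
        if len(set(loci)) != len(loci):
            raise ValueError("duplicate locus names")
        self.population_id = population_id
        self.individuals = list(individuals)
        self.loci = list(loci)
        ind_set, loc_set = set(individuals), set(loci)
        self._geno: dict[tuple[str, str], Genotype] = {}
        for (sample, locus), pair in genotypes.items():
            if sample not in ind_set:
                raise KeyError(f"unknown sample id {sample!r}")
            if locus not in loc_set:
                raise KeyError(f"unknown locus {locus!r}")
            a, b = pair
            self._geno[(sample, locus)] = sort_genotype(a, b)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def genotype(self, sample: str, locus: str) -> Genotype | None:
        """The stored unordered pair, or None if missing."""
        return self._geno.get((sample, locus))

    def locus_genotypes(self, locus: str) -> list[Genotype]:
        """All typed genotypes at a locus, in individual order."""
        if locus not in self.loci:
            raise KeyError(f"unknown locus {locus!r}")
        out = []
        for sample in self.individuals:
            g = self._geno.get((sample, locus))
            if g is not None:
                out.append(g)
        return out

    def n_typed(self, locus: str) -> int:
        return len(self.locus_genotypes(locus))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.population_id == other.population_id
            and self.individuals == other.individuals
            and self.loci == other.loci
            and self._geno == other._geno
        )

    def __repr__(self) -> str:
        return (
            f"<GenotypeTable {self.population_id!r}: "
            f"{self.n_individuals} individuals x {len(self.loci)} loci>"
        )


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele frequencies with per-locus typed sample sizes.

    ``frequencies[locus][allele]`` is the fraction of the ``2 * n[locus]``
    gene copies carrying that allele; only observed alleles appear.
    """

    population_id: str
    frequencies: dict[str, dict[AlleleLabel, float]] = field(default_factory=dict)
    n: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_genotypes(cls, table: GenotypeTable) -> "AlleleFrequencyTable":
        out = cls(population_id=table.population_id)
        for locus in table.loci:
            pairs = table.locus_genotypes(locus)
            if not pairs:
                raise ValueError(f"no data at locus {locus!r}")
            counts: Counter[AlleleLabel] = Counter()
            for a, b in pairs:
                counts[a] += 1
                counts[b] += 1
            n_l = len(pairs)
            out.frequencies[locus] = {
                allele: counts[allele] / (2 * n_l) for allele in sorted(counts)
            }
            out.n[locus] = n_l
        return out

    @property
    def loci(self) -> list[str]:
        return list(self.frequencies)

    def alleles(self, locus: str) -> list[AlleleLabel]:
        return sorted(self.frequencies[locus])

    def frequency(self, locus: str, allele: AlleleLabel) -> float:
        """Frequency of an allele, 0.0 if unobserved at the locus."""
        return self.frequencies[locus].get(allele, 0.0)

    def frequency_vector(self, locus: str) -> list[float]:
        return [self.frequencies[locus][a] for a in self.alleles(locus)]

    def count_observed_alleles(self, loci: Iterable[str] | None = None) -> int:
        """Number of (locus, allele) pairs with positive frequency."""
        loci = self.loci if loci is None else list(loci)
        return sum(
            sum(1 for f in self.frequencies[locus].values() if f > 0)
            for locus in loci
        )

    def validate(self, atol: float = 1e-9) -> None:
        """Check simplex and resolution invariants at every locus."""
        for locus, freqs in self.frequencies.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > atol:
                raise ValueError(f"frequencies at {locus!r} sum to {total}")
            if any(f <= 0 for f in freqs.values()):
                raise ValueError(f"non-positive frequency at {locus!r}")
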