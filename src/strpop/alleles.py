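"""STR allele nomenclature.

Forensic STR alleles are named by their repeat count, with microvariant
alleles carrying a partial-repeat suffix: "13" is thirteen full repeats,
"13.2" is thirteen repeats plus two bases.  Allele labels sort first by
repeat count and then by the partial suffix, so "13" < "13.2" < "14".
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import total_ordering

__all__ = ["AlleleLabel", "Genotype", "sort_genotype"]

_ALLELE_RE = re.compile(r"^(\d+)(?:\.(\d))?$")


@total_ordering
@dataclass(frozen=True)
class AlleleLabel:
    """An STR allele: full repeat units plus an optional microvariant suffix.

    Parameters
    ----------
    repeat_units : int
        Number of complete repeat units (non-negative).
    partial_repeat : int
        Microvariant suffix in {0, 1, 2, 3}; 0 means a full repeat allele.
    """

    repeat_units: int
    partial_repeat: int = 0

    def __post_init__(self) -> None:
        if self.repeat_units < 0:
            raise ValueError(f"negative repeat count: {self.repeat_units}")
        if self.partial_repeat not in (0, 1, 2, 3):
            raise ValueError(
                f"partial repeat must be in {{0,1,2,3}}, got {self.partial_repeat}"
            )

    @classmethod
    def from_string(cls, text: str) -> "AlleleLabel":
        m = _ALLELE_RE.match(text.strip())
        if m is None:
            raise ValueError(f"malformed allele label: {text!r}")
        return cls(int(m.group(1)), int(m.group(2)) if m.group(2) else 0)

    def __str__(self) -> str:
        if self.partial_repeat:
            return f"{self.repeat_units}.{self.partial_repeat}"
        return str(self.repeat_units)

    def __repr__(self) -> str:
        return f"AlleleLabel({self})"

    def __lt__(self, other: "AlleleLabel") -> bool:
        if not isinstance(other, AlleleLabel):
            return NotImplemented
        return (self.repeat_units, self.partial_repeat) < (
            other.repeat_units,
            other.partial_repeat,
        )

    # GenePop interchange: allele "R.P" -> integer 10*R + P in a 3-digit
    # field, e.g. 13.2 -> 132, 14 -> 140.  Decodable because P < 10.
    def genepop_code(self) -> int:
        code = 10 * self.repeat_units + self.partial_repeat
        if not 1 <= code <= 999:
            # 0 is reserved for the GenePop missing sentinel
            raise ValueError(
                f"allele {self} not encodable in a 3-digit GenePop field"
            )
        return code

    @classmethod
    def from_genepop_code(cls, code: int) -> "AlleleLabel":
        if not 1 <= code <= 999:
            raise ValueError(f"invalid GenePop allele code {code}")
        return cls(code // 10, code % 10)


#: An unordered diploid genotype, stored as a sorted pair.
Genotype = tuple[AlleleLabel, AlleleLabel]


def sort_genotype(a: AlleleLabel, b: AlleleLabel) -> Genotype:
    """Canonical order-free storage form of an unordered allele pair."""
    return (a, b) if a <= b else (b, a)
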