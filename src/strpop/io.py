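"""Readers and writers for genotype and allele-frequency tables.

Two text formats are supported for genotypes:

* a simple CSV dialect — header ``Sample,<locus>,<locus>,...``, genotype
  cells ``a/b`` (or ``a,b`` when quoted), blank for missing;
* the GenePop format, with microvariant alleles encoded as 3-digit
  integers ``10*repeat + partial`` (``13.2`` -> ``132``).  GenePop has no
  native microvariant or population-name support, so the code mapping and
  the population ids are declared in the file's free-text title line.

Frequency tables are CSV with allele labels as rows and loci as columns
(the layout of a published STR frequency table), with an optional ``n``
row carrying per-locus typed sample sizes.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Sequence

from .alleles import AlleleLabel
from .tables import AlleleFrequencyTable, GenotypeTable

__all__ = [
    "read_genotype_csv",
    "write_genotype_csv",
    "read_genepop",
    "write_genepop",
    "read_frequency_csv",
    "write_frequency_csv",
]

_MISSING_GENEPOP = "000000"


def _parse_cell(cell: str, sample: str, locus: str) -> tuple[AlleleLabel, AlleleLabel] | None:
    cell = cell.strip()
    if not cell:
        return None
    for sep in ("/", ","):
        if sep in cell:
            parts = cell.split(sep)
            if len(parts) != 2:
                break
            try:
                return (
                    AlleleLabel.from_string(parts[0]),
                    AlleleLabel.from_string(parts[1]),
                )
            except ValueError as exc:
                raise ValueError(
                    f"sample {sample!r}, locus {locus!r}: {exc}"
                ) from None
    raise ValueError(
        f"sample {sample!r}, locus {locus!r}: malformed genotype cell {cell!r}"
    )


def read_genotype_csv(path: str | Path, population_id: str | None = None) -> GenotypeTable:
    """Read a genotype table from the package CSV dialect.

    The header row names the loci; the first column holds sample ids.
    Blank cells are missing genotypes (per-locus deletion downstream).
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0]
    loci = [c.strip() for c in header[1:]]
    individuals: list[str] = []
    genotypes: dict[tuple[str, str], tuple[AlleleLabel, AlleleLabel]] = {}
    for row in rows[1:]:
        if not row or not any(c.strip() for c in row):
            continue
        sample = row[0].strip()
        individuals.append(sample)
        for locus, cell in zip(loci, row[1:]):
            pair = _parse_cell(cell, sample, locus)
            if pair is not None:
                genotypes[(sample, locus)] = pair
    return GenotypeTable(
        population_id or path.stem, individuals, loci, genotypes
    )


def write_genotype_csv(table: GenotypeTable, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["Sample", *table.loci])
        for sample in table.individuals:
            row = [sample]
            for locus in table.loci:
                g = table.genotype(sample, locus)
                row.append("" if g is None else f"{g[0]}/{g[1]}")
            w.writerow(row)


def write_genepop(
    tables: Sequence[GenotypeTable], path: str | Path, title: str | None = None
) -> None:
    """Write one or more population samples as a GenePop file.

    Alleles use the 3-digit ``10*repeat + partial`` code; the mapping and
    the population ids are recorded in the title line so that the file
    round-trips through :func:`read_genepop`.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no populations to write")
    loci = tables[0].loci
    for t in tables[1:]:
        if t.loci != loci:
            raise ValueError("populations disagree on locus list")
    pop_ids = "|".join(t.population_id for t in tables)
    header = title or "strpop export"
    header += f" ; allele code 10*repeat+partial ; populations={pop_ids}"
    lines = [header]
    lines.extend(loci)
    for t in tables:
        lines.append("POP")
        for sample in t.individuals:
            fields = []
            for locus in loci:
                g = t.genotype(sample, locus)
                if g is None:
                    fields.append(_MISSING_GENEPOP)
                else:
                    fields.append(
                        f"{g[0].genepop_code():03d}{g[1].genepop_code():03d}"
                    )
            lines.append(f"{sample} ,  " + " ".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genepop(path: str | Path) -> list[GenotypeTable]:
    """Read a GenePop file written with the package's allele convention."""
    raw = Path(path).read_text().splitlines()
    if len(raw) < 3:
        raise ValueError(f"{path}: not a GenePop file")
    title = raw[0]
    m = re.search(r"populations=(\S+)", title)
    declared = m.group(1).split("|") if m else None
    # locus names: one per line (or a single comma-separated line) up to POP
    i = 1
    loci: list[str] = []
    while i < len(raw) and raw[i].strip().upper() != "POP":
        loci.extend(s.strip() for s in raw[i].split(",") if s.strip())
        i += 1
    pops: list[GenotypeTable] = []
    block: list[tuple[str, list[str]]] = []

    def flush() -> None:
        if block is None:
            return
        idx = len(pops)
        pop_id = declared[idx] if declared and idx < len(declared) else f"pop_{idx + 1}"
        individuals = [s for s, _ in block]
        genotypes: dict[tuple[str, str], tuple[AlleleLabel, AlleleLabel]] = {}
        for sample, fields in block:
            if len(fields) != len(loci):
                raise ValueError(
                    f"{path}: sample {sample!r} has {len(fields)} genotypes "
                    f"for {len(loci)} loci"
                )
            for locus, tok in zip(loci, fields):
                if tok == _MISSING_GENEPOP or set(tok) == {"0"}:
                    continue
                if len(tok) != 6:
                    raise ValueError(f"{path}: bad genotype field {tok!r}")
                genotypes[(sample, locus)] = (
                    AlleleLabel.from_genepop_code(int(tok[:3])),
                    AlleleLabel.from_genepop_code(int(tok[3:])),
                )
        pops.append(GenotypeTable(pop_id, individuals, loci, genotypes))

    while i < len(raw):
        line = raw[i].strip()
        i += 1
        if not line:
            continue
        if line.upper() == "POP":
            if block:
                flush()
            block = []
            continue
        if "," not in line:
            raise ValueError(f"{path}: malformed record line {line!r}")
        sample, rest = line.split(",", 1)
        block.append((sample.strip(), rest.split()))
    flush()
    return pops


def read_frequency_csv(
    path: str | Path, population_id: str | None = None, n: int | None = None
) -> AlleleFrequencyTable:
    """Read a frequency table (rows = allele labels, columns = loci).

    A row labelled ``n`` (case-insensitive) gives per-locus typed sample
    sizes; alternatively a single ``n`` applying to every locus may be
    passed.  Blank cells mean the allele was not observed at that locus.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    header = rows[0]
    loci = [c.strip() for c in header[1:]]
    table = AlleleFrequencyTable(population_id or path.stem)
    table.frequencies = {locus: {} for locus in loci}
    sizes: dict[str, int] = {}
    for row in rows[1:]:
        if not row or not any(c.strip() for c in row):
            continue
        label = row[0].strip()
        if label.lower() == "n":
            for locus, cell in zip(loci, row[1:]):
                if cell.strip():
                    sizes[locus] = int(float(cell))
            continue
        allele = AlleleLabel.from_string(label)
        for locus, cell in zip(loci, row[1:]):
            if cell.strip():
                f = float(cell)
                if f > 0:
                    table.frequencies[locus][allele] = f
    if n is not None:
        sizes = {locus: n for locus in loci}
    table.n = sizes
    return table


def write_frequency_csv(table: AlleleFrequencyTable, path: str | Path) -> None:
    loci = table.loci
    alleles = sorted({a for locus in loci for a in table.frequencies[locus]})
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["allele", *loci])
        if table.n:
            w.writerow(["n", *[table.n.get(locus, "") for locus in loci]])
        for allele in alleles:
            row = [str(allele)]
            for locus in loci:
                f = table.frequencies[locus].get(allele)
                row.append("" if f is None else repr(float(f)))
            w.writerow(row)
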