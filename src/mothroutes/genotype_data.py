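"""Diploid microsatellite genotype container and GenePop-format I/O.

Genotypes are unordered pairs of allele sizes in base pairs.  A genotype is
either fully observed or wholly missing: following the GenePop convention,
any allele code of 0 marks the whole genotype as missing.  Individuals are
grouped into named populations whose order is preserved through I/O.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LocusInfo",
    "Individual",
    "GenotypeDataset",
    "AlleleCounts",
    "GenePopError",
    "read_genepop",
    "write_genepop",
    "allele_counts",
    "write_table",
]


class GenePopError(ValueError):
    """Raised for malformed GenePop input or un-encodable output."""


@dataclass(frozen=True)
class LocusInfo:
    """Locus label with an optional allele-size range (bp) and repeat motif length."""

    name: str
    size_min: int | None = None
    size_max: int | None = None
    motif: int | None = None


@dataclass
class Individual:
    label: str
    #: one slot per locus: (a, b) unordered pair of allele sizes, or None
    genotypes: list[tuple[int, int] | None] = field(default_factory=list)


@dataclass
class GenotypeDataset:
    loci: list[LocusInfo]
    populations: list[str]
    #: parallel to ``populations``: individuals of each population
    individuals: list[list[Individual]]

    def __post_init__(self) -> None:
        if len(set(self.populations)) != len(self.populations):
            raise ValueError("population labels must be unique")
        if len(self.individuals) != len(self.populations):
            raise ValueError("one individual list per population required")
        n_loci = len(self.loci)
        for pop, inds in zip(self.populations, self.individuals):
            for ind in inds:
                if len(ind.genotypes) != n_loci:
                    raise ValueError(
                        f"individual {ind.label!r} in {pop!r} has "
                        f"{len(ind.genotypes)} genotypes, expected {n_loci}"
                    )
                for g in ind.genotypes:
                    if g is not None and (g[0] <= 0 or g[1] <= 0):
                        raise ValueError("allele sizes must be positive integers")

    # -- convenience accessors -------------------------------------------------

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def population_index(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError:
            raise KeyError(f"unknown population {population!r}") from None

    def locus_index(self, locus: str) -> int:
        try:
            return self.locus_names.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def sample_sizes(self) -> dict[str, int]:
        return {p: len(inds) for p, inds in zip(self.populations, self.individuals)}

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Flatten to ``(alleles, pop_idx)``.

        ``alleles`` has shape (n_individuals, n_loci, 2) with -1 for missing;
        ``pop_idx`` maps each row to its population's index.  Row order follows
        population order, then within-population order.
        """
        n = sum(len(inds) for inds in self.individuals)
        alleles = np.full((n, self.n_loci, 2), -1, dtype=np.int32)
        pop_idx = np.empty(n, dtype=np.int32)
        row = 0
        for p, inds in enumerate(self.individuals):
            for ind in inds:
                for j, g in enumerate(ind.genotypes):
                    if g is not None:
                        alleles[row, j, 0] = g[0]
                        alleles[row, j, 1] = g[1]
                pop_idx[row] = p
                row += 1
        return alleles, pop_idx

    @classmethod
    def from_arrays(
        cls,
        alleles: np.ndarray,
        pop_idx: np.ndarray,
        populations: Sequence[str],
        loci: Sequence[LocusInfo | str],
        labels: Sequence[str] | None = None,
    ) -> "GenotypeDataset":
        """Inverse of :meth:`to_arrays`; -1 (or any non-positive allele) = missing."""
        loci_info = [l if isinstance(l, LocusInfo) else LocusInfo(l) for l in loci]
        per_pop: list[list[Individual]] = [[] for _ in populations]
        for row in range(alleles.shape[0]):
            p = int(pop_idx[row])
            label = labels[row] if labels is not None else f"{populations[p]}_{len(per_pop[p]) + 1}"
            genos: list[tuple[int, int] | None] = []
            for j in range(alleles.shape[1]):
                a, b = int(alleles[row, j, 0]), int(alleles[row, j, 1])
                genos.append(None if a <= 0 or b <= 0 else (a, b))
            per_pop[p].append(Individual(label, genos))
        return cls(loci_info, list(populations), per_pop)


@dataclass
class AlleleCounts:
    """Gene-copy counts of one locus in one population."""

    locus: str
    population: str
    counts: dict[int, int]
    n_genes: int

    def frequencies(self) -> dict[int, float]:
        if self.n_genes == 0:
            return {}
        return {a: c / self.n_genes for a, c in self.counts.items()}


# -- GenePop I/O ----------------------------------------------------------------


def _parse_genotype_token(token: str, line_no: int) -> tuple[int, int] | None:
    if len(token) == 4:
        w = 2
    elif len(token) == 6:
        w = 3
    else:
        raise GenePopError(
            f"line {line_no}: genotype token {token!r} is not 4 or 6 digits"
        )
    if not token.isdigit():
        raise GenePopError(f"line {line_no}: genotype token {token!r} is not numeric")
    a, b = int(token[:w]), int(token[w:])
    if a == 0 or b == 0:
        return None
    return (a, b)


def read_genepop(path) -> GenotypeDataset:
    """Parse a GenePop text file.

    Accepts both 2- and 3-digit allele encodings, locus names one per line or
    comma-separated, and case-insensitive ``POP`` delimiters.  The individual
    label is everything before the final comma of each genotype line.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenePopError("empty file")

    # title line is lines[0]; locus names run until the first POP line
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        chunk = lines[i].strip()
        if chunk:
            locus_names.extend(s.strip() for s in chunk.split(",") if s.strip())
        i += 1
    if i == len(lines):
        raise GenePopError("no POP delimiter found")
    if not locus_names:
        raise GenePopError("no locus names before first POP")

    populations: list[str] = []
    individuals: list[list[Individual]] = []
    current: list[Individual] | None = None
    for line_no in range(i, len(lines)):
        raw = lines[line_no]
        line = raw.strip()
        if not line:
            continue
        if line.upper() == "POP":
            current = []
            individuals.append(current)
            populations.append(f"pop{len(individuals)}")
            continue
        if current is None:
            raise GenePopError(f"line {line_no + 1}: genotype data before any POP")
        if "," not in line:
            raise GenePopError(f"line {line_no + 1}: missing comma after individual label")
        label, _, geno_part = line.rpartition(",")
        label = label.strip()
        tokens = geno_part.split()
        if len(tokens) != len(locus_names):
            raise GenePopError(
                f"line {line_no + 1}: {len(tokens)} genotypes for "
                f"{len(locus_names)} loci"
            )
        genos = [_parse_genotype_token(t, line_no + 1) for t in tokens]
        current.append(Individual(label, genos))

    # GenePop has no population-name field; the common convention labels
    # individuals "<pop>_<k>" or repeats the population name.  Derive the
    # population label from the first individual (trailing _<number> stripped);
    # fall back to pop1..popN on collision.
    names = []
    for k, inds in enumerate(individuals):
        if inds:
            stem, _, tail = inds[0].label.rpartition("_")
            names.append(stem if stem and tail.isdigit() else inds[0].label)
        else:
            names.append(f"pop{k + 1}")
    if len(set(names)) == len(names):
        populations = names
    return GenotypeDataset([LocusInfo(n) for n in locus_names], populations, individuals)


def write_genepop(ds: GenotypeDataset, path, title: str = "mothroutes export") -> None:
    """Write GenePop text; 3-digit allele encoding whenever any allele exceeds 99."""
    if not ds.populations:
        raise GenePopError("cannot write a dataset with no populations")
    max_allele = 0
    for inds in ds.individuals:
        for ind in inds:
            for g in ind.genotypes:
                if g is not None:
                    max_allele = max(max_allele, g[0], g[1])
    if max_allele > 999:
        raise GenePopError(f"allele size {max_allele} exceeds GenePop 3-digit encoding")
    w = 3 if max_allele > 99 else 2
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(title + "\n")
        for name in ds.locus_names:
            fh.write(name + "\n")
        for inds in ds.individuals:
            fh.write("POP\n")
            for ind in inds:
                toks = []
                for g in ind.genotypes:
                    if g is None:
                        toks.append("0" * (2 * w))
                    else:
                        toks.append(f"{g[0]:0{w}d}{g[1]:0{w}d}")
                fh.write(f"{ind.label}, " + " ".join(toks) + "\n")


def allele_counts(ds: GenotypeDataset, locus: str, population: str) -> AlleleCounts:
    """Count gene copies of ``locus`` in ``population`` (2 per non-missing genotype)."""
    p = ds.population_index(population)
    j = ds.locus_index(locus)
    counter: Counter[int] = Counter()
    for ind in ds.individuals[p]:
        g = ind.genotypes[j]
        if g is not None:
            counter[g[0]] += 1
            counter[g[1]] += 1
    return AlleleCounts(locus, population, dict(counter), sum(counter.values()))


def write_table(ds: GenotypeDataset, path, sep: str = "\t") -> None:
    """Plain-table export: one row per individual, two columns per locus."""
    with open(path, "wt", encoding="utf-8") as fh:
        header = ["individual", "population"]
        for name in ds.locus_names:
            header += [f"{name}_1", f"{name}_2"]
        fh.write(sep.join(header) + "\n")
        for pop, inds in zip(ds.populations, ds.individuals):
            for ind in inds:
                row = [ind.label, pop]
                for g in ind.genotypes:
                    row += ["", ""] if g is None else [str(g[0]), str(g[1])]
                fh.write(sep.join(row) + "\n")
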