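"""Data model and readers/writers for InDel genotype and frequency tables.

A biallelic insertion/deletion (DIP) marker has two alleles, denoted
DIP+ (insertion) and DIP- (deletion).  Internally every genotype is a
single integer *insertion dosage* — the number of DIP+ alleles carried,
0, 1 or 2 — with ``NaN`` for missing.  The ``plusminus`` reader dialect
("+/+", "+/-", "-/-", "./.") is translated to dosages on input; dosage
is the only representation downstream code ever sees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyDataError,
    InconsistencyError,
    ParseError,
    ValidationError,
)

__all__ = [
    "Locus",
    "GenotypeTable",
    "GenotypeCounts",
    "AlleleFreqs",
    "FrequencyTable",
    "read_genotype_table",
    "write_genotype_table",
    "read_frequency_table",
    "write_frequency_table",
    "tally_genotypes",
    "reconstruct_genotype_counts",
    "round_half_away_from_zero",
]

_PLUSMINUS_TO_DOSAGE = {
    "-/-": 0.0,
    "+/-": 1.0,
    "-/+": 1.0,
    "+/+": 2.0,
    "./.": np.nan,
}
_DOSAGE_TO_PLUSMINUS = {0: "-/-", 1: "+/-", 2: "+/+"}


@dataclass(frozen=True)
class Locus:
    """A single biallelic InDel marker."""

    name: str
    rs_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("locus name must be non-empty")


@dataclass
class GenotypeTable:
    """Sample x locus insertion-dosage matrix with population labels.

    ``dosage[i, j]`` is the number of insertion (DIP+) alleles sample ``i``
    carries at locus ``j`` (0, 1 or 2), or NaN if missing.
    """

    samples: list[str]
    populations: list[str]
    loci: list[Locus]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, l = len(self.samples), len(self.loci)
        if self.dosage.shape != (n, l):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} != (samples={n}, loci={l})"
            )
        if len(self.populations) != n:
            raise ValidationError("one population label required per sample")
        if len(set(self.samples)) != n:
            raise ValidationError("duplicate sample ids")
        names = [loc.name for loc in self.loci]
        if len(set(names)) != l:
            raise ValidationError("duplicate locus names")
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))][0]
            raise ValidationError(f"dosage value {bad!r} outside {{0,1,2}}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def locus_names(self) -> list[str]:
        return [loc.name for loc in self.loci]

    def locus_index(self, locus: "Locus | str") -> int:
        name = locus.name if isinstance(locus, Locus) else locus
        try:
            return self.locus_names.index(name)
        except ValueError:
            raise KeyError(f"locus {name!r} not in table") from None

    def population_mask(self, population: Optional[str]) -> np.ndarray:
        if population is None:
            return np.ones(self.n_samples, dtype=bool)
        mask = np.array([p == population for p in self.populations])
        if not mask.any():
            raise KeyError(f"population {population!r} not in table")
        return mask

    def subset(self, population: str) -> "GenotypeTable":
        mask = self.population_mask(population)
        return GenotypeTable(
            samples=[s for s, m in zip(self.samples, mask) if m],
            populations=[p for p, m in zip(self.populations, mask) if m],
            loci=list(self.loci),
            dosage=self.dosage[mask],
        )

    def population_labels(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        return list(dict.fromkeys(self.populations))


@dataclass(frozen=True)
class GenotypeCounts:
    """Per-locus genotype tallies: deletion homozygotes, heterozygotes,
    insertion homozygotes."""

    n_del_hom: int
    n_het: int
    n_ins_hom: int

    def __post_init__(self) -> None:
        for v in (self.n_del_hom, self.n_het, self.n_ins_hom):
            if v < 0 or v != int(v):
                raise ValidationError("genotype counts must be non-negative integers")
        if self.n == 0:
            raise ValidationError("genotype counts must sum to a positive N")

    @property
    def n(self) -> int:
        return self.n_del_hom + self.n_het + self.n_ins_hom

    @property
    def n_del_alleles(self) -> int:
        return 2 * self.n_del_hom + self.n_het

    @property
    def is_monomorphic(self) -> bool:
        return self.n_del_alleles in (0, 2 * self.n)

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_del_hom, self.n_het, self.n_ins_hom)


@dataclass(frozen=True)
class AlleleFreqs:
    """Deletion/insertion allele frequencies at one locus, with the
    number of gene copies (2N) they were estimated from."""

    p_del: float
    p_ins: float
    n_alleles: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_del <= 1.0):
            raise ValidationError(f"p_del={self.p_del} outside [0, 1]")
        if abs(self.p_del + self.p_ins - 1.0) > 1e-12:
            raise ValidationError("p_del + p_ins must equal 1")
        if self.n_alleles <= 0 or self.n_alleles % 2:
            raise ValidationError("n_alleles must be positive and even")


@dataclass
class FrequencyTable:
    """Population x locus matrix of deletion-allele (DIP-) frequencies."""

    populations: list[str]
    loci: list[Locus]
    p_del: np.ndarray

    def __post_init__(self) -> None:
        self.p_del = np.asarray(self.p_del, dtype=float)
        shape = (len(self.populations), len(self.loci))
        if self.p_del.shape != shape:
            raise ValidationError(f"p_del shape {self.p_del.shape} != {shape}")
        if ((self.p_del < 0) | (self.p_del > 1)).any():
            raise ValidationError("frequencies must lie in [0, 1]")

    @property
    def locus_names(self) -> list[str]:
        return [loc.name for loc in self.loci]

    def row(self, population: str) -> np.ndarray:
        return self.p_del[self.populations.index(population)]


def round_half_away_from_zero(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Python's built-in ``round`` uses banker's rounding, which is unstable
    for recovering integer counts from 4-decimal-place frequencies.
    """
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def _parse_cell(raw: str, dialect: str, row: str, col: str) -> float:
    raw = raw.strip()
    if dialect == "plusminus":
        try:
            return _PLUSMINUS_TO_DOSAGE[raw]
        except KeyError:
            raise ParseError(
                f"sample {row!r}, locus {col!r}: invalid genotype {raw!r} "
                "(expected +/+, +/-, -/- or ./.)"
            ) from None
    if raw in ("", "NA", "NaN", "nan", "."):
        return np.nan
    try:
        value = float(raw)
    except ValueError:
        raise ParseError(
            f"sample {row!r}, locus {col!r}: invalid dosage {raw!r}"
        ) from None
    if value not in (0.0, 1.0, 2.0):
        raise ParseError(
            f"sample {row!r}, locus {col!r}: dosage {raw!r} outside {{0,1,2}}"
        )
    return value


def read_genotype_table(path, dialect: str = "dosage") -> GenotypeTable:
    """Read a genotype TSV: ``sample_id  population  <locus1> ... <locusL>``.

    ``dialect="dosage"`` expects cells 0/1/2/NA (insertion-allele count);
    ``dialect="plusminus"`` expects "+/+", "+/-", "-/-" or "./.".
    """
    if dialect not in ("dosage", "plusminus"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 3 or list(df.columns[:2]) != ["sample_id", "population"]:
        raise ParseError(
            "genotype TSV must start with columns 'sample_id', 'population' "
            "followed by at least one locus column"
        )
    locus_names = list(df.columns[2:])
    samples = df["sample_id"].tolist()
    if len(set(samples)) != len(samples):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise ValidationError(f"duplicate sample ids: {dupes}")
    dosage = np.empty((len(samples), len(locus_names)))
    for j, name in enumerate(locus_names):
        col = df[name].tolist()
        dosage[:, j] = [
            _parse_cell(raw, dialect, samples[i], name) for i, raw in enumerate(col)
        ]
    return GenotypeTable(
        samples=samples,
        populations=df["population"].tolist(),
        loci=[Locus(name) for name in locus_names],
        dosage=dosage,
    )


def write_genotype_table(table: GenotypeTable, path, dialect: str = "dosage") -> None:
    """Write a genotype table as TSV in either reader dialect."""

    def fmt(v: float) -> str:
        if not np.isfinite(v):
            return "./." if dialect == "plusminus" else "NA"
        if dialect == "plusminus":
            return _DOSAGE_TO_PLUSMINUS[int(v)]
        return str(int(v))

    df = pd.DataFrame(
        [[fmt(v) for v in row] for row in table.dosage],
        columns=table.locus_names,
    )
    df.insert(0, "population", table.populations)
    df.insert(0, "sample_id", table.samples)
    df.to_csv(path, sep="\t", index=False)


def read_frequency_table(path) -> FrequencyTable:
    """Read a frequency CSV: ``population,<locus1>,...,<locusL>`` with cells
    holding the DIP- (deletion) allele frequency."""
    df = pd.read_csv(path)
    if df.shape[1] < 2 or df.columns[0] != "population":
        raise ParseError(
            "frequency CSV must have a leading 'population' column "
            "followed by one column per locus"
        )
    return FrequencyTable(
        populations=df["population"].astype(str).tolist(),
        loci=[Locus(name) for name in df.columns[1:]],
        p_del=df.iloc[:, 1:].to_numpy(dtype=float),
    )


def write_frequency_table(freqs: FrequencyTable, path) -> None:
    df = pd.DataFrame(freqs.p_del, columns=freqs.locus_names)
    df.insert(0, "population", freqs.populations)
    df.to_csv(path, index=False)


def tally_genotypes(
    table: GenotypeTable,
    locus: "Locus | str",
    population: Optional[str] = None,
) -> GenotypeCounts:
    """Count (del-hom, het, ins-hom) genotypes at one locus, over one
    population or the whole table; missing genotypes are excluded."""
    j = table.locus_index(locus)
    mask = table.population_mask(population)
    col = table.dosage[mask, j]
    col = col[np.isfinite(col)]
    if col.size == 0:
        raise EmptyDataError(
            f"no non-missing genotypes at locus "
            f"{locus.name if isinstance(locus, Locus) else locus!r}"
        )
    counts = np.bincount(col.astype(int), minlength=3)
    return GenotypeCounts(int(counts[0]), int(counts[1]), int(counts[2]))


def tally_all_loci(
    table: GenotypeTable, population: Optional[str] = None
) -> list[GenotypeCounts]:
    """Per-locus genotype tallies for every locus in the table."""
    return [tally_genotypes(table, loc, population) for loc in table.loci]


def reconstruct_genotype_counts(
    p_del: float, ho: float, n: int
) -> GenotypeCounts:
    """Recover integer genotype counts from a published (DIP- frequency,
    observed heterozygosity, sample size) row.

    Published panel tables print allele frequencies and Ho to 4 decimal
    places; at forensic sample sizes (n in the low hundreds) that precision
    identifies the underlying integer counts uniquely.  The heterozygote
    count is ``round(ho * n)``, the deletion allele count ``round(p_del * 2n)``,
    and the homozygote counts follow by subtraction.  A parity/negativity
    check rejects rows that cannot come from integer counts.
    """
    if not (0.0 <= p_del <= 1.0):
        raise ValidationError(f"p_del={p_del} outside [0, 1]")
    if not (0.0 <= ho <= 1.0):
        raise ValidationError(f"ho={ho} outside [0, 1]")
    if n <= 0:
        raise ValidationError("n must be positive")
    n_het = round_half_away_from_zero(ho * n)
    n_del_alleles = round_half_away_from_zero(p_del * 2 * n)
    if (n_del_alleles - n_het) % 2:
        raise InconsistencyError(
            f"(p_del={p_del}, ho={ho}, n={n}): deletion allele count "
            f"{n_del_alleles} and heterozygote count {n_het} have opposite "
            "parity; no integer genotype counts exist"
        )
    n_del_hom = (n_del_alleles - n_het) // 2
    n_ins_hom = n - n_het - n_del_hom
    if n_del_hom < 0 or n_ins_hom < 0:
        raise InconsistencyError(
            f"(p_del={p_del}, ho={ho}, n={n}) implies a negative genotype count"
        )
    return GenotypeCounts(n_del_hom, n_het, n_ins_hom)
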