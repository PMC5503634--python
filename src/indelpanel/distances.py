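"""Inter-population differentiation: Weir-Cockerham Fst and Nei's D_A.

Fst is estimated by the Weir & Cockerham (1984) theta for two populations,
computed from genotype counts so that the within-individual variance
component (observed heterozygosity) enters the estimator; significance
comes from permuting individuals between the two samples.  Nei's D_A
distance operates on allele-frequency tables:

    D_A = 1 - (1/L) * sum_loci sum_alleles sqrt(x_ia * y_ia)

which for biallelic loci uses the (p_del, 1 - p_del) pair per locus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genotype_io import FrequencyTable, GenotypeCounts, GenotypeTable

__all__ = [
    "DistanceMatrix",
    "FstResult",
    "nei_da",
    "da_matrix",
    "wc_fst_two_pops",
    "fst_permutation_test",
]


@dataclass
class DistanceMatrix:
    """Labeled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValidationError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.all(np.diag(self.values) == 0):
            raise ValidationError("distance matrix diagonal must be zero")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_phylip(self, precision: int = 6) -> str:
        """Lower-triangle PHYLIP distance-matrix format."""
        lines = [f"{len(self.labels)}"]
        for i, label in enumerate(self.labels):
            row = " ".join(f"{self.values[i, j]:.{precision}f}" for j in range(i))
            lines.append(f"{label:<10s} {row}".rstrip())
        return "\n".join(lines) + "\n"

    @classmethod
    def from_phylip(cls, text: str) -> "DistanceMatrix":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        k = int(lines[0].split()[0])
        labels, values = [], np.zeros((k, k))
        for i, line in enumerate(lines[1 : k + 1]):
            parts = line.split()
            labels.append(parts[0])
            for j, v in enumerate(parts[1 : i + 1]):
                values[i, j] = values[j, i] = float(v)
        return cls(labels=labels, values=values)


@dataclass
class FstResult:
    """Per-locus and multilocus Weir-Cockerham theta, with permutation
    p-values when a permutation test was run."""

    locus_names: list[str]
    per_locus: np.ndarray          # theta-hat per locus (NaN if undefined)
    multilocus: float              # sum(a) / sum(a + b + c)
    per_locus_p: Optional[np.ndarray] = None
    multilocus_p: Optional[float] = None
    n_permutations: int = 0
    seed: Optional[int] = None

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"locus": self.locus_names, "fst": self.per_locus})
        if self.per_locus_p is not None:
            df["p"] = self.per_locus_p
        return df


def nei_da(x: Sequence[np.ndarray], y: Sequence[np.ndarray]) -> float:
    """Nei's D_A distance between two populations' per-locus allele
    frequency vectors (same loci, same allele order)."""
    if len(x) != len(y):
        raise ValidationError("populations must share the same locus list")
    total = 0.0
    for fx, fy in zip(x, y):
        fx = np.asarray(fx, dtype=float)
        fy = np.asarray(fy, dtype=float)
        if fx.shape != fy.shape:
            raise ValidationError("allele sets differ at a locus")
        total += float(np.sqrt(fx * fy).sum())
    return 1.0 - total / len(x)


def da_matrix(freqs: FrequencyTable) -> DistanceMatrix:
    """All pairwise D_A distances between the populations of a biallelic
    frequency table (each locus expands to the (p_del, 1-p_del) pair)."""
    k = len(freqs.populations)
    if k < 2:
        raise ValidationError("need at least 2 populations")
    values = np.zeros((k, k))
    vectors = [
        [np.array([p, 1.0 - p]) for p in freqs.p_del[i]] for i in range(k)
    ]
    for i in range(k):
        for j in range(i + 1, k):
            values[i, j] = values[j, i] = nei_da(vectors[i], vectors[j])
    return DistanceMatrix(labels=list(freqs.populations), values=values)


def _wc_components(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) variance components a, b, c per locus for two
    populations, from sample sizes, allele frequencies and heterozygote
    fractions (all arrays over loci)."""
    r = 2.0
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (n_bar / n_c) * (
            s2
            - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar)
            - (r - 1) / r * s2
            - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
        )
    c = h_bar / 2.0
    return a, b, c


def _theta_from_components(
    a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> tuple[np.ndarray, float]:
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = a / (a + b + c)
    keep = np.isfinite(per_locus)
    denom = (a + b + c)[keep].sum()
    multi = float(a[keep].sum() / denom) if denom != 0 else float("nan")
    return per_locus, multi


def _counts_to_nph(
    counts: Sequence[GenotypeCounts],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = np.array([c.n for c in counts], dtype=float)
    p = np.array([c.n_del_alleles for c in counts]) / (2 * n)
    h = np.array([c.n_het for c in counts]) / n
    return n, p, h


def wc_fst_two_pops(
    counts_x: Sequence[GenotypeCounts],
    counts_y: Sequence[GenotypeCounts],
    locus_names: Optional[Sequence[str]] = None,
) -> FstResult:
    """Weir-Cockerham theta between two population samples, per locus and
    multilocus (ratio of summed variance components).

    Loci monomorphic in the pooled sample carry no information and are
    excluded from the multilocus sums (their per-locus entry is NaN).
    Estimates may be slightly negative; they are reported as computed.
    """
    if len(counts_x) != len(counts_y):
        raise ValidationError("populations must cover the same loci")
    if any(c.n < 2 for c in counts_x) or any(c.n < 2 for c in counts_y):
        raise ValidationError("each population needs N >= 2 at every locus")
    n1, p1, h1 = _counts_to_nph(counts_x)
    n2, p2, h2 = _counts_to_nph(counts_y)
    a, b, c = _wc_components(n1, p1, h1, n2, p2, h2)
    per_locus, multi = _theta_from_components(a, b, c)
    n_dropped = int((~np.isfinite(per_locus)).sum())
    if n_dropped:
        warnings.warn(
            f"{n_dropped} locus/loci monomorphic in the pooled sample "
            "excluded from the multilocus estimate",
            stacklevel=2,
        )
    names = (
        list(locus_names)
        if locus_names is not None
        else [f"locus{i+1}" for i in range(len(counts_x))]
    )
    return FstResult(locus_names=names, per_locus=per_locus, multilocus=multi)


def _dosage_nph(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n, p_del, het fraction) per locus from a dosage matrix with NaN
    missing values."""
    finite = np.isfinite(dosage)
    n = finite.sum(axis=0).astype(float)
    ins = np.where(finite, dosage, 0.0).sum(axis=0)
    het = np.where(finite, dosage == 1.0, False).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_del = 1.0 - ins / (2 * n)
        h = het / n
    return n, p_del, h


def _theta_from_dosage(
    dx: np.ndarray, dy: np.ndarray
) -> tuple[np.ndarray, float]:
    a, b, c = _wc_components(*_dosage_nph(dx), *_dosage_nph(dy))
    return _theta_from_components(a, b, c)


def fst_permutation_test(
    table_x: GenotypeTable,
    table_y: GenotypeTable,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> FstResult:
    """Permutation test of differentiation between two genotype tables.

    Individuals (rows, both alleles together) are pooled and reassigned
    uniformly at random to the two original sample sizes; the p-value is
    (1 + #{theta* >= theta_obs}) / (n_perm + 1), per locus and multilocus,
    so it can never be exactly zero.
    """
    if table_x.locus_names != table_y.locus_names:
        raise ValidationError("tables must cover the same loci in the same order")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if seed is None:
        raise ValidationError("a seed is required for the permutation test")
    rng = np.random.default_rng(seed)
    dx, dy = table_x.dosage, table_y.dosage
    obs_per_locus, obs_multi = _theta_from_dosage(dx, dy)
    pooled = np.vstack([dx, dy])
    n_x = dx.shape[0]
    ge_locus = np.zeros(len(table_x.loci))
    ge_multi = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        px, py = pooled[perm[:n_x]], pooled[perm[n_x:]]
        per_locus, multi = _theta_from_dosage(px, py)
        with np.errstate(invalid="ignore"):
            ge_locus += np.where(
                np.isfinite(per_locus) & np.isfinite(obs_per_locus),
                per_locus >= obs_per_locus,
                0,
            )
        if np.isfinite(multi) and np.isfinite(obs_multi) and multi >= obs_multi:
            ge_multi += 1
    per_locus_p = (1.0 + ge_locus) / (n_perm + 1.0)
    per_locus_p = np.where(np.isfinite(obs_per_locus), per_locus_p, np.nan)
    return FstResult(
        locus_names=table_x.locus_names,
        per_locus=obs_per_locus,
        multilocus=obs_multi,
        per_locus_p=per_locus_p,
        multilocus_p=(1.0 + ge_multi) / (n_perm + 1.0),
        n_permutations=n_perm,
        seed=seed,
    )
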