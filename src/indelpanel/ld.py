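"""Pairwise linkage disequilibrium (r^2) between unphased biallelic loci.

For two unphased diallelic markers the only phase ambiguity sits in the
double heterozygotes, which may carry either the coupling (``++``/``--``)
or the repulsion (``+-``/``-+``) haplotype pair.  Maximum-likelihood
haplotype frequencies are obtained by the classic EM iteration over that
ambiguity, after which r^2 = D^2 / (p_A q_A p_B q_B) with
D = f(++) - p_A p_B (insertion-allele marginals).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .errors import EmptyDataError, UndefinedStatisticError
from .genotype_io import GenotypeTable, Locus

__all__ = ["LDMatrix", "em_haplotype_freqs", "r_squared", "ld_screen"]

# haplotype order used throughout: (--, -+, +-, ++), i.e. (alleles at
# locus A, locus B) with "-" = deletion, "+" = insertion
HAPLOTYPE_ORDER = ("--", "-+", "+-", "++")


@dataclass
class LDMatrix:
    """Symmetric matrix of pairwise r^2 values over a locus panel.

    Entries are NaN where LD is undefined (a monomorphic locus or no
    pairwise-complete samples).  ``n`` holds the pairwise-complete sample
    count used for each pair.
    """

    loci: list[Locus]
    r2: np.ndarray
    n: np.ndarray
    threshold: float

    @property
    def flagged_pairs(self) -> list[tuple[str, str, float]]:
        out = []
        for i, j in itertools.combinations(range(len(self.loci)), 2):
            if np.isfinite(self.r2[i, j]) and self.r2[i, j] >= self.threshold:
                out.append((self.loci[i].name, self.loci[j].name, self.r2[i, j]))
        return out

    @property
    def n_pairs_flagged(self) -> int:
        return len(self.flagged_pairs)

    @property
    def max_r2(self) -> float:
        off = self.r2[~np.eye(len(self.loci), dtype=bool)]
        off = off[np.isfinite(off)]
        return float(off.max()) if off.size else float("nan")


def _pair_table(dosages_a: np.ndarray, dosages_b: np.ndarray) -> np.ndarray:
    """3x3 contingency table of dosage pairs over pairwise-complete samples."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep].astype(int), b[keep].astype(int)
    if a.size == 0:
        raise EmptyDataError("no pairwise-complete genotypes")
    return np.bincount(3 * a + b, minlength=9).reshape(3, 3)


def em_haplotype_freqs(
    dosages_a: np.ndarray,
    dosages_b: np.ndarray,
    *,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> np.ndarray:
    """ML haplotype frequencies (--, -+, +-, ++) for two unphased loci.

    EM is initialised at linkage equilibrium (products of the observed
    allele frequencies) and iterated on the expected phase split of the
    double heterozygotes until the log-likelihood changes by less than
    ``tol``.  Marginals of the result equal the counted single-locus
    allele frequencies.
    """
    t = _pair_table(dosages_a, dosages_b)
    n = t.sum()
    p_a = (2 * t[2, :].sum() + t[1, :].sum()) / (2 * n)  # insertion freq, locus A
    p_b = (2 * t[:, 2].sum() + t[:, 1].sum()) / (2 * n)
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise UndefinedStatisticError("LD undefined: a locus is monomorphic")

    # unambiguous haplotype counts: every genotype except the double het
    # contributes known haplotypes
    base = np.array(
        [
            2 * t[0, 0] + t[0, 1] + t[1, 0],  # --
            2 * t[0, 2] + t[0, 1] + t[1, 2],  # -+
            2 * t[2, 0] + t[2, 1] + t[1, 0],  # +-
            2 * t[2, 2] + t[2, 1] + t[1, 2],  # ++
        ],
        dtype=float,
    )
    dh = t[1, 1]  # double heterozygotes: ++/-- vs +-/-+
    q_a, q_b = 1.0 - p_a, 1.0 - p_b
    f = np.array([q_a * q_b, q_a * p_b, p_a * q_b, p_a * p_b])
    prev_ll = -np.inf
    for _ in range(max_iter):
        coupling = f[0] * f[3]
        repulsion = f[1] * f[2]
        total = coupling + repulsion
        share = coupling / total if total > 0 else 0.5
        counts = base + dh * np.array([share, 1 - share, 1 - share, share])
        f = counts / (2 * n)
        ll = float(np.sum(base * np.log(np.where(f > 0, f, 1.0))))
        if dh and total > 0:
            ll += dh * np.log(2 * total)
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    return f


def r_squared(hap_freqs: np.ndarray) -> float:
    """r^2 from haplotype frequencies in (--, -+, +-, ++) order."""
    f = np.asarray(hap_freqs, dtype=float)
    p_a = f[2] + f[3]  # insertion frequency at locus A
    p_b = f[1] + f[3]
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom <= 0:
        raise UndefinedStatisticError("r^2 undefined: a marginal is fixed")
    d = f[3] - p_a * p_b
    return float(min(1.0, d * d / denom))


def ld_screen(table: GenotypeTable, threshold: float = 0.8) -> LDMatrix:
    """All pairwise r^2 values for a panel, flagging pairs >= ``threshold``.

    Forensic panels require loci to be statistically independent; this is
    the screen for pairs in strong LD.  Undefined pairs (monomorphic
    locus, no complete observations) are reported as NaN, never as 0.
    """
    n_loci = len(table.loci)
    if n_loci < 2:
        raise ValueError("LD screen needs at least 2 loci")
    r2 = np.full((n_loci, n_loci), np.nan)
    n = np.zeros((n_loci, n_loci), dtype=int)
    polymorphic = []
    for j in range(n_loci):
        col = table.dosage[:, j]
        col = col[np.isfinite(col)]
        poly = col.size > 0 and 0 < col.sum() < 2 * col.size
        polymorphic.append(poly)
        if poly:
            r2[j, j] = 1.0
        n[j, j] = col.size
    for i, j in itertools.combinations(range(n_loci), 2):
        keep = np.isfinite(table.dosage[:, i]) & np.isfinite(table.dosage[:, j])
        n[i, j] = n[j, i] = int(keep.sum())
        if not (polymorphic[i] and polymorphic[j]):
            continue
        try:
            f = em_haplotype_freqs(table.dosage[:, i], table.dosage[:, j])
            r2[i, j] = r2[j, i] = r_squared(f)
        except UndefinedStatisticError:
            pass  # monomorphic within the pairwise-complete subset
    return LDMatrix(loci=list(table.loci), r2=r2, n=n, threshold=threshold)
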