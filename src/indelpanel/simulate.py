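"""Synthetic genotype and frequency tables with the statistical structure
the analysis pipeline assumes.

Two generative layers are provided:

* a single-population sampler drawing genotypes from inbreeding-adjusted
  Hardy-Weinberg proportions, P(het) = 2pq(1 - F_IS), which reduces to
  exact HWE at F_IS = 0 and emulates a forensic study sample of N
  unrelated diploid individuals typed at independent biallelic loci;
* a multi-population sampler under the Balding-Nichols model, where each
  population's locus frequency is drawn from
  Beta(p (1 - Fst) / Fst, (1 - p) (1 - Fst) / Fst) around the ancestral
  frequency p, then genotypes follow HWE within each population.

A single seeded generator is consumed in a documented order
(population-major, then locus, then individual), so tables are
bit-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .bai_panel import bai_loci, bai_reference_frequencies
from .errors import ValidationError
from .genotype_io import FrequencyTable, GenotypeTable, Locus

__all__ = [
    "SimulationConfig",
    "simulate_population",
    "simulate_diverged_populations",
    "reference_panel_frequencies",
]


def reference_panel_frequencies() -> FrequencyTable:
    """The published 30-locus DIP- frequency table (single population),
    the default ancestral frequencies for simulations."""
    return bai_reference_frequencies()


@dataclass
class SimulationConfig:
    """Parameters of a synthetic genotype table.

    ``p_del`` holds the ancestral deletion-allele frequency per locus;
    ``f_is`` is the within-population inbreeding coefficient and ``fst``
    the Balding-Nichols divergence parameter between populations.
    """

    loci: list[Locus]
    p_del: np.ndarray
    n_individuals: int = 125
    f_is: float = 0.0
    fst: float = 0.0
    n_populations: int = 1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.p_del = np.asarray(self.p_del, dtype=float)
        if self.p_del.shape != (len(self.loci),):
            raise ValidationError("one ancestral frequency required per locus")
        if ((self.p_del < 0) | (self.p_del > 1)).any():
            raise ValidationError("frequencies must lie in [0, 1]")
        if self.n_individuals <= 0:
            raise ValidationError("n_individuals must be positive")
        if not (0.0 <= self.f_is < 1.0):
            raise ValidationError("f_is must lie in [0, 1)")
        if not (0.0 <= self.fst < 1.0):
            raise ValidationError("fst must lie in [0, 1)")
        if self.n_populations < 1:
            raise ValidationError("n_populations must be >= 1")
        if self.seed is None:
            raise ValidationError("a seed is required for reproducibility")

    @classmethod
    def from_reference_panel(cls, **kwargs) -> "SimulationConfig":
        """Config preloaded with the published 30-locus panel frequencies."""
        ref = bai_reference_frequencies()
        return cls(loci=list(ref.loci), p_del=ref.p_del[0].copy(), **kwargs)


def _genotype_probs(p_del: float, f: float) -> np.ndarray:
    """(P(del hom), P(het), P(ins hom)) under inbreeding coefficient f.

    Dosage counts insertion alleles, so the deletion homozygote has
    dosage 0 and frequency p^2 + f p q with p = p_del.
    """
    p, q = p_del, 1.0 - p_del
    return np.array([p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q])


def _sample_genotypes(
    rng: np.random.Generator, p_del: np.ndarray, f: float, n: int
) -> np.ndarray:
    """n x L dosage matrix; loci drawn in order, individuals vectorised
    per locus."""
    out = np.empty((n, len(p_del)))
    for j, p in enumerate(p_del):
        probs = _genotype_probs(p, f)
        if (probs < -1e-12).any():
            raise ValidationError(
                f"invalid genotype probabilities at locus {j} (p={p}, f={f})"
            )
        out[:, j] = rng.choice(3, size=n, p=np.clip(probs, 0, None) / probs.sum())
    return out.astype(float)


def simulate_population(config: SimulationConfig) -> GenotypeTable:
    """One population of unrelated diploids at independent biallelic loci,
    with genotype frequencies p^2 + Fpq : 2pq(1-F) : q^2 + Fpq."""
    if config.n_populations != 1:
        raise ValidationError("simulate_population requires n_populations=1")
    rng = np.random.default_rng(config.seed)
    dosage = _sample_genotypes(rng, config.p_del, config.f_is, config.n_individuals)
    n = config.n_individuals
    return GenotypeTable(
        samples=[f"pop1_ind{i+1}" for i in range(n)],
        populations=["pop1"] * n,
        loci=list(config.loci),
        dosage=dosage,
    )


def balding_nichols_freqs(
    rng: np.random.Generator, p_del: np.ndarray, fst: float
) -> np.ndarray:
    """Draw one population's locus frequencies around the ancestral ones.

    Beta(p (1-Fst)/Fst, (1-p)(1-Fst)/Fst) has mean p and variance
    Fst p (1-p).  Loci fixed ancestrally (p in {0, 1}) stay fixed.
    """
    if fst <= 0.0:
        return p_del.copy()
    ratio = (1.0 - fst) / fst
    out = np.empty_like(p_del)
    for j, p in enumerate(p_del):
        if p in (0.0, 1.0):
            out[j] = p
        else:
            out[j] = rng.beta(p * ratio, (1.0 - p) * ratio)
    return out


def simulate_diverged_populations(config: SimulationConfig) -> GenotypeTable:
    """Multiple populations diverged from a common ancestor at a given Fst
    (Balding-Nichols frequencies, then HWE genotypes within populations).

    At fst = 0 every population shares the exact ancestral frequencies —
    the degenerate no-divergence case, allowed and occasionally useful
    for null calibrations.
    """
    if config.n_populations < 2:
        raise ValidationError("need n_populations >= 2 for divergence")
    rng = np.random.default_rng(config.seed)
    samples: list[str] = []
    populations: list[str] = []
    blocks: list[np.ndarray] = []
    n = config.n_individuals
    for k in range(config.n_populations):
        name = f"pop{k+1}"
        freqs = balding_nichols_freqs(rng, config.p_del, config.fst)
        blocks.append(_sample_genotypes(rng, freqs, config.f_is, n))
        samples.extend(f"{name}_ind{i+1}" for i in range(n))
        populations.extend([name] * n)
    return GenotypeTable(
        samples=samples,
        populations=populations,
        loci=list(config.loci),
        dosage=np.vstack(blocks),
    )
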