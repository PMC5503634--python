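import numpy as np
import pytest

from indelpanel import GenotypeTable, Locus
from indelpanel.bai_panel import BAI_PANEL, SAMPLE_SIZE, bai_genotype_counts, bai_loci


@pytest.fixture(scope="session")
def bai_counts():
    """Integer genotype counts recovered from the published panel rows."""
    return bai_genotype_counts()


@pytest.fixture(scope="session")
def bai_table(bai_counts):
    """A 125-sample genotype table whose per-locus tallies equal the
    reconstructed published counts (sample order within a locus is
    arbitrary and irrelevant to every statistic computed here)."""
    loci = bai_loci()
    dosage = np.empty((SAMPLE_SIZE, len(loci)))
    for j, locus in enumerate(loci):
        c = bai_counts[locus.name]
        dosage[:, j] = [0] * c.n_del_hom + [1] * c.n_het + [2] * c.n_ins_hom
    return GenotypeTable(
        samples=[f"BAI{i+1:03d}" for i in range(SAMPLE_SIZE)],
        populations=["Bai"] * SAMPLE_SIZE,
        loci=loci,
        dosage=dosage,
    )


def round_half_up(x: float, places: int) -> float:
    """Round as published forensic tables do (half away from zero), not
    as Python's banker's rounding does."""
    from decimal import ROUND_HALF_UP, Decimal

    return float(Decimal(repr(float(x))).quantize(Decimal(10) ** -places, ROUND_HALF_UP))
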