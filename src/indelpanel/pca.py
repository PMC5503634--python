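"""Principal component analysis of population allele-frequency tables.

Populations are observations and loci are features (one DIP- frequency
per locus).  Columns are mean-centered but not scaled — the features
share a common [0, 1] scale already — and the decomposition is of the
covariance across populations.  Because the two columns of a biallelic
locus are perfectly anti-correlated (p and 1-p), using one column per
locus changes nothing but an overall sqrt(2) factor on the scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genotype_io import FrequencyTable

__all__ = ["PCAResult", "pca_populations"]


@dataclass
class PCAResult:
    """Scores, loadings and explained-variance fractions of a frequency PCA."""

    populations: list[str]
    scores: np.ndarray             # populations x components
    loadings: np.ndarray           # loci x components (orthonormal columns)
    explained_fraction: np.ndarray
    n_components: int

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores,
            index=self.populations,
            columns=[f"PC{i+1}" for i in range(self.n_components)],
        )
        df.index.name = "population"
        return df


def pca_populations(
    freqs: FrequencyTable, n_components: Optional[int] = None
) -> PCAResult:
    """PCA of a population x locus DIP- frequency matrix.

    Components are ordered by decreasing eigenvalue; each eigenvector's
    sign is fixed so that its largest-magnitude loading is positive.
    ``explained_fraction`` covers all min(n_pops - 1, n_loci) components
    regardless of how many score columns are requested.
    """
    x = freqs.p_del
    n_pops, n_loci = x.shape
    if n_pops < 2:
        raise ValidationError("PCA needs at least 2 populations")
    max_rank = min(n_pops - 1, n_loci)
    if n_components is None:
        n_components = max_rank
    if not (1 <= n_components <= max_rank):
        raise ValidationError(
            f"n_components must lie in [1, {max_rank}] for this table"
        )
    centered = x - x.mean(axis=0, keepdims=True)
    # thin SVD: eigenvalues of the covariance are s^2 / (n_pops - 1)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    order = np.argsort(s)[::-1]
    u, s, vt = u[:, order], s[order], vt[order]
    u, s, vt = u[:, :max_rank], s[:max_rank], vt[:max_rank]
    # deterministic sign: largest |loading| of each component positive
    for k in range(max_rank):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    eigvals = s**2
    total = eigvals.sum()
    explained = eigvals / total if total > 0 else np.zeros_like(eigvals)
    scores = u * s
    return PCAResult(
        populations=list(freqs.populations),
        scores=scores[:, :n_components],
        loadings=vt.T[:, :n_components],
        explained_fraction=explained,
        n_components=n_components,
    )
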