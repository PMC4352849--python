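"""Principal component analysis of population allele frequencies.

Each population is a point in allele-frequency space: the feature matrix
is populations x (locus, allele) over the union of observed alleles,
with 0 for an allele a population lacks.  Columns are mean-centered only
(no unit-variance scaling) by default; scores and explained-variance
fractions come from the SVD, with ``min(n_populations - 1, n_features)``
components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .alleles import AlleleLabel
from .tables import AlleleFrequencyTable

__all__ = ["PCAResult", "pca_populations", "frequency_matrix"]


@dataclass
class PCAResult:
    """Scores and explained-variance fractions of a population PCA."""

    coordinates: pd.DataFrame  # populations x components
    explained: np.ndarray  # variance fractions, non-increasing
    feature_labels: list[tuple[str, AlleleLabel]]


def frequency_matrix(
    populations: Sequence[AlleleFrequencyTable],
    loci: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[tuple[str, AlleleLabel]], list[str]]:
    """Populations x (locus, allele) frequency matrix over the allele union."""
    loci = list(loci) if loci is not None else populations[0].loci
    features: list[tuple[str, AlleleLabel]] = []
    for locus in loci:
        union = sorted({a for p in populations for a in p.frequencies[locus]})
        features.extend((locus, allele) for allele in union)
    x = np.zeros((len(populations), len(features)))
    for r, pop in enumerate(populations):
        for c, (locus, allele) in enumerate(features):
            x[r, c] = pop.frequencies[locus].get(allele, 0.0)
    return x, features, [p.population_id for p in populations]


def pca_populations(
    populations: Sequence[AlleleFrequencyTable],
    loci: Sequence[str] | None = None,
    scale: bool = False,
) -> PCAResult:
    """PCA of populations in allele-frequency space.

    ``scale=True`` additionally divides each centered column by its
    standard deviation (correlation-matrix PCA); the default matches the
    covariance-matrix convention.
    """
    if len(populations) < 2:
        raise ValueError("PCA needs at least two populations")
    x, features, ids = frequency_matrix(populations, loci)
    if scale:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    n_components = min(len(populations) - 1, x.shape[1])
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    coords = pd.DataFrame(
        scores, index=ids, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    return PCAResult(coords, model.explained_variance_ratio_.copy(), features)
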