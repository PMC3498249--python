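"""Similarity indices for plot-census comparisons.

The central quantity is the quantitative Bray-Curtis similarity computed
separately on stem counts and on basal areas; their mean is the combined
recovery index.  Two proportionate comparators (abundance-based
Chao-Jaccard and Morisita-Horn) are provided for contrast: both are
invariant to uniform scaling of one community, which is exactly the
behaviour the combined index avoids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .census_io import Census, CensusCollection, abundance_vectors
from .errors import UndefinedSimilarityError, ValidationError

__all__ = [
    "INDEX_NAMES",
    "SimilarityResult",
    "bray_curtis",
    "tanner_index",
    "horn_morisita",
    "chao_jaccard",
    "pairwise_similarity",
]

#: Index identifiers accepted throughout the package.
INDEX_NAMES = (
    "bray_curtis_density",
    "bray_curtis_ba",
    "tanner",
    "chao_jaccard",
    "horn_morisita",
)


@dataclass(frozen=True)
class SimilarityResult:
    """A named similarity value in [0, 1] for one ordered comparison."""

    index_name: str
    plot_a: tuple[str, str]
    plot_b: tuple[str, str]
    value: float


def _validate_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError(
            f"abundance vectors must be 1-D and of equal length; got shapes "
            f"{x.shape} and {y.shape}"
        )
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("abundance vectors must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        raise UndefinedSimilarityError(
            "similarity is undefined when both vectors are all-zero"
        )
    return x, y


def bray_curtis(x, y) -> float:
    """Quantitative Bray-Curtis similarity 2·Σmin(xᵢ,yᵢ) / (Σxᵢ + Σyᵢ).

    This is the similarity orientation (1 minus the Bray-Curtis
    dissimilarity).  Both-empty input is an error, not 0 or 1.
    """
    x, y = _validate_pair(x, y)
    return float(2.0 * np.minimum(x, y).sum() / (x.sum() + y.sum()))


def tanner_index(
    census_a: Census, census_b: Census, species_union: Sequence[str]
) -> tuple[float, float, float]:
    """Combined recovery index of two censuses over a fixed species order.

    Returns ``(bc_density, bc_ba, bc_ri)`` where ``bc_ri`` is the mean of
    the Bray-Curtis similarity on stem counts and on basal areas.
    """
    species_union = list(species_union)

    def vec(census: Census, measure: str) -> np.ndarray:
        out = np.zeros(len(species_union))
        for i, sp in enumerate(species_union):
            ab = census.abundances.get(sp)
            if ab is not None:
                out[i] = ab.stems if measure == "density" else ab.basal_area
        return out

    bc_density = bray_curtis(vec(census_a, "density"), vec(census_b, "density"))
    bc_ba = bray_curtis(vec(census_a, "basal_area"), vec(census_b, "basal_area"))
    return bc_density, bc_ba, (bc_density + bc_ba) / 2.0


def horn_morisita(x, y) -> float:
    """Morisita-Horn similarity 2·Σxᵢyᵢ / [(Σxᵢ²/X² + Σyᵢ²/Y²)·X·Y].

    Proportionate: invariant under scaling either vector by a positive
    constant.  Returns 0 when exactly one vector is empty.
    """
    x, y = _validate_pair(x, y)
    X, Y = x.sum(), y.sum()
    if X == 0 or Y == 0:
        return 0.0
    num = 2.0 * (x * y).sum()
    if num == 0:
        return 0.0
    denom = ((x * x).sum() / X**2 + (y * y).sum() / Y**2) * X * Y
    return float(min(1.0, num / denom))


def chao_jaccard(x, y, corrected: bool = True) -> float:
    """Abundance-based Jaccard similarity UV / (U + V − UV).

    U (resp. V) is the total relative abundance in ``x`` (resp. ``y``) of
    the species shared by both vectors.  With ``corrected=True`` the
    unseen-shared-species adjustment is applied: each total gets an added
    term (m−1)/m · f₊₁/(2·f₊₂) · Σ(relative abundance of shared species
    that are singletons in the other sample), with f₊₂ floored at 1, and
    U, V clipped to 1.  The corrected estimator requires integer counts.
    """
    x, y = _validate_pair(x, y)
    if corrected and (
        not np.allclose(x, np.round(x)) or not np.allclose(y, np.round(y))
    ):
        raise ValidationError(
            "the bias-corrected Chao-Jaccard estimator requires integer counts"
        )
    n, m = x.sum(), y.sum()
    if n == 0 or m == 0:
        return 0.0
    shared = (x > 0) & (y > 0)
    if not shared.any():
        return 0.0
    U = x[shared].sum() / n
    V = y[shared].sum() / m
    if corrected:
        # f₊₁/f₊₂: shared species that are singletons/doubletons in the
        # *other* sample drive the unseen-shared correction.
        f_plus1 = int(((y == 1) & shared).sum())
        f_plus2 = max(int(((y == 2) & shared).sum()), 1)
        U += (m - 1) / m * f_plus1 / (2.0 * f_plus2) * (
            x[shared & (y == 1)].sum() / n
        )
        f1_plus = int(((x == 1) & shared).sum())
        f2_plus = max(int(((x == 2) & shared).sum()), 1)
        V += (n - 1) / n * f1_plus / (2.0 * f2_plus) * (
            y[shared & (x == 1)].sum() / m
        )
        U = min(U, 1.0)
        V = min(V, 1.0)
    value = U * V / (U + V - U * V)
    return float(min(1.0, max(0.0, value)))


def _census_similarity(
    collection: CensusCollection,
    a: tuple[str, str],
    b: tuple[str, str],
    index_name: str,
    chao_corrected: bool = True,
) -> float:
    """Dispatch one comparison; count-based indices use stem densities."""
    if index_name not in INDEX_NAMES:
        raise ValueError(f"unknown index {index_name!r}; expected one of {INDEX_NAMES}")
    if index_name == "tanner":
        _, _, ri = tanner_index(
            collection.get_census(*a), collection.get_census(*b), collection.species_union
        )
        return ri
    if index_name == "bray_curtis_ba":
        measure = "basal_area"
    else:
        measure = "density"
    xa = abundance_vectors(collection, a[0], a[1], measure)
    xb = abundance_vectors(collection, b[0], b[1], measure)
    if index_name in ("bray_curtis_density", "bray_curtis_ba"):
        return bray_curtis(xa, xb)
    if index_name == "horn_morisita":
        return horn_morisita(xa, xb)
    return chao_jaccard(xa, xb, corrected=chao_corrected)


def pairwise_similarity(
    collection: CensusCollection,
    comparisons: Iterable[tuple[tuple[str, str], tuple[str, str]]],
    index_name: str,
    chao_corrected: bool = True,
) -> list[SimilarityResult]:
    """Evaluate one index over a list of ((plot, census), (plot, census)) pairs.

    Results come back in input order, one per comparison.
    """
    results = []
    for a, b in comparisons:
        a = (str(a[0]), str(a[1]))
        b = (str(b[0]), str(b[1]))
        value = _census_similarity(collection, a, b, index_name, chao_corrected)
        results.append(SimilarityResult(index_name, a, b, value))
    return results
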