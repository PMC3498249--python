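"""Indicator species analysis (Dufrêne-Legendre IndVal).

For species *s* and group *g*:

* specificity A = mean abundance of *s* in *g* divided by the sum of its
  group-mean abundances (group means, not sums, so unequal group sizes do
  not bias A);
* fidelity B = fraction of plots in *g* where *s* is present;
* IndVal = A·B, reported for the group that maximizes it, on a 0–1 scale.

Significance comes from Monte Carlo relabeling of plots (free permutation,
no stratification) with p = (r + 1)/(n_permutations + 1), or from exhaustive
enumeration of all distinct label assignments when ``exact=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np

from .errors import DesignError

__all__ = ["IndicatorResult", "indval"]


@dataclass(frozen=True)
class IndicatorResult:
    species: str
    group: str
    specificity_A: float
    fidelity_B: float
    indval: float
    p_value: float
    n_permutations: int


def _indval_matrix(X: np.ndarray, group_rows: list[np.ndarray]) -> np.ndarray:
    """(n_groups, n_species) IndVal components A·B for one labeling."""
    means = np.stack([X[rows].mean(axis=0) for rows in group_rows])
    denom = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(denom > 0, means / np.where(denom > 0, denom, 1.0), 0.0)
    B = np.stack([(X[rows] > 0).mean(axis=0) for rows in group_rows])
    return A * B


def _distinct_label_permutations(labels: np.ndarray) -> Iterator[np.ndarray]:
    """All distinct orderings of a label multiset, lexicographic."""
    labels = np.sort(labels)

    def rec(prefix: list, remaining: list) -> Iterator[list]:
        if not remaining:
            yield prefix
            return
        seen = set()
        for i, lab in enumerate(remaining):
            if lab in seen:
                continue
            seen.add(lab)
            yield from rec(prefix + [lab], remaining[:i] + remaining[i + 1 :])

    for perm in rec([], list(labels)):
        yield np.array(perm)


def indval(
    abundance: np.ndarray,
    groups: Sequence[str],
    n_permutations: int = 999,
    seed: Optional[int] = None,
    species_names: Optional[Sequence[str]] = None,
    exact: bool = False,
) -> list[IndicatorResult]:
    """IndVal scores and permutation p-values for a plots × species matrix.

    ``groups`` assigns a label to every row (plot).  Results are sorted by
    descending IndVal (ties by species name).  An all-zero species gets
    IndVal 0 and p = 1.  With ``exact=True`` the p-value is the exact
    fraction of all distinct label assignments whose IndVal is >= the
    observed one (the identity assignment included), and
    ``n_permutations`` is ignored.
    """
    X = np.asarray(abundance, dtype=float)
    if X.ndim != 2:
        raise ValueError("abundance must be a 2-D plots × species matrix")
    n_plots, n_species = X.shape
    labels = np.asarray([str(g) for g in groups])
    if labels.shape[0] != n_plots:
        raise ValueError("groups must assign one label per plot (row)")
    group_names = sorted(set(labels))
    if len(group_names) < 2:
        raise DesignError("indval needs >= 2 groups")
    for g in group_names:
        if (labels == g).sum() == 0:  # pragma: no cover - unreachable via set()
            raise DesignError(f"group {g!r} has zero plots")
    if not exact and n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if species_names is None:
        species_names = [f"sp{i}" for i in range(n_species)]
    species_names = [str(s) for s in species_names]

    def rows_for(lab_vector: np.ndarray) -> list[np.ndarray]:
        return [np.where(lab_vector == g)[0] for g in group_names]

    observed_matrix = _indval_matrix(X, rows_for(labels))
    best_group_idx = observed_matrix.argmax(axis=0)
    observed = observed_matrix.max(axis=0)

    if exact:
        perms = list(_distinct_label_permutations(labels))
        exceed = np.zeros(n_species)
        for perm in perms:
            exceed += _indval_matrix(X, rows_for(perm)).max(axis=0) >= observed - 1e-12
        p_values = exceed / len(perms)
        n_perm_reported = len(perms)
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(n_species)
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            exceed += _indval_matrix(X, rows_for(perm)).max(axis=0) >= observed - 1e-12
        p_values = (exceed + 1.0) / (n_permutations + 1.0)
        n_perm_reported = n_permutations

    # specificity/fidelity of the best group, for reporting
    means = np.stack([X[rows].mean(axis=0) for rows in rows_for(labels)])
    denom = means.sum(axis=0)
    results = []
    for s in range(n_species):
        g = int(best_group_idx[s])
        A = float(means[g, s] / denom[s]) if denom[s] > 0 else 0.0
        B = float((X[rows_for(labels)[g], s] > 0).mean())
        results.append(
            IndicatorResult(
                species=species_names[s],
                group=group_names[g],
                specificity_A=A,
                fidelity_B=B,
                indval=float(observed[s]),
                p_value=float(p_values[s]),
                n_permutations=n_perm_reported,
            )
        )
    results.sort(key=lambda r: (-r.indval, r.species))
    return results
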