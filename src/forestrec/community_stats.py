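"""Stand-level descriptors: importance values, paired change tests and
individual-based rarefaction."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .census_io import Census, CensusCollection, Treatment
from .errors import ConfigError, DesignError, InsufficientDataError

__all__ = [
    "CHANGE_VARIABLES",
    "ChangeTestResult",
    "RarefactionResult",
    "importance_values",
    "change_tests",
    "rarefy",
]

CHANGE_VARIABLES = ("stem_density", "species_density", "endemic_density", "basal_area")


def importance_values(
    collection: CensusCollection,
    scope: Iterable[tuple[str, str]],
) -> pd.DataFrame:
    """Per-species importance value table for a pooled set of censuses.

    IV = (relative density + relative basal area) / 2, in percent; the
    table is sorted by descending IV with ties broken by species name.
    Relative density and relative basal area each sum to 100 over the
    pooled scope.
    """
    scope = list(scope)
    if not scope:
        raise DesignError("importance_values needs a non-empty scope")
    stems: dict[str, float] = {}
    ba: dict[str, float] = {}
    for plot_id, label in scope:
        census = collection.get_census(str(plot_id), str(label))
        for sp, ab in census.abundances.items():
            stems[sp] = stems.get(sp, 0) + ab.stems
            ba[sp] = ba.get(sp, 0.0) + ab.basal_area
    total_stems = sum(stems.values())
    total_ba = sum(ba.values())
    if total_stems == 0:
        raise DesignError("importance_values scope contains no stems")
    rows = []
    for sp in sorted(stems):
        rel_d = 100.0 * stems[sp] / total_stems
        rel_b = 100.0 * ba[sp] / total_ba if total_ba > 0 else 0.0
        rows.append(
            {
                "species": sp,
                "relative_density": rel_d,
                "relative_ba": rel_b,
                "iv": (rel_d + rel_b) / 2.0,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["iv", "species"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df


@dataclass(frozen=True)
class ChangeTestResult:
    variable: str
    excluded_species: Optional[str]
    gap_mean_change: float
    gap_se_change: float
    control_mean_change: float
    control_se_change: float
    t: float
    df: int
    p_two_tailed: float
    n_pairs: int


def _census_variable(
    census: Census,
    area_m2: float,
    variable: str,
    endemic_species: Optional[set[str]],
    exclude_species: Optional[str],
) -> float:
    abunds = {
        sp: ab
        for sp, ab in census.abundances.items()
        if sp != exclude_species and ab.stems > 0
    }
    if variable == "stem_density":
        return float(sum(a.stems for a in abunds.values()))
    if variable == "species_density":
        return float(len(abunds))
    if variable == "endemic_density":
        if endemic_species is None:
            raise ConfigError("endemic_density requires an endemic-species list")
        return float(len([sp for sp in abunds if sp in endemic_species]))
    if variable == "basal_area":
        # m² per plot -> m² ha⁻¹
        return sum(a.basal_area for a in abunds.values()) * 10_000.0 / area_m2
    raise ValueError(f"unknown variable {variable!r}; expected one of {CHANGE_VARIABLES}")


def _se(values: Sequence[float]) -> float:
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        return math.nan
    return float(arr.std(ddof=1) / math.sqrt(arr.size))


def change_tests(
    collection: CensusCollection,
    pre_label: str = "pre",
    post_label: str = "post",
    variables: Optional[Sequence[str]] = None,
    exclude_species: Optional[str] = None,
    endemic_species: Optional[Iterable[str]] = None,
) -> list[ChangeTestResult]:
    """Paired tests of pre→post change in gap vs control plots.

    For each variable, the per-plot change (post − pre) is computed, then a
    two-tailed paired t-test compares gap changes against control changes,
    paired by pair_id (df = n_pairs − 1).  Mean ± SE of the change is
    reported over all gap plots (including any unpaired ones) and all
    control plots.  ``exclude_species`` recomputes every variable with that
    species removed.
    """
    endemics = set(endemic_species) if endemic_species is not None else None
    if variables is None:
        # endemic_density only makes sense with an endemic-species list
        variables = [
            v for v in CHANGE_VARIABLES
            if v != "endemic_density" or endemics is not None
        ]
    pairs = collection.complete_pairs()
    if len(pairs) < 2:
        raise InsufficientDataError(
            f"change_tests needs >= 2 complete pairs; found {len(pairs)}"
        )

    gap_plots = sorted(
        collection.plots_by_treatment(Treatment.GAP), key=lambda m: m.plot_id
    )
    control_plots = sorted(
        collection.plots_by_treatment(Treatment.CONTROL), key=lambda m: m.plot_id
    )

    results = []
    for variable in variables:
        def change(meta) -> float:
            pre = _census_variable(
                collection.get_census(meta.plot_id, pre_label),
                meta.area_m2, variable, endemics, exclude_species,
            )
            post = _census_variable(
                collection.get_census(meta.plot_id, post_label),
                meta.area_m2, variable, endemics, exclude_species,
            )
            return post - pre

        gap_changes = [change(m) for m in gap_plots]
        control_changes = [change(m) for m in control_plots]
        paired_gap = []
        paired_control = []
        for _, gap, control in pairs:
            paired_gap.append(change(gap))
            paired_control.append(change(control))

        diffs = np.array(paired_gap) - np.array(paired_control)
        if np.allclose(diffs, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(paired_gap, paired_control)
        results.append(
            ChangeTestResult(
                variable=variable,
                excluded_species=exclude_species,
                gap_mean_change=float(np.mean(gap_changes)),
                gap_se_change=_se(gap_changes),
                control_mean_change=float(np.mean(control_changes)),
                control_se_change=_se(control_changes),
                t=float(t),
                df=len(pairs) - 1,
                p_two_tailed=float(p),
                n_pairs=len(pairs),
            )
        )
    return results


@dataclass(frozen=True)
class RarefactionResult:
    n_target: int
    expected_species: float
    variance: float
    mode: str


def _counts_from(source: Union[Census, Sequence[int]]) -> np.ndarray:
    if isinstance(source, Census):
        counts = [a.stems for a in source.abundances.values() if a.stems > 0]
    else:
        counts = [int(c) for c in source if c > 0]
    return np.asarray(counts, dtype=int)


def rarefy(
    source: Union[Census, Sequence[int]],
    n_target: int,
    mode: str = "analytic",
    seed: Optional[int] = None,
    n_resamples: int = 1000,
) -> RarefactionResult:
    """Expected species richness in a random subsample of ``n_target`` stems.

    Analytic mode uses the hypergeometric expectation
    E[S(n)] = Σₛ [1 − C(N−Nₛ, n)/C(N, n)] with the matching variance
    (Heck et al. 1975 formula); resample mode estimates the same quantity
    by seeded Monte-Carlo subsampling, for cross-checking.
    """
    counts = _counts_from(source)
    N = int(counts.sum())
    if N == 0:
        raise DesignError("cannot rarefy an empty census")
    if not 1 <= n_target <= N:
        raise ValueError(f"n_target must be in [1, {N}]; got {n_target}")

    if mode == "resample":
        rng = np.random.default_rng(seed)
        pool = np.repeat(np.arange(counts.size), counts)
        richness = np.empty(n_resamples)
        for b in range(n_resamples):
            sub = rng.choice(pool, size=n_target, replace=False)
            richness[b] = np.unique(sub).size
        return RarefactionResult(
            n_target, float(richness.mean()), float(richness.var(ddof=1)), "resample"
        )
    if mode != "analytic":
        raise ValueError(f"mode must be 'analytic' or 'resample'; got {mode!r}")

    denom = math.comb(N, n_target)

    def miss(k: int) -> float:
        # P(none of a species with k stems is drawn)
        return math.comb(N - k, n_target) / denom if N - k >= n_target else 0.0

    miss_p = np.array([miss(int(k)) for k in counts])
    expected = float((1.0 - miss_p).sum())

    var = float((miss_p * (1.0 - miss_p)).sum())
    for i in range(counts.size):
        for j in range(i + 1, counts.size):
            both_gone = counts[i] + counts[j]
            joint = (
                math.comb(N - both_gone, n_target) / denom
                if N - both_gone >= n_target
                else 0.0
            )
            var += 2.0 * (joint - miss_p[i] * miss_p[j])
    return RarefactionResult(n_target, expected, var, "analytic")
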