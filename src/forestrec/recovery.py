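"""Recovery assessment for paired gap/control plot censuses.

Observed similarity is normalized by the maximum similarity attainable in
the absence of the disturbance effect:

* temporal mode — observed = sim(pre-gap, post-gap) per gap plot;
  maximum = sim(pre-control, post-control) per pair;
* spatial mode — observed = sim(post-gap, post-control) per pair;
  maximum = sim(pre-gap, pre-control) per pair.

Percent of maximum is the ratio of the two means (not the mean of
per-pair ratios).  Gap plots without a monitored control contribute to
temporal observed means but are excluded from spatial comparisons and
from the paired test; ``strict_pairs=True`` drops them everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
from scipy import stats

from ._rounding import round_half_up
from .census_io import CensusCollection, Treatment
from .errors import DesignError, UndefinedRecoveryError
from .similarity import INDEX_NAMES, _census_similarity

__all__ = [
    "PairComparison",
    "RecoveryAssessment",
    "BaselineResult",
    "assess_recovery",
    "baseline_similarity",
    "recovery_percent",
]


@dataclass(frozen=True)
class PairComparison:
    pair_id: Optional[str]
    observed: float
    maximum: float  # NaN when the pair has no monitored control


@dataclass(frozen=True)
class RecoveryAssessment:
    mode: str
    index_name: str
    per_pair: list[PairComparison]
    mean_observed: float
    mean_maximum: float
    percent_of_maximum: float
    #: (t, df, two-tailed p) for observed vs maximum paired by pair_id,
    #: or None when fewer than two complete pairs exist.
    comparison_test: Optional[tuple[float, int, float]]

    @property
    def percent_display(self) -> int:
        return int(round_half_up(self.percent_of_maximum))

    @property
    def significant(self) -> Optional[bool]:
        if self.comparison_test is None:
            return None
        return self.comparison_test[2] <= 0.05


def recovery_percent(observed: float, maximum: float) -> float:
    """100·observed/maximum, full precision (display rounds half-up)."""
    if maximum <= 0:
        raise UndefinedRecoveryError(
            f"maximum similarity must be positive; got {maximum!r}"
        )
    if observed < 0:
        raise UndefinedRecoveryError(f"observed similarity must be >= 0; got {observed!r}")
    return 100.0 * observed / maximum


def assess_recovery(
    collection: CensusCollection,
    mode: str,
    index_name: str,
    pre_label: str = "pre",
    post_label: str = "post",
    strict_pairs: bool = False,
    chao_corrected: bool = True,
) -> RecoveryAssessment:
    """Per-pair observed and maximum similarities plus the normalized summary."""
    if mode not in ("temporal", "spatial"):
        raise ValueError(f"mode must be 'temporal' or 'spatial'; got {mode!r}")
    if index_name not in INDEX_NAMES:
        raise ValueError(f"unknown index {index_name!r}")

    def sim(a: tuple[str, str], b: tuple[str, str]) -> float:
        return _census_similarity(collection, a, b, index_name, chao_corrected)

    per_pair: list[PairComparison] = []
    pairs = collection.complete_pairs()
    if not pairs:
        raise DesignError("no complete gap/control pairs in the collection")

    for pair_id, gap, control in pairs:
        g, c = gap.plot_id, control.plot_id
        if mode == "temporal":
            observed = sim((g, pre_label), (g, post_label))
            maximum = sim((c, pre_label), (c, post_label))
        else:
            observed = sim((g, post_label), (c, post_label))
            maximum = sim((g, pre_label), (c, pre_label))
        per_pair.append(PairComparison(pair_id, observed, maximum))

    if mode == "temporal" and not strict_pairs:
        for gap in sorted(collection.unpaired_gaps(), key=lambda m: m.plot_id):
            g = gap.plot_id
            observed = sim((g, pre_label), (g, post_label))
            per_pair.append(PairComparison(None, observed, math.nan))

    observed_vals = np.array([p.observed for p in per_pair])
    maximum_vals = np.array([p.maximum for p in per_pair])
    mean_observed = float(observed_vals.mean())
    mean_maximum = float(np.nanmean(maximum_vals))
    percent = recovery_percent(mean_observed, mean_maximum)

    complete = [p for p in per_pair if not math.isnan(p.maximum)]
    test = None
    if len(complete) >= 2:
        obs = [p.observed for p in complete]
        mx = [p.maximum for p in complete]
        if np.allclose(np.array(obs) - np.array(mx), 0.0):
            test = (0.0, len(complete) - 1, 1.0)
        else:
            t, p = stats.ttest_rel(obs, mx)
            test = (float(t), len(complete) - 1, float(p))

    return RecoveryAssessment(
        mode=mode,
        index_name=index_name,
        per_pair=per_pair,
        mean_observed=mean_observed,
        mean_maximum=mean_maximum,
        percent_of_maximum=percent,
        comparison_test=test,
    )


@dataclass(frozen=True)
class BaselineResult:
    index_name: str
    group_by: str
    per_group: dict[str, float]  # group -> mean similarity
    group_sizes: dict[str, int]
    overall_mean: float  # mean over all pairwise comparisons, pooled
    n_comparisons: int


def baseline_similarity(
    collection: CensusCollection,
    group_by: str = "forest_type",
    index_name: str = "tanner",
    census_label: Optional[str] = None,
    chao_corrected: bool = True,
) -> BaselineResult:
    """Within-group pairwise similarity among single-census reference plots.

    Every unordered pair of reference plots sharing the same value of the
    ``group_by`` metadata field is compared; n_comparisons = Σ_g C(n_g, 2).
    Means are reported without error estimates (the comparisons reuse
    plots and are not independent).
    """
    refs = collection.plots_by_treatment(Treatment.REFERENCE)
    if not refs:
        raise DesignError("no reference plots in the collection")

    def label_for(plot_id: str) -> str:
        if census_label is not None:
            return census_label
        labels = [
            c.census_label for c in collection.censuses if c.plot_id == plot_id
        ]
        if len(labels) != 1:
            raise DesignError(
                f"reference plot {plot_id!r} must have exactly one census "
                f"(found {len(labels)}); pass census_label to disambiguate"
            )
        return labels[0]

    groups: dict[str, list[str]] = {}
    for m in refs:
        key = str(getattr(m, group_by))
        groups.setdefault(key, []).append(m.plot_id)

    per_group: dict[str, float] = {}
    group_sizes: dict[str, int] = {}
    all_values: list[float] = []
    n_comparisons = 0
    for group in sorted(groups):
        plots = sorted(groups[group])
        if len(plots) < 2:
            raise DesignError(
                f"group {group!r} has {len(plots)} reference plot(s); need >= 2"
            )
        values = []
        for a, b in combinations(plots, 2):
            values.append(
                _census_similarity(
                    collection,
                    (a, label_for(a)),
                    (b, label_for(b)),
                    index_name,
                    chao_corrected,
                )
            )
        per_group[group] = float(np.mean(values))
        group_sizes[group] = len(plots)
        all_values.extend(values)
        n_comparisons += len(values)

    return BaselineResult(
        index_name=index_name,
        group_by=group_by,
        per_group=per_group,
        group_sizes=group_sizes,
        overall_mean=float(np.mean(all_values)),
        n_comparisons=n_comparisons,
    )
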