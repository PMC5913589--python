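"""Time-series analytics and group statistics for the drought features.

The dynamic analysis rests on the day-to-day first derivative
``d_i = X_i - X_{i-1}``: under intensifying drought PAR rises while TBR
and TCR fall, and the extremum of the derivative (peak for PAR, valley
for TBR/TCR) marks the day leaf-rolling becomes visible.  Group
discrimination (resistant vs. sensitive accessions) uses the classical
one-way ANOVA F; agreement between controlled-condition and field
measurements is assessed with Pearson correlation.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .features_pipeline import FEATURE_NAMES, DroughtFeatures

__all__ = [
    "FeatureSeries",
    "OnsetReport",
    "GroupComparison",
    "feature_change",
    "first_derivative",
    "detect_rolling_onset",
    "anova_oneway",
    "pearson_r",
]

# GPAR tracks senescence, not rolling; onset voting uses the shape trio only.
SHAPE_DESCRIPTORS = ("par", "tbr", "tcr")


@dataclasses.dataclass
class FeatureSeries:
    """Ordered feature values for one plant; missing timepoints are NaN.

    ``timepoints`` are strictly increasing ordinals (days, or stage ranks);
    ``values`` maps a feature name to an array aligned with ``timepoints``.
    """

    plant_id: str
    timepoints: np.ndarray
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=int)
        if self.timepoints.ndim != 1 or len(self.timepoints) == 0:
            raise ValueError("timepoints must be a non-empty 1-D sequence")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        self.values = {
            k: np.asarray(v, dtype=float) for k, v in self.values.items()
        }
        for name, arr in self.values.items():
            if arr.shape != self.timepoints.shape:
                raise ValueError(f"values[{name!r}] length does not match timepoints")

    @classmethod
    def from_features(
        cls,
        plant_id: str,
        timepoints: Sequence[int],
        features: Sequence[Optional[DroughtFeatures]],
    ) -> "FeatureSeries":
        """Build a series from per-timepoint feature quadruples (None = missing)."""
        values = {
            name: np.array(
                [math.nan if f is None else getattr(f, name) for f in features],
                dtype=float,
            )
            for name in FEATURE_NAMES
        }
        return cls(plant_id=plant_id, timepoints=np.asarray(timepoints), values=values)


@dataclasses.dataclass(frozen=True)
class OnsetReport:
    """Leaf-rolling onset call with the per-descriptor candidates.

    ``onset_index`` is the timepoint ordinal at which rolling became
    visible, or None when every derivative is flat (no onset).
    ``magnitude`` is the PAR derivative at the reported onset.
    """

    onset_index: Optional[int]
    per_descriptor_votes: dict[str, Optional[int]]
    magnitude: float


@dataclasses.dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA outcome for a feature across labeled groups."""

    group_labels: tuple
    F: float
    df_between: int
    df_within: int
    p: float
    degenerate_within: bool = False


def feature_change(
    before: Optional[DroughtFeatures], after: Optional[DroughtFeatures]
) -> dict[str, float]:
    """Per-feature delta: value after stress minus value before stress.

    A missing side yields NaN deltas for every feature.
    """
    if before is None or after is None:
        return {name: math.nan for name in FEATURE_NAMES}
    return {
        name: getattr(after, name) - getattr(before, name) for name in FEATURE_NAMES
    }


def first_derivative(series: FeatureSeries, feature_name: str) -> np.ndarray:
    """Day-to-day differences d_i = X_i - X_{i-1}, indexed by the later day.

    The result aligns with ``series.timepoints[1:]``.  An entry is NaN when
    either value is missing or when the two timepoints are not consecutive
    ordinals (gaps are never interpolated).  Series with fewer than two
    timepoints give an empty result.
    """
    if feature_name not in series.values:
        raise KeyError(f"series has no feature {feature_name!r}")
    x = series.values[feature_name]
    t = series.timepoints
    if len(x) < 2:
        return np.empty(0, dtype=float)
    d = x[1:] - x[:-1]
    consecutive = np.diff(t) == 1
    return np.where(consecutive, d, math.nan)


def detect_rolling_onset(series: FeatureSeries) -> OnsetReport:
    """Call leaf-rolling onset from derivative extrema of the shape trio.

    Each shape descriptor votes for the timepoint of its derivative
    extremum — the peak for PAR (rolling raises it) and the valley for TBR
    and TCR (rolling lowers them).  The onset is the majority vote; ties
    fall to the PAR candidate, PAR being the most robust and sensitive of
    the three descriptors.  A series whose derivatives are all zero (or all
    missing) yields a no-onset report.
    """
    if len(series.timepoints) < 3:
        raise ValueError("onset detection requires at least 3 timepoints")
    later = series.timepoints[1:]
    votes: dict[str, Optional[int]] = {}
    for name in SHAPE_DESCRIPTORS:
        d = first_derivative(series, name)
        valid = ~np.isnan(d)
        if not valid.any() or np.all(d[valid] == 0.0):
            votes[name] = None
            continue
        masked = np.where(valid, d, -math.inf if name == "par" else math.inf)
        idx = int(np.argmax(masked)) if name == "par" else int(np.argmin(masked))
        votes[name] = int(later[idx])

    candidates = [v for v in votes.values() if v is not None]
    if not candidates:
        return OnsetReport(onset_index=None, per_descriptor_votes=votes, magnitude=0.0)

    counts: dict[int, int] = {}
    for v in candidates:
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.values())
    winners = sorted(t for t, c in counts.items() if c == best)
    if len(winners) == 1:
        onset = winners[0]
    elif votes["par"] is not None and votes["par"] in winners:
        onset = votes["par"]
    else:
        onset = winners[0]

    d_par = first_derivative(series, "par")
    at = np.nonzero(later == onset)[0]
    magnitude = float(d_par[at[0]]) if at.size and not np.isnan(d_par[at[0]]) else 0.0
    return OnsetReport(onset_index=onset, per_descriptor_votes=votes, magnitude=magnitude)


def anova_oneway(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence] = None,
) -> GroupComparison:
    """Classical one-way ANOVA: F = MS_between / MS_within.

    Degrees of freedom are (k - 1, N - k) for k groups and N observations;
    the p-value is the upper tail of the F distribution.  Requires at least
    two groups of at least two values each.  When within-group variance is
    exactly zero but groups differ, F is reported as infinite with p = 0
    and the comparison flagged degenerate; identical constant groups are
    rejected as carrying no information.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA requires at least two groups")
    if any(a.ndim != 1 or len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least two values")
    if any(np.isnan(a).any() for a in arrays):
        raise ValueError("NaN values are not allowed; drop missing records first")

    if labels is None:
        labels = tuple(range(len(arrays)))
    n_total = sum(len(a) for a in arrays)
    k = len(arrays)
    grand = sum(a.sum() for a in arrays) / n_total
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = k - 1
    df_within = n_total - k

    if ss_within == 0.0:
        if ss_between == 0.0:
            raise ValueError("all observations identical; ANOVA undefined")
        return GroupComparison(
            group_labels=tuple(labels),
            F=math.inf,
            df_between=df_between,
            df_within=df_within,
            p=0.0,
            degenerate_within=True,
        )

    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f_stat, df_between, df_within))
    # F == 0 (identical group means) gives sf == 1 exactly
    return GroupComparison(
        group_labels=tuple(labels),
        F=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        p=p,
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation with pairwise deletion of missing values.

    Raises ``ValueError`` when fewer than three complete pairs remain or
    when either side has zero variance (the coefficient is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: Pearson correlation undefined")
    return float(stats.pearsonr(x, y).statistic)
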