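"""Longitudinal fluorescent-object count analysis for motor-neuron survival.

The endpoint statistic is net death: first count minus last count of a
series.  Pairwise group comparisons use an unpaired two-sample test on
replicate-level net death with Sidak (default), BH or no multiplicity
adjustment.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InsufficientDataError, InsufficientReplicatesError
from .secretome_diff import adjust_pvalues, sidak_adjust, unpaired_t

SURVIVAL_COLUMNS = ("condition", "treatment", "replicate", "time_h", "count")


@dataclass(frozen=True)
class SurvivalSeries:
    """Time-stamped object counts for one (condition, treatment, replicate)."""

    condition: str
    treatment: str
    replicate: str
    times: np.ndarray  # hours, strictly increasing from 0
    counts: np.ndarray  # nonnegative integers

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "counts", counts)
        if times.shape != counts.shape or times.ndim != 1:
            raise DomainError("times and counts must be 1-D and equal-length")
        if times.size and np.any(np.diff(times) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any(counts < 0):
            raise DomainError("counts must be nonnegative")

    @property
    def label(self) -> tuple[str, str]:
        return (self.condition, self.treatment)


def net_death(s: SurvivalSeries) -> int:
    """First count minus last count; negative means net growth."""
    if s.times.size < 2:
        raise InsufficientDataError(
            "net death needs at least 2 time points, got "
            f"{s.times.size} for {s.condition}/{s.treatment}/{s.replicate}"
        )
    return int(s.counts[0] - s.counts[-1])


def trajectory_auc(s: SurvivalSeries) -> float:
    """Trapezoidal area under counts versus time, in count-hours."""
    if s.times.size < 2:
        raise InsufficientDataError("AUC needs at least 2 time points")
    return float(np.trapezoid(s.counts.astype(float), s.times))


def fit_decay_rate(s: SurvivalSeries) -> float:
    """Per-hour decay rate from a log-linear fit of counts over time.

    Counts must be strictly positive.  On a noiseless exponential series the
    configured hazard is recovered to floating-point accuracy.
    """
    if s.times.size < 2:
        raise InsufficientDataError("decay fit needs at least 2 time points")
    if np.any(s.counts <= 0):
        raise DomainError("decay fit requires strictly positive counts")
    slope, _, _, _, _ = stats.linregress(s.times, np.log(s.counts.astype(float)))
    return float(-slope)


def death_table(series: Iterable[SurvivalSeries]) -> pd.DataFrame:
    """Per-replicate summary: net death, growth flag and trajectory AUC."""
    rows = []
    for s in series:
        nd = net_death(s)
        rows.append(
            {
                "condition": s.condition,
                "treatment": s.treatment,
                "replicate": s.replicate,
                "net_death": nd,
                "net_growth": nd < 0,
                "auc_count_h": trajectory_auc(s),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "condition",
            "treatment",
            "replicate",
            "net_death",
            "net_growth",
            "auc_count_h",
        ],
    )


def compare_death(
    series: Iterable[SurvivalSeries] | pd.DataFrame,
    adjustment: str = "sidak",
    variant: str = "welch",
    alpha: float = 0.05,
    pairs: Sequence[tuple[tuple[str, str], tuple[str, str]]] | None = None,
) -> pd.DataFrame:
    """Pairwise comparisons of replicate-level net death between groups.

    Groups are (condition, treatment) pairs.  ``pairs`` restricts the planned
    comparisons (defaults to all pairs); the adjustment is applied over the
    number of pairs actually tested.
    """
    if isinstance(series, pd.DataFrame):
        table = series
    else:
        table = death_table(series)
    groups: dict[tuple[str, str], np.ndarray] = {
        key: sub["net_death"].to_numpy(float)
        for key, sub in table.groupby(["condition", "treatment"], sort=True)
    }
    if len(groups) < 2:
        raise InsufficientDataError("compare_death needs at least 2 groups")
    for key, vals in groups.items():
        if vals.size < 2:
            raise InsufficientReplicatesError(
                f"group {key} has {vals.size} replicate(s); need >= 2"
            )
    if pairs is None:
        pairs = list(itertools.combinations(sorted(groups), 2))
    else:
        for a, b in pairs:
            for key in (a, b):
                if tuple(key) not in groups:
                    raise DomainError(f"unknown group {key} in planned pairs")
    rows = []
    for a, b in pairs:
        va, vb = groups[tuple(a)], groups[tuple(b)]
        t, p = unpaired_t(va, vb, variant=variant)
        rows.append(
            {
                "group_a": "/".join(a),
                "group_b": "/".join(b),
                "n_a": va.size,
                "n_b": vb.size,
                "mean_a": va.mean(),
                "mean_b": vb.mean(),
                "t": t,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = adjust_pvalues(out["p"].to_numpy(float), adjustment, m=len(pairs))
    out["significant"] = out["p_adj"] < alpha
    out.attrs["adjustment"] = adjustment
    out.attrs["m"] = len(pairs)
    return out


def rolling_median(s: SurvivalSeries, window: int = 3) -> SurvivalSeries:
    """Optional dropout smoothing; off by default everywhere."""
    if window < 1 or window % 2 == 0:
        raise DomainError("window must be a positive odd integer")
    smoothed = (
        pd.Series(s.counts)
        .rolling(window, center=True, min_periods=1)
        .median()
        .round()
        .astype(int)
        .to_numpy()
    )
    return SurvivalSeries(s.condition, s.treatment, s.replicate, s.times, smoothed)


def series_to_frame(series: Iterable[SurvivalSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for t, c in zip(s.times, s.counts):
            rows.append(
                {
                    "condition": s.condition,
                    "treatment": s.treatment,
                    "replicate": s.replicate,
                    "time_h": t,
                    "count": int(c),
                }
            )
    return pd.DataFrame(rows, columns=list(SURVIVAL_COLUMNS))


def series_from_frame(df: pd.DataFrame) -> list[SurvivalSeries]:
    from .errors import FormatError

    for col in SURVIVAL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column: {col!r}")
    out = []
    for (cond, treat, rep), sub in df.groupby(
        ["condition", "treatment", "replicate"], sort=True
    ):
        sub = sub.sort_values("time_h")
        out.append(
            SurvivalSeries(
                condition=str(cond),
                treatment=str(treat),
                replicate=str(rep),
                times=sub["time_h"].to_numpy(float),
                counts=sub["count"].to_numpy(int),
            )
        )
    return out


__all__ = [
    "SurvivalSeries",
    "net_death",
    "trajectory_auc",
    "fit_decay_rate",
    "death_table",
    "compare_death",
    "rolling_median",
    "sidak_adjust",
    "series_to_frame",
    "series_from_frame",
]
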