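"""Core screen analytics: normalization, viability exclusion, thresholds,
hit classification, ranking and cross-platform intersection.

Scoring is percent decrease against the platform's vehicle mean,
100 * (1 - value / vehicle_mean).  A compound is a hit on an analyte when its
percent decrease is strictly greater than the threshold for that
(platform, analyte) and it was not excluded for viability.  Thresholds come
from the negative control's own percent decrease, subject to a configurable
floor: an inert negative control must not make every compound a hit.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError
from .screen_data import ScreenDataset

DEFAULT_FLOOR_PCT = 15.0
DEFAULT_VIABILITY_TOLERANCE = 0.2
DEFAULT_SHORTLIST = 15

VIABILITY_REFERENCES = ("vehicle", "untreated", "both")


def percent_decrease(value: float, vehicle_mean: float) -> float:
    """100 * (1 - value / vehicle_mean); negative when the analyte is elevated."""
    if not vehicle_mean > 0:
        raise DomainError(f"vehicle mean must be > 0, got {vehicle_mean}")
    if value < 0:
        raise DomainError(f"concentration must be >= 0, got {value}")
    return 100.0 * (1.0 - value / vehicle_mean)


def vehicle_means(ds: ScreenDataset) -> dict[tuple[str, str], float]:
    """Arithmetic mean of vehicle wells per (platform, analyte)."""
    out: dict[tuple[str, str], float] = {}
    for platform in ds.platforms():
        for analyte in ds.analyte_panel:
            vals = ds.analyte_array("vehicle", platform, analyte)
            if vals.size:
                out[(platform, analyte)] = float(vals.mean())
    return out


# ---------------------------------------------------------------------------
# viability
# ---------------------------------------------------------------------------


@dataclass
class ViabilityResult:
    """Per-platform compound exclusion sets from the diameter criterion."""

    excluded: dict[str, frozenset[str]]
    unknown: dict[str, frozenset[str]]
    reference_mean: dict[str, float]
    tolerance: float
    reference: str
    warnings: list[str] = field(default_factory=list)

    def excluded_on(self, platform: str) -> frozenset[str]:
        return self.excluded.get(platform, frozenset())

    def unknown_on(self, platform: str) -> frozenset[str]:
        return self.unknown.get(platform, frozenset())

    @property
    def excluded_any(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.excluded.values():
            out |= s
        return frozenset(out)


def viability_filter(
    ds: ScreenDataset,
    tolerance: float = DEFAULT_VIABILITY_TOLERANCE,
    reference: str = "vehicle",
) -> ViabilityResult:
    """Exclude compounds whose diameter shrank beyond ``tolerance``.

    A compound is excluded on a platform when its diameter is below
    ``(1 - tolerance) * reference_mean`` for that platform; the reference
    mean pools vehicle wells, untreated wells, or both.  Compounds with a
    missing diameter are flagged unknown (retained) with a warning.
    """
    if not 0 <= tolerance < 1:
        raise ConfigError(f"tolerance must be in [0, 1), got {tolerance}")
    if reference not in VIABILITY_REFERENCES:
        raise ConfigError(
            f"reference must be one of {VIABILITY_REFERENCES}, got {reference!r}"
        )
    ref_roles = {"vehicle": ("vehicle",), "untreated": ("untreated",), "both": (
        "vehicle",
        "untreated",
    )}[reference]
    excluded: dict[str, frozenset[str]] = {}
    unknown: dict[str, frozenset[str]] = {}
    ref_means: dict[str, float] = {}
    warnings: list[str] = []
    for platform in ds.platforms():
        compounds = ds.wells_where(role="compound", platform=platform)
        if not compounds:
            continue
        ref_diams = [
            w.diameter_um
            for role in ref_roles
            for w in ds.wells_where(role=role, platform=platform)
            if w.diameter_um is not None
        ]
        if not ref_diams:
            raise ConfigError(
                f"no {'/'.join(ref_roles)} reference diameters on platform "
                f"{platform!r}; cannot apply the viability filter"
            )
        ref_mean = float(np.mean(ref_diams))
        ref_means[platform] = ref_mean
        cutoff = (1.0 - tolerance) * ref_mean
        excl: set[str] = set()
        unk: set[str] = set()
        for w in compounds:
            if w.diameter_um is None:
                unk.add(w.compound_id)
                warnings.append(
                    f"compound {w.compound_id} on {platform} has no diameter; "
                    "viability unknown, well retained"
                )
            elif w.diameter_um < cutoff:
                excl.add(w.compound_id)
        excluded[platform] = frozenset(excl)
        unknown[platform] = frozenset(unk)
    return ViabilityResult(
        excluded=excluded,
        unknown=unknown,
        reference_mean=ref_means,
        tolerance=tolerance,
        reference=reference,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------


@dataclass
class Thresholds:
    """Hit thresholds in percent-decrease units with their provenance.

    Provenance per (platform, analyte) is ``negative_control`` when the
    tocilizumab-vs-vehicle percent decrease set the value, else ``floor``.
    """

    values: dict[tuple[str, str], float]
    provenance: dict[tuple[str, str], str]
    floor: float

    def get(self, platform: str, analyte: str) -> float:
        try:
            return self.values[(platform, analyte)]
        except KeyError:
            raise ConfigError(
                f"no threshold for platform {platform!r}, analyte {analyte!r}"
            ) from None

    @classmethod
    def manual(cls, values: Mapping[tuple[str, str], float], floor: float = 0.0):
        return cls(
            values=dict(values),
            provenance={k: "manual" for k in values},
            floor=floor,
        )


def derive_thresholds(ds: ScreenDataset, floor: float = DEFAULT_FLOOR_PCT) -> Thresholds:
    """Anchor thresholds on the negative control's percent decrease.

    threshold = max(percent_decrease(mean_negative, mean_vehicle), floor),
    per (platform, analyte).  Missing negative controls are an error: supply
    ``Thresholds.manual`` instead.
    """
    if floor < 0:
        raise ConfigError(f"threshold floor must be >= 0, got {floor}")
    veh = vehicle_means(ds)
    values: dict[tuple[str, str], float] = {}
    provenance: dict[tuple[str, str], str] = {}
    for platform in ds.platforms():
        for analyte in ds.analyte_panel:
            neg = ds.analyte_array("negative", platform, analyte)
            if neg.size == 0:
                raise ConfigError(
                    f"no negative-control wells for {analyte!r} on platform "
                    f"{platform!r}; derive_thresholds needs them -- provide "
                    "explicit manual thresholds instead"
                )
            if (platform, analyte) not in veh:
                raise ConfigError(
                    f"no vehicle wells for {analyte!r} on platform {platform!r}"
                )
            derived = percent_decrease(float(neg.mean()), veh[(platform, analyte)])
            if derived >= floor:
                values[(platform, analyte)] = derived
                provenance[(platform, analyte)] = "negative_control"
            else:
                values[(platform, analyte)] = floor
                provenance[(platform, analyte)] = "floor"
    return Thresholds(values=values, provenance=provenance, floor=floor)


# ---------------------------------------------------------------------------
# hit table
# ---------------------------------------------------------------------------

HIT_COLUMNS = (
    "compound_id",
    "platform",
    "analyte",
    "concentration_pg_ml",
    "percent_decrease",
    "viability",
    "hit",
    "rank",
)


@dataclass
class HitTable:
    """Per (compound, platform, analyte) scores, flags and dense hit ranks."""

    data: pd.DataFrame
    thresholds: Thresholds

    def hit_compounds(
        self, platform: str | None = None, analyte: str | None = None
    ) -> frozenset[str]:
        sub = self.data[self.data["hit"]]
        if platform is not None:
            sub = sub[sub["platform"] == platform]
        if analyte is not None:
            sub = sub[sub["analyte"] == analyte]
        return frozenset(sub["compound_id"])

    def analytes(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.data["analyte"]))


def _normalize_excluded(
    excluded: "ViabilityResult | Mapping[str, Iterable[str]] | Iterable[str] | None",
    platform: str,
) -> tuple[frozenset[str], frozenset[str]]:
    """(excluded, unknown) compound sets applying to ``platform``."""
    if excluded is None:
        return frozenset(), frozenset()
    if isinstance(excluded, ViabilityResult):
        return excluded.excluded_on(platform), excluded.unknown_on(platform)
    if isinstance(excluded, Mapping):
        return frozenset(excluded.get(platform, ())), frozenset()
    return frozenset(excluded), frozenset()


def call_hits(
    ds: ScreenDataset,
    thresholds: Thresholds,
    excluded: "ViabilityResult | Mapping[str, Iterable[str]] | Iterable[str] | None" = None,
) -> HitTable:
    """Classify every (compound, platform, analyte) against its threshold.

    Hit iff percent_decrease > threshold (strict) and the compound was not
    excluded for viability on that platform.  Unknown-viability compounds
    remain eligible.  Ranks are dense 1..k per (platform, analyte) over hits,
    by descending percent decrease with compound-id tie-break.
    """
    veh = vehicle_means(ds)
    rows = []
    for platform in ds.platforms():
        excl, unk = _normalize_excluded(excluded, platform)
        for w in ds.wells_where(role="compound", platform=platform):
            for analyte in ds.analyte_panel:
                if analyte not in w.analyte_values:
                    continue
                if (platform, analyte) not in veh:
                    raise ConfigError(
                        f"no vehicle wells for {analyte!r} on {platform!r}"
                    )
                thr = thresholds.get(platform, analyte)
                pd_pct = percent_decrease(
                    w.analyte_values[analyte], veh[(platform, analyte)]
                )
                if w.compound_id in excl:
                    viability = "excluded"
                elif w.compound_id in unk:
                    viability = "unknown"
                else:
                    viability = "pass"
                rows.append(
                    {
                        "compound_id": w.compound_id,
                        "platform": platform,
                        "analyte": analyte,
                        "concentration_pg_ml": w.analyte_values[analyte],
                        "percent_decrease": pd_pct,
                        "viability": viability,
                        "hit": (pd_pct > thr) and viability != "excluded",
                        "rank": np.nan,
                    }
                )
    data = pd.DataFrame(rows, columns=list(HIT_COLUMNS))
    for (_, _), idx in data.groupby(["platform", "analyte"], sort=False).groups.items():
        sub = data.loc[idx]
        hits = sub[sub["hit"]].sort_values(
            ["percent_decrease", "compound_id"], ascending=[False, True]
        )
        data.loc[hits.index, "rank"] = np.arange(1, len(hits) + 1, dtype=float)
    return HitTable(data=data, thresholds=thresholds)


def rank_hits(
    ht: HitTable, k: int = DEFAULT_SHORTLIST
) -> dict[tuple[str, str], pd.DataFrame]:
    """Top-``k`` shortlist per (platform, analyte), by potency of inhibition."""
    if k < 1:
        raise ValueError(f"shortlist size must be >= 1, got {k}")
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for (platform, analyte), sub in ht.data.groupby(["platform", "analyte"], sort=False):
        hits = sub[sub["hit"]].sort_values(
            ["percent_decrease", "compound_id"], ascending=[False, True]
        )
        out[(platform, analyte)] = hits.head(k)[
            ["compound_id", "percent_decrease", "rank"]
        ].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# intersection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IntersectionResult:
    """Shared and exclusive hit sets; the three partition the union."""

    shared: frozenset[str]
    only_a: frozenset[str]
    only_b: frozenset[str]

    @property
    def union(self) -> frozenset[str]:
        return self.shared | self.only_a | self.only_b


def intersect_hits(
    a: HitTable, b: HitTable, mode: str = "any_analyte"
) -> "IntersectionResult | dict[str, IntersectionResult]":
    """Venn-style intersection of hit compound sets from two screens.

    ``any_analyte`` pools hits across analytes; ``per_analyte`` returns one
    result per analyte present in either table.
    """
    if mode == "any_analyte":
        sa, sb = a.hit_compounds(), b.hit_compounds()
        return IntersectionResult(
            shared=sa & sb, only_a=sa - sb, only_b=sb - sa
        )
    if mode == "per_analyte":
        analytes = tuple(dict.fromkeys(a.analytes() + b.analytes()))
        out = {}
        for analyte in analytes:
            sa = a.hit_compounds(analyte=analyte)
            sb = b.hit_compounds(analyte=analyte)
            out[analyte] = IntersectionResult(
                shared=sa & sb, only_a=sa - sb, only_b=sb - sa
            )
        return out
    raise ValueError(f"mode must be 'any_analyte' or 'per_analyte', got {mode!r}")
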