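"""Synthetic screen, survival and composition generators with known truth.

Every generator is a pure function of its config (seed included), so each
analysis stage can be tested against configured ground truth.  Assay noise is
multiplicative log-normal: concentrations are positive and right-skewed, and
with the noise SD set to zero each draw collapses to its expectation exactly.
"""

from __future__ import annotations

import string
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .screen_data import ScreenDataset, Well
from .survival_kinetics import SurvivalSeries

#: Default dual readout of the screen.
DEFAULT_PANEL = ("IL-6", "IL-8")

#: The 14-plex inflammatory cytokine panel used for full profiling.
CYTOKINE_PANEL_14 = (
    "IL-6",
    "IL-8",
    "IL-2",
    "IL-4",
    "IL-5",
    "IL-10",
    "IL-12",
    "IL-12p70",
    "IL-13",
    "IL-17a",
    "IL-1b",
    "GM-CSF",
    "IFN-gamma",
    "TNF-alpha",
)

_ROW_LETTERS = string.ascii_uppercase[:16]  # virtual 384-well grid per plate


def _position_labels(n: int) -> list[tuple[str, str]]:
    """(plate suffix, position) labels filling 384-well plates row-major."""
    out = []
    per_plate = len(_ROW_LETTERS) * 24
    for i in range(n):
        plate_idx, offset = divmod(i, per_plate)
        row, col = divmod(offset, 24)
        out.append((f"plate{plate_idx + 1}", f"{_ROW_LETTERS[row]}{col + 1:02d}"))
    return out


# ---------------------------------------------------------------------------
# screen
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenSimConfig:
    """Parameters of the simulated single-well-per-compound screen.

    Baseline (vehicle-mean) concentrations are arbitrary: the source screen
    reports only relative reductions, never absolute vehicle levels, so any
    positive values work and the defaults are chosen for readability.
    """

    n_compounds: int = 190
    analyte_panel: tuple[str, ...] = DEFAULT_PANEL
    baseline: Mapping[str, float] | None = None  # pg/mL; default 200 each
    noise_sigma_log: float = 0.1
    lps_fold: Mapping[str, float] | None = None  # default 8x each analyte
    toci_effect: Mapping[str, float] | None = None  # default IL-6 ~0, others 0.3
    control_replicates: int = 3
    untreated_replicates: int = 3
    diameter_mean: float = 100.0
    diameter_sd: float = 2.0
    platforms: tuple[str, ...] = ("spinal_microtissue", "microglia_spheroid")
    compound_dose_um: float = 5.0
    negative_dose_um: float = 1.0  # tocilizumab
    positive_dose: float = 1.0  # LPS, recorded in μg/mL by convention
    vehicle_dmso_pct: float = 0.01
    seed: int = 0

    def resolved_baseline(self) -> dict[str, float]:
        if self.baseline is None:
            return {a: 200.0 for a in self.analyte_panel}
        return dict(self.baseline)

    def resolved_lps_fold(self) -> dict[str, float]:
        if self.lps_fold is None:
            return {a: 8.0 for a in self.analyte_panel}
        return dict(self.lps_fold)

    def resolved_toci_effect(self) -> dict[str, float]:
        if self.toci_effect is None:
            return {a: (0.02 if a == "IL-6" else 0.3) for a in self.analyte_panel}
        return dict(self.toci_effect)

    def validate(self) -> None:
        if self.n_compounds < 0:
            raise ConfigError("n_compounds must be >= 0")
        if not self.analyte_panel:
            raise ConfigError("analyte_panel must be nonempty")
        if self.noise_sigma_log < 0:
            raise ConfigError("noise_sigma_log must be >= 0")
        if self.control_replicates < 1:
            raise ConfigError("control_replicates must be >= 1")
        if self.untreated_replicates < 0:
            raise ConfigError("untreated_replicates must be >= 0")
        if not self.diameter_mean > 0 or self.diameter_sd < 0:
            raise ConfigError("diameter_mean must be > 0 and diameter_sd >= 0")
        for a, v in self.resolved_baseline().items():
            if not v > 0:
                raise ConfigError(f"baseline for {a!r} must be > 0, got {v}")
        for a, v in self.resolved_lps_fold().items():
            if not v > 1:
                raise ConfigError(f"lps_fold for {a!r} must be > 1, got {v}")
        for a, v in self.resolved_toci_effect().items():
            if not 0 <= v < 1:
                raise ConfigError(f"toci_effect for {a!r} must be in [0, 1), got {v}")


@dataclass(frozen=True)
class EffectSpec:
    """Ground truth: per compound x analyte fractional reduction, plus toxicity."""

    effects: Mapping[str, Mapping[str, float]]
    toxic: frozenset[str] = frozenset()
    diameter_shrink: float = 0.3

    def __post_init__(self) -> None:
        for cid, per_analyte in self.effects.items():
            for a, f in per_analyte.items():
                if not 0 <= f < 1:
                    raise ConfigError(
                        f"effect for {cid}/{a} must be in [0, 1), got {f}"
                    )
        if not 0 <= self.diameter_shrink < 1:
            raise ConfigError("diameter_shrink must be in [0, 1)")

    def effect(self, compound_id: str, analyte: str) -> float:
        return self.effects.get(compound_id, {}).get(analyte, 0.0)

    def is_toxic(self, compound_id: str) -> bool:
        return compound_id in self.toxic

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "compound_id": cid,
                "analyte": a,
                "true_effect": f,
                "toxic": cid in self.toxic,
            }
            for cid, per_analyte in self.effects.items()
            for a, f in per_analyte.items()
        ]
        return pd.DataFrame(rows, columns=["compound_id", "analyte", "true_effect", "toxic"])


def compound_ids(n: int) -> list[str]:
    return [f"C{i:03d}" for i in range(1, n + 1)]


def draw_effects(
    ids: Sequence[str],
    analyte_panel: Sequence[str],
    rng: np.random.Generator,
    active_rate: float = 0.15,
    effect_range: tuple[float, float] = (0.2, 0.7),
    effect_choices: Sequence[float] | None = None,
    choice_weights: Sequence[float] | None = None,
    toxic_rate: float = 0.02,
    diameter_shrink: float = 0.3,
) -> EffectSpec:
    """Draw a random ground-truth effect spec.

    When ``effect_choices`` is given, each (compound, analyte) effect is drawn
    from that discrete set (with ``choice_weights``); otherwise a fraction
    ``active_rate`` of pairs get a uniform effect in ``effect_range`` and the
    rest are inert.
    """
    effects: dict[str, dict[str, float]] = {}
    toxic: set[str] = set()
    for cid in ids:
        per: dict[str, float] = {}
        for a in analyte_panel:
            if effect_choices is not None:
                per[a] = float(rng.choice(np.asarray(effect_choices, float), p=choice_weights))
            elif rng.random() < active_rate:
                per[a] = float(rng.uniform(*effect_range))
            else:
                per[a] = 0.0
        effects[cid] = per
        if rng.random() < toxic_rate:
            toxic.add(cid)
    return EffectSpec(effects=effects, toxic=frozenset(toxic), diameter_shrink=diameter_shrink)


def generate_screen(
    cfg: ScreenSimConfig, effects: EffectSpec | None = None
) -> tuple[ScreenDataset, EffectSpec]:
    """Simulate a screen dataset plus its ground truth.

    One well per compound per platform; ``control_replicates`` vehicle,
    positive (LPS) and negative (tocilizumab) wells, plus optional untreated
    wells, per platform.  Concentration of analyte ``a`` in a compound well
    is ``baseline_a * (1 - f) * exp(eps)`` with ``eps ~ N(0, sigma)``; toxic
    compounds get diameters centered on ``(1 - shrink) * diameter_mean``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ids = compound_ids(cfg.n_compounds)
    if effects is None:
        effects = draw_effects(ids, cfg.analyte_panel, rng)
    baseline = cfg.resolved_baseline()
    lps_fold = cfg.resolved_lps_fold()
    toci = cfg.resolved_toci_effect()
    sigma = cfg.noise_sigma_log

    def conc(mean: float) -> float:
        return mean * float(np.exp(rng.normal(0.0, sigma)))

    def diameter(mean: float) -> float:
        d = float(rng.normal(mean, cfg.diameter_sd))
        return max(d, 1e-6)

    wells: list[Well] = []
    for platform in cfg.platforms:
        layout: list[tuple[str, str, float | None]] = []
        layout += [("vehicle", "", cfg.vehicle_dmso_pct)] * cfg.control_replicates
        layout += [("positive", "", cfg.positive_dose)] * cfg.control_replicates
        layout += [("negative", "", cfg.negative_dose_um)] * cfg.control_replicates
        layout += [("untreated", "", None)] * cfg.untreated_replicates
        layout += [("compound", cid, cfg.compound_dose_um) for cid in ids]
        labels = _position_labels(len(layout))
        for (role, cid, dose), (plate_suffix, pos) in zip(layout, labels):
            values: dict[str, float] = {}
            for a in cfg.analyte_panel:
                if role == "positive":
                    mean = baseline[a] * lps_fold[a]
                elif role == "negative":
                    mean = baseline[a] * (1.0 - toci[a])
                elif role == "compound":
                    mean = baseline[a] * (1.0 - effects.effect(cid, a))
                else:  # vehicle, untreated
                    mean = baseline[a]
                values[a] = conc(mean)
            d_mean = cfg.diameter_mean
            if role == "compound" and effects.is_toxic(cid):
                d_mean *= 1.0 - effects.diameter_shrink
            wells.append(
                Well(
                    plate_id=f"{platform}-{plate_suffix}",
                    position=pos,
                    role=role,
                    platform=platform,
                    compound_id=cid,
                    dose_um=dose,
                    analyte_values=values,
                    diameter_um=diameter(d_mean),
                )
            )
    ds = ScreenDataset(
        wells=wells,
        analyte_panel=tuple(cfg.analyte_panel),
        metadata={"seed": cfg.seed, "noise_sigma_log": sigma},
    )
    return ds, effects


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivalSimConfig:
    """Constant-hazard exponential decline sampled on a fixed cadence."""

    interval_h: float = 4.0
    duration_h: float = 336.0
    n0: int = 500
    death_rate: float = 0.002  # per hour
    count_noise: bool = True  # Poisson counts around the expectation
    n_replicates: int = 3
    condition: str = "triculture"
    treatment: str = "vehicle"
    seed: int = 0

    def validate(self) -> None:
        if self.interval_h <= 0 or self.duration_h <= 0:
            raise ConfigError("interval_h and duration_h must be > 0")
        ratio = self.duration_h / self.interval_h
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigError(
                f"duration_h ({self.duration_h}) must be an integer multiple of "
                f"interval_h ({self.interval_h})"
            )
        if self.n0 <= 0:
            raise ConfigError("n0 must be > 0")
        if self.death_rate < 0:
            raise ConfigError("death_rate must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration_h / self.interval_h))
        return np.arange(n + 1, dtype=float) * self.interval_h


def generate_survival(cfg: SurvivalSimConfig) -> list[SurvivalSeries]:
    """Simulate replicate count series; noiseless mode rounds the expectation."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    times = cfg.time_grid()
    expected = cfg.n0 * np.exp(-cfg.death_rate * times)
    out = []
    for r in range(1, cfg.n_replicates + 1):
        if cfg.count_noise:
            counts = rng.poisson(expected)
        else:
            counts = np.rint(expected).astype(int)
        out.append(
            SurvivalSeries(
                condition=cfg.condition,
                treatment=cfg.treatment,
                replicate=f"R{r}",
                times=times,
                counts=counts,
            )
        )
    return out


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

MARKER_COLUMNS = ("motor_neuron", "astrocyte", "microglia")


@dataclass(frozen=True)
class CompositionSimConfig:
    """Microtissue cell-type counts over time, with genotype-dependent MN loss.

    ``ratio`` is astrocyte:MN:microglia parts.  The disease genotype loses a
    fraction ``mn_decline_rate`` of its motor neurons per day, compounded
    from the earliest configured timepoint (composition is defined at the
    first observation day, where the two genotypes are indistinguishable).
    """

    total_cells: int = 7500
    ratio: tuple[int, int, int] = (1, 3, 1)  # astrocyte : MN : microglia
    mn_decline_rate: float = 0.0
    timepoints: tuple[float, ...] = (5.0, 7.0, 14.0)
    sampling: str = "exact"  # or "multinomial"
    n_samples: int = 3
    genotypes: tuple[str, ...] = ("control", "disease")
    treatment: str = "vehicle"
    seed: int = 0

    def validate(self) -> None:
        if self.total_cells <= 0:
            raise ConfigError("total_cells must be > 0")
        if len(self.ratio) != 3 or any(
            (not isinstance(r, (int, np.integer))) or r <= 0 for r in self.ratio
        ):
            raise ConfigError("ratio must be three positive integer parts")
        if self.sampling not in ("exact", "multinomial"):
            raise ConfigError("sampling must be 'exact' or 'multinomial'")
        if self.sampling == "exact" and self.total_cells % sum(self.ratio) != 0:
            raise ConfigError(
                f"total_cells ({self.total_cells}) must be divisible by the "
                f"ratio part sum ({sum(self.ratio)}) in exact mode"
            )
        if not 0 <= self.mn_decline_rate < 1:
            raise ConfigError("mn_decline_rate must be in [0, 1)")
        if not self.timepoints:
            raise ConfigError("timepoints must be nonempty")
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")

    def base_counts(self) -> dict[str, float]:
        unit = self.total_cells / sum(self.ratio)
        astro, mn, micro = self.ratio
        return {
            "astrocyte": astro * unit,
            "motor_neuron": mn * unit,
            "microglia": micro * unit,
        }


def generate_composition(cfg: CompositionSimConfig) -> pd.DataFrame:
    """Simulate classified-object counts per (sample, genotype, timepoint).

    Columns: sample_id, genotype, treatment, timepoint_day, motor_neuron,
    astrocyte, microglia, unclassified.  Exact mode is deterministic;
    multinomial mode resamples the expected composition at the full cell
    count per sample.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    base = cfg.base_counts()
    day0 = min(cfg.timepoints)
    rows = []
    for genotype in cfg.genotypes:
        declining = genotype != "control"
        for day in cfg.timepoints:
            mn = base["motor_neuron"]
            if declining:
                mn *= (1.0 - cfg.mn_decline_rate) ** (day - day0)
            expected = {
                "motor_neuron": mn,
                "astrocyte": base["astrocyte"],
                "microglia": base["microglia"],
            }
            for s in range(1, cfg.n_samples + 1):
                if cfg.sampling == "exact":
                    counts = {k: int(round(v)) for k, v in expected.items()}
                else:
                    total = sum(expected.values())
                    probs = np.array([expected[k] for k in MARKER_COLUMNS]) / total
                    draw = rng.multinomial(cfg.total_cells, probs)
                    counts = dict(zip(MARKER_COLUMNS, (int(x) for x in draw)))
                rows.append(
                    {
                        "sample_id": f"{genotype}-d{day:g}-s{s}",
                        "genotype": genotype,
                        "treatment": cfg.treatment,
                        "timepoint_day": day,
                        **{k: counts[k] for k in MARKER_COLUMNS},
                        "unclassified": 0,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "genotype",
            "treatment",
            "timepoint_day",
            *MARKER_COLUMNS,
            "unclassified",
        ],
    )


__all__ = [
    "DEFAULT_PANEL",
    "CYTOKINE_PANEL_14",
    "MARKER_COLUMNS",
    "ScreenSimConfig",
    "EffectSpec",
    "SurvivalSimConfig",
    "CompositionSimConfig",
    "compound_ids",
    "draw_effects",
    "generate_screen",
    "generate_survival",
    "generate_composition",
]
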