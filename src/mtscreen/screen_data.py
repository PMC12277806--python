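"""Domain types, validation and I/O for plate-format screen tables.

The exchange format is a long-form CSV with one row per well.  Required
columns are ``plate_id, position, role, compound_id, dose_um, platform,
diameter_um`` followed by one column per analyte in the panel, holding
concentrations in pg/mL.  Diameters are in μm and may be missing; doses are
in μM (the LPS positive control carries its dose in μg/mL by convention,
recorded in the same column).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import math

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError

ROLES = ("compound", "vehicle", "positive", "negative", "untreated")
PLATFORMS = ("spinal_microtissue", "microglia_spheroid", "coculture", "triculture")
CONTROL_ROLES = ("vehicle", "positive", "negative")

#: Columns every screen table must declare, in canonical order.
REQUIRED_COLUMNS = (
    "plate_id",
    "position",
    "role",
    "compound_id",
    "dose_um",
    "platform",
    "diameter_um",
)


@dataclass(frozen=True)
class Well:
    """A single well: the atom of the screen.

    ``analyte_values`` maps analyte name to concentration in pg/mL;
    ``diameter_um`` is the microtissue diameter or ``None`` when the plate
    was not measured.
    """

    plate_id: str
    position: str
    role: str
    platform: str
    compound_id: str = ""
    dose_um: float | None = None
    analyte_values: Mapping[str, float] = field(default_factory=dict)
    diameter_um: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise FormatError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.platform not in PLATFORMS:
            raise FormatError(
                f"unknown platform {self.platform!r}; expected one of {PLATFORMS}"
            )
        for analyte, value in self.analyte_values.items():
            if not math.isfinite(value) or value < 0:
                raise DomainError(
                    f"well {self.plate_id}/{self.position}: analyte {analyte!r} "
                    f"concentration must be finite and >= 0, got {value}"
                )
        if self.diameter_um is not None and not self.diameter_um > 0:
            raise DomainError(
                f"well {self.plate_id}/{self.position}: diameter must be > 0, "
                f"got {self.diameter_um}"
            )


@dataclass
class ScreenDataset:
    """A collection of wells plus the ordered analyte panel they share."""

    wells: list[Well]
    analyte_panel: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.analyte_panel = tuple(self.analyte_panel)
        panel = set(self.analyte_panel)
        for w in self.wells:
            extra = set(w.analyte_values) - panel
            if extra:
                raise FormatError(
                    f"well {w.plate_id}/{w.position} references analytes "
                    f"{sorted(extra)} not in the panel {self.analyte_panel}"
                )

    # -- accessors -------------------------------------------------------

    def platforms(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for w in self.wells:
            seen.setdefault(w.platform, None)
        return tuple(seen)

    def wells_where(
        self,
        role: str | None = None,
        platform: str | None = None,
        plate_id: str | None = None,
    ) -> list[Well]:
        out = self.wells
        if role is not None:
            out = [w for w in out if w.role == role]
        if platform is not None:
            out = [w for w in out if w.platform == platform]
        if plate_id is not None:
            out = [w for w in out if w.plate_id == plate_id]
        return out

    def analyte_array(self, role: str, platform: str, analyte: str) -> np.ndarray:
        """Concentrations of ``analyte`` across wells of ``role`` on ``platform``."""
        vals = [
            w.analyte_values[analyte]
            for w in self.wells_where(role=role, platform=platform)
            if analyte in w.analyte_values
        ]
        return np.asarray(vals, dtype=float)

    def counts(self) -> dict[tuple[str, str], int]:
        """Well counts keyed by (platform, role)."""
        out: dict[tuple[str, str], int] = {}
        for w in self.wells:
            key = (w.platform, w.role)
            out[key] = out.get(key, 0) + 1
        return out

    # -- frame conversion ------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in self.wells:
            row: dict[str, object] = {
                "plate_id": w.plate_id,
                "position": w.position,
                "role": w.role,
                "compound_id": w.compound_id,
                "dose_um": np.nan if w.dose_um is None else w.dose_um,
                "platform": w.platform,
                "diameter_um": np.nan if w.diameter_um is None else w.diameter_um,
            }
            for a in self.analyte_panel:
                row[a] = w.analyte_values.get(a, np.nan)
            rows.append(row)
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + list(self.analyte_panel))

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, analyte_panel: Iterable[str] | None = None
    ) -> "ScreenDataset":
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"missing required column: {col!r}")
        if analyte_panel is None:
            panel = tuple(c for c in df.columns if c not in REQUIRED_COLUMNS)
        else:
            panel = tuple(analyte_panel)
            missing = [a for a in panel if a not in df.columns]
            if missing:
                raise FormatError(
                    f"missing analyte column(s): {', '.join(repr(m) for m in missing)}"
                )
        wells = []
        for i, rec in enumerate(df.to_dict("records")):
            values: dict[str, float] = {}
            for a in panel:
                raw = rec[a]
                if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                    continue
                try:
                    v = float(raw)
                except (TypeError, ValueError) as exc:
                    raise FormatError(
                        f"row {i}: analyte {a!r} value {raw!r} is not numeric"
                    ) from exc
                if v < 0:
                    raise DomainError(
                        f"row {i}: negative concentration {v} for analyte {a!r}"
                    )
                values[a] = v
            try:
                well = Well(
                    plate_id=_as_str(rec["plate_id"]),
                    position=_as_str(rec["position"]),
                    role=_as_str(rec["role"]),
                    platform=_as_str(rec["platform"]),
                    compound_id=_as_str(rec["compound_id"]),
                    dose_um=_as_opt_float(rec["dose_um"]),
                    analyte_values=values,
                    diameter_um=_as_opt_float(rec["diameter_um"]),
                )
            except (FormatError, DomainError) as exc:
                raise type(exc)(f"row {i}: {exc}") from None
            wells.append(well)
        return cls(wells=wells, analyte_panel=panel)


def _as_str(x: object) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return str(x)


def _as_opt_float(x: object) -> float | None:
    if x is None or x == "":
        return None
    v = float(x)  # type: ignore[arg-type]
    return None if math.isnan(v) else v


def load_screen_table(
    path, analyte_panel: Iterable[str] | None = None
) -> ScreenDataset:
    """Read a screen table CSV into a :class:`ScreenDataset`.

    When ``analyte_panel`` is given, those columns must be present; otherwise
    every non-required column is taken as an analyte, in file order.
    """
    try:
        # round_trip parsing keeps written floats bit-identical on re-read
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty screen table: {path}") from None
    if df.shape[0] == 0:
        raise FormatError(f"screen table has a header but no wells: {path}")
    return ScreenDataset.from_frame(df, analyte_panel=analyte_panel)


def write_screen_table(ds: ScreenDataset, path) -> None:
    """Write a dataset back to the CSV dialect read by :func:`load_screen_table`."""
    ds.to_frame().to_csv(path, index=False)


@dataclass
class ValidationReport:
    """Outcome of structural layout validation; empty ``errors`` means pass."""

    errors: list[str]
    warnings: list[str]
    counts: dict[tuple[str, str], int]

    @property
    def valid(self) -> bool:
        return not self.errors


def validate_layout(
    ds: ScreenDataset, min_control_replicates: int = 3
) -> ValidationReport:
    """Check a dataset against the screen's layout rules.

    Rules: each control role (vehicle/positive/negative) appears at least
    ``min_control_replicates`` times per platform; compound wells carry a
    compound id; (plate, position) pairs are unique per platform; any plate
    holding compound wells also holds at least one vehicle well.  Untreated
    wells are optional (their absence is a warning only, since viability can
    fall back to the vehicle reference).  Findings never raise; they are
    accumulated into the report, and validation is pure.
    """
    errors: list[str] = []
    warnings: list[str] = []
    counts = ds.counts()

    for platform in ds.platforms():
        for role in CONTROL_ROLES:
            n = counts.get((platform, role), 0)
            if n < min_control_replicates:
                errors.append(
                    f"{role} replicate count < {min_control_replicates} on "
                    f"platform {platform!r} (found {n})"
                )
        if counts.get((platform, "untreated"), 0) == 0:
            warnings.append(
                f"no untreated wells on platform {platform!r}; viability "
                "reference limited to vehicle wells"
            )

    seen: set[tuple[str, str, str]] = set()
    plates_with_compounds: set[tuple[str, str]] = set()
    plates_with_vehicle: set[tuple[str, str]] = set()
    n_missing_diameter = 0
    for w in ds.wells:
        key = (w.platform, w.plate_id, w.position)
        if key in seen:
            errors.append(
                f"duplicate well position {w.position!r} on plate "
                f"{w.plate_id!r} ({w.platform})"
            )
        seen.add(key)
        if w.role == "compound":
            plates_with_compounds.add((w.platform, w.plate_id))
            if not w.compound_id:
                errors.append(
                    f"compound well {w.plate_id}/{w.position} has no compound_id"
                )
        elif w.role == "vehicle":
            plates_with_vehicle.add((w.platform, w.plate_id))
        if w.diameter_um is None:
            n_missing_diameter += 1

    for platform, plate in sorted(plates_with_compounds - plates_with_vehicle):
        errors.append(
            f"plate {plate!r} ({platform}) has compound wells but no vehicle "
            "well; normalization is impossible"
        )
    if n_missing_diameter:
        warnings.append(
            f"{n_missing_diameter} well(s) have no diameter; viability "
            "filtering will flag them as unknown"
        )
    return ValidationReport(errors=errors, warnings=warnings, counts=counts)
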