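"""Assay-robustness statistics: control summaries and the Z'-factor.

Z' = 1 - 3(SD_pos + SD_veh)/|mean_pos - mean_veh|, the standard screening
window statistic.  It is computed on log-transformed signals by default
(assay signals are inspected on the log scale), with the raw-scale value
reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientReplicatesError, UndefinedSeparationError
from .screen_data import CONTROL_ROLES, ScreenDataset

#: Advisory verdict bands, screening-literature convention.
VERDICT_EXCELLENT = 0.5


@dataclass
class ControlSummary:
    """Per (platform, analyte, role) summary statistics on raw and log scale."""

    data: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


def control_summary(ds: ScreenDataset, roles: tuple[str, ...] | None = None) -> ControlSummary:
    """Summarize control wells per platform, analyte and role.

    Sample (n-1) SD; groups of one report SD as NaN with a warning; log-scale
    entries are NaN when any value is nonpositive.
    """
    if roles is None:
        roles = CONTROL_ROLES + ("untreated",)
    rows = []
    warnings: list[str] = []
    for platform in ds.platforms():
        for role in roles:
            present = any(True for _ in ds.wells_where(role=role, platform=platform))
            if not present:
                if role in CONTROL_ROLES:
                    warnings.append(
                        f"role {role!r} absent on platform {platform!r}; "
                        "summary cell omitted"
                    )
                continue
            for analyte in ds.analyte_panel:
                vals = ds.analyte_array(role, platform, analyte)
                if vals.size == 0:
                    continue
                sd = float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")
                if vals.size == 1:
                    warnings.append(
                        f"single well for {role}/{analyte} on {platform}; "
                        "SD undefined"
                    )
                if np.all(vals > 0):
                    logv = np.log(vals)
                    log_mean = float(logv.mean())
                    log_sd = (
                        float(np.std(logv, ddof=1)) if logv.size > 1 else float("nan")
                    )
                else:
                    log_mean = log_sd = float("nan")
                    warnings.append(
                        f"nonpositive value in {role}/{analyte} on {platform}; "
                        "log-scale summary omitted"
                    )
                rows.append(
                    {
                        "platform": platform,
                        "analyte": analyte,
                        "role": role,
                        "n": vals.size,
                        "mean": float(vals.mean()),
                        "sd": sd,
                        "log_mean": log_mean,
                        "log_sd": log_sd,
                    }
                )
    data = pd.DataFrame(
        rows,
        columns=["platform", "analyte", "role", "n", "mean", "sd", "log_mean", "log_sd"],
    )
    return ControlSummary(data=data, warnings=warnings)


def zprime(positive, vehicle) -> float:
    """Screening-window Z' between two control groups.

    Always <= 1; symmetric in its arguments; strictly decreasing in either
    sample SD at fixed means.
    """
    p = np.asarray(positive, dtype=float)
    v = np.asarray(vehicle, dtype=float)
    if p.size < 2 or v.size < 2:
        raise InsufficientReplicatesError(
            f"Z' needs >= 2 values per group (got {p.size} and {v.size})"
        )
    mp, mv = p.mean(), v.mean()
    if mp == mv:
        raise UndefinedSeparationError(
            "control means are equal; Z' separation is undefined"
        )
    return float(1.0 - 3.0 * (p.std(ddof=1) + v.std(ddof=1)) / abs(mp - mv))


def zprime_verdict(z: float) -> str:
    if np.isnan(z):
        return "undefined"
    if z >= VERDICT_EXCELLENT:
        return "excellent"
    if z >= 0.0:
        return "acceptable"
    return "failed"


@dataclass
class QCReport:
    """Per (platform, analyte) Z' on log and raw scales with a verdict."""

    data: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


def qc_report(ds: ScreenDataset, scale: str = "log") -> QCReport:
    """Z'-factor separation of positive versus vehicle controls.

    The verdict is taken from the chosen ``scale`` ('log' default, 'raw'
    alternative).
    """
    if scale not in ("log", "raw"):
        raise ValueError(f"scale must be 'log' or 'raw', got {scale!r}")
    rows = []
    warnings: list[str] = []
    for platform in ds.platforms():
        for analyte in ds.analyte_panel:
            pos = ds.analyte_array("positive", platform, analyte)
            veh = ds.analyte_array("vehicle", platform, analyte)
            if pos.size < 2 or veh.size < 2:
                warnings.append(
                    f"insufficient control replicates for {analyte} on "
                    f"{platform}; Z' skipped"
                )
                continue
            z_raw = _zprime_or_nan(pos, veh, warnings, platform, analyte, "raw")
            if np.all(pos > 0) and np.all(veh > 0):
                z_log = _zprime_or_nan(
                    np.log(pos), np.log(veh), warnings, platform, analyte, "log"
                )
            else:
                z_log = float("nan")
                warnings.append(
                    f"nonpositive control value for {analyte} on {platform}; "
                    "log-scale Z' omitted"
                )
            chosen = z_log if scale == "log" else z_raw
            rows.append(
                {
                    "platform": platform,
                    "analyte": analyte,
                    "n_positive": pos.size,
                    "n_vehicle": veh.size,
                    "zprime_log": z_log,
                    "zprime_raw": z_raw,
                    "scale": scale,
                    "verdict": zprime_verdict(chosen),
                }
            )
    data = pd.DataFrame(
        rows,
        columns=[
            "platform",
            "analyte",
            "n_positive",
            "n_vehicle",
            "zprime_log",
            "zprime_raw",
            "scale",
            "verdict",
        ],
    )
    return QCReport(data=data, warnings=warnings)


def _zprime_or_nan(p, v, warnings, platform, analyte, label) -> float:
    try:
        return zprime(p, v)
    except UndefinedSeparationError:
        warnings.append(
            f"equal control means for {analyte} on {platform} ({label} scale); "
            "Z' undefined"
        )
        return float("nan")
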