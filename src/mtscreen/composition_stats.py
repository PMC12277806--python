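"""Cell-type proportion quantification and group comparison over time.

Operates on classified-object count tables (one row per sample) with marker
columns ``motor_neuron, astrocyte, microglia`` plus ``unclassified``.
Comparisons act on per-sample fractions, since the underlying reports are
marker-positive percentages; unclassified objects are excluded from the
denominator by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, InsufficientReplicatesError
from .secretome_diff import adjust_pvalues, unpaired_t
from .synthetic_screen import MARKER_COLUMNS

UNCLASSIFIED = "unclassified"
ID_COLUMNS = ("sample_id", "genotype", "treatment", "timepoint_day")


def _check_table(ct: pd.DataFrame, include_unclassified: bool) -> tuple[str, ...]:
    markers = MARKER_COLUMNS + ((UNCLASSIFIED,) if include_unclassified else ())
    needed = [c for c in ("sample_id", "timepoint_day") if c not in ct.columns]
    needed += [m for m in MARKER_COLUMNS if m not in ct.columns]
    if needed:
        raise FormatError(f"missing required column(s): {needed}")
    if include_unclassified and UNCLASSIFIED not in ct.columns:
        raise FormatError(f"missing required column(s): ['{UNCLASSIFIED}']")
    counts = ct[list(markers)].to_numpy(float)
    if np.any(counts < 0) or np.any(~np.isfinite(counts)):
        raise DomainError("marker counts must be finite and >= 0")
    return markers


def proportions(ct: pd.DataFrame, include_unclassified: bool = False) -> pd.DataFrame:
    """Per-sample marker fractions; rows keep their id columns.

    Fractions are computed over the included markers and sum to 1 within
    1e-9 per sample.  An all-zero denominator is an error naming the sample.
    """
    markers = _check_table(ct, include_unclassified)
    totals = ct[list(markers)].sum(axis=1)
    zero = totals == 0
    if zero.any():
        bad = ct.loc[zero, "sample_id"].iloc[0]
        raise DomainError(f"sample {bad!r} has zero total classified count")
    out = ct.loc[:, [c for c in ID_COLUMNS if c in ct.columns]].copy()
    for m in markers:
        out[m] = ct[m] / totals
    return out


def compare_proportions(
    ct: pd.DataFrame,
    factor: str = "genotype",
    adjustment: str = "sidak",
    variant: str = "welch",
    alpha: float = 0.05,
    include_unclassified: bool = False,
) -> pd.DataFrame:
    """Two-group comparison of marker fractions per (marker, timepoint).

    ``factor`` must take exactly two levels across the table.  The
    multiplicity adjustment spans all (marker, timepoint) cells actually
    tested.  Markers absent everywhere are skipped; skips are recorded in
    ``.attrs['warnings']``.
    """
    markers = _check_table(ct, include_unclassified)
    if factor not in ct.columns:
        raise FormatError(f"factor column {factor!r} not in the table")
    levels = sorted(ct[factor].astype(str).unique())
    if len(levels) != 2:
        raise DomainError(
            f"factor {factor!r} must have exactly 2 levels, found {levels}"
        )
    frac = proportions(ct, include_unclassified=include_unclassified)
    frac[factor] = ct[factor].astype(str).to_numpy()
    warnings: list[str] = []
    rows = []
    for marker in markers:
        if (ct[marker] == 0).all():
            warnings.append(
                f"marker {marker!r} absent everywhere; comparisons skipped"
            )
            continue
        for tp in sorted(frac["timepoint_day"].unique()):
            sub = frac[frac["timepoint_day"] == tp]
            ga = sub.loc[sub[factor] == levels[0], marker].to_numpy(float)
            gb = sub.loc[sub[factor] == levels[1], marker].to_numpy(float)
            if ga.size < 2 or gb.size < 2:
                raise InsufficientReplicatesError(
                    f"marker {marker!r} at day {tp}: groups "
                    f"{levels[0]} (n={ga.size}) and {levels[1]} (n={gb.size}) "
                    "need >= 2 samples each"
                )
            t, p = unpaired_t(ga, gb, variant=variant)
            rows.append(
                {
                    "marker": marker,
                    "timepoint_day": tp,
                    "group_a": levels[0],
                    "group_b": levels[1],
                    "n_a": ga.size,
                    "n_b": gb.size,
                    "mean_a": ga.mean(),
                    "mean_b": gb.mean(),
                    "t": t,
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = adjust_pvalues(out["p"].to_numpy(float), adjustment, m=len(out))
        out["significant"] = out["p_adj"] < alpha
    else:
        out["p_adj"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    out.attrs["warnings"] = warnings
    out.attrs["adjustment"] = adjustment
    out.attrs["m"] = len(rows)
    return out
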