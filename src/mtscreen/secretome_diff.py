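"""Differential-abundance statistics for secretome/cytokine tables.

Log2 fold change on group means, an unpaired two-sample t-test (pooled or
Welch), Benjamini-Hochberg step-up q-values and the q <= cutoff significance
rule used for volcano-style annotation.
"""

from __future__ import annotations

import logging
import math
import warnings as _warnings
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InsufficientReplicatesError

logger = logging.getLogger(__name__)

T_VARIANTS = ("student", "welch")


def log2fc(a, b, log_means: bool = False) -> float:
    """Log2 ratio of group abundances; positive means higher in group ``a``.

    Default is log2 of the ratio of arithmetic group means.  With
    ``log_means=True`` the mean is taken on the log scale instead
    (difference of mean log2 abundances).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientReplicatesError("log2fc requires nonempty groups")
    for name, arr in (("a", a), ("b", b)):
        if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
            raise DomainError(
                f"log2fc requires strictly positive finite abundances in group {name}"
            )
    if log_means:
        return float(np.mean(np.log2(a)) - np.mean(np.log2(b)))
    return float(np.log2(a.mean() / b.mean()))


def unpaired_t(a, b, variant: str = "student") -> tuple[float, float]:
    """Two-sided unpaired t-test; ``student`` pools variances, ``welch`` does not.

    Degenerate convention: when both groups have zero variance, identical
    means give (t, p) = (0, 1) with a warning; distinct means give
    (+/-inf, 0).
    """
    if variant not in T_VARIANTS:
        raise ValueError(f"variant must be one of {T_VARIANTS}, got {variant!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicatesError(
            f"unpaired t-test needs >= 2 values per group (got {a.size} and {b.size})"
        )
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            _warnings.warn(
                "both groups have zero variance and equal means; p = 1 by convention",
                stacklevel=2,
            )
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending sort, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise DomainError("bh_adjust expects a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def sidak_adjust(p, m: int) -> np.ndarray:
    """Sidak adjustment for ``m`` planned comparisons: 1 - (1 - p)^m."""
    p = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DomainError("p-values must lie in [0, 1]")
    if m < 1:
        raise DomainError(f"number of comparisons must be >= 1, got {m}")
    return 1.0 - (1.0 - p) ** m


def adjust_pvalues(p, method: str, m: int | None = None) -> np.ndarray:
    """Dispatch multiplicity adjustment: 'sidak', 'bh' or 'none'."""
    p = np.asarray(p, dtype=float)
    if method == "none":
        return p.copy()
    if method == "bh":
        return bh_adjust(p)
    if method == "sidak":
        return sidak_adjust(p, p.size if m is None else m)
    raise ValueError(f"unknown adjustment {method!r}; use 'sidak', 'bh' or 'none'")


def differential_table(
    df: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    variant: str = "student",
    log_means: bool = False,
    id_col: str = "protein_id",
) -> pd.DataFrame:
    """Per-row log2FC and unpaired t-test between two sample-column groups.

    Missing abundances are handled row-wise complete-case within each group;
    rows where either group retains fewer than 2 values are dropped (the count
    is logged and recorded in ``.attrs['n_dropped']``).  Nonpositive
    abundances are a domain error naming the row.
    """
    for col in (id_col, *group_a, *group_b):
        if col not in df.columns:
            raise DomainError(f"column {col!r} not found in the abundance table")
    rows = []
    n_dropped = 0
    for _, rec in df.iterrows():
        a = pd.to_numeric(rec[list(group_a)], errors="coerce").dropna().to_numpy(float)
        b = pd.to_numeric(rec[list(group_b)], errors="coerce").dropna().to_numpy(float)
        if a.size < 2 or b.size < 2:
            n_dropped += 1
            continue
        if np.any(a <= 0) or np.any(b <= 0):
            raise DomainError(
                f"row {rec[id_col]!r}: abundances must be > 0 for log2FC"
            )
        t, p = unpaired_t(a, b, variant=variant)
        rows.append(
            {
                id_col: rec[id_col],
                "n_a": a.size,
                "n_b": b.size,
                "log2fc": log2fc(a, b, log_means=log_means),
                "t": t,
                "p": p,
            }
        )
    if n_dropped:
        logger.info("dropped %d row(s) with fewer than 2 values in a group", n_dropped)
    out = pd.DataFrame(rows, columns=[id_col, "n_a", "n_b", "log2fc", "t", "p"])
    out.attrs["n_dropped"] = n_dropped
    out.attrs["sign_convention"] = "positive log2fc = higher in group A"
    return out


def volcano_table(
    diff: pd.DataFrame,
    q_cutoff: float = 0.05,
    fc_cutoff: float | None = None,
) -> pd.DataFrame:
    """Annotate a differential table with BH q-values and a significance flag.

    q is computed jointly across all rows; a row is significant when
    q <= ``q_cutoff`` (inclusive) and, if ``fc_cutoff`` is given,
    \\|log2fc\\| >= ``fc_cutoff``.  Rows come back sorted by q then
    descending \\|log2fc\\|.
    """
    out = diff.copy()
    if out.shape[0] == 0:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    out["q"] = bh_adjust(out["p"].to_numpy(float))
    sig = out["q"] <= q_cutoff
    if fc_cutoff is not None:
        sig &= out["log2fc"].abs() >= fc_cutoff
    out["significant"] = sig
    order = np.lexsort((-out["log2fc"].abs().to_numpy(), out["q"].to_numpy()))
    return out.iloc[order].reset_index(drop=True)


@dataclass
class ProteomicsTable:
    """A wide abundance table bound to its two sample groups."""

    data: pd.DataFrame
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    id_col: str = "protein_id"
    metadata: dict = field(default_factory=dict)

    def analyze(
        self,
        variant: str = "student",
        log_means: bool = False,
        q_cutoff: float = 0.05,
        fc_cutoff: float | None = None,
    ) -> pd.DataFrame:
        diff = differential_table(
            self.data,
            self.group_a,
            self.group_b,
            variant=variant,
            log_means=log_means,
            id_col=self.id_col,
        )
        return volcano_table(diff, q_cutoff=q_cutoff, fc_cutoff=fc_cutoff)
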