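"""Population-level statistics of the classified phage pool.

Covers the wild-type accounting (WT share of all reads and of removed
reads), per-library read counts and propagation fold changes, the
distinct/repeated diversity partition, and plaque-count titer arithmetic
for the non-competitive assay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .libraries import LIBRARY_ORDER
from .reads import TimepointCounts


def wt_percentage(counts: TimepointCounts) -> float:
    """WT reads as a fraction of *all* reads at the time point."""
    if counts.total_reads == 0:
        raise InputError("cannot compute WT percentage of an empty time point")
    return counts.wt_count / counts.total_reads


def wt_share_of_removed(counts: TimepointCounts) -> float | None:
    """WT reads as a fraction of removed reads; None (with warning) if none removed."""
    if counts.removed_count == 0:
        warnings.warn("no removed reads; WT share undefined", stacklevel=2)
        return None
    return counts.wt_count / counts.removed_count


def library_fold_change(
    counts_t0: TimepointCounts,
    counts_t: TimepointCounts,
    normalize_depth: bool = False,
) -> dict[str, float]:
    """Per-library fold change of cleaned read counts between two time points.

    With ``normalize_depth`` the ratio is taken between per-time-point
    proportions (library count / cleaned total) instead of raw counts,
    removing differences in sequencing depth.
    """
    out: dict[str, float] = {}
    for lib in LIBRARY_ORDER:
        c0 = counts_t0.library_count(lib)
        ct = counts_t.library_count(lib)
        if c0 == 0:
            raise InputError(f"{lib}: zero cleaned reads at t={counts_t0.timepoint}")
        if normalize_depth:
            out[lib] = (ct / counts_t.cleaned_count) / (c0 / counts_t0.cleaned_count)
        else:
            out[lib] = ct / c0
    return out


@dataclass(frozen=True)
class DiversitySummary:
    """Distinct/repeated partition of the cleaned pool at one time point.

    ``distinct_pct`` counts one representative read per unique peptide;
    ``repeated_pct`` counts the surplus copies, so the two always sum to
    100.  ``per_library_distinct_pct`` splits the distinct share by the
    library of origin (all percentages use total cleaned reads as the
    denominator).
    """

    timepoint: int
    distinct_pct: float
    repeated_pct: float
    per_library_distinct_pct: dict[str, float]


def diversity_summary(
    counts: TimepointCounts, mode: str = "unique"
) -> DiversitySummary:
    """Partition cleaned reads into distinct and repeated sequences.

    ``mode="unique"`` (default): every unique peptide contributes one
    distinct read and ``count - 1`` repeated reads.  ``mode="singleton"``:
    only peptides seen exactly once count as distinct; all copies of a
    repeated peptide count as repeated.  Both partitions sum to 100%.
    """
    if mode not in ("unique", "singleton"):
        raise InputError(f"unknown diversity mode {mode!r}")
    cleaned = counts.cleaned_count
    if cleaned == 0:
        raise InputError("cannot summarize diversity of an empty cleaned pool")
    per_lib: dict[str, float] = {}
    distinct = 0
    for lib in LIBRARY_ORDER:
        counter = counts.per_library[lib]
        if mode == "unique":
            d = len(counter)
        else:
            d = sum(1 for c in counter.values() if c == 1)
        per_lib[lib] = 100.0 * d / cleaned
        distinct += d
    distinct_pct = 100.0 * distinct / cleaned
    return DiversitySummary(
        timepoint=counts.timepoint,
        distinct_pct=distinct_pct,
        repeated_pct=100.0 - distinct_pct,
        per_library_distinct_pct=per_lib,
    )


REQUIRED_PLAQUE_COLUMNS = (
    "library",
    "timepoint_min",
    "replicate",
    "plaques",
    "dilution",
    "volume_ml",
)


def titer_fold_change(plaques: pd.DataFrame) -> pd.DataFrame:
    """Plaque counts -> titers (pfu/mL) with SEM and fold change vs t=0.

    Input columns: ``library, timepoint_min, replicate, plaques, dilution,
    volume_ml``.  Titer per replicate is ``plaques * dilution / volume_ml``;
    per (library, time point) the mean titer, SEM (sd/sqrt(n); 0 for a single
    replicate) and the fold change against the library's t=0 mean titer are
    reported.
    """
    missing = [c for c in REQUIRED_PLAQUE_COLUMNS if c not in plaques.columns]
    if missing:
        raise InputError(f"plaque table missing columns: {', '.join(missing)}")
    if (plaques["dilution"] <= 0).any() or (plaques["volume_ml"] <= 0).any():
        raise InputError("dilution and volume_ml must be positive")
    table = plaques.copy()
    table["titer"] = table["plaques"] * table["dilution"] / table["volume_ml"]
    grouped = (
        table.groupby(["library", "timepoint_min"])["titer"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    grouped["sem"] = np.where(
        grouped["count"] > 1,
        grouped["std"] / np.sqrt(grouped["count"]),
        0.0,
    )
    out_rows = []
    for lib, sub in grouped.groupby("library"):
        t0 = sub[sub["timepoint_min"] == 0]
        if t0.empty:
            raise InputError(f"{lib}: missing t=0 row in plaque table")
        base = float(t0["mean"].iloc[0])
        for row in sub.itertuples(index=False):
            out_rows.append(
                {
                    "library": lib,
                    "timepoint_min": row.timepoint_min,
                    "titer": row.mean,
                    "sem": row.sem,
                    "fold_change": row.mean / base,
                    "n_replicates": row.count,
                }
            )
    return pd.DataFrame(out_rows).sort_values(
        ["library", "timepoint_min"]
    ).reset_index(drop=True)
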