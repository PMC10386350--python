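"""Relative-frequency and enrichment-factor (EF) analysis.

The EF of a peptide between two time points is the ratio of its relative
frequencies, ``EF = f_later / f_earlier``, computed only for peptides
observed at *both* time points ("overlapping" sequences; no pseudocounts
are added, so sequences appearing or vanishing between the two samples are
simply absent).  Relative frequencies use the total cleaned read count
across all libraries as the denominator by default; the total including
removed reads is available via ``denominator="all"``.

EF > 1 marks copy-number enrichment during the interval; the per-library
share of enriched sequences and the per-library EF histogram summarize
which library out-propagates the others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .libraries import LIBRARY_ORDER
from .reads import TimepointCounts


@dataclass(frozen=True)
class FrequencyTable:
    """Per-peptide relative frequencies at one time point."""

    timepoint: int
    denominator: int
    table: pd.DataFrame  # columns: library, peptide, count, freq


@dataclass(frozen=True)
class EFTable:
    """Enrichment factors for peptides overlapping two time points."""

    interval: tuple[int, int]
    table: pd.DataFrame  # columns: library, peptide, f_earlier, f_later, ef


def relative_frequencies(
    counts: TimepointCounts, denominator: str = "cleaned"
) -> FrequencyTable:
    """Relative frequency of every cleaned peptide at one time point."""
    if denominator == "cleaned":
        den = counts.cleaned_count
    elif denominator == "all":
        den = counts.total_reads
    else:
        raise ConfigurationError(f"unknown denominator mode {denominator!r}")
    if counts.cleaned_count == 0:
        raise InputError("cannot compute frequencies of an empty cleaned pool")
    rows = []
    for lib in LIBRARY_ORDER:
        for peptide, count in counts.per_library[lib].items():
            rows.append((lib, peptide, count, count / den))
    table = (
        pd.DataFrame(rows, columns=["library", "peptide", "count", "freq"])
        .sort_values(["library", "peptide"], kind="stable")
        .reset_index(drop=True)
    )
    if denominator == "cleaned":
        assert abs(table["freq"].sum() - 1.0) < 1e-12
    return FrequencyTable(timepoint=counts.timepoint, denominator=den, table=table)


def enrichment_factors(earlier: FrequencyTable, later: FrequencyTable) -> EFTable:
    """EF = f_later / f_earlier over the peptides present at both time points."""
    if earlier.timepoint >= later.timepoint:
        raise InputError(
            f"time points out of order: {earlier.timepoint} !< {later.timepoint}"
        )
    merged = earlier.table.merge(
        later.table,
        on=["library", "peptide"],
        how="inner",
        suffixes=("_earlier", "_later"),
    )
    if merged.empty:
        warnings.warn(
            f"no overlapping peptides between t={earlier.timepoint} "
            f"and t={later.timepoint}",
            stacklevel=2,
        )
    merged = merged.rename(
        columns={"freq_earlier": "f_earlier", "freq_later": "f_later"}
    )
    merged["ef"] = merged["f_later"] / merged["f_earlier"]
    out = merged[["library", "peptide", "f_earlier", "f_later", "ef"]]
    return EFTable(interval=(earlier.timepoint, later.timepoint), table=out)


def _round_half_up(value: float, digits: int = 1) -> float:
    return float(
        Decimal(repr(value)).quantize(Decimal(f"1e-{digits}"), rounding=ROUND_HALF_UP)
    )


def ef_library_shares(
    ef: EFTable, rounded: bool = False
) -> dict[str, float] | None:
    """Per-library percentage of sequences with EF strictly above 1.

    Sequences with EF exactly 1 are excluded.  Returns ``None`` (with a
    warning) if no sequence is enriched.  ``rounded`` reports one decimal
    place, half-up.
    """
    retained = ef.table[ef.table["ef"] > 1.0]
    if retained.empty:
        warnings.warn(
            f"no sequence with EF > 1 in interval {ef.interval}", stacklevel=2
        )
        return None
    total = len(retained)
    shares = {
        lib: 100.0 * int((retained["library"] == lib).sum()) / total
        for lib in LIBRARY_ORDER
    }
    if rounded:
        shares = {lib: _round_half_up(v) for lib, v in shares.items()}
    return shares


def ef_distribution(ef: EFTable, bins) -> pd.DataFrame:
    """Per-library histogram of EF values over the given bin edges.

    Edges must be positive and strictly increasing; values outside the
    outermost edges are not counted (numpy half-open bins, last bin closed).
    Columns: ``library, bin_left, bin_right, count``.
    """
    edges = np.asarray(bins, dtype=float)
    if edges.ndim != 1 or edges.size < 2:
        raise ConfigurationError("bins must be a 1-D sequence of >= 2 edges")
    if (edges <= 0).any() or (np.diff(edges) <= 0).any():
        raise ConfigurationError("bin edges must be positive and strictly increasing")
    if ef.table.empty:
        raise InputError("cannot histogram an empty EF table")
    rows = []
    for lib in LIBRARY_ORDER:
        values = ef.table.loc[ef.table["library"] == lib, "ef"].to_numpy()
        counts, _ = np.histogram(values, bins=edges)
        for left, right, count in zip(edges[:-1], edges[1:], counts):
            rows.append((lib, left, right, int(count)))
    return pd.DataFrame(rows, columns=["library", "bin_left", "bin_right", "count"])
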