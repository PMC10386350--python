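"""Read classification: extract the displayed-peptide window and sort reads.

Each amplicon read is anchored by a constant motif immediately 5' of the
insert.  The 17 codons following the anchor are translated; after dropping
the constant leading residue this yields a 16-residue *window* on which all
classification rules operate (1-based positions, position 1 = first residue
after the leading one):

* ``PhDC7C`` — position 1 = C, position 9 = C, positions 10-13 = GGGS,
  positions 2-8 free of ``*``/``X``; peptide = positions 2-8.
* ``PhD12``  — positions 13-16 = GGGS, positions 1-12 free of ``*``/``X``;
  peptide = positions 1-12.  This rule deliberately outranks PhD7, so a
  dodecapeptide that happens to contain GGGS at positions 8-11 is still a
  PhD12 read.
* ``PhD7``   — positions 8-11 = GGGS, positions 1-7 free of ``*``/``X``;
  peptide = positions 1-7.
* otherwise ``REMOVED``.  Removed reads are additionally screened for the
  insertless wild-type signature (AETVESCLAKSH with at most one mismatch,
  absorbing single sequencing errors).

The precedence order C7C > 12 > 7 is a single-pass equivalent of running
per-library filters and then deduplicating cleaned reads out of the other
libraries' removed pools: C7C cannot collide with the linear rules (it
needs C at position 9 where they need G), and the only genuine overlap is
the dual-GGGS dodecapeptide case resolved to PhD12.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ConfigurationError, InputError
from .libraries import CODON_TO_AA, LIBRARY_ORDER, LINKER, WT_SIGNATURE

REMOVED = "REMOVED"

#: codons in the anchored window (leading residue + 16 classified positions)
WINDOW_CODONS = 17
WINDOW_NT = WINDOW_CODONS * 3

_MIN_ANCHOR = 10
_INVALID = frozenset("*X")


def translate(nt: str) -> str:
    """Translate a nucleotide string with the standard genetic code.

    Stop codons become ``'*'``; any codon containing an ambiguous base (or
    any character outside A/C/G/T) becomes ``'X'``, which classification
    treats as invalid.
    """
    if len(nt) % 3 != 0:
        raise InputError(f"sequence length {len(nt)} is not a multiple of 3")
    nt = nt.upper()
    return "".join(
        CODON_TO_AA.get(nt[i : i + 3], "X") for i in range(0, len(nt), 3)
    )


def locate_window(read_nt: str, anchor: str) -> str | None:
    """Return the 51 nt immediately following the unique anchor occurrence.

    ``None`` (read becomes REMOVED) if the anchor is absent, occurs more
    than once, or fewer than 51 nt follow it.
    """
    if len(anchor) < _MIN_ANCHOR:
        raise ConfigurationError(
            f"anchor must be at least {_MIN_ANCHOR} nt, got {len(anchor)}"
        )
    start = read_nt.find(anchor)
    if start < 0:
        return None
    if read_nt.find(anchor, start + 1) >= 0:
        return None
    begin = start + len(anchor)
    window = read_nt[begin : begin + WINDOW_NT]
    if len(window) < WINDOW_NT:
        return None
    return window


@dataclass(frozen=True)
class PeptideWindow:
    """Translated anchored window: 17 residues, leading residue included."""

    full_window: str

    @property
    def residues(self) -> str:
        """The 16 classified positions (leading residue dropped), 1-based."""
        return self.full_window[1:]


@dataclass(frozen=True)
class ClassifiedRead:
    read_id: str | None
    label: str  # PhD7 | PhD12 | PhDC7C | REMOVED
    peptide: str | None = None  # randomized residues only; None for REMOVED
    is_wt: bool = False


def _clean(segment: str) -> bool:
    return not (_INVALID & set(segment))


def classify_window(residues: str) -> tuple[str, str | None]:
    """Apply the label rules to a 16-residue window; returns (label, peptide)."""
    if len(residues) != 16:
        return REMOVED, None
    if (
        residues[0] == "C"
        and residues[8] == "C"
        and residues[9:13] == LINKER
        and _clean(residues[1:8])
    ):
        return "PhDC7C", residues[1:8]
    if residues[12:16] == LINKER and _clean(residues[:12]):
        return "PhD12", residues[:12]
    if residues[7:11] == LINKER and _clean(residues[:7]):
        return "PhD7", residues[:7]
    return REMOVED, None


def classify_read(window: PeptideWindow, read_id: str | None = None) -> ClassifiedRead:
    """Classify one translated window (wild-type screening included)."""
    label, peptide = classify_window(window.residues)
    is_wt = label == REMOVED and detect_wt(window.full_window)
    return ClassifiedRead(read_id=read_id, label=label, peptide=peptide, is_wt=is_wt)


def detect_wt(full_window: str) -> bool:
    """True iff the first 12 residues are within Hamming distance 1 of AETVESCLAKSH."""
    if len(full_window) < len(WT_SIGNATURE):
        return False
    prefix = full_window[: len(WT_SIGNATURE)]
    mismatches = sum(a != b for a, b in zip(prefix, WT_SIGNATURE))
    return mismatches <= 1


def classify_sequence(seq: str, anchor: str, read_id: str | None = None) -> ClassifiedRead:
    """Locate, translate and classify one raw read sequence."""
    window_nt = locate_window(seq, anchor)
    if window_nt is None:
        return ClassifiedRead(read_id=read_id, label=REMOVED)
    return classify_read(PeptideWindow(translate(window_nt)), read_id=read_id)


# --- aggregation ------------------------------------------------------------

@dataclass
class TimepointCounts:
    """Per-time-point classification tallies.

    ``per_library`` maps library name -> Counter(peptide -> absolute count);
    conservation (cleaned + removed = total) is asserted on construction.
    """

    timepoint: int
    per_library: dict[str, Counter] = field(
        default_factory=lambda: {lib: Counter() for lib in LIBRARY_ORDER}
    )
    removed_count: int = 0
    wt_count: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def cleaned_count(self) -> int:
        return sum(sum(c.values()) for c in self.per_library.values())

    @property
    def total_reads(self) -> int:
        return self.cleaned_count + self.removed_count

    def library_count(self, library: str) -> int:
        return sum(self.per_library[library].values())

    def validate(self) -> None:
        if self.removed_count < 0 or self.wt_count < 0:
            raise InputError("counts must be non-negative")
        if self.wt_count > self.removed_count:
            raise InputError(
                f"wt_count {self.wt_count} exceeds removed_count {self.removed_count}"
            )
        for lib, counter in self.per_library.items():
            if any(c < 0 for c in counter.values()):
                raise InputError(f"negative peptide count in {lib}")

    # -- TSV round trip ------------------------------------------------------

    def write_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# timepoint={self.timepoint}\n")
            fh.write(f"# removed_count={self.removed_count}\n")
            fh.write(f"# wt_count={self.wt_count}\n")
            fh.write("peptide\tlibrary\tcount\n")
            for lib in LIBRARY_ORDER:
                for peptide, count in sorted(self.per_library[lib].items()):
                    fh.write(f"{peptide}\t{lib}\t{count}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TimepointCounts":
        path = Path(path)
        meta: dict[str, int] = {}
        with path.open() as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = int(value)
        table = pd.read_csv(path, sep="\t", comment="#")
        per_library = {lib: Counter() for lib in LIBRARY_ORDER}
        for row in table.itertuples(index=False):
            per_library[row.library][row.peptide] = int(row.count)
        return cls(
            timepoint=meta.get("timepoint", 0),
            per_library=per_library,
            removed_count=meta.get("removed_count", 0),
            wt_count=meta.get("wt_count", 0),
        )


def process_records(
    records: Iterable[tuple[str, str]],
    anchor: str,
    timepoint: int,
    collect: bool = False,
) -> TimepointCounts | tuple[TimepointCounts, list[ClassifiedRead]]:
    """Classify an iterable of ``(read_id, sequence)`` pairs.

    Classification is memoized per unique sequence (simulated pools repeat
    clone templates heavily).  With ``collect=True`` the per-read results
    are returned alongside the tallies.
    """
    per_library: dict[str, Counter] = {lib: Counter() for lib in LIBRARY_ORDER}
    removed = 0
    wt = 0
    cache: dict[str, tuple[str, str | None, bool]] = {}
    collected: list[ClassifiedRead] = []
    n = 0
    for read_id, seq in records:
        n += 1
        hit = cache.get(seq)
        if hit is None:
            result = classify_sequence(seq, anchor)
            hit = (result.label, result.peptide, result.is_wt)
            cache[seq] = hit
        label, peptide, is_wt = hit
        if label == REMOVED:
            removed += 1
            wt += is_wt
        else:
            per_library[label][peptide] += 1
        if collect:
            collected.append(ClassifiedRead(read_id, label, peptide, is_wt))
    if n == 0:
        raise InputError("no reads to classify")
    counts = TimepointCounts(
        timepoint=timepoint,
        per_library=per_library,
        removed_count=removed,
        wt_count=int(wt),
    )
    assert counts.total_reads == n  # conservation
    return (counts, collected) if collect else counts


def _iter_fastq(path: Path) -> Iterator[tuple[str, str]]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        index = 0
        parser = FastqGeneralIterator(fh)
        while True:
            try:
                item = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise InputError(
                    f"malformed FASTQ record near record {index} in {path}: {exc}"
                ) from exc
            title, seq, _qual = item
            yield title.split()[0], seq
            index += 1


def process_fastq(path: str | Path, anchor: str, timepoint: int) -> TimepointCounts:
    """Classify every read of a FASTQ file (gzip accepted) into tallies."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTQ file not found: {path}")
    try:
        return process_records(_iter_fastq(path), anchor, timepoint)
    except InputError as exc:
        if "no reads" in str(exc):
            raise InputError(f"empty FASTQ file: {path}") from None
        raise


def summary_frame(counts: Iterable[TimepointCounts]) -> pd.DataFrame:
    """One row per time point: per-library, removed, WT and total read counts."""
    rows = []
    for tc in counts:
        row = {"timepoint": tc.timepoint}
        for lib in LIBRARY_ORDER:
            row[lib.lower()] = tc.library_count(lib)
        row["removed"] = tc.removed_count
        row["wt"] = tc.wt_count
        row["total"] = tc.total_reads
        rows.append(row)
    return pd.DataFrame(rows).sort_values("timepoint").reset_index(drop=True)
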