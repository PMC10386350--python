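"""Library definitions and codon-level constants for M13KE phage-display peptide libraries.

Three widely used commercial libraries (NEB Ph.D. series) display random
peptides fused to the N-terminus of the minor coat protein pIII:

=========  ===================  =========================================
name       displayed window     layout
=========  ===================  =========================================
PhD7       ``A-X7-GGGS``        linear heptapeptide
PhD12      ``A-X12-GGGS``       linear dodecapeptide
PhDC7C     ``AC-X7-CGGGS``      disulfide-constrained heptapeptide loop
=========  ===================  =========================================

``X`` positions are NNK-randomized (N = A/C/G/T, K = G/T): 32 codons that
cover all 20 canonical amino acids plus the single amber stop TAG.  The
GGGS tetrapeptide linker joins the displayed peptide to mature pIII, whose
N-terminal sequence ``AETVESCLAKSH`` is the diagnostic signature of
insertless wild-type (WT) clones.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .errors import ConfigurationError

# --- genetic code -----------------------------------------------------------

_STANDARD = unambiguous_dna_by_id[1]

#: codon -> amino acid, stops mapped to '*'
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"

#: the 20 canonical residues, alphabetical
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: the 32 NNK codons (N = A/C/G/T, K = G/T)
NNK_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "GT"
)

#: amino acid -> NNK codons encoding it ('*' maps to the amber codon TAG)
NNK_BY_AA: dict[str, tuple[str, ...]] = {}
for _codon in NNK_CODONS:
    _aa = CODON_TO_AA[_codon]
    NNK_BY_AA[_aa] = NNK_BY_AA.get(_aa, ()) + (_codon,)

AMBER_CODON = "TAG"

# deterministic codon choice for constant (non-randomized) positions;
# restricted to NNK members so every emitted insert codon is NNK
_CONSTANT_CODON = {aa: codons[0] for aa, codons in NNK_BY_AA.items()}

LINKER = "GGGS"
LINKER_NT = "".join(_CONSTANT_CODON[aa] for aa in LINKER)  # GGT GGT GGT TCT
LEADING_RESIDUE = "A"
LEADING_NT = _CONSTANT_CODON["A"]
CYS_NT = _CONSTANT_CODON["C"]

#: N-terminus of mature pIII; reads from insertless WT clones start here
WT_SIGNATURE = "AETVESCLAKSH"

# --- synthetic read layout --------------------------------------------------
# The classifier's contract is only "a unique anchor motif immediately 5' of
# the displayed-window codons"; the concrete flanks below are synthetic
# stand-ins for the vector context around the insert.

#: default anchor: the 3' end of the pIII signal-peptide coding region
ANCHOR_DEFAULT = "TTTCTATTCTCACTCT"

FLANK5_DEFAULT = "CCTTTAGTGGTACC" + ANCHOR_DEFAULT

#: mature pIII N-terminal residues encoded by the synthetic 3' flank;
#: >= 17 residues so that even an insertless read yields a full window
PIII_DOWNSTREAM_AA = "AETVESCLAKSHTENSFTNVWK"


def _fixed_codons(aa_seq: str) -> str:
    table = {}
    for codon in sorted(CODON_TO_AA):
        table.setdefault(CODON_TO_AA[codon], codon)
    return "".join(table[aa] for aa in aa_seq)


FLANK3_DEFAULT = _fixed_codons(PIII_DOWNSTREAM_AA)


# --- library specs ----------------------------------------------------------

@dataclass(frozen=True)
class LibrarySpec:
    """Format of one displayed-peptide library.

    ``peptide_length`` counts only the randomized (X) residues; ``cyclic``
    libraries add a fixed cysteine on each side of the randomized stretch.
    """

    name: str
    peptide_length: int
    cyclic: bool
    linker: str = LINKER
    leading_residue: str = LEADING_RESIDUE

    def displayed_window(self, peptide: str) -> str:
        """Amino-acid string of the full insert (leading residue included)."""
        if len(peptide) != self.peptide_length:
            raise ConfigurationError(
                f"{self.name}: peptide {peptide!r} has length {len(peptide)}, "
                f"expected {self.peptide_length}"
            )
        if self.cyclic:
            return f"{self.leading_residue}C{peptide}C{self.linker}"
        return f"{self.leading_residue}{peptide}{self.linker}"

    @property
    def window_length(self) -> int:
        """Number of residues in the displayed window, leading residue included."""
        extra = 2 if self.cyclic else 0
        return 1 + extra + self.peptide_length + len(self.linker)


LIBRARIES: dict[str, LibrarySpec] = {
    "PhD7": LibrarySpec("PhD7", peptide_length=7, cyclic=False),
    "PhD12": LibrarySpec("PhD12", peptide_length=12, cyclic=False),
    "PhDC7C": LibrarySpec("PhDC7C", peptide_length=7, cyclic=True),
}

LIBRARY_ORDER: tuple[str, ...] = ("PhD7", "PhD12", "PhDC7C")


def get_library(name: str) -> LibrarySpec:
    try:
        return LIBRARIES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown library {name!r}; expected one of {', '.join(LIBRARY_ORDER)}"
        ) from None
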