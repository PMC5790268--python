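"""Core sequence containers and nucleotide alphabet utilities.

Sequences are stored DNA-style (U is normalized to T on ingest) over the
IUPAC nucleotide alphabet.  Internal coordinates are 0-based half-open
throughout the package; anything written to a report is 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

GAP = "-"

#: IUPAC nucleotide code -> set of unambiguous bases it stands for.
IUPAC = {
    "A": {"A"},
    "C": {"C"},
    "G": {"G"},
    "T": {"T"},
    "R": {"A", "G"},
    "Y": {"C", "T"},
    "S": {"C", "G"},
    "W": {"A", "T"},
    "K": {"G", "T"},
    "M": {"A", "C"},
    "B": {"C", "G", "T"},
    "D": {"A", "G", "T"},
    "H": {"A", "C", "T"},
    "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

#: Codes treated as missing data by the statistics modules.
AMBIGUOUS = frozenset(IUPAC) - {"A", "C", "G", "T"}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-"
)

#: Watson-Crick partners.
WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
#: G.U wobble partners (U stored as T).
GU_PAIRS = {("G", "T"), ("T", "G")}


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_residues(raw: str, *, context: str = "sequence") -> str:
    """Uppercase, U->T, validate against the IUPAC nucleotide alphabet."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - set(IUPAC) - {GAP}
    if bad:
        raise FormatError(
            f"{context}: non-IUPAC nucleotide character(s) {sorted(bad)!r}"
        )
    return seq


def iupac_match(code_a: str, code_b: str) -> bool:
    """True when two IUPAC codes can denote the same base."""
    return not IUPAC[code_a].isdisjoint(IUPAC[code_b])


def can_pair(a: str, b: str, *, allow_gu: bool = True) -> bool:
    """Watson-Crick (optionally + GU wobble) pairing test on concrete bases.

    Ambiguity codes never pair (conservative: a stem is only extended
    through unambiguous evidence).
    """
    if (a, b) in WC_PAIRS:
        return True
    return allow_gu and (a, b) in GU_PAIRS


@dataclass
class SeqRecord:
    """One nucleotide sequence with identity and provenance."""

    id: str
    residues: str
    taxon: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty residues")
        self.residues = normalize_residues(
            self.residues, context=f"record {self.id!r}"
        )
        if not self.taxon:
            self.taxon = self.id

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """Equal-length gapped rows; gap symbol is '-'."""

    records: list[SeqRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment needs at least one row")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise FormatError(f"rows of unequal length: {sorted(lengths)}")
        if self.column_count < 1:
            raise ValueError("alignment needs at least one column")

    @property
    def column_count(self) -> int:
        return len(self.records[0].residues)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def row(self, rec_id: str) -> SeqRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.records)

    def degap_row(self, rec_id: str) -> str:
        return self.row(rec_id).residues.replace(GAP, "")
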