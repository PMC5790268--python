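"""Readers and writers for FASTA, PHYLIP, Stockholm and GenBank input.

FASTA and GenBank parsing is delegated to Biopython; PHYLIP and Stockholm
are written/parsed here because the package needs tight control over the
dialect (relaxed PHYLIP names, per-column region annotation in Stockholm).
PHYLIP is accepted in both sequential and interleaved layout, with strict
(10-character) or relaxed whitespace-delimited names.
"""

from __future__ import annotations

import os
import string
from typing import Iterable

from Bio import SeqIO

from .records import (
    GAP,
    Alignment,
    FormatError,
    SeqRecord,
    normalize_residues,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_phylip",
    "write_phylip",
    "read_stockholm",
    "write_stockholm",
    "extract_rrna_gene",
    "parse_pairing_string",
]


# ---------------------------------------------------------------- FASTA


def read_fasta(path: str | os.PathLike) -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords (order preserved, U->T).

    Raises FormatError on an empty file, duplicate ids or non-IUPAC
    residues, naming the offending record.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            SeqRecord(
                id=rec.id,
                residues=str(rec.seq),
                taxon=rec.description or rec.id,
                source=os.fspath(path),
            )
        )
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), 70):
                fh.write(rec.residues[i : i + 70] + "\n")


# ---------------------------------------------------------------- PHYLIP


def _phylip_blocks(lines: list[str]) -> list[list[str]]:
    blocks: list[list[str]] = [[]]
    for line in lines:
        if line.strip():
            blocks[-1].append(line.rstrip("\n"))
        elif blocks[-1]:
            blocks.append([])
    if blocks and not blocks[-1]:
        blocks.pop()
    return blocks


def _split_name(line: str) -> tuple[str, str]:
    """Split a PHYLIP row into (name, residue chunk).

    Accepts relaxed (whitespace-delimited) names and strict 10-column
    names without internal spaces.
    """
    parts = line.split(None, 1)
    if len(parts) == 1:
        return parts[0], ""
    return parts[0], "".join(parts[1].split())


def read_phylip(path: str | os.PathLike) -> Alignment:
    """Read a sequential or interleaved PHYLIP alignment."""
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise FormatError(f"empty PHYLIP file {path}")
    header = lines[0].split()
    if len(header) < 2:
        raise FormatError(f"{path}: malformed PHYLIP header {lines[0]!r}")
    try:
        ntaxa, ncols = int(header[0]), int(header[1])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric PHYLIP header") from exc

    blocks = _phylip_blocks(lines[1:])
    names: list[str] = []
    seqs: list[str] = []

    if len(blocks) == 1 and len(blocks[0]) != ntaxa:
        # sequential with wrapped rows: name, then residues until ncols
        for line in blocks[0]:
            if not seqs or len(seqs[-1]) >= ncols:
                name, chunk = _split_name(line)
                names.append(name)
                seqs.append(chunk)
            else:
                seqs[-1] += "".join(line.split())
    else:
        first, *rest = blocks
        if len(first) != ntaxa:
            raise FormatError(
                f"{path}: expected {ntaxa} rows in first block, "
                f"found {len(first)}"
            )
        for line in first:
            name, chunk = _split_name(line)
            names.append(name)
            seqs.append(chunk)
        for block in rest:
            if len(block) != ntaxa:
                raise FormatError(
                    f"{path}: interleaved block of {len(block)} rows, "
                    f"expected {ntaxa}"
                )
            for i, line in enumerate(block):
                parts = line.split()
                if parts and parts[0] == names[i]:
                    parts = parts[1:]
                seqs[i] += "".join(parts)

    if len(names) != ntaxa:
        raise FormatError(
            f"{path}: header says {ntaxa} taxa, found {len(names)}"
        )
    for name, seq in zip(names, seqs):
        if len(seq) != ncols:
            raise FormatError(
                f"{path}: row {name!r} has {len(seq)} columns, "
                f"header says {ncols}"
            )
    return Alignment(
        records=[
            SeqRecord(id=n, residues=s, source=os.fspath(path))
            for n, s in zip(names, seqs)
        ]
    )


def write_phylip(aln: Alignment, path: str | os.PathLike) -> None:
    """Write relaxed sequential PHYLIP (name, two spaces, full row)."""
    with open(path, "w") as fh:
        fh.write(f"{len(aln.records)} {aln.column_count}\n")
        for rec in aln.records:
            fh.write(f"{rec.id}  {rec.residues}\n")


# ------------------------------------------------------------- Stockholm

_OPEN = "<("
_CLOSE = ">)"
_UNPAIRED = ".,_-:~"

#: characters usable for the per-column region line (gap excluded).
_RGN_CHARS = (
    string.ascii_uppercase + string.ascii_lowercase + string.digits
    + "!\"#$%&'*+/;=?@^`|~"
)


def parse_pairing_string(ss: str) -> list[tuple[int, int]]:
    """Parse a dot-bracket / WUSS-style consensus line into (i, j) pairs.

    Raises FormatError at the first unmatched bracket.
    """
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, ch in enumerate(ss):
        if ch in _OPEN:
            stack.append(idx)
        elif ch in _CLOSE:
            if not stack:
                raise FormatError(
                    f"unmatched closing bracket at position {idx + 1}"
                )
            pairs.append((stack.pop(), idx))
        elif ch not in _UNPAIRED:
            raise FormatError(f"bad pairing character {ch!r} at {idx + 1}")
    if stack:
        raise FormatError(
            f"unmatched opening bracket at position {stack[0] + 1}"
        )
    return sorted(pairs)


def write_stockholm(
    aln: Alignment,
    path: str | os.PathLike,
    ss_cons: str | None = None,
    per_column_labels: list[str] | None = None,
) -> None:
    """Write Stockholm 1.0 with optional SS_cons and region lines.

    Region labels (one per column, e.g. helix ids) are encoded as a
    one-character-per-column ``#=GC RGN`` line plus ``#=GF RGNMAP``
    legend lines, so that arbitrary label strings round-trip.
    """
    if ss_cons is not None:
        if len(ss_cons) != aln.column_count:
            raise FormatError(
                f"SS_cons length {len(ss_cons)} != "
                f"column count {aln.column_count}"
            )
        parse_pairing_string(ss_cons)  # validates balance
    if per_column_labels is not None and len(per_column_labels) != aln.column_count:
        raise FormatError("per-column label list length != column count")

    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        label_map: dict[str, str] = {}
        if per_column_labels is not None:
            for lab in per_column_labels:
                if lab not in label_map:
                    if len(label_map) >= len(_RGN_CHARS):
                        raise FormatError("too many distinct region labels")
                    label_map[lab] = _RGN_CHARS[len(label_map)]
            for lab, ch in label_map.items():
                fh.write(f"#=GF RGNMAP {ch} {lab}\n")
        width = max(len(r.id) for r in aln.records) + 2
        width = max(width, len("#=GC SS_cons") + 2)
        for rec in aln.records:
            fh.write(f"{rec.id:<{width}}{rec.residues}\n")
        if ss_cons is not None:
            fh.write(f"{'#=GC SS_cons':<{width}}{ss_cons}\n")
        if per_column_labels is not None:
            rgn = "".join(label_map[lab] for lab in per_column_labels)
            fh.write(f"{'#=GC RGN':<{width}}{rgn}\n")
        fh.write("//\n")


def read_stockholm(
    path: str | os.PathLike,
) -> tuple[Alignment, str | None, list[str] | None]:
    """Read Stockholm 1.0; returns (alignment, ss_cons, region labels)."""
    seqs: dict[str, str] = {}
    order: list[str] = []
    ss_cons: str | None = None
    rgn: str | None = None
    label_map: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# STOCKHOLM"):
            raise FormatError(f"{path}: missing Stockholm header")
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("//"):
                continue
            if line.startswith("#=GF RGNMAP"):
                _, _, ch, lab = line.split(None, 3)
                label_map[ch] = lab
            elif line.startswith("#=GC SS_cons"):
                ss_cons = (ss_cons or "") + line.split(None, 2)[2]
            elif line.startswith("#=GC RGN"):
                rgn = (rgn or "") + line.split(None, 2)[2]
            elif line.startswith("#"):
                continue
            else:
                name, chunk = _split_name(line)
                if name not in seqs:
                    seqs[name] = ""
                    order.append(name)
                seqs[name] += chunk
    if not order:
        raise FormatError(f"{path}: no sequences")
    aln = Alignment(
        records=[
            SeqRecord(id=n, residues=seqs[n], source=os.fspath(path))
            for n in order
        ]
    )
    labels = None
    if rgn is not None:
        try:
            labels = [label_map[ch] for ch in rgn]
        except KeyError as exc:
            raise FormatError(f"{path}: RGN char {exc} missing from RGNMAP")
    return aln, ss_cons, labels


# -------------------------------------------------------------- GenBank


class ExtractionError(ValueError):
    """An rRNA gene could not be located in a GenBank record."""


_GENE_TAGS = {
    "rrnS": ("rrns", "12s", "s-rrna", "small subunit ribosomal"),
    "rrnL": ("rrnl", "16s", "l-rrna", "large subunit ribosomal"),
}


def _feature_text(feat) -> str:
    vals = []
    for key in ("gene", "product", "note", "standard_name"):
        vals.extend(feat.qualifiers.get(key, []))
    return " ".join(vals).lower()


def _find_trna(record, amino: str, anticodon: str | None = None):
    """Locate a tRNA feature by amino acid and optional anticodon tag."""
    hits = []
    for feat in record.features:
        if feat.type != "tRNA":
            continue
        text = _feature_text(feat)
        if f"trna-{amino.lower()}" in text or f"trn{amino[0].lower()}" in text:
            if anticodon is None or anticodon.lower() in text:
                hits.append(feat)
    return hits[0] if hits else None


def extract_rrna_gene(record, gene: str) -> SeqRecord:
    """Extract an rRNA gene from an annotated mitogenome record.

    ``record`` is a path to a GenBank flat file or a Biopython SeqRecord.
    Preferred source is the annotated rRNA feature (returned in coding
    orientation, i.e. reverse-complemented for minus-strand features).
    When no rRNA feature is present the inter-feature span is used:
    trnL1(tag)->trnV(tac) for rrnL, trnV(tac)->control region for rrnS,
    oriented by the strand of the flanking trnV.
    """
    if gene not in _GENE_TAGS:
        raise ValueError(f"gene must be rrnS or rrnL, got {gene!r}")
    if isinstance(record, (str, os.PathLike)):
        record = next(SeqIO.parse(os.fspath(record), "genbank"))

    tags = _GENE_TAGS[gene]
    for feat in record.features:
        if feat.type != "rRNA":
            continue
        if any(tag in _feature_text(feat) for tag in tags):
            seq = str(feat.extract(record.seq))
            return SeqRecord(
                id=f"{record.id}|{gene}",
                residues=seq,
                taxon=record.annotations.get("organism", record.id),
                source=f"{record.id}:{feat.location}",
            )

    # fall back to the span between flanking features
    trnv = _find_trna(record, "Val", "tac") or _find_trna(record, "Val")
    if trnv is None:
        raise ExtractionError(
            f"{record.id}: no {gene} rRNA feature and no trnV(tac) "
            "flanking feature"
        )
    strand = trnv.location.strand or 1
    if gene == "rrnL":
        trnl1 = _find_trna(record, "Leu", "tag")
        if trnl1 is None:
            raise ExtractionError(
                f"{record.id}: no rrnL feature and no trnL1(tag) feature"
            )
        # on the minus strand rrnL lies between trnL1 and trnV
        lo = min(int(trnv.location.end), int(trnl1.location.end))
        hi = max(int(trnv.location.start), int(trnl1.location.start))
    else:
        ctrl = None
        for feat in record.features:
            if feat.type in ("D-loop", "misc_feature") and (
                "control region" in _feature_text(feat)
                or feat.type == "D-loop"
            ):
                ctrl = feat
                break
        if ctrl is None:
            raise ExtractionError(
                f"{record.id}: no rrnS feature and no control region feature"
            )
        lo = min(int(trnv.location.end), int(ctrl.location.end))
        hi = max(int(trnv.location.start), int(ctrl.location.start))
    if hi <= lo:
        raise ExtractionError(
            f"{record.id}: flanking features of {gene} overlap or abut"
        )
    seq = str(record.seq[lo:hi])
    if strand == -1:
        from .records import reverse_complement

        seq = reverse_complement(seq)
    return SeqRecord(
        id=f"{record.id}|{gene}",
        residues=seq,
        taxon=record.annotations.get("organism", record.id),
        source=f"{record.id}:{lo + 1}..{hi} (inter-feature)",
    )
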