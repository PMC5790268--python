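"""Structure-partitioned multiple alignment.

Annotated sequences are cut into blocks of homologous subsequences (one
block per shared helix, interleaved with linker / hypervariable blocks),
each block is aligned on its own, and the aligned blocks are concatenated
into a structure-annotated alignment with a consensus pairing line.

The block aligner is a deterministic progressive (star) aligner over an
affine-gap Gotoh core (match +2, mismatch -1, gap open -4, gap extend -1).
For helix blocks the anchor columns are forced into register and only the
enclosed part is aligned freely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import GAP, Alignment, SeqRecord
from .annotate import SecondaryStructure
from .template import StructureTemplate

MATCH = 2
MISMATCH = -1
GAP_OPEN = -4
GAP_EXTEND = -1

NEG = float("-inf")


# ------------------------------------------------------------ alignment core


def _col_score(col: str, c: str) -> float:
    s = 0
    for ch in col:
        if ch != GAP:
            s += MATCH if ch == c else MISMATCH
    return s


def align_to_profile(
    profile: list[str], seq: str
) -> tuple[list[str], str, float]:
    """Global affine-gap alignment of a sequence against a profile.

    ``profile`` is a list of equal-length column strings.  Returns the
    new column list, the gapped sequence, and the alignment score.
    Deterministic: ties resolve match > gap-in-seq > gap-in-profile.
    """
    n, m = len(profile), len(seq)
    nrows = len(profile[0]) if profile else 1
    # three-state Gotoh; X = gap in seq (profile column consumed),
    # Y = gap in profile (seq char consumed)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = GAP_OPEN + GAP_EXTEND * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = GAP_OPEN + GAP_EXTEND * (j - 1)
    for i in range(1, n + 1):
        col = profile[i - 1]
        for j in range(1, m + 1):
            s = _col_score(col, seq[j - 1])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] + GAP_OPEN,
                X[i - 1][j] + GAP_EXTEND,
                Y[i - 1][j] + GAP_OPEN,
            )
            Y[i][j] = max(
                M[i][j - 1] + GAP_OPEN,
                Y[i][j - 1] + GAP_EXTEND,
                X[i][j - 1] + GAP_OPEN,
            )
    i, j = n, m
    finals = (M[n][m], X[n][m], Y[n][m])
    score = max(finals)
    state = "MXY"[finals.index(score)]
    out_cols: list[str] = []
    out_seq: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            out_cols.append(profile[i - 1])
            out_seq.append(seq[j - 1])
            prev = (M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            s = _col_score(profile[i - 1], seq[j - 1])
            state = "MXY"[prev.index(M[i][j] - s)]
            i, j = i - 1, j - 1
        elif state == "X":
            out_cols.append(profile[i - 1])
            out_seq.append(GAP)
            if i == 1 and j == 0:
                state = "M"
            elif X[i][j] == X[i - 1][j] + GAP_EXTEND:
                state = "X"
            elif X[i][j] == M[i - 1][j] + GAP_OPEN:
                state = "M"
            else:
                state = "Y"
            i -= 1
        else:
            out_cols.append(GAP * (len(profile[0]) if profile else 1))
            out_seq.append(seq[j - 1])
            if j == 1 and i == 0:
                state = "M"
            elif Y[i][j] == Y[i][j - 1] + GAP_EXTEND:
                state = "Y"
            elif Y[i][j] == M[i][j - 1] + GAP_OPEN:
                state = "M"
            else:
                state = "X"
            j -= 1
    out_cols.reverse()
    out_seq.reverse()
    # re-pad gap columns inserted into the profile to the right row count
    out_cols = [c if len(c) == nrows else GAP * nrows for c in out_cols]
    return out_cols, "".join(out_seq), score


def pairwise_align(a: str, b: str) -> tuple[str, str, float]:
    """Optimal global alignment of two sequences under the block scoring."""
    cols, gapped_b, score = align_to_profile(list(a), b)
    return "".join(c[0] for c in cols), gapped_b, score


def _identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    k = min(len(a), len(b))
    return sum(a[i] == b[i] for i in range(k)) / max(len(a), len(b))


def progressive_align(rows: list[str]) -> list[str]:
    """Deterministic star alignment: most-central row first, the rest by
    descending identity to it (ties keep input order)."""
    nonempty = [(idx, r) for idx, r in enumerate(rows) if r]
    if not nonempty:
        return list(rows)
    if len(nonempty) == 1:
        idx, r = nonempty[0]
        out = [GAP * len(r)] * len(rows)
        out[idx] = r
        return out
    totals = [
        sum(_identity(r, q) for _, q in nonempty) for _, r in nonempty
    ]
    center = max(range(len(nonempty)), key=lambda k: (totals[k], -k))
    order = [center] + sorted(
        (k for k in range(len(nonempty)) if k != center),
        key=lambda k: (-_identity(nonempty[center][1], nonempty[k][1]), k),
    )
    profile = list(nonempty[order[0]][1])  # one-char columns
    placed = [order[0]]
    for k in order[1:]:
        profile, gapped, _ = align_to_profile(profile, nonempty[k][1])
        profile = [
            col + ch for col, ch in zip(profile, gapped)
        ]
        placed.append(k)
    width = len(profile)
    out = [GAP * width] * len(rows)
    for rank, k in enumerate(placed):
        idx = nonempty[k][0]
        out[idx] = "".join(col[rank] for col in profile)
    return out


# ------------------------------------------------------------------ blocks


@dataclass
class Block:
    """Homologous subsequences of one region across taxa (unaligned)."""

    label: str
    kind: str  # helix | linker | hypervariable
    taxa: list[str]
    rows: dict[str, str]
    pairs: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    anchor5_len: int = 0
    anchor3_len: int = 0


@dataclass
class AlignedBlock:
    label: str
    kind: str
    taxa: list[str]
    rows: dict[str, str]  # gapped, equal width

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())))


@dataclass
class StructAlignment:
    """Alignment plus per-column region labels and consensus pairing."""

    base: Alignment
    column_region: list[str]
    ss_cons: str
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.base.column_count
        if len(self.column_region) != n or len(self.ss_cons) != n:
            raise ValueError("annotation lines must match column count")

    def helix_columns(self, crw_id: str) -> list[int]:
        cols = [j for j, lab in enumerate(self.column_region) if lab == crw_id]
        if not cols:
            raise KeyError(f"no columns labeled {crw_id!r}")
        return cols


def _helix_order(structures: list[SecondaryStructure]) -> list[str]:
    """Shared helix order: by mean footprint midpoint across taxa."""
    mids: dict[str, list[float]] = {}
    for s in structures:
        for h in s.helices:
            mids.setdefault(h.crw_id, []).append(
                (h.footprint[0] + h.footprint[1]) / 2.0
            )
        for crw_id in s.missing_helices:
            mids.setdefault(crw_id, [])
    return sorted(
        mids,
        key=lambda cid: (
            sum(mids[cid]) / len(mids[cid]) if mids[cid] else float("inf"),
            cid,
        ),
    )


def segment_by_structure(
    records: list[SeqRecord],
    structures: list[SecondaryStructure],
    template: StructureTemplate | None = None,
    hv_threshold: int = 15,
) -> list[Block]:
    """Cut each sequence into helix and linker blocks.

    Block order follows the shared helix order; concatenating one row's
    blocks reconstructs its input sequence exactly.  A taxon missing a
    helix contributes an empty row to that helix block (its residues fall
    into the neighboring linker).
    """
    if len(records) != len(structures):
        raise ValueError("one structure per record required")
    by_id = {s.seq_id: s for s in structures}
    if set(by_id) != {r.id for r in records}:
        raise ValueError(
            "structure/record id mismatch: "
            f"{sorted(set(by_id) ^ {r.id for r in records})}"
        )
    taxa = [r.id for r in records]
    order = _helix_order(structures)
    spec_by_id = (
        {h.crw_id: h for h in template.helices} if template is not None else {}
    )

    blocks: list[Block] = []
    for k, crw_id in enumerate(order):
        spec = spec_by_id.get(crw_id)
        blocks.append(
            Block(
                label=f"L{k}", kind="linker", taxa=taxa,
                rows={t: "" for t in taxa},
            )
        )
        blocks.append(
            Block(
                label=crw_id, kind="helix", taxa=taxa,
                rows={t: "" for t in taxa},
                anchor5_len=len(spec.anchor5) if spec else 0,
                anchor3_len=len(spec.anchor3) if spec else 0,
            )
        )
    blocks.append(
        Block(
            label=f"L{len(order)}", kind="linker", taxa=taxa,
            rows={t: "" for t in taxa},
        )
    )

    for rec in records:
        s = by_id[rec.id]
        cursor = 0
        for k, crw_id in enumerate(order):
            linker, helixblk = blocks[2 * k], blocks[2 * k + 1]
            h = s.helix(crw_id)
            if h is None:
                linker.rows[rec.id] = ""
                helixblk.rows[rec.id] = ""
                continue
            b, e = h.footprint
            if b < cursor:
                raise ValueError(
                    f"{rec.id}: helix {crw_id} footprint out of order"
                )
            linker.rows[rec.id] = rec.residues[cursor:b]
            helixblk.rows[rec.id] = rec.residues[b:e]
            helixblk.pairs[rec.id] = [
                (p.i - b, p.j - b) for p in h.pairs
            ]
            cursor = e
        blocks[-1].rows[rec.id] = rec.residues[cursor:]

    # drop linker blocks that are empty in every row; classify the rest
    kept: list[Block] = []
    for blk in blocks:
        if blk.kind == "linker":
            lens = sorted(len(r) for r in blk.rows.values())
            if lens[-1] == 0:
                continue
            median = lens[len(lens) // 2]
            if median > hv_threshold:
                blk.kind = "hypervariable"
                blk.label = "HV" + blk.label[1:]
        kept.append(blk)
    return kept


def align_block(block: Block) -> AlignedBlock:
    """Align one block; helix anchors are forced into register."""
    taxa = block.taxa
    rows = [block.rows[t] for t in taxa]
    a5, a3 = block.anchor5_len, block.anchor3_len
    nonempty = [r for r in rows if r]
    if not nonempty:
        raise ValueError(f"block {block.label}: no nonempty rows")
    if (
        block.kind == "helix"
        and a5 + a3 > 0
        and all(len(r) >= a5 + a3 for r in nonempty)
    ):
        middles = [r[a5 : len(r) - a3] if r else "" for r in rows]
        mid_aln = progressive_align(middles)
        width_mid = len(mid_aln[0]) if any(middles) else 0
        out = {}
        for t, r, mid in zip(taxa, rows, mid_aln):
            if r:
                out[t] = r[:a5] + (mid if width_mid else "") + r[len(r) - a3 :]
            else:
                out[t] = GAP * (a5 + width_mid + a3)
        return AlignedBlock(block.label, block.kind, taxa, out)
    aligned = progressive_align(rows)
    width = max((len(r) for r in aligned), default=0)
    out = {
        t: (r if r else GAP * width) for t, r in zip(taxa, aligned)
    }
    return AlignedBlock(block.label, block.kind, taxa, out)


def _colmap(gapped: str) -> list[int]:
    """Map ungapped residue index -> column index."""
    return [j for j, ch in enumerate(gapped) if ch != GAP]


def _consensus_pairs(
    block: Block, aligned: AlignedBlock, offset: int
) -> list[tuple[int, int]]:
    """Majority-rule consensus pairs of a helix block (global columns)."""
    votes: dict[tuple[int, int], int] = {}
    n_present = 0
    for t in block.taxa:
        if not block.rows[t]:
            continue
        n_present += 1
        cmap = _colmap(aligned.rows[t])
        for li, lj in block.pairs.get(t, []):
            key = (cmap[li] + offset, cmap[lj] + offset)
            votes[key] = votes.get(key, 0) + 1
    need = 0.5 * n_present
    cands = sorted(
        (p for p, v in votes.items() if v >= need),
        key=lambda p: (-votes[p], p),
    )
    chosen: list[tuple[int, int]] = []
    used: set[int] = set()
    for i, j in cands:
        if i in used or j in used:
            continue
        if any(a < i < b < j or i < a < j < b for a, b in chosen):
            continue
        chosen.append((i, j))
        used.update((i, j))
    return sorted(chosen)


def assemble_alignment(
    blocks: list[Block], aligned: list[AlignedBlock]
) -> StructAlignment:
    """Concatenate aligned blocks into a structure-annotated alignment."""
    taxa_sets = {tuple(b.taxa) for b in aligned}
    if len(taxa_sets) != 1:
        raise ValueError("blocks carry inconsistent taxa sets")
    taxa = aligned[0].taxa
    rows = {t: [] for t in taxa}
    labels: list[str] = []
    pairs: list[tuple[int, int]] = []
    offset = 0
    for blk, ab in zip(blocks, aligned):
        for t in taxa:
            rows[t].append(ab.rows[t])
        labels.extend([ab.label] * ab.width)
        if blk.kind == "helix":
            pairs.extend(_consensus_pairs(blk, ab, offset))
        offset += ab.width
    ss = ["."] * offset
    for i, j in pairs:
        ss[i], ss[j] = "<", ">"
    base = Alignment(
        records=[
            SeqRecord(id=t, residues="".join(rows[t]), source="assembled")
            for t in taxa
        ]
    )
    return StructAlignment(
        base=base,
        column_region=labels,
        ss_cons="".join(ss),
        provenance={t: t for t in taxa},
    )


def build_struct_alignment(
    records: list[SeqRecord],
    structures: list[SecondaryStructure],
    template: StructureTemplate | None = None,
) -> StructAlignment:
    """segment -> per-block align -> assemble, in one call."""
    blocks = segment_by_structure(records, structures, template)
    aligned = [align_block(b) for b in blocks]
    return assemble_alignment(blocks, aligned)


# ------------------------------------------------------------ gap stripping


def strip_gap_columns(
    aln: Alignment, tolerance: float
) -> tuple[Alignment, dict[int, int]]:
    """Remove columns whose gap fraction strictly exceeds ``tolerance``.

    A 40% tolerance keeps columns with at most 40% gaps.  Returns the
    stripped alignment and an old->new column map for the survivors.
    Idempotent.
    """
    if not 0.0 <= tolerance <= 1.0:
        raise ValueError("tolerance must be in [0, 1]")
    n_rows = len(aln.records)
    kept = [
        j
        for j in range(aln.column_count)
        if aln.column(j).count(GAP) / n_rows <= tolerance
    ]
    if not kept:
        raise ValueError("no columns survive gap stripping")
    colmap = {old: new for new, old in enumerate(kept)}
    recs = [
        SeqRecord(
            id=r.id,
            residues="".join(r.residues[j] for j in kept),
            taxon=r.taxon,
            source=r.source,
        )
        for r in aln.records
    ]
    return Alignment(records=recs), colmap


def strip_struct_alignment(
    saln: StructAlignment, tolerance: float
) -> tuple[StructAlignment, dict[int, int]]:
    """Gap-strip a structure alignment, keeping labels and pairing in sync.

    Consensus pairs with a removed partner become unpaired.
    """
    stripped, colmap = strip_gap_columns(saln.base, tolerance)
    labels = [saln.column_region[old] for old in sorted(colmap)]
    from .seq_io import parse_pairing_string

    old_pairs = parse_pairing_string(saln.ss_cons)
    ss = ["."] * stripped.column_count
    for i, j in old_pairs:
        if i in colmap and j in colmap:
            ss[colmap[i]], ss[colmap[j]] = "<", ">"
    return (
        StructAlignment(
            base=stripped,
            column_region=labels,
            ss_cons="".join(ss),
            provenance=dict(saln.provenance),
        ),
        colmap,
    )
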