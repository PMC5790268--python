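"""Template-guided secondary-structure annotation of rRNA sequences.

The annotation realizes a reference helix model on one sequence by a
comparative procedure: locate the conserved anchor motifs of each helix
near its expected position, then search for uninterrupted complementary
base pairing (Watson-Crick plus optional G.U wobble) between the anchored
regions.  Helices are resolved greedily in template order; a resolved
footprint is excluded from later searches, so the result is deterministic.
Spans between helices longer than a threshold are labeled hypervariable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import GAP, SeqRecord, can_pair, iupac_match
from .template import HelixSpec, StructureTemplate

Interval = tuple[int, int]  # 0-based half-open


@dataclass(frozen=True)
class BasePair:
    i: int
    j: int
    kind: str  # "WC" or "GU"

    def __post_init__(self) -> None:
        if self.i >= self.j:
            raise ValueError(f"base pair ({self.i},{self.j}) not i<j")


@dataclass(frozen=True)
class StemRun:
    """A maximal uninterrupted antiparallel run of base pairs.

    Pairs are (i_start + a, j_start - a) for a in range(length).
    """

    i_start: int
    j_start: int
    length: int

    @property
    def i_end(self) -> int:  # last paired 5' position
        return self.i_start + self.length - 1

    @property
    def j_end(self) -> int:  # last (innermost) paired 3' position
        return self.j_start - self.length + 1

    def positions(self) -> list[tuple[int, int]]:
        return [
            (self.i_start + a, self.j_start - a) for a in range(self.length)
        ]


@dataclass
class HelixAnnotation:
    crw_id: str
    strand5: Interval
    strand3: Interval
    pairs: list[BasePair]
    stems_count: int = 0
    loops_count: int = 0
    internal_unpaired_len: int = 0
    score: float = 0.0

    @property
    def footprint(self) -> Interval:
        return (self.strand5[0], self.strand3[1])


@dataclass
class SecondaryStructure:
    seq_id: str
    gene: str
    helices: list[HelixAnnotation] = field(default_factory=list)
    missing_helices: list[str] = field(default_factory=list)
    hypervariable_intervals: list[Interval] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def helix(self, crw_id: str) -> HelixAnnotation | None:
        for h in self.helices:
            if h.crw_id == crw_id:
                return h
        return None

    @property
    def all_pairs(self) -> list[BasePair]:
        return [p for h in self.helices for p in h.pairs]


# ----------------------------------------------------------- primitives


def locate_anchor(
    seq: SeqRecord | str,
    motif: str,
    window: Interval,
    max_mismatch: int,
    excluded: tuple[Interval, ...] = (),
) -> int | None:
    """Best (fewest-mismatch, leftmost) IUPAC-aware motif hit in a window.

    Returns the 0-based start position, or None when no placement has at
    most ``max_mismatch`` mismatches.  Placements overlapping any
    ``excluded`` interval are skipped.
    """
    s = seq.residues if isinstance(seq, SeqRecord) else seq
    lo = max(0, window[0])
    hi = min(len(s), window[1])
    m = len(motif)
    best_pos, best_mm = None, max_mismatch + 1
    for pos in range(lo, hi - m + 1):
        if any(pos < e and pos + m > b for b, e in excluded):
            continue
        mm = 0
        for k in range(m):
            if not iupac_match(motif[k], s[pos + k]):
                mm += 1
                if mm >= best_mm:
                    break
        if mm < best_mm:
            best_pos, best_mm = pos, mm
    return best_pos


def extend_stem(
    seq: SeqRecord | str,
    region5: Interval,
    region3: Interval,
    allow_gu: bool = True,
    min_run: int = 2,
    min_sep: int = 3,
) -> list[StemRun]:
    """All maximal uninterrupted antiparallel pairing runs between regions.

    Every diagonal (i + j constant) is scanned; maximal runs of at least
    ``min_run`` complementary pairs are returned, sorted by length
    (descending) then 5'-most start.  Pairs enclosing fewer than
    ``min_sep`` nucleotides are disallowed (minimum hairpin loop).
    """
    s = seq.residues if isinstance(seq, SeqRecord) else seq
    s5, e5 = max(0, region5[0]), min(len(s), region5[1])
    s3, e3 = max(0, region3[0]), min(len(s), region3[1])
    if e5 <= s5 or e3 <= s3:
        return []
    if not (e5 <= s3):
        raise ValueError("region5 must lie wholly 5' of region3")
    runs: list[StemRun] = []
    for c in range(s5 + s3, (e5 - 1) + (e3 - 1) + 1):
        i_lo = max(s5, c - (e3 - 1))
        i_hi = min(e5 - 1, c - s3)
        run_start = None
        for i in range(i_lo, i_hi + 2):  # +1 sentinel to flush final run
            j = c - i
            ok = (
                i <= i_hi
                and j - i - 1 >= min_sep
                and can_pair(s[i], s[j], allow_gu=allow_gu)
            )
            if ok and run_start is None:
                run_start = i
            elif not ok and run_start is not None:
                length = i - run_start
                if length >= min_run:
                    runs.append(StemRun(run_start, c - run_start, length))
                run_start = None
    runs.sort(key=lambda r: (-r.length, r.i_start, -r.j_start))
    return runs


def _pair_kind(a: str, b: str) -> str:
    return "WC" if (a, b) in {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")} else "GU"


def count_structure_elements(h: HelixAnnotation) -> tuple[int, int, int]:
    """(stems, loops, internal unpaired length) of one annotated helix.

    Stems are maximal runs of stacked pairs (i+1 paired with j-1); loops
    are maximal runs of unpaired nucleotides enclosed by the outermost
    pair, the terminal loop included; the internal unpaired length is the
    stretch enclosed by the innermost pair.
    """
    if not h.pairs:
        return 0, 0, max(0, h.strand3[0] - h.strand5[1])
    pairs = sorted(((p.i, p.j) for p in h.pairs))
    stems = 1
    for (i0, j0), (i1, j1) in zip(pairs, pairs[1:]):
        if not (i1 == i0 + 1 and j1 == j0 - 1):
            stems += 1
    paired = {i for i, _ in pairs} | {j for _, j in pairs}
    outer_i, outer_j = pairs[0]
    loops = 0
    in_run = False
    for p in range(outer_i + 1, outer_j):
        if p not in paired:
            if not in_run:
                loops += 1
                in_run = True
        else:
            in_run = False
    inner_i = max(i for i, _ in pairs)
    inner_j = min(j for _, j in pairs)
    internal = inner_j - inner_i - 1
    return stems, loops, internal


def to_dot_bracket(s: SecondaryStructure, seq_length: int) -> str:
    """Render all pairs as a dot-bracket string; pseudoknots are errors."""
    out = ["."] * seq_length
    pairs = sorted(((p.i, p.j) for p in s.all_pairs))
    for (i0, j0), (i1, j1) in zip(pairs, pairs[1:]):
        if i0 < i1 < j0 < j1:
            raise ValueError(
                f"crossing pairs ({i0},{j0}) and ({i1},{j1}): "
                "pseudoknots unsupported"
            )
    for i, j in pairs:
        if j >= seq_length:
            raise ValueError(f"pair ({i},{j}) outside sequence")
        if out[i] != "." or out[j] != ".":
            raise ValueError(f"position {i} or {j} paired twice")
        out[i], out[j] = "(", ")"
    return "".join(out)


# ------------------------------------------------------- helix assembly


def _assemble_runs(
    runs: list[StemRun],
    expected_center: float,
    max_internal_break: int,
) -> list[StemRun]:
    """Greedy choice of compatible (nested, non-crossing) stem runs.

    Tie-break order: more base pairs, then center closest to the
    template expectation, then 5'-most.  Each accepted extra run uses one
    internal break.
    """
    if not runs:
        return []
    ordered = sorted(
        runs,
        key=lambda r: (
            -r.length,
            abs((r.i_start + r.j_start) / 2.0 - expected_center),
            r.i_start,
        ),
    )
    chosen = [ordered[0]]
    breaks = 0
    for cand in ordered[1:]:
        if breaks >= max_internal_break:
            break
        compatible = True
        for c in chosen:
            inside = cand.i_start > c.i_end and cand.j_start < c.j_end
            outside = cand.i_end < c.i_start and cand.j_end > c.j_start
            if not (inside or outside):
                compatible = False
                break
        if compatible:
            chosen.append(cand)
            breaks += 1
    chosen.sort(key=lambda r: r.i_start)
    return chosen


def _free_span(pos: int, occupied: list[Interval], length: int) -> Interval:
    """The maximal unoccupied interval containing ``pos``."""
    lo, hi = 0, length
    for b, e in occupied:
        if e <= pos:
            lo = max(lo, e)
        elif b > pos:
            hi = min(hi, b)
    return lo, hi


def annotate_sequence(
    seq: SeqRecord,
    template: StructureTemplate,
    allow_gu: bool = True,
    max_internal_break: int = 1,
    hv_threshold: int = 15,
    window_min: int = 20,
    window_frac: float = 0.05,
    min_pairs: int = 3,
) -> SecondaryStructure:
    """Realize a structure template on one sequence.

    Each helix is resolved to at most one annotation; helices whose
    anchors cannot be placed, or whose anchored regions support fewer
    than ``min_pairs`` base pairs, are reported in ``missing_helices``.
    Inter-helix spans longer than ``hv_threshold`` become hypervariable
    intervals.  The procedure is deterministic.
    """
    L = len(seq)
    if L == 0:
        raise ValueError("empty sequence")
    if template.nominal_length is not None:
        if not 0.5 * template.nominal_length <= L <= 2.0 * template.nominal_length:
            raise ValueError(
                f"sequence length {L} outside 0.5-2x of template "
                f"nominal length {template.nominal_length}"
            )

    result = SecondaryStructure(seq_id=seq.id, gene=template.gene)
    occupied: list[Interval] = []
    w = max(window_min, int(window_frac * L))

    for spec in template.helices:
        center = spec.expected_center * L
        win5 = (
            int(center - spec.max_footprint / 2 - w),
            int(center + w),
        )
        a5 = locate_anchor(
            seq, spec.anchor5, win5, spec.max_anchor_mismatch,
            excluded=tuple(occupied),
        )
        if a5 is None:
            result.missing_helices.append(spec.crw_id)
            continue
        # everything for this helix must stay inside the free span
        span_lo, span_hi = _free_span(a5, occupied, L)
        win3 = (
            a5 + len(spec.anchor5),
            min(span_hi, a5 + spec.max_footprint + w),
        )
        a3 = locate_anchor(
            seq, spec.anchor3, win3, spec.max_anchor_mismatch,
        )
        if a3 is None:
            result.missing_helices.append(spec.crw_id)
            continue
        a3_end = a3 + len(spec.anchor3)
        slack = 2
        region5 = (a5, min(a5 + spec.stem_len[1] + slack, a3))
        region3 = (max(a3_end - spec.stem_len[1] - slack, region5[1]), a3_end)
        runs = extend_stem(seq, region5, region3, allow_gu=allow_gu)
        chosen = _assemble_runs(runs, center, max_internal_break)
        n_pairs = sum(r.length for r in chosen)
        if n_pairs < min_pairs:
            result.missing_helices.append(spec.crw_id)
            continue
        pairs = [
            BasePair(i, j, _pair_kind(seq.residues[i], seq.residues[j]))
            for run in chosen
            for i, j in run.positions()
        ]
        i_min = min(p.i for p in pairs)
        i_max = max(p.i for p in pairs)
        j_min = min(p.j for p in pairs)
        j_max = max(p.j for p in pairs)
        strand5 = (min(a5, i_min), i_max + 1)
        strand3 = (j_min, max(a3_end, j_max + 1))
        ann = HelixAnnotation(
            crw_id=spec.crw_id,
            strand5=strand5,
            strand3=strand3,
            pairs=pairs,
            score=float(n_pairs),
        )
        ann.stems_count, ann.loops_count, ann.internal_unpaired_len = (
            count_structure_elements(ann)
        )
        result.helices.append(ann)
        occupied.append(ann.footprint)
        occupied.sort()

    # hypervariable spans between annotated footprints
    cursor = 0
    for b, e in occupied:
        if b - cursor > hv_threshold:
            result.hypervariable_intervals.append((cursor, b))
        cursor = e
    if L - cursor > hv_threshold:
        result.hypervariable_intervals.append((cursor, L))

    n_total = len(template.helices)
    if n_total and len(result.missing_helices) > 0.5 * n_total:
        result.warnings.append(
            f"degraded annotation: {len(result.missing_helices)} of "
            f"{n_total} template helices not located"
        )
    return result


def annotation_report(s: SecondaryStructure) -> str:
    """Per-sequence annotation TSV (1-based inclusive intervals)."""
    lines = [
        "crw_id\tstrand5_start\tstrand5_end\tstrand3_start\tstrand3_end"
        "\tpairs\tstems\tloops\tinternal_unpaired\tscore"
    ]
    for h in s.helices:
        lines.append(
            "\t".join(
                str(v)
                for v in (
                    h.crw_id,
                    h.strand5[0] + 1,
                    h.strand5[1],
                    h.strand3[0] + 1,
                    h.strand3[1],
                    len(h.pairs),
                    h.stems_count,
                    h.loops_count,
                    h.internal_unpaired_len,
                    f"{h.score:g}",
                )
            )
        )
    for crw_id in s.missing_helices:
        lines.append(f"{crw_id}\t.\t.\t.\t.\t0\t0\t0\t0\t0")
    return "\n".join(lines) + "\n"
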