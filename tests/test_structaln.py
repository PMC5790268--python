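"""Block alignment, assembly, and gap-column stripping."""

import re

import numpy as np
import pytest

from mitorrna.records import GAP, Alignment, SeqRecord
from mitorrna.structaln import (
    AlignedBlock,
    Block,
    align_block,
    assemble_alignment,
    build_struct_alignment,
    pairwise_align,
    progressive_align,
    segment_by_structure,
    strip_gap_columns,
)


# --------------------------------------------------------- aligner core


def _oracle_best_score(a: str, b: str) -> float:
    """Exhaustive enumeration of all global alignments (tiny inputs)."""

    def score(x: str, y: str) -> int:
        s = 0
        for cx, cy in zip(x, y):
            if cx != GAP and cy != GAP:
                s += 2 if cx == cy else -1
        for row in (x, y):
            for m in re.finditer(r"-+", row):
                s += -4 - (len(m.group()) - 1)
        return s

    best = [float("-inf")]

    def rec(i, j, xa, xb):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score(xa, xb))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, xa + a[i], xb + b[j])
        if i < len(a):
            rec(i + 1, j, xa + a[i], xb + GAP)
        if j < len(b):
            rec(i, j + 1, xa + GAP, xb + b[j])

    rec(0, 0, "", "")
    return best[0]


def test_pairwise_single_gap_example():
    ga, gb, score = pairwise_align("ACGT", "ACT")
    assert len(ga) == len(gb) == 4
    assert gb.count(GAP) == 1
    assert score == _oracle_best_score("ACGT", "ACT") == 2


def test_pairwise_matches_exhaustive_oracle_on_short_strings():
    rng = np.random.default_rng(31)
    for _ in range(60):
        a = "".join("ACGT"[k] for k in rng.integers(0, 4, rng.integers(1, 7)))
        b = "".join("ACGT"[k] for k in rng.integers(0, 4, rng.integers(1, 7)))
        _, _, score = pairwise_align(a, b)
        assert score == _oracle_best_score(a, b), (a, b)


def test_identical_rows_align_without_gaps():
    rows = ["ACGTACGT"] * 4
    out = progressive_align(rows)
    assert out == rows


def test_progressive_alignment_preserves_residues():
    rng = np.random.default_rng(41)
    rows = [
        "".join("ACGT"[k] for k in rng.integers(0, 4, rng.integers(8, 20)))
        for _ in range(5)
    ]
    out = progressive_align(rows)
    assert len({len(r) for r in out}) == 1
    for raw, gapped in zip(rows, out):
        assert gapped.replace(GAP, "") == raw


# ---------------------------------------------------------- segmentation


def test_segmentation_reconstruction_identity(sim, sim_structures, rrns_template):
    blocks = segment_by_structure(
        sim.leaf_records, list(sim_structures.values()), rrns_template
    )
    for rec in sim.leaf_records:
        joined = "".join(b.rows[rec.id] for b in blocks)
        assert joined == rec.residues


def test_segmentation_missing_helix_gives_empty_row(sim, sim_structures, rrns_template):
    blocks = segment_by_structure(
        sim.leaf_records, list(sim_structures.values()), rrns_template
    )
    divergent = sim_structures["T01"]
    assert "H47" in divergent.missing_helices
    h47 = next(b for b in blocks if b.label == "H47")
    assert h47.rows["T01"] == ""
    assert sum(1 for t, r in h47.rows.items() if r) == 10


def test_segmentation_single_taxon(sim, sim_structures, rrns_template):
    rec = sim.leaf_records[1]
    blocks = segment_by_structure(
        [rec], [sim_structures[rec.id]], rrns_template
    )
    assert "".join(b.rows[rec.id] for b in blocks) == rec.residues


def test_segmentation_rejects_id_mismatch(sim, sim_structures, rrns_template):
    with pytest.raises(ValueError, match="mismatch"):
        segment_by_structure(
            sim.leaf_records[:3],
            list(sim_structures.values())[3:6],
            rrns_template,
        )


# -------------------------------------------------------------- assembly


def _stub_block(label, taxa, width):
    rows = {t: "A" * width for t in taxa}
    return (
        Block(label=label, kind="linker", taxa=taxa, rows=rows),
        AlignedBlock(label=label, kind="linker", taxa=taxa, rows=rows),
    )


def test_assembly_concatenates_block_widths():
    taxa = ["a", "b"]
    b1, a1 = _stub_block("L0", taxa, 10)
    b2, a2 = _stub_block("L1", taxa, 5)
    saln = assemble_alignment([b1, b2], [a1, a2])
    assert saln.base.column_count == 15
    assert saln.column_region == ["L0"] * 10 + ["L1"] * 5


def test_assembly_rejects_inconsistent_taxa():
    b1, a1 = _stub_block("L0", ["a", "b"], 4)
    b2, a2 = _stub_block("L1", ["a", "c"], 4)
    with pytest.raises(ValueError, match="inconsistent"):
        assemble_alignment([b1, b2], [a1, a2])


def test_assembled_alignment_degaps_to_inputs(sim, sim_structures, rrns_template):
    saln = build_struct_alignment(
        sim.leaf_records, list(sim_structures.values()), rrns_template
    )
    for rec in sim.leaf_records:
        assert saln.base.degap_row(rec.id) == rec.residues


def test_helix_block_column_accuracy_on_ground_truth(sim, sim_structures, rrns_template):
    """Sum-of-pairs column accuracy >= 0.9 inside helix blocks."""
    saln = build_struct_alignment(
        sim.leaf_records, list(sim_structures.values()), rrns_template
    )
    # residue index -> true alignment column, per taxon
    true_col = {}
    for row in sim.true_alignment.records:
        true_col[row.id] = [
            j for j, ch in enumerate(row.residues) if ch != GAP
        ]
    # assembled column -> residue index, per taxon
    res_idx = {}
    for row in saln.base.records:
        idx, out = 0, []
        for ch in row.residues:
            out.append(idx if ch != GAP else None)
            if ch != GAP:
                idx += 1
        res_idx[row.id] = out
    helix_labels = {
        h.crw_id for s in sim_structures.values() for h in s.helices
    }
    good = total = 0
    taxa = saln.base.ids
    for j, lab in enumerate(saln.column_region):
        if lab not in helix_labels:
            continue
        present = [
            t for t in taxa if res_idx[t][j] is not None
        ]
        for x in range(len(present)):
            for y in range(x + 1, len(present)):
                tx, ty = present[x], present[y]
                total += 1
                if (
                    true_col[tx][res_idx[tx][j]]
                    == true_col[ty][res_idx[ty][j]]
                ):
                    good += 1
    assert total > 1000
    assert good / total >= 0.9


# ---------------------------------------------------------- gap stripping


def _random_gapped(rng, n, m, gap_p):
    rows = []
    for i in range(n):
        row = "".join(
            GAP if rng.random() < gap_p else "ACGT"[int(rng.integers(0, 4))]
            for _ in range(m)
        )
        rows.append(row)
    # ensure no row is all gaps
    rows = [r if set(r) != {GAP} else "A" + r[1:] for r in rows]
    return Alignment(
        records=[SeqRecord(id=f"t{i}", residues=r) for i, r in enumerate(rows)]
    )


def test_strip_keeps_gap_free_alignment():
    aln = Alignment(
        records=[SeqRecord(id=f"t{i}", residues="ACGTACGT") for i in range(4)]
    )
    out, colmap = strip_gap_columns(aln, 0.4)
    assert [r.residues for r in out.records] == [r.residues for r in aln.records]
    assert colmap == {j: j for j in range(8)}


def test_strip_removes_column_above_tolerance():
    rows = ["A-CG", "A-CG", "A-CG", "AACG", "AACG"]
    aln = Alignment(
        records=[SeqRecord(id=f"t{i}", residues=r) for i, r in enumerate(rows)]
    )
    out, _ = strip_gap_columns(aln, 0.4)  # 3/5 = 0.6 > 0.4 -> removed
    assert out.column_count == 3
    assert [r.residues for r in out.records] == ["ACG"] * 3 + ["ACG"] * 2


def test_strip_tolerance_one_removes_nothing():
    rows = ["A---", "AC--", "ACG-", "ACGT"]
    aln = Alignment(
        records=[SeqRecord(id=f"t{i}", residues=r) for i, r in enumerate(rows)]
    )
    out, _ = strip_gap_columns(aln, 1.0)
    assert out.column_count == 4


def test_strip_matches_direct_count_oracle_and_is_idempotent():
    rng = np.random.default_rng(59)
    for _ in range(40):
        aln = _random_gapped(rng, 6, 40, 0.3)
        tol = float(rng.choice([0.0, 0.2, 0.4, 0.6, 0.8]))
        out, colmap = strip_gap_columns(aln, tol)
        expect = [
            j
            for j in range(aln.column_count)
            if aln.column(j).count(GAP) / 6 <= tol
        ]
        assert sorted(colmap) == expect
        again, colmap2 = strip_gap_columns(out, tol)
        assert [r.residues for r in again.records] == [
            r.residues for r in out.records
        ]
        assert colmap2 == {j: j for j in range(out.column_count)}
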