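"""Anchor search, stem extension, helix assembly, dot-bracket output."""

import numpy as np
import pytest

from mitorrna.annotate import (
    BasePair,
    HelixAnnotation,
    SecondaryStructure,
    annotate_sequence,
    count_structure_elements,
    extend_stem,
    locate_anchor,
    to_dot_bracket,
)
from mitorrna.records import IUPAC, SeqRecord, can_pair, iupac_match
from mitorrna.seq_io import parse_pairing_string
from mitorrna.simulate import build_root


# -------------------------------------------------------------- anchors


def test_locate_anchor_exact_match():
    assert locate_anchor("AAGGATTCAA", "GGATTC", (0, 10), 0) == 2


def test_locate_anchor_iupac_degeneracy_is_free():
    assert locate_anchor("AAGGATTCAA", "GGRTTC", (0, 10), 0) == 2


def test_locate_anchor_absence_returns_none():
    assert locate_anchor("AAAAAAAAAA", "GGGGG", (0, 10), 1) is None


def _oracle_locate(seq, motif, window, max_mm):
    best = None
    for pos in range(window[0], window[1] - len(motif) + 1):
        mm = sum(
            not iupac_match(motif[k], seq[pos + k]) for k in range(len(motif))
        )
        if mm <= max_mm and (best is None or mm < best[1]):
            best = (pos, mm)
    return None if best is None else best[0]


def test_locate_anchor_matches_exhaustive_scan():
    rng = np.random.default_rng(5)
    codes = list(IUPAC)
    for _ in range(200):
        seq = "".join("ACGT"[k] for k in rng.integers(0, 4, 200))
        motif = "".join(codes[k] for k in rng.integers(0, 4, 8))
        if rng.random() < 0.3:  # occasionally degenerate motif codes
            motif = motif[:4] + codes[int(rng.integers(0, len(codes)))] + motif[5:]
        got = locate_anchor(seq, motif, (0, 200), 1)
        assert got == _oracle_locate(seq, motif, (0, 200), 1)


# ---------------------------------------------------------------- stems


def test_extend_stem_perfect_complement():
    #           GGCAG....CTGCC  (revcomp pairing, 4-nt spacer)
    seq = "GGCAGTTTTCTGCC"
    runs = extend_stem(seq, (0, 5), (9, 14), allow_gu=False)
    assert len(runs) == 1
    assert runs[0].length == 5
    assert runs[0].positions() == [(0, 13), (1, 12), (2, 11), (3, 10), (4, 9)]
    assert all(can_pair(seq[i], seq[j]) for i, j in runs[0].positions())


def test_extend_stem_gu_wobble_toggle():
    seq = "GGTAGTTTTCTGCC"  # T at position 2 pairs G only via wobble
    with_gu = extend_stem(seq, (0, 5), (9, 14), allow_gu=True)
    assert with_gu[0].length == 5
    without = extend_stem(seq, (0, 5), (9, 14), allow_gu=False)
    assert all(r.length < 5 for r in without)


def _oracle_runs(seq, r5, r3, allow_gu=True, min_run=2, min_sep=3):
    pairable = {
        (i, j)
        for i in range(*r5)
        for j in range(*r3)
        if j - i - 1 >= min_sep and can_pair(seq[i], seq[j], allow_gu=allow_gu)
    }
    runs = set()
    for i, j in pairable:
        if (i - 1, j + 1) in pairable:
            continue  # not a run start
        length = 0
        while (i + length, j - length) in pairable:
            length += 1
        if length >= min_run:
            runs.add((i, j, length))
    return runs


@pytest.mark.parametrize("allow_gu", [True, False])
def test_extend_stem_equals_exhaustive_enumeration(allow_gu):
    rng = np.random.default_rng(17 if allow_gu else 18)
    for _ in range(150):
        n5 = int(rng.integers(1, 31))
        n3 = int(rng.integers(1, 31))
        gap = int(rng.integers(0, 8))
        seq = "".join("ACGT"[k] for k in rng.integers(0, 4, n5 + gap + n3))
        r5, r3 = (0, n5), (n5 + gap, n5 + gap + n3)
        got = {
            (r.i_start, r.j_start, r.length)
            for r in extend_stem(seq, r5, r3, allow_gu=allow_gu)
        }
        assert got == _oracle_runs(seq, r5, r3, allow_gu=allow_gu)


def test_extend_stem_ordering_is_deterministic():
    seq = "GGCAGAAAGGCAGTTTTCTGCCTTTCTGCC"
    runs = extend_stem(seq, (0, 13), (17, 30))
    lengths = [r.length for r in runs]
    assert lengths == sorted(lengths, reverse=True)
    again = extend_stem(seq, (0, 13), (17, 30))
    assert runs == again


# ------------------------------------------------------- element counts


def _helix(pairs, strand5, strand3):
    h = HelixAnnotation(
        crw_id="HX", strand5=strand5, strand3=strand3,
        pairs=[BasePair(i, j, "WC") for i, j in pairs],
    )
    return h


def test_count_elements_simple_hairpin():
    pairs = [(i, 15 - i) for i in range(6)]
    assert count_structure_elements(_helix(pairs, (0, 6), (10, 16))) == (1, 1, 4)


def test_count_elements_three_bulged_stems():
    pairs = (
        [(i, 40 - i) for i in range(6)]          # 6 bp
        + [(7 + a, 33 - a) for a in range(3)]    # 3 bp after a bulge
        + [(11 + a, 29 - a) for a in range(4)]   # 4 bp after a bulge
    )
    stems, _, _ = count_structure_elements(_helix(pairs, (0, 15), (26, 41)))
    assert stems == 3


def test_count_elements_h47_like_shapes():
    # two long stems + one short stem, one-sided bulges: 3 stems, 3 loops
    mega = (
        [(i, 40 - i) for i in range(8)]
        + [(9 + a, 32 - a) for a in range(6)]
        + [(16 + a, 26 - a) for a in range(3)]
    )
    stems, loops, _ = count_structure_elements(_helix(mega, (0, 19), (24, 41)))
    assert (stems, loops) == (3, 3)
    # one long stem + one short stem: 2 stems, 2 loops, wide middle
    raphi = (
        [(i, 40 - i) for i in range(10)]
        + [(11 + a, 30 - a) for a in range(4)]
    )
    stems, loops, internal = count_structure_elements(
        _helix(raphi, (0, 15), (27, 41))
    )
    assert (stems, loops) == (2, 2)
    assert internal == 12


# ------------------------------------------------------------ dot-bracket


def test_dot_bracket_empty_structure():
    s = SecondaryStructure(seq_id="x", gene="rrnS")
    assert to_dot_bracket(s, 8) == "........"


def test_dot_bracket_single_stem():
    s = SecondaryStructure(
        seq_id="x", gene="rrnS",
        helices=[_helix([(0, 9), (1, 8), (2, 7)], (0, 3), (7, 10))],
    )
    assert to_dot_bracket(s, 10) == "(((....)))"


def test_dot_bracket_rejects_crossing_pairs():
    s = SecondaryStructure(
        seq_id="x", gene="rrnS",
        helices=[_helix([(0, 5), (2, 8)], (0, 3), (5, 9))],
    )
    with pytest.raises(ValueError, match="crossing"):
        to_dot_bracket(s, 10)


def _random_nested_pairs(rng, lo, hi, depth=0):
    pairs = []
    pos = lo
    while pos < hi - 5:
        if rng.random() < 0.4 and depth < 4:
            close = int(rng.integers(pos + 5, hi))
            pairs.append((pos, close))
            pairs.extend(_random_nested_pairs(rng, pos + 1, close - 4, depth + 1))
            pos = close + 1
        else:
            pos += 1
    return pairs


def test_dot_bracket_round_trip_on_random_nested_structures():
    rng = np.random.default_rng(23)
    for _ in range(50):
        pairs = _random_nested_pairs(rng, 0, 60)
        if not pairs:
            continue
        s = SecondaryStructure(
            seq_id="x", gene="rrnS",
            helices=[_helix(sorted(pairs), (0, 1), (58, 60))],
        )
        db = to_dot_bracket(s, 60)
        assert sorted(parse_pairing_string(db.replace("(", "<").replace(")", ">"))) == sorted(pairs)


# ----------------------------------------------------- template realization


def test_annotate_recovers_constructed_root(rrns_template):
    rec, truth = build_root(rrns_template, 790, seed=4)
    ann = annotate_sequence(rec, rrns_template)
    assert ann.missing_helices == []
    for got, want in zip(ann.helices, truth.helices):
        assert got.crw_id == want.crw_id
        assert got.footprint == want.footprint


def test_annotate_reports_exactly_the_corrupted_helix(rrns_template):
    rec, truth = build_root(rrns_template, 790, seed=4)
    target = truth.helix("H921")
    b, e = target.strand3
    rng = np.random.default_rng(99)
    scrambled = "".join("ACGT"[k] for k in rng.integers(0, 4, e - b))
    corrupted = SeqRecord(
        id=rec.id, residues=rec.residues[:b] + scrambled + rec.residues[e:]
    )
    ann = annotate_sequence(corrupted, rrns_template)
    assert ann.missing_helices == ["H921"]


def test_annotate_is_deterministic(sim, rrns_template):
    rec = sim.leaf_records[3]
    a = annotate_sequence(rec, rrns_template)
    b = annotate_sequence(rec, rrns_template)
    assert [(h.crw_id, h.footprint, [(p.i, p.j) for p in h.pairs])
            for h in a.helices] == [
        (h.crw_id, h.footprint, [(p.i, p.j) for p in h.pairs])
        for h in b.helices
    ]
    assert a.missing_helices == b.missing_helices


def test_annotate_footprints_disjoint_and_pairs_nested(sim_structures):
    for s in sim_structures.values():
        fps = sorted(h.footprint for h in s.helices)
        for (b1, e1), (b2, e2) in zip(fps, fps[1:]):
            assert e1 <= b2
        pairs = sorted((p.i, p.j) for h in s.helices for p in h.pairs)
        for (i0, j0), (i1, j1) in zip(pairs, pairs[1:]):
            assert not (i0 < i1 < j0 < j1)


def test_annotate_rejects_length_far_from_template(rrns_template):
    rec = SeqRecord(id="tiny", residues="ACGT" * 20)
    with pytest.raises(ValueError, match="0.5-2x"):
        annotate_sequence(rec, rrns_template)
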