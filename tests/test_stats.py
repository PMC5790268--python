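"""Site classification, helix conservation, divergence, outlier flags."""

from collections import Counter

import numpy as np
import pytest

from mitorrna.annotate import BasePair, HelixAnnotation, SecondaryStructure
from mitorrna.records import Alignment, SeqRecord
from mitorrna.stats import (
    classify_sites,
    compare_helix_across_taxa,
    helix_conservation,
    p_distance_matrix,
)
from mitorrna.structaln import StructAlignment

MISSING = set("RYSWKMBDHVN-")


def _aln(rows):
    return Alignment(
        records=[SeqRecord(id=f"t{i}", residues=r) for i, r in enumerate(rows)]
    )


# -------------------------------------------------------- classify_sites


def _oracle_classify(rows):
    """Independent per-column state enumeration."""
    cons = var = pi = single = excl = 0
    for j in range(len(rows[0])):
        col = [r[j] for r in rows if r[j] not in MISSING]
        if len(col) < 2:
            excl += 1
            continue
        states = Counter(col)
        if len(states) == 1:
            cons += 1
        else:
            var += 1
            if sum(v >= 2 for v in states.values()) >= 2:
                pi += 1
            else:
                single += 1
    return cons, var, pi, single, excl


def test_classify_identical_rows():
    sc = classify_sites(_aln(["ACGTACGTAC"] * 4))
    assert (sc.conserved, sc.variable) == (10, 0)
    assert sc.counted_sites == 10


def test_classify_pi_and_singleton_definitions():
    sc = classify_sites(_aln(["AA", "AA", "GA", "GG"]))
    # column 0: A,A,G,G -> PI; column 1: A,A,A,G -> singleton
    assert sc.parsimony_informative == 1
    assert sc.singleton == 1
    assert sc.variable == 2


def test_classify_single_row_errors():
    with pytest.raises(ValueError, match="two rows"):
        classify_sites(_aln(["ACGT"]))


def test_classify_matches_bruteforce_oracle_on_random_alignments():
    rng = np.random.default_rng(71)
    alphabet = "ACGT-N"
    for _ in range(200):
        rows = [
            "".join(alphabet[k] for k in rng.integers(0, 6, 50))
            for _ in range(6)
        ]
        sc = classify_sites(_aln(rows))
        assert (
            sc.conserved, sc.variable, sc.parsimony_informative,
            sc.singleton, sc.excluded_sites,
        ) == _oracle_classify(rows)


def test_classify_invariant_under_row_and_column_permutation():
    rng = np.random.default_rng(73)
    rows = ["".join("ACGT-"[k] for k in rng.integers(0, 5, 60)) for _ in range(5)]
    base = classify_sites(_aln(rows)).as_row()
    perm_rows = [rows[i] for i in rng.permutation(5)]
    cols = rng.permutation(60)
    perm_cols = ["".join(r[j] for j in cols) for r in perm_rows]
    assert classify_sites(_aln(perm_cols)).as_row() == base


# --------------------------------------------------- helix conservation


def _saln(rows, label="H9"):
    base = _aln(rows)
    return StructAlignment(
        base=base,
        column_region=[label] * base.column_count,
        ss_cons="." * base.column_count,
    )


def test_helix_conservation_identical_rows_is_100():
    hc = helix_conservation(_saln(["ACGTACGTACGT"] * 4), "H9")
    assert hc.percent_conserved == 100.0


def test_helix_conservation_three_of_twelve_mutated_is_75():
    rows = ["ACGTACGTACGT"] * 3 + ["TCGTTCGTTCGT"]  # columns 0, 4, 8 differ
    hc = helix_conservation(_saln(rows), "H9")
    assert hc.percent_conserved == 75.00
    assert hc.composition.loc["t0", "A"] == 3


def test_helix_conservation_counts_gap_as_mismatch():
    rows = ["ACGT", "ACGT", "AC-T"]
    hc = helix_conservation(_saln(rows), "H9")
    assert hc.conserved_columns == 3


def test_helix_conservation_unknown_id_errors():
    with pytest.raises(KeyError):
        helix_conservation(_saln(["ACGT"] * 3), "H404")


def test_helix_conservation_non_increasing_under_mutation():
    rng = np.random.default_rng(79)
    rows = ["ACGTACGTACGTACGTACGT"] * 5
    last = 100.0
    for _ in range(12):
        i = int(rng.integers(0, 5))
        j = int(rng.integers(0, 20))
        orig = "ACGTACGTACGTACGTACGT"[j]
        repl = "ACGT"[("ACGT".index(orig) + 1) % 4]  # never the consensus base
        rows[i] = rows[i][:j] + repl + rows[i][j + 1 :]
        pct = helix_conservation(_saln(rows), "H9").percent_conserved
        assert pct <= last
        last = pct


# ------------------------------------------------------------ p-distance


def test_p_distance_trivial_cases():
    dm = p_distance_matrix(_aln(["AAAA", "AAAA", "AAAT"]))
    assert dm.d[0, 1] == 0.0
    assert dm.d[0, 2] == 0.25


def test_p_distance_matches_hand_count_with_pairwise_deletion():
    rng = np.random.default_rng(83)
    for _ in range(30):
        rows = [
            "".join("ACGT-N"[k] for k in rng.integers(0, 6, 40))
            for _ in range(4)
        ]
        dm = p_distance_matrix(_aln(rows))
        assert np.allclose(dm.d, dm.d.T, equal_nan=True)
        assert np.all(np.diag(dm.d) == 0)
        for a in range(4):
            for b in range(a + 1, 4):
                pairs = [
                    (x, y)
                    for x, y in zip(rows[a], rows[b])
                    if x not in MISSING and y not in MISSING
                ]
                if not pairs:
                    assert np.isnan(dm.d[a, b])
                else:
                    want = sum(x != y for x, y in pairs) / len(pairs)
                    assert dm.d[a, b] == pytest.approx(want)


# ------------------------------------------------------- outlier flagging


def _structure(taxon, pairs, strand5, strand3, crw_id="H837"):
    h = HelixAnnotation(
        crw_id=crw_id, strand5=strand5, strand3=strand3,
        pairs=[BasePair(i, j, "WC") for i, j in pairs],
    )
    return SecondaryStructure(seq_id=taxon, gene="rrnL", helices=[h])


def test_no_flags_when_all_structures_identical():
    pairs = [(i, 30 - i) for i in range(8)]
    structures = [
        _structure(f"t{k}", pairs, (0, 8), (23, 31)) for k in range(6)
    ]
    df = compare_helix_across_taxa(structures, "H837")
    assert not df["flagged"].any()


def test_longer_middle_unpaired_region_is_flagged():
    # five taxa with a 9-nt enclosed stretch, one with 19 nt (> 1.5x modal)
    normal = [(i, 30 - i) for i in range(8)]  # inner pair (7,23): 15 enclosed
    structures = [
        _structure(f"t{k}", [(i, 24 - i) for i in range(8)], (0, 8), (17, 25))
        for k in range(5)
    ]
    structures.append(_structure("odd", normal, (0, 8), (23, 31)))
    df = compare_helix_across_taxa(structures, "H837")
    flagged = set(df[df["flagged"]]["taxon"])
    assert flagged == {"odd"}


def test_divergent_shape_and_missing_both_flagged():
    three_stem = (
        [(i, 40 - i) for i in range(8)]
        + [(9 + a, 32 - a) for a in range(6)]
        + [(16 + a, 26 - a) for a in range(3)]
    )
    structures = [
        _structure(f"t{k}", three_stem, (0, 19), (24, 41), crw_id="H47")
        for k in range(5)
    ]
    two_stem = [(i, 40 - i) for i in range(10)] + [
        (11 + a, 30 - a) for a in range(4)
    ]
    structures.append(_structure("raphi", two_stem, (0, 15), (27, 41), "H47"))
    missing = SecondaryStructure(seq_id="lost", gene="rrnS")
    missing.missing_helices.append("H47")
    structures.append(missing)
    df = compare_helix_across_taxa(structures, "H47")
    assert set(df[df["flagged"]]["taxon"]) == {"raphi", "lost"}


def test_exactly_the_simulated_divergent_taxon_is_flagged(sim, sim_structures):
    df = compare_helix_across_taxa(list(sim_structures.values()), "H47")
    assert set(df[df["flagged"]]["taxon"]) == {"T01"}
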