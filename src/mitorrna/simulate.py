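"""Structure-constrained rRNA-like sequence simulation with ground truth.

The generator emulates the statistical shape of an insect mitochondrial
rRNA gene: conserved helices (anchored stems kept paired by compensatory
substitution) interleaved with hypervariable unpaired regions that
accumulate indels, evolved along a known tree.  One leaf may be
designated "divergent": selected helices have their 3' strand randomized
and their enclosed loop doubled, mimicking a structurally deviant
outgroup-like lineage.

Every column of the evolving sequences carries an immutable key
(a Fraction position plus a creation serial), so the true multiple
alignment is maintained exactly through arbitrary insertion/deletion
histories: removing gaps from any true-alignment row reproduces the leaf
sequence verbatim.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from fractions import Fraction

import dendropy
import numpy as np

from .records import Alignment, SeqRecord, can_pair
from .annotate import (
    BasePair,
    HelixAnnotation,
    SecondaryStructure,
    count_structure_elements,
)
from .template import StructureTemplate

BASES = "ACGT"
_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}

Key = tuple[Fraction, int]


@dataclass(frozen=True)
class ColInfo:
    kind: str  # stem5 | stem3 | loop | linker
    region: str  # crw_id or linker id
    partner: Key | None = None
    hypervariable: bool = False


@dataclass
class SimConfig:
    """Study conditions of one simulation run."""

    template: StructureTemplate
    tree: str  # newick with branch lengths (expected substitutions/site)
    gene_length: int = 790
    sub_rate_unpaired: float = 1.0
    sub_rate_paired: float = 0.3
    compensatory_prob: float = 0.9
    indel_rate_hv: float = 0.05
    indel_len_geom_p: float = 0.5
    hv_threshold: int = 15
    divergent_taxon: str | None = None
    divergent_helices: tuple[str, ...] = ()
    gc_bias_taxon: str | None = None
    gc_bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("compensatory_prob", "indel_len_geom_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("sub_rate_unpaired", "sub_rate_paired", "indel_rate_hv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.divergent_taxon and not self.divergent_helices:
            raise ValueError(
                "divergent_taxon set but no divergent_helices designated"
            )


@dataclass
class SimOutput:
    leaf_records: list[SeqRecord]
    true_structures: dict[str, SecondaryStructure]
    true_alignment: Alignment
    column_region: list[str]
    event_log: list[tuple]
    perturbed: set[tuple[str, str]] = field(default_factory=set)

    def structure_of(self, taxon: str) -> SecondaryStructure:
        return self.true_structures[taxon]


# ------------------------------------------------------------------ root


def build_root(
    template: StructureTemplate,
    gene_length: int,
    seed: int | np.random.Generator = 0,
) -> tuple[SeqRecord, SecondaryStructure]:
    """A root sequence realizing the template with perfect pairing."""
    record, structure, _, _ = _build_root_state(template, gene_length, seed)
    return record, structure


def _build_root_state(
    template: StructureTemplate,
    gene_length: int,
    seed: int | np.random.Generator,
    hv_threshold: int = 15,
):
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    helices = template.helices  # sorted by expected_center
    parts = []  # (crw_id, strand5, loop, strand3)
    for spec in helices:
        if len(spec.anchor5) > spec.stem_len[1]:
            raise ValueError(
                f"{spec.crw_id}: anchor longer than maximal stem"
            )
        stem = int(rng.integers(spec.stem_len[0], spec.stem_len[1] + 1))
        stem = max(stem, len(spec.anchor5))
        loop = int(rng.integers(spec.loop_len[0], spec.loop_len[1] + 1))
        pad = "".join(
            BASES[k] for k in rng.integers(0, 4, stem - len(spec.anchor5))
        )
        strand5 = spec.anchor5 + pad
        strand3 = _revcomp(strand5)
        # loops are drawn from a non-self-pairing alphabet (A/C admit no
        # Watson-Crick or GU pair), so the root's true structure is
        # unambiguous: stems cannot extend into loops by chance
        loop_seq = "".join("AC"[k] for k in rng.integers(0, 2, loop))
        parts.append((spec.crw_id, strand5, loop_seq, strand3))

    min_linker = 2
    need = sum(len(s5) + len(lp) + len(s3) for _, s5, lp, s3 in parts)
    need += min_linker * (len(parts) + 1)
    if need > gene_length:
        raise ValueError(
            f"template needs at least {need} nt, gene_length is {gene_length}"
        )
    # desired starts from expected centers, made feasible in two passes
    starts = []
    for spec, (_, s5, lp, s3) in zip(helices, parts):
        fp = len(s5) + len(lp) + len(s3)
        starts.append(int(round(spec.expected_center * gene_length - fp / 2)))
    fps = [len(s5) + len(lp) + len(s3) for _, s5, lp, s3 in parts]
    for k in range(len(starts)):
        lo = (starts[k - 1] + fps[k - 1] if k else 0) + min_linker
        starts[k] = max(starts[k], lo)
    limit = gene_length - min_linker
    for k in range(len(starts) - 1, -1, -1):
        hi = (starts[k + 1] if k + 1 < len(starts) else limit + min_linker)
        starts[k] = min(starts[k], hi - min_linker - fps[k])
        if starts[k] < (starts[k - 1] + fps[k - 1] + min_linker if k else 0):
            raise ValueError("template cannot fit: footprints collide")

    bases: list[str] = []
    info: list[ColInfo] = []
    structure = SecondaryStructure(seq_id="root", gene=template.gene)
    cursor = 0
    linker_idx = 0

    def emit_linker(upto: int) -> None:
        nonlocal cursor, linker_idx
        n = upto - cursor
        region = f"L{linker_idx}"
        hv = n > hv_threshold
        for k in rng.integers(0, 4, n):
            bases.append(BASES[k])
            info.append(ColInfo("linker", region, hypervariable=hv))
        if hv:
            structure.hypervariable_intervals.append((cursor, upto))
        linker_idx += 1
        cursor = upto

    for (crw_id, s5, lp, s3), start in zip(parts, starts):
        emit_linker(start)
        b5 = len(bases)
        bases.extend(s5)
        bases.extend(lp)
        bases.extend(s3)
        e3 = len(bases)
        n = len(s5)
        pairs = []
        for a in range(n):
            i = b5 + a
            j = e3 - 1 - a
            info_i = ColInfo("stem5", crw_id)
            pairs.append((i, j))
            info.append(info_i)
        for _ in lp:
            info.append(ColInfo("loop", crw_id))
        for _ in s3:
            info.append(ColInfo("stem3", crw_id))
        ann = HelixAnnotation(
            crw_id=crw_id,
            strand5=(b5, b5 + n),
            strand3=(e3 - n, e3),
            pairs=[BasePair(i, j, "WC") for i, j in pairs],
            score=float(n),
        )
        ann.stems_count, ann.loops_count, ann.internal_unpaired_len = (
            count_structure_elements(ann)
        )
        structure.helices.append(ann)
        cursor = e3
    emit_linker(gene_length)

    record = SeqRecord(id="root", residues="".join(bases), source="simulated")
    # column metadata keyed for the evolver: root column i -> (Fraction(i), 0)
    keys: list[Key] = [(Fraction(i), 0) for i in range(gene_length)]
    colinfo: dict[Key, ColInfo] = {}
    partner_of: dict[int, int] = {}
    for h in structure.helices:
        for p in h.pairs:
            partner_of[p.i] = p.j
            partner_of[p.j] = p.i
    for i, ci in enumerate(info):
        partner = (
            (Fraction(partner_of[i]), 0) if i in partner_of else None
        )
        colinfo[keys[i]] = replace(ci, partner=partner)
    state = list(zip(keys, bases))
    return record, structure, state, colinfo


def _revcomp(s: str) -> str:
    return "".join(_WC[c] for c in reversed(s))


# ------------------------------------------------------------- evolution


def _evolve_branch(
    state: list[tuple[Key, str]],
    colinfo: dict[Key, ColInfo],
    blen: float,
    cfg: SimConfig,
    rng: np.random.Generator,
    serial: list[int],
    log: list[tuple],
    branch_label: str,
    gc_bias: float = 0.0,
) -> list[tuple[Key, str]]:
    state = list(state)
    index = {key: pos for pos, (key, _) in enumerate(state)}

    # substitutions (Gillespie-style per-site event counts)
    rates = np.array(
        [
            cfg.sub_rate_paired
            if colinfo[key].kind in ("stem5", "stem3")
            else cfg.sub_rate_unpaired
            for key, _ in state
        ]
    )
    n_events = rng.poisson(rates * blen)
    if gc_bias > 0:
        base_w = np.array([1 - gc_bias, 1 + gc_bias, 1 + gc_bias, 1 - gc_bias])
    else:
        base_w = np.ones(4)
    for pos in np.nonzero(n_events)[0]:
        key = state[pos][0]
        ci = colinfo[key]
        for _ in range(int(n_events[pos])):
            old = state[pos][1]
            others = [b for b in BASES if b != old]
            w = np.array([base_w[BASES.index(b)] for b in others])
            new = rng.choice(others, p=w / w.sum())
            state[pos] = (key, new)
            log.append((branch_label, "sub", key, old, new))
            if (
                ci.partner is not None
                and ci.partner in index
                and rng.random() < cfg.compensatory_prob
            ):
                ppos = index[ci.partner]
                pold = state[ppos][1]
                state[ppos] = (ci.partner, _WC[new])
                if pold != _WC[new]:
                    log.append(
                        (branch_label, "comp", ci.partner, pold, _WC[new])
                    )

    # indels, confined to hypervariable linker regions
    if cfg.indel_rate_hv > 0 and blen > 0:
        regions = sorted(
            {
                colinfo[key].region
                for key, _ in state
                if colinfo[key].hypervariable
            }
        )
        for region in regions:
            positions = [
                pos
                for pos, (key, _) in enumerate(state)
                if colinfo[key].region == region
            ]
            if not positions:
                continue
            k_events = rng.poisson(cfg.indel_rate_hv * len(positions) * blen)
            for _ in range(int(k_events)):
                positions = [
                    pos
                    for pos, (key, _) in enumerate(state)
                    if colinfo[key].region == region
                ]
                if not positions:
                    break
                length = int(rng.geometric(cfg.indel_len_geom_p))
                at = int(rng.choice(positions))
                if rng.random() < 0.5 and len(positions) > length:
                    # deletion: consecutive columns of this region
                    doomed = []
                    p = at
                    while (
                        p < len(state)
                        and len(doomed) < length
                        and colinfo[state[p][0]].region == region
                    ):
                        doomed.append(p)
                        p += 1
                    for p in reversed(doomed):
                        log.append(
                            (branch_label, "del", state[p][0], state[p][1], "")
                        )
                        del state[p]
                else:
                    _insert_after(
                        state, at, length, region, colinfo, rng, serial,
                        log, branch_label, kind="linker", hv=True,
                    )
    return state


def _insert_after(
    state: list[tuple[Key, str]],
    at: int,
    length: int,
    region: str,
    colinfo: dict[Key, ColInfo],
    rng: np.random.Generator,
    serial: list[int],
    log: list[tuple],
    branch_label: str,
    kind: str,
    hv: bool,
) -> None:
    """Insert new random columns after list position ``at``.

    New column keys are Fraction midpoints between neighbors, so global
    key order stays consistent with every lineage's residue order.
    """
    left = state[at][0][0]
    right = state[at + 1][0][0] if at + 1 < len(state) else left + 1
    for n in range(length):
        frac = (left + right) / 2
        serial[0] += 1
        key: Key = (frac, serial[0])
        base = BASES[int(rng.integers(0, 4))]
        colinfo[key] = ColInfo(kind, region, hypervariable=hv)
        state.insert(at + 1 + n, (key, base))
        log.append((branch_label, "ins", key, "", base))
        left = frac


def _perturb_divergent(
    state: list[tuple[Key, str]],
    colinfo: dict[Key, ColInfo],
    helices: tuple[str, ...],
    rng: np.random.Generator,
    serial: list[int],
    log: list[tuple],
    label: str,
) -> None:
    """Randomize the 3' strand and double the loop of designated helices."""
    for crw_id in helices:
        loop_positions = []
        for pos, (key, base) in enumerate(state):
            ci = colinfo[key]
            if ci.region != crw_id:
                continue
            if ci.kind == "stem3":
                new = BASES[int(rng.integers(0, 4))]
                state[pos] = (key, new)
                log.append((label, "divergent_sub", key, base, new))
            elif ci.kind == "loop":
                loop_positions.append(pos)
        if loop_positions:
            _insert_after(
                state, loop_positions[-1], len(loop_positions), crw_id,
                colinfo, rng, serial, log, label, kind="loop", hv=False,
            )


def evolve(config: SimConfig) -> SimOutput:
    """Evolve the root along the configured tree; full ground truth out."""
    rng = np.random.default_rng(config.seed)
    _, root_structure, root_state, colinfo = _build_root_state(
        config.template, config.gene_length, rng, config.hv_threshold
    )
    tree = dendropy.Tree.get(data=config.tree, schema="newick")
    serial = [0]
    log: list[tuple] = []
    leaves: dict[str, list[tuple[Key, str]]] = {}
    perturbed: set[tuple[str, str]] = set()

    node_counter = [0]

    def descend(node, state):
        for child in node.child_nodes():
            blen = child.edge.length or 0.0
            node_counter[0] += 1
            label = (
                child.taxon.label if child.taxon is not None
                else f"node{node_counter[0]}"
            )
            is_leaf = child.is_leaf()
            bias = (
                config.gc_bias
                if is_leaf and label == config.gc_bias_taxon
                else 0.0
            )
            child_state = _evolve_branch(
                state, colinfo, blen, config, rng, serial, log, label,
                gc_bias=bias,
            )
            if is_leaf:
                if label == config.divergent_taxon:
                    _perturb_divergent(
                        child_state, colinfo, config.divergent_helices,
                        rng, serial, log, label,
                    )
                    perturbed.update(
                        (label, h) for h in config.divergent_helices
                    )
                leaves[label] = child_state
            else:
                descend(child, child_state)

    descend(tree.seed_node, root_state)
    if not leaves:
        raise ValueError("tree has no labeled leaves")

    # ---- true alignment over the union of all columns ever observed
    all_keys = sorted({key for st in leaves.values() for key, _ in st})
    col_of = {key: j for j, key in enumerate(all_keys)}
    taxa = sorted(leaves)
    rows = {}
    for taxon in taxa:
        row = ["-"] * len(all_keys)
        for key, base in leaves[taxon]:
            row[col_of[key]] = base
        rows[taxon] = "".join(row)
    true_alignment = Alignment(
        records=[
            SeqRecord(id=t, residues=rows[t], source="simulated-truth")
            for t in taxa
        ]
    )
    column_region = [colinfo[key].region for key in all_keys]

    # ---- per-leaf true structures mapped through surviving columns
    structures = {}
    for taxon in taxa:
        st = leaves[taxon]
        posmap = {key: pos for pos, (key, _) in enumerate(st)}
        seq = "".join(base for _, base in st)
        s = SecondaryStructure(seq_id=taxon, gene=config.template.gene)
        for h in root_structure.helices:
            pos_by_kind: dict[str, list[int]] = {
                "stem5": [], "stem3": [], "loop": []
            }
            for pos, (key, _) in enumerate(st):
                ci = colinfo[key]
                if ci.region == h.crw_id:
                    pos_by_kind[ci.kind].append(pos)
            if not pos_by_kind["stem5"] or not pos_by_kind["stem3"]:
                s.missing_helices.append(h.crw_id)
                continue
            pairs = []
            for p in h.pairs:
                k5, k3 = (Fraction(p.i), 0), (Fraction(p.j), 0)
                if k5 in posmap and k3 in posmap:
                    i, j = posmap[k5], posmap[k3]
                    if can_pair(seq[i], seq[j]):
                        kind = (
                            "WC" if (seq[i], seq[j]) not in
                            {("G", "T"), ("T", "G")} else "GU"
                        )
                        pairs.append(BasePair(i, j, kind))
            ann = HelixAnnotation(
                crw_id=h.crw_id,
                strand5=(
                    min(pos_by_kind["stem5"]), max(pos_by_kind["stem5"]) + 1
                ),
                strand3=(
                    min(pos_by_kind["stem3"]), max(pos_by_kind["stem3"]) + 1
                ),
                pairs=pairs,
                score=float(len(pairs)),
            )
            ann.stems_count, ann.loops_count, ann.internal_unpaired_len = (
                count_structure_elements(ann)
            )
            s.helices.append(ann)
        hv_positions: dict[str, list[int]] = {}
        for pos, (key, _) in enumerate(st):
            ci = colinfo[key]
            if ci.hypervariable:
                hv_positions.setdefault(ci.region, []).append(pos)
        for region in sorted(hv_positions):
            ps = hv_positions[region]
            s.hypervariable_intervals.append((min(ps), max(ps) + 1))
        structures[taxon] = s

    leaf_records = [
        SeqRecord(
            id=t,
            residues="".join(b for _, b in leaves[t]),
            source="simulated",
        )
        for t in taxa
    ]
    return SimOutput(
        leaf_records=leaf_records,
        true_structures=structures,
        true_alignment=true_alignment,
        column_region=column_region,
        event_log=log,
        perturbed=perturbed,
    )


# ------------------------------------------------------------- evaluation


def _jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0


def helix_recovery(
    sim: SimOutput,
    annotated: dict[str, SecondaryStructure],
    min_jaccard: float = 0.8,
) -> float:
    """Fraction of true helices whose annotated footprint overlaps truth.

    A (taxon, helix) pair counts as recovered when the annotated
    footprint has Jaccard overlap >= ``min_jaccard`` with the true
    footprint.  Structurally perturbed helices of the divergent taxon
    are excluded from the denominator (their truth deviates by design).
    """
    hits = total = 0
    for taxon, truth in sim.true_structures.items():
        ann = annotated[taxon]
        for th in truth.helices:
            if (taxon, th.crw_id) in sim.perturbed:
                continue
            total += 1
            ah = ann.helix(th.crw_id)
            if ah is not None and _jaccard(
                ah.footprint, th.footprint
            ) >= min_jaccard:
                hits += 1
    if total == 0:
        raise ValueError("no unperturbed true helices to score")
    return hits / total


# ----------------------------------------------------------- fixture suite

#: An 11-leaf tree shaped like a three-order sampling with one early
#: divergent lineage (T01).  Edge lengths scale with ``depth`` so the
#: deepest root-to-leaf path equals the requested depth.
_TREE_SHAPE = (
    "((T01:{d2},(T02:{d1},T03:{d1}):{d1}):{d2},"
    "((T04:{d2},(T05:{d1},T06:{d1}):{d1}):{d1},"
    "((T07:{d1},T08:{d1}):{d2},"
    "(T09:{d2},(T10:{d1},T11:{d1}):{d1}):{d1}):{d1}):{d1});"
)


def default_tree(depth: float = 0.05) -> str:
    """Newick for the canonical 11-taxon simulation tree."""
    return _TREE_SHAPE.format(d1=depth / 4, d2=depth / 2)


def default_config(
    template: StructureTemplate,
    depth: float = 0.05,
    seed: int = 11,
    **overrides,
) -> SimConfig:
    """The canonical 11-taxon study conditions (T01 divergent at H47)."""
    kwargs = dict(
        template=template,
        tree=default_tree(depth),
        gene_length=template.nominal_length or 790,
        divergent_taxon="T01",
        divergent_helices=("H47",) if any(
            h.crw_id == "H47" for h in template.helices
        ) else (template.helices[1].crw_id,),
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def make_fixture_suite(
    seed: int = 11, outdir: str | os.PathLike = "fixtures"
) -> dict[str, str]:
    """Write the canonical simulated fixture set to disk.

    Layout: fasta/ (leaf sequences), structures/ (true dot-bracket),
    alignments/ (true alignment as PHYLIP and Stockholm), templates/
    (the rrnS example template), and a key-value manifest.  Byte-stable
    for a fixed seed.
    """
    from . import seq_io
    from .annotate import to_dot_bracket
    from .template import load_example_template, serialize_template

    outdir = os.fspath(outdir)
    for sub in ("fasta", "structures", "alignments", "templates"):
        os.makedirs(os.path.join(outdir, sub), exist_ok=True)
    template = load_example_template("rrnS")
    cfg = default_config(template, seed=seed)
    sim = evolve(cfg)

    seq_io.write_fasta(
        sim.leaf_records, os.path.join(outdir, "fasta", "leaves.fasta")
    )
    for rec in sim.leaf_records:
        s = sim.true_structures[rec.id]
        db = to_dot_bracket(s, len(rec.residues))
        with open(
            os.path.join(outdir, "structures", f"{rec.id}.dotbracket"), "w"
        ) as fh:
            fh.write(f">{rec.id}\n{rec.residues}\n{db}\n")
    seq_io.write_phylip(
        sim.true_alignment,
        os.path.join(outdir, "alignments", "true_alignment.phy"),
    )
    seq_io.write_stockholm(
        sim.true_alignment,
        os.path.join(outdir, "alignments", "true_alignment.sto"),
        per_column_labels=sim.column_region,
    )
    serialize_template(
        template, os.path.join(outdir, "templates", "rrns_helices.tsv")
    )
    manifest = {
        "seed": str(seed),
        "n_leaves": str(len(sim.leaf_records)),
        "gene": cfg.template.gene,
        "gene_length": str(cfg.gene_length),
        "tree": cfg.tree,
        "divergent_taxon": str(cfg.divergent_taxon),
        "divergent_helices": ",".join(cfg.divergent_helices),
        "alignment_columns": str(sim.true_alignment.column_count),
    }
    with open(os.path.join(outdir, "manifest.txt"), "w") as fh:
        for k, v in manifest.items():
            fh.write(f"{k}\t{v}\n")
    return manifest
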