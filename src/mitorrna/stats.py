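"""Per-column and per-helix conservation statistics.

Two gap policies coexist deliberately.  ``classify_sites`` treats gaps
and ambiguity codes as missing data (MEGA-like variable-site semantics);
``helix_conservation`` counts a gap as a mismatch, because per-helix
conservation percentages refer to aligned structural positions.  Every
report states which policy produced it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import AMBIGUOUS, GAP, Alignment
from .annotate import SecondaryStructure, count_structure_elements
from .structaln import StructAlignment

BASES = ("A", "C", "G", "T")
_MISSING = set(AMBIGUOUS) | {GAP}


@dataclass
class SiteClassCounts:
    conserved: int
    variable: int
    parsimony_informative: int
    singleton: int
    counted_sites: int
    excluded_sites: int
    gap_policy: str = "gaps and ambiguity codes treated as missing"

    def as_row(self) -> dict[str, int]:
        return {
            "conserved": self.conserved,
            "variable": self.variable,
            "parsimony_informative": self.parsimony_informative,
            "singleton": self.singleton,
            "counted_sites": self.counted_sites,
            "excluded_sites": self.excluded_sites,
        }


@dataclass
class HelixConservation:
    crw_id: str
    columns: int
    conserved_columns: int
    percent_conserved: float
    composition: pd.DataFrame  # rows = taxa, columns = A/C/G/T counts
    gap_policy: str = "gap counts as mismatch"


@dataclass
class DivergenceMatrix:
    taxa: list[str]
    d: np.ndarray
    undefined: list[tuple[str, str]] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.taxa, columns=self.taxa)


def classify_sites(aln: Alignment) -> SiteClassCounts:
    """Classify alignment columns into conserved / variable / PI / singleton.

    Gaps and ambiguity codes are missing; a column with fewer than two
    non-missing residues is excluded.  A column is conserved when all
    non-missing residues agree; parsimony-informative when at least two
    states each occur in at least two rows; singleton otherwise.
    """
    if len(aln.records) < 2:
        raise ValueError("site classification needs at least two rows")
    conserved = variable = pi = singleton = excluded = 0
    for j in range(aln.column_count):
        col = [ch for ch in aln.column(j) if ch not in _MISSING]
        if len(col) < 2:
            excluded += 1
            continue
        counts = Counter(col)
        if len(counts) == 1:
            conserved += 1
            continue
        variable += 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            pi += 1
        else:
            singleton += 1
    return SiteClassCounts(
        conserved=conserved,
        variable=variable,
        parsimony_informative=pi,
        singleton=singleton,
        counted_sites=conserved + variable,
        excluded_sites=excluded,
    )


def helix_conservation(saln: StructAlignment, crw_id: str) -> HelixConservation:
    """Conservation and base composition of one helix block.

    A column is conserved when every row carries the same residue; any
    gap makes the column non-conserved.  The composition table counts
    A/C/G/T per taxon over the helix columns (S6/S7-style).
    """
    cols = saln.helix_columns(crw_id)
    rows = saln.base.records
    conserved = 0
    for j in cols:
        column = saln.base.column(j)
        if GAP not in column and len(set(column)) == 1:
            conserved += 1
    comp = {
        r.id: {
            b: sum(r.residues[j] == b for j in cols) for b in BASES
        }
        for r in rows
    }
    return HelixConservation(
        crw_id=crw_id,
        columns=len(cols),
        conserved_columns=conserved,
        percent_conserved=round(100.0 * conserved / len(cols), 2),
        composition=pd.DataFrame.from_dict(comp, orient="index")[list(BASES)],
    )


def conservation_table(saln: StructAlignment) -> pd.DataFrame:
    """Per-helix conservation summary over all helix-labeled regions."""
    seen: list[str] = []
    for lab in saln.column_region:
        if lab.startswith(("L", "HV")) or lab in seen:
            continue
        seen.append(lab)
    rows = []
    for cid in seen:
        hc = helix_conservation(saln, cid)
        rows.append(
            {
                "crw_id": cid,
                "columns": hc.columns,
                "conserved_columns": hc.conserved_columns,
                "percent_conserved": hc.percent_conserved,
            }
        )
    return pd.DataFrame(rows)


def p_distance_matrix(aln: Alignment) -> DivergenceMatrix:
    """Pairwise p-distances with pairwise deletion of missing sites."""
    if len(aln.records) < 2:
        raise ValueError("p-distance needs at least two rows")
    arr = np.array([list(r.residues) for r in aln.records])
    ok = ~np.isin(arr, list(_MISSING))
    n = len(aln.records)
    d = np.zeros((n, n))
    undefined = []
    for a in range(n):
        for b in range(a + 1, n):
            both = ok[a] & ok[b]
            m = int(both.sum())
            if m == 0:
                d[a, b] = d[b, a] = np.nan
                undefined.append((aln.records[a].id, aln.records[b].id))
            else:
                mismatch = int((arr[a][both] != arr[b][both]).sum())
                d[a, b] = d[b, a] = mismatch / m
    return DivergenceMatrix(taxa=aln.ids, d=d, undefined=undefined)


def compare_helix_across_taxa(
    structures: list[SecondaryStructure], crw_id: str
) -> pd.DataFrame:
    """Cross-taxon table of helix element counts with outlier flags.

    A taxon is flagged when its (stems, loops) differs from the modal
    value across taxa, when its internal unpaired stretch exceeds the
    modal value by more than 50% (and by more than 3 nt, so that small
    helices are not flagged on 1-2 nt of annotation jitter), or when the
    helix is missing.
    """
    rows = []
    for s in structures:
        h = s.helix(crw_id)
        if h is None:
            rows.append(
                {"taxon": s.seq_id, "present": False,
                 "stems": 0, "loops": 0, "internal_unpaired": 0}
            )
        else:
            stems, loops, internal = count_structure_elements(h)
            rows.append(
                {"taxon": s.seq_id, "present": True,
                 "stems": stems, "loops": loops,
                 "internal_unpaired": internal}
            )
    df = pd.DataFrame(rows)
    present = df[df["present"]]
    if len(present):
        shape_mode = (
            present.groupby(["stems", "loops"]).size()
            .sort_values(ascending=False).index[0]
        )
        iul_mode = int(
            present["internal_unpaired"].mode().min()
        )
    else:
        shape_mode, iul_mode = (0, 0), 0
    flags = []
    for _, r in df.iterrows():
        if not r["present"]:
            flags.append(True)
            continue
        shape_dev = (r["stems"], r["loops"]) != shape_mode
        iul_dev = (
            iul_mode > 0
            and r["internal_unpaired"] > 1.5 * iul_mode
            and r["internal_unpaired"] - iul_mode > 3
        )
        flags.append(bool(shape_dev or iul_dev))
    df["flagged"] = flags
    return df
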