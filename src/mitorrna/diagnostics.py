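"""Alignment diagnostics: substitution saturation and base homogeneity.

The substitution-saturation index is the entropy-based Iss: the mean
per-site Shannon entropy (base 2, over A/C/G/T among non-missing
residues) divided by the full-saturation entropy computed from the
global base frequencies.  Critical values are re-derived by Monte Carlo:
JC69 evolution is simulated on balanced (symmetric) or pectinate
(asymmetric) reference trees over a grid of branch depths, and the
critical Iss is the value at which neighbor joining on p-distances
recovers the true topology in 95% of replicates.

Base-composition homogeneity is tested per taxon against the pooled
composition (chi-square, df 3) and overall on the taxa x bases
contingency table (df 3(R-1)), IQ-TREE / PAUP* style.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import AMBIGUOUS, GAP, Alignment

BASES = ("A", "C", "G", "T")
_MISSING = set(AMBIGUOUS) | {GAP}


# ------------------------------------------------------------ Iss index


def _base_matrix(aln: Alignment) -> np.ndarray:
    """Alignment as int codes: 0..3 = ACGT, -1 = missing."""
    arr = np.array([list(r.residues) for r in aln.records])
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for k, b in enumerate(BASES):
        codes[arr == b] = k
    return codes


def _iss_from_codes(codes: np.ndarray) -> float:
    counts = np.stack(
        [(codes == k).sum(axis=0) for k in range(4)], axis=0
    ).astype(float)  # 4 x sites
    n = counts.sum(axis=0)
    use = n >= 2
    if not use.any():
        raise ValueError("no column with two or more non-missing residues")
    c = counts[:, use]
    p = c / c.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_site = -np.nansum(np.where(p > 0, p * np.log2(p), 0.0), axis=0)
    f = counts.sum(axis=1)
    f = f / f.sum()
    h_max = float(-np.sum(np.where(f > 0, f * np.log2(f), 0.0)))
    if h_max == 0.0:
        return 0.0
    return float(h_site.mean() / h_max)


def iss_index(aln: Alignment) -> float:
    """Entropy-based index of substitution saturation.

    0 for invariant data; 1 when every site is fully saturated relative
    to the global base frequencies.  Sites with fewer than two
    non-missing residues are skipped.
    """
    if len(aln.records) < 4:
        raise ValueError("Iss needs at least 4 sequences")
    return _iss_from_codes(_base_matrix(aln))


# ------------------------------------------------- reference-tree machinery


def _balanced_tree(labels: list[int]):
    if len(labels) == 1:
        return labels[0]
    h = (len(labels) + 1) // 2
    return (_balanced_tree(labels[:h]), _balanced_tree(labels[h:]))


def _pectinate_tree(labels: list[int]):
    node = (labels[0], labels[1])
    for lab in labels[2:]:
        node = (node, lab)
    return node


def _tree_splits(tree, all_leaves: frozenset[int]) -> set[frozenset[int]]:
    """Nontrivial splits of a rooted binary tree, treated as unrooted.

    Each split is canonicalized to the side not containing the smallest
    leaf label.
    """
    splits: set[frozenset[int]] = set()
    anchor = min(all_leaves)

    def clade(node) -> frozenset[int]:
        if isinstance(node, int):
            return frozenset((node,))
        left, right = node
        c = clade(left) | clade(right)
        if 1 < len(c) < len(all_leaves) - 1:
            side = all_leaves - c if anchor in c else c
            splits.add(side)
        return c

    clade(tree)
    return splits


def _simulate_jc(
    tree, n_sites: int, branch_len: float, rng: np.random.Generator
) -> dict[int, np.ndarray]:
    """JC69 site evolution; every edge has length ``branch_len``."""
    p_change = 0.75 * (1.0 - np.exp(-4.0 * branch_len / 3.0))
    leaves: dict[int, np.ndarray] = {}

    def descend(node, seq):
        mask = rng.random(n_sites) < p_change
        child = seq.copy()
        child[mask] = (
            child[mask] + rng.integers(1, 4, int(mask.sum()))
        ) % 4
        if isinstance(node, int):
            leaves[node] = child
        else:
            descend(node[0], child)
            descend(node[1], child)

    root = rng.integers(0, 4, n_sites).astype(np.int8)
    descend(tree[0], root)
    descend(tree[1], root)
    return leaves


def neighbor_joining_splits(
    d: np.ndarray, labels: list[int] | None = None
) -> set[frozenset[int]]:
    """Nontrivial splits of the neighbor-joining tree of ``d``.

    Canonical Saitou-Nei updates; ties break on the lowest taxon pair.
    Used internally for the critical-value simulation; a full tree object
    is never needed, only the induced bipartitions.
    """
    n = d.shape[0]
    if labels is None:
        labels = list(range(n))
    all_leaves = frozenset(labels)
    anchor = min(all_leaves)
    clusters: list[frozenset[int]] = [frozenset((lab,)) for lab in labels]
    dm = d.astype(float).copy()
    splits: set[frozenset[int]] = set()
    while len(clusters) > 3:
        m = len(clusters)
        r = dm.sum(axis=1)
        q = (m - 2) * dm - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                key = (q[a, b], min(clusters[a] | clusters[b]))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        if 1 < len(merged) < len(all_leaves) - 1:
            side = all_leaves - merged if anchor in merged else merged
            splits.add(side)
        new_row = 0.5 * (dm[a] + dm[b] - dm[a, b])
        keep = [k for k in range(m) if k not in (a, b)]
        new_dm = np.zeros((m - 1, m - 1))
        new_dm[:-1, :-1] = dm[np.ix_(keep, keep)]
        new_dm[-1, :-1] = new_dm[:-1, -1] = new_row[keep]
        clusters = [clusters[k] for k in keep] + [merged]
        dm = new_dm
    return splits


def _p_dist(leaves: dict[int, np.ndarray]) -> tuple[np.ndarray, list[int]]:
    labels = sorted(leaves)
    n = len(labels)
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d[a, b] = d[b, a] = float(
                (leaves[labels[a]] != leaves[labels[b]]).mean()
            )
    return d, labels


@dataclass
class _DepthPoint:
    depth: float
    recovery: float
    iss_mean: float
    iss_samples: np.ndarray


def _critical_curve(
    num_otu: int,
    n_sites: int,
    topology: str,
    reps: int,
    rng: np.random.Generator,
    depths: np.ndarray | None = None,
) -> list[_DepthPoint]:
    if topology == "sym":
        tree = _balanced_tree(list(range(num_otu)))
    elif topology == "asym":
        tree = _pectinate_tree(list(range(num_otu)))
    else:
        raise ValueError("topology must be 'sym' or 'asym'")
    true_splits = _tree_splits(tree, frozenset(range(num_otu)))
    if depths is None:
        depths = np.geomspace(0.01, 2.0, 12)
    points = []
    for depth in depths:
        hits = 0
        iss_vals = np.empty(reps)
        for rep in range(reps):
            leaves = _simulate_jc(tree, n_sites, float(depth), rng)
            codes = np.stack([leaves[k] for k in sorted(leaves)])
            iss_vals[rep] = _iss_from_codes(codes)
            d, labels = _p_dist(leaves)
            if neighbor_joining_splits(d, labels) == true_splits:
                hits += 1
        points.append(
            _DepthPoint(
                depth=float(depth),
                recovery=hits / reps,
                iss_mean=float(iss_vals.mean()),
                iss_samples=iss_vals,
            )
        )
    return points


def _interpolate_critical(
    points: list[_DepthPoint], level: float = 0.95
) -> tuple[float, np.ndarray]:
    """Iss at the ``level`` topology-recovery crossing, plus the replicate
    Iss values pooled from the bracketing depths."""
    for k in range(len(points) - 1):
        lo, hi = points[k], points[k + 1]
        if lo.recovery >= level and hi.recovery < level:
            span = lo.recovery - hi.recovery
            w = (lo.recovery - level) / span if span > 0 else 0.5
            iss_c = lo.iss_mean + w * (hi.iss_mean - lo.iss_mean)
            pool = np.concatenate([lo.iss_samples, hi.iss_samples])
            return iss_c, pool
    if all(p.recovery >= level for p in points):
        last = points[-1]
        return last.iss_mean, last.iss_samples
    first = points[0]
    return first.iss_mean, first.iss_samples


def iss_critical(
    num_otu: int,
    n_sites: int,
    topology: str,
    reps: int = 100,
    seed: int = 0,
) -> float:
    """Monte-Carlo critical Iss for a symmetric or asymmetric topology.

    Simulates JC69 on the reference tree over a depth grid and returns
    the interpolated Iss at 95% neighbor-joining topology recovery.
    Reproducible for a fixed seed.
    """
    if not 4 <= num_otu <= 32:
        raise ValueError("num_otu must be in 4..32")
    if reps < 20:
        raise ValueError("reps must be >= 20 to interpolate the crossing")
    rng = np.random.default_rng(seed)
    points = _critical_curve(num_otu, n_sites, topology, reps, rng)
    iss_c, _ = _interpolate_critical(points)
    return iss_c


# --------------------------------------------------------- saturation test


@dataclass
class SaturationResult:
    iss: float
    iss_c_sym: float
    iss_c_asym: float
    p_sym: float
    p_asym: float
    num_otu: int
    n_sites: int
    reps: int

    @property
    def saturated_sym(self) -> bool:
        return self.iss >= self.iss_c_sym

    @property
    def saturated_asym(self) -> bool:
        return self.iss >= self.iss_c_asym

    @property
    def verdict(self) -> str:
        if self.saturated_sym:
            return "saturated"
        if self.saturated_asym:
            return "saturated (asymmetric topology)"
        return "unsaturated"


def _two_sided_p(obs: float, samples: np.ndarray) -> float:
    n = len(samples)
    lo = (np.sum(samples <= obs) + 1) / (n + 1)
    hi = (np.sum(samples >= obs) + 1) / (n + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))


def saturation_test(
    aln: Alignment, reps: int = 100, seed: int = 0
) -> SaturationResult:
    """Iss of an alignment against Monte-Carlo critical values.

    The two-sided p-values compare the observed Iss with the replicate
    Iss distribution at the critical depth of each reference topology.
    """
    iss = iss_index(aln)
    num_otu = len(aln.records)
    codes = _base_matrix(aln)
    n_sites = int(((codes >= 0).sum(axis=0) >= 2).sum())
    rng = np.random.default_rng(seed)
    out = {}
    for topo in ("sym", "asym"):
        points = _critical_curve(
            min(num_otu, 32), n_sites, topo, reps, rng
        )
        iss_c, pool = _interpolate_critical(points)
        out[topo] = (iss_c, _two_sided_p(iss, pool))
    return SaturationResult(
        iss=iss,
        iss_c_sym=out["sym"][0],
        iss_c_asym=out["asym"][0],
        p_sym=out["sym"][1],
        p_asym=out["asym"][1],
        num_otu=num_otu,
        n_sites=n_sites,
        reps=reps,
    )


# -------------------------------------------------- composition homogeneity


@dataclass
class CompositionTestResult:
    per_taxon: pd.DataFrame  # taxon, counts, chi2, df, p, pass
    overall_chi2: float
    overall_df: int
    overall_p: float
    counts: pd.DataFrame
    notes: list[str] = field(default_factory=list)


def chi_square_composition(
    aln: Alignment, alpha: float = 0.05
) -> CompositionTestResult:
    """Chi-square base-composition homogeneity tests.

    Per taxon: observed A/C/G/T counts against expectations from the
    pooled composition (df 3).  Overall: the R x 4 contingency test
    (df 3(R-1)).  Gaps and ambiguity codes are excluded.  Bases absent
    from the pooled data are dropped from the per-taxon statistic with a
    reduced df and a warning.
    """
    if len(aln.records) < 2:
        raise ValueError("composition test needs at least two rows")
    codes = _base_matrix(aln)
    counts = np.stack(
        [(codes == k).sum(axis=1) for k in range(4)], axis=1
    ).astype(float)  # R x 4
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = [aln.ids[i] for i in np.where(totals == 0)[0]]
        raise ValueError(f"rows with no unambiguous residues: {bad}")
    f = counts.sum(axis=0) / counts.sum()
    notes = []
    live = f > 0
    if not live.all():
        dead = [BASES[k] for k in np.where(~live)[0]]
        msg = (
            f"base(s) {dead} absent from pooled data; cells excluded, "
            f"per-taxon df reduced to {int(live.sum()) - 1}"
        )
        notes.append(msg)
        warnings.warn(msg)
    df_taxon = int(live.sum()) - 1
    rows = []
    for i, taxon in enumerate(aln.ids):
        exp = totals[i] * f[live]
        chi2 = float(((counts[i, live] - exp) ** 2 / exp).sum())
        p = float(sps.chi2.sf(chi2, df_taxon))
        freqs = counts[i] / totals[i]
        rows.append(
            {
                "taxon": taxon,
                **{f"pct_{b}": 100.0 * freqs[k] for k, b in enumerate(BASES)},
                "chi2": chi2,
                "df": df_taxon,
                "p": p,
                "passed": p >= alpha,
            }
        )
    per_taxon = pd.DataFrame(rows)
    live_counts = counts[:, live]
    chi2_all, p_all, df_all, _ = sps.chi2_contingency(
        live_counts, correction=False
    )
    return CompositionTestResult(
        per_taxon=per_taxon,
        overall_chi2=float(chi2_all),
        overall_df=int(df_all),
        overall_p=float(p_all),
        counts=pd.DataFrame(counts, index=aln.ids, columns=list(BASES)),
        notes=notes,
    )


def diagnostics_report(
    name: str, sat: SaturationResult
) -> pd.DataFrame:
    """One saturation-test row shaped like a published saturation table."""
    return pd.DataFrame(
        [
            {
                "partition": name,
                "NumOTU": sat.num_otu,
                "Iss": round(sat.iss, 3),
                "Iss.cSym": round(sat.iss_c_sym, 3),
                "P_sym": round(sat.p_sym, 4),
                "Iss.cAsym": round(sat.iss_c_asym, 3),
                "P_asym": round(sat.p_asym, 4),
                "verdict": sat.verdict,
            }
        ]
    )
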