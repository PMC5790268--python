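"""Reference secondary-structure models that guide helix annotation.

A template lists the helices of a reference model (honeybee / fruit-fly
style mitochondrial rRNA structures, CRW helix numbering) as short
conserved anchor motifs plus expected stem/loop geometry and a fractional
position in the gene.  Templates live in a small TSV format; two example
templates (rrnS and rrnL) ship with the package.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from importlib import resources

from .records import FormatError, normalize_residues

DOMAINS = ("I", "II", "III", "IV", "V", "VI")

_COLUMNS = (
    "crw_id",
    "domain",
    "anchor5",
    "anchor3",
    "stem_min",
    "stem_max",
    "loop_min",
    "loop_max",
    "expected_center",
    "max_mismatch",
)


@dataclass(frozen=True)
class HelixSpec:
    """Expected geometry and anchors of one helix of the reference model."""

    crw_id: str
    domain: str
    anchor5: str
    anchor3: str
    stem_len: tuple[int, int]
    loop_len: tuple[int, int]
    expected_center: float
    max_anchor_mismatch: int = 1

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise FormatError(
                f"{self.crw_id}: domain {self.domain!r} not in {DOMAINS}"
            )
        for name, (lo, hi) in (
            ("stem_len", self.stem_len),
            ("loop_len", self.loop_len),
        ):
            if lo > hi or lo < 0:
                raise FormatError(
                    f"{self.crw_id}: {name} range ({lo},{hi}) invalid"
                )
        if not 0.0 <= self.expected_center <= 1.0:
            raise FormatError(
                f"{self.crw_id}: expected_center {self.expected_center} "
                "outside [0,1]"
            )
        object.__setattr__(
            self, "anchor5",
            normalize_residues(self.anchor5, context=f"{self.crw_id} anchor5"),
        )
        object.__setattr__(
            self, "anchor3",
            normalize_residues(self.anchor3, context=f"{self.crw_id} anchor3"),
        )

    @property
    def min_footprint(self) -> int:
        """Smallest number of nucleotides the helix can occupy."""
        return 2 * self.stem_len[0] + self.loop_len[0]

    @property
    def max_footprint(self) -> int:
        return 2 * self.stem_len[1] + self.loop_len[1]


@dataclass
class StructureTemplate:
    """Ordered helix model for one gene (rrnS or rrnL)."""

    gene: str
    helices: list[HelixSpec] = field(default_factory=list)
    nominal_length: int | None = None

    def __post_init__(self) -> None:
        if self.gene not in ("rrnS", "rrnL"):
            raise FormatError(f"gene must be rrnS or rrnL, got {self.gene!r}")
        ids = [h.crw_id for h in self.helices]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise FormatError(f"duplicate helix id(s): {sorted(dup)}")
        # the insect mitochondrial rrnL model lacks domain III
        if self.gene == "rrnL" and "III" in self.domains_present:
            raise FormatError("rrnL template must not contain domain III")
        self.helices = sorted(self.helices, key=lambda h: h.expected_center)

    @property
    def domains_present(self) -> set[str]:
        return {h.domain for h in self.helices}

    def helix(self, crw_id: str) -> HelixSpec:
        for h in self.helices:
            if h.crw_id == crw_id:
                return h
        raise KeyError(crw_id)


def parse_template(path: str | os.PathLike) -> StructureTemplate:
    """Parse a helix-template TSV (one helix per line, '#' comments).

    Required columns: crw_id, domain, anchor5, anchor3, stem_min,
    stem_max, loop_min, loop_max, expected_center, max_mismatch.  A
    ``# gene: rrnS`` (or rrnL) comment line declares the gene.
    """
    gene = None
    nominal_length: int | None = None
    header: list[str] | None = None
    helices: list[HelixSpec] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("gene:"):
                    gene = body.split(":", 1)[1].strip()
                elif body.lower().startswith("length:"):
                    nominal_length = int(body.split(":", 1)[1])
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                missing = set(_COLUMNS) - set(header)
                if missing:
                    raise FormatError(
                        f"{path}:{lineno}: missing column(s) {sorted(missing)}"
                    )
                continue
            row = dict(zip(header, (f.strip() for f in fields)))
            try:
                helices.append(
                    HelixSpec(
                        crw_id=row["crw_id"],
                        domain=row["domain"],
                        anchor5=row["anchor5"],
                        anchor3=row["anchor3"],
                        stem_len=(int(row["stem_min"]), int(row["stem_max"])),
                        loop_len=(int(row["loop_min"]), int(row["loop_max"])),
                        expected_center=float(row["expected_center"]),
                        max_anchor_mismatch=int(row["max_mismatch"]),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    if gene is None:
        raise FormatError(f"{path}: no '# gene:' declaration")
    if not helices:
        raise FormatError(f"{path}: no helix rows")
    return StructureTemplate(
        gene=gene, helices=helices, nominal_length=nominal_length
    )


def serialize_template(t: StructureTemplate, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# gene: {t.gene}\n")
        if t.nominal_length is not None:
            fh.write(f"# length: {t.nominal_length}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for h in t.helices:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.crw_id,
                        h.domain,
                        h.anchor5,
                        h.anchor3,
                        h.stem_len[0],
                        h.stem_len[1],
                        h.loop_len[0],
                        h.loop_len[1],
                        f"{h.expected_center:.4f}",
                        h.max_anchor_mismatch,
                    )
                )
                + "\n"
            )


def validate_template(t: StructureTemplate, gene_length: int) -> list[str]:
    """Sanity-check a template against a gene length; returns warnings."""
    if gene_length <= 0:
        raise ValueError("gene_length must be positive")
    warnings: list[str] = []
    seen_centers: dict[float, str] = {}
    for h in t.helices:
        if h.expected_center in seen_centers:
            warnings.append(
                f"{h.crw_id} and {seen_centers[h.expected_center]} share "
                f"expected_center {h.expected_center}"
            )
        else:
            seen_centers[h.expected_center] = h.crw_id
    # expected footprints around their centers, checked for overlap
    prev_end, prev_id = -1, ""
    for h in t.helices:
        center = h.expected_center * gene_length
        start = center - h.min_footprint / 2
        end = center + h.min_footprint / 2
        if start < prev_end:
            warnings.append(
                f"expected footprints of {prev_id} and {h.crw_id} overlap"
            )
        if end > gene_length:
            warnings.append(
                f"{h.crw_id} expected footprint extends past gene end"
            )
        prev_end, prev_id = end, h.crw_id
    total = sum(h.min_footprint for h in t.helices)
    if total > gene_length:
        warnings.append(
            f"summed minimal footprints ({total} nt) exceed gene length "
            f"({gene_length} nt)"
        )
    return warnings


def load_example_template(gene: str) -> StructureTemplate:
    """Load the packaged example template for rrnS or rrnL."""
    name = {"rrnS": "rrns_helices.tsv", "rrnL": "rrnl_helices.tsv"}[gene]
    with resources.as_file(
        resources.files("mitorrna.data").joinpath(name)
    ) as p:
        return parse_template(p)
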