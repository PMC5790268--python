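"""End-to-end orchestration: extract -> annotate -> align -> statistics.

The pipeline is configured by a flat key=value text file with a strict
schema (unknown keys are rejected — silent typos are the main field
failure mode).  All outputs are plain-text reports re-readable by the
package's own readers; a run log records versions, seed and the full
config echo.
"""

from __future__ import annotations

import importlib.metadata
import os
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np

from . import seq_io
from .annotate import annotate_sequence, annotation_report, to_dot_bracket
from .diagnostics import (
    chi_square_composition,
    diagnostics_report,
    saturation_test,
)
from .records import SeqRecord
from .stats import (
    classify_sites,
    compare_helix_across_taxa,
    conservation_table,
    helix_conservation,
)
from .structaln import (
    build_struct_alignment,
    strip_struct_alignment,
)
from .template import parse_template


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    template: str
    outdir: str
    fasta: str | None = None
    genbank: list[str] = field(default_factory=list)
    gene: str = "rrnS"
    gap_tolerance: float = 0.40
    reps: int = 50
    seed: int = 0
    allow_gu: bool = True
    hv_threshold: int = 15
    max_internal_break: int = 1
    diagnostics: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.gap_tolerance <= 1.0:
            raise ConfigError("gap_tolerance must be in [0,1]")
        if not self.fasta and not self.genbank:
            raise ConfigError("either 'fasta' or 'genbank' input is required")
        for path in [self.template, self.fasta, *self.genbank]:
            if path and not os.path.exists(path):
                raise ConfigError(f"input path does not exist: {path}")


_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


def parse_config(path: str | os.PathLike) -> PipelineConfig:
    """Parse the flat key=value pipeline config (strict schema)."""
    known = {f.name: f.type for f in dc_fields(PipelineConfig)}
    raw: dict[str, object] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected key = value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in known:
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
            if key == "genbank":
                raw[key] = value.split()
            elif key in ("gap_tolerance",):
                raw[key] = float(value)
            elif key in ("reps", "seed", "hv_threshold", "max_internal_break"):
                raw[key] = int(value)
            elif key in ("allow_gu", "diagnostics"):
                if value.lower() not in _BOOL:
                    raise ConfigError(f"{path}:{lineno}: bad boolean {value!r}")
                raw[key] = _BOOL[value.lower()]
            else:
                raw[key] = value
    try:
        return PipelineConfig(**raw)  # type: ignore[arg-type]
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run all stages; returns a map of report name -> file path."""
    os.makedirs(config.outdir, exist_ok=True)
    out: dict[str, str] = {}
    logl: list[str] = []

    def save(name: str, filename: str) -> str:
        path = os.path.join(config.outdir, filename)
        out[name] = path
        return path

    try:
        version = importlib.metadata.version("mitorrna")
    except importlib.metadata.PackageNotFoundError:
        version = "dev"
    logl.append(f"mitorrna {version} (numpy {np.__version__})")
    logl.append(f"seed {config.seed}")
    for f in dc_fields(PipelineConfig):
        logl.append(f"config {f.name} = {getattr(config, f.name)}")

    # ---- stage: input
    try:
        template = parse_template(config.template)
        records: list[SeqRecord] = []
        if config.fasta:
            records.extend(seq_io.read_fasta(config.fasta))
        for gb in config.genbank:
            records.append(seq_io.extract_rrna_gene(gb, config.gene))
    except Exception as exc:
        raise StageError("input", str(exc)) from exc
    logl.append(f"loaded {len(records)} sequences, template {template.gene} "
                f"with {len(template.helices)} helices")

    # ---- stage: annotation
    structures = []
    try:
        for rec in records:
            s = annotate_sequence(
                rec, template,
                allow_gu=config.allow_gu,
                max_internal_break=config.max_internal_break,
                hv_threshold=config.hv_threshold,
            )
            structures.append(s)
            with open(
                save(f"annotation:{rec.id}", f"annotation_{rec.id}.tsv"), "w"
            ) as fh:
                fh.write(annotation_report(s))
            with open(
                save(f"dotbracket:{rec.id}", f"{rec.id}.dotbracket"), "w"
            ) as fh:
                fh.write(
                    f">{rec.id}\n{rec.residues}\n"
                    f"{to_dot_bracket(s, len(rec.residues))}\n"
                )
            for w in s.warnings:
                logl.append(f"warning [{rec.id}]: {w}")
    except StageError:
        raise
    except Exception as exc:
        rec_id = records[len(structures)].id if records else "?"
        raise StageError("annotation", f"record {rec_id}: {exc}") from exc

    if len(records) < 2:
        logl.append(
            "warning: single-sequence input; alignment and statistics "
            "stages skipped"
        )
        with open(save("log", "run_log.txt"), "w") as fh:
            fh.write("\n".join(logl) + "\n")
        return out

    # ---- stage: structure alignment
    try:
        saln = build_struct_alignment(records, structures, template)
        seq_io.write_stockholm(
            saln.base,
            save("alignment", "structure_alignment.sto"),
            ss_cons=saln.ss_cons,
            per_column_labels=saln.column_region,
        )
        stripped, colmap = strip_struct_alignment(saln, config.gap_tolerance)
        seq_io.write_phylip(
            stripped.base, save("stripped", "stripped_alignment.phy")
        )
        with open(save("colmap", "column_map.tsv"), "w") as fh:
            fh.write("old_column\tnew_column\n")
            for old in sorted(colmap):
                fh.write(f"{old + 1}\t{colmap[old] + 1}\n")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("alignment", str(exc)) from exc
    logl.append(
        f"alignment: {saln.base.column_count} columns, "
        f"{stripped.base.column_count} after gap stripping at "
        f"{config.gap_tolerance:.0%} tolerance"
    )

    # ---- stage: conservation statistics
    try:
        with open(save("site_classes", "site_classes.tsv"), "w") as fh:
            fh.write(
                "alignment\tconserved\tvariable\tparsimony_informative"
                "\tsingleton\tcounted_sites\texcluded_sites\tgap_policy\n"
            )
            for name, aln in (
                ("structure", saln.base),
                ("stripped", stripped.base),
            ):
                sc = classify_sites(aln)
                row = sc.as_row()
                fh.write(
                    name + "\t"
                    + "\t".join(
                        str(row[k])
                        for k in (
                            "conserved", "variable", "parsimony_informative",
                            "singleton", "counted_sites", "excluded_sites",
                        )
                    )
                    + f"\t{sc.gap_policy}\n"
                )
        cons = conservation_table(saln)
        cons.to_csv(
            save("conservation", "helix_conservation.tsv"),
            sep="\t", index=False,
        )
        comp_frames = []
        for cid in cons["crw_id"]:
            hc = helix_conservation(saln, cid)
            df = hc.composition.copy()
            df.insert(0, "crw_id", cid)
            df.insert(1, "taxon", df.index)
            comp_frames.append(df)
        if comp_frames:
            import pandas as pd

            pd.concat(comp_frames).to_csv(
                save("composition_per_helix", "helix_composition.tsv"),
                sep="\t", index=False,
            )
        flag_rows = []
        for cid in cons["crw_id"]:
            df = compare_helix_across_taxa(structures, cid)
            df.insert(0, "crw_id", cid)
            flag_rows.append(df)
        if flag_rows:
            import pandas as pd

            flags = pd.concat(flag_rows)
            flags.to_csv(
                save("structure_outliers", "structure_outliers.tsv"),
                sep="\t", index=False,
            )
            flagged = sorted(set(flags[flags["flagged"]]["taxon"]))
            logl.append(f"structure outliers flagged: {flagged or 'none'}")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("statistics", str(exc)) from exc

    # ---- stage: diagnostics
    if config.diagnostics and len(records) >= 4:
        try:
            import pandas as pd

            tables = []
            for name, aln in (
                ("structure", saln.base),
                ("stripped", stripped.base),
            ):
                sat = saturation_test(
                    aln, reps=config.reps, seed=config.seed
                )
                tables.append(diagnostics_report(name, sat))
            pd.concat(tables).to_csv(
                save("saturation", "saturation.tsv"), sep="\t", index=False
            )
            comp = chi_square_composition(stripped.base)
            comp.per_taxon.to_csv(
                save("composition_test", "composition_test.tsv"),
                sep="\t", index=False,
            )
            logl.append(
                f"composition homogeneity: overall chi2 "
                f"{comp.overall_chi2:.2f} (df {comp.overall_df}, "
                f"p {comp.overall_p:.3g})"
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError("diagnostics", str(exc)) from exc

    with open(save("log", "run_log.txt"), "w") as fh:
        fh.write("\n".join(logl) + "\n")
    return out
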