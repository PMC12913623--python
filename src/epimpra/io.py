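"""File formats: library FASTA + manifest TSV, count tables, activity
tables, BED site export, QC JSON and the run configuration.

All tables are tab-separated with a header row; sequences travel as
FASTA.  Site intervals are 1-based closed in TSVs and 0-based half-open
in the BED export.  Readers validate against the design manifest where
one is supplied and report offending ids or line numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import DesignedElement, LibraryDesign, TemplateSeq
from .motifs import MotifDef

MANIFEST_COLUMNS = [
    "id",
    "class_label",
    "template_id",
    "motif_layout",
    "variant_info",
    "adapter_5",
    "adapter_3",
    "category",
]


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# library round-trip


def _layout_to_str(layout: Sequence[tuple[str, int, int]]) -> str:
    return ";".join(f"{name}:{copies}:{slot}" for name, copies, slot in layout)


def _layout_from_str(text: str) -> tuple[tuple[str, int, int], ...]:
    if not text:
        return ()
    out = []
    for part in text.split(";"):
        name, copies, slot = part.split(":")
        out.append((name, int(copies), int(slot)))
    return tuple(out)


def write_library(design: LibraryDesign, fasta_path: str | Path, manifest_path: str | Path) -> None:
    """Write element sequences as FASTA and the design manifest as TSV."""
    records = [
        SeqRecord(Seq(e.sequence), id=e.id, description="") for e in design.elements
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = []
    for e in design.elements:
        rows.append(
            {
                "id": e.id,
                "class_label": e.class_label,
                "template_id": e.template_id or "",
                "motif_layout": _layout_to_str(e.motif_layout),
                "variant_info": json.dumps(e.variant_info, sort_keys=True)
                if e.variant_info
                else "",
                "adapter_5": e.adapters[0],
                "adapter_3": e.adapters[1],
                "category": e.category or "",
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.insert(1, "seed", design.seed if design.seed is not None else "")
    with open(manifest_path, "w") as fh:
        header_meta = {
            "motifs": ";".join(f"{m.name}:{m.consensus}" for m in design.motif_set),
            "templates": ";".join(f"{t.id}:{t.sequence}:{t.source_coords}" for t in design.templates),
        }
        fh.write(f"#{json.dumps(header_meta, sort_keys=True)}\n")
        manifest.to_csv(fh, sep="\t", index=False)


def read_library(fasta_path: str | Path, manifest_path: str | Path) -> LibraryDesign:
    """Read a library back; FASTA and manifest must agree element-for-element."""
    sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    with open(manifest_path, newline="") as fh:
        first = fh.readline()
        meta: dict[str, str] = {}
        if first.startswith("#"):
            meta = json.loads(first[1:])
            manifest = pd.read_csv(fh, sep="\t", dtype=str).fillna("")
        else:
            fh.seek(0)
            manifest = pd.read_csv(fh, sep="\t", dtype=str).fillna("")
    manifest_ids = list(manifest["id"])
    missing_fasta = sorted(set(manifest_ids) - set(sequences))
    missing_manifest = sorted(set(sequences) - set(manifest_ids))
    if missing_fasta or missing_manifest:
        raise FormatError(
            f"FASTA/manifest mismatch: missing from FASTA {missing_fasta[:5]}, "
            f"missing from manifest {missing_manifest[:5]}"
        )
    elements = []
    for row in manifest.itertuples(index=False):
        variant_info = json.loads(row.variant_info) if row.variant_info else None
        elements.append(
            DesignedElement(
                id=row.id,
                class_label=row.class_label,
                sequence=sequences[row.id],
                motif_layout=_layout_from_str(row.motif_layout),
                template_id=row.template_id or None,
                variant_info=variant_info,
                adapters=(row.adapter_5, row.adapter_3),
                category=row.category or None,
            )
        )
    motif_set = []
    if meta.get("motifs"):
        for part in meta["motifs"].split(";"):
            name, consensus = part.split(":")
            motif_set.append(MotifDef(name, consensus))
    templates = []
    if meta.get("templates"):
        for part in meta["templates"].split(";"):
            tid, seq, coords = part.split(":", 2)
            templates.append(TemplateSeq(tid, seq, coords))
    seed_text = str(manifest["seed"].iloc[0]) if "seed" in manifest.columns and len(manifest) else ""
    seed = int(float(seed_text)) if seed_text not in ("", "nan") else None
    return LibraryDesign(elements=elements, motif_set=motif_set, templates=templates, seed=seed)


# ---------------------------------------------------------------------------
# count / barcode / activity tables


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path, manifest_ids: Iterable[str] | None = None) -> pd.DataFrame:
    """Read a tidy count TSV, validating count values.

    Negative or non-integer counts raise :class:`FormatError` naming the
    first offending line.  With ``manifest_ids``, unknown elements are
    collected into the frame's ``quarantined`` attr instead of failing.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"element_id", "sample", "assay", "count"}
    if not required.issubset(df.columns):
        raise FormatError(f"count table missing columns: {sorted(required - set(df.columns))}")
    values = pd.to_numeric(df["count"], errors="coerce")
    bad = values.isna() | (values < 0) | (values % 1 != 0)
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise FormatError(f"invalid count {df['count'].iloc[bad.idxmax()]!r} at line {line}")
    df["count"] = values.astype(int)
    df.attrs["quarantined"] = []
    if manifest_ids is not None:
        known = set(manifest_ids)
        unknown = sorted(set(df["element_id"]) - known)
        if unknown:
            df.attrs["quarantined"] = unknown
            df = df[df["element_id"].isin(known)].reset_index(drop=True)
            df.attrs["quarantined"] = unknown
    return df


def write_barcode_counts(barcodes: pd.DataFrame, path: str | Path) -> None:
    barcodes.to_csv(path, sep="\t", index=False)


def read_barcode_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"element_id", "barcode", "sample", "dna_count", "rna_count"}
    if not required.issubset(df.columns):
        raise FormatError(f"barcode table missing columns: {sorted(required - set(df.columns))}")
    for col in ("dna_count", "rna_count"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values < 0) | (values % 1 != 0)
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise FormatError(f"invalid {col} {df[col].iloc[bad.idxmax()]!r} at line {line}")
        df[col] = values.astype(int)
    return df


def write_activity(activity: pd.DataFrame, path: str | Path) -> None:
    activity.to_csv(path, sep="\t", index=False)


def read_activity(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_qc_report(report: Mapping[str, object], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# BED export for site calls


def sites_to_bed(sites: pd.DataFrame, path: str | Path) -> None:
    """Write site calls (1-based closed ``start``/``end``) as 0-based
    half-open BED with the extreme MAD value in the score column."""
    with open(path, "w") as fh:
        for row in sites.itertuples(index=False):
            name = f"{row.assay}_site"
            strand = "+" if row.sign > 0 else "-"
            fh.write(
                f"{row.cre_id}\t{row.start - 1}\t{row.end}\t{name}\t{row.extreme_mad:.4f}\t{strand}\n"
            )


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Pipeline thresholds, seeds and paths (YAML-serializable).

    Unknown keys are rejected so silent typos cannot change an analysis.
    """

    out_dir: str = "results"
    seed: int = 1
    n_motifs: int = 9
    n_replicates: int = 3
    assays: tuple[str, ...] = ("mpra", "atac", "cuttag")
    min_barcodes: int = 5
    min_inserted: int = 5
    trend_fdr: float = 0.05
    synergy_fdr: float = 0.01
    anova_fdr: float = 0.01
    variant_p: float = 0.01
    n_extreme: int = 200
    peak_threshold: float = 0.75
    sigma: float = 2.0
    inserted_depth: float = 400.0
    enriched_depth: float = 50.0
    dispersion: float = 0.1
    noise_sd: float = 0.15

    def __post_init__(self) -> None:
        for name in (
            "min_barcodes",
            "min_inserted",
            "trend_fdr",
            "synergy_fdr",
            "anova_fdr",
            "variant_p",
            "n_extreme",
            "peak_threshold",
            "sigma",
        ):
            if getattr(self, name) is None or getattr(self, name) < 0:
                raise ValueError(f"config key {name} must be nonnegative")
        self.assays = tuple(self.assays)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise FormatError(f"unknown config keys: {unknown}")
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    data = {f.name: getattr(config, f.name) for f in fields(RunConfig)}
    data["assays"] = list(config.assays)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
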