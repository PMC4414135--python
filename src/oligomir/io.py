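"""Plain-text readers and writers for the pipeline's tabular formats.

Panel TSV / GFF3, differential-set lists, GMT gene sets, group mappings,
target-score TSV, expression TSV, survival TSV and the ground-truth JSON
sidecar.  All formats are uncompressed tab-separated or JSON text.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .enrichment import Pathway, PathwayCollection, TargetScoreTable, UNASSIGNED
from .locus import ArrayPanel, DifferentialMirSet, MirRecord
from .suppression import ExpressionMatrix
from .survival import SurvivalRecord

PANEL_COLUMNS = ["mir_id", "chrom", "start", "end", "locus_label"]


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------- panel

def write_panel_tsv(panel: ArrayPanel, path: str | Path) -> None:
    rows = [
        {
            "mir_id": r.mir_id,
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "locus_label": r.locus_label,
        }
        for r in panel.records
    ]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def load_panel(path: str | Path, name: str | None = None) -> ArrayPanel:
    """Load a panel from TSV (header mir_id/chrom/start/end/locus_label)
    or GFF3 (extension .gff/.gff3, `locus=` attribute)."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _load_panel_gff3(path, name=name or path.stem)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty panel file") from None
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ParseError(f"{path}: panel has no records")
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                MirRecord(
                    mir_id=str(row.mir_id),
                    chrom=str(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    locus_label="" if pd.isna(row.locus_label) else str(row.locus_label),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path} line {lineno}: {exc}") from None
    try:
        return ArrayPanel(records=tuple(records), name=name or path.stem)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_panel_gff3(panel: ArrayPanel, path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for r in panel.records:
        attrs = f"ID={r.mir_id};Name={r.mir_id}"
        if r.locus_label:
            attrs += f";locus={r.locus_label}"
        lines.append(
            "\t".join(
                [r.chrom, "oligomir", "miRNA", str(r.start), str(r.end), ".", "+",
                 ".", attrs]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _load_panel_gff3(path: Path, name: str) -> ArrayPanel:
    records = []
    text = path.read_text().splitlines()
    if not any(line.strip() and not line.startswith("#") for line in text):
        raise ParseError(f"{path}: empty panel file")
    for lineno, line in enumerate(text, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(f"{path} line {lineno}: expected 9 GFF3 columns")
        chrom, _, _, start, end, _, _, _, attrs = fields
        attr = {}
        for item in attrs.split(";"):
            if "=" in item:
                k, v = item.split("=", 1)
                attr[k.strip()] = v.strip()
        mir_id = attr.get("ID") or attr.get("Name")
        if not mir_id:
            raise ParseError(f"{path} line {lineno}: no ID/Name attribute")
        try:
            records.append(
                MirRecord(mir_id, chrom, int(start), int(end), attr.get("locus", ""))
            )
        except ValueError as exc:
            raise ParseError(f"{path} line {lineno}: {exc}") from None
    try:
        return ArrayPanel(records=tuple(records), name=name)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


# ------------------------------------------------------- differential sets

def write_mir_list(diff: DifferentialMirSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(diff.mir_ids)) + "\n")


def load_mir_list(path: str | Path, dataset_label: str | None = None) -> DifferentialMirSet:
    path = Path(path)
    ids = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not ids:
        raise ParseError(f"{path}: empty differential set")
    return DifferentialMirSet(
        dataset_label=dataset_label or path.stem, mir_ids=frozenset(ids)
    )


# ---------------------------------------------------------------- GMT

def write_gmt(pathways: PathwayCollection, path: str | Path) -> None:
    """Standard GMT: name <tab> description <tab> gene1 <tab> gene2 ...

    The functional group rides in the description field as ``group=XXX``.
    """
    lines = []
    for pid in pathways.ids():
        pw = pathways[pid]
        desc = f"{pw.name}|group={pw.group}"
        lines.append("\t".join([pid, desc] + sorted(pw.genes)))
    Path(path).write_text("\n".join(lines) + "\n")


def load_gmt(path: str | Path) -> PathwayCollection:
    out = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path} line {lineno}: GMT needs id, description, genes")
        pid, desc, *genes = fields
        group = UNASSIGNED
        name = desc
        if "|group=" in desc:
            name, group = desc.rsplit("|group=", 1)
        out[pid] = Pathway(pid, name, frozenset(genes), group)
    if not out:
        raise ParseError(f"{path}: empty GMT file")
    return PathwayCollection(out)


def write_group_mapping(mapping: dict[str, str], path: str | Path) -> None:
    df = pd.DataFrame(
        sorted(mapping.items()), columns=["pathway_id", "group"]
    )
    df.to_csv(path, sep="\t", index=False)


def load_group_mapping(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"pathway_id", "group"}.issubset(df.columns):
        raise ParseError(f"{path}: need columns pathway_id, group")
    return dict(zip(df["pathway_id"], df["group"]))


# ----------------------------------------------------------- target scores

def write_target_scores(table: TargetScoreTable, path: str | Path) -> None:
    table.scores.to_csv(path, sep="\t", index=False, float_format="%.6f")


def load_target_scores(
    path: str | Path, universe: set[str] | None = None
) -> TargetScoreTable:
    df = pd.read_csv(path, sep="\t", dtype={"mir_id": str, "gene_id": str})
    return TargetScoreTable.from_frame(df, universe=universe)


# ------------------------------------------------------------- expression

def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id", float_format="%.6f")


def load_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    return ExpressionMatrix(values=df)


# --------------------------------------------------------------- survival

def write_survival(records: list[SurvivalRecord], path: str | Path) -> None:
    mirs = sorted({m for r in records for m in r.expr})
    rows = []
    for r in records:
        row = {"id": r.patient_id, "time_months": r.time, "event": r.event}
        for m in mirs:
            row[f"expr_{m}"] = r.expr.get(m, float("nan"))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")


def load_survival(path: str | Path) -> list[SurvivalRecord]:
    df = pd.read_csv(path, sep="\t")
    need = {"id", "time_months", "event"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: need columns {sorted(need)}")
    expr_cols = [c for c in df.columns if c.startswith("expr_")]
    out = []
    for row in df.to_dict("records"):
        expr = {c[len("expr_"):]: float(row[c]) for c in expr_cols}
        out.append(
            SurvivalRecord(
                patient_id=str(row["id"]),
                time=float(row["time_months"]),
                event=int(row["event"]),
                expr=expr,
            )
        )
    return out


# ------------------------------------------------------------------ JSON

def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_json(path: str | Path):
    return json.loads(Path(path).read_text())
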