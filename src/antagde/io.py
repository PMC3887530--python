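"""Readers and writers for the tab-separated interchange formats.

Formats:

* expression matrix TSV — first column gene id, one column per sample;
* sample sheet TSV — columns ``sample``, ``genotype``, ``replicate``;
* annotation TSV — columns ``gene``, ``chrom``, ``strand``, ``tss``,
  ``start``, ``end`` (1-based inclusive coordinates), optional ``category``;
* detection-call TSV — same axes as the matrix, cells in {P, M, A};
* BED3+ peak files — 0-based half-open intervals.

Parse failures raise :class:`~antagde.core.ValidationError` naming the
offending row or column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import DetectionCalls, ExpressionMatrix, ValidationError

ANNOTATION_COLUMNS = ["chrom", "strand", "tss", "start", "end"]


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in ("chrom",) if c not in ann.columns]
    if missing:
        raise ValidationError(f"annotation {path} lacks columns {missing}")
    if ann.index.has_duplicates:
        dups = ann.index[ann.index.duplicated()][:5].tolist()
        raise ValidationError(f"annotation {path}: duplicate gene ids {dups}")
    return ann


def read_expression_matrix(matrix_path, sample_sheet_path, annotation_path) -> ExpressionMatrix:
    """Load and validate an expression bundle.

    Rows whose chromosome label is not one of I–V, X are rejected, and every
    matrix column must appear in the sample sheet (and vice versa).
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0)
    for col in raw.columns:
        if not np.issubdtype(raw[col].dtype, np.number):
            bad_rows = raw.index[pd.to_numeric(raw[col], errors="coerce").isna()][:3].tolist()
            raise ValidationError(
                f"non-numeric cells in column {col!r}, e.g. rows {bad_rows}"
            )
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    if "sample" not in sheet.columns:
        raise ValidationError(f"sample sheet {sample_sheet_path} lacks a 'sample' column")
    sheet = sheet.set_index("sample")
    unknown = set(raw.columns) - set(sheet.index)
    if unknown:
        raise ValidationError(f"samples missing from sheet: {sorted(unknown)}")
    unused = set(sheet.index) - set(raw.columns)
    if unused:
        raise ValidationError(f"sheet samples absent from matrix: {sorted(unused)}")
    sheet = sheet.loc[raw.columns]

    ann = read_annotation(annotation_path)
    missing_genes = raw.index.difference(ann.index)
    if len(missing_genes):
        raise ValidationError(
            f"genes missing from annotation, e.g. {missing_genes[:5].tolist()}"
        )
    ann = ann.loc[raw.index]
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()][:5].tolist()
        raise ValidationError(f"duplicate gene ids without a probe-set mapping: {dups}")
    return ExpressionMatrix(raw.astype(float), sheet, ann)


def write_expression_matrix(matrix: ExpressionMatrix, matrix_path, sample_sheet_path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(matrix_path, sep="\t", float_format="%.6f")
    sheet = matrix.samples.copy()
    sheet.index.name = "sample"
    sheet.to_csv(sample_sheet_path, sep="\t")


def write_annotation(ann: pd.DataFrame, path) -> None:
    out = ann.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_detection_calls(path) -> DetectionCalls:
    return DetectionCalls(pd.read_csv(path, sep="\t", index_col=0))


def write_detection_calls(calls: DetectionCalls, path) -> None:
    out = calls.labels.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file into a (chrom, start, end) frame, 0-based half-open."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{i}: expected ≥3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValidationError(f"{path}:{i}: start {start} ≥ end {end}")
            rows.append((chrom, start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_bed(intervals: pd.DataFrame, path) -> None:
    intervals[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def write_gene_set(gene_set, tables: dict[str, pd.DataFrame], path) -> None:
    """One TSV per gene set: members with their defining contrast statistics."""
    rows = pd.DataFrame(index=pd.Index(gene_set.sorted_members(), name="gene"))
    for label, table in tables.items():
        sub = table.set_index("gene").loc[rows.index]
        rows[f"log2fc_{label}"] = sub["log2fc"].to_numpy()
        rows[f"q_{label}"] = sub["q"].to_numpy()
        if "chrom" not in rows.columns and "chrom" in sub.columns:
            rows.insert(0, "chrom", sub["chrom"].to_numpy())
    rows.to_csv(path, sep="\t")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
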