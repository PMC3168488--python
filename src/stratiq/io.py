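"""Readers and writers for the pipeline's plain-text interchange formats.

Formats:

* expression matrix — TSV, first column ``probe_id``, header row of sample ids
* sample sheet — TSV with columns sample_id, line, tissue, diet, replicate
* probe annotation — TSV with columns probe_id, gene_id, symbol, chromosome,
  position_bp (empty gene_id/symbol mark unidentified probes)
* QTL intervals — BED (0-based half-open); converted on read to the internal
  1-based inclusive convention
* gene sets — GMT (name, description, tab-separated members)
"""

from __future__ import annotations

import os
from typing import Union

import pandas as pd

from .data import (
    ANNOTATION_COLUMNS,
    ExpressionStudy,
    GeneSetCollection,
    QtlInterval,
    SampleInfo,
    ValidationError,
    validate_annotation,
)

PathLike = Union[str, os.PathLike]

SAMPLE_SHEET_COLUMNS = ("sample_id", "line", "tissue", "diet", "replicate")


def load_study(matrix_path: PathLike, sample_sheet_path: PathLike) -> ExpressionStudy:
    """Load an expression matrix plus sample sheet into a validated study.

    The design (snapshot vs quantitative) is auto-detected from the
    replicate structure of the sample sheet.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    mat.index = mat.index.astype(str)
    mat.columns = mat.columns.astype(str)
    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype=str)
    for col in SAMPLE_SHEET_COLUMNS:
        if col not in sheet.columns:
            raise ValidationError(f"sample sheet missing column {col!r}")
    samples = [
        SampleInfo(
            sample_id=row.sample_id,
            line=row.line,
            tissue=row.tissue,
            diet=row.diet,
            replicate=int(row.replicate),
        )
        for row in sheet.itertuples()
    ]
    return ExpressionStudy(intensities=mat, samples=samples)


def write_study(study: ExpressionStudy, matrix_path: PathLike, sample_sheet_path: PathLike) -> None:
    """Write a study back to matrix + sample sheet TSVs (round-trip exact)."""
    mat = study.intensities.copy()
    mat.index.name = "probe_id"
    mat.to_csv(matrix_path, sep="\t")
    rows = [
        (s.sample_id, s.line, s.tissue, s.diet, s.replicate) for s in study.samples
    ]
    pd.DataFrame(rows, columns=list(SAMPLE_SHEET_COLUMNS)).to_csv(
        sample_sheet_path, sep="\t", index=False
    )


def load_annotation(path: PathLike) -> pd.DataFrame:
    """Load a probe-annotation TSV, indexed by probe_id."""
    ann = pd.read_csv(
        path,
        sep="\t",
        dtype={"probe_id": str, "gene_id": str, "symbol": str, "chromosome": str},
    )
    for col in ("probe_id",) + ANNOTATION_COLUMNS:
        if col not in ann.columns:
            raise ValidationError(f"annotation missing column {col!r}")
    return validate_annotation(ann)


def write_annotation(annotation: pd.DataFrame, path: PathLike) -> None:
    ann = validate_annotation(annotation).copy()
    ann.index.name = "probe_id"
    ann.to_csv(path, sep="\t")


def load_intervals(path: PathLike) -> list[QtlInterval]:
    """Load QTL intervals from a BED-like 4-column file.

    BED coordinates are 0-based half-open; they are converted to the
    internal 1-based inclusive convention (start+1, end). Overlapping
    intervals are retained unmerged; an empty file yields an empty list.
    """
    intervals: list[QtlInterval] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValidationError(
                    f"{path}: line {lineno}: expected 4 columns (chrom start end name)"
                )
            chrom, start, end, name = fields[:4]
            try:
                start_bp, end_bp = int(start), int(end)
            except ValueError as exc:
                raise ValidationError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            if start_bp > end_bp:
                raise ValidationError(
                    f"{path}: line {lineno}: start {start_bp} > end {end_bp}"
                )
            if name in seen:
                raise ValidationError(f"{path}: line {lineno}: duplicate name {name!r}")
            seen.add(name)
            intervals.append(
                QtlInterval(name=name, chromosome=chrom, start_bp=start_bp + 1, end_bp=end_bp)
            )
    return intervals


def write_intervals(intervals: list[QtlInterval], path: PathLike) -> None:
    """Write intervals as BED (converting back from 1-based inclusive)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chromosome}\t{iv.start_bp - 1}\t{iv.end_bp}\t{iv.name}\n")


def load_gene_sets(path: PathLike, source: str | None = None) -> GeneSetCollection:
    """Load a GMT gene-set collection; duplicate members within a line collapse."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, desc = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            if name in sets:
                raise ValidationError(f"{path}: line {lineno}: duplicate set {name!r}")
            if not members:
                raise ValidationError(f"{path}: line {lineno}: set {name!r} is empty")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, source=source, descriptions=descriptions)


def write_gene_sets(collection: GeneSetCollection, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")
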