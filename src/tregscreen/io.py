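"""Readers and writers for the pipeline's interchange formats.

Plate tables are plain CSV (comma-separated, UTF-8, "." decimal); expression
matrices use GCT 1.2; gene sets use GMT. Readers validate on the way in and
raise :class:`FormatError` / :class:`ValidationError` with actionable messages;
every writer/reader pair is an inverse on valid data.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .datamodel import (
    Assay,
    ExpressionMatrix,
    FormatError,
    GeneSet,
    PlateGrid,
    ScreenBatch,
    ValidationError,
    Well,
    WellRole,
)

logger = logging.getLogger(__name__)

PLATE_CSV_COLUMNS = [
    "plate_id",
    "batch_id",
    "assay",
    "row",
    "col",
    "role",
    "compound_id",
    "dose_uM",
    "pct_positive",
    "live_cells",
]

#: plate_id convention for a batch's dedicated 48+48 control plate
CONTROL_PLATE_SUFFIX = "_CTRL"


def read_plate_table(path: str | Path) -> list[ScreenBatch]:
    """Read a plate-level well CSV into validated :class:`ScreenBatch` objects.

    The control plate of each batch is recognised by the ``_CTRL`` plate-id
    suffix. Unknown roles or assays and out-of-range measurements are rejected.
    """
    df = pd.read_csv(path, dtype={"plate_id": str, "batch_id": str, "row": str})
    missing = [c for c in PLATE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    batches: list[ScreenBatch] = []
    for batch_id, bdf in df.groupby("batch_id", sort=True):
        plates: list[PlateGrid] = []
        control_plate: PlateGrid | None = None
        for plate_id, pdf in bdf.groupby("plate_id", sort=True):
            wells = [_well_from_row(rec) for rec in pdf.to_dict("records")]
            assays = pdf["assay"].unique()
            if len(assays) != 1:
                raise ValidationError(
                    f"plate {plate_id}: mixed assay labels {sorted(assays)}"
                )
            try:
                assay = Assay(assays[0])
            except ValueError:
                raise FormatError(
                    f"plate {plate_id}: unknown assay {assays[0]!r}"
                ) from None
            grid = PlateGrid(str(plate_id), str(batch_id), assay, wells)
            if str(plate_id).endswith(CONTROL_PLATE_SUFFIX):
                control_plate = grid
            else:
                plates.append(grid)
        if control_plate is None:
            raise ValidationError(
                f"batch {batch_id}: no control plate "
                f"(expected a plate_id ending in {CONTROL_PLATE_SUFFIX!r})"
            )
        batches.append(ScreenBatch(str(batch_id), plates, control_plate))
    logger.info("read %d batches, %d wells from %s", len(batches), len(df), path)
    return batches


def _well_from_row(rec: dict) -> Well:
    try:
        role = WellRole(rec["role"])
    except ValueError:
        raise FormatError(
            f"well {rec['plate_id']}:{rec['row']}{rec['col']}: "
            f"unknown role {rec['role']!r}"
        ) from None
    compound = rec.get("compound_id")
    if compound is None or (isinstance(compound, float) and np.isnan(compound)):
        compound = None
    dose = rec.get("dose_uM")
    if dose is None or (isinstance(dose, float) and np.isnan(dose)):
        dose = None
    return Well(
        plate_id=str(rec["plate_id"]),
        row=str(rec["row"]),
        col=int(rec["col"]),
        role=role,
        compound_id=None if compound is None else str(compound),
        dose_uM=None if dose is None else float(dose),
        pct_positive=float(rec["pct_positive"]),
        live_cells=float(rec["live_cells"]),
    )


def write_plate_table(batches: Iterable[ScreenBatch], path: str | Path) -> None:
    df = pd.concat([b.to_frame() for b in batches], ignore_index=True)
    df[PLATE_CSV_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GCT 1.2


def read_gct(path: str | Path) -> ExpressionMatrix:
    """Read a GCT 1.2 expression matrix (``#1.2`` header, dimension line,
    Name/Description columns)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(f"{path}: not a GCT 1.2 file (first line {version!r})")
        dims = fh.readline().split("\t")
        if len(dims) < 2:
            raise FormatError(f"{path}: malformed GCT dimension line")
        try:
            n_genes, n_samples = int(dims[0]), int(dims[1])
        except ValueError:
            raise FormatError(f"{path}: non-integer GCT dimensions") from None
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "Name":
            raise FormatError(f"{path}: GCT header must start with Name\\tDescription")
        sample_ids = header[2:]
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            gene_ids.append(parts[0])
            rows.append([float(x) for x in parts[2:]])
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(sample_ids)))
    if values.shape != (n_genes, n_samples) or len(sample_ids) != n_samples:
        raise FormatError(
            f"{path}: dimension line claims {n_genes}x{n_samples}, "
            f"parsed {values.shape[0]}x{len(sample_ids)}"
        )
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_gct(matrix: ExpressionMatrix, path: str | Path) -> None:
    n_genes, n_samples = matrix.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#1.2\n")
        fh.write(f"{n_genes}\t{n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
        for g, row in zip(matrix.gene_ids, matrix.values):
            fh.write(g + "\tna\t" + "\t".join(repr(float(x)) for x in row) + "\n")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (tab-separated: name, description, genes...).

    Duplicate genes within a line are deduplicated with a logged warning.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields "
                    f"(name, description, genes...), found {len(parts)}"
                )
            name, genes = parts[0], [g for g in parts[2:] if g]
            if len(set(genes)) != len(genes):
                logger.warning(
                    "%s:%d: gene set %s contains duplicate genes; deduplicated",
                    path,
                    lineno,
                    name,
                )
            sets.append(GeneSet.from_genes(name, genes))
    return sets


def write_gmt(gene_sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in gene_sets:
            fh.write(gs.name + "\tna\t" + "\t".join(sorted(gs.gene_ids)) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-gene-per-line universe file."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(g + "\n")
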