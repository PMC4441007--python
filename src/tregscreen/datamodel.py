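"""Shared domain types for the screening pipeline.

The screen measures percent lineage-positive cells (e.g. %FOXP3+ for the
regulatory T-cell lineage) and live-cell counts per well of 96-well plates.
Each plate carries positive controls (near-maximal cytokine-driven
differentiation), negative controls (sub-maximal conditions), and
compound-treated wells; each batch additionally carries a dedicated control
plate of 48 positive and 48 negative control wells.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "WellRole",
    "Assay",
    "Well",
    "PlateGrid",
    "ScreenBatch",
    "ExpressionMatrix",
    "GeneSet",
    "ValidationError",
    "FormatError",
]

ROWS = "ABCDEFGH"
N_COLS = 12


class ValidationError(ValueError):
    """Input violates a domain invariant (e.g. percent outside [0, 100])."""


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class WellRole(enum.Enum):
    POS_CTRL = "POS_CTRL"
    NEG_CTRL = "NEG_CTRL"
    COMPOUND = "COMPOUND"
    DMSO = "DMSO"


class Assay(enum.Enum):
    """Differentiation condition of a plate.

    *_LOW are sub-maximal cytokine conditions (enhancement read-out),
    *_HI near-maximal (inhibition read-out), TH0 no lineage-driving cytokines.
    """

    TREG_LOW = "TREG_LOW"
    TREG_HI = "TREG_HI"
    TH1_LOW = "TH1_LOW"
    TH1_HI = "TH1_HI"
    TH17_LOW = "TH17_LOW"
    TH17_HI = "TH17_HI"
    TH0 = "TH0"


@dataclass(frozen=True)
class Well:
    """One well of a 96-well screen plate."""

    plate_id: str
    row: str  # letter A-H
    col: int  # 1-12
    role: WellRole
    pct_positive: float  # percent lineage-positive cells, in [0, 100]
    live_cells: float  # nonnegative live-cell count
    compound_id: str | None = None
    dose_uM: float | None = None

    def __post_init__(self) -> None:
        if self.row not in ROWS:
            raise ValidationError(
                f"well {self.plate_id}:{self.row}{self.col}: row must be one of {ROWS!r}"
            )
        if not 1 <= self.col <= N_COLS:
            raise ValidationError(
                f"well {self.plate_id}:{self.row}{self.col}: column must be in 1..{N_COLS}"
            )
        if not 0.0 <= self.pct_positive <= 100.0:
            raise ValidationError(
                f"well {self.plate_id}:{self.row}{self.col}: "
                f"pct_positive={self.pct_positive} outside [0, 100]"
            )
        if self.live_cells < 0:
            raise ValidationError(
                f"well {self.plate_id}:{self.row}{self.col}: negative live_cells"
            )
        if self.role is WellRole.COMPOUND and not self.compound_id:
            raise ValidationError(
                f"well {self.plate_id}:{self.row}{self.col}: "
                "role=COMPOUND requires a compound_id"
            )

    @property
    def position(self) -> str:
        return f"{self.row}{self.col}"


@dataclass
class PlateGrid:
    """One 96-well plate with its role annotations."""

    plate_id: str
    batch_id: str
    assay: Assay
    wells: list[Well] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for w in self.wells:
            if w.position in seen:
                raise ValidationError(
                    f"plate {self.plate_id}: duplicate well position {w.position}"
                )
            seen.add(w.position)

    def count_role(self, role: WellRole) -> int:
        return sum(1 for w in self.wells if w.role is role)

    def validate_controls(self, min_each: int = 8) -> None:
        n_pos = self.count_role(WellRole.POS_CTRL)
        n_neg = self.count_role(WellRole.NEG_CTRL)
        if n_pos < min_each or n_neg < min_each:
            raise ValidationError(
                f"plate {self.plate_id}: needs >= {min_each} wells of each control "
                f"role, found {n_pos} POS_CTRL and {n_neg} NEG_CTRL"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plate_id": [w.plate_id for w in self.wells],
                "batch_id": self.batch_id,
                "assay": self.assay.value,
                "row": [w.row for w in self.wells],
                "col": [w.col for w in self.wells],
                "role": [w.role.value for w in self.wells],
                "compound_id": [w.compound_id for w in self.wells],
                "dose_uM": [w.dose_uM for w in self.wells],
                "pct_positive": [w.pct_positive for w in self.wells],
                "live_cells": [w.live_cells for w in self.wells],
            }
        )


@dataclass
class ScreenBatch:
    """All plates of one experimental batch plus its dedicated control plate."""

    batch_id: str
    plates: list[PlateGrid]
    control_plate: PlateGrid

    CONTROL_PLATE_N_EACH = 48

    def __post_init__(self) -> None:
        n_pos = self.control_plate.count_role(WellRole.POS_CTRL)
        n_neg = self.control_plate.count_role(WellRole.NEG_CTRL)
        if n_pos != self.CONTROL_PLATE_N_EACH or n_neg != self.CONTROL_PLATE_N_EACH:
            raise ValidationError(
                f"batch {self.batch_id}: control plate must hold exactly "
                f"{self.CONTROL_PLATE_N_EACH} wells of each control role, "
                f"found {n_pos} POS_CTRL and {n_neg} NEG_CTRL"
            )

    def to_frame(self, include_control_plate: bool = True) -> pd.DataFrame:
        frames = [p.to_frame() for p in self.plates]
        if include_control_plate:
            frames.append(self.control_plate.to_frame())
        return pd.concat(frames, ignore_index=True)


class ExpressionMatrix:
    """Genes x samples matrix of log2-scale expression with sample group labels."""

    def __init__(
        self,
        gene_ids: Iterable[str],
        sample_ids: Iterable[str],
        values: np.ndarray,
        group_of_sample: Mapping[str, str] | None = None,
    ) -> None:
        self.gene_ids = list(gene_ids)
        self.sample_ids = list(sample_ids)
        self.values = np.asarray(values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene_ids must be unique")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        self.group_of_sample = dict(group_of_sample or {})

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_of_sample.get(s) == group]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in genes]
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in keep if g not in idx]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing[:10]}")
        rows = [idx[g] for g in keep]
        return ExpressionMatrix(
            keep, self.sample_ids, self.values[rows, :], self.group_of_sample
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (e.g. disease-locus genes from a GMT file)."""

    name: str
    gene_ids: frozenset[str]

    @classmethod
    def from_genes(cls, name: str, genes: Iterable[str]) -> "GeneSet":
        return cls(name=name, gene_ids=frozenset(genes))

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene: str) -> bool:
        return gene in self.gene_ids
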