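"""Domain records and table I/O for the retinal PSE growth analysis.

The unit record is one embryo at one developmental stage
(:class:`StageMeasurement`): the 3D morphometric quantities produced by
tissue-wide segmentation — tissue volume, apical and total surface area,
thickness sampled at several positions, total and mitotic cell counts,
mitotic-cell diameters, and the nuclear-zone geometry.  All lengths are in
μm, areas in μm², volumes in μm³, and developmental time in hours post
fertilization (hpf).  No unit auto-detection is attempted.

Tables are exchanged as plain CSV in a fixed dialect (see
:func:`read_stage_table` / :func:`write_stage_table`); mitotic diameters
travel in a long-format companion file because their number varies per
retina (typically 15–20 measured cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._errors import SchemaError, ValidationError

__all__ = [
    "StageMeasurement",
    "StageTable",
    "read_stage_table",
    "write_stage_table",
    "STAGE_TABLE_COLUMNS",
]

#: hpf values are grouped after rounding to this resolution (tables are stage-binned)
STAGE_ROUND_H = 0.1

_N_THICKNESS_COLS = 5

STAGE_TABLE_COLUMNS = (
    ["embryo_id", "stage_hpf", "tissue_volume_um3", "apical_area_um2", "total_surface_area_um2"]
    + [f"thickness_um_{i}" for i in range(1, _N_THICKNESS_COLS + 1)]
    + ["n_cells", "n_mitotic", "nuclear_zone_height_um", "nuclear_long_axis_um"]
)

DIAMETER_COLUMNS = ["embryo_id", "stage_hpf", "diameter_um"]


def round_stage(stage_hpf: float) -> float:
    return round(float(stage_hpf) / STAGE_ROUND_H) * STAGE_ROUND_H


@dataclass
class StageMeasurement:
    """Morphometric record for one embryo at one stage.

    Invariants (enforced on construction):

    * all lengths/areas/volumes strictly positive,
    * ``apical_area < total_surface_area`` (the basal area is their difference),
    * ``0 <= n_mitotic <= n_cells``,
    * at least one thickness sample.

    ``mitotic_diameters`` may be empty — only a subset of cells per retina is
    measured — and operations that need them raise ``MissingDataError``.
    """

    embryo_id: str
    stage_hpf: float
    tissue_volume: float
    apical_area: float
    total_surface_area: float
    thickness_samples: list[float]
    n_cells: int
    n_mitotic: int
    nuclear_zone_height: float
    nuclear_long_axis: float
    mitotic_diameters: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.thickness_samples = [float(t) for t in self.thickness_samples]
        self.mitotic_diameters = [float(d) for d in self.mitotic_diameters]
        self.validate()

    def validate(self) -> None:
        pos = {
            "tissue_volume": self.tissue_volume,
            "apical_area": self.apical_area,
            "total_surface_area": self.total_surface_area,
            "nuclear_zone_height": self.nuclear_zone_height,
            "nuclear_long_axis": self.nuclear_long_axis,
        }
        for name, value in pos.items():
            if not (math.isfinite(value) and value > 0):
                raise ValidationError(f"{name} must be positive and finite, got {value!r}")
        if not self.thickness_samples:
            raise ValidationError("thickness_samples must contain at least one value")
        if any(not (math.isfinite(t) and t > 0) for t in self.thickness_samples):
            raise ValidationError(f"thickness_samples must be positive: {self.thickness_samples}")
        if any(not (math.isfinite(d) and d > 0) for d in self.mitotic_diameters):
            raise ValidationError(f"mitotic_diameters must be positive: {self.mitotic_diameters}")
        if self.apical_area >= self.total_surface_area:
            raise ValidationError(
                f"apical_area ({self.apical_area}) must be smaller than "
                f"total_surface_area ({self.total_surface_area})"
            )
        if not (0 <= self.n_mitotic <= self.n_cells):
            raise ValidationError(
                f"need 0 <= n_mitotic <= n_cells, got {self.n_mitotic} / {self.n_cells}"
            )

    @property
    def basal_area(self) -> float:
        return self.total_surface_area - self.apical_area

    @property
    def stage_key(self) -> float:
        return round_stage(self.stage_hpf)


@dataclass
class StageTable:
    """A collection of :class:`StageMeasurement` rows across stages."""

    rows: list[StageMeasurement]

    @property
    def stages(self) -> list[float]:
        return sorted({r.stage_key for r in self.rows})

    def __len__(self) -> int:
        return len(self.rows)

    def at_stage(self, stage_hpf: float) -> list[StageMeasurement]:
        key = round_stage(stage_hpf)
        return [r for r in self.rows if r.stage_key == key]

    def groupby_stage(self) -> dict[float, list[StageMeasurement]]:
        out: dict[float, list[StageMeasurement]] = {}
        for r in self.rows:
            out.setdefault(r.stage_key, []).append(r)
        return dict(sorted(out.items()))

    def to_frame(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            rec = {
                "embryo_id": r.embryo_id,
                "stage_hpf": r.stage_hpf,
                "tissue_volume_um3": r.tissue_volume,
                "apical_area_um2": r.apical_area,
                "total_surface_area_um2": r.total_surface_area,
                "n_cells": r.n_cells,
                "n_mitotic": r.n_mitotic,
                "nuclear_zone_height_um": r.nuclear_zone_height,
                "nuclear_long_axis_um": r.nuclear_long_axis,
            }
            for i in range(_N_THICKNESS_COLS):
                rec[f"thickness_um_{i + 1}"] = (
                    r.thickness_samples[i] if i < len(r.thickness_samples) else np.nan
                )
            records.append(rec)
        return pd.DataFrame.from_records(records, columns=STAGE_TABLE_COLUMNS)

    def diameters_frame(self) -> pd.DataFrame:
        records = [
            {"embryo_id": r.embryo_id, "stage_hpf": r.stage_hpf, "diameter_um": d}
            for r in self.rows
            for d in r.mitotic_diameters
        ]
        return pd.DataFrame.from_records(records, columns=DIAMETER_COLUMNS)


def _require_columns(frame: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_stage_table(path, diameters_path=None) -> StageTable:
    """Read a stage table CSV (and optional mitotic-diameter companion CSV).

    Malformed rows are rejected collectively with row-indexed messages;
    missing headers raise :class:`SchemaError`.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(
            f"{path}: empty file, expected header with columns {STAGE_TABLE_COLUMNS}"
        ) from None
    base_cols = [c for c in STAGE_TABLE_COLUMNS if not c.startswith("thickness_um_")]
    _require_columns(frame, base_cols, path)
    thickness_cols = sorted(
        (c for c in frame.columns if c.startswith("thickness_um_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    if not thickness_cols:
        raise SchemaError(f"{path}: missing required column(s) ['thickness_um_1']")

    diameters: dict[tuple[str, float], list[float]] = {}
    if diameters_path is not None:
        dframe = pd.read_csv(diameters_path)
        _require_columns(dframe, DIAMETER_COLUMNS, diameters_path)
        for rec in dframe.itertuples(index=False):
            key = (str(rec.embryo_id), round_stage(rec.stage_hpf))
            diameters.setdefault(key, []).append(float(rec.diameter_um))

    rows: list[StageMeasurement] = []
    errors: list[str] = []
    for idx, rec in frame.iterrows():
        thickness = [float(rec[c]) for c in thickness_cols if pd.notna(rec[c])]
        key = (str(rec["embryo_id"]), round_stage(rec["stage_hpf"]))
        try:
            rows.append(
                StageMeasurement(
                    embryo_id=str(rec["embryo_id"]),
                    stage_hpf=float(rec["stage_hpf"]),
                    tissue_volume=float(rec["tissue_volume_um3"]),
                    apical_area=float(rec["apical_area_um2"]),
                    total_surface_area=float(rec["total_surface_area_um2"]),
                    thickness_samples=thickness,
                    n_cells=int(rec["n_cells"]),
                    n_mitotic=int(rec["n_mitotic"]),
                    nuclear_zone_height=float(rec["nuclear_zone_height_um"]),
                    nuclear_long_axis=float(rec["nuclear_long_axis_um"]),
                    mitotic_diameters=diameters.get(key, []),
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"row {idx}: {exc}")
    if errors:
        raise ValidationError(f"{path}: {len(errors)} malformed row(s): " + "; ".join(errors))
    return StageTable(rows=rows)


def write_stage_table(table: StageTable, path, diameters_path=None) -> None:
    """Write the CSV dialect read by :func:`read_stage_table`.

    Floats are serialized with 17 significant digits so a value-level round
    trip is exact well beyond the 12-digit contract.
    """
    path = Path(path)
    table.to_frame().to_csv(path, index=False, float_format="%.17g")
    if diameters_path is not None:
        table.diameters_frame().to_csv(diameters_path, index=False, float_format="%.17g")


def stage_means(values: Sequence[float]) -> float:
    return float(np.mean(np.asarray(values, dtype=float)))
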