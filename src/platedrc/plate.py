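"""In-memory containers for microplate annotations and kinetic growth data.

A plate map records what is in each well (compound, concentration, growth
condition, cell type); plate data records the kinetic growth metric (e.g.
percent confluence) per well over elapsed time.  Both are plain containers;
file readers and writers live in :mod:`platedrc.plate_io`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import PlateValidationError

#: Row letters for plates up to 384 wells (16 rows x 24 columns).
ROW_LETTERS = "ABCDEFGHIJKLMNOP"
MAX_COLUMNS = 24

#: Compound label used for the pooled vehicle-control group.
VEHICLE_LABEL = "vehicle_control"

_WELL_RE = re.compile(r"^([A-Pa-p])(\d{1,2})$")


class SampleType(str, Enum):
    COMPOUND = "compound"
    VEHICLE_CONTROL = "vehicle_control"
    BLANK = "blank"


@dataclass(frozen=True, order=True)
class WellAddress:
    """A well coordinate: letter row (A..P) and 1-based column (1..24)."""

    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in ROW_LETTERS:
            raise PlateValidationError(f"invalid well row {self.row!r} (expected A..P)")
        if not 1 <= self.column <= MAX_COLUMNS:
            raise PlateValidationError(
                f"invalid well column {self.column} (expected 1..{MAX_COLUMNS})"
            )

    @classmethod
    def from_label(cls, label: str) -> "WellAddress":
        """Parse a bench-style label such as ``"B2"`` or ``"H12"``."""
        m = _WELL_RE.match(label.strip())
        if not m:
            raise PlateValidationError(f"unparseable well label {label!r}")
        return cls(m.group(1).upper(), int(m.group(2)))

    @property
    def label(self) -> str:
        return f"{self.row}{self.column}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass(frozen=True)
class WellAnnotation:
    """Per-well plate-map entry.

    ``sample_type`` decides the role downstream: ``compound`` wells enter the
    dose-response table, ``vehicle_control`` wells define the untreated growth
    baseline, ``blank`` wells are ignored by the analysis.
    """

    address: WellAddress
    sample_type: SampleType = SampleType.BLANK
    compound_name: str = ""
    concentration: float = 0.0
    concentration_units: str = ""
    growth_condition: str = ""
    cell_type: str = ""
    passage: str = ""
    seeding_density: float = 0.0

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise PlateValidationError(
                f"well {self.address}: negative concentration {self.concentration}"
            )
        if self.seeding_density < 0:
            raise PlateValidationError(
                f"well {self.address}: negative seeding density"
            )
        if self.sample_type is SampleType.COMPOUND:
            if not self.compound_name:
                raise PlateValidationError(
                    f"well {self.address}: compound well without a compound name"
                )
            if self.concentration <= 0:
                raise PlateValidationError(
                    f"well {self.address}: compound well requires concentration > 0"
                )
        if self.sample_type is SampleType.VEHICLE_CONTROL and self.concentration != 0:
            raise PlateValidationError(
                f"well {self.address}: vehicle control must have concentration 0"
            )

    @property
    def group_key(self) -> tuple:
        """Grouping key for replicate pooling: (compound, concentration).

        Vehicle controls pool under a single shared key regardless of any
        label on the well.
        """
        if self.sample_type is SampleType.VEHICLE_CONTROL:
            return (VEHICLE_LABEL, 0.0)
        return (self.compound_name, float(self.concentration))


@dataclass
class PlateMap:
    """A plate identifier plus one annotation per occupied well."""

    plate_id: str
    wells: list[WellAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.wells:
            raise PlateValidationError(f"plate map {self.plate_id!r}: no wells")
        seen: set[WellAddress] = set()
        for w in self.wells:
            if w.address in seen:
                raise PlateValidationError(
                    f"plate map {self.plate_id!r}: duplicate well {w.address}"
                )
            seen.add(w.address)
        self.wells = sorted(self.wells, key=lambda w: w.address)

    def __len__(self) -> int:
        return len(self.wells)

    @property
    def addresses(self) -> set[WellAddress]:
        return {w.address for w in self.wells}

    def well(self, address: WellAddress) -> WellAnnotation:
        for w in self.wells:
            if w.address == address:
                return w
        raise KeyError(address)

    def subset(self, addresses: Iterable[WellAddress]) -> "PlateMap":
        keep = set(addresses)
        return PlateMap(self.plate_id, [w for w in self.wells if w.address in keep])

    def control_wells(self) -> list[WellAnnotation]:
        return [w for w in self.wells if w.sample_type is SampleType.VEHICLE_CONTROL]

    def compound_wells(self) -> list[WellAnnotation]:
        return [w for w in self.wells if w.sample_type is SampleType.COMPOUND]

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-well table (one row per well)."""
        rows = [
            {
                "row": w.address.row,
                "col": w.address.column,
                "sampleid": w.compound_name,
                "conc": w.concentration,
                "units": w.concentration_units,
                "growthcondition": w.growth_condition,
                "celltype": w.cell_type,
                "passage": w.passage,
                "seedingdensity": w.seeding_density,
                "samptype": w.sample_type.value,
            }
            for w in self.wells
        ]
        return pd.DataFrame(rows)


@dataclass
class PlateData:
    """Long-format kinetic growth values: one record per (well, elapsed time).

    ``df`` columns: ``row``, ``col``, ``elapsed_h``, ``value``.  The export
    format is rectangular (every well observed at every timepoint) and that
    invariant is enforced here.
    """

    plate_id: str
    metric: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"row", "col", "elapsed_h", "value"}
        missing = required - set(self.df.columns)
        if missing:
            raise PlateValidationError(f"plate data missing columns {sorted(missing)}")
        if len(self.df) == 0:
            raise PlateValidationError("plate data has no records")
        if (self.df["elapsed_h"] < 0).any():
            raise PlateValidationError("negative elapsed time in plate data")
        if not np.isfinite(self.df["value"]).all():
            raise PlateValidationError("non-finite growth values in plate data")
        self.df = self.df.sort_values(["row", "col", "elapsed_h"]).reset_index(drop=True)
        # rectangular export: all wells share one timepoint set
        per_well = self.df.groupby(["row", "col"])["elapsed_h"]
        timesets = {tuple(np.sort(v.to_numpy())) for _, v in per_well}
        if len(timesets) > 1:
            raise PlateValidationError("wells do not share a common set of timepoints")
        times = next(iter(timesets))
        if len(times) != len(set(times)):
            raise PlateValidationError("duplicate timepoints within a well")

    @property
    def addresses(self) -> set[WellAddress]:
        return {
            WellAddress(r, int(c))
            for r, c in self.df[["row", "col"]].drop_duplicates().itertuples(index=False)
        }

    @property
    def timepoints(self) -> np.ndarray:
        return np.sort(self.df["elapsed_h"].unique())

    def well_series(self, address: WellAddress) -> pd.DataFrame:
        sub = self.df[(self.df["row"] == address.row) & (self.df["col"] == address.column)]
        if len(sub) == 0:
            raise KeyError(address)
        return sub[["elapsed_h", "value"]].reset_index(drop=True)

    def subset(self, addresses: Iterable[WellAddress]) -> "PlateData":
        keys = {(a.row, a.column) for a in addresses}
        mask = [
            (r, int(c)) in keys for r, c in zip(self.df["row"], self.df["col"])
        ]
        return PlateData(self.plate_id, self.metric, self.df[mask].copy())

    @classmethod
    def from_records(
        cls,
        plate_id: str,
        metric: str,
        records: Iterable[tuple[WellAddress, float, float]],
    ) -> "PlateData":
        rows = [
            {"row": a.row, "col": a.column, "elapsed_h": float(t), "value": float(v)}
            for a, t, v in records
        ]
        return cls(plate_id, metric, pd.DataFrame(rows))
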