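"""The central analysis container: one plate-map/plate-data pairing sharing a
single common vehicle-control growth background.

A :class:`DRCSet` is only valid when every well it carries shares one
(growth condition, cell type) pair, because downstream all wells are read
against the *same* pooled control growth curve and cut time.  Plates laid
out with several cell lines or growth conditions are split into one set per
condition with :func:`split_drc_sets`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

from .errors import PlateValidationError
from .plate import PlateData, PlateMap, SampleType

logger = logging.getLogger(__name__)


@dataclass
class DRCSet:
    """Plate map + kinetic data restricted to one control background.

    Fitted models and derived tables attach to the set as the workflow
    progresses; changing the cut time clears everything downstream of it so
    stale EC50s can never survive a cut-time change.
    """

    platemap: PlateMap
    platedata: PlateData
    cut_time_h: Optional[float] = None
    metadata: dict = field(default_factory=dict)
    # attached results
    growth_models_grouped: Optional[dict] = None
    growth_models_individual: Optional[dict] = None
    cut_time_result: Optional[object] = None
    drc_records: Optional[list] = None
    dose_response_results: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.platemap.addresses != self.platedata.addresses:
            raise PlateValidationError(
                "plate map and plate data must cover identical well sets"
            )
        pairs = {(w.growth_condition, w.cell_type) for w in self.platemap.wells}
        if len(pairs) > 1:
            raise PlateValidationError(
                f"wells mix (growth_condition, cell_type) pairs {sorted(pairs)}; "
                "all data in a set must share a common control growth curve — "
                "use split_drc_sets"
            )
        if self.cut_time_h is not None and self.cut_time_h < 0:
            raise PlateValidationError("cut time must be nonnegative")

    @property
    def condition(self) -> tuple[str, str]:
        w = self.platemap.wells[0]
        return (w.growth_condition, w.cell_type)

    @property
    def label(self) -> str:
        gc, ct = self.condition
        parts = [p for p in (ct, gc) if p]
        return "_".join(parts) if parts else self.platemap.plate_id

    def set_cut_time(self, cut_time_h: Optional[float]) -> None:
        """Set (or clear) the cut time, invalidating downstream results."""
        if cut_time_h is not None and cut_time_h < 0:
            raise PlateValidationError("cut time must be nonnegative")
        self.cut_time_h = cut_time_h
        self.drc_records = None
        self.dose_response_results = None

    def describe(self) -> str:
        """Human-readable per-set summary (wells, compounds, dose ranges)."""
        pm = self.platemap
        lines = [
            f"DRCSet {self.label!r}: {len(pm)} wells, "
            f"{len(pm.control_wells())} vehicle controls, metric {self.platedata.metric!r}",
            f"  condition: growth_condition={self.condition[0]!r} cell_type={self.condition[1]!r}",
            f"  elapsed time: {self.platedata.timepoints.min():g}-"
            f"{self.platedata.timepoints.max():g} h "
            f"({self.platedata.timepoints.size} timepoints)",
            f"  cut time: {self.cut_time_h if self.cut_time_h is not None else 'unset'}",
        ]
        by_compound: dict[str, list[float]] = {}
        for w in pm.compound_wells():
            by_compound.setdefault(w.compound_name, []).append(w.concentration)
        for name in sorted(by_compound):
            concs = sorted(set(by_compound[name]))
            lines.append(
                f"  compound {name}: {len(concs)} concentrations "
                f"[{concs[0]:g} .. {concs[-1]:g}], {len(by_compound[name])} wells"
            )
        return "\n".join(lines)


def make_drc_set(
    platemap: PlateMap,
    platedata: PlateData,
    cut_time_h: Optional[float] = None,
    metadata: Optional[dict] = None,
) -> DRCSet:
    """Pair a plate map with kinetic data into a single :class:`DRCSet`.

    Both inputs are restricted to the intersection of their well sets; a
    warning is logged when wells are dropped.  Mixed-condition plates raise —
    use :func:`split_drc_sets` for those.
    """
    common = platemap.addresses & platedata.addresses
    if not common:
        raise PlateValidationError("plate map and plate data share no wells")
    dropped = (platemap.addresses | platedata.addresses) - common
    if dropped:
        logger.warning(
            "make_drc_set: dropping %d wells absent from one input: %s",
            len(dropped),
            sorted(a.label for a in dropped),
        )
    return DRCSet(
        platemap=platemap.subset(common),
        platedata=platedata.subset(common),
        cut_time_h=cut_time_h,
        metadata=dict(metadata or {}),
    )


def split_drc_sets(platemap: PlateMap, platedata: PlateData) -> list[DRCSet]:
    """Partition a plate into one :class:`DRCSet` per (growth condition,
    cell type) pair, auto-populating each set's metadata.

    The vehicle-control wells of each condition stay with that condition.  A
    condition without any vehicle control gets a warning attached — its cut
    time cannot be computed later.
    """
    common = platemap.addresses & platedata.addresses
    if not common:
        raise PlateValidationError("plate map and plate data share no wells")
    pm = platemap.subset(common)
    groups: dict[tuple[str, str], list] = {}
    for w in pm.wells:
        groups.setdefault((w.growth_condition, w.cell_type), []).append(w.address)
    sets = []
    for (gc, ct) in sorted(groups):
        addrs = groups[(gc, ct)]
        s = make_drc_set(
            pm.subset(addrs),
            platedata.subset(addrs),
            metadata={
                "growth_condition": gc,
                "cell_type": ct,
                "plate_id": platemap.plate_id,
            },
        )
        if not s.platemap.control_wells():
            warnings.warn(
                f"DRCSet {s.label!r} has no vehicle-control wells; "
                "cut-time computation will fail for it"
            )
            s.metadata["no_controls"] = "true"
        sets.append(s)
    return sets
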