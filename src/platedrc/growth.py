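"""Growth-curve fitting: pooled (grouped) and per-well (individual) LOESS
smoothers over elapsed time, with prediction restricted to the observed
time range.

Grouped fits pool the raw points of all replicate wells at one
(compound, concentration) — including the pooled vehicle-control group —
so replicates weight the curve naturally.  Individual fits give one curve
per well and are what the dose-response extraction reads at the cut time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .drcset import DRCSet
from .errors import FitError
from .plate import SampleType, VEHICLE_LABEL, WellAddress
from .smoothing import LocalRegression

GRID_POINTS = 200


@dataclass
class GrowthCurveModel:
    """A fitted growth curve for one group of wells (or one well).

    ``group_key`` is ``(compound_name, concentration)`` for grouped fits
    (vehicle controls pool under ``("vehicle_control", 0.0)``) or a
    :class:`WellAddress` for individual fits.  Prediction is defined exactly
    on ``time_domain``; extrapolation raises.
    """

    group_key: object
    smoother: LocalRegression
    span: float
    _grid: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def time_domain(self) -> tuple[float, float]:
        return self.smoother.domain

    def predict(self, times) -> np.ndarray:
        return self.smoother.predict(times)

    @property
    def fitted_grid(self) -> np.ndarray:
        """(time, fitted value) pairs on an even grid, for plotting."""
        if self._grid is None:
            lo, hi = self.time_domain
            t = np.linspace(lo, hi, GRID_POINTS)
            self._grid = np.column_stack([t, self.predict(t)])
        return self._grid


def _fit_one(key, times, values, span) -> GrowthCurveModel:
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise FitError(f"group {key}: non-finite growth values")
    if np.unique(times).size < 4:
        raise FitError(
            f"group {key}: needs >= 4 distinct timepoints, got {np.unique(times).size}"
        )
    return GrowthCurveModel(key, LocalRegression(times, values, span=span), span)


def fit_growth_curves_grouped(drcset: DRCSet, span: float = 0.5) -> DRCSet:
    """Fit one pooled growth curve per (compound, concentration) group.

    Replicate wells are pooled point-by-point (no pre-averaging), so each
    replicate contributes its own weight to the local fits.  Models are
    stored on the set under ``growth_models_grouped`` and the set is
    returned to allow pipeline chaining.
    """
    groups: dict[tuple, list] = {}
    for w in drcset.platemap.wells:
        if w.sample_type is SampleType.BLANK:
            continue
        groups.setdefault(w.group_key, []).append(w.address)
    models = {}
    for key in sorted(groups, key=str):
        t_all, v_all = [], []
        for addr in groups[key]:
            series = drcset.platedata.well_series(addr)
            t_all.append(series["elapsed_h"].to_numpy())
            v_all.append(series["value"].to_numpy())
        models[key] = _fit_one(key, np.concatenate(t_all), np.concatenate(v_all), span)
    drcset.growth_models_grouped = models
    return drcset


def fit_growth_curves_individual(drcset: DRCSet, span: float = 0.5) -> DRCSet:
    """Fit one growth curve per non-blank well, keyed by well address."""
    models = {}
    for w in drcset.platemap.wells:
        if w.sample_type is SampleType.BLANK:
            continue
        series = drcset.platedata.well_series(w.address)
        models[w.address] = _fit_one(
            w.address, series["elapsed_h"].to_numpy(), series["value"].to_numpy(), span
        )
    drcset.growth_models_individual = models
    return drcset


def control_model(drcset: DRCSet) -> GrowthCurveModel:
    """The pooled vehicle-control growth model of a set (grouped fit)."""
    if drcset.growth_models_grouped is None:
        raise FitError("grouped growth curves not fitted; run fit_growth_curves_grouped")
    key = (VEHICLE_LABEL, 0.0)
    if key not in drcset.growth_models_grouped:
        raise FitError("no vehicle-control wells in this set; cannot form a control curve")
    return drcset.growth_models_grouped[key]


def predict_growth(model: GrowthCurveModel, times) -> np.ndarray:
    """Predicted growth values at the given times (within the fitted domain)."""
    return model.predict(times)
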