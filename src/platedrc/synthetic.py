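"""Synthetic plate generator with known ground truth.

Simulates a cell-proliferation screen as imaged by a live-cell instrument:
each well grows by a delayed logistic law and cytostatic compounds scale the
growth *rate* through a hill function of dose,

    y(t) = y0                                          for t <= lag
    y(t) = K y0 / (y0 + (K - y0) exp(-r_eff (t-lag)))  for t >  lag
    r_eff = (ln 2 / doubling_time) * (1 - Imax * C^h / (C^h + EC50^h))

Logistic-with-lag (not pure exponential) growth is deliberate: the
exponential-phase detection in the cut-time algorithm is only exercised by
curves that decelerate.  Noise is additive Gaussian on the growth metric,
clipped at zero (the confluence floor).  Everything is deterministic given
the seed, and the noiseless trajectories are returned as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .doseresponse import LogLogistic4
from .errors import PlateValidationError
from .plate import (
    ROW_LETTERS,
    PlateData,
    PlateMap,
    SampleType,
    WellAddress,
    WellAnnotation,
)

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class CompoundSpec:
    """A simulated cytostatic compound.

    ``pec50`` is -log10 of the molar EC50 acting on the growth rate;
    ``max_inhibition`` in (0, 1] is the fraction of the rate removed at
    saturating dose (1 = full growth arrest).
    """

    name: str
    pec50: float
    hill: float = 1.0
    max_inhibition: float = 1.0

    @property
    def ec50_uM(self) -> float:
        return 10.0 ** (6.0 - self.pec50)


def default_compounds() -> tuple[CompoundSpec, ...]:
    """Six compounds spanning ~1.5 decades of potency within the dose range."""
    return (
        CompoundSpec("CMP001", pec50=7.5),
        CompoundSpec("CMP002", pec50=7.0),
        CompoundSpec("CMP003", pec50=6.8, hill=1.5),
        CompoundSpec("CMP004", pec50=6.5),
        CompoundSpec("CMP005", pec50=6.2, hill=2.0),
        CompoundSpec("CMP006", pec50=6.0, max_inhibition=0.9),
    )


@dataclass(frozen=True)
class SimulationSpec:
    """Layout, growth kinetics, potencies and noise of a simulated screen.

    Defaults describe the standard study condition: a 384-well (16x24)
    plate carrying 6 compounds at 8 half-log doses x 3 replicates plus 6
    vehicle-control wells, imaged every 2 h for 96 h, doubling time 24 h,
    additive noise sd 1.5 confluence units.
    """

    rows: int = 16
    cols: int = 24
    doubling_time_h: float = 24.0
    y0: float = 5.0
    K: float = 100.0
    lag_h: float = 4.0
    compounds: tuple[CompoundSpec, ...] = field(default_factory=default_compounds)
    top_dose_uM: float = 10.0
    dilution_factor: float = 10.0 ** 0.5
    n_doses: int = 8
    replicates: int = 3
    n_controls: int = 6
    t_start_h: float = 0.0
    t_end_h: float = 96.0
    t_interval_h: float = 2.0
    noise_sd: float = 1.5
    seed: int = 0
    growth_condition: str = "standard"
    cell_type: str = "SIMU-1"
    units: str = "uM"
    metric: str = "percent confluence"

    def __post_init__(self) -> None:
        if not 0 < self.y0 < self.K:
            raise PlateValidationError("require 0 < y0 < K")
        if self.top_dose_uM <= 0 or self.dilution_factor <= 1:
            raise PlateValidationError("doses must be positive and decreasing")
        needed = len(self.compounds) * self.n_doses * self.replicates + self.n_controls
        if needed > self.rows * self.cols:
            raise PlateValidationError(
                f"layout needs {needed} wells but plate holds {self.rows * self.cols}"
            )
        if self.rows > len(ROW_LETTERS):
            raise PlateValidationError(f"at most {len(ROW_LETTERS)} rows supported")

    @property
    def doses_uM(self) -> np.ndarray:
        return self.top_dose_uM / self.dilution_factor ** np.arange(self.n_doses)

    @property
    def times_h(self) -> np.ndarray:
        n = int(np.floor((self.t_end_h - self.t_start_h) / self.t_interval_h + 1e-9))
        return self.t_start_h + self.t_interval_h * np.arange(n + 1)

    def rate(self, compound: Optional[CompoundSpec] = None, dose_uM: float = 0.0) -> float:
        """Effective logistic growth rate (1/h) under a compound dose."""
        r = LN2 / self.doubling_time_h
        if compound is None or dose_uM <= 0:
            return r
        inh = compound.max_inhibition * dose_uM ** compound.hill / (
            dose_uM ** compound.hill + compound.ec50_uM ** compound.hill
        )
        return r * (1.0 - inh)

    def trajectory(self, times_h, rate: float) -> np.ndarray:
        """Noiseless delayed-logistic growth at the given rate."""
        t = np.asarray(times_h, dtype=float)
        dt = np.maximum(t - self.lag_h, 0.0)
        return self.K * self.y0 / (self.y0 + (self.K - self.y0) * np.exp(-rate * dt))


def simulate_plate(spec: SimulationSpec) -> tuple[PlateMap, PlateData, dict]:
    """Generate a (PlateMap, PlateData, ground-truth) triple from a spec.

    Wells are laid out row-major: vehicle controls first, then each
    compound's dose series replicate by replicate.  Ground truth carries the
    noiseless trajectory and effective rate per well.
    """
    rng = np.random.default_rng(spec.seed)
    addresses = [
        WellAddress(ROW_LETTERS[r], c + 1)
        for r in range(spec.rows)
        for c in range(spec.cols)
    ]
    annotations: list[WellAnnotation] = []
    truth_wells: dict[str, dict] = {}
    times = spec.times_h
    cursor = 0

    def place(stype, compound=None, dose=0.0):
        nonlocal cursor
        addr = addresses[cursor]
        cursor += 1
        annotations.append(
            WellAnnotation(
                address=addr,
                sample_type=stype,
                compound_name=compound.name if compound else "",
                concentration=float(dose),
                concentration_units=spec.units if compound else "",
                growth_condition=spec.growth_condition,
                cell_type=spec.cell_type,
                passage="p1",
                seeding_density=1000.0,
            )
        )
        r = spec.rate(compound, dose)
        truth_wells[addr.label] = {
            "rate_per_h": r,
            "noiseless": spec.trajectory(times, r),
            "compound": compound.name if compound else "",
            "dose_uM": float(dose),
        }

    for _ in range(spec.n_controls):
        place(SampleType.VEHICLE_CONTROL)
    for compound in spec.compounds:
        for dose in spec.doses_uM:
            for _ in range(spec.replicates):
                place(SampleType.COMPOUND, compound, dose)

    platemap = PlateMap(f"sim_seed{spec.seed}", annotations)
    records = []
    for ann in annotations:
        clean = truth_wells[ann.address.label]["noiseless"]
        noisy = clean + rng.normal(0.0, spec.noise_sd, size=clean.size) if spec.noise_sd > 0 else clean
        noisy = np.maximum(noisy, 0.0)
        records.extend(
            (ann.address, float(t), float(v)) for t, v in zip(times, noisy)
        )
    platedata = PlateData.from_records(platemap.plate_id, spec.metric, records)
    truth = {
        "spec": spec,
        "times_h": times,
        "wells": truth_wells,
        "control_rate_per_h": spec.rate(),
    }
    return platemap, platedata, truth


def apparent_ec50_oracle(
    spec: SimulationSpec, compound_name: str, cut_time_h: float, n_grid: int = 200
) -> float:
    """Brute-force apparent EC50 at a cut time, independent of the pipeline.

    Evaluates the *noiseless* growth value at ``cut_time_h`` on a dense
    log-dose grid and fits the LL.4 model to that clean curve.  This is the
    reference value pipeline EC50 estimates are judged against: because the
    compound acts on the growth rate, the apparent (value-scale) EC50 at a
    finite time differs from the rate-scale EC50.
    """
    matches = [c for c in spec.compounds if c.name == compound_name]
    if not matches:
        raise KeyError(f"compound {compound_name!r} not in simulation spec")
    compound = matches[0]
    if compound.max_inhibition <= 0:
        raise ValueError(
            f"compound {compound_name!r} has no effect (max_inhibition=0); "
            "apparent EC50 undefined"
        )
    if not spec.t_start_h <= cut_time_h <= spec.t_end_h:
        raise ValueError(f"cut time {cut_time_h} h outside simulated range")
    doses = np.geomspace(compound.ec50_uM / 1e3, compound.ec50_uM * 1e3, n_grid)
    values = np.array(
        [spec.trajectory([cut_time_h], spec.rate(compound, d))[0] for d in doses]
    )
    fit = LogLogistic4(doses, values, compound=compound_name).fit()
    if not fit.converged:
        raise RuntimeError(f"oracle fit failed for {compound_name!r}")
    return fit.ec50
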