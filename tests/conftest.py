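"""Shared fixtures and builders: hand-made plates with closed-form growth
laws, and random plate generators for round-trip/partition suites."""

from __future__ import annotations

import numpy as np
import pytest

from platedrc import (
    CompoundSpec,
    PlateData,
    PlateMap,
    SampleType,
    SimulationSpec,
    WellAddress,
    WellAnnotation,
    make_drc_set,
)
from platedrc.plate import ROW_LETTERS


def make_platedata(wells: dict, times, plate_id="plate", metric="percent confluence"):
    """Build PlateData from {address_label: value_function_or_array}."""
    times = np.asarray(times, dtype=float)
    records = []
    for label, values in wells.items():
        addr = WellAddress.from_label(label)
        v = values(times) if callable(values) else np.asarray(values, dtype=float)
        records.extend((addr, float(t), float(x)) for t, x in zip(times, v))
    return PlateData.from_records(plate_id, metric, records)


def control_annotation(label, **kw):
    return WellAnnotation(
        address=WellAddress.from_label(label),
        sample_type=SampleType.VEHICLE_CONTROL,
        **kw,
    )


def compound_annotation(label, name, conc, **kw):
    return WellAnnotation(
        address=WellAddress.from_label(label),
        sample_type=SampleType.COMPOUND,
        compound_name=name,
        concentration=conc,
        concentration_units="uM",
        **kw,
    )


def control_set(value_fn, times, n_wells=2, plate_id="ctrl"):
    """A DRCSet of only vehicle-control wells following one growth law."""
    labels = [f"A{i + 1}" for i in range(n_wells)]
    pm = PlateMap(plate_id, [control_annotation(l) for l in labels])
    pdata = make_platedata({l: value_fn for l in labels}, times, plate_id)
    return make_drc_set(pm, pdata)


@pytest.fixture
def exponential_set():
    """Noiseless exponential growth y(t) = 10 * 2**(t/24), 0-96 h / 2 h."""
    times = np.arange(0.0, 97.0, 2.0)
    return control_set(lambda t: 10.0 * 2.0 ** (t / 24.0), times)


def logistic(t, K=100.0, y0=2.0, r=0.1):
    t = np.asarray(t, dtype=float)
    return K / (1.0 + ((K - y0) / y0) * np.exp(-r * t))


@pytest.fixture
def logistic_set():
    """Closed-form logistic growth K=100, y0=2, r=0.1/h on 0-120 h."""
    times = np.arange(0.0, 121.0, 2.0)
    return control_set(lambda t: logistic(t), times)


def random_platemap(rng: np.random.Generator, n_conditions=1, plate_id="rand"):
    """A random valid plate map with controls and compounds per condition."""
    n_rows, n_cols = 8, 12
    addresses = [
        WellAddress(ROW_LETTERS[r], c + 1) for r in range(n_rows) for c in range(n_cols)
    ]
    rng.shuffle(addresses)
    cursor = 0
    wells = []
    for ci in range(n_conditions):
        gc, ct = f"cond{ci}", f"line{ci}"
        n_ctrl = int(rng.integers(1, 4))
        for _ in range(n_ctrl):
            wells.append(
                WellAnnotation(
                    address=addresses[cursor], sample_type=SampleType.VEHICLE_CONTROL,
                    growth_condition=gc, cell_type=ct,
                )
            )
            cursor += 1
        n_cmp = int(rng.integers(1, 3))
        for k in range(n_cmp):
            for conc in 10.0 ** rng.uniform(-3, 1, size=int(rng.integers(1, 5))):
                wells.append(
                    WellAnnotation(
                        address=addresses[cursor], sample_type=SampleType.COMPOUND,
                        compound_name=f"c{ci}_{k}", concentration=float(conc),
                        concentration_units="uM", growth_condition=gc, cell_type=ct,
                        passage=f"p{int(rng.integers(1, 30))}",
                        seeding_density=float(rng.integers(500, 5000)),
                    )
                )
                cursor += 1
    return PlateMap(plate_id, wells)


def random_platedata(rng: np.random.Generator, platemap: PlateMap, n_times=6):
    times = np.sort(rng.uniform(0, 96, size=n_times))
    values = {
        w.address.label: rng.uniform(0, 100, size=n_times) for w in platemap.wells
    }
    return make_platedata(values, times, platemap.plate_id)


@pytest.fixture
def small_sim_spec():
    """A reduced simulated screen for fast end-to-end tests."""
    return SimulationSpec(
        rows=8, cols=12,
        compounds=(
            CompoundSpec("CMPA", pec50=7.0),
            CompoundSpec("CMPB", pec50=6.3, hill=1.5),
        ),
        n_doses=6, replicates=2, n_controls=4, noise_sd=1.0, seed=7,
    )
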