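"""End-to-end pipeline: import -> split -> fit -> cut time -> dose response
-> exports, driven by a flat key=value run configuration.

The pipeline is deterministic: identical configuration and input files
produce bit-identical output files (fixed 6-significant-digit formatting,
no timestamps in any artifact).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

from . import __version__
from .cuttime import CutTimeParams, calculate_cut_time
from .doseresponse import (
    calculate_drc_data,
    export_drc_table,
    export_ec50_table,
    fit_dose_response,
)
from .drcset import split_drc_sets
from .errors import ConfigError, PlateDRCError
from .growth import fit_growth_curves_grouped, fit_growth_curves_individual
from .plate_io import import_plate_data, import_platemap_table, import_platemap_xml

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"
VALID_LAYOUTS = ("long", "prism", "dotmatics")

#: keys that select the automatic cut-time algorithm; mutually exclusive
#: with an explicit ``cut_time_h``.
CUT_PARAM_KEYS = ("baseline_time_h", "no_doublings", "max_val", "window_n", "grid_step_h")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    platemap: str = ""
    platedata: str = ""
    metric: str = ""
    span: float = 0.5
    cut_time_h: Optional[float] = None
    baseline_time_h: float = 0.0
    no_doublings: float = 2.0
    max_val: float = 80.0
    window_n: int = 30
    grid_step_h: Optional[float] = None
    layouts: tuple[str, ...] = ("long",)
    outdir: str = "platedrc_out"
    plots: bool = False
    verbosity: int = 1
    explicit_keys: set = field(default_factory=set)

    def validate(self) -> None:
        if not self.platemap or not self.platedata:
            raise ConfigError("config requires both 'platemap' and 'platedata' paths")
        for p in (self.platemap, self.platedata):
            if not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")
        if self.cut_time_h is not None:
            clash = sorted(self.explicit_keys & set(CUT_PARAM_KEYS))
            if clash:
                raise ConfigError(
                    f"contradictory cut-time settings: 'cut_time_h' and {clash} "
                    "are both set; supply exactly one of an explicit cut time or "
                    "automatic cut-time parameters"
                )
        unknown = [l for l in self.layouts if l not in VALID_LAYOUTS]
        if unknown:
            raise ConfigError(f"unknown export layout(s) {unknown}; valid: {VALID_LAYOUTS}")
        if not 0 < self.span <= 1:
            raise ConfigError(f"span must be in (0, 1], got {self.span}")

    @property
    def cut_params(self) -> CutTimeParams:
        return CutTimeParams(
            baseline_time_h=self.baseline_time_h,
            no_doublings=self.no_doublings,
            max_val=self.max_val,
            window_n=self.window_n,
            grid_step_h=self.grid_step_h,
        )


_CASTS = {
    "span": float, "cut_time_h": float, "baseline_time_h": float,
    "no_doublings": float, "max_val": float, "window_n": int,
    "grid_step_h": float, "verbosity": int,
    "plots": lambda s: s.strip().lower() in ("1", "true", "yes"),
    "layouts": lambda s: tuple(x.strip() for x in s.split(",") if x.strip()),
}


def load_config(path, overrides: Optional[dict] = None) -> RunConfig:
    """Read a flat ``key = value`` config file; CLI overrides win.

    Lines starting with ``#`` and blank lines are ignored; unknown keys get
    a warning, not an error.
    """
    cfg = RunConfig()
    known = {f.name for f in fields(RunConfig)} - {"explicit_keys"}
    items: dict[str, str] = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        for lineno, ln in enumerate(p.read_text(encoding="utf-8").splitlines(), 1):
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            if "=" not in ln:
                raise ConfigError(f"{p}:{lineno}: expected 'key = value', got {ln!r}")
            key, _, val = ln.partition("=")
            items[key.strip()] = val.strip()
    for key, val in (overrides or {}).items():
        if val is not None:
            items[key] = val
    for key, val in items.items():
        if key not in known:
            logger.warning("config: unknown key %r ignored", key)
            continue
        cast = _CASTS.get(key, str)
        try:
            setattr(cfg, key, cast(val) if isinstance(val, str) else val)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"config key {key!r}: bad value {val!r}") from exc
        cfg.explicit_keys.add(key)
    cfg.validate()
    return cfg


def _import_platemap(path: str):
    if str(path).lower().endswith(".xml"):
        return import_platemap_xml(path)
    return import_platemap_table(path)


def run_pipeline(config: RunConfig) -> int:
    """Execute the full workflow and write artifacts under ``config.outdir``.

    Per-set failures are logged and do not abort sibling sets; the exit
    status is nonzero when any stage failed.  Artifacts per set: a cut-time
    JSON, one DRC table per requested layout, an EC50 table, and a combined
    machine-readable ``run_log.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "package": "platedrc",
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
            if k != "explicit_keys"
        },
        "sets": [],
        "failures": [],
    }

    def fail(stage: str, label: str, exc: Exception) -> None:
        logger.error("stage %s failed for set %r: %s", stage, label, exc)
        log["failures"].append({"stage": stage, "set": label, "error": str(exc)})

    try:
        platemap = _import_platemap(config.platemap)
        platedata = import_plate_data(config.platedata, config.metric or None)
        sets = split_drc_sets(platemap, platedata)
    except PlateDRCError as exc:
        fail("import", "*", exc)
        _write_log(log, outdir)
        return 1

    for s in sets:
        label = s.label or s.platemap.plate_id
        entry: dict = {"set": label, "wells": len(s.platemap), "metadata": s.metadata}
        try:
            fit_growth_curves_grouped(s, span=config.span)
            fit_growth_curves_individual(s, span=config.span)
        except PlateDRCError as exc:
            fail("fit_growth_curves", label, exc)
            continue
        try:
            if config.cut_time_h is not None:
                s.set_cut_time(config.cut_time_h)
                entry["cut_time"] = {"cut_time_h": config.cut_time_h, "mode": "explicit"}
            else:
                res = calculate_cut_time(s, config.cut_params)
                entry["cut_time"] = {**res.to_dict(), "mode": "auto"}
            (outdir / f"cuttime_{label}.json").write_text(
                json.dumps(entry["cut_time"], indent=2, sort_keys=True) + "\n"
            )
        except PlateDRCError as exc:
            fail("cut_time", label, exc)
            continue
        try:
            calculate_drc_data(s)
            for layout in config.layouts:
                df = export_drc_table(s, layout)
                df.to_csv(
                    outdir / f"drc_{layout}_{label}.tsv",
                    sep="\t", index=False, float_format=FLOAT_FORMAT,
                )
            fit_dose_response(s)
            ec50 = export_ec50_table(s)
            ec50.to_csv(
                outdir / f"ec50_{label}.tsv", sep="\t", index=False,
                float_format=FLOAT_FORMAT,
            )
            entry["ec50"] = {
                row["compound"]: (None if row["converged"] is False else row["ec50"])
                for _, row in ec50.iterrows()
            }
        except PlateDRCError as exc:
            fail("dose_response", label, exc)
            continue
        if config.plots:
            try:
                from . import plotting

                plotting.plot_growth_curves(s, outdir / f"growth_{label}.png")
                plotting.plot_cut_time_diagnostics(s, config.cut_params,
                                                   outdir / f"cuttime_{label}.png")
                for name in (s.dose_response_results or {}):
                    plotting.plot_dose_response(
                        s.dose_response_results[name],
                        outdir / f"drc_{name}_{label}.png",
                    )
            except Exception as exc:  # plots are best-effort
                fail("plots", label, exc)
        log["sets"].append(entry)

    _write_log(log, outdir)
    return 1 if log["failures"] else 0


def _write_log(log: dict, outdir: Path) -> None:
    (outdir / "run_log.json").write_text(
        json.dumps(log, indent=2, sort_keys=True, default=str) + "\n"
    )
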