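"""Plot writers: growth-curve panels, cut-time diagnostics, dose-response
curves.  All figures are written to file (PNG/SVG), never shown."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cuttime import CutTimeParams, cut_time_diagnostics
from .doseresponse import LogLogistic4Results
from .drcset import DRCSet

_SAVE_KW = {"dpi": 110, "metadata": {"Software": None}}


def _save(fig, path) -> None:
    path = Path(path)
    kw = dict(_SAVE_KW)
    if path.suffix.lower() == ".svg":
        kw["metadata"] = {"Date": None}
    fig.savefig(path, **kw)
    plt.close(fig)


def plot_growth_curves(drcset: DRCSet, path) -> None:
    """One facet per compound, a line per concentration, controls dashed,
    cut time as a vertical dashed line."""
    models = drcset.growth_models_grouped or {}
    compounds = sorted({k[0] for k in models if k[0] != "vehicle_control"})
    ncol = min(3, max(1, len(compounds)))
    nrow = max(1, int(np.ceil(len(compounds) / ncol)))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow),
                             squeeze=False, sharex=True, sharey=True)
    control = models.get(("vehicle_control", 0.0))
    for i, name in enumerate(compounds or [""]):
        ax = axes[i // ncol][i % ncol]
        keys = sorted([k for k in models if k[0] == name], key=lambda k: k[1])
        for key in keys:
            grid = models[key].fitted_grid
            ax.plot(grid[:, 0], grid[:, 1], lw=1, label=f"{key[1]:g}")
        if control is not None:
            grid = control.fitted_grid
            ax.plot(grid[:, 0], grid[:, 1], "k--", lw=1.2, label="control")
        if drcset.cut_time_h is not None:
            ax.axvline(drcset.cut_time_h, color="b", ls="--", lw=1)
        ax.set_title(name or drcset.label, fontsize=9)
        ax.set_xlabel("elapsed time (h)")
        ax.set_ylabel(drcset.platedata.metric)
    for j in range(len(compounds), nrow * ncol):
        axes[j // ncol][j % ncol].axis("off")
    fig.tight_layout()
    _save(fig, path)


def plot_cut_time_diagnostics(drcset: DRCSet, params: CutTimeParams, path) -> None:
    """Two-panel diagnostic: control curve (top) and moving-average
    second-difference profile (bottom); dashed black = user parameters,
    dashed blue = computed values, blue vertical line = cut time."""
    diag = cut_time_diagnostics(drcset, params)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    ax1.plot(diag["curve_times"], diag["curve_values"], "g-")
    m = diag["markers"]
    ax1.axhline(m["max_val"], color="k", ls="--", lw=1)
    ax1.axvline(m["baseline_time_h"], color="k", ls="--", lw=1)
    ax1.axhline(m["target_value"], color="b", ls="--", lw=1)
    ax1.axvline(m["cut_time_h"], color="b", ls="--", lw=1.5)
    ax1.axvline(m["truncation_time_h"], color="b", ls=":", lw=1)
    ax1.set_ylabel(drcset.platedata.metric)
    ax1.set_title(f"cut time = {m['cut_time_h']:.2f} h"
                  + (" (capped)" if diag["capped"] else ""))
    ax2.plot(diag["profile_times"], diag["profile_values"], "g-")
    ax2.axvline(m["cut_time_h"], color="b", ls="--", lw=1.5)
    ax2.axvline(m["truncation_time_h"], color="b", ls=":", lw=1)
    ax2.set_xlabel("elapsed time (h)")
    ax2.set_ylabel("moving-avg 2nd differences")
    fig.tight_layout()
    _save(fig, path)


def plot_dose_response(result: LogLogistic4Results, path) -> None:
    """Fitted curve over a 3-decade dose span with the data points and a
    red dashed EC50 vertical line; log10 x-axis."""
    fig, ax = plt.subplots(figsize=(5, 4))
    d = result.model.dose
    ax.semilogx(d, result.model.response, "ko", ms=4, alpha=0.7)
    span = np.geomspace(d.min() / 3.0, d.max() * 3.0, 200)
    ax.semilogx(span, result.predict(span), "g-")
    if result.converged:
        ax.axvline(result.ec50, color="r", ls="--", lw=1.2,
                   label=f"EC50 = {result.ec50:.3g}")
        ax.legend(fontsize=8)
    ax.set_xlabel("concentration")
    ax.set_ylabel("growth value at cut time")
    ax.set_title(result.compound, fontsize=10)
    fig.tight_layout()
    _save(fig, path)
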