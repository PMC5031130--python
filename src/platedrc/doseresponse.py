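"""Four-parameter log-logistic dose-response fitting and EC50 estimation.

The model is the standard LL.4 parameterisation

    f(x) = c + (d - c) / (1 + exp(b * (ln x - ln e)))

with hill slope ``b`` (positive for responses that decrease with dose),
lower asymptote ``c``, upper asymptote ``d`` and inflection dose ``e``.  The
relative EC50 — the dose of half-maximal effect between the asymptotes — is
``e`` itself, and ``f(e) = (c + d) / 2`` exactly.

:class:`LogLogistic4` is a model object built from dose/response arrays;
``fit()`` runs multi-start nonlinear least squares and returns a
:class:`LogLogistic4Results` carrying the estimates, their standard errors,
diagnostics and a ``summary()`` table.  The workflow functions
(:func:`calculate_drc_data`, :func:`fit_dose_response`, ...) drive it per
compound on a :class:`~platedrc.drcset.DRCSet`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .drcset import DRCSet
from .errors import CutTimeError, FitError
from .plate import SampleType, VEHICLE_LABEL

__all__ = [
    "LogLogistic4",
    "LogLogistic4Results",
    "DRCRecord",
    "ll4",
    "calculate_drc_data",
    "fit_dose_response",
    "calculate_ec50",
    "export_drc_table",
    "export_ec50_table",
]


def ll4(x, b, c, d, e):
    """Evaluate the four-parameter log-logistic function at dose ``x > 0``."""
    x = np.asarray(x, dtype=float)
    return c + (d - c) / (1.0 + np.exp(b * (np.log(x) - np.log(e))))


@dataclass
class DRCRecord:
    """Growth values extracted at the cut time for one (compound, dose)."""

    compound_name: str
    concentration: float
    values: list[float]
    mean_value: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.values:
            raise FitError("DRCRecord requires at least one replicate value")
        self.mean_value = float(np.mean(self.values))


class LogLogistic4:
    """Four-parameter log-logistic dose-response model.

    Parameters
    ----------
    dose : array-like, positive
        Compound concentrations (replicate-level points, not means).
    response : array-like
        Growth values at the cut time, one per point.
    compound : str
        Label carried through to results and exports.
    """

    #: hill-slope starting values tried in the multi-start (both signs).
    START_SLOPES: Sequence[float] = (0.5, 1.0, 2.0, -1.0)

    def __init__(self, dose, response, compound: str = ""):
        dose = np.asarray(dose, dtype=float)
        response = np.asarray(response, dtype=float)
        if dose.shape != response.shape:
            raise FitError("dose and response must have equal length")
        if (dose <= 0).any():
            raise FitError("doses must be positive (zero-dose controls are excluded)")
        if not np.isfinite(response).all():
            raise FitError("non-finite responses")
        if np.unique(dose).size < 4:
            raise FitError(
                f"compound {compound!r}: needs >= 4 distinct concentrations, "
                f"got {np.unique(dose).size}"
            )
        self.dose = dose
        self.response = response
        self.compound = compound

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, dose_col: str = "conc", response_col: str = "value",
        compound: str = "",
    ) -> "LogLogistic4":
        return cls(df[dose_col].to_numpy(), df[response_col].to_numpy(), compound)

    # -- fitting -----------------------------------------------------------

    def _residuals(self, theta):
        b, c, d, log_e = theta
        return ll4(self.dose, b, c, d, np.exp(log_e)) - self.response

    def _starts(self):
        lo, hi = float(self.response.min()), float(self.response.max())
        half = 0.5 * (lo + hi)
        e0 = float(self.dose[np.argmin(np.abs(self.response - half))])
        for b0 in self.START_SLOPES:
            yield np.array([b0, lo, hi, np.log(e0)])

    def fit(self) -> "LogLogistic4Results":
        """Multi-start nonlinear least squares; best residual sum wins,
        ties broken by the shallowest slope (smallest ``|log|b||``)."""
        log_d = np.log(self.dose)
        best = None
        for x0 in self._starts():
            try:
                sol = least_squares(
                    self._residuals, x0, method="lm",
                    xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=10000,
                )
            except Exception:
                continue
            if not np.isfinite(sol.fun).all():
                continue
            rss = float(np.sum(sol.fun ** 2))
            key = (round(rss, 12), abs(np.log(abs(sol.x[0]))) if sol.x[0] != 0 else np.inf)
            if best is None or key < best[0]:
                best = (key, sol, rss)
        if best is None:
            return LogLogistic4Results(
                model=self, b=np.nan, c=np.nan, d=np.nan, e=np.nan,
                converged=False, rss=np.nan, jac=None,
            )
        _, sol, rss = best
        b, c, d, log_e = sol.x
        # (b, c, d, e) and (-b, d, c, e) define the same curve; canonicalise
        # to d >= c so decreasing responses carry the conventional b > 0
        if c > d:
            b, c, d = -b, d, c
            if sol.jac is not None:
                sol.jac = sol.jac[:, [0, 2, 1, 3]]
        converged = bool(sol.success) and np.isfinite(sol.x).all()
        # a flat fit (d ~ c) cannot identify e or b
        if abs(d - c) <= 1e-8 * max(1.0, abs(d), abs(c)):
            converged = False
        res = LogLogistic4Results(
            model=self, b=float(b), c=float(c), d=float(d), e=float(np.exp(log_e)),
            converged=converged, rss=rss, jac=sol.jac,
        )
        if converged and not (
            self.dose.min() / 10.0 <= res.e <= self.dose.max() * 10.0
        ):
            res.flags.append("extrapolated_ec50")
        return res


@dataclass
class LogLogistic4Results:
    """Fitted LL.4 parameters, diagnostics and the relative EC50."""

    model: LogLogistic4
    b: float
    c: float
    d: float
    e: float
    converged: bool
    rss: float
    jac: Optional[np.ndarray] = field(repr=False, default=None)
    flags: list[str] = field(default_factory=list)

    @property
    def compound(self) -> str:
        return self.model.compound

    @property
    def n_points(self) -> int:
        return self.model.dose.size

    @property
    def params(self) -> dict:
        return {"b": self.b, "c": self.c, "d": self.d, "e": self.e}

    @property
    def ec50(self) -> float:
        """Relative EC50: the dose of half-maximal effect (= parameter e)."""
        if not self.converged:
            raise FitError(f"compound {self.compound!r}: model did not converge")
        return self.e

    def predict(self, dose) -> np.ndarray:
        return ll4(dose, self.b, self.c, self.d, self.e)

    @property
    def bse(self) -> dict:
        """Asymptotic standard errors (b, c, d, e) from the final Jacobian.

        NaN when the fit is unconverged or the information matrix is
        singular (e.g. noiseless data).
        """
        nan = {k: np.nan for k in ("b", "c", "d", "e")}
        if not self.converged or self.jac is None or self.n_points <= 4:
            return nan
        try:
            jtj_inv = np.linalg.inv(self.jac.T @ self.jac)
        except np.linalg.LinAlgError:
            return nan
        sigma2 = self.rss / (self.n_points - 4)
        se = np.sqrt(np.maximum(np.diag(jtj_inv) * sigma2, 0.0))
        # the model is fitted in log(e); delta method back to the e scale
        return {"b": se[0], "c": se[1], "d": se[2], "e": se[3] * self.e}

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        se = self.bse
        lines = [
            "Four-parameter log-logistic dose-response fit",
            "=" * 52,
            f"compound:      {self.compound or '(unnamed)'}",
            f"observations:  {self.n_points}",
            f"converged:     {self.converged}",
            f"rss:           {self.rss:.6g}",
            "-" * 52,
            f"{'param':<8}{'estimate':>14}{'std err':>14}",
        ]
        for k in ("b", "c", "d", "e"):
            lines.append(f"{k:<8}{getattr(self, k):>14.6g}{se[k]:>14.6g}")
        lines.append("-" * 52)
        if self.converged:
            lines.append(f"EC50 (relative): {self.ec50:.6g}")
        if self.flags:
            lines.append(f"flags: {', '.join(self.flags)}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# workflow operations on a DRCSet
# ---------------------------------------------------------------------------

def calculate_drc_data(drcset: DRCSet, include_control: bool = True) -> DRCSet:
    """Read each well's individual growth curve at the cut time and build
    one :class:`DRCRecord` per (compound, concentration).

    Vehicle controls are optionally included as a zero-dose pseudo-record
    (exported but never fitted — log 0 is undefined).
    """
    if drcset.cut_time_h is None:
        raise CutTimeError("cut time unset; set one or run calculate_cut_time")
    if drcset.growth_models_individual is None:
        raise FitError("individual growth curves not fitted")
    cut = drcset.cut_time_h
    by_group: dict[tuple, list[float]] = {}
    for w in drcset.platemap.wells:
        if w.sample_type is SampleType.BLANK:
            continue
        if w.sample_type is SampleType.VEHICLE_CONTROL and not include_control:
            continue
        model = drcset.growth_models_individual[w.address]
        lo, hi = model.time_domain
        if not lo <= cut <= hi:
            raise CutTimeError(
                f"cut time {cut:g} h outside well {w.address} domain [{lo:g}, {hi:g}]"
            )
        by_group.setdefault(w.group_key, []).append(float(model.predict([cut])[0]))
    drcset.drc_records = [
        DRCRecord(name, conc, by_group[(name, conc)])
        for name, conc in sorted(by_group, key=lambda k: (k[0], k[1]))
    ]
    return drcset


def _fit_points(drcset: DRCSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Replicate-level (dose, value) arrays per compound, controls excluded."""
    pts: dict[str, tuple[list, list]] = {}
    for rec in drcset.drc_records or []:
        if rec.compound_name == VEHICLE_LABEL or rec.concentration <= 0:
            continue
        d, v = pts.setdefault(rec.compound_name, ([], []))
        d.extend([rec.concentration] * len(rec.values))
        v.extend(rec.values)
    return {k: (np.array(d), np.array(v)) for k, (d, v) in pts.items()}


def fit_dose_response(drcset: DRCSet) -> DRCSet:
    """Fit one LL.4 model per compound from the extracted DRC data.

    Replicate-level points are fitted (not means).  Non-convergence is
    recorded on the stored results, not raised.
    """
    if drcset.drc_records is None:
        raise FitError("DRC data not calculated; run calculate_drc_data")
    results = {}
    for name, (dose, value) in sorted(_fit_points(drcset).items()):
        results[name] = LogLogistic4(dose, value, compound=name).fit()
        if not results[name].converged:
            warnings.warn(f"dose-response fit for {name!r} did not converge")
    drcset.dose_response_results = results
    return drcset


def calculate_ec50(result: LogLogistic4Results) -> float:
    """Relative EC50 of a converged fit (raises for unconverged models)."""
    return result.ec50


def export_drc_table(drcset: DRCSet, layout: str = "long") -> pd.DataFrame:
    """Extracted cut-time values in one of three text-table layouts.

    ``long``: tidy rows (compound, conc, replicate, value).
    ``prism``: one concentration column then replicate value columns per
    compound — paste-ready for curve-fitting software using grouped columns.
    ``dotmatics``: stacked per-compound blocks with identifier columns and
    one replicate per column.
    """
    if drcset.drc_records is None:
        raise FitError("DRC data not calculated; run calculate_drc_data")
    recs = drcset.drc_records
    if layout == "long":
        rows = [
            {"compound": r.compound_name, "conc": r.concentration,
             "replicate": i + 1, "value": v}
            for r in recs
            for i, v in enumerate(r.values)
        ]
        return pd.DataFrame(rows)
    if layout == "prism":
        concs = sorted({r.concentration for r in recs if r.concentration > 0})
        out = pd.DataFrame({"conc": concs})
        for name in sorted({r.compound_name for r in recs if r.concentration > 0}):
            nrep = max(
                len(r.values) for r in recs if r.compound_name == name
            )
            cols = {f"{name}_{i + 1}": [np.nan] * len(concs) for i in range(nrep)}
            for r in recs:
                if r.compound_name != name or r.concentration <= 0:
                    continue
                row = concs.index(r.concentration)
                for i, v in enumerate(r.values):
                    cols[f"{name}_{i + 1}"][row] = v
            for k, v in cols.items():
                out[k] = v
        return out
    if layout == "dotmatics":
        rows = []
        for r in recs:
            if r.concentration <= 0:
                continue
            row = {"sample_id": r.compound_name, "conc": r.concentration,
                   "n_replicates": len(r.values)}
            row.update({f"value_{i + 1}": v for i, v in enumerate(r.values)})
            rows.append(row)
        return pd.DataFrame(rows)
    raise ValueError(f"unknown layout {layout!r} (expected long/prism/dotmatics)")


def export_ec50_table(drcset: DRCSet) -> pd.DataFrame:
    """One row per fitted compound: LL.4 parameters, EC50, diagnostics and
    the set's cut time and metadata tags.  Unconverged rows stay present
    with an empty EC50 and ``converged=False``."""
    if drcset.dose_response_results is None:
        raise FitError("dose-response models not fitted; run fit_dose_response")
    rows = []
    for name in sorted(drcset.dose_response_results):
        res = drcset.dose_response_results[name]
        rows.append(
            {
                "compound": name,
                "b": res.b, "c": res.c, "d": res.d, "e": res.e,
                "ec50": res.ec50 if res.converged else np.nan,
                "converged": res.converged,
                "rss": res.rss,
                "n_points": res.n_points,
                "cut_time_h": drcset.cut_time_h,
                **{f"meta_{k}": v for k, v in sorted(drcset.metadata.items())},
            }
        )
    return pd.DataFrame(rows)
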