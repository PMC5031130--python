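"""Local polynomial regression (LOESS) with prediction at arbitrary points.

Classic tricube-weighted local regression: for each prediction point the
``span`` fraction of nearest observations is selected, weighted by the
tricube kernel on scaled distance, and a weighted polynomial of the given
degree is fitted by least squares; the fitted value at the point is
returned.  Degree >= 1 reproduces affine data to machine precision, which is
the primary regression test for this backend.

Replicate observations (tied x values) are handled natively — each point
contributes its own weight, so pooled replicates weight the fit the way
repeated measurements should.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ExtrapolationError, FitError

_DOMAIN_TOL = 1e-9


@dataclass
class LocalRegression:
    """Tricube local polynomial smoother fitted to (x, y) points.

    Parameters
    ----------
    x, y : array-like
        Observations; x need not be sorted and may contain ties.
    span : float in (0, 1]
        Fraction of points in each local window.
    degree : int
        Local polynomial degree (2 by default, LOESS convention).
    """

    x: np.ndarray
    y: np.ndarray
    span: float = 0.5
    degree: int = 2
    _order: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.x.shape != self.y.shape:
            raise FitError("x and y must have equal length")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise FitError("non-finite values in smoother input")
        if not 0 < self.span <= 1:
            raise FitError(f"span must be in (0, 1], got {self.span}")
        n_distinct = np.unique(self.x).size
        if n_distinct < self.degree + 2:
            raise FitError(
                f"need at least {self.degree + 2} distinct x values, got {n_distinct}"
            )
        self._order = np.argsort(self.x, kind="stable")

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.x.min()), float(self.x.max())

    def _window_size(self) -> int:
        n = self.x.size
        return int(min(n, max(self.degree + 2, int(np.ceil(self.span * n)))))

    def predict(self, xnew) -> np.ndarray:
        """Fitted values at ``xnew``; raises on extrapolation."""
        xnew = np.atleast_1d(np.asarray(xnew, dtype=float))
        lo, hi = self.domain
        if (xnew < lo - _DOMAIN_TOL).any() or (xnew > hi + _DOMAIN_TOL).any():
            bad = xnew[(xnew < lo - _DOMAIN_TOL) | (xnew > hi + _DOMAIN_TOL)]
            raise ExtrapolationError(
                f"prediction at {bad[0]:g} outside fitted domain [{lo:g}, {hi:g}]"
            )
        xnew = np.clip(xnew, lo, hi)
        k = self._window_size()
        xs = self.x[self._order]
        ys = self.y[self._order]
        out = np.empty_like(xnew)
        for j, x0 in enumerate(xnew):
            d = np.abs(xs - x0)
            idx = np.argpartition(d, k - 1)[:k]
            dloc = d[idx]
            dmax = dloc.max()
            if dmax <= 0:
                w = np.ones_like(dloc)
            else:
                w = (1.0 - np.minimum(dloc / dmax, 1.0) ** 3) ** 3
                w = np.maximum(w, 1e-9)  # keep boundary points from zeroing out
            t = xs[idx] - x0
            scale = max(dmax, 1.0)
            deg = min(self.degree, np.unique(xs[idx]).size - 1)
            design = np.vander(t / scale, deg + 1, increasing=True)
            sw = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(design * sw[:, None], ys[idx] * sw, rcond=None)
            out[j] = beta[0]
        return out

    def __call__(self, xnew) -> np.ndarray:  # pragma: no cover - sugar
        return self.predict(xnew)
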