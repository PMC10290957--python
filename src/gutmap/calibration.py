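"""Calibration-curve fitting for targeted metabolite quantification.

A standard mixture is serially diluted (by default a 24-point series from
150 uM down to 17.9 pM) and measured; the ion response is linear in
log-log space only over an interior window — the top of the series
saturates the detector and the bottom disappears into the noise floor.
The fitting procedure therefore trims up to ``max_top`` dilution steps
from the concentrated end and up to ``max_bottom`` from the dilute end,
exhaustively, keeping the window that maximizes R^2 of the ordinary
least-squares fit of log10(ion count) on log10(concentration).  The
lowest and highest retained dilution steps define the lower limit of
quantification (LLOQ) and the upper limit of linearity (ULOL); sample
values outside this range are censored rather than extrapolated.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CalibrationError",
    "CalibrationFit",
    "CalibrationCurve",
    "make_dilution_series",
    "fit_calibration",
    "select_modification",
]

#: measured adduct/modification identifiers
MODIFICATIONS = (
    "deprotonated_anion",
    "protonated_cation",
    "sodium_adduct_cation",
    "dimer_cation",
    "dimer_sodium_adduct_cation",
)


class CalibrationError(ValueError):
    """Raised when a calibration series cannot be fitted."""


def make_dilution_series(
    top_concentration: float, n_points: int, dilution_factor: float = 2.0
) -> np.ndarray:
    """Serial dilution concentrations, element i = top / factor**i.

    The default two-fold series of 24 points from 150 uM spans roughly
    seven orders of magnitude, bottoming out at 17.9 pM.
    """
    if top_concentration <= 0:
        raise ValueError("top_concentration must be > 0")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must be > 1")
    return top_concentration / dilution_factor ** np.arange(n_points, dtype=float)


@dataclass(frozen=True)
class CalibrationFit:
    """Result of the trimmed log-log regression for one modification."""

    slope: float
    intercept: float
    r2: float
    removed_top: int
    removed_bottom: int
    lloq: float   # lowest retained concentration (molar)
    ulol: float   # highest retained concentration (molar)
    n_retained: int

    @property
    def log_range(self) -> float:
        """Width of the linear range in log10 units."""
        return math.log10(self.ulol) - math.log10(self.lloq)


def _ols_loglog(log_c: np.ndarray, log_y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept, r, _, _ = stats.linregress(log_c, log_y)
    return float(slope), float(intercept), float(r * r)


def fit_calibration(
    concentrations: Sequence[float],
    counts: Sequence[float],
    max_top: int = 6,
    max_bottom: int = 12,
    min_points: int = 5,
) -> CalibrationFit:
    """Fit the calibration line with exhaustive top/bottom trimming.

    ``concentrations`` must be sorted in descending order (the dilution
    order).  All (t, b) removals with 0 <= t <= max_top and
    0 <= b <= max_bottom are evaluated; the window maximizing R^2 wins,
    with ties broken by fewer total removals, then fewer top removals.
    Windows containing non-positive ion counts are skipped (the log is
    undefined there), not the whole series.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(counts, dtype=float)
    if c.ndim != 1 or c.shape != y.shape:
        raise ValueError("concentrations and counts must be 1-D and equal length")
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")
    if np.any(np.diff(c) >= 0):
        raise ValueError("concentrations must be strictly decreasing")
    n = c.size
    if n - max_top - max_bottom < min_points:
        raise CalibrationError(
            f"series of {n} points cannot retain {min_points} after removing "
            f"up to {max_top} top and {max_bottom} bottom steps"
        )

    log_c = np.log10(c)
    best: tuple | None = None  # (-r2, t+b, t, fit)
    for t, b in itertools.product(range(max_top + 1), range(max_bottom + 1)):
        lo, hi = t, n - b
        if hi - lo < min_points:
            continue
        yw = y[lo:hi]
        if np.any(yw <= 0):
            continue
        slope, intercept, r2 = _ols_loglog(log_c[lo:hi], np.log10(yw))
        key = (-r2, t + b, t)
        if best is None or key < best[0]:
            fit = CalibrationFit(
                slope=slope,
                intercept=intercept,
                r2=r2,
                removed_top=t,
                removed_bottom=b,
                lloq=float(c[hi - 1]),
                ulol=float(c[lo]),
                n_retained=hi - lo,
            )
            best = (key, fit)
    if best is None:
        raise CalibrationError("no candidate window with all-positive ion counts")
    return best[1]


def matrix_effect(water_fit: CalibrationFit, matrix_fit: CalibrationFit) -> float:
    """Slope ratio of a matrix-matched curve over the water curve.

    A spiked pooled-background series can be fitted alongside the
    water-based standards; the slope ratio is reported as a QC metric
    for ionization suppression/enhancement.  Quantification always uses
    the water curve.
    """
    if water_fit.slope <= 0:
        raise ValueError("water-curve slope must be > 0")
    return matrix_fit.slope / water_fit.slope


def select_modification(
    fits: dict[str, CalibrationFit], coverage: dict[str, int]
) -> str:
    """Pick the modification used for quantification.

    Ranking is deterministic: detected-sample coverage (descending),
    then R^2 (descending), then linear-range width in log10 units
    (descending); modification id breaks exact ties for stability.
    """
    if not fits:
        raise CalibrationError("no successful calibration fit for any modification")
    missing = set(fits) - set(coverage)
    if missing:
        raise ValueError(f"coverage missing for modifications: {sorted(missing)}")

    def key(mod: str):
        f = fits[mod]
        return (-coverage[mod], -f.r2, -f.log_range, mod)

    return min(fits, key=key)


class CalibrationCurve(BaseEstimator, RegressorMixin):
    """Sklearn-style estimator for one metabolite/modification curve.

    ``fit`` takes the dilution-series concentrations (molar, shape
    ``(n, 1)`` or ``(n,)``) and measured ion counts, performs the trimmed
    log-log regression, and exposes the fitted line and linear range as
    trailing-underscore attributes.  ``predict`` maps concentrations to
    expected ion counts; ``predict_concentration`` inverts the curve,
    returning NaN outside the linear range together with a censoring
    code array (-1 below LLOQ, +1 above ULOL, 0 in range).

    Parameters
    ----------
    max_top, max_bottom:
        Maximum dilution steps removable from the concentrated and
        dilute ends of the series.
    min_points:
        Minimum retained points for an acceptable window.
    """

    def __init__(self, max_top: int = 6, max_bottom: int = 12, min_points: int = 5):
        self.max_top = max_top
        self.max_bottom = max_bottom
        self.min_points = min_points

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single concentration column")
            X = X[:, 0]
        fit = fit_calibration(
            X, y, max_top=self.max_top, max_bottom=self.max_bottom,
            min_points=self.min_points,
        )
        self.fit_ = fit
        self.slope_ = fit.slope
        self.intercept_ = fit.intercept
        self.r2_ = fit.r2
        self.lloq_ = fit.lloq
        self.ulol_ = fit.ulol
        self.n_retained_ = fit.n_retained
        return self

    def predict(self, X):
        check_is_fitted(self, "fit_")
        X = np.asarray(X, dtype=float)
        flat = X[:, 0] if X.ndim == 2 else X
        return 10.0 ** (self.intercept_ + self.slope_ * np.log10(flat))

    def predict_concentration(self, counts):
        """Invert the curve; returns (concentration_molar, censor_code)."""
        check_is_fitted(self, "fit_")
        from .quantify import invert_counts

        return invert_counts(np.asarray(counts, dtype=float), self.fit_)
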