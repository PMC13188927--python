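"""Turn raw experimental series into calibrated initial rates and DH curves.

Initial rates on insoluble substrates are only meaningful while substrate
conversion is negligible; the extraction here enforces a conversion cutoff
(default 1%) and regresses product release on time over the retained prefix
of points.  A reducing-sugar standard curve (absorbance at 540 nm vs glucose
concentration) is fitted by ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "StandardCurve",
    "ProgressCurve",
    "InitialRate",
    "DHSeries",
    "fit_standard_curve",
    "initial_rate",
    "dh_series",
]


@dataclass(frozen=True)
class StandardCurve:
    """Linear calibration absorbance → concentration (nM)."""

    slope: float  # nM per absorbance unit
    intercept: float  # nM
    r_squared: float

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("standard-curve slope must be positive")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("R² must lie in [0, 1]")

    def concentration(self, absorbance):
        return self.slope * np.asarray(absorbance, dtype=float) + self.intercept


@dataclass
class ProgressCurve:
    """A product-release time course.

    ``times`` in s (strictly increasing), ``product`` in nM reducing sugar.
    ``substrate_total`` is the nM-equivalent hydrolyzable product at complete
    conversion, used to express the conversion fraction; alternatively a
    precomputed ``conversion`` fraction series may be attached when the
    total is unknown.
    """

    times: np.ndarray
    product: np.ndarray
    substrate_total: float | None = None
    conversion: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.product = np.asarray(self.product, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.product.shape:
            raise ValueError("times and product must be 1-D and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.product < 0):
            raise ValueError("product must be nonnegative")
        if self.conversion is not None:
            self.conversion = np.asarray(self.conversion, dtype=float)
            if self.conversion.shape != self.times.shape:
                raise ValueError("conversion series length mismatch")

    def conversion_fraction(self) -> np.ndarray:
        if self.conversion is not None:
            return self.conversion
        if self.substrate_total is None or self.substrate_total <= 0:
            raise ValueError(
                "conversion fraction unavailable: provide substrate_total "
                "or an explicit conversion series"
            )
        return self.product / self.substrate_total


class InitialRate(NamedTuple):
    rate: float  # nM/s
    n_points_used: int
    r_squared: float
    negative_rate: bool  # noise flag, rate < 0 is reported, not raised


class DHSeries(NamedTuple):
    dh: np.ndarray  # percent
    monotone_violation: bool


def _ols_line(x: np.ndarray, y: np.ndarray, *, force_origin: bool = False):
    if force_origin:
        slope = float(x @ y / (x @ x))
        intercept = 0.0
    else:
        design = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        slope, intercept = float(coef[0]), float(coef[1])
    resid = y - (slope * x + intercept)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else float("nan")
    return slope, intercept, r2


def fit_standard_curve(absorbances, concentrations) -> StandardCurve:
    """OLS line mapping A540 absorbance to glucose concentration (nM)."""
    a = np.asarray(absorbances, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if a.shape != c.shape or a.ndim != 1:
        raise ValueError("absorbances and concentrations must match in length")
    if a.size < 3:
        raise ValueError("standard curve needs at least 3 points")
    if np.ptp(a) == 0:
        raise ValueError("absorbances are constant; calibration is degenerate")
    slope, intercept, r2 = _ols_line(a, c)
    return StandardCurve(slope=slope, intercept=intercept, r_squared=max(r2, 0.0))


def initial_rate(curve: ProgressCurve, max_conversion: float = 0.01,
                 *, force_origin: bool = False) -> InitialRate:
    """Initial rate (nM/s) from the prefix of points under the conversion cutoff.

    Points are retained while the conversion fraction stays ≤
    ``max_conversion`` (default 1%); an OLS line with intercept (blank
    offset) is fitted unless ``force_origin``.  Appending points beyond the
    cutoff never changes the result.  Fewer than 3 eligible points is an
    error: a 2-point slope is never reported.
    """
    frac = curve.conversion_fraction()
    eligible = frac <= max_conversion
    # retained prefix: stop at the first point over the cutoff
    n = int(np.argmin(eligible)) if not eligible.all() else eligible.size
    if n < 3:
        raise ValueError(
            f"only {n} points under the {max_conversion:.2%} conversion "
            "cutoff; at least 3 are required for an initial rate"
        )
    t = curve.times[:n]
    p = curve.product[:n]
    slope, _, r2 = _ols_line(t, p, force_origin=force_origin)
    return InitialRate(rate=slope, n_points_used=n, r_squared=r2,
                       negative_rate=slope < 0)


def dh_series(w0: float, residual_masses) -> DHSeries:
    """Element-wise degree of hydrolysis for a residual-mass series.

    Monotone nondecrease of DH is not enforced (drying/weighing noise) but a
    violation flag is returned alongside the series.
    """
    from .kinetics import degree_of_hydrolysis

    masses = np.asarray(residual_masses, dtype=float)
    dh = np.atleast_1d(degree_of_hydrolysis(w0, masses))
    violation = bool(np.any(np.diff(dh) < 0)) if dh.size > 1 else False
    return DHSeries(dh=dh, monotone_violation=violation)
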