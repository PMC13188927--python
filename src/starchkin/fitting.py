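"""Nonlinear least-squares estimation of the saturation models.

All four model forms in this package (conventional MM on dissolved starch,
conventional and inverse MM on granules, and the Langmuir isotherm) share
one shape, ``y = Vmax·x/(K + x)``, so a single estimator serves them all.

The estimator is a damped Gauss–Newton (Levenberg-style) iteration on the
log-parameters, which keeps both parameters positive with a smooth
optimizer path and guarantees a monotone SSE decrease on every accepted
step.  Initialization: ``Vmax0 = 1.1·max(y)``; ``K0`` from monotone linear
interpolation of the half-maximum crossing on sorted unique x (ties in y
broken by lowest x).  Convergence: relative change in both parameters
< 1e-10 or SSE change < 1e-14·SSE, at most 500 iterations; non-convergence
is flagged, never silent.

A brute-force grid search (:func:`grid_oracle`) and case-resampling
bootstrap intervals (:func:`bootstrap_ci`) accompany the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .kinetics import EnzymeSpec, SubstrateSpec, coverage_from_depletion

__all__ = [
    "RateDataset",
    "BindingDataset",
    "SaturationFit",
    "GridFit",
    "BootstrapCI",
    "fit_saturation",
    "fit_rate_dataset",
    "fit_langmuir",
    "grid_oracle",
    "bootstrap_ci",
]

MAX_ITER = 500
PARAM_TOL = 1e-10
SSE_TOL = 1e-14


def _name(spec) -> str:
    if isinstance(spec, (EnzymeSpec, SubstrateSpec)):
        return spec.name
    return str(spec)


@dataclass
class RateDataset:
    """Replicated (E0, massS0, v0) observations for one enzyme×substrate×mode.

    ``mode`` is "CMM" (substrate load varied, enzyme fixed),
    "IMM" (enzyme varied, load fixed) or "MM_gelatinized".
    Units: e0 nM, mass_s0 mg/mL, v0 nM/s.
    """

    mode: str
    enzyme: str | EnzymeSpec
    substrate: str | SubstrateSpec
    e0: np.ndarray
    mass_s0: np.ndarray
    v0: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self):
        if self.mode not in ("CMM", "IMM", "MM_gelatinized"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.e0 = np.asarray(self.e0, dtype=float)
        self.mass_s0 = np.asarray(self.mass_s0, dtype=float)
        self.v0 = np.asarray(self.v0, dtype=float)
        n = self.v0.size
        if self.e0.size == 1:
            self.e0 = np.full(n, float(self.e0))
        if self.mass_s0.size == 1:
            self.mass_s0 = np.full(n, float(self.mass_s0))
        if not (self.e0.size == self.mass_s0.size == n):
            raise ValueError("e0, mass_s0, v0 must have equal length")
        if self.replicate is None:
            self.replicate = np.zeros(n, dtype=int)
        else:
            self.replicate = np.asarray(self.replicate)
        if np.any(self.e0 <= 0) or np.any(self.mass_s0 <= 0):
            raise ValueError("concentrations and loads must be positive")
        if self.mode in ("CMM", "MM_gelatinized") and np.ptp(self.e0) != 0:
            raise ValueError("CMM mode requires a constant enzyme concentration")
        if self.mode == "IMM" and np.ptp(self.mass_s0) != 0:
            raise ValueError("IMM mode requires a constant substrate load")

    @property
    def enzyme_name(self) -> str:
        return _name(self.enzyme)

    @property
    def substrate_name(self) -> str:
        return _name(self.substrate)


@dataclass
class BindingDataset:
    """(E0, Efree) adsorption observations at one constant substrate load.

    Units: e0, e_free µM; mass_s0 mg/mL.
    """

    e0: np.ndarray
    e_free: np.ndarray
    mass_s0: np.ndarray
    replicate: np.ndarray | None = None
    enzyme: str | EnzymeSpec = ""
    substrate: str | SubstrateSpec = ""

    def __post_init__(self):
        self.e0 = np.asarray(self.e0, dtype=float)
        self.e_free = np.asarray(self.e_free, dtype=float)
        self.mass_s0 = np.asarray(self.mass_s0, dtype=float)
        n = self.e0.size
        if self.mass_s0.size == 1:
            self.mass_s0 = np.full(n, float(self.mass_s0))
        if not (self.e_free.size == self.mass_s0.size == n):
            raise ValueError("e0, e_free, mass_s0 must have equal length")
        if self.replicate is None:
            self.replicate = np.zeros(n, dtype=int)
        if np.any(self.e_free < 0) or np.any(self.e_free > self.e0):
            raise ValueError("e_free must lie in [0, e0]")
        if np.ptp(self.mass_s0) != 0:
            raise ValueError("binding data require a constant substrate load")

    def coverage(self) -> np.ndarray:
        """Γ (nmol/g) via enzyme depletion."""
        return coverage_from_depletion(self.e0, self.e_free, self.mass_s0)


@dataclass
class SaturationFit:
    """Result of fitting y = Vmax·x/(K+x)."""

    vmax: float
    k: float
    se_vmax: float = float("nan")
    se_k: float = float("nan")
    ci_vmax: tuple = (float("nan"), float("nan"))
    ci_k: tuple = (float("nan"), float("nan"))
    r_squared: float = float("nan")
    sse: float = float("nan")
    n_obs: int = 0
    n_iter: int = 0
    converged: bool = False
    flags: tuple = field(default_factory=tuple)

    def predict(self, x):
        return self.vmax * np.asarray(x, dtype=float) / (self.k + np.asarray(x, dtype=float))


class GridFit(NamedTuple):
    vmax: float
    k: float
    sse: float


class BootstrapCI(NamedTuple):
    ci_vmax: tuple
    ci_k: tuple
    n_used: int
    n_dropped: int
    high_dropout: bool


def _half_saturation_guess(x: np.ndarray, y: np.ndarray) -> float:
    xs = np.unique(x)
    ys = np.array([y[x == xi].mean() for xi in xs])
    half = ys.max() / 2.0
    if ys[0] >= half:
        return xs[0] / 2.0 if xs[0] > 0 else float(xs[-1]) / 2.0
    reach = np.nonzero(ys >= half)[0]
    i = int(reach[0])  # first crossing; ties in y resolved at lowest x
    x0, x1, y0, y1 = xs[i - 1], xs[i], ys[i - 1], ys[i]
    if y1 == y0:
        return float(x1)
    return float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))


def fit_saturation(x, y, *, weighting: str = "none",
                   init: tuple | None = None) -> SaturationFit:
    """Fit y = Vmax·x/(K+x) by damped Gauss–Newton on (log Vmax, log K).

    ``weighting``: "none" (unweighted, the default) or "relative"
    (1/y² weights).  ``init`` optionally overrides the automatic
    (Vmax0, K0) starting point, e.g. for bootstrap refits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if np.unique(x).size < 4:
        raise ValueError("at least 4 distinct x values are required")
    if np.any(x < 0):
        raise ValueError("x must be nonnegative")
    if not np.any(y != 0):
        raise ValueError("y is identically zero")
    if weighting not in ("none", "relative"):
        raise ValueError("weighting must be 'none' or 'relative'")

    flags: list[str] = []
    if np.ptp(y) <= 1e-10 * np.max(np.abs(y)):
        # constant response carries no information about K
        return SaturationFit(vmax=float(y[0]), k=float("nan"), n_obs=x.size,
                             converged=False, flags=("degenerate",))

    if weighting == "relative":
        if np.any(y == 0):
            raise ValueError("relative weighting undefined with zero rates")
        w = 1.0 / np.abs(y)
    else:
        w = np.ones_like(y)

    if init is None:
        v0 = 1.1 * float(y.max())
        k0 = _half_saturation_guess(x, y)
    else:
        v0, k0 = float(init[0]), float(init[1])
    if v0 <= 0 or k0 <= 0 or not np.isfinite(k0):
        v0 = max(abs(v0), np.abs(y).max())
        k0 = float(np.median(x[x > 0])) if np.any(x > 0) else 1.0
    theta = np.log([v0, k0])

    def sse_of(th):
        v, k = np.exp(th)
        r = w * (y - v * x / (k + x))
        return float(r @ r), r

    sse, r = sse_of(theta)
    lam = 1e-3
    converged = False
    n_iter = 0
    for n_iter in range(1, MAX_ITER + 1):
        v, k = np.exp(theta)
        m = v * x / (k + x)
        # columns: ∂m/∂logV, ∂m/∂logK
        J = np.column_stack([w * m, -w * m * k / (k + x)])
        g = J.T @ (w * (y - m))
        H = J.T @ J
        accepted = False
        for _ in range(60):
            damp = H + lam * np.diag(np.maximum(np.diag(H), 1e-30))
            try:
                delta = np.linalg.solve(damp, g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            sse_new, _ = sse_of(theta + delta)
            if sse_new <= sse:
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            break
        lam = max(lam / 3.0, 1e-14)
        theta = theta + delta
        drop = sse - sse_new
        sse = sse_new
        if np.max(np.abs(delta)) < PARAM_TOL or drop < SSE_TOL * max(sse, 1e-300):
            converged = True
            break

    v, k = np.exp(theta)
    if not converged:
        flags.append("not_converged")
    if k >= x.max():
        flags.append("saturation_not_reached")

    # linearized (Wald) uncertainty in the original parameterization
    dof = x.size - 2
    se_v = se_k = float("nan")
    ci_v = ci_k = (float("nan"), float("nan"))
    if dof > 0:
        Jo = np.column_stack([w * x / (k + x), -w * v * x / (k + x) ** 2])
        try:
            cov = (sse / dof) * np.linalg.inv(Jo.T @ Jo)
            se_v, se_k = np.sqrt(np.maximum(np.diag(cov), 0.0))
            tq = float(stats.t.ppf(0.975, dof))
            ci_v = (v - tq * se_v, v + tq * se_v)
            ci_k = (k - tq * se_k, k + tq * se_k)
        except np.linalg.LinAlgError:
            flags.append("singular_covariance")

    sst = float(np.sum((w * (y - np.average(y, weights=w**2))) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return SaturationFit(vmax=float(v), k=float(k), se_vmax=float(se_v),
                         se_k=float(se_k), ci_vmax=ci_v, ci_k=ci_k,
                         r_squared=r2, sse=sse, n_obs=x.size, n_iter=n_iter,
                         converged=converged, flags=tuple(flags))


def fit_rate_dataset(ds: RateDataset, **kw):
    """Fit the saturation model appropriate to the dataset's mode.

    Returns ``(fit, params)``: for CMM-like modes the fitted Vmax is
    ``kcat·E0`` and the turnover is recovered from the constant enzyme
    concentration; for IMM the fit parameters are (inv_Vmax, K_M) directly.
    """
    from .kinetics import CMMParams, IMMParams, MMParams

    if ds.mode == "IMM":
        fit = fit_saturation(ds.e0, ds.v0, **kw)
        params = (IMMParams(inv_vmax=fit.vmax, k_m_inverse=fit.k)
                  if fit.converged and fit.vmax > 0 and fit.k > 0 else None)
        return fit, params
    e0 = float(ds.e0[0])
    fit = fit_saturation(ds.mass_s0, ds.v0, **kw)
    if not (fit.converged and fit.vmax > 0 and fit.k > 0):
        return fit, None
    if ds.mode == "CMM":
        return fit, CMMParams(conv_kcat=fit.vmax / e0, k_half=fit.k)
    return fit, MMParams(kcat=fit.vmax / e0, km=fit.k)


def fit_langmuir(data: BindingDataset, **kw) -> SaturationFit:
    """Fit the Langmuir isotherm Γ = ads_Γmax·Efree/(Kd+Efree).

    Coverage is computed from enzyme depletion; the returned fit has
    ``vmax`` = ads_Γmax (nmol/g) and ``k`` = Kd (µM).
    """
    gamma = data.coverage()
    if np.unique(data.e_free).size < 4:
        raise ValueError("at least 4 distinct e_free values are required")
    return fit_saturation(data.e_free, gamma, **kw)


def grid_oracle(x, y, vmax_grid, k_grid) -> GridFit:
    """Exhaustive SSE minimization of y = Vmax·x/(K+x) over a finite grid.

    Deterministic brute force; exists to bound the NLS solution in tests.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vg = np.asarray(vmax_grid, dtype=float)
    kg = np.asarray(k_grid, dtype=float)
    if vg.size == 0 or kg.size == 0:
        raise ValueError("empty parameter grid")
    model = vg[:, None, None] * x[None, None, :] / (kg[None, :, None] + x[None, None, :])
    sse = np.sum((y[None, None, :] - model) ** 2, axis=-1)
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    return GridFit(vmax=float(vg[i]), k=float(kg[j]), sse=float(sse[i, j]))


def bootstrap_ci(x, y, *, n_boot: int = 1000, seed: int | None = None,
                 rng: np.random.Generator | None = None) -> BootstrapCI:
    """Case-resampling percentile bootstrap for (Vmax, K).

    Resamples observations with replacement, refits each resample (warm
    start at the full-data estimate), and reports 2.5/97.5% percentile
    intervals.  Non-convergent or degenerate resamples are dropped and
    counted; more than 20% dropped raises the ``high_dropout`` flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    full = fit_saturation(x, y)
    if not full.converged:
        raise ValueError("bootstrap requires a converged full-data fit")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = x.size
    vs, ks = [], []
    dropped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            f = fit_saturation(x[idx], y[idx], init=(full.vmax, full.k))
        except ValueError:
            dropped += 1
            continue
        if not f.converged:
            dropped += 1
            continue
        vs.append(f.vmax)
        ks.append(f.k)
    if not vs:
        raise ValueError("all bootstrap resamples failed")
    lo_v, hi_v = np.percentile(vs, [2.5, 97.5])
    lo_k, hi_k = np.percentile(ks, [2.5, 97.5])
    return BootstrapCI(ci_vmax=(float(lo_v), float(hi_v)),
                       ci_k=(float(lo_k), float(hi_k)),
                       n_used=len(vs), n_dropped=dropped,
                       high_dropout=dropped > 0.2 * n_boot)
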