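"""Mechanistic forward model of amylase action on starch granules.

The granule surface carries distinct classes of productive binding sites
(PBSs): amylose chains and amylopectin double helices expose different
site densities, affinities and turnover to a given enzyme.  Each class c
is described by a site density gamma_c (nmol per g accessible substrate),
a dissociation constant kd_c (nM), a per-site turnover kcat_c (reducing
sugar equivalents/s) and a capacity — the fraction of granule mass that
can be removed through that class before it is exhausted.

Binding is quasi-equilibrium: at any instant the free enzyme satisfies

    E0 = Efree + sum_c sigma_c * Efree / (kd_c + Efree),

with sigma_c = gamma_c * (accessible class mass per volume) in nM (the
bridge nmol/g x mg/mL = nM is exact).  The conservation function is
strictly increasing in Efree, so the closure is solved by bracketed
root-finding.  Rates are v0 = sum_c kcat_c * complex_c.

Limiting behaviour anchors the simulator to the closed-form models: with a
single class and substrate excess (sigma >> E0) the rate approaches the
conventional MM mass-load form with K_1/2 = kd/gamma and conv_kcat = kcat;
with enzyme excess (E0 >> sigma) it approaches the inverse MM form with
K_M = kd and inv_Vmax = kcat*sigma.

Hydrolysis progress integrates d m_c/dt = -kcat_c * complex_c(t) * mu with
mu the mass removed per nmol of product (default one anhydroglucose unit,
162.14 g/mol); site density scales with remaining accessible class mass,
the simplest depletion law, which yields smooth enzyme-specific plateaus
at the summed class capacities.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

from .fitting import BindingDataset, RateDataset
from .kinetics import (CMMParams, IMMParams, MASS_PER_EVENT_DEFAULT,
                       cmm_rate, imm_rate)

__all__ = [
    "SiteClass",
    "GranuleModel",
    "NoiseModel",
    "Partitioning",
    "ProgressResult",
    "solve_partitioning",
    "mechanistic_rate",
    "model_from_printed",
    "gen_rate_dataset",
    "gen_binding_dataset",
    "simulate_progress",
]


@dataclass(frozen=True)
class SiteClass:
    """One productive-binding-site class on the granule surface."""

    name: str
    gamma: float  # site density, nmol/g
    kd_site: float  # nM
    kcat_site: float  # 1/s, reducing-sugar equivalents per site; 0 = dead site
    capacity: float = 1.0  # fraction of granule mass reachable via this class

    def __post_init__(self):
        if self.gamma <= 0 or self.kd_site <= 0 or self.kcat_site < 0:
            raise ValueError("gamma and kd_site must be positive, kcat_site nonnegative")
        if not 0.0 <= self.capacity <= 1.0:
            raise ValueError("capacity must lie in [0, 1]")


@dataclass(frozen=True)
class GranuleModel:
    """A granule suspension: site classes plus mass load (mg/mL)."""

    classes: tuple
    mass_load: float  # mg/mL
    w0: float | None = None  # mg total granules, metadata only

    def __post_init__(self):
        object.__setattr__(self, "classes", tuple(self.classes))
        if not self.classes:
            raise ValueError("at least one site class is required")
        if self.mass_load <= 0:
            raise ValueError("mass_load must be positive")
        if sum(c.capacity for c in self.classes) > 1.0 + 1e-12:
            raise ValueError("class capacities sum above 1")

    def with_load(self, mass_load: float) -> "GranuleModel":
        return dataclasses.replace(self, mass_load=mass_load)

    def sigmas(self) -> np.ndarray:
        """Attack-site concentrations per class, nM."""
        return np.array([c.gamma for c in self.classes]) * self.mass_load


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian measurement noise, truncated at 4 sigma."""

    cv: float = 0.0
    n_replicates: int = 1
    seed: int | None = None

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def perturb(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.cv == 0.0:
            return np.array(values, dtype=float, copy=True)
        z = np.clip(rng.standard_normal(np.shape(values)), -4.0, 4.0)
        return values * (1.0 + self.cv * z)


class Partitioning(NamedTuple):
    e_free: float  # nM
    complexes: np.ndarray  # nM per class
    residual: float  # conservation residual, nM


class ProgressResult(NamedTuple):
    times: np.ndarray  # s
    dh: np.ndarray  # percent
    residual_mass: np.ndarray  # mg/mL per class at each time, (t, classes)
    hydrolyzed: np.ndarray  # mg/mL total at each time
    n_substeps: int


def _partition(e0: float, sigmas: np.ndarray, kds: np.ndarray) -> Partitioning:
    if e0 < 0:
        raise ValueError("e0 must be nonnegative")
    if e0 == 0 or np.all(sigmas <= 0):
        comp = np.zeros_like(sigmas)
        return Partitioning(e_free=float(e0), complexes=comp, residual=0.0)

    def conservation(ef):
        return ef + np.sum(sigmas * ef / (kds + ef)) - e0

    ef = brentq(conservation, 0.0, e0, rtol=1e-14, xtol=1e-300, maxiter=300)
    comp = sigmas * ef / (kds + ef)
    return Partitioning(e_free=float(ef), complexes=comp,
                        residual=float(conservation(ef)))


def solve_partitioning(e0: float, model: GranuleModel) -> Partitioning:
    """Quasi-equilibrium split of total enzyme into free and per-class bound.

    Solves the monotone conservation closure by bracketed root-finding on
    [0, E0]; the residual is reported.  All concentrations in nM.
    """
    kds = np.array([c.kd_site for c in model.classes])
    return _partition(float(e0), model.sigmas(), kds)


def mechanistic_rate(e0: float, model: GranuleModel) -> float:
    """v0 = sum_c kcat_c·complex_c in nM/s."""
    part = solve_partitioning(e0, model)
    kcats = np.array([c.kcat_site for c in model.classes])
    return float(kcats @ part.complexes)


def model_from_printed(k_half: float, gamma: float, conv_kcat: float,
                       capacity: float = 1.0, name: str = "site") -> SiteClass:
    """Build a single site class from measurable parameters.

    Inverts the limiting relations: kd_site = K_1/2·gamma (nM, exact unit
    bridge mg/mL × nmol/g = nM) and kcat_site = conv_kcat.
    """
    if k_half <= 0 or gamma <= 0 or conv_kcat <= 0:
        raise ValueError("k_half, gamma, conv_kcat must be positive")
    return SiteClass(name=name, gamma=gamma, kd_site=k_half * gamma,
                     kcat_site=conv_kcat, capacity=capacity)


def _replicate_rows(base_x: np.ndarray, base_v: np.ndarray,
                    noise: NoiseModel):
    rng = noise.rng()
    xs, vs, reps = [], [], []
    for i, (x, v) in enumerate(zip(base_x, base_v)):
        noisy = noise.perturb(np.full(noise.n_replicates, v), rng)
        xs.append(np.full(noise.n_replicates, x))
        vs.append(noisy)
        reps.append(np.arange(noise.n_replicates))
    return np.concatenate(xs), np.concatenate(vs), np.concatenate(reps)


def gen_rate_dataset(mode: str, *, loads=None, e0: float | None = None,
                     e0_grid=None, mass_s0: float | None = None,
                     model: GranuleModel | None = None,
                     params=None, noise: NoiseModel = NoiseModel(),
                     enzyme: str = "enzyme",
                     substrate: str = "substrate") -> RateDataset:
    """Generate a synthetic rate dataset.

    Modes: "CMM"/"IMM" draw rates from the mechanistic model (pass
    ``model``); "ideal_CMM"/"ideal_IMM" draw directly from the closed-form
    equations (pass ``params`` as CMMParams/IMMParams).  CMM-type modes
    need ``loads`` (mg/mL grid) and a fixed ``e0`` (nM); IMM-type modes
    need ``e0_grid`` (nM) and a fixed ``mass_s0`` (mg/mL, taken from
    ``model.mass_load`` when a model is given).  Noise is multiplicative
    Gaussian with the given CV, replicated and seeded; cv=0 returns exact
    model values.
    """
    if mode in ("CMM", "ideal_CMM"):
        if loads is None or e0 is None:
            raise ValueError("CMM modes need loads and a fixed e0")
        loads = np.asarray(loads, dtype=float)
        if np.any(loads <= 0) or e0 <= 0:
            raise ValueError("design grid must be positive")
        if mode == "CMM":
            if model is None:
                raise ValueError("mechanistic CMM needs a GranuleModel")
            base = np.array([mechanistic_rate(e0, model.with_load(s))
                             for s in loads])
        else:
            if not isinstance(params, CMMParams):
                raise ValueError("ideal_CMM needs CMMParams")
            base = cmm_rate(e0, loads, params)
        x, v, rep = _replicate_rows(loads, base, noise)
        return RateDataset(mode="CMM", enzyme=enzyme, substrate=substrate,
                           e0=np.full_like(x, e0), mass_s0=x, v0=v,
                           replicate=rep)
    if mode in ("IMM", "ideal_IMM"):
        if e0_grid is None:
            raise ValueError("IMM modes need an e0_grid")
        e0s = np.asarray(e0_grid, dtype=float)
        if np.any(e0s <= 0):
            raise ValueError("design grid must be positive")
        if mode == "IMM":
            if model is None:
                raise ValueError("mechanistic IMM needs a GranuleModel")
            s0 = model.mass_load
            base = np.array([mechanistic_rate(e, model) for e in e0s])
        else:
            if not isinstance(params, IMMParams):
                raise ValueError("ideal_IMM needs IMMParams")
            if mass_s0 is None or mass_s0 <= 0:
                raise ValueError("ideal_IMM needs the constant mass_s0")
            s0 = mass_s0
            base = imm_rate(e0s, params)
        x, v, rep = _replicate_rows(e0s, base, noise)
        return RateDataset(mode="IMM", enzyme=enzyme, substrate=substrate,
                           e0=x, mass_s0=np.full_like(x, s0), v0=v,
                           replicate=rep)
    raise ValueError(f"unknown mode {mode!r}")


def gen_binding_dataset(e0_grid_um, model: GranuleModel,
                        noise: NoiseModel = NoiseModel(),
                        enzyme: str = "enzyme",
                        substrate: str = "substrate") -> BindingDataset:
    """Generate an adsorption dataset (catalysis disabled, acarbose-style).

    E0 grid in µM; free enzyme follows the quasi-equilibrium partitioning,
    and measurement noise acts multiplicatively on the *bound* amount
    (E0 − Efree), mirroring a depletion measurement.  With a single site
    class the noise-free isotherm is exactly Langmuir with
    ads_Γmax = gamma and Kd = kd_site.
    """
    e0s = np.asarray(e0_grid_um, dtype=float)
    if np.any(e0s <= 0):
        raise ValueError("e0 grid must be positive (µM)")
    rng = noise.rng()
    rows_e0, rows_ef, rows_rep = [], [], []
    for e0_um in e0s:
        part = solve_partitioning(e0_um * 1000.0, model)
        bound_um = (e0_um * 1000.0 - part.e_free) / 1000.0
        noisy_bound = np.clip(
            noise.perturb(np.full(noise.n_replicates, bound_um), rng),
            0.0, e0_um)
        rows_e0.append(np.full(noise.n_replicates, e0_um))
        rows_ef.append(e0_um - noisy_bound)
        rows_rep.append(np.arange(noise.n_replicates))
    return BindingDataset(e0=np.concatenate(rows_e0),
                          e_free=np.concatenate(rows_ef),
                          mass_s0=np.full(e0s.size * noise.n_replicates,
                                          model.mass_load),
                          replicate=np.concatenate(rows_rep),
                          enzyme=enzyme, substrate=substrate)


def simulate_progress(model: GranuleModel, e0: float, t_grid,
                      mass_per_event: float = MASS_PER_EVENT_DEFAULT,
                      *, tol: float = 1e-6,
                      max_refine: int = 14) -> ProgressResult:
    """Integrate granule hydrolysis and return the DH(t) series (percent).

    Fixed-step RK4 between requested time points, with the substep count
    doubled until the DH trajectory changes by less than ``tol`` (percent,
    absolute).  Class site density scales with remaining accessible class
    mass, so each class's contribution dies out as its capacity exhausts
    and DH plateaus at 100·Σ capacities.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    if t[0] < 0 or e0 < 0:
        raise ValueError("time and e0 must be nonnegative")
    if mass_per_event <= 0:
        raise ValueError("mass_per_event must be positive")

    gammas = np.array([c.gamma for c in model.classes])
    kds = np.array([c.kd_site for c in model.classes])
    kcats = np.array([c.kcat_site for c in model.classes])
    caps = np.array([c.capacity for c in model.classes])
    m_init = caps * model.mass_load  # accessible mass per class, mg/mL
    # mass removal per unit complex: nM/s * (mg/nmol) -> mg/(L*s) -> mg/(mL*s)
    mu = mass_per_event * 1e-3

    def deriv(state):
        m = np.maximum(state[:-1], 0.0)
        part = _partition(e0, gammas * m, kds)
        dm = -kcats * part.complexes * mu
        return np.append(dm, -dm.sum())

    def integrate(n_sub):
        state = np.append(m_init, 0.0)  # class masses + hydrolyzed total
        out_m = [m_init.copy()]
        out_h = [0.0]
        for a, b in zip(t[:-1], t[1:]):
            h = (b - a) / n_sub
            for _ in range(n_sub):
                k1 = deriv(state)
                k2 = deriv(state + 0.5 * h * k1)
                k3 = deriv(state + 0.5 * h * k2)
                k4 = deriv(state + h * k3)
                state = state + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                state[:-1] = np.maximum(state[:-1], 0.0)
            out_m.append(state[:-1].copy())
            out_h.append(float(state[-1]))
        return np.array(out_m), np.array(out_h)

    n_sub = 1
    m_path, h_path = integrate(n_sub)
    for _ in range(max_refine):
        n_sub *= 2
        m_new, h_new = integrate(n_sub)
        dh_old = 100.0 * (m_init.sum() - m_path.sum(axis=1)) / model.mass_load
        dh_new = 100.0 * (m_init.sum() - m_new.sum(axis=1)) / model.mass_load
        m_path, h_path = m_new, h_new
        if np.max(np.abs(dh_new - dh_old)) < tol:
            break

    dh = 100.0 * (m_init.sum() - m_path.sum(axis=1)) / model.mass_load
    cap_total = 100.0 * caps.sum()
    if np.any(dh > cap_total + 1e-9 * max(cap_total, 1.0)):
        raise RuntimeError("conservation violation: DH exceeds total capacity")
    return ProgressResult(times=t, dh=dh, residual_mass=m_path,
                          hydrolyzed=h_path, n_substeps=n_sub)
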