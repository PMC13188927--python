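"""Closed-form quantities of interfacial amylase–starch kinetics.

Everything in this module is a pure function or a small frozen container.
Canonical units are fixed package-wide and conversions happen only at I/O:

* enzyme concentration           nM
* substrate mass load (massS0)   mg/mL
* adsorption / site density      nmol per g substrate
* reaction rate v0               nM/s reducing-sugar glucose equivalents
* adsorption dissociation K_d    µM
* turnover (kcat-like)           1/s

Two exact unit bridges are used throughout and are worth spelling out:
``nM / (mg/mL) = nmol/g`` (so K_M / K_1/2 is a site density with no extra
factor) and ``µM = nmol/mL`` (so enzyme depletion per mass load converts to
nmol/g with a factor of 1000).

The model family:

* conventional Michaelis–Menten on dissolved substrate,
  ``v0 = kcat·E0·S0/(Km+S0)``;
* conventional MM on granules (mass-load form),
  ``v0 = conv_kcat·E0·massS0/(K_1/2+massS0)``;
* inverse MM on granules (enzyme-varied),
  ``v0 = inv_Vmax·E0/(K_M+E0)`` with ``inv_Vmax = inv_kcat·massS0``;
* Langmuir adsorption, ``Γ = ads_Γmax·Efree/(Kd+Efree)``;
* attack-site density, ``kin_Γmax = K_M/K_1/2``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ANHYDROGLUCOSE_G_PER_MOL",
    "MASS_PER_EVENT_DEFAULT",
    "SubstrateState",
    "SubstrateSpec",
    "EnzymeSpec",
    "MMParams",
    "CMMParams",
    "IMMParams",
    "LangmuirParams",
    "InterfacialParameterSet",
    "degree_of_hydrolysis",
    "langmuir_coverage",
    "coverage_from_depletion",
    "mm_rate",
    "cmm_rate",
    "imm_rate",
    "inv_kcat_from_vmax",
    "kin_gamma_max",
    "specificity_constants",
    "derive_panel",
]

#: molar mass of an anhydroglucose unit in starch, g/mol
ANHYDROGLUCOSE_G_PER_MOL = 162.14

#: default mass removed from a granule per nmol of reducing-sugar glucose
#: equivalent released, mg/nmol (one anhydroglucose unit per equivalent)
MASS_PER_EVENT_DEFAULT = ANHYDROGLUCOSE_G_PER_MOL * 1e-6


def _arr(x, name: str, *, nonneg: bool = False, positive: bool = False):
    a = np.asarray(x, dtype=float)
    if positive and np.any(a <= 0):
        raise ValueError(f"{name} must be strictly positive")
    if nonneg and np.any(a < 0):
        raise ValueError(f"{name} must be nonnegative")
    return a


def _ret(a: np.ndarray):
    return float(a) if a.ndim == 0 else a


class SubstrateState(enum.Enum):
    GRANULAR = "granular"
    GELATINIZED = "gelatinized"


@dataclass(frozen=True)
class SubstrateSpec:
    """A starch substrate: name, short code, botanical source, amylose content."""

    name: str
    abbreviation: str
    source: str = ""
    aac: float = float("nan")  # apparent amylose content, percent
    state: SubstrateState = SubstrateState.GRANULAR

    def __post_init__(self):
        if not np.isnan(self.aac) and not 0.0 <= self.aac <= 100.0:
            raise ValueError("apparent amylose content must lie in [0, 100] %")


@dataclass(frozen=True)
class EnzymeSpec:
    """An amylase: name and molecular weight (kDa) for U↔molar conversions."""

    name: str
    molecular_weight: float = float("nan")  # kDa
    notes: str = ""

    def __post_init__(self):
        if not np.isnan(self.molecular_weight) and self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be positive (kDa)")


@dataclass(frozen=True)
class MMParams:
    """Conventional MM on dissolved substrate: kcat (1/s), Km (mg/mL)."""

    kcat: float
    km: float

    def __post_init__(self):
        if self.kcat <= 0 or self.km <= 0:
            raise ValueError("kcat and Km must be strictly positive")


@dataclass(frozen=True)
class CMMParams:
    """Conventional MM on granules: conv_kcat (1/s), K_1/2 (mg/mL)."""

    conv_kcat: float
    k_half: float

    def __post_init__(self):
        if self.conv_kcat <= 0 or self.k_half <= 0:
            raise ValueError("conv_kcat and K_1/2 must be strictly positive")


@dataclass(frozen=True)
class IMMParams:
    """Inverse MM on granules: inv_Vmax (nM/s), K_M (nM)."""

    inv_vmax: float
    k_m_inverse: float

    def __post_init__(self):
        if self.inv_vmax <= 0 or self.k_m_inverse <= 0:
            raise ValueError("inv_Vmax and K_M must be strictly positive")


@dataclass(frozen=True)
class LangmuirParams:
    """Langmuir isotherm: ads_Γmax (nmol/g), Kd (µM)."""

    ads_gamma_max: float
    kd: float

    def __post_init__(self):
        if self.ads_gamma_max <= 0 or self.kd <= 0:
            raise ValueError("ads_Γmax and Kd must be strictly positive")


@dataclass(frozen=True)
class InterfacialParameterSet:
    """The full derived panel for one enzyme×substrate.

    ``kin_gamma_max = K_M / K_1/2`` holds by construction (build instances
    through :func:`derive_panel`); ``mass_s0_imm`` is the constant substrate
    load of the inverse-MM experiment that converts inv_Vmax to inv_kcat.
    """

    cmm: CMMParams
    imm: IMMParams
    inv_kcat: float  # nmol/(g·s)
    kin_gamma_max: float  # nmol/g
    conv_specificity: float  # mL/(mg·s)
    inv_specificity: float  # mL/(mg·s)
    mass_s0_imm: float  # mg/mL

    def __post_init__(self):
        for f in ("inv_kcat", "kin_gamma_max", "conv_specificity",
                  "inv_specificity", "mass_s0_imm"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be strictly positive")
        expected = self.imm.k_m_inverse / self.cmm.k_half
        if abs(self.kin_gamma_max - expected) > 1e-12 * expected:
            raise ValueError("kin_gamma_max inconsistent with K_M/K_1/2")


def degree_of_hydrolysis(w0, w1):
    """Degree of hydrolysis DH (%) = 100·(W0 − W1)/W0.

    ``w0`` is the initial granule mass and ``w1`` the residual dry mass,
    both in the same units.  Raises ``ValueError`` on an impossible mass
    balance (w1 > w0 or w0 ≤ 0).
    """
    w0a = _arr(w0, "w0", positive=True)
    w1a = _arr(w1, "w1", nonneg=True)
    if np.any(w1a > w0a):
        raise ValueError("residual mass w1 exceeds initial mass w0")
    return _ret(100.0 * (w0a - w1a) / w0a)


def langmuir_coverage(e_free, p: LangmuirParams):
    """Adsorbed enzyme Γ (nmol/g) at free concentration ``e_free`` (µM)."""
    ef = _arr(e_free, "e_free", nonneg=True)
    return _ret(p.ads_gamma_max * ef / (p.kd + ef))


def coverage_from_depletion(e0, e_free, mass_s0):
    """Coverage Γ = (E0 − Efree)/massS0 in nmol/g.

    E0, Efree in µM (= nmol/mL), massS0 in mg/mL; the factor 1000 converts
    nmol/mg to nmol/g.
    """
    e0a = _arr(e0, "e0", nonneg=True)
    efa = _arr(e_free, "e_free", nonneg=True)
    sa = _arr(mass_s0, "mass_s0", positive=True)
    if np.any(efa > e0a):
        raise ValueError("e_free exceeds e0 (negative adsorption)")
    return _ret(1000.0 * (e0a - efa) / sa)


def mm_rate(e0, s0, p: MMParams):
    """v0 = kcat·E0·S0/(Km + S0) in nM/s (E0 nM, S0 mg/mL)."""
    e0a = _arr(e0, "e0", nonneg=True)
    s0a = _arr(s0, "s0", nonneg=True)
    return _ret(p.kcat * e0a * s0a / (p.km + s0a))


def cmm_rate(e0, mass_s0, p: CMMParams):
    """v0 = conv_kcat·E0·massS0/(K_1/2 + massS0) in nM/s."""
    e0a = _arr(e0, "e0", nonneg=True)
    s0a = _arr(mass_s0, "mass_s0", nonneg=True)
    return _ret(p.conv_kcat * e0a * s0a / (p.k_half + s0a))


def imm_rate(e0, p: IMMParams):
    """v0 = inv_Vmax·E0/(K_M + E0) in nM/s (E0 nM)."""
    e0a = _arr(e0, "e0", nonneg=True)
    return _ret(p.inv_vmax * e0a / (p.k_m_inverse + e0a))


def inv_kcat_from_vmax(inv_vmax, mass_s0):
    """inv_kcat = inv_Vmax/massS0 in nmol/(g·s); nM/(mg/mL) = nmol/g exactly."""
    va = _arr(inv_vmax, "inv_vmax", nonneg=True)
    sa = _arr(mass_s0, "mass_s0", positive=True)
    return _ret(va / sa)


def kin_gamma_max(k_m_inverse, k_half):
    """Attack-site density kin_Γmax = K_M/K_1/2 in nmol/g.

    K_M in nM, K_1/2 in mg/mL; the unit bridge nM/(mg/mL) = nmol/g is exact,
    so the plain ratio is already in nmol per gram of substrate.
    """
    ka = _arr(k_m_inverse, "k_m_inverse", positive=True)
    ha = _arr(k_half, "k_half", positive=True)
    return _ret(ka / ha)


def specificity_constants(cmm: CMMParams, imm: IMMParams, mass_s0):
    """(conv_kcat/K_1/2, inv_kcat/K_M), both in mL/(mg·s).

    The inverse-limb constant uses inv_kcat = inv_Vmax/massS0; units:
    (nmol/(g·s)) / nM = (1/s)/(mg/mL)·... reduces exactly to mL/(mg·s).
    """
    sa = _arr(mass_s0, "mass_s0", positive=True)
    conv = cmm.conv_kcat / cmm.k_half
    inv = (imm.inv_vmax / sa) / imm.k_m_inverse
    return _ret(np.asarray(conv, dtype=float)), _ret(np.asarray(inv))


def derive_panel(cmm: CMMParams, imm: IMMParams, mass_s0: float) -> InterfacialParameterSet:
    """Assemble the full derived panel from the two fitted limbs.

    ``mass_s0`` must be the constant substrate load of the inverse-MM
    experiment (mg/mL).
    """
    conv, inv = specificity_constants(cmm, imm, mass_s0)
    return InterfacialParameterSet(
        cmm=cmm,
        imm=imm,
        inv_kcat=inv_kcat_from_vmax(imm.inv_vmax, mass_s0),
        kin_gamma_max=kin_gamma_max(imm.k_m_inverse, cmm.k_half),
        conv_specificity=conv,
        inv_specificity=inv,
        mass_s0_imm=float(mass_s0),
    )
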