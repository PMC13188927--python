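"""Dual CMM+IMM interfacial analysis per enzyme×substrate.

The conventional limb (substrate-load titration at fixed enzyme) yields
(K_1/2, conv_kcat); the inverse limb (enzyme titration at fixed load)
yields (K_M, inv_Vmax).  Combining the two gives the attack-site density
kin_Γmax = K_M/K_1/2 and both specificity constants, and — when an
adsorption isotherm is available — the fraction of adsorbed enzyme that
sits on productive attack sites, kin_Γmax/ads_Γmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import (BindingDataset, RateDataset, SaturationFit,
                      fit_langmuir, fit_rate_dataset)
from .kinetics import (CMMParams, IMMParams, InterfacialParameterSet,
                       derive_panel)

__all__ = [
    "EnzymeSubstrateResult",
    "analyze_pair",
    "compare_enzymes",
    "kin_ads_ratio",
    "report",
]

#: parameters compared across enzymes, with accessors on a result
_FOLD_PARAMS = ("K_1/2", "K_M", "conv_kcat/K_1/2", "inv_kcat/K_M",
                "K_d", "1/K_d")


@dataclass
class EnzymeSubstrateResult:
    """All fits and the derived panel for one enzyme on one substrate."""

    enzyme: str
    substrate: str
    cmm_fit: SaturationFit
    imm_fit: SaturationFit
    cmm_params: CMMParams | None
    imm_params: IMMParams | None
    derived: InterfacialParameterSet | None
    langmuir_fit: SaturationFit | None = None
    kin_ads_ratio: float | None = None  # percent, this substrate only
    flags: tuple = ()

    def value(self, parameter: str) -> float:
        """Look up one of the comparison-table parameters."""
        if self.derived is None:
            raise ValueError(f"{self.enzyme}×{self.substrate}: no derived panel")
        d = self.derived
        table = {
            "K_1/2": d.cmm.k_half,
            "conv_kcat": d.cmm.conv_kcat,
            "K_M": d.imm.k_m_inverse,
            "inv_Vmax": d.imm.inv_vmax,
            "inv_kcat": d.inv_kcat,
            "kin_Gamma_max": d.kin_gamma_max,
            "conv_kcat/K_1/2": d.conv_specificity,
            "inv_kcat/K_M": d.inv_specificity,
        }
        if parameter in table:
            return table[parameter]
        if parameter in ("K_d", "1/K_d"):
            if self.langmuir_fit is None:
                raise ValueError(f"no binding data for {self.enzyme}×{self.substrate}")
            kd = self.langmuir_fit.k
            return kd if parameter == "K_d" else 1.0 / kd
        if parameter == "ads_Gamma_max":
            if self.langmuir_fit is None:
                raise ValueError(f"no binding data for {self.enzyme}×{self.substrate}")
            return self.langmuir_fit.vmax
        raise KeyError(parameter)


def analyze_pair(cmm_data: RateDataset, imm_data: RateDataset,
                 binding_data: BindingDataset | None = None) -> EnzymeSubstrateResult:
    """Run the dual-limb analysis for one enzyme×substrate.

    The substrate load entering inv_kcat (and the inverse specificity
    constant) is the inverse experiment's constant load, never anything
    taken from the conventional dataset.  If either limb fails to converge
    the result carries flags and the derived panel is withheld.
    """
    if cmm_data.mode != "CMM" or imm_data.mode != "IMM":
        raise ValueError("analyze_pair expects a CMM dataset and an IMM dataset")
    if (cmm_data.enzyme_name != imm_data.enzyme_name
            or cmm_data.substrate_name != imm_data.substrate_name):
        raise ValueError(
            "datasets disagree on enzyme/substrate: "
            f"{cmm_data.enzyme_name}×{cmm_data.substrate_name} vs "
            f"{imm_data.enzyme_name}×{imm_data.substrate_name}")

    cmm_fit, cmm_params = fit_rate_dataset(cmm_data)
    imm_fit, imm_params = fit_rate_dataset(imm_data)
    flags = []
    if cmm_params is None:
        flags.append("cmm_fit_failed")
    if imm_params is None:
        flags.append("imm_fit_failed")

    derived = None
    if not flags:
        mass_s0 = float(imm_data.mass_s0[0])
        derived = derive_panel(cmm_params, imm_params, mass_s0)

    langmuir = None
    ratio = None
    if binding_data is not None:
        langmuir = fit_langmuir(binding_data)
        if not langmuir.converged:
            flags.append("langmuir_fit_failed")
        elif derived is not None:
            ratio = 100.0 * derived.kin_gamma_max / langmuir.vmax

    return EnzymeSubstrateResult(
        enzyme=cmm_data.enzyme_name, substrate=cmm_data.substrate_name,
        cmm_fit=cmm_fit, imm_fit=imm_fit, cmm_params=cmm_params,
        imm_params=imm_params, derived=derived, langmuir_fit=langmuir,
        kin_ads_ratio=ratio, flags=tuple(flags))


def compare_enzymes(a: list[EnzymeSubstrateResult],
                    b: list[EnzymeSubstrateResult]) -> pd.DataFrame:
    """Per-substrate fold changes between two enzymes.

    Folds are reported as max/min (≥ 1) with a direction column naming the
    enzyme with the lower value; K_d-derived rows appear only where both
    results carry binding fits.
    """
    sub_a = {r.substrate for r in a}
    sub_b = {r.substrate for r in b}
    if sub_a != sub_b:
        raise ValueError(
            "substrate sets differ: only in A "
            f"{sorted(sub_a - sub_b)}, only in B {sorted(sub_b - sub_a)}")
    by_a = {r.substrate: r for r in a}
    by_b = {r.substrate: r for r in b}
    rows = []
    for sub in sorted(sub_a):
        ra, rb = by_a[sub], by_b[sub]
        for param in _FOLD_PARAMS:
            try:
                va, vb = ra.value(param), rb.value(param)
            except ValueError:
                continue
            lo, hi = min(va, vb), max(va, vb)
            direction = ("equal" if va == vb
                         else ("A lower" if va < vb else "B lower"))
            rows.append({"substrate": sub, "parameter": param,
                         "enzyme_a": ra.enzyme, "value_a": va,
                         "enzyme_b": rb.enzyme, "value_b": vb,
                         "fold": hi / lo, "direction": direction})
    return pd.DataFrame(rows)


def kin_ads_ratio(kin_values, ads_values, *, per_substrate: bool = False):
    """100·mean(kin_Γmax)/mean(ads_Γmax), in percent.

    ``per_substrate=True`` instead returns the element-wise paired ratios
    (the averaging set is otherwise the arithmetic mean over substrates).
    """
    kin = np.asarray(kin_values, dtype=float)
    ads = np.asarray(ads_values, dtype=float)
    if kin.size == 0 or ads.size == 0:
        raise ValueError("empty input list")
    if per_substrate:
        if kin.shape != ads.shape:
            raise ValueError("paired mode needs equal-length lists")
        if np.any(ads <= 0):
            raise ValueError("adsorption densities must be positive")
        return 100.0 * kin / ads
    if kin.mean() <= 0 or ads.mean() <= 0:
        raise ValueError("means must be positive")
    return float(100.0 * kin.mean() / ads.mean())


def report(results: list[EnzymeSubstrateResult]) -> dict:
    """Deterministic parameter tables for a set of results.

    Returns ``{"parameters": DataFrame, "folds": DataFrame|None}``; rows
    ordered by (enzyme, substrate abbreviation), fold table emitted when
    exactly two enzymes are present with matching substrate sets.
    Duplicate enzyme×substrate entries are an error.
    """
    if not results:
        raise ValueError("no results to report")
    seen = set()
    for r in results:
        key = (r.enzyme, r.substrate)
        if key in seen:
            raise ValueError(f"duplicate result for {r.enzyme}×{r.substrate}")
        seen.add(key)
    ordered = sorted(results, key=lambda r: (r.enzyme, r.substrate))
    rows = []
    for r in ordered:
        row = {"enzyme": r.enzyme, "substrate": r.substrate,
               "flags": ";".join(r.flags)}
        if r.derived is not None:
            d = r.derived
            row.update({
                "K_half_mg_per_mL": d.cmm.k_half,
                "conv_kcat_per_s": d.cmm.conv_kcat,
                "conv_kcat_over_K_half_mL_per_mg_s": d.conv_specificity,
                "K_M_nM": d.imm.k_m_inverse,
                "inv_Vmax_nM_per_s": d.imm.inv_vmax,
                "inv_kcat_nmol_per_g_s": d.inv_kcat,
                "inv_kcat_over_K_M_mL_per_mg_s": d.inv_specificity,
                "kin_Gamma_max_nmol_per_g": d.kin_gamma_max,
            })
        if r.langmuir_fit is not None and r.langmuir_fit.converged:
            row["ads_Gamma_max_nmol_per_g"] = r.langmuir_fit.vmax
            row["K_d_uM"] = r.langmuir_fit.k
        if r.kin_ads_ratio is not None:
            row["kin_over_ads_percent"] = r.kin_ads_ratio
        rows.append(row)
    params = pd.DataFrame(rows)

    folds = None
    enzymes = sorted({r.enzyme for r in ordered})
    if len(enzymes) == 2:
        a = [r for r in ordered if r.enzyme == enzymes[0] and r.derived]
        b = [r for r in ordered if r.enzyme == enzymes[1] and r.derived]
        if a and b and {r.substrate for r in a} == {r.substrate for r in b}:
            folds = compare_enzymes(a, b)
    return {"parameters": params, "folds": folds}
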