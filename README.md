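# starchkin

Interfacial enzyme kinetics of raw-starch-degrading amylases, as a
reusable Python library and CLI.

Hydrolysis of native starch granules is an interfacial reaction: the
enzyme works on an insoluble particle surface, so classical solution
kinetics need to be reformulated.  `starchkin` implements the two
complementary experiments used to characterize such systems and the
parameter algebra that connects them:

* **Conventional Michaelis–Menten (CMM)** — substrate mass load varied at
  fixed enzyme: `v0 = conv_kcat · E0 · massS0 / (K_1/2 + massS0)`, giving
  the half-saturating mass load `K_1/2` (mg/mL) and turnover `conv_kcat`
  (1/s).
* **Inverse Michaelis–Menten (IMM)** — enzyme varied at fixed load:
  `v0 = inv_Vmax · E0 / (K_M + E0)`, giving the molar attack-site
  half-saturation `K_M` (nM) and the site-saturated rate `inv_Vmax`
  (nM/s), with `inv_Vmax = inv_kcat · massS0`.
* **Attack-site density** — combining the limbs:
  `kin_Γmax = K_M / K_1/2` (nmol of enzyme-attackable sites per gram of
  substrate; the unit bridge nM / (mg/mL) = nmol/g is exact).
* **Langmuir adsorption** — `Γ = ads_Γmax · Efree / (Kd + Efree)` from
  enzyme-depletion measurements, so kinetically productive sites
  (`kin_Γmax`) can be compared with total adsorption sites (`ads_Γmax`).
* **Specificity constants** — `conv_kcat/K_1/2` and `inv_kcat/K_M`, both
  in mL/(mg·s); for a single homogeneous site class the two coincide.

Around that core the package provides initial-rate extraction from
progress curves under a conversion cutoff, degree-of-hydrolysis (DH)
series, one-way ANOVA with Duncan's multiple range test and compact
letter displays, and a mechanistic granule simulator in which
heterogeneous productive-binding-site classes (amylose-type vs
amylopectin-double-helix-type) with individual densities, affinities,
turnovers and depletable capacities generate saturation curves, binding
isotherms and plateauing hydrolysis curves.

Intended users: enzymologists and modellers analyzing amylase (or other
interfacial depolymerase) titration data, and anyone needing a
transparent synthetic-data generator for such experiments.

## Worked example

Generate a noisy triplicate CMM + IMM experiment for one enzyme on
granular amylose and run the dual-limb analysis:

```python
import numpy as np
from starchkin import (CMMParams, IMMParams, NoiseModel, analyze_pair,
                       gen_rate_dataset)

loads = np.linspace(10, 300, 12)          # mg/mL substrate loads
e0_grid = np.geomspace(4, 125, 8)         # nM enzyme grid
noise = NoiseModel(cv=0.05, n_replicates=3, seed=7)

cmm = gen_rate_dataset("ideal_CMM", loads=loads, e0=12.0,
                       params=CMMParams(conv_kcat=100.0, k_half=105.2),
                       noise=noise, enzyme="wildtype", substrate="CAM")
imm = gen_rate_dataset("ideal_IMM", e0_grid=e0_grid, mass_s0=25.0,
                       params=IMMParams(inv_vmax=950.0, k_m_inverse=39.976),
                       noise=noise, enzyme="wildtype", substrate="CAM")

result = analyze_pair(cmm, imm)
d = result.derived
print(f"K_1/2      = {d.cmm.k_half:8.1f} mg/mL")
print(f"conv_kcat  = {d.cmm.conv_kcat:8.1f} 1/s")
print(f"K_M        = {d.imm.k_m_inverse:8.1f} nM")
print(f"inv_Vmax   = {d.imm.inv_vmax:8.1f} nM/s")
print(f"kin_Gmax   = {d.kin_gamma_max:8.3f} nmol/g")
print(f"conv spec. = {d.conv_specificity:8.3f} mL/(mg*s)")
print(f"inv  spec. = {d.inv_specificity:8.3f} mL/(mg*s)")
```

Output:

```
K_1/2      =     99.9 mg/mL
conv_kcat  =     95.5 1/s
K_M        =     37.3 nM
inv_Vmax   =    893.2 nM/s
kin_Gmax   =    0.373 nmol/g
conv spec. =    0.956 mL/(mg*s)
inv  spec. =    0.958 mL/(mg*s)
```

The data were generated with K_1/2 = 105.2 mg/mL and K_M = 39.976 nM, a
single-site parameterization whose true site density is
39.976/105.2 = 0.38 nmol/g; at 5% measurement noise the pipeline recovers
K_1/2 within ~5%, the site density as 0.373 nmol/g, and the two
specificity constants agree — the signature of a single homogeneous site
class.

The same analysis is available from the shell:

```sh
starchkin simulate --config sim.toml --out data/
starchkin pipeline --cmm data/rates_cmm.csv --imm data/rates_imm.csv \
    --binding data/binding.csv --out results/
starchkin duncan --input groups.csv --alpha 0.05
```

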