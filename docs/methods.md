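# Methods

## Models

### Saturation forms

All estimation in this package reduces to one functional form,
`y = Vmax·x/(K + x)`, instantiated four ways:

| form | x | y | Vmax | K |
|---|---|---|---|---|
| MM (dissolved substrate) | S0 (mg/mL) | v0 (nM/s) | kcat·E0 | Km |
| CMM (granules, load varied) | massS0 (mg/mL) | v0 (nM/s) | conv_kcat·E0 | K_1/2 |
| IMM (granules, enzyme varied) | E0 (nM) | v0 (nM/s) | inv_Vmax | K_M |
| Langmuir adsorption | Efree (µM) | Γ (nmol/g) | ads_Γmax | Kd |

Canonical units are fixed package-wide — enzyme nM, substrate mass load
mg/mL, coverage and site densities nmol/g, rates nM/s of reducing-sugar
glucose equivalents, adsorption Kd in µM — and unit conversion happens
only at I/O.  Two bridges are exact and used without numeric factors:
nM / (mg/mL) = nmol/g and µM = nmol/mL.  One enzyme unit (U) is defined
as 1 µmol reducing sugar released per second.

Rates on granular substrates are molar reducing-sugar production rates
(nM/s), which is what makes the kcat-like parameters carry units of 1/s.
Zero substrate or zero enzyme yields rate 0 (a well-defined limit), not
an error.

### Derived interfacial panel

From the two granular limbs fitted independently:

* `inv_kcat = inv_Vmax / massS0` (nmol·g⁻¹·s⁻¹), using the **inverse**
  experiment's constant load — never anything from the conventional
  dataset;
* attack-site density `kin_Γmax = K_M / K_1/2` (nmol/g);
* specificity constants `conv_kcat/K_1/2` and `inv_kcat/K_M`, both
  mL·mg⁻¹·s⁻¹.

For a single homogeneous site class with density γ, dissociation
constant kd and per-site turnover kcat, the limiting relations are
K_1/2 = kd/γ, K_M = kd, conv_kcat = kcat and inv_Vmax = kcat·γ·massS0;
the two specificity constants then coincide algebraically.  This
identity is the main internal consistency check of the pipeline.

The ratio of kinetically productive to total adsorbed sites is reported
as 100·mean(kin_Γmax)/mean(ads_Γmax) across substrates (arithmetic
means); because the averaging set of such "-ave" summaries is a
convention rather than a derivation, a per-substrate paired-ratio mode
is exposed as well.

## Estimation

### Nonlinear least squares

`fit_saturation` minimizes the unweighted SSE by a damped (Levenberg)
Gauss–Newton iteration on (log Vmax, log K).  The log-parameterization
enforces positivity with a smooth optimizer path instead of clipping.
Steps are accepted only when the SSE does not increase; the damping
factor is decreased ×3 on acceptance and increased ×10 on rejection.

* Initialization: `Vmax0 = 1.1·max(y)`; `K0` from monotone linear
  interpolation of the half-maximum crossing on sorted unique x (y
  averaged over replicates, ties resolved at the lowest x).
* Convergence: relative change in both parameters < 1e-10, or SSE
  decrease < 1e-14·SSE; at most 500 iterations.  Non-convergence is
  flagged on the returned fit, never silent.
* Flags: `saturation_not_reached` when the fitted K lies at or beyond
  the design range (the data are effectively linear); `degenerate` when
  the response is constant to within 1e-10 relative.
* Unweighted least squares is the default (matching the common
  spreadsheet/Origin workflow these experiments are analyzed with); a
  1/y² relative-weighting switch is available.
* Replicates enter as individual observations rather than as means,
  preserving the error structure for the bootstrap.

Uncertainty is reported two ways: linearized (Wald) standard errors and
t-based 95% intervals from the Jacobian at the optimum, and a
case-resampling percentile bootstrap (2.5/97.5%), seeded and
reproducible, with non-convergent resamples dropped and counted (a
>20% drop rate raises a flag).  A deterministic brute-force grid search
over (Vmax, K) exists purely as an oracle bound for testing the
optimizer.

### Initial rates and calibration

Initial rates are OLS slopes of product vs time over the prefix of
points whose conversion fraction stays at or below a cutoff (default
1%); the regression includes an intercept by default (reagent blanks
drift), with a force-through-origin switch.  Fewer than three eligible
points is an error — a two-point slope is never reported.  When the
substrate-equivalent total is unknown, a user-supplied conversion
series drives the cutoff instead.  The reducing-sugar standard curve is
a plain OLS line from absorbance to concentration; no absorbance
nonlinearity correction is attempted.

DH series apply `DH(%) = 100·(W0−W1)/W0` element-wise; experimental
noise can make the series non-monotone, so monotonicity is flagged
rather than enforced.

## Group statistics

Duncan's multiple range test operates on ranked group means with
critical ranges `R_p = q(α_p, p, df)·√(MSE/n)` and protection levels
`α_p = 1−(1−α)^(p−1)`, with the standard step-down rule: a span found
homogeneous is never subdivided.  Only balanced designs are accepted;
the triplicate designs this package targets are balanced, and harmonic
mean approximations for unbalanced data are deliberately not offered.
Studentized-range quantiles come from scipy's `studentized_range`
distribution (CDF by numerical integration, quantiles by root-finding);
for k = 2 the identity q = √2·t is used as a correctness check, and a
seeded Monte-Carlo estimate serves as an independent oracle in tests.
Equal means tie-break by group label order.

Compact letter displays use insert-and-absorb: every significant pair
splits the columns containing both members, subsets are absorbed, and
letters are assigned to columns ordered by the highest-mean member.
The display is exact — two groups share a letter iff their comparison
is non-significant — though the letter count is not guaranteed minimal.
The figure convention of uppercase letters across enzymes and lowercase
across substrates is realized as two independent one-way analyses, one
per factor slice.

## Granule simulator

The synthetic-data generator is a mechanistic model of interfacial
catalysis, not a curve-with-noise: granule surfaces carry one or more
productive-binding-site classes, each with density γ (nmol/g), kd (nM),
per-site turnover (1/s, reducing-sugar equivalents; 0 = catalytically
dead class, useful for adsorption-only experiments) and a capacity (the
granule mass fraction reachable through that class).

* **Partitioning.** Enzyme distributes over classes by quasi-equilibrium
  binding; the monotone conservation closure is solved by bracketed
  root-finding (Brent) on [0, E0] to ~1e-14 relative, with the residual
  reported.  The single-class case has a closed-form quadratic root that
  serves as the test oracle.
* **Rates.** v0 = Σ kcat_c·complex_c.  Regime separation (σ/E0 or E0/σ)
  of 10²–10³ reproduces the ideal CMM/IMM forms to ≲0.5%, and this
  convergence is tested at both separations.
* **Progress curves.** d m_c/dt = −kcat_c·complex_c·µ with µ the mass
  per nmol product; σ_c scales with remaining accessible class mass —
  the simplest depletion law — so each class decays out smoothly and DH
  plateaus at 100·Σ capacities.  Integration is fixed-step RK4 between
  requested time points with substep doubling until the DH trajectory
  changes < 1e-6 (percent, absolute); hydrolyzed + residual mass is
  conserved to ≤1e-9 relative.  µ defaults to one anhydroglucose unit
  (162.14 g/mol) per glucose equivalent and is overridable, since
  maltohexaose-range products shift the mass-per-equivalent.
* **Noise.** Multiplicative Gaussian with a chosen CV, truncated at ±4σ
  to prevent negative rates; one seed drives all replicates, and
  generation is bit-reproducible.  For adsorption data the noise acts on
  the measured depletion (E0−Efree): a CV on the bound amount is what a
  Bradford-based depletion assay produces, whereas noising Efree itself
  would inflate the error of small depletions at high E0 without bound.

Default study conditions mirror the experimental designs the package
targets: granular CMM at 12 loads spanning 10–300 mg/mL with 12 nM
enzyme; IMM over 4–125 nM enzyme at 25 mg/mL; adsorption over 0.2–7 µM
at 25 mg/mL; triplicates at 5% CV (rates) or 3% CV (binding).

What the simulator does **not** emulate: granule geometry and surface
area evolution, pore diffusion, product-length distributions, binding
on/off rates (quasi-equilibrium is re-solved at every integration
step), time-varying turnover, and temperature/pH dependence.  Passing
tests therefore demonstrate correctness of the estimation machinery and
internal consistency of the site-class picture — not that real granule
data satisfy these idealizations.

## Problem sizes and numerical choices

The test suite and the reproduction script run on deliberately small
problems — tens of observations per fit, ≤ 200 simulated experiments
for bootstrap-coverage checks, 100 seeded datasets for optimizer-vs-grid
bounds, 2×10⁶ draws for the Monte-Carlo quantile oracle — sizes at
which every check completes in seconds while the statistical tolerances
(15% for K recovery at 5% CV, 10% for saturation coverage at 3% CV,
established by simulation) hold with margin.

Known numerical edge cases: K escaping the design range (flagged, see
above); exactly collinear bootstrap resamples (dropped and counted);
zero within-group variance in ANOVA (flagged; all critical ranges
collapse to zero, so any nonzero difference is significant); progress
integration near exhaustion (class masses clamped at 0; DH is checked
against total capacity to 1e-9).

## Limitations

* The dual-limb analysis assumes a shared steady state between the CMM
  and IMM experiments; when site classes are heterogeneous the derived
  kin_Γmax reflects the enzyme's *targeted* class, not the surface
  total — that gap is exactly what comparing kin_Γmax with ads_Γmax is
  for.
* Whether granular-limb rates should be enzyme-normalized before fitting
  is a design freedom; here E0 is explicit and conv_kcat is fitted
  jointly from Vmax/E0.
* Langmuir Kd is expressed in molar enzyme units (µM); mass-based
  affinities require conversion through the enzyme's molecular weight.
* No global multi-dataset fitting or model selection beyond the stated
  forms; no spatially resolved granule modeling.
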