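# Methods

## Scope and unit system

The package models a 14-day repeated-dosing experiment on renal proximal
tubule epithelial cells (RPTECs): 2000 µm³ cells, 2.1×10⁶ cells per well,
3 mL serum-free medium, daily doses of cyclosporine A (CsA) at 5 or 15
µmol/L with the medium renewed before each dose.  All bookkeeping is per
representative cell: one cell, its share of the medium
(3 mL / 2.1×10⁶ ≈ 1.43×10⁶ µm³) and of the vial wall.  Internal units are
zmol for quantities, µm³ for volumes and seconds for time, chosen so that
1 µmol/L = 1 zmol/µm³ exactly; unit conversion happens only at the I/O
boundary.  This makes the published per-cell parameter values directly
usable and avoids silent exponent errors at the 10⁶–10⁸ zmol magnitudes
involved.

## Disposition model

Three pools (cytosol, extracellular medium, vial wall) plus a cumulative
metabolism integral.  Uptake is first-order in the extracellular
concentration (clearance `CLin1`, µm³/s).  Efflux is Michaelis–Menten in
the *intracellular concentration*: `CLout1·C_cyt/(Kmout1 + C_cyt)` with
`Kmout1` in µmol/L and `CLout1` parameterized as the ratio
`CLout1/Kmout1` (µm³/s) times `Kmout1`.  The concentration reading of the
Michaelis term is the only dimensionally consistent one given those units,
and it reproduces the published repeated-dosing behaviour (accumulation
ratios, steady-state times).  Wall exchange is first-order attachment
`k1·Q_ext` with fractional-order ("fractal") detachment `k2·Q_wall^k3`,
`k3 ∈ (0, 0.95]`; the detachment term is evaluated as 0 at `Q_wall = 0`
and the state is clipped at 0 inside the right-hand side to guard against
solver micro-undershoot.  Metabolism is Michaelis–Menten in the
intracellular quantity (`vmax` zmol/s, `Km2` zmol) into a metabolite sink.

Medium renewal semantics: at each dosing event the extracellular pool is
*reset* to dose × medium volume; the discarded quantity is recorded in an
audit trail so the total mass balance (dosed = in compartments +
metabolized + discarded) closes to solver tolerance.  Wall-bound drug
persists through renewals — whether the wall is partially stripped by a
medium change is unknowable from the data, and keeping it is the
conservative choice.  Observation times falling exactly on a dose
boundary report the pre-renewal state, matching the sampling protocol
("at 24 h, just before changing the medium").

Integration uses LSODA at rtol 10⁻⁶ / atol 10⁻⁹ zmol with a hard restart
at every dosing event (no interpolation across the discontinuity).  A
fixed-step classical Runge–Kutta path (`simulate_pk_fast`, numba-compiled,
dt = 60–120 s) serves the MCMC likelihood: the disposition system's rates
are all slower than ~10⁻³/s, so the fixed-step solution agrees with the
adaptive one to ~10⁻⁶ relative, far below measurement noise.

## Coupled pathway model — a documented reconstruction

The cell-stress module is an oxidative-stress gene-regulation network in
the lineage of the generic Keap1–Nrf2–ARE kinetic models.  The published
source for its complete equation list and fixed-parameter table is
supplementary material that is not distributed with this package, so the
network is **reconstructed** from the documented structure: which
processes exist, which 27 parameters were calibrated (with their units and
posterior modes), and which qualitative behaviours the calibrated model
exhibits.  The reconstruction is a first-class model in its own right;
its agreement and disagreement with the published behaviour are reported
honestly below.

States (41): drug in cytosol/medium/wall/nucleus + metabolized integral;
ROS and a cleared-ROS integral; Keap1 and oxidized Keap1; free cytosolic
Nrf2, Nrf2–Keap1 complex, oxidized complex, nuclear Nrf2; Maf and the
Nrf2–Maf dimer; per-gene ARE occupancy, mRNA and protein for eight target
genes (Nrf2, CYP3A5, GS, GCLC, GCLM, GST, GPx, MRP2/ABCC2) plus the GCL
holoenzyme; γ-glutamylcysteine and glutathione.

Process structure:

* drug transport identical to the disposition model plus first-order
  nuclear partitioning (~10% of cytosol at equilibrium); metabolism scaled
  by CYP3A5 protein (`vmax_csa_metabolism`, 1/s per zmol CYP3A5);
* ROS: production `kf_basal + k_ROS·Q_cyt`, clearance by GPx protein with
  Michaelis saturation in ROS and a GSH co-substrate factor, consuming
  2 GSH per ROS cleared, into a non-reactive sink;
* Keap1 and the Nrf2–Keap1 complex oxidized at `k_ox·ROS·target`;
  oxidized Keap1 is slowly reduced back; the oxidized complex releases
  free Nrf2; Keap1-bound Nrf2 is degraded with Keap1 recycled;
* nuclear Nrf2 dimerizes with a conserved Maf pool (`kb_nrf2_maf`); the
  dimer occupies per-gene ARE sites by mass action; transcription is
  `(k_basal + k_induction·occupancy)·gene_dose`, so induction saturates
  at full promoter occupancy;
* GCLC + GCLM assemble into GCL; γ-GC synthesis by GCL (and free GCLC) is
  feedback-inhibited by GSH; GS converts γ-GC to GSH; GSH is also turned
  over by a Michaelis–Menten degradation pathway;
* the AhR receptor branch is carried with its drug-binding constants
  pinned at zero (CsA is not an AhR ligand); simulations reject nonzero
  values.

The 27 calibrated parameters default to the published posterior modes.
The remaining fixed constants were designed once, by steady-state balance,
to give a plausible baseline cell and are not tuning knobs:
gene dose 0.01 zmol (~6 promoter copies); mRNA half-life ~2 h, protein
half-life ~19 h; translation rates set so that (i) baseline CYP3A5
(~214 zmol) reproduces the standalone disposition model's lumped `vmax`
(0.187 × 214 ≈ 40 zmol/s), keeping the two-step calibration consistent,
and (ii) baseline GPx (~200 zmol) gives a basal ROS-clearance capacity a
few-fold above basal ROS production, which places the capacity-overload
dose in the 5–15 µM window spanned by the experiment; Keap1 pool ~100
zmol with ~25% basal oxidation; a conserved 1-zmol Maf pool; GSH feedback
constant 2×10⁵ zmol giving a ~6 mM baseline GSH.  The drug-free baseline
state is computed, not tabulated: the autonomous system is relaxed for
400 simulated days and polished with a Newton solve; every exposure
simulation starts there, and the control trajectory is that fixed point.

**What the reconstruction reproduces.**  The dose-regime structure: ROS
profiles oscillate (daily period) below ~8 µM and switch abruptly — at
8.5 µM on a 1–20 µM scan — to hockey-stick growth, because sustained
clearance is capped by both GPx capacity and the maximal GSH synthesis
rate; nuclear Nrf2 plateaus at high dose; mRNA/protein fold-changes are
modest (saturating promoter occupancy) while γ-GC and GSH respond
strongly; predicted ROS at 40 µM (near the viability EC50) far exceeds
the 15 µM response.  **What it does not.**  The published multi-day
(2–4 day) oscillation periods and the slow decay of GSH oscillations at
15 µM (vanishing near day 30): in the reconstruction the oscillation is
driven by the daily dosing pulse and dies within ~1 day at 15 µM once ROS
saturates the clearance term.  Matching the slow limit-cycle decay would
require the original fixed-parameter table.

## Calibration

Likelihoods are lognormal around model predictions — geometric SDs
specific to the three drug measurement types (medium, cell lysate, wall)
and one shared omics GSD, each calibrated with a log-uniform prior
spanning coefficients of variation from 1% to a factor 2.  Structural
priors: vague log-uniform/uniform for the disposition model; for the
pathway model, lognormal priors centred on the parent-model literature
values with geometric SD 3 (GPx priors cloned from GST, which has no
literature value), and vague uniforms for the two ROS rate constants.

The sampler is random-walk Metropolis in log space for positively
supported parameters (with the log-transform Jacobian included in the
sampling-space density) and reflection at uniform bounds.  The default
`vector` update adapts a joint proposal covariance to the chain history
during the discarded warm-up half and freezes it afterwards; a
`component` update with per-component scales is available.  Chains start
at the best of 100 independent prior draws; seeds derive from a master
seed + chain index, making runs bit-reproducible.  Any correct MCMC
targeting the same posterior is considered equivalent — the contract is
equivalence in distribution, not bitwise identity with other tools.
Convergence is monitored with the classic Gelman–Rubin PSRF.

The two-step protocol freezes the disposition parameters at their joint
posterior mode (maximum-log-posterior draw) for the pathway calibration.
The study-scale protocol (5 chains × 200,000 iterations, thin 100, first
half discarded) is available by configuration; the default reduced
protocol used in CI-scale checks is 5 × 20,000.  At that reduced protocol,
calibrating on synthetic data generated at the posterior modes returns
95% credible intervals covering the generating values for 8/8 disposition
parameters.  A Monte Carlo sensitivity screen (|Spearman ρ| between prior
draws and output summaries) supports the choice of which structural
parameters to calibrate.

## Viability meta-analysis

Cell viability follows the decreasing log-logistic
`top/(1 + (d/EC50)^slope)`.  The renal line's doses lie entirely below its
EC50, so the hierarchical fit shares a single slope across cell lines
(line-specific top and EC50) — the minimal pooling structure that lets the
truncated line inherit curvature from the fully observed 3T3 and HepaRG
lines.  Viability is normalized to untreated control before fitting;
measurement error is additive normal with calibrated SD.  On synthetic
truncated data the shared-slope posterior covers the generating renal
EC50 and is several-fold narrower than a no-pooling fit.  The published
renal EC50 estimate cannot be recomputed here because the underlying
viability tables are external; the machinery is validated by synthetic
recovery instead.

## Synthetic data

Generators are pure functions of (scenario, seed).  Drug and omics noise
is multiplicative lognormal (matching the likelihood; no additive floor);
viability noise is additive normal truncated at 0.  Defaults follow the
study design: doses 5/15 µM, triplicates, drug sampling on days
1/3/5/7/10/14 (intra-day grids on days 1 and 14), omics at days 1/3/14
for 13 species; the omics generator can drop trailing values to mirror
the study's 227 observed values out of a nominal 234.  What the generator
does *not* emulate: array/MS measurement physics, batch effects,
inter-well variability, or transcript decreases below control (the model
only induces) — so passing recovery tests demonstrate statistical
correctness of the machinery, not biological completeness of the model.

## Numerical and analysis conventions

* Steady-state timing: the first day `d` whose dosing cycle matches the
  next cycle within 5% maximum pointwise relative deviation (0-based: a
  constant trajectory converges at day 0); the tolerance is exposed.
* Regime classification: linear detrend of the tail (day 4 onward);
  ≥3 peaks with prominence ≥5% of the mean level ⇒ oscillating (period =
  median inter-peak spacing); relative trend >5%/day persisting through
  the tail ⇒ unbounded growth; otherwise plateau.  Both thresholds are
  defaults exposed in the API and reported with results.
* Ratio windows: "day 1" = [0, 24 h], "last day" = [13, 14] days,
  trapezoidal time averages.
* Mean prediction–data discrepancy is mean |pred − obs|/obs at the
  posterior mode.
* Fold-change reference: the first omics observation time (end of day 1)
  of the control run, exposed as a design parameter.
* Problem sizes used in the shipped checks: 14-day simulations at 240
  output samples/day (disposition) and 48–96/day (coupled); dose scans
  over 10 grid points; reduced MCMC protocols as above.

## Known limitations

The pathway reconstruction fixes baseline physiology by design
calculation rather than by the original fixed-parameter table; absolute
state scales (copies per cell) are plausible but not data-derived, and
only fold-changes should be interpreted.  Only one ROS-scavenging system
(GPx/GSH) is described; transcript down-regulation cannot be produced;
metabolite identity is not tracked (the metabolite is a sink); no
protein binding in the medium and no inter-well variability are modeled.
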