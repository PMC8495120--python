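# Methods

## Scope and model structure

`permpbpk` implements a gestational PBPK model for the two permethrin
isomers in the rat.  Each isomer is simulated independently with an
identical structure (no stereochemical interconversion, no metabolite
kinetics).  The state vector tracks amounts (mg) in:

* gut lumen: stomach → intestinal lumen (first-order transfer `k_si`),
  absorption into GI tissue (`k_ai`), fecal excretion from the lumen
  (`k_fec`);
* flow-limited maternal tissues: GI tissue, liver (hepatic arterial +
  portal inflow, single venous outflow), rapidly perfused tissue, placenta;
* diffusion-limited maternal tissues: brain, muscle, kidney, fat, mammary
  gland, slowly perfused tissue.  Each is split into a residual
  tissue-blood sub-compartment (volume `BV_T · V_T`) exchanging with the
  cellular sub-compartment through a permeability–surface-area product
  `PS_T` (L/h); venous return leaves at the tissue-blood concentration;
* one well-mixed maternal blood pool (arterial ≡ mixed-venous
  concentration).  Metabolic clearances (L/h/kg, scaled by current maternal
  BW) act on the liver and GI equilibrium-leaving concentrations and on the
  blood concentration;
* the fetal litter, lumped into one model: blood, flow-limited liver and
  rest-of-body, diffusion-limited brain.  Fetal metabolism is zero;
* cumulative sinks (hepatic/blood/GI metabolism, feces), so that the total
  of all slots equals the administered dose exactly between boluses.  The
  whole system is linear in the state: `dA/dt = M(t) A`, with `M` depending
  on time only through physiology.

Placental transfer is bidirectional diffusion with allometric scaling
`Ktrans_i = scKtrans_i · BW_maternal(t)^0.75` applied to both directions.
Measured ("homogenate") concentrations of diffusion-limited tissues include
the residual blood: `(A_T + A_TB) / (V_T + V_TB)`.  Fetal matrices are
litter-total concentrations, matching litter-pooled sampling.

## Gestational physiology

Maternal body weight is piecewise-linear through (GD0, 0.277 kg),
(GD15, 0.356 kg), (GD20, 0.422 kg); the cardiac output index falls
linearly 24.56 → 21.6 L/h/kg.  Constant-fraction tissues are fractions of
the *initial* BW (volumes) and of the *initial* cardiac output (flows) and
do not grow; slowly perfused volume closes the balance
(1 − organs − 0.05 non-perfused) and rapidly perfused flow closes the
cardiac output at every instant.  Mammary volume (0.0024 → 0.013 L), fat
depot, and the mammary/fat flows interpolate linearly over GD0–GD20.

The conceptus (placenta, fetuses) activates at implantation (GD6) and
grows along a logistic curve with midpoint GD15 and time-scale 1.5 days,
anchored at zero on GD6 and at the GD20 endpoint (placenta 0.167 L,
1.42 L/h; per-fetus BW 6.8 g) — placental and conceptus weights grow
roughly exponentially over the last gestation week, and the logistic gives
a smooth, bounded version of that with exact endpoint anchoring.  Before
onset the conceptus ODEs are frozen and a 1e-9 L volume floor guards
divisions.  The litter (default 13.5 fetuses; non-integer means are
allowed, they only scale continuous totals) is lumped; the fetal brain and
liver endpoint volumes (0.0034 / 0.0044 L) are litter-lumped values at the
reference litter of 13.5 — read per-fetus they would exceed the per-fetus
body weight — and scale linearly with litter size.  Physiology evaluates up
to GD21 (linear/logistic trend extension) because the GD20 group is
sampled to 24 h post-dose.

**Fat volume.**  Total fat is modelled as a whole-body adipose baseline of
7% of the initial BW *plus* the gestation-varying depot (0.017 → 0.024 L).
The varying range alone, read as total fat, would make the adipose fraction
*fall* during gestation, contradicts the literature baseline the
physiology table itself cites, and makes the model overshoot the reported
fat AUCs about two-fold at every gestational stage; with the baseline
included the model reproduces the reported fat exposure at GD1 and GD20
within ~25% with the same chemical parameters.  This is the package's own
reading; the original growth equations were not published in full.

## Dosing

Daily oral gavage from GD1 up to and including the sacrifice day (so the
GD1 group receives exactly one dose), 50 mg/kg total permethrin, of which
40% cis / 60% trans.  Each dose is a bolus into the stomach at the dosing
instant (integration restarts at the event), scaled by the current body
weight by default (animals are weighed for mg/kg dosing); a fixed-weight
option reproduces single-dose scenarios pinned at 0.277 kg.

## Numerics

The reference integrator is LSODA (`scipy.integrate.solve_ivp`) with the
analytic Jacobian (`M(t)` itself), rtol 1e-8 / atol 1e-10; mass balance
over a full 20-dose gestation holds to < 1e-6 relative.  For
likelihood and sensitivity workloads the model exploits its linearity: each
inter-dose day is advanced with the matrix exponential of `M` frozen at the
day midpoint (one eigendecomposition per day, verified against `expm` and
falling back to it when ill-conditioned).  Against the full time-varying
ODE this day-frozen propagator agrees to ~1% at GD1 and ~5% after 15
days of gestational drift — well inside the 15% measurement error the
likelihood assumes.  Flow-limited override (used to verify the
PS → ∞ limit) represents the same homogenate with effective partition
`BV + (1 − BV) · PC`, the exact infinite-permeability limit of the split
tissue.

## PK metrics

AUC(0–24) is the linear trapezoid over the provided points without
extrapolation; observed-style composite curves from destructive sampling
average the replicate concentrations per time point and prepend a (0, 0)
anchor by default (configurable — the study does not state its anchoring;
the 24-h sample of repeated-dose days is likewise used as sampled).
Tmax is the sampling time of the maximum, ties broken earliest.  The
terminal half-life is `ln 2 / λ` with λ from a log-linear least-squares fit
over the points from Tmax onward (peak included; with 7-point designs and a
6-h Tmax a strictly-after rule would leave the reported half-lives
undefined), requiring ≥ 3 positive points and a negative slope, otherwise
undefined.  Detected-below-LOQ values enter as LOQ/2; non-detected values
are excluded.

## Synthetic studies

The generator reproduces the in-vivo design: groups of 4, sacrifice times
1, 2, 3, 4, 6, 10, 24 h post-dose at GD1/GD15/GD20; feces as 24-h
cumulative amounts at GD1/GD15 (metabolic cages); placenta from GD15;
litter-pooled fetal blood/liver/brain at GD20.  Records are model
predictions under the full dosing history times `exp(ε)`,
ε ~ N(0, 0.15²) — multiplicative lognormal measurement error is the sole
stochastic term, matching the calibration likelihood; no inter-animal
kinetic variability is simulated (the study treats residual error as the
only noise).  Matrix-specific LOQs (e.g. cis 26 ng/ml blood, 4 ng/g
placenta; trans 52 ng/ml blood) censor the records: latent values below
LOQ are recorded at LOQ/2 as detected-below-LOQ, and below LOQ/10
(configurable; the study gives no explicit rule) as not-detected.  The
per-gram feces LOQ is converted to an amount threshold with a nominal
10 g/24 h fecal mass.  Fetal matrices reuse the corresponding maternal
LOQs (not reported separately).  Consequently, passing recovery tests show
that the inference machinery is self-consistent under the assumed error
model; they cannot show robustness to inter-animal variability, analytical
drift or model misspecification present in real data.

## Bayesian calibration

Priors follow the study's table: truncated normals (CV 50%, printed
bounds) where an adult-rat value exists, uniforms elsewhere, fixed values
(`k_ai`, `cl_gi`, `cl_blood`, muscle/rapidly-perfused coefficients,
trans kidney PC) unsampled.  The likelihood is lognormal with fixed
log-scale SD 0.15 around the model prediction; censored records enter at
their LOQ/2 value exactly as they were fitted (an integrated-censoring
likelihood is deliberately not the default).  Sampling runs on log
parameters with the Jacobian term, via independent affine-invariant
ensembles (emcee) started overdispersed from the prior with distinct
sub-seeds; 3 ensembles play the role of 3 chains in the classic
Gelman–Rubin `R̂ = sqrt(((n−1)/n · W + B/n)/W)`, with 1.2 the convergence
threshold.  The default budget (3 × 2,000 iterations, last 800 retained
thinned by 2) is the package's reduced test budget; the study-scale budget
(3 × 10,000, one-in-two of the last 4,000) is a `fit()` argument away.
Two modes mirror the study: `gd1` fits maternal parameters per isomer on
single-dose data (and rejects conceptus matrices); `gd15_20` fits GD15+GD20
jointly, adding the placenta partition and the placental-transfer/fetal
block, which is shared across isomers by default (the study's fetal
posteriors are identical across isomer columns).  Reduced-budget recovery
runs sample the six parameters the GD1 data constrain most
(`cl_liv, k_si, k_fec, pc_fat, pc_brain, pc_liv`) with the rest fixed at
truth; on the default synthetic design this recovers the four headline
parameters within 25% with max R̂ ≈ 1.01.

## Sensitivity analysis

Sobol indices (Saltelli-2010 estimators on a Sobol' quasirandom design,
`scipy.stats.sobol_indices`) of the cis-isomer chemical parameters under
the repeated-gavage scenario.  Parameter distributions are truncated
normals centred on the late-gestation posterior means with CV 30%,
truncated at the prior bounds (the analysis distributions' bounds are not
otherwise specified).  Outputs: maternal blood, fetal blood and fetal
brain concentrations at +4/6/12 h on GD15 or GD20.  Base sample 256 for
tests (≈ 6,000 model runs via the linear propagator), 1,024 for reported
runs; bootstrap (100 resamples) gives index confidence bounds.  Hepatic
clearance dominates the maternal blood output; the fetal outputs add the
placental transfer constants, and the fetal brain adds its own partition
and permeability — matching the study's qualitative ranking.

## Problem sizes used by the shipped checks

Forward-simulation checks use a dense 0.05–0.25 h output grid over single
dose days and a 2-h grid over full gestation.  The acceptance pipeline
runs one single-dose GD1 simulation (481 grid points over 24 h) and one
reduced-budget recovery calibration (169 usable records, 3 × 2,000
iterations, 16 walkers), chosen so the whole pipeline completes in a few
minutes on one CPU.

## Known limitations

* The published mammary exposure is over-predicted ~3–4-fold with the
  printed mammary volume/flow ranges under any reading we could construct;
  the printed mammary blood flow already caps uptake above the reported
  exposure level.  The unpublished growth equations presumably differ.
* With the printed placenta equation and no fetal elimination, the
  placenta is in quasi-steady state with maternal blood within a day, so
  its AUC ratio to blood equals `PC_Pla`; the study's model-estimated
  ratio is lower (~1.7–2.5), which this structure cannot produce.  The
  same quasi-steady-state argument makes the model's feto-maternal blood
  ratio approach `Ktrans1/Ktrans2` (0.76) rather than the reported
  model-estimated 0.25.
* No enterohepatic recirculation, protein-binding submodel, metabolite
  (3-PBA) kinetics, active placental transport, or inter-animal
  variability; human extrapolation is out of scope.
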