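# Methods

This note documents the kinetic model, the statistical machinery and the
numerical choices behind `dinchpbpk`, together with the design decisions that
were genuinely open and the limitations a user should know about.

## The kinetic model

DINCH (di-isononyl-cyclohexane-1,2-dicarboxylate) is an extremely lipophilic
diester plasticizer (Log Pow ≈ 9.8).  After a single oral dose its monoester
MINCH is oxidised to OH-MINCH and cx-MINCH, the two metabolites measured in
urine, and urinary concentrations are reported per gram creatinine.  The
model is a flow-limited, whole-body compartmental system written in molar
amounts (µmol of DINCH-equivalents), with time in hours from the start of
ingestion:

* **Ingestion and absorption.** The dose enters the stomach lumen at a
  zero-order rate over the drinking time (default 0.25 h), empties into the
  gut lumen at a single effective first-order gastric-emptying rate (default
  the fast bound `k_max = 10.2 /h`; a small liquid dose), and is absorbed at
  `k_Ga = 25.1 /h`.
* **First-pass split.** A fraction `FracDOSE` (default 0.7) of the absorbed
  flux is taken up into the liver via the portal vein; the complement enters
  a well-mixed lymphatic compartment through the intestinal lacteals and
  drains into venous blood at the lymph flow over lymph volume
  (≈ 1.6 /h), bypassing the liver.
* **Portal material is hydrolysed on first pass.** Dose routed to the liver
  enters the MINCH sub-model there.  This is the reading of "fraction of
  dose taken up into liver" under which the whole analysis is coherent: the
  urinary metabolite yield is proportional to `FracDOSE`, reverse dosimetry
  confounds dose with `FracDOSE`, and the lymph-routed remainder is the
  only parent chemical reaching the systemic circulation, where plasma
  protein binding (fraction unbound ~1.2e-4) makes its subsequent hepatic
  clearance extremely slow.  Had parent-diester conversion been modelled as
  binding-limited everywhere, less than 0.1% of the dose would convert
  within 48 h, orders of magnitude short of observed urinary recoveries.
* **Distribution.** Both species perfuse stomach, gut, liver, adipose, and
  lumped slowly/rapidly perfused tissues (`dA/dt = Q (C_blood − A/(V·P))`),
  with stomach and gut venous blood draining through the liver.  Blood is a
  single lumped compartment.  Tissue:blood partition coefficients are
  consumed as inputs (predicted from Log Pow by published
  tissue-composition algorithms).
* **Metabolism.** Systemic DINCH is cleared in liver and gut tissue by the
  well-stirred model `CL_H = Q fu CLint / (Q + fu CLint / R_rbc)` — binding
  limited, hence the ~10,000 h plasma persistence of lymph-routed parent
  and the strong sensitivity of plasma clearance to the bound fraction.
  MINCH oxidation in the liver is applied as the whole-organ intrinsic
  clearance acting on the venous liver concentration (delivery-limited by
  liver blood flow); plasma binding is not applied a second time here
  because the large liver:blood partition coefficient (54.8) already
  represents hepatic accumulation, and a binding-limited monoester
  clearance (≈3 L/h against a ~930 L steady-state volume) would stretch
  metabolite excretion over weeks, contradicting the observed 48-h
  excretion window.
* **Urinary elimination.** The cleared MINCH flux splits into OH-MINCH
  (`FracMetabOH`), cx-MINCH (`FracMetabcx`) and a lumped sink of unmodelled
  downstream metabolites.  OH/cx occupy zero-volume transit pools draining
  into a bladder compartment at first-order rates `K1_OH`, `K1_cx`;
  micturition events empty the bladder and report interval-averaged
  concentrations in mg/L and mg/g creatinine, with urine volume
  `Rurine × interval` and constant creatinine concentration (both
  overridable per void).

Mass-balance closure follows the standard re-parameterisation: the slowly
perfused volume absorbs the volume residual so compartment volumes sum to
95% of body weight, and the rapidly perfused flow absorbs the flow residual
so perfused flows sum to the cardiac output; infeasible residuals raise an
error (sensitivity designs rely on this rejection).

A note on naming: the configuration keys `FBDINCH`/`FBMINCH` follow the
published abbreviations, but their values (0.0001249, 0.0146477) are the
plasma *unbound* fractions — DINCH is 99.99% bound.  The package interprets
them as `fu` throughout.

## IVIVE

In vitro substrate depletion in pooled human liver microsomes (0.5 mg
protein/ml) is corrected for non-specific binding by fitting a straight
line to the binding-control series and rescaling each time point by
intercept/fitted value, then fitted with `y = b exp(−t/k)` by
Levenberg–Marquardt least squares (initialised at the first observation and
`t_max/ln 2`).  The half-life `ln(2)·k` gives
`CL_in_vitro = ln(2)/T½ × (ml incubation / mg protein)`; whole-organ
intrinsic clearance is `CL_in_vitro × MPY × organ mass × 60/1000` L/h (the
ml→L conversion is made explicit).  At the measured MINCH half-life of
30.53 min with MPY 34 mg/g and a 2.234 kg liver this gives 206.9 L/h.  The
plasma fraction unbound comes from the lipophilicity regression
`fu = 1/(10^x + 1)`, `x = 0.4485·logP − 0.4782`, for neutral chemicals at
pH 7.4.

## Solvers

With fixed parameters the system is piecewise linear and time-invariant
(zero-order input, first-order transfers, linear clearances, instantaneous
void resets), so the default propagator advances the state with cached
matrix exponentials between breakpoints — exact, unconditionally stable,
and mole-conserving to machine precision (the columns of the rate matrix
sum to zero by construction).  An LSODA path integrates an independently
hand-coded right-hand side (`rtol 1e-8`, `atol 1e-10` by default) and is
cross-checked against the exponential propagator in the tests.  States are
clipped at zero within a 1e-6 µmol tolerance; anything below that is a hard
error.

## Uncertainty and sensitivity analysis

* **Design:** a maximin Latin hypercube (best of 20 candidate hypercubes by
  minimum pairwise distance), 200 points by default, over stated uniform
  bounds or the 5th/95th percentiles of normal/lognormal parameters.
  Infeasible closures are resampled within their stratum.
* **Screening:** Morris elementary effects (default 20 trajectories, 8
  levels, Δ = p/(2(p−1))) over the full enumerated parameter set — every
  kinetic/physiological parameter plus all 14 partition coefficients with
  half/double ranges, 49 names in total.  Screening uses the log of the
  per-metabolite urinary concentration profiles (the output spans orders of
  magnitude, and retention should reflect relative influence); |EE|
  statistics are normalised per output component and combined by their
  maximum, so a parameter is retained if it matters anywhere in the
  profile.  Trajectories hitting infeasible closures are dropped with a
  logged count.
* **Variance decomposition:** eFAST with driver frequency
  `(N−1)/(2M)` (interference factor M = 4), complementary frequencies at
  most `driver/(2M)`, main effect from the driver harmonics and total
  effect from one minus the low-frequency mass.  Spectral masses are pooled
  across random-phase resampled curves before ratios are taken; per-curve
  ratios fluctuate badly because the low-frequency complementary parameters
  are phase-locked along any single curve.  The estimator is validated
  against the Ishigami closed forms in the tests.  With many parameters
  and small N (e.g. 65 samples per parameter with 11 parameters) the
  total-effect estimator carries a large positive bias: all complementary
  parameters collapse onto frequency 1, and strongly non-linear responses
  (the reciprocal creatinine/urine-rate normalisation) leak spectral mass
  into non-complementary bins.  Converged total effects are better read
  from the Monte-Carlo (Jansen) estimator used as an oracle in
  development.
* **Truncation:** normal distributions are truncated at their 0.1/99.9
  percentiles for sampling, and for strictly positive parameters the lower
  bound is never below one tenth of the mean — without this, draws of the
  urine production rate near zero make the creatinine-normalised output
  explode.
* **Lowry summaries** order parameters by total effect; the interaction
  ribbon is bounded below by cumulative main effects and above by the
  smaller of cumulative total effects and one minus the main effects still
  to come, capped at one.

## Calibration

The measurement model is log-normal with natural logarithms and a single
error scale σ shared across metabolites and volunteers, written as a
density on log-measurements (no 1/y Jacobian) — σ ≈ 0.28 reads as ~28%
multiplicative error.  Zero (non-detect) concentrations are excluded with a
logged count.  Kinetic parameters are shared across volunteers; the urine
production rate and creatinine concentration are individualised with
correlated bivariate-normal priors (correlation −0.7; dilute urine is
produced faster), and σ carries the improper 1/σ prior.

Sampling is a bespoke random-walk Metropolis–Hastings: a diagonal Gaussian
proposal sized from the prior spreads, upgraded during burn-in to the
empirical covariance of the burn-in history (Haario-style) with a global
scale adapted in windows of 25 iterations towards 30% acceptance, then
frozen for the sampling phase.  By default a short Nelder–Mead
posterior-mode search from the prior medians precedes sampling; without it,
chains of the published length (1,000 burn-in + 10,000 iterations, thinned
by 10) do not reliably reach the posterior bulk on this 9–11 dimensional
correlated target.  Non-physical proposals (negative protein yield,
infeasible closures) are treated as zero-likelihood rather than errors.

Two identifiability facts shape what calibration can and cannot recover,
and both are intrinsic to creatinine-normalised urinary data rather than to
the implementation:

1. predictions depend on `FracMetab`, `Rurine` and `Creat` only through
   `FracMetab/(Rurine·Creat)` — the three factors lie on an exact
   likelihood ridge resolved only by their priors;
2. each metabolite's profile identifies the pair (systemic MINCH
   elimination rate, `K1`) only up to the two-exponential exchange
   symmetry.  With the default kinetics the MINCH elimination rate
   (~0.115 /h) falls between the calibrated `K1_cx` (0.10) and `K1_OH`
   (0.15), so posteriors compromise along this ridge and the flat
   U(0.05, 2) `K1` priors place most volume above the truth; in
   fixed-truth recovery experiments the `K1` marginals skew high and MPY
   low, and 90% credible intervals cover the generating values slightly
   less often than nominally.

Reverse dosimetry (dose treated as unknown) adds the dose to the same
product ridge: urinary data pin `dose × FracDOSE × FracMetab`, so the dose
marginal is wide, widens further under flat `FracMetab` priors, and
single chains can dwell at one ridge point for thousands of iterations —
analyses pool several independently seeded chains.

## Synthetic data

The generator emulates the design of the underlying biomonitoring study —
three male volunteers (82–90 kg), a single oral dose of 0.552–0.606 mg/kg
taken over ~0.25 h, and complete urine collection over 48 h — with a
16-void schedule (0.75…48 h; the study's actual void times are
unpublished, so the schedule is a stated convention) and multiplicative
log-normal noise (σ = 0.28 by default), the same error model the
calibration assumes.  True kinetic parameters default to the
calibrated-scale values (FracDOSE 0.74, MPY 38, K1_OH 0.15, K1_cx 0.10,
FracMetabOH 0.23, FracMetabcx 0.05).  The volunteer-C preset triples the
urine volumes and divides the creatinine concentrations by three for the
first four voids, reproducing that subject's documented early water
intake, which violates the model's constant-production assumption in the
same qualitative way.  The depletion-curve generator couples the linear
non-specific-binding losses into the total-metabolism series so that the
binding correction restores the clean exponential.

What the generator does **not** emulate: circadian or within-day variation
in urine and creatinine production (beyond the volunteer-C preset),
inter-occasion variability in absorption, analytical-chemistry artefacts
(limits of detection, batch effects), or real inter-individual kinetic
variability beyond the covariates.  Passing the recovery tests therefore
demonstrates internal consistency of model, generator and sampler — not
that the model is correct for real humans.

## Problem sizes

The test suite and the acceptance script run at desk scale: eFAST at 65
samples per parameter (and 257 with 4 resamples for the Ishigami
validation), Morris at 16–24 trajectories, parameter recovery over 10
replicates of two synthetic volunteers (16 voids each) with chains of
1,000 burn-in + 10,000 iterations thinned by 10, and pooled 3-chain
reverse-dosimetry comparisons at 15,000 iterations per chain.

## Known limitations

* A single effective gastric-emptying rate (the named fast/slow bounds are
  sampled in sensitivity analyses but no interpolating function is used).
* Lymphatic transfer is a single well-mixed compartment — a deliberately
  simplistic mixing mechanism.
* No enterohepatic recirculation, no dermal/inhalation routes, no
  metabolites beyond OH-/cx-MINCH (lumped sink), no diffusion-limited
  tissues.
* The eFAST total-effect estimator is biased upward at small sample sizes
  (see above); converged indices require either far larger N or the
  Monte-Carlo estimator.
* Fixed-truth frequentist coverage of Bayesian credible intervals is not
  guaranteed in the ridge geometries described above.
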