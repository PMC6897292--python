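# dinchpbpk

A physiologically based pharmacokinetic (PBPK) toolkit for interpreting
human biomonitoring of the plasticizer **DINCH**
(di-isononyl-cyclohexane-1,2-dicarboxylate) after single oral doses.  The
package is aimed at toxicokinetic modellers who want to go from in vitro
microsomal measurements and in silico property predictions to calibrated
predictions of urinary biomarker concentrations — and back again (reverse
dosimetry).

It provides, as importable library modules and a thin CLI:

* **`ivive`** — in vitro → in vivo extrapolation: non-specific-binding
  correction and exponential-decay fitting of substrate-depletion curves
  (`y = b·e^(−t/k)`, `T½ = ln 2·k`), scaling to whole-organ intrinsic
  clearance via the microsomal protein yield
  (`CL_int = CL_in vitro · MPY · M_organ · 60/1000` L/h), the well-stirred
  liver model
  `CL_H = Q_H·fu·CL_int / (Q_H + fu·CL_int/(C_RBC/C_P))`, and the
  lipophilicity regression `fu = 1/(10^x+1)`, `x = 0.4485·logP − 0.4782`.
* **`params` / `model`** — the oral-dose PBPK model: stomach/gut uptake, a
  lymphatic pathway that lets part of the dose bypass first-pass
  metabolism, a MINCH sub-model joined at the liver, first-order urinary
  excretion of OH-/cx-MINCH through a bladder compartment with discrete
  micturition events, and creatinine-adjusted urinary concentrations.
  Amounts are µmol; DINCH-equivalent moles are conserved to machine
  precision by construction.
* **`priors`** — the published parameter distributions, the half/double
  rule for point-valued parameters, and the calibration priors including a
  correlated (Rurine, Creat) bivariate normal (ρ = −0.7) and an improper
  1/σ error-scale prior.
* **`gsa`** — maximin Latin-hypercube uncertainty propagation, Morris
  elementary-effects screening, eFAST variance-based indices (S_M, S_T)
  and Lowry-plot summaries.
* **`calibration`** — a log-normal measurement model, a bespoke adaptive
  Metropolis–Hastings sampler, posterior summaries (median, 90% CI),
  posterior-predictive bands, and reverse dosimetry.
* **`synth`** — synthetic volunteer void datasets and depletion curves
  with known ground truth, emulating a three-volunteer, 48-h urine
  collection design (the original biomonitoring data are not public).

## Worked example

```python
import dataclasses
from dinchpbpk import ivive, model, params, synth

# 1. In vitro clearance chain: a depletion curve with decay constant
#    k = 44.05 min (half-life 30.53 min), corrected for non-specific binding
curve, truth = synth.generate_depletion(k=44.05, noise_sd=0.0)
factors = ivive.fit_binding_scaling(curve)
fit = ivive.fit_decay(curve.times, curve.total_conc * factors)
clv = ivive.cl_in_vitro(fit.half_life, curve.incubation_volume, curve.protein_mass)
clint = ivive.scale_clint(clv, mpy=34.0, organ_mass=2234.07)
print(fit.half_life, clv, clint)
# 30.53 min   0.04540 ml/min/mg   206.9 L/h

# 2. Plasma binding from lipophilicity
print(ivive.fraction_unbound(9.77).fu)   # 0.000125 — DINCH is 99.99% bound

# 3. Simulate a dosed volunteer with a 16-void collection schedule
bundle = dataclasses.replace(
    params.default_bundle(),
    urine=params.UrineParams(r_urine=0.104, creat=1.278,
                             void_times=synth.DEFAULT_VOID_SCHEDULE),
)
res = model.simulate(params.resolve_parameters(bundle), t_end=48.0)
print(res.voids[["time_h", "conc_OH_mg_per_g_creat"]].head(4))
#    time_h  conc_OH_mg_per_g_creat
#      0.75                   1.000
#      1.50                   2.820
#      2.25                   3.081
#      3.00                   3.014
print(res.mass_balance_error().max())    # ~1e-13
```

The urinary OH-MINCH concentration rises to ~3 mg/g creatinine within
2–3 h of a 0.555 mg/kg dose and decays to near zero by the end of the
48-h collection — the qualitative shape the model is built to reproduce.

Calibration against a (synthetic) void dataset:

```python
from dinchpbpk import calibration, priors, synth

data, truth = synth.generate_voids(synth.volunteer_preset("A"), seed=1)
spec = calibration.CalibrationSpec(
    prior=priors.prior_set("table4_fixed_dose", volunteers=("A",)),
    n_burn=1000, n_iter=10000, thin=10,
)
chain = calibration.metropolis_hastings(spec, data, seed=2)
print(chain.summary())   # per-parameter median and 90% credible interval
```

## Command line

```bash
dinch-pbpk synth voids --preset A --seed 1 --out voids.csv
dinch-pbpk synth depletion --k 44.05 --out depletion.csv
dinch-pbpk ivive fit --data depletion.csv --out clearance.json
dinch-pbpk simulate --config run.json --t-end 50 --out sim.json
dinch-pbpk sweep-binding --fb 0.9999 --fb 0.999 --t-end 1000 --out sweep.csv
dinch-pbpk ua --n 200 --seed 1 --out envelope.csv
dinch-pbpk gsa morris --r 20 --seed 1 --out ranking.csv
dinch-pbpk gsa efast --n-per-curve 65 --seed 1 --out indices.csv
dinch-pbpk calibrate --data voids.csv --priors table4_fixed_dose --seed 1 --out fit.json
```

Every artifact embeds the seed, configuration hash and package version;
deterministic stages are bit-for-bit reproducible.

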