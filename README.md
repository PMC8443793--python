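# dphp-pbpk

A human physiologically based pharmacokinetic (PBPK) model for the
plasticiser **DPHP** (di-(2-propylheptyl) phthalate) and its monoester
metabolite **MPHP**, for toxicokinetic modellers and biomonitoring
scientists who need to interpret blood and urine measurements after oral
exposure.

Human data for DPHP show a counter-intuitive pattern: MPHP peaks in blood
*before* the parent compound, and the second-order metabolites OH-MPHP and
cx-MPHP peak in urine before DPHP peaks in blood. The model explains this
with a lymphatic uptake route that bypasses hepatic first-pass metabolism,
very high plasma-protein binding, and efficient hepatic extraction —
together with enterohepatic recirculation (EHR) that produces secondary
"harmonics" in the urinary excretion-rate curves at roughly 8 h intervals.

## What is in the package

* **`dphp_pbpk.ivive`** — in vitro → in vivo extrapolation: substrate
  depletion half-life T½ to intrinsic clearance
  `CL_invitro = (ln 2 / T½) · (mL incubation / mg microsomes)`, organ
  scaling `CLint = CL_invitro · MPY · V_organ · 60`, the well-stirred
  liver model
  `CL_H = Q_H · fu · CLint / (Q_H + fu · CLint / (C_RBC/C_P))`,
  fraction unbound from log P(ow), and fractions metabolised from molar
  metabolite amounts.
* **`dphp_pbpk.model`** — the two-chemical PBPK core, solved as a system of
  delay differential equations (absorption lag, lymph lag, biliary
  transport lag), with a stomach/GI description, a three-way dose split
  (hepatic route / lymphatic route / unabsorbed), EHR for both chemicals,
  flow-limited tissue distribution, equilibrium plasma binding, and
  first-order urinary elimination of OH-MPHP and cx-MPHP. Two engines: an
  adaptive method-of-steps reference integrator and a compiled fixed-step
  scheme for batch work. Molar mass balance is monitored on every run.
* **`dphp_pbpk.sensitivity`** — maxi-min Latin hypercube uncertainty
  batches, Morris elementary-effects screening (μ*/σ, 59-parameter
  registry, retention at 0.8·max-μ*), and eFAST variance-based indices.
* **`dphp_pbpk.calibration`** — hierarchical Bayesian calibration with
  zero-truncated normal likelihoods on blood concentrations and per-void
  urinary deposition rates, global vs per-volunteer parameters, and
  adaptive Metropolis-within-Gibbs sampling with posterior summaries and
  pointwise credible bands.
* **`dphp_pbpk.synthetic`** — six-volunteer synthetic biomonitoring
  studies with the same truncated-normal error structure the calibration
  assumes, for end-to-end generate → calibrate → recover testing.
* **`dphp_pbpk.cli` / `dphp_pbpk.report`** — a `dphp-pbpk` command with
  stages `derive-params`, `simulate`, `uncertainty`, `gsa-screen`,
  `gsa-efast`, `synth`, `calibrate`, `report`.

The scientific background, parameter defaults, priors and numerical
choices are documented in `docs/methods.md`.

## Worked example

Simulate a 83 kg volunteer drinking a single 0.717 mg/kg dose:

```python
from dphp_pbpk import ExposureScenario, build_subject_from_flat, simulate, mass_balance
import numpy as np

scen = ExposureScenario(dose=0.717, BW=83.0, t_end=48.0)
subject = build_subject_from_flat({}, scen)      # packaged defaults
res = simulate(subject, scen)

for name in ("CBlood_DPHP", "CBlood_MPHP", "RUrine_OH"):
    y = res.series(name)
    print(f"{name}: peak {y.max():.4g} at {res.t[np.argmax(y)]:.1f} h")
print(f"faecal at 48 h: {res.bowel_mass[-1]:.1f} mg of {subject.dose_total:.1f} mg dosed")
print(f"mass-balance residual: {np.abs(mass_balance(res)).max()/subject.dose_total:.2e} of dose")
```

prints

```
CBlood_DPHP: peak 0.4113 at 14.8 h
CBlood_MPHP: peak 0.03899 at 1.9 h
RUrine_OH: peak 0.09784 at 2.4 h
faecal at 48 h: 50.2 mg of 59.5 mg dosed
mass-balance residual: 8.12e-15 of dose
```

Read: the monoester peaks in blood at ~2 h and the urinary OH-MPHP
deposition rate at ~2.4 h, while parent DPHP in blood — retained by
protein binding and fed slowly from the lymph — does not peak until ~15 h;
84% of the dose passes unabsorbed to faeces; and the molar account of
parent plus all metabolites closes to machine precision. A secondary
urinary maximum appears near 10.5 h (≈8 h after the primary peak), the
enterohepatic-recirculation signature: setting `k1_DPHP_liver` and
`k1_MPHP_liver` to zero removes it.

The same run from the shell:

```bash
dphp-pbpk simulate --dose 0.717 --bw 83 --out trajectories.csv
dphp-pbpk derive-params --out derived_parameters.csv   # clearances, binding
```

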