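# Methods

This note documents the model, its numerical treatment, the synthetic-data
conditions, and the design choices made where the underlying science left the
design open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The model

DPHP (di-(2-propylheptyl) phthalate) is an extremely lipophilic plasticiser.
After a single oral dose, human biomonitoring shows a counter-intuitive
pattern: the monoester metabolite MPHP peaks in blood *before* the parent,
and the second-order metabolites (OH-MPHP, cx-MPHP) peak in urine before the
parent peaks in blood. The model explains this with three mechanisms:

1. **Lymphatic bypass.** A small fraction of the dose (`FracDOSELymph`) is
   taken up via the intestinal lacteals, bypasses first-pass metabolism, and
   empties into venous blood only after a lag (`Lymphlag`), at a rate
   proportional to the lymph content (`K1Lymph`).
2. **Very high plasma protein binding.** Only the unbound fraction
   (`fu = 1 − FB`, of order 0.25–1.5%) of blood-borne chemical exchanges
   with tissues and is available for metabolism. Parent reaching blood is
   therefore retained for a long time, delaying and flattening its blood
   peak.
3. **Efficient hepatic first pass.** The hepatic-route fraction
   (`FracDOSEHep`) is absorbed through the gut wall (where some DPHP is
   already converted to MPHP) into the portal circulation and is almost
   completely metabolised in the liver; only traces reach systemic blood.

The complement `1 − FracDOSEHep − FracDOSELymph` passes unabsorbed to
faeces. Both chemicals undergo enterohepatic recirculation (EHR): first-order
biliary uptake in the liver (`k1_*_liver`) with a transport delay
(`Bilelag`) before reappearing in the gut lumen, where reabsorption competes
with faecal elimination (`k1_*_gut`). EHR produces secondary local maxima
("harmonics") in the urinary deposition-rate curves.

### Compartments and kinetics

Each chemical has flow-limited tissue compartments (liver, adipose, gut
tissue, stomach tissue, slowly and rapidly perfused residuals) with
tissue:blood partition coefficients, a single blood pool, and (for DPHP) a
lymph pathway. Gut and stomach tissues drain to the liver (portal flow).
The oral input is zero-order over the drink duration; gastric emptying uses
a time-varying first-order coefficient
`k(t) = k_min + (k_max − k_min)·exp(−t/τ_ge)` — the published work gives
only the maximum and minimum, so the exponential relaxation (time constant
`τ_ge`, default 1 h) is a package choice, and `τ_ge` carries uncertainty
U(0.5, 2) h in the sensitivity registry.

Metabolism is parameterised by in vitro→in vivo extrapolation: microsomal
substrate-depletion half-life → in vitro intrinsic clearance (0.5 mg
microsomal protein per mL incubation) → whole-organ intrinsic clearance via
microsomal protein yield (MPY, liver; MPY_gut, gut) and organ mass, with
the single minutes→hours conversion in one place. In the dynamic model the
intrinsic clearance acts on the venous-equilibrated tissue concentration
(`CLint·C_T/P_T`); plasma binding restricts the *delivery* of blood-borne
chemical to the tissues. Applying the plasma unbound fraction a second time
inside the liver would double-count binding and reduce first-pass
extraction to a few percent, which contradicts the mechanism the model
exists to express; the classical well-stirred clearance formula (with `fu`
and the red-cell/plasma ratio) is implemented verbatim in the derivation
module and reported by `derive-params`.

MPHP metabolism splits into OH-MPHP (`FracMetabOH`) and cx-MPHP
(`FracMetabcx`) with the remainder booked to an "other metabolites" pool
(oxo-MPHP etc.) that closes the molar balance; the two measured metabolites
occupy central pools eliminated to urine by first-order rates (`K1_MOH`,
`K1_cx`). Mole conversions use shipped molecular-weight constants
(DPHP 446.66, MPHP 306.40, OH-MPHP 322.40, cx-MPHP 336.38 g/mol),
overridable in configuration.

### Units and conventions

Time in hours from dose start; masses in mg; concentrations mg/L; urinary
outputs as deposition rates in mg/h (per-void mean rates, not
creatinine-adjusted); clearances L/h; half-lives in minutes inside the
in vitro expressions. Blood concentrations reported are total
(bound + free). Cardiac output scales allometrically, `QCC·BW^0.75`
(linear scaling would give an impossible ~1000 L/h at 72 kg; the allometric
form gives ≈346 L/h and reproduces the 20.8 L/h hepatic-artery flow used in
the worked clearance example). Flow fractions are renormalised to sum to
cardiac output; slowly/rapidly perfused masses take the residual of the
vascularised fraction (0.95·BW) after the named organs, split in the
tabulated ratio.

Known oddities of the shipped defaults are preserved deliberately (the
table is the source of truth, inconsistencies included): `FBDPHP`/`FBMPHP`
hold the printed plasma *unbound* fractions (0.0025, 0.0146) although their
row label says "bound"; `T_half_DPHP` default 3 min sits outside its prior
U(15, 60); `GIPERM` default 5.1 h⁻¹ outside U(0.1, 0.3). The
fraction-unbound regression `fu = 1/(10^(0.4485·logP − 0.4782) + 1)` does
not reproduce the printed fu values at the printed log P's (it gives
4.2×10⁻⁵ and 0.0125); the formula is exposed and tested, while defaults use
the printed values.

## Delay handling and solvers

Every lagged transfer runs through an explicit transit pool: inflow is the
instantaneous uptake flux `F(t)`, outflow is `F(t − lag)`. This conserves
mass exactly, keeps states non-negative, and reduces to the ODE model when
lags vanish (the transit pools become constants). Three lags exist: GI
absorption (`Gutlag`), lymph-to-blood (`Lymphlag`), and biliary transport
(`Bilelag`).

Two integration engines:

* **Adaptive (default, reference).** Method of steps with LSODA: the
  horizon is split at propagated discontinuity points (dose start/end plus
  lag combinations), segment length is capped at the shortest positive lag
  so lagged lookups always fall in already-integrated segments, and each
  segment's dense interpolant is kept as history. Default tolerances
  rtol 1e-7, atol 1e-10 mg (configurable); at these tolerances the molar
  balance residual is at machine-precision scale.
* **Fixed-step compiled (`engine="rk4"`).** A numba-jitted classical
  Runge-Kutta scheme with linear interpolation into the step history for
  the delay terms. The step divides the drink duration (exact dose
  delivery), is bounded by the explicit-scheme stability limit derived from
  the fastest rate coefficient, and defaults to 0.005 h. Used by the
  simulation-hungry stages (uncertainty batches, Morris, eFAST, MCMC);
  cross-checked against the adaptive engine in the suite (sup-norm
  agreement ≤ 1e-3 asserted; typically ~1e-5).

Lags shorter than two steps are treated as zero in the fixed-step engine.
Degenerate inputs: zero dose yields the zero trajectory; a peak on the grid
boundary is flagged by the metric extractor rather than silently reported.

## Uncertainty and sensitivity analysis

59 parameters are varied: the 38 published distributions, the three delay
terms, the gastric relaxation time, the liver microsomal protein yield, the
dose fractions, the metabolised fractions, and the 12 independent partition
coefficients (the stomach coefficient follows the gut surrogate). Normals
and lognormals are truncated at the 5th/95th percentiles of the untruncated
law. Where no distribution was published the package chooses once:

* `MPY` U(17, 68) mg/g — a factor-2 band around the default 34, mirroring
  the published gut-yield prior U(1.95, 7.8) around 3.9;
* partition coefficients U(PC/2, 2·PC) — factor-2 bands around the
  predicted values;
* `FracDOSEHep` U(0.02, 0.2) and `FracDOSELymph` U(0.01, 0.1) — bracketing
  the reported 2–16.3% total uptake with the hepatic route about five-fold
  the lymphatic;
* `FracMetabOH` U(0.2, 0.45), `FracMetabcx` U(0.01, 0.03) — bracketing the
  per-volunteer measured fractions and the calibrated posterior;
* `Gutlag` U(0.25, 2) h, `Lymphlag` U(2, 10) h, `Bilelag` U(3, 9) h.

`Bilelag` defaults to 7.8 h: the biliary delay plus gut/liver transit
(~0.3 h) places the first urinary harmonic at ≈8 h after the primary peak,
the spacing the data show. Uncertainty analysis uses a maxi-min Latin
hypercube (best of 20 random LHDs by minimal inter-point distance; 200
points by default) with eight monitored outputs and a molar mass-balance
check on every run.

Screening uses Morris trajectories (r = 5 by default, 8 levels,
mean-absolute elementary effect μ* and standard deviation σ) over 18
metrics: probe-time values of the four biomonitoring outputs and
peak/time-of-peak/post-peak-rate of the two plasma-bound masses. Retention
keeps any parameter with μ* ≥ 0.8·max-μ* under any metric (the "within 0.2
of the maximum" rule read as relative; the absolute variant is selectable).
eFAST (interference factor M = 4, one resampling) assigns the driven
parameter the maximum frequency `(Ns−1)/(2M)` and spreads the complement
over low frequencies; first-order indices read the driven harmonics, total
indices the complement of the low-frequency band. The estimators are
validated against analytic variance decompositions in the suite; at least
257 runs per parameter are needed for well-separated frequencies at M = 4
(the implementation enforces the minimum 4M²+1 = 65 and the suite uses 257).

A note on rank structure: the absorption-phase blood metrics are governed
by how much chemical enters (dose fractions, permeabilities, `Gutlag`),
while the elimination window (12 h probes; peak, peak time and post-peak
rate of the plasma masses) is governed by the binding fractions — the
acceptance checks assert binding dominance over that elimination window,
and uptake/metabolised-fraction dominance of the urinary metrics.

## Calibration

Zero-truncated normal likelihoods compare observed blood concentrations
(DPHP, MPHP) and per-void urinary deposition rates (OH-MPHP, cx-MPHP) with
model predictions; the truncation normaliser Φ(μ/σ) is included. Urinary
predictions are per-interval mean rates computed from the cumulative
urinary outputs, matching how the observed rates are formed
(concentration × void volume / inter-void interval, the first interval
starting at dose time). Error SDs carry gamma(0.01, 0.01) priors.

The sampler is adaptive random-walk Metropolis within Gibbs blocks: a joint
proposal for the global block θ, one joint proposal per volunteer for
ω_j, and a log-scale walk for the four error SDs (which costs no
simulations because per-volunteer predictions are cached). Scales adapt
toward ~30% acceptance during burn-in (first 20% of iterations) only.
Initial values are prior medians; draws outside the truncated prior support
are rejected outright. With the likelihood disabled the sampler reproduces
the prior (checked by Kolmogorov–Smirnov in the suite). The credible band
simulates per retained draw, orders predictions pointwise and reads the
2.5th/97.5th percentiles; the central curve is the highest-posterior draw.

Default calibrated-parameter membership (config-driven): global
θ = {K1_MOH, K1_cx, FracMetabOH}; per-volunteer ω = {FracDOSEHep}. The
full registry can be substituted; θ and ω must be disjoint and every name
must exist in the model parameter set. The "unusual" volunteer is carried
as a dataset-level exclusion flag.

## Synthetic studies

The generator emulates the six-volunteer single-oral-dose design: body
weights {83, 75, 76, 74, 90, 108} kg, doses 0.639–0.783 mg/kg, 48 h
horizon. The real sampling schedules are not public; the package
conventions are blood samples half-hourly to 4 h then 5, 6, 8, 12, 24, 36,
48 h (resolving the absorption phase and the MPHP-before-DPHP ordering),
and urine voids every 2–4 h with uniform jitter (Nyquist-adequate for ~8 h
EHR harmonics) and volumes U(100, 350) mL. Noise is zero-truncated normal
around model predictions with stream SDs σ_OH = 0.01 mg/h,
σ_cx = 0.0005 mg/h, σ_DPHP = 0.018 mg/L, σ_MPHP = 0.019 mg/L (the
calibrated error scales of the study). At σ → 0 observations equal the
model predictions exactly and void concentrations invert back to the
simulated deposition rates.

What passing on synthetic data does and does not show: the round trip
demonstrates that the estimation machinery is consistent under the model's
own error structure; it cannot detect model misspecification present in
real data (meal effects, second absorption events, early MPHP blood spikes
that the single-gut-compartment structure cannot reproduce), and the real
study's headline posterior values depend on the non-public volunteer data
and are not reproduced here.

## Problem sizes used by the suite and the acceptance script

Chosen to characterise each property at desk scale: conservation over the
full 200-point Latin hypercube; Morris at r = 4–5 over all 59 parameters;
eFAST at 257 runs per parameter over the retained set (plus the urinary
rate constants for the rank checks); calibration recovery over five seeds,
each with the six-volunteer design (one volunteer excluded, as in the
study), chains of 2000 adaptive iterations (30% burn-in, thinned by 4),
3 global + 5 subject-level parameters.
Recovery is judged by posterior-median relative error (≤25% for the
identifiable set) and 95%-interval coverage (≥90% pooled across seeds and
parameters).

## Known limitations

* Single-compartment gut: no multi-segment (ACAT-style) intestinal model,
  so multi-phase absorption events are not representable.
* Binding is an equilibrium free-fraction split; no on/off kinetics, and
  the red-cell and bound-plasma pools are derived quantities of one blood
  state rather than separate states.
* MPHP produced in the gut wall is, by default, fully available for
  first-pass metabolism before any plasma binding — the behaviour that
  matches the urinary data, and the acknowledged source of misfit to early
  blood MPHP spikes. A configuration switch (`gut_mphp_to_blood`) routes
  gut-wall-formed monoester straight into the blood pool (where binding
  applies) for exploring the alternative.
* The fixed-step engine is non-stiff; its step control guards stability
  for the shipped prior ranges but extremely fast kinetics outside them
  require the adaptive engine.
* Thermodynamic-integration MCMC and marginal-likelihood estimates are out
  of scope; no model-comparison claims are made.
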