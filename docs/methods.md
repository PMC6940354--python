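# Methods

This note documents the models implemented in `pdepkpd`, their assumptions,
the numerical choices made, and what the synthetic-data generator does and
does not emulate.

## Units and parameterization

All amounts are per kg of body mass: doses mg/kg, volumes L/kg, clearances
L/min/kg, drug concentrations mg/L, TNF-α concentrations ng/L (≡ pg/mL).
The PK models run in minutes; the arthritis progression model runs in days
with an explicit minute↔day bridge for the drug input. The reference
parameter tables in `pdepkpd.published` print clearances per kg: only that
reading is consistent with the per-kg volumes and the derived half-lives
(ln2·1.60/0.053 ≈ 21 min for GRMS-55 in female Lewis rats), so the per-kg
convention is used throughout.

Apparent (bioavailability-confounded) constants are stored as such: the
rolipram Lewis model holds V/F and Cl_t/F, and the lisofylline (LSF)
interconversion model stores the composite volume V_PTXm/fm, because only
those composites are identifiable from the fitted routes.

## Pharmacokinetic structures

Four structures cover the studied compounds (all states are amounts/kg;
concentrations are amount/volume projections):

1. **One-compartment**, first-order elimination Cl_t/V, optional first-order
   absorption depot (ka) with fraction absorbed F.
2. **Two-compartment**, elimination from the central compartment and
   inter-compartmental exchange via a distribution clearance, optional
   depot.
3. **Parent–metabolite interconversion** (LSF ⇄ pentoxifylline, PTX):
   first-order parent disappearance k_d feeds the metabolite pool, which
   eliminates with k_em and back-converts with k_conv. A notable emergent
   property: with the female-Lewis estimates the slow eigenvalue of this
   system is ≈0.0301/min, i.e. a ≈23-min terminal half-life after SC
   dosing — the flip-flop regime in which the terminal slope is set by the
   slow absorption (ka = 0.032/min ≪ k_d = 0.212/min) rather than by
   disposition.
4. **Saturable elimination** (male Wistar LSF/PTX): Michaelis–Menten parent
   disappearance (Vmax, Km) feeding a metabolite with a peripheral
   compartment (k_m12/k_m21) and first-order elimination. The published
   parameter set for this structure lists volumes, Vmax/Km and the
   metabolite rate constants without printing the differential equations;
   the structure implemented here is the one implied by those names and
   units, with the whole parent flux entering the metabolite pool. It
   reduces to a linear one-compartment model with Cl = Vmax/Km for
   C ≪ Km (verified to <1 % for C < Km/100). Dosing PTX itself is
   represented by placing the bolus directly into the metabolite
   compartment.

**Dosing and integration.** Doses are instantaneous state jumps (IV into
the central compartment; IP/SC into the depot multiplied by F) and the
adaptive stiff-capable integrator (LSODA, rtol 1e-8, atol 1e-10) restarts
at every administration time. For the linear structures an exact
closed-form solution (eigendecomposition of the rate matrix, superposed
over doses) backs `concentration_profile`; it is used wherever a drug
concentration function must be evaluated inside another ODE right-hand
side, and doses whose slowest exponential has decayed below double
precision are skipped. The nonlinear structure falls back to a dense
numerical solution.

**NCA.** The model-free AUC is the linear trapezoid from the first to the
last quantified sample, with below-LOQ values excluded and no terminal
extrapolation; bioavailability is the dose-normalized AUC ratio and is not
clamped at 1.

## In-vitro inhibition

Relative activity is the sample/control mean ratio in percent. The sigmoid
inhibition model E(C) = E₀ − Imax·C^γ/(C^γ+IC₅₀^γ) is fitted by unweighted
least squares on the percent scale with E₀ fixed to 100 %. Starting values
are IC₅₀ at the geometric mean of tested concentrations, Imax = 90,
γ = 1 — a robust default for sigmoid fits; Imax is bounded (0, 110] so that
noise excursions past complete inhibition do not stall the optimizer.
Flat (no-inhibition) data are flagged as non-converged rather than
returning an arbitrary potency. Potencies reported only as bounds
("IC₅₀ > 100 µM") are stored as censoring bounds, not numbers.

## Endotoxemia TNF-α model

A turnover (indirect-response) model with transit delay: a TNF-α precursor
is produced at zero-order rate k_in during [0, t_lag] only and degraded
with k_out; four transit compartments with common mean transit time τ
(the chain length that fitted the study data best) delay the signal before
it appears as plasma TNF-α. Every compartment starts at the measured basal
TNF-α of 12.7 ng/L, which is a constant of the model, not a fitted
parameter. Drugs scale the production by ∏(1 − Imax·C/(IC₅₀+C)) with Imax
fixed to 1; the LSF+PTX experiment multiplies both inhibition factors (the
model is described as an additive drug interaction in the indirect-response
sense, although the factors compose multiplicatively).

The piecewise production has two readings. Read literally, the precursor
derivative is zero for t ≥ t_lag, which freezes the precursor and prevents
the observed return toward baseline. The implementation defaults to the
time-limited-production semantics — production stops at t_lag while
degradation continues — which is the only reading that produces the
observed unimodal TNF-α burst; `production_cutoff="literal"` selects the
frozen-precursor reading.

With the published turnover scales, drug-free TNF-α only reaches
13–59 ng/L above a 12.7 ng/L baseline; see the note on censoring under
*Monte-Carlo recovery studies*.

## Arthritis progression model

Relative paw swelling is preprocessed geometrically: each paw and ankle
section is an ellipse with area π·a·b/4 from the two caliper diameters;
the section areas are summed and normalized to the same paw at day 0, so
the measure is exactly 1 at day 0 and invariant to the absolute paw size.

The disease model is a type-I indirect-response model with transduction:
after onset at t_onset the precursor is produced at
k_in(t) = k_in⁰·e^(−k_deg·t) (the exponential decay encodes natural
remission; the decay clock starts at t = 0 as the model is defined) and
lost with k_out; four transit compartments delay the signal; swelling
additionally grows at the natural rate k_grow = 0.004/day, fixed from an
independent growth study in healthy rats. Drug effect scales k_in(t) by
(1 − Imax·Cp/(IC₅₀+Cp)), Imax fixed to 1, with Cp the parent plasma
concentration only (a single potency per compound; metabolite inhibition
is not part of this model).

**Growth-term semantics.** Applying the transit pull (T₄ − Paw)/τ to total
swelling would let the chain (resting at 1) cancel the growth term almost
entirely, leaving a healthy paw at ≈1 + k_grow·τ ≈ 1.001 forever —
inconsistent with a growth constant measured in days and with the observed
pre-onset growth. The implementation therefore references the pull to the
disease component of swelling (integrate u′ = (T₄ − u)/τ and report
Paw = u + k_grow·t), so a healthy paw follows 1 + k_grow·t exactly and a
remitted paw returns to that baseline; `growth="literal"` selects the
other reading.

**Time-scale bridge.** The disease ODE runs in days while the drug input
is a minute-scale PK profile (daily boluses, half-lives 20–30 min, pulse
width ≲2 h ≈ 0.1 day). The integrator restarts at every dosing day and
caps the step at 0.005 day during the first 0.25 day after each dose so
the adaptive solver cannot step over a pulse; dose timing is preserved to
well under a minute. Accuracy against a tightened-tolerance reference is
~1e-7 on the trajectory.

With the published drug-free parameters the trajectory peaks at ~1.51×
day-0 area around day 23.6 (within the observed "peak near day 20"
window) and reads 1.47 at day 20. The raw study animals satisfied a
stricter criterion (90 % above 1.50 at day 20) than the fitted curve
itself reaches; tests of the generator therefore assert the threshold the
model does guarantee (≥90 % of control animals above 1.40 by day 20).

## Estimation

Weighted least squares minimizes Σ wᵢ(yᵢ − ŷᵢ)². The default weighting
1/ŷ² encodes a proportional (constant-CV) error model — the natural choice
for concentration data spanning decades — with 1/y² and unit weights
selectable. Censored (below-LOQ) observations are excluded from the
objective and counted in the result. Multiple analytes or animals are
fitted simultaneously against a single parameter set. CV% comes from the
asymptotic covariance of the estimates; a singular covariance is reported,
not hidden. A small multi-start (log-spaced joint rescaling of the free
starting values, 5 starts by default) guards against local minima.

Model ranking uses the WSSR-based forms AIC = n·ln(WSSR/n) + 2p and
SBC = n·ln(WSSR/n) + p·ln(n). Absolute values of these criteria differ
between software conventions; only differences and rankings across
candidates fitted to the same data are meaningful, and the tests assert
rankings only.

## Monte-Carlo recovery studies

`pdepkpd.studies` answers the design question: at the study's group sizes,
schedules and noise, how well is the potency recovered?

- **CIA**: 6 treated animals, once-daily dosing days 20–39, measurement
  days 0–36, 10 % proportional noise on relative swelling; each replicate
  regenerates raw caliper data, re-derives relative swelling and refits
  IC₅₀ with the disease parameters and PK fixed at their generating values
  (the study likewise fixed separately-estimated PK parameters; fixing the
  disease parameters isolates the potency estimate and keeps each
  replicate inside a few seconds). At 10 % noise the recovered IC₅₀ is
  median-unbiased to within the scatter implied by the study size (the
  replicate spread has CV ≈ 40 %, matching the imprecision reported for
  this design); at 1 % noise recovery is essentially exact, confirming the
  estimator itself is consistent.
- **Endotoxemia**: 4 treated rats, samples 30–180 min (0–180 min for the
  LSF/PTX design), 15 % noise, turnover parameters fixed at truth. The
  refit data are generated *without* the 12.5 ng/L ELISA censoring: at the
  published turnover scale almost every post-peak treated sample would
  fall below the floor, leaving the potency unidentifiable; the uncensored
  design isolates estimator performance. The generator proper keeps the
  censoring.

All stochastic routines take explicit seeds; replicate seed lists are
attached to the output tables.

## Synthetic-data generator

Residual error is multiplicative log-normal with σ² = ln(1 + CV²), so the
empirical CV equals the requested CV; default CVs (PK 10 %, TNF-α 15 %,
paw 10 %, plates 5 %) are calibrated so that refits reproduce the order of
parameter imprecision reported for these designs, which is the only
guide available. LOQ censoring uses 0.050 mg/L (GRMS-55), 0.020 mg/L
(rolipram) and 12.5 ng/L (TNF-α ELISA); the LSF/PTX bioanalytical floor is
not published and is set to 0.050 mg/L. Paw geometry is generated around a
nominal healthy paw (10×8 mm) and ankle (12×9 mm) with a per-animal size
jitter — only area ratios reach the models, and the pipeline's invariance
to absolute scale is asserted by test. Optional log-normal inter-animal
variability on k_in⁰ and t_onset is off by default so oracle tests remain
exact.

What the generator does **not** emulate: assay-specific error structure
(additive floors, plate edge effects), inter-occasion variability,
drop-out, diseased-vs-healthy PK differences (the study found none), and
any histology, body-weight or clinical-score endpoints. Passing tests
therefore demonstrate correctness of the estimation machinery under the
assumed error model, not robustness to real-data pathologies.

## Known limitations

- Naïve-pooled fitting only; no mixed-effects or Bayesian estimation, and
  asymptotic CV% only (no profile likelihood).
- The group-level observed in-vivo numbers (e.g. the 30–35 % endpoint
  reductions in relative paw swelling) depend on the animal data and are
  not reproducible from the published parameters alone; the corresponding
  behaviour is covered qualitatively (treated arms below control, unimodal
  TNF-α burst, flare peaking near day 20).
- Two endpoint-reduction conventions are provided (relative to the control
  value, or to control swelling in excess of baseline) because the
  convention behind the published percentages is not stated; neither is
  asserted against those numbers.
- The LPS dose is fixed at the study scenario (1 mg/kg IV); no LPS
  dose–response, no cytokines other than TNF-α, no survival modelling.
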