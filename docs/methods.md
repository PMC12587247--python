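# Methods

This note records the models implemented in `ogttkit`, their assumptions,
the default constants and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices that a
maintainer would otherwise have to reverse-engineer from the code.

## Study design emulated

The package targets a dual-tracer OGTT in a three-arm porcine design:
sham endoscopy (control), an endoscopic duodenal-bypass device, and a
GLP-1 receptor-agonist drug, four animals per arm. After an overnight
fast, [6,6-²H₂]-glucose is infused (prime 32 µmol/kg, constant rate
0.32 µmol·kg⁻¹·min⁻¹) for a 2-h basal equilibration; at t = 0 a 75 g oral
glucose load enriched with 0.9 g [U-¹³C]-glucose is given, and blood is
sampled at 0, 5, 10, 15, 20, 25 min and then every 10 min to 180 min.
Internally the basal period is represented as negative times so that t = 0
is always load administration.

Canonical units throughout: minutes; mmol/L (glucose); pM (insulin,
C-peptide); dimensionless tracer-to-tracee ratios (TTR);
µmol·kg⁻¹·min⁻¹ (fluxes). Conversions on input: mg/dL ÷ 18.016 → mmol/L;
mU/L × 6.0 → pM.

## Oral glucose minimal model

States: plasma glucose G (mmol/L) and remote insulin action Z (min⁻¹),

    dG/dt = −(S_G + Z)·G + S_G·G_b + Ra(t)/V_G,
    dZ/dt = −p·Z + p·S_I·(I(t) − I_b),

with G(0) = G_b, Z(0) = 0. Insulin I(t) and the tracer-derived oral
glucose appearance Ra(t) are measured forcing functions, interpolated
piecewise linearly between samples. Ra/V_G is bridged into mmol·L⁻¹·min⁻¹
(1 µmol/dL = 0.01 mmol/L). Assumptions: a single well-mixed glucose pool;
insulin acts through a first-order remote compartment; basal equilibrium
before the load (G = G_b, Z = 0 is an exact fixed point of the equations
under basal forcing, and the test suite asserts this to 1e-12).

Parameters and reporting scales: S_G (min⁻¹, reported ×10²), S_I
(min⁻¹·pM⁻¹, reported ×10⁴), p (min⁻¹), V_G (dL/kg). Box bounds for the
constrained fit are generous physiological envelopes — S_G ∈ [1e-4, 0.2],
S_I ∈ [1e-7, 1e-2], p ∈ [1e-3, 1], V_G ∈ [0.5, 5] — searched in log space.

The Ra forcing is deliberately an input rather than a fitted parametric
shape: the dual-tracer protocol measures it, and reusing it couples the
model to the flux module instead of adding free parameters.

## C-peptide secretion model

Two-compartment C-peptide kinetics (central concentration CP1 = measured
C-peptide, pM):

    dCP1/dt = −(k01 + k21)·CP1 + k12·CP2 + SR(t),
    dCP2/dt = k21·CP1 − k12·CP2,

driven by the secretion rate per unit central volume SR = SR_b + Y + SR_d
with basal secretion SR_b = k01·CP_b, a delayed static pathway
dY/dt = −(Y − Φ_s·(G − h)⁺)/τ, and a dynamic pathway Φ_d·(dG/dt)⁺ active
only while glucose rises. Glucose enters the secretion arithmetic in pM
(1 mmol/L = 1e9 pM), which puts Φ_s, Φ_d, Φ₁ on the conventional ×10⁹
reporting scale. The threshold h is fixed at basal glucose, so the basal
state is an exact steady state; a washout mode without basal secretion
exposes the pure kinetic impulse response for verification.

Fitted parameters: Φ_s, Φ_d, τ (bounds Φ_s ∈ [1e-11, 1e-6] min⁻¹,
Φ_d ∈ [1e-10, 1e-5], τ ∈ [1, 120] min, log-space search). Derived indices:

* **Φ (total)** — secretion-amount-weighted combination
  Φ = Φ_s + Φ_d·ΔG⁺ / ∫(G − h)⁺ dt, where ΔG⁺ is the positive part of the
  peak excursion. It reduces to Φ_s when Φ_d = 0 and weighs the dynamic
  contribution by how much secretion it actually released relative to the
  static glucose exposure. This weighting is one of several defensible
  definitions of a "total" sensitivity; it is documented here precisely
  because published tables rarely state theirs.
* **Φ₁ (first phase)** — dynamic-pathway release over the first 10 min
  divided by the early above-basal glucose exposure ∫₀¹⁰(G − G_b)⁺ dt.
* **ISR** (pmol·kg⁻¹·min⁻¹) = SR·V_c, with trapezoidal AUC over the test
  reported in nmol (requires body weight).
* **Disposition index** DI = Φ × S_I, computed on the reporting scales
  (Φ×10⁹, S_I×10⁴).

The kinetic constants k01, k12, k21, V_c are population-level inputs, not
fitted. The shipped defaults (0.06, 0.05, 0.02 min⁻¹, 0.06 L/kg) are a
generic documented set: porcine C-peptide kinetics vary and no constant in
this package is load-bearing — every recovery test passes the generator's
kinetics explicitly, and users with individually estimated kinetics should
supply them. Consequently the *absolute* ISR and AUC_ISR scale is only as
good as the supplied kinetics; comparisons across subjects analysed with
the same kinetics are unaffected.

## Steele non-steady-state fluxes

Single-pool estimator for total glucose appearance from the infused-tracer
enrichment E_inf:

    Ra_total(t) = [F − p·V_D·C̄(t)·dE_inf/dt] / E_inf(t),

F = tracer infusion rate (µmol·kg⁻¹·min⁻¹), p = pool fraction, V_D =
distribution volume (dL/kg), C̄ = tracee glucose in the pool. At tracer
steady state this is exactly F/E. The oral component scales Ra_total by
the oral-tracer-derived fraction of plasma glucose,
Ra_oral = Ra_total·E_oral/r_load with r_load = 0.9/75 = 0.012, and
EGP = Ra_total − Ra_oral holds identically by construction (asserted
pointwise in the tests). The percent of the ingested dose appearing
systemically integrates Ra_oral over the test (trapezoid), scaled by body
weight and the 180.16 g/mol molar mass.

Defaults and choices:

* **Pool fraction 0.65, V_D 1.6 dL/kg.** Conventional glucose-turnover
  values; porcine constants for this preparation are not established, so
  both are explicit `SteeleConfig` fields rather than buried constants.
* **Tracee correction.** When E_inf + E_oral > 1%, measured glucose is
  deflated by (1 + E_inf + E_oral) before entering the pool term, so
  tracer mass does not inflate the non-steady-state correction.
* **Derivatives.** dE/dt defaults to the slope of the piecewise-linear
  interpolant (weighted central differences, one-sided at the ends) —
  reproducible and parameter-free. An optional GCV smoothing-spline
  estimator is available; any smoother must return an exactly zero
  derivative for a constant channel (contract enforced by test).
* **Negative values** of Ra or EGP are retained and flagged by default;
  clipping to zero is opt-in, and flags survive clipping so diagnostics
  are never lost.

Finite-difference derivatives on the 5–10-min sampling grid are the
dominant error source: on noiseless synthetic subjects the recovered flux
profiles are within ~1% RMS of truth in time-averages but can deviate by
a few tenths of µmol·kg⁻¹·min⁻¹ pointwise during the early enrichment
transient. For this reason the minimal-model recovery benchmarks drive
the fit with the generator's true Ra; feeding the Steele-estimated Ra
instead propagates that forcing error into parameter bias of up to ~20%
for weakly excited subjects, which is a property of the estimator chain,
not of the optimizer.

## Estimation engine

Both models minimise the normalised weighted least-squares cost
F(θ) = (z − g(θ))ᵀW(z − g(θ)) / zᵀz with diagonal W. The scalar zᵀz makes
the cost dimensionless; it does not move the minimiser for fixed W.
Default weights assume constant-CV measurement error: 2% for glucose, 4%
for C-peptide, both configurable (`WeightSpec` also accepts per-sample
SDs or raw weights).

Pipeline:

1. **Fast-greedy initialisation.** The cost is evaluated on a log-spaced
   lattice (default 5 nodes per parameter); the best nodes are refined by
   one pass of step-halving coordinate descent. Ties break to the
   first-found lowest cost in a fixed iteration order, so the result is
   deterministic. Because the S_G/p/S_I exchange makes the glucose-model
   surface multi-basined for weakly excited subjects, the descent is
   restarted from the 8 best (deduplicated) candidates and the lowest
   final cost kept; the C-peptide fit uses 2 starts.
2. **Constrained descent.** `scipy.optimize.least_squares` with a
   Levenberg–Marquardt-type trust-region step in log10-parameter space
   (positivity by construction, box bounds mapped to log space), ftol/xtol
   1e-10, at most 500 residual evaluations. The final cost never exceeds
   the starting cost.
3. **Uncertainty.** Linearisation method: the covariance of ln θ̂ is
   s²·(J_lnᵀJ_ln)⁻¹ with J_ln the residual sensitivity to ln θ and
   s² the mean squared weighted residual with n − p degrees of freedom.
   The diagonal is directly the squared relative SE, so CV% is computed on
   a scale-free matrix — essential here because parameters span ~10 orders
   of magnitude (Φ_s ~ 1e-8 vs τ ~ 10) and a natural-scale J would
   spuriously trip rank checks. Rank deficiency raises a singularity error
   naming the weakest direction; inside a fit it degrades to infinite CVs
   with the quality flag cleared.
4. **Quality bar.** Any parameter CV ≥ 20% marks the fit non-converged
   (`cv_ok`/`converged` flags). On noiseless synthetic data all CVs are
   far below the bar; at realistic assay noise, subjects with small
   glycaemic excursions genuinely fail it (see limitations).

## Group-level statistics

* **Sample size.** Two-sample normal-approximation formula
  n = 2σ²(z₁₋α/₂ + z₁₋β)²/Δ² with exact standard-normal quantiles
  (1.959964…, 0.841621…), ceiling to an integer, minimum 2. At the design
  values (Δ = 0.6, σ = 0.3, α = 0.05, power 0.80) the raw value is 3.92
  and the per-group n is 4; truncated textbook quantiles (1.96, 0.84)
  give the same n.
* **Summary arithmetic.** Percent change 100(final − initial)/initial,
  percent reduction 100(1 − a/b), fold change a/b; display rounding is
  half-up (ties away from zero), and all comparisons in tests use
  unrounded values.
* **Non-inferiority simulation.** Only group means are available for the
  absorption endpoint, so n = 12 subject-level values per group are
  simulated as mean·exp(ε), ε ~ N(0, σ²) with σ = √ln(1 + CV²) — the
  multiplicative CV then equals the configured value exactly. The single
  subject-level factor realises "within-subject correlation" as one
  multiplicative deviation per subject, since the analysed endpoint is one
  number per subject. Ratios to the comparator are analysed on the log
  scale with Welch degrees of freedom; one-sided 95% lower bounds are
  Holm step-down adjusted across the simultaneous treatment tests, and a
  treatment is non-inferior when its adjusted lower bound reaches the
  0.80 margin. Replicated runs average the point ratio on the log scale
  (geometric mean), consistent with the log-scale analysis; at the study
  settings the averages converge to 0.67 (device/sham) and ≈1.13
  (drug/sham), with the device failing and the drug passing the margin.
* **Rank tests.** Kruskal–Wallis (independent) and Friedman (repeated)
  with Bonferroni-adjusted pairwise follow-ups are thin wrappers over
  scipy, provided as reporting glue only.

## Synthetic-data generator

Strictly forward construction per subject: (1) insulin is a parametric
gamma-shaped excursion over basal, evaluated at the sampling grid and
treated as piecewise linear from there — the minimal models regard insulin
as a measured input, so no insulin-kinetics model is simulated, and the
samples carry the full forcing information; (2) glucose follows the
minimal model under the truth parameters and truth oral Ra (a
piecewise-linear profile whose breakpoints sit on the sampling grid);
(3) C-peptide follows the secretion model driven by the sampled glucose
trajectory; (4) the infused-tracer TTR integrates the single-pool tracer
balance dE/dt = (F − Ra_total·E)/(p·V_D·C̄) under the truth total Ra, with
the same tracee-correction convention the estimator applies, starting from
the basal equilibrium E_b = F/EGP_b; (5) the oral-tracer TTR is
r_load·Ra_oral/Ra_total; (6) channels are sampled on the protocol grid
(basal samples at −30, −15, 0 min) and multiplicative log-normal noise is
applied independently per channel.

Truth EGP follows EGP_b·(f + (1 − f)e^(−t/τ_e)), parameterised by its
0–180-min time-average so arm presets can state suppression directly. Arm
presets mirror the emulated study's group contrasts: minimal-model and
secretion indices at the reported group means, oral absorption means
3.11 / 2.09 / 3.50 and EGP means 9.38 / 4.60 / 8.55 µmol·kg⁻¹·min⁻¹ for
control / device / drug, large insulin excursions for the control arm and
a flat, insulin-sparing device response. Default noise CVs mirror the
stated assay precisions: glucose 2%, insulin 3.5%, C-peptide 3.6%; TTR 2%
is this package's choice (GC/MS precision is not stated).

What the generator does **not** emulate: assay drift or additive error
floors, error correlation across channels, gastric-emptying physiology
behind the oral-Ra shape (it is imposed, not mechanistic), drug
pharmacokinetics, day-to-day biological variability, or any microbiome or
metabolomic readout. Passing recovery tests therefore demonstrate that the
estimators invert the stated models under the stated noise — not that the
models are correct for any particular animal.

## Problem sizes

The default test suite fits one noiseless subject per model plus a
20-replicate Monte-Carlo study at 2% glucose noise, and the replicated
non-inferiority analysis uses 1000 seeded replicates (the whole suite runs
in well under a minute on one core). The acceptance script reruns the
non-inferiority procedure at 1000 replicates. These sizes were chosen so
Monte-Carlo error is comfortably below the tolerances being asserted
(e.g. the 1000-replicate point-ratio SE is ~0.4%).

## Known limitations

* At realistic assay noise, subjects with small glycaemic excursions carry
  little information about S_G and p; linearisation CVs then exceed 20%
  and the fit is flagged. This is inherent to the printed absorption
  means of the emulated design (mean oral Ra ≈ 2–3.5 µmol·kg⁻¹·min⁻¹
  implies excursions of a few tenths of mmol/L under the tabulated S_G
  and S_I), not an optimizer artefact.
* Φ (total) and Φ₁ are interpretation-dependent indices. With this
  package's definitions, DI = Φ×S_I is internally consistent, but Φ is
  not numerically identical to other groups' totals, and published DI
  values divided by S_I need not match either Φ or Φ₁ here.
* The Steele estimator is single-pool with a fixed pool fraction;
  two-compartment and time-varying-volume variants are out of scope, and
  early-transient fluxes inherit finite-difference error from the
  sampling grid.
* The linearisation covariance is a local approximation; profile
  likelihood or Monte-Carlo intervals would be more faithful near bounds.
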