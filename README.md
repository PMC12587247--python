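# ogttkit

Dual-tracer oral glucose tolerance test (OGTT) analysis for metabolic
physiology studies: minimal-model estimation of insulin sensitivity and
β-cell function, non-steady-state tracer fluxes, and the group-level
statistics of a three-arm preclinical design (sham control, an endoscopic
duodenal-bypass device, and a GLP-1 receptor-agonist drug) in growing pigs.

The package is aimed at investigators who run primed-constant
[6,6-²H₂]-glucose infusions with a [U-¹³C]-glucose-labelled oral load and
need the full quantitative chain from raw sampled curves to physiological
indices — without access to proprietary modelling code.

## What it computes

**Oral glucose minimal model.** Post-load glucose dynamics with two states,
plasma glucose G (mmol/L) and remote insulin action Z (min⁻¹):

    dG/dt = −(S_G + Z)·G + S_G·G_b + Ra(t)/V_G
    dZ/dt = −p·Z + p·S_I·(I(t) − I_b)

Estimated parameters: glucose effectiveness S_G (min⁻¹), insulin
sensitivity S_I (min⁻¹·pM⁻¹, reported ×10⁴), insulin-action rate constant
p (min⁻¹), distribution volume V_G (dL/kg). The oral glucose rate of
appearance Ra(t) is the tracer-derived forcing, not a fitted shape.

**C-peptide secretion minimal model.** Two-compartment C-peptide kinetics
deconvolve plasma C-peptide into the insulin secretion rate (ISR), driven
by a delayed static pathway Φ_s·(G − h)⁺ and a dynamic pathway
Φ_d·(dG/dt)⁺. Outputs: static (Φ_s), dynamic (Φ_d), total (Φ) and
first-phase (Φ₁) β-cell glucose sensitivity (reported ×10⁹), ISR, and its
trapezoidal AUC. The disposition index is DI = Φ × S_I.

**Steele non-steady-state fluxes.** Single-pool estimator

    Ra_total(t) = [F − p·V_D·C̄(t)·dE/dt] / E(t)

from the infused-tracer enrichment E, partitioned into oral Ra via the
oral-tracer enrichment relative to the load (0.9 g tracer / 75 g glucose),
with endogenous glucose production EGP = Ra_total − Ra_oral and the
percent of the ingested dose appearing systemically.

**Estimation engine.** Normalised weighted least squares
(z−g(θ))ᵀW(z−g(θ))/zᵀz, deterministic fast-greedy initialisation on a
log-spaced lattice, bound-constrained Levenberg–Marquardt-type descent in
log-parameter space, and linearisation standard errors reported as CV%
(fits with any CV ≥ 20% are flagged).

**Group statistics.** A-priori two-sample sample size, trapezoidal AUCs,
percent-gain / fold-change / percent-reduction arithmetic, rank-based group
comparisons, and a simulated-subject non-inferiority analysis: subject
values drawn as mean·exp(ε) with log-scale SD √ln(1+CV²), treatment/sham
ratios analysed on the log scale with Holm-adjusted one-sided 95% bounds
against a 0.80 margin.

**Synthetic data.** A forward generator with known ground truth emulates
the three-arm protocol (sampling grid 0, 5, 10, 15, 20, 25 then every
10 min to 180; prime 32 µmol/kg; infusion 0.32 µmol·kg⁻¹·min⁻¹), so every
pipeline stage is testable end to end without animal data.

## Worked example

```python
import ogttkit as ok

spec = ok.arm_scenario("sham", body_weight=55.0, seed=7)   # synthetic pig
series, truth = ok.generate_subject(spec)

profile = ok.compute_fluxes(series, spec.protocol)
print(round(ok.mean_flux(profile, "ra_oral", (0, 180)), 2))  # 3.08
print(round(ok.mean_flux(profile, "egp", (0, 180)), 2))      # 9.35

result = ok.GlucoseMinimalModel(series, profile.ra_oral).fit()
print(result.summary())
```

```
Oral glucose minimal model fit
==============================================
n obs                         22
cost (normalised WLS)  3.332e-02
converged                  False
all CV% < 20               False
----------------------------------------------
param         estimate       CV%
SG x10^2 (1/min)            1.39     566.8
SI x10^4 (1/min/pM)       0.7803     326.6
p (1/min)                0.02586     486.6
VG (dL/kg)                 1.568      29.0
----------------------------------------------
Gb = 5 mmol/L, Ib = 58.29 pM
```

The flux means recover the generating truth (3.11 and 9.38 µmol·kg⁻¹·min⁻¹)
to about 1%. The fitted S_I×10⁴ of 0.78 matches the generating value, but
the CV% column shows that with this subject's small glycaemic excursion and
2% assay noise the disposal parameters are weakly identified — the fit is
therefore flagged (`converged False`). On noiseless data the same pipeline
returns all four parameters within 2% with CV% below 20 (see the test
suite); low-excursion subjects under realistic noise genuinely carry little
information about S_G and p, and the flag says so rather than hiding it.

A C-peptide fit on the same subject
(`ok.CPeptideMinimalModel(series, spec.cp_truth.kinetics, body_weight=55.0).fit()`)
returns Φ_s×10⁹ = 58.6 and Φ_d×10⁹ = 627.7 against generating values of
59.4 and 965.9 — the dynamic index is attenuated by the noise on this
single draw — plus the reconstructed ISR and its AUC.

The same pipeline is scriptable from a shell:

```sh
ogttkit simulate --n 4 --seed 7 --out data/
ogttkit fluxes --in data/sham_01.csv --body-weight 55 --out fluxes.csv
ogttkit fit-glucose --in data/sham_01.csv --ra fluxes.csv --out fit.json
ogttkit power --mu1 1.4 --mu2 2.0 --sigma 0.3
ogttkit noninferiority --means sham=3.11,device=2.09,drug=3.50 --seed 1
```

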