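# Methods

## Model structure

The system couples two two-compartment PK models to three
pharmacodynamic modules and a four-compartment tumor model; all state
is integrated jointly in hours.

**PK.** Pemetrexed (i.p., bioavailability fixed at 1) and osimertinib
(oral, apparent V/F parameterisation) each follow a depot + central +
peripheral model. Amounts are per kg body weight (mg/kg, volumes in
L/kg), so mouse body weight never enters the simulation; it would only
be needed to convert to absolute amounts. Plasma concentrations are
kept on the scales of the plasma potencies: mg/L for PEM (EC50
0.47315 mg/L) and µg/L for OSI (EC50 48.86 µg/L).

**Folate cascade.** PEM stimulates the loss term of a normalized
folate-metabolising enzyme pool (Emax model in C_pem); folate synthesis
is slaved to the enzyme pool through a power γ_enzyme. Both pools have
baseline 1, giving the algebraic steady states
Enzyme_ss = 1/(1+Emax·C/(EC50+C)) and Folate_ss = Enzyme_ss^γ_enzyme
under constant exposure, which the tests check against integration.

**EGFR signal.** A turnover model with baseline 1. OSI stimulates the
loss term through a Hill function; the synthesis term is amplified by
the damaged-cell fraction (`1 + k_fb·Damaged^γ_fb`), which produces the
EGFR rebound after PEM damage. Damaged is a fraction in [0,1], not a
percentage; k_fb is therefore on the fraction scale (a percent-scale
gain would need rescaling by 100^γ_fb).

**Tumor.** Proliferating volume X₁ grows by a Simeoni
exponential-to-linear law with switching exponent ψ = 20 (standard
value; the switch variable is total volume X). Growth is multiplied by
EGFR^γ_EGFR. The X₁→X₂ transition — the cytotoxic flux — is
`k₁·X₁·(1+Emax_f·D^γ_f/(EC50_f^γ_f+D^γ_f))·EGFR^γ_G1` with folate
deficit D = max(0, 1−Folate): folate above baseline produces no kill,
and EGFR below baseline (G1 arrest) gates the whole flux, not only its
drug-amplified part. One shared expression computes this flux for both
compartments, so mass conservation holds by construction. Damaged
cells transit X₂→X₃→X₄ and are cleared from X₄ at
`k₂·(1+k_bim·max(0,1−EGFR)^γ_bim)`; feedback-elevated EGFR (>1) gives
zero Bim amplification rather than a negative one. The cleared-volume
integral is carried as an explicit CumDead state.

The kill term carries the Hill exponent γ_folate in both the X₁ and X₂
equations (the shared-flux form); γ_folate = 1 recovers the simpler
printed form of the in vitro mini-model, and conservation leaves no
alternative.

## Dosing and regimens

The study design is cyclic (7-day cycles, 3 cycles for the mouse
efficacy setting): PEM 35 mg/kg i.p. three times daily at 4 h spacing
on days 1–2 of each cycle — six doses producing ≈48 h of continuous
exposure given PEM's ~35 min murine half-life — and OSI 1 mg/kg
orally once daily from cycle start (concurrent) or from `interval_h`
after the cycle's first PEM dose (sequential), to cycle end. Doses are
instantaneous additions to the absorption compartments with hard
integrator restarts. All of this is overridable (doses, cycle length,
number of cycles, custom event tables from CSV).

## Numerics

Two integrators share one vectorised right-hand side:

* LSODA (stiff/non-stiff switching), rtol 1e-6 / atol 1e-9, for single
  trajectories;
* a fixed-step classical RK4 vectorised across subjects (default 16
  steps/h; dose events land on integer hours so every batch member
  sees identical breakpoints), for Monte Carlo populations and Sobol
  sampling where thousands of parameter sets integrate simultaneously.

The two agree to <0.5% on trajectory volumes, and the population ORR
is step-size converged (8 vs 16 steps/h differ by <0.05 ORR points).
Hill drivers clip their arguments at zero inside the RHS so solver
undershoot cannot generate negative concentrations or deficits; raw
states are untouched and monitored (positivity to −1e−9·scale).

## Parameter provenance and calibration

Directly fixed values: λ₀ = 0.1032/day and λ₁ = 51.08 mm³/day
(control-growth fit), k_out,EGFR = 1.5/day (signal-recovery fit), OSI
plasma EC50 = 48.86 µg/L via the free-fraction chain (fu_plasma 5.35%,
plasma protein 10× medium, MW 499.6 g/mol), PEM plasma EC50 =
0.47315 mg/L, wild-type k_bim = 211 with the BIM-deletion genotype at
21.1 (10%) and a fivefold γ_bim, V₀ = 200 mm³, 11.5% deletion
prevalence, 30% log-normal IIV, 2000 subjects, 210-day horizon,
responder threshold 0.7·V₀.

The remaining rates and gains are not published as a table, so they
were calibrated once, jointly, against the reported emergent behaviour
— the interval ordering (concurrent > 24 h > 48 h ≈ 72 h ≈ 96 h with
the 48 h endpoint below half the 24 h endpoint), the relative endpoint
ratios of the combination arms versus OSI monotherapy, and the
population-level time-averaged ORRs (≈91.6% sequential, ≈67.1%
concurrent) — and then frozen as the package defaults. The calibrated
regime is mechanistically specific: enzyme/folate turnover of
0.12/h each places the folate-deficit kill window at roughly hours
10–60 of each cycle (late enough that a 24 h OSI start still truncates
it, closed early enough that 72/96 h starts gain nothing); damaged
cells are near-immortal without OSI (k₂ = 0.02/day) but clear within
days under Bim amplification, which is what makes PEM monotherapy
stall rather than shrink tumors while the sequential arm clears them;
and the G1 gate (γ_G1 = 0.97) sets how much of the concurrent arm's
kill survives co-exposure. Mouse PK defaults give PEM a ~35 min
terminal half-life and OSI a ~4.6 h one.

Two reported behaviours could not be reproduced simultaneously with
this set: the day-18 TGI% sensitivity ranking (Bim/OSI-sensitivity
parameters leading for the sequential arm) requires Bim-limited
clearance (k₂·k_bim ≲ 1/day), which is incompatible with the flat
48/72/96 endpoints at day 21 (slowly clearing pools then differ by the
two-day OSI-start shift). The defaults favour the endpoint behaviour;
the sensitivity analysis with these defaults ranks the folate-kill
block first instead, and the corresponding checks in the test suite
document the discrepancy rather than hide it.

## Virtual population

Genotype is drawn first (Bernoulli, 11.5%), setting (k_bim, γ_bim) by
a two-point distribution; median-preserving log-normal variability
(θ·e^η, η ~ N(0, ln(1+CV²)), CV 0.30) is then applied to those and to
all other PD and growth parameters (PK and the structural ψ, V₀ stay
fixed — plasma sampling, not tumor biology, identifies PK). EC50_folate
draws are capped at 1, its physical bound on the deficit-fraction
scale; without the cap the log-normal tail silently abolishes
cytotoxicity for a third of subjects. The weekly mouse cycle repeats
for the whole 210-day horizon. A responder at time t has
V(t) ≤ 0.7·V₀ (instantaneous mode, which makes the ORR–time curve
fluctuate as tumors cross the threshold; a cumulative best-response
mode is provided since RECIST best response is cumulative). The
time-averaged ORR is the mean of ORR(t) over the daily grid.

## Sensitivity analysis

Saltelli radial sampling (scrambled Sobol' sequence, n(d+2) model
runs) with Jansen estimators for first- and total-order indices and
bootstrap percentile intervals. Parameters vary uniformly on
0.5–2× their baseline (2/3–3/2× for Emax_folate and kout_enzyme); the
output metric is the day-18 TGI% of the treated arm against a control
sharing the same parameter draw. Estimator correctness is checked
against the analytic additive model and the Ishigami benchmark.

## Synthetic data

Generators cover every calibration input: per-animal tumor-volume
curves (every-3-days grid, log-normal 20% CV), two-compartment plasma
profiles (proportional 15% error, with a sparse pooled-subgroup mode
emulating serial microsampling), EGFR-recovery curves on the
0–72 h washout grid and 4PL inhibition tables (additive 5% of
baseline), and virtual cohorts. All noise flows from a single master
seed through named child streams recorded in a JSON `GroundTruth`
side-car, so regeneration is bit-identical. These emulate the *designs*
of the source experiments, not their biology: real blots have
batch effects and saturation, real volumes have correlated
measurement error within animals, and real PK has BQL censoring — none
of which is modelled, so zero-noise round-trip recovery shows fitter
correctness, not field performance.

## Fitting conventions

Bounded nonlinear least squares (trust-region reflective) from five
log-spaced multiplicative starts; PK profiles are fitted on
log-concentrations (equivalent to 1/ŷ² weighting), TGI% curves with
unit weights. NCA uses linear-up/log-down trapezoids; the terminal
slope takes the post-Tmax tail (≥3 points) with the best adjusted R².
The DDI window is the closed bioequivalence interval [0.8, 1.25] on
exposure ratios. The in vitro control compartment keeps the printed
baseline loss term (−k₁·X₅); a switch drops it if that term is deemed
a typo. In vitro potencies are converted with MW 427.4 g/mol for PEM
(free acid — this reproduces the printed 300 nM ↔ 0.1282 µg/mL) and
499.6 g/mol for OSI; molecular weights are data, not constants.

## Known limitations

* The defaults are a calibrated reconstruction, not the study's
  estimated table; absolute volumes should be read comparatively.
* OSI active metabolites, intratumoral PK, resistance dynamics and PFS
  are out of scope.
* The fixed-step batch integrator assumes the calibrated stiffness
  regime; raising k₂·k_bim or PK rates by orders of magnitude calls
  for the LSODA path.
* The 72-vs-96 h endpoints differ by ~14% (each within ~8% of the
  48 h endpoint): one extra uncovered day costs λ₀-scale regrowth of
  the residual proliferating pool, a floor set by the weekly-cycle
  design itself.
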