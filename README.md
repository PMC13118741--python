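# pemosi

A mechanistic QSP–PK–PD model of **schedule-dependent synergy between
pemetrexed (PEM) and osimertinib (OSI)** in EGFR-mutant NSCLC
xenografts, for pharmacometricians and systems-pharmacology modellers
who want to simulate, calibrate and stress-test sequential-versus-
concurrent combination schedules.

Combining an antifolate with an EGFR tyrosine-kinase inhibitor is
schedule-dependent: given concurrently, OSI-induced G1 arrest keeps
cells out of S phase and blunts PEM cytotoxicity; given sequentially
(PEM→OSI), PEM first drives proliferating cells into a damaged state
and provokes a pro-survival EGFR signalling rebound, which OSI then
shuts down while amplifying Bim-mediated apoptosis of the damaged
cells. The package encodes that mechanism as a coupled ODE system and
lets the schedule dependence *emerge* from one parameter set.

## Model

Five coupled modules (state in parentheses):

* **PEM PK** — two-compartment i.p. model (depot, central, peripheral);
  C₁ = X₁/V₁ in mg/L.
* **OSI PK** — two-compartment oral model on the apparent V/F basis;
  C₁ = X₁/(V₁/Fa) in µg/L.
* **Folate** — indirect-response cascade: PEM stimulates loss of
  folate-metabolising enzymes (Emax model), folate synthesis follows
  the enzyme pool (`Folate_ss = Enzyme^γ_enzyme`).
* **EGFR** — turnover with OSI-stimulated inactivation
  (Imax·C^γ/(EC50^γ+C^γ)) and damage-driven synthesis feedback
  (`kin·(1 + k_fb·Damaged%^γ_fb)`), the signal-rebound mechanism.
* **Tumor (TGI)** — Simeoni-type growth with exponential→linear switch
  `λ₀X₁·EGFR^γ_EGFR / [1+(λ₀/λ₁·X)^ψ]^{1/ψ}`, a folate-deficit-driven
  X₁→X₂ kill flux gated by `EGFR^γ_G1` (G1 arrest), a damaged-cell
  transit chain X₂→X₃→X₄, and Bim-amplified clearance
  `k₂·(1 + k_bim·(1−EGFR)^γ_bim)`.

Around the core sit an IVIVE module (free-fraction potency correction,
molar↔mass conversion, growth-rate scaling), stepwise calibration
fitters (two-compartment PK, EGFR-recovery, 4PL, γ_EGFR, the folate
block, γ_bim, Simeoni control growth, NCA and the 0.8–1.25 DDI
window), Sobol global sensitivity analysis (Saltelli sampling, Jansen
estimators), Monte Carlo virtual populations, and synthetic-data
generators with known ground truth for every calibration input.

## Worked example

```python
import pemosi

params = pemosi.ModelParams()           # calibrated defaults
res = pemosi.compare_intervals(params, [0.0, 24.0, 48.0, 72.0, 96.0],
                               n_cycles=3)
for iv, v in res["final_volume"].items():
    print(f"interval {iv:5.0f} h -> final volume {v:6.1f} mm^3")
```

prints (day-21 endpoint of a 3-cycle weekly schedule, PEM 35 mg/kg
t.i.d. days 1–2, OSI 1 mg/kg daily):

```
interval     0 h -> final volume  125.8 mm^3
interval    24 h -> final volume   70.9 mm^3
interval    48 h -> final volume   25.5 mm^3
interval    72 h -> final volume   23.5 mm^3
interval    96 h -> final volume   27.0 mm^3
```

Interval 0 is concurrent dosing. The ordering concurrent > 24 h > 48 h
with a plateau at 48–96 h is the schedule-dependence signature: a 48 h
head start for PEM lets the damaged-cell pool build before OSI's G1
arrest gates the transition, and the 48 h endpoint is less than half
the 24 h endpoint, while waiting 72–96 h adds nothing.

On the IVIVE side,

```python
ctx = pemosi.BindingContext(fu_plasma=0.0535, protein_ratio=10.0)
pemosi.ec50_to_plasma(14.49, ctx, pemosi.OSI)   # -> 48.86 ug/L
pemosi.scale_growth_rate(0.1032)                # -> (0.4888/day, 0.0204/h)
```

converts the in vitro medium potency of OSI (14.49 nM) to its plasma
scale and the in vivo exponential growth rate to its in vitro
counterpart.

A CLI wraps the same stages:

```bash
pemosi simulate --out out/            # one trajectory + TGI% vs control
pemosi intervals --out out/           # the table above as CSV
pemosi population --seed 1 --out out/ # virtual-population ORR curves
```

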