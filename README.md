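# nmrkin

Enzyme-kinetic parameter estimation from NMR progress curves, built
around the two initial glycolytic enzymes of *Escherichia coli*:
phosphoglucose isomerase (PGI, G6P ⇌ F6P) and phosphofructokinase
(PFK, F6P + ATP → FBP + ADP, inhibited by PEP).

## Who this is for

Systems-biology modellers need rate laws that capture reversibility,
cooperativity and allosteric modulation under near-physiological
conditions — not irreversible Michaelis–Menten constants from
initial-rate assays.  ³¹P-NMR time courses of a cell extract incubated
with substrates deliver whole progress curves for *every*
phosphorylated species at once.  This package turns such data (or
faithful synthetic stand-ins) into fitted generalized Hill rate laws
with standard errors, and validates them by simulating the coupled
two-enzyme system.

## The model

Concentrations enter scaled by half-saturation constants
(σ = [S]/S₀.₅, π = [P]/P₀.₅, μ = [M]/M₀.₅); Γ = [P]/[S] is the
mass-action ratio.

Reversible uni-uni Hill law (PGI; at *h* = 1 it is the reversible
Michaelis–Menten equation):

```
v = Vf · σ (1 − Γ/Keq) · (σ+π)^(h−1) / (1 + (σ+π)^h)
```

Irreversible bi-substrate Hill law with a hyperbolic allosteric
modifier (PFK, modifier PEP with effect α < 1 = inhibition):

```
v = Vf · (σ₁σ₂)^h / (M + σ₁^h + σ₂^h + (σ₁σ₂)^h),   M = (1+μ^h)/(1+αμ^h)
```

The reverse maximal rate of a reversible law follows from the Haldane
relationship `Vr = Vf·P₀.₅/(S₀.₅·Keq)` rather than being fitted.

The pipeline: FID array → exponential apodization (8.5 Hz) → FFT,
phasing, baseline → box integration or Lorentzian deconvolution →
internal-standard (TEP) and T1-saturation calibration → independent
cubic smoothing splines per species → stoichiometry-signed derivative
averages as rate samples → global fit of the rate law by a seeded
genetic algorithm refined with Levenberg–Marquardt, with SEMs from the
residual-variance-scaled covariance `(JᵀJ)⁻¹·RSS/(n−p)`.

## Worked example

```python
from nmrkin import GlobalRateFit, ReversibleHillUni
from nmrkin.pipeline import build_problem
from nmrkin.synthetic import NOISELESS, pgi_scenario, simulate_noisy_timecourses

curves, truth = simulate_noisy_timecourses(pgi_scenario(noise=NOISELESS))
problem = build_problem(curves, ReversibleHillUni("G6P", "F6P"),
                        fixed={"h": 1.0}, smoothing=0.0)
print(problem.fit(seed=42).summary())
```

prints

```
Global rate-law fit: ReversibleHillUni(G6P <-> F6P)
  n samples 180, free parameters 4, dof 176
  RSS 1.10236e-08   R^2 1.0000   converged True  (seed 42)
  parameter      estimate          SEM
  vf             0.355064     1.22e-05
  ks             0.549918     0.000189
  kp             0.151996     4.84e-05
  keq               0.286     1.29e-06
  h                     1      (fixed)
```

Here `vf` is the volumetric maximal rate in mM·min⁻¹ at 0.1 mg·mL⁻¹
extract protein — 0.355/0.1 = 3.55 µmol·min⁻¹·mg⁻¹ specific activity —
and `ks`/`kp` are the G6P and F6P half-saturation constants in mM,
recovered from the synthetic assays' generating values (3.551, 0.550,
0.152, Keq 0.286) to within a tenth of a percent.  The SEM column is
the covariance-based standard error; `keq` is pinned almost exactly by
the near-equilibrium portions of the time courses.

A CLI wraps the same steps (`nmrkin synth | quantify | rates | fit |
scan | simulate`); see `nmrkin --help`.

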