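# Methods

## Rate laws

The toolkit fits the generalized reversible Hill family, chosen for
its small, operationally defined parameter set: half-saturation
constants per species, a Hill coefficient *h* shared by substrates and
modifier, a modifier effect α (α < 1 inhibitor, α > 1 activator,
α = 1 inert), and Keq for reversible schemes.  Mechanistic
Monod–Wyman–Changeux descriptions of PFK are deliberately out of
scope.

The uni-uni reversible form is

v = Vf·σ(1 − Γ/Keq)·(σ+π)^(h−1) / (1 + (σ+π)^h),

implemented with the driving term rewritten as (s − p/Keq)/S₀.₅ so the
s → 0 limit is an algebraic evaluation rather than a 0/0; the doubly
zero corner (s = p = 0) is defined as v = 0.  Thermodynamic
consistency — sign(v) = sign(1 − Γ/Keq), v = 0 exactly on Γ = Keq, and
the Haldane identity Vr = Vf·P₀.₅/(S₀.₅·Keq) — is property-tested.

The bi-substrate irreversible Hill form with one modifier is

v = Vf·(σ₁σ₂)^h / (M + σ₁^h + σ₂^h + (σ₁σ₂)^h),  M = (1+μ^h)/(1+αμ^h).

This reconstruction reduces to the single-substrate Hill equation when
one substrate saturates, places the modifier term where the constant
"1" sits in the uni-substrate law, and uses one shared *h* (the
modifier exponent is not fitted separately).  The rate-law registry is
pluggable, so an alternative algebraic form can be swapped in without
touching the fitter; all laws broadcast over numpy arrays in both
concentrations and parameters, which lets the genetic algorithm
evaluate an entire population in one vectorized call.

Units: maximal rates are stored as specific activities
(µmol·min⁻¹·mg⁻¹) and converted to volumetric mM·min⁻¹ through the
extract protein concentration (mg·mL⁻¹); half-saturations and
concentrations are mM; *h*, α and Keq are dimensionless.

## NMR processing

Each arrayed acquisition is a set of complex FIDs with timing
metadata, readable from Varian-dialect fid/procpar directories (a
hand-written binary reader; ~float32/int32/int16 big-endian) or a
portable JSON form.  Processing follows standard practice:
exponential apodization (default 8.5 Hz line broadening, adding
exactly that to every Lorentzian FWHM), zero-filling to a power of
two (×2), FFT with the first point halved to suppress the constant
offset, zero-order phasing (automatic by minimizing baseline
negativity, or explicit), optional polynomial baseline.

Quantification is the ratio to the internal standard (triethyl
phosphate, TEP), corrected for ³¹P counts per molecule and for
incomplete T1 relaxation with the steady-state Ernst factor
(1 − E)sinθ/(1 − E·cosθ), E = exp(−TR/T1); correction factors may also
be supplied directly, as from a fully relaxed reference spectrum.  Two
integration modes exist:

* **Box integration** over narrow (±0.2 ppm) windows with a local
  *flanking baseline*: a straight line through the median intensity of
  0.06-ppm strips just outside the window is subtracted first.
  Lorentzian tails of neighbouring lines are locally linear at that
  distance, so this removes most cross-peak leakage; the window's own
  symmetric tail loss is the same relative amount for every
  equal-width window and cancels in the ratio to the standard.
* **Lorentzian deconvolution** (least squares, optional fitted linear
  baseline) for crowded regions.  The canonical hard case — F6P at
  ~2.45 ppm between the FBP β-anomer lines at 2.6/2.3 ppm — defeats
  box integration outright but is recovered exactly by a joint
  three-component fit; the alternative used in practice is inferring
  F6P from equilibrium with G6P (F6P = Keq·G6P) once the much faster
  isomerase has equilibrated.

Blocks whose standard area vanishes are excluded and logged; negative
concentrations from noise are clipped to zero and flagged, never
propagated.

## Rate extraction

Progress curves are fitted *independently* with cubic smoothing
splines — mass conservation is never imposed, though the conservation
defect is available as a diagnostic.  The smoothing budget defaults to
n·σ̂² with σ̂ estimated from second differences of the curve, i.e. the
spline smooths at the noise level; 0 interpolates.  Reaction rates are
the stoichiometry-signed mean of the available species derivatives at
the measured time points (e.g. ½(dF6P/dt − dG6P/dt) for PGI); species
perturbed by side reactions (ADP under background hydrolysis, ATP
maintained by pyruvate kinase) are excluded from the average while
still appearing in the concentration vector.  The two outermost grid
points of each curve are not sampled and the remaining edge samples
are down-weighted (0.5): spline derivatives are least reliable at the
boundary, and the initial reaction corner is steepest there.

Assays from different NMR sessions or extracts are normalized by a
per-session maximal-rate reference (median rate over the first
quartile of the reference course) and rescaled once by an externally
determined Vmax.  Data acquired before the PGI equilibration criterion
|F6P/G6P − Keq| ≤ 0.05·Keq (relative tolerance configurable) are
excluded from fitting and kept separately for model validation.

## Global fitting

Rate samples pooled across assays are fitted by weighted least
squares.  Because Hill-type landscapes are multimodal — notably a flat
"inert modifier" valley at (M₀.₅ → ∞, α arbitrary) — optimization is
staged: a seeded genetic algorithm (population 64, tournament
selection of 3, arithmetic crossover 0.7, Gaussian mutation of sd 0.15
in log₁₀ space, elitism 2, 200 generations; all configurable) searches
the bounded log-parameter box, then the three best mutually distinct
individuals are each refined with Levenberg–Marquardt in log space
(positivity by construction) and the lowest final RSS wins, ties going
to the first candidate.  Fits are bitwise reproducible given the seed.

Standard errors come from cov = (JᵀJ)⁻¹·RSS/(n−p) with J the
finite-difference Jacobian with respect to the *natural* parameters at
the solution; rank-deficient directions are flagged with infinite SEM
rather than silently inverted.  Goodness of fit is R² = 1 − RSS/TSS
over the pooled rates.

The truncation scan deletes the k latest (closest-to-equilibrium)
samples of every assay for k = 0…max and refits, reporting SEMs under
two degrees-of-freedom conventions — rescaled to the truncated count
(n_k − p) and held at the original (n₀ − p) — to separate error growth
from losing data generally versus losing near-equilibrium data
specifically.  The ambiguity between per-assay and pooled truncation
counts is resolved as per-assay tails, with the pooled count reported
alongside.

## Minimal coupled model

The validation model couples the fitted PGI and PFK laws with
rapid-equilibrium Mg²⁺ binding (K_MgATP = 10⁴ M⁻¹, K_MgADP = 10³ M⁻¹,
free Mg²⁺ clamped at 1 mM) and a slow background hydrolysis
(k = 2×10⁻⁴ min⁻¹, never fitted) consuming MgADP to AMP + Pi + Mg²⁺.
The binding equilibria are substituted algebraically at each
derivative evaluation instead of being simulated as fast reactions,
which avoids artificial stiffness; state variables are nucleotide
totals, with the complexed/free forms as derived outputs.  Two
readings of the hydrolysis step exist in the source practice — rate
proportional to MgATP (default) or an elementary decay of MgADP — and
both are implemented behind a switch, neither presented as ground
truth.  PFK consumes the ATP total by default, matching the convention
under which its ATP₀.₅ was fitted; an MgATP-pool mode is available.
Adenylate and hexose-phosphate totals are conserved by construction
(tested to < 10⁻⁶ relative drift).  The bare hydrolysis constant is
taken as min⁻¹.  SBML export is not provided (no SBML library in the
supported dependency set); models serialize to JSON and trajectories
to CSV.

## Synthetic study conditions

The generator is the package's definition of the study it emulates;
its defaults are fixed and not tuned per test:

* **PGI**: five assays with initial (G6P, F6P) = (10, 0), (5, 0),
  (0, 8.5), (2, 6) and (1, 0.5) mM, each sampled at 40 uniform points
  over a horizon ending near its own equilibration (35, 20, 47, 30 and
  7 min) — real courses are stopped near equilibrium, not left idling
  on it.
* **PFK**: six assays crossing F6P ∈ {3, 10} and ATP ∈ {2.5, 5} mM
  without inhibitor, plus two inhibitor assays at sub-saturating
  substrate (F6P = ATP = 1 mM) with PEP at 4 and 8 mM; 40 points over
  60 min.  PEP decays first-order (0.08 min⁻¹), standing in for the
  enolase/phosphoglycerate-mutase and pyruvate-kinase exit routes, and
  thereby sweeps μ through its half-saturation range within one
  course.  Both choices are identifiability requirements: at
  saturating substrates the modifier term is swamped by the substrate
  terms (< 0.01 % rate change) and with static PEP ≫ PEP₀.₅ the pair
  (PEP₀.₅, α) is structurally unidentifiable.
* Extract protein 0.1 mg·mL⁻¹, giving maximal volumetric rates that
  make the PGI courses span tens of minutes as observed in practice.
* Noise: 3 % multiplicative on concentrations by default;
  FID synthesis adds complex Gaussian noise (sd 1.8 per point ≈
  spectral SNR 50 for a 5 mM species) on Lorentzian lines of 2 Hz
  natural width placed at the ³¹P shifts of the species (TEP anchoring
  0 ppm), with amplitudes scaled by concentration, ³¹P count and T1
  saturation.

What the generator does *not* emulate: lock drift, phase roll,
higher-order baseline curvature, J-coupling multiplet structure
(the FBP "quartet" is reduced to its two anomer lines), enzyme
denaturation, and the ADP/ATP side-reaction network beyond the PEP
decay and the minimal model's hydrolysis step.  Passing round-trip
tests therefore demonstrate the correctness of the analysis chain
under these idealized conditions, not robustness to every artefact of
real spectra.

## Numerical choices and limitations

* ODEs: LSODA with rtol 10⁻⁸/atol 10⁻¹⁰ (generator: 10⁻¹⁰/10⁻¹²);
  cross-checked against a fixed-step RK4 re-implementation.
* Default fit bounds: Vf within a factor 10–100 of the largest
  observed rate, half-saturations in [10⁻³, 10²] mM, Keq and α in
  [10⁻³, 10³], h in [0.2, 8]; parameters are fitted in log space.
* Degenerate inputs: all-zero spectra flag deconvolution as
  degenerate; zero-variance rate sets make R² an explicit error; GA
  fitness ties break to the lowest index.
* Problem sizes in the shipped tests and the reproduction script —
  5 × 40 and 6 × 40-point assays, 100-replicate calibration runs, 14-
  and 9-step truncation scans — were chosen so the whole suite
  completes in about a minute on a single core while leaving the
  statistical assertions comfortable margins.
* Known limitations: with realistic (3 %) concentration noise the
  spline-derivative route inflates half-saturation uncertainties
  substantially (the reversible law's S₀.₅ values are the worst
  affected — an intrinsic weakness of progress-curve data that the
  truncation scan makes visible); per-block area noise at SNR 50 is
  ~10 % for small peaks because apodized spectral noise is correlated
  across bins; the PFK modifier pair occasionally collapses into the
  inert-modifier valley in noisy replicates, which the rank-deficiency
  flagging reports rather than hides.
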