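"""Synthetic study generator: noisy progress curves and FID series.

Everything the pipeline consumes can be generated here from known
ground truth, so recovery and calibration tests need no external data.
Two canonical scenarios mirror the assay designs of the PGI/PFK study
the toolkit is built around:

* :func:`pgi_scenario` — five reversible-isomerase time courses with
  initial G6P/F6P pairs spanning 0–10 mM (one starting from 8.5 mM F6P
  and no G6P), 40 points over 47 min.
* :func:`pfk_scenario` — six irreversible-kinase time courses crossing
  F6P in {3, 10} mM and ATP in {2.5, 5} mM, with the PEP inhibitor at
  0, 4 and 8 mM; 40 points over 60 min.

Defaults: protein 0.5 mg·mL⁻¹, 3 % multiplicative concentration noise
(the scatter level typical of ³¹P peak integrals), optional per-session
maximal-rate jitter for normalization exercises.  FID synthesis places
each species at its ³¹P chemical shifts (the FBP β-anomer as two lines
at 2.6 / 2.3 ppm bracketing F6P at 2.4 ppm — the documented hard case
for box integration), scales amplitudes by concentration, ³¹P count
and T1 saturation, and adds complex Gaussian noise sized to give a
spectral SNR around 50 for a 5 mM species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .nmr import FIDSeries, PeakWindow, RelaxationCalibration, saturation_fraction
from .progress import ProgressCurve
from .ratelaws import (RateLaw, RateLawParameters,
                       irreversible_hill_bi_rate, reversible_hill_uni_rate)

__all__ = [
    "NoiseModel",
    "SyntheticAssay",
    "ScenarioSpec",
    "TABLE_PGI",
    "TABLE_PFK",
    "pgi_parameters",
    "pfk_parameters",
    "pgi_scenario",
    "pfk_scenario",
    "simulate_noisy_timecourses",
    "Resonance",
    "DEFAULT_PEAK_MAP",
    "default_windows",
    "default_calibration",
    "AcquisitionParams",
    "synthesize_fid_series",
]

# Fitted parameter sets of the source study (ground truth for round trips).
TABLE_PGI = {"vf": 3.551, "ks": 0.550, "kp": 0.152, "keq": 0.286, "h": 1.0}
TABLE_PFK = {"vf": 0.4435, "ks1": 0.4174, "ks2": 0.5444, "km": 0.0863,
             "alpha": 0.3797, "h": 1.883}

DEFAULT_PROTEIN = 0.1  # mg/mL, matching ~47-min extract time courses


def pgi_parameters(protein_conc: float = DEFAULT_PROTEIN) -> RateLawParameters:
    return RateLawParameters(vf=TABLE_PGI["vf"],
                             half_sat={"G6P": TABLE_PGI["ks"],
                                       "F6P": TABLE_PGI["kp"]},
                             h=TABLE_PGI["h"], keq=TABLE_PGI["keq"],
                             protein_conc=protein_conc)


def pfk_parameters(protein_conc: float = DEFAULT_PROTEIN) -> RateLawParameters:
    return RateLawParameters(vf=TABLE_PFK["vf"],
                             half_sat={"F6P": TABLE_PFK["ks1"],
                                       "ATP": TABLE_PFK["ks2"],
                                       "PEP": TABLE_PFK["km"]},
                             h=TABLE_PFK["h"], alpha=TABLE_PFK["alpha"],
                             protein_conc=protein_conc)


@dataclass
class NoiseModel:
    """Noise on concentrations (curve level) and on FIDs (signal level)."""

    conc_multiplicative_sd: float = 0.03
    conc_additive_sd: float = 0.0      # mM
    fid_noise_sd: float = 0.0          # complex Gaussian, per point
    linewidth_hz: float = 2.0          # natural Lorentzian FWHM

    def __post_init__(self):
        for name in ("conc_multiplicative_sd", "conc_additive_sd",
                     "fid_noise_sd", "linewidth_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def noiseless(self) -> bool:
        return (self.conc_multiplicative_sd == 0 and
                self.conc_additive_sd == 0 and self.fid_noise_sd == 0)


NOISELESS = NoiseModel(0.0, 0.0, 0.0)

# complex noise sd giving a spectral SNR of roughly 50 for a 5 mM species
# under the default acquisition and 8.5 Hz line broadening
FID_NOISE_SNR50 = 1.8


@dataclass
class SyntheticAssay:
    assay_id: str
    initial: dict[str, float]
    t_grid: np.ndarray
    session: str = "s1"

    def __post_init__(self):
        self.t_grid = np.asarray(self.t_grid, dtype=float)


@dataclass
class ScenarioSpec:
    """A full synthetic study: law + truth + assay designs + noise + seed."""

    kind: str                       # "pgi" or "pfk"
    params: RateLawParameters
    assays: list[SyntheticAssay]
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    session_vf_jitter: float = 0.0  # relative sd of per-session Vf factors
    pep_decay_rate: float = 0.0     # min^-1, first-order PEP consumption by
                                    # side reactions (enolase/PGM, pyruvate
                                    # kinase); sweeps the modifier through
                                    # its half-saturation range

    def __post_init__(self):
        if not self.assays:
            raise ValueError("a scenario needs at least one assay")
        if self.kind not in ("pgi", "pfk"):
            raise ValueError("kind must be 'pgi' or 'pfk'")


def pgi_scenario(seed: int = 0, noise: NoiseModel | None = None,
                 n_points: int = 40, t_max: float | None = None,
                 protein_conc: float = DEFAULT_PROTEIN,
                 session_vf_jitter: float = 0.0) -> ScenarioSpec:
    """Five-assay reversible PGI design (initial G6P/F6P in mM).

    Horizons are per assay: small pools relax faster and are sampled
    over a shorter window so the same 40 blocks resolve the approach to
    equilibrium.
    """
    initials = [(10.0, 0.0, 35.0), (5.0, 0.0, 20.0), (0.0, 8.5, 47.0),
                (2.0, 6.0, 30.0), (1.0, 0.5, 7.0)]
    assays = [SyntheticAssay(f"pgi{i+1}", {"G6P": g, "F6P": f},
                             np.linspace(0.0, t_max or tm, n_points))
              for i, (g, f, tm) in enumerate(initials)]
    return ScenarioSpec("pgi", pgi_parameters(protein_conc), assays,
                        noise or NoiseModel(), seed, session_vf_jitter)


def pfk_scenario(seed: int = 0, noise: NoiseModel | None = None,
                 n_points: int = 40, t_max: float = 60.0,
                 protein_conc: float = DEFAULT_PROTEIN,
                 session_vf_jitter: float = 0.0) -> ScenarioSpec:
    """Six-assay irreversible PFK design crossing F6P, ATP and PEP levels.

    The two inhibitor assays run at sub-saturating substrate (1 mM
    F6P and ATP): the hyperbolic modifier term competes with the scaled
    substrate terms in the rate-law denominator, so at saturating
    substrates PEP inhibition is invisible and the modifier parameters
    would be unidentifiable.  PEP itself decays first-order (side
    reactions), sweeping the modifier through its half-saturation
    range within a single time course.
    """
    designs = [(3.0, 2.5, 0.0), (10.0, 2.5, 0.0), (3.0, 5.0, 0.0),
               (10.0, 5.0, 0.0), (1.0, 1.0, 4.0), (1.0, 1.0, 8.0)]
    t = np.linspace(0.0, t_max, n_points)
    assays = [SyntheticAssay(f"pfk{i+1}",
                             {"F6P": f, "ATP": a, "PEP": p, "FBP": 0.0,
                              "ADP": 0.0}, t)
              for i, (f, a, p) in enumerate(designs)]
    return ScenarioSpec("pfk", pfk_parameters(protein_conc), assays,
                        noise or NoiseModel(), seed, session_vf_jitter,
                        pep_decay_rate=0.08)


def _pgi_rhs_factory(p: Mapping[str, float], vmm: float):
    def rhs(t, y):
        v = vmm * reversible_hill_uni_rate(max(y[0], 0.0), max(y[1], 0.0),
                                           validate=False, **p)
        return [-v, v]
    return rhs


def _pfk_rhs_factory(p: Mapping[str, float], vmm: float, k_pep: float):
    def rhs(t, y):
        v = vmm * irreversible_hill_bi_rate(max(y[0], 0.0), max(y[1], 0.0),
                                            max(y[4], 0.0), validate=False, **p)
        return [-v, -v, v, v, -k_pep * max(y[4], 0.0)]
    return rhs


def exact_timecourse(spec: ScenarioSpec, assay: SyntheticAssay,
                     vf_factor: float = 1.0) -> dict[str, np.ndarray]:
    """Noise-free ODE solution of one assay (species -> concentration)."""
    law_p = {}
    if spec.kind == "pgi":
        law_p = {"vf": spec.params.vf, "ks": spec.params.half_sat["G6P"],
                 "kp": spec.params.half_sat["F6P"],
                 "keq": spec.params.require_keq(), "h": spec.params.h}
        vmm = spec.params.vf_volumetric() / spec.params.vf * vf_factor
        y0 = [assay.initial.get("G6P", 0.0), assay.initial.get("F6P", 0.0)]
        sol = solve_ivp(_pgi_rhs_factory(law_p, vmm),
                        (assay.t_grid[0], assay.t_grid[-1]), y0,
                        t_eval=assay.t_grid, method="LSODA",
                        rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise RuntimeError(f"assay {assay.assay_id}: {sol.message}")
        return {"G6P": sol.y[0], "F6P": sol.y[1]}
    law_p = {"vf": spec.params.vf, "ks1": spec.params.half_sat["F6P"],
             "ks2": spec.params.half_sat["ATP"],
             "km": spec.params.half_sat["PEP"],
             "alpha": spec.params.alpha, "h": spec.params.h}
    vmm = spec.params.vf_volumetric() / spec.params.vf * vf_factor
    y0 = [assay.initial.get("F6P", 0.0), assay.initial.get("ATP", 0.0),
          assay.initial.get("FBP", 0.0), assay.initial.get("ADP", 0.0),
          assay.initial.get("PEP", 0.0)]
    sol = solve_ivp(_pfk_rhs_factory(law_p, vmm, spec.pep_decay_rate),
                    (assay.t_grid[0], assay.t_grid[-1]), y0,
                    t_eval=assay.t_grid, method="LSODA",
                    rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"assay {assay.assay_id}: {sol.message}")
    return {"F6P": sol.y[0], "ATP": sol.y[1], "FBP": sol.y[2],
            "ADP": sol.y[3], "PEP": sol.y[4]}


def simulate_noisy_timecourses(spec: ScenarioSpec
                               ) -> tuple[list[ProgressCurve], dict]:
    """Generate progress curves for a scenario; returns (curves, truth).

    The truth record holds the generating parameters, the per-session Vf
    factors and the exact (noise-free) trajectories, so recovery tests
    can compare against it directly.
    """
    rng = np.random.default_rng(spec.seed)
    sessions = sorted({a.session for a in spec.assays})
    if spec.session_vf_jitter > 0:
        factors = {s: float(np.exp(rng.normal(0.0, spec.session_vf_jitter)))
                   for s in sessions}
    else:
        factors = {s: 1.0 for s in sessions}
    curves: list[ProgressCurve] = []
    truth = {"params": spec.params, "kind": spec.kind,
             "session_vf_factors": factors, "exact": {}}
    for assay in spec.assays:
        exact = exact_timecourse(spec, assay, factors[assay.session])
        truth["exact"][assay.assay_id] = exact
        for sp, conc in exact.items():
            noisy = conc * (1.0 + rng.normal(
                0.0, spec.noise.conc_multiplicative_sd, conc.shape))
            if spec.noise.conc_additive_sd > 0:
                noisy = noisy + rng.normal(0.0, spec.noise.conc_additive_sd,
                                           conc.shape)
            noisy = np.maximum(noisy, 0.0)
            curves.append(ProgressCurve(assay.assay_id, sp,
                                        assay.t_grid.copy(), noisy))
    return curves, truth


# ---------------------------------------------------------------------------
# FID synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Resonance:
    """One ³¹P line of a species: shift, relative ³¹P weight, T1."""

    ppm: float
    weight: float = 1.0
    t1: float = 0.5


# ³¹P assignments used by the generator (TEP anchors the scale at 0 ppm;
# the FBP β-anomer pair brackets F6P).  T1 values span the measured range
# 0.2 s (nucleoside phosphates) to 6 s (TEP).
DEFAULT_PEAK_MAP: dict[str, tuple[Resonance, ...]] = {
    "TEP": (Resonance(0.0, 1.0, 6.0),),
    "G6P": (Resonance(3.3, 1.0, 1.0),),
    "F6P": (Resonance(2.45, 1.0, 1.0),),
    "FBP": (Resonance(2.6, 1.0, 1.0), Resonance(2.3, 1.0, 1.0)),
    "Pi": (Resonance(1.5, 1.0, 1.0),),
    "PEP": (Resonance(-1.3, 1.0, 1.0),),
    "ATP": (Resonance(-7.4, 1.0, 0.2), Resonance(-10.5, 1.0, 0.2),
            Resonance(-21.3, 1.0, 0.2)),
    "ADP": (Resonance(-6.8, 1.0, 0.2), Resonance(-9.8, 1.0, 0.2)),
}


@dataclass
class AcquisitionParams:
    """Synthetic spectrometer settings (³¹P on a 600 MHz instrument)."""

    spectral_width: float = 10000.0   # Hz
    n_points: int = 8192
    spectrometer_freq: float = 242.87  # MHz
    acquisition_time: float = 0.8192
    relaxation_delay: float = 0.5
    pulse_angle: float = 90.0
    transients: int = 100
    carrier_ppm: float = -9.0


def default_windows(species: Sequence[str], half_width: float = 0.2,
                    peak_map: Mapping[str, tuple[Resonance, ...]] | None = None,
                    ) -> list[PeakWindow]:
    """One integration window per resonance, ±half_width ppm.

    Narrow windows keep the slowly decaying Lorentzian tails of
    neighbouring lines out; the symmetric truncation of a peak's own
    tails cancels in the ratio to the internal standard, whose window
    has the same width.
    """
    peak_map = peak_map or DEFAULT_PEAK_MAP
    windows = []
    for sp in species:
        for res in peak_map[sp]:
            windows.append(PeakWindow(sp, res.ppm - half_width,
                                      res.ppm + half_width))
    return windows


def default_calibration(species: Sequence[str], acq: AcquisitionParams,
                        peak_map: Mapping[str, tuple[Resonance, ...]] | None = None,
                        ) -> RelaxationCalibration:
    """Saturation correction factors matching the generator's T1 values."""
    peak_map = peak_map or DEFAULT_PEAK_MAP
    tr = acq.acquisition_time + acq.relaxation_delay
    t1 = {sp: peak_map[sp][0].t1 for sp in species}
    return RelaxationCalibration.from_t1(t1, tr, acq.pulse_angle)


def synthesize_fid_series(trajectories: Mapping[str, np.ndarray],
                          times_min: np.ndarray,
                          acq: AcquisitionParams | None = None,
                          noise: NoiseModel | None = None,
                          seed: int = 0,
                          peak_map: Mapping[str, tuple[Resonance, ...]] | None = None,
                          standard: tuple[str, float] = ("TEP", 10.0),
                          ) -> FIDSeries:
    """Inverse of the quantification chain: concentrations to raw FIDs.

    Each species contributes one decaying complex exponential per
    resonance, amplitude proportional to concentration × ³¹P weight ×
    steady-state saturation fraction for its T1; the internal standard
    is constant across blocks.  Complex Gaussian noise of
    ``noise.fid_noise_sd`` per point is added (seeded).
    """
    acq = acq or AcquisitionParams()
    noise = noise or NOISELESS
    peak_map = dict(peak_map or DEFAULT_PEAK_MAP)
    times_min = np.asarray(times_min, dtype=float)
    rng = np.random.default_rng(seed)
    std_species, std_conc = standard

    dwell = 1.0 / acq.spectral_width
    t = np.arange(acq.n_points) * dwell
    tr = acq.acquisition_time + acq.relaxation_delay
    t2 = 1.0 / (math.pi * noise.linewidth_hz) if noise.linewidth_hz > 0 else np.inf
    decay = np.exp(-t / t2)

    def add_species(block, conc, resonances):
        for res in resonances:
            frac = saturation_fraction(res.t1, tr, acq.pulse_angle)
            f_hz = (res.ppm - acq.carrier_ppm) * acq.spectrometer_freq
            amp = conc * res.weight * frac
            block += amp * np.exp(2j * math.pi * f_hz * t) * decay
        return block

    blocks = []
    for i in range(times_min.size):
        block = np.zeros(acq.n_points, dtype=complex)
        block = add_species(block, std_conc, peak_map[std_species])
        for sp, conc in trajectories.items():
            block = add_species(block, float(conc[i]), peak_map[sp])
        if noise.fid_noise_sd > 0:
            block = block + (rng.normal(0, noise.fid_noise_sd, acq.n_points)
                             + 1j * rng.normal(0, noise.fid_noise_sd,
                                               acq.n_points))
        blocks.append(block)
    return FIDSeries(np.asarray(blocks), acq.spectral_width,
                     acq.spectrometer_freq, acq.acquisition_time,
                     acq.relaxation_delay, acq.pulse_angle, acq.transients,
                     times_min, acq.carrier_ppm)
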