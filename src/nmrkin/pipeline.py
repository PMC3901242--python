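"""End-to-end workflows: curves -> splines -> rate samples -> global fit.

These helpers wire the library modules together in the standard order
used throughout the tests and the reproduction script: spline-fit every
progress curve of every assay independently, differentiate at the
measured time points, average the stoichiometry-signed derivatives into
reaction-rate samples, and globally fit a rate law with the GA +
Levenberg–Marquardt pipeline.

The two recovery studies regenerate the canonical synthetic scenarios
(see :mod:`nmrkin.synthetic`) and fit them from scratch; with the noise
switched off the fitted parameters land on the generating ones, which
is the toolkit's primary self-check.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .fitting import FreeParameter, GAConfig, GlobalRateFit
from .progress import (AssayRun, ProgressCurve, RateSample,
                       fit_smoothing_spline, rates_from_splines)
from .ratelaws import IrreversibleHillBi, RateLaw, ReversibleHillUni
from .synthetic import (NOISELESS, NoiseModel, ScenarioSpec,
                        pfk_scenario, pgi_scenario,
                        simulate_noisy_timecourses)

__all__ = [
    "spline_rate_dataset",
    "default_free_parameters",
    "build_problem",
    "pgi_recovery_study",
    "pfk_recovery_study",
]

# species whose derivatives are unreliable for the reaction-rate average
# (consumed/maintained by side reactions in extract assays)
DEFAULT_EXCLUDE = {"reversible_hill_uni": (),
                   "irreversible_hill_bi": ("ADP", "ATP")}


def spline_rate_dataset(curves: Sequence[ProgressCurve], law: RateLaw,
                        assay_meta: Mapping[str, AssayRun] | None = None,
                        smoothing="auto",
                        exclude: Sequence[str] | None = None,
                        trim: int = 2) -> list[RateSample]:
    """Spline-differentiate assay curves into pooled rate samples.

    ``trim`` drops that many measured points from each end of the rate
    grid: spline derivatives at the boundary carry the largest error,
    and near the start the reaction corner is steepest.
    """
    if exclude is None:
        exclude = DEFAULT_EXCLUDE.get(law.name, ())
    by_assay: dict[str, dict[str, ProgressCurve]] = {}
    for c in curves:
        by_assay.setdefault(c.assay_id, {})[c.species] = c
    samples: list[RateSample] = []
    for assay_id, sp_curves in by_assay.items():
        assay = (assay_meta or {}).get(assay_id, AssayRun(assay_id))
        splines = {sp: fit_smoothing_spline(c, smoothing)
                   for sp, c in sp_curves.items()}
        times = next(iter(sp_curves.values())).time
        if trim > 0:
            times = times[trim:-trim]
        samples.extend(rates_from_splines(assay, splines, law.scheme,
                                          times, exclude=exclude))
    return samples


def default_free_parameters(law: RateLaw,
                            samples: Sequence[RateSample],
                            fixed: Mapping[str, float] = (),
                            ) -> list[FreeParameter]:
    """Data-driven initial guesses and generic bounds for a fit.

    Vf starts at twice the largest observed |rate| (bounded a decade
    either way beyond that); half-saturation constants start at 1 mM in
    [1e-3, 100] mM; keq at the final-sample mass-action ratio scale;
    alpha and h in wide dimensionless boxes.
    """
    vmax_obs = max(abs(s.rate) for s in samples)
    if vmax_obs <= 0:
        raise ValueError("all observed rates are zero")
    fixed = dict(fixed) if fixed else {}
    out = []
    for name in law.param_names:
        if name in fixed:
            continue
        if name == "vf":
            out.append(FreeParameter("vf", 2 * vmax_obs, vmax_obs / 10,
                                     vmax_obs * 100))
        elif name in ("ks", "kp", "ks1", "ks2", "km"):
            out.append(FreeParameter(name, 1.0, 1e-3, 100.0))
        elif name == "keq":
            out.append(FreeParameter("keq", 1.0, 1e-3, 1e3))
        elif name == "alpha":
            out.append(FreeParameter("alpha", 1.0, 1e-3, 1e3))
        elif name == "h":
            out.append(FreeParameter("h", 1.0, 0.2, 8.0))
        else:
            out.append(FreeParameter(name, 1.0))
    return out


def build_problem(curves: Sequence[ProgressCurve], law: RateLaw,
                  fixed: Mapping[str, float] | None = None,
                  smoothing="auto", weights="unit") -> GlobalRateFit:
    samples = spline_rate_dataset(curves, law, smoothing=smoothing)
    free = default_free_parameters(law, samples, fixed or {})
    return GlobalRateFit(samples, law, free, fixed or {}, weights)


def exact_rate_samples(spec: ScenarioSpec, law: RateLaw,
                       rate_noise_sd: float = 0.0,
                       seed: int = 0, trim: int = 2) -> list[RateSample]:
    """Rate samples from exact trajectories and exact rate-law evaluation.

    Bypasses the spline differentiation: concentrations come from the
    noise-free ODE solution at the measured times and the rate is the
    generating law evaluated there, optionally with multiplicative
    Gaussian noise.  This isolates the fitter from the rate-extraction
    stage, e.g. for error-bar calibration studies.
    """
    from .synthetic import exact_timecourse

    rng = np.random.default_rng(seed)
    if spec.kind == "pgi":
        p = {"vf": spec.params.vf_volumetric(),
             "ks": spec.params.half_sat["G6P"],
             "kp": spec.params.half_sat["F6P"],
             "keq": spec.params.require_keq(), "h": spec.params.h}
    else:
        p = {"vf": spec.params.vf_volumetric(),
             "ks1": spec.params.half_sat["F6P"],
             "ks2": spec.params.half_sat["ATP"],
             "km": spec.params.half_sat["PEP"],
             "alpha": spec.params.alpha, "h": spec.params.h}
    samples = []
    for assay in spec.assays:
        exact = exact_timecourse(spec, assay)
        sl = slice(trim, -trim) if trim else slice(None)
        times = assay.t_grid[sl]
        conc = {sp: traj[sl] for sp, traj in exact.items()}
        v = np.asarray(law.rate(conc, p), dtype=float)
        if rate_noise_sd > 0:
            v = v * (1.0 + rng.normal(0.0, rate_noise_sd, v.shape))
        for i, t in enumerate(times):
            samples.append(RateSample(
                time=float(t), conc={sp: float(c[i]) for sp, c in conc.items()},
                rate=float(v[i]), source_species="exact",
                assay_id=assay.assay_id))
    return samples


def _run_study(spec: ScenarioSpec, law: RateLaw, fixed, seed, ga) -> dict:
    curves, truth = simulate_noisy_timecourses(spec)
    smoothing = 0.0 if spec.noise.noiseless else "auto"
    problem = build_problem(curves, law, fixed, smoothing=smoothing)
    results = problem.fit(seed=seed, ga=ga or GAConfig())
    protein = spec.params.protein_conc or 1.0
    recovered = dict(results.params)
    specific = dict(recovered)
    if "vf" in specific:
        specific["vf"] = specific["vf"] / protein
    bse_specific = dict(results.bse)
    if "vf" in bse_specific:
        bse_specific["vf"] = bse_specific["vf"] / protein
    return {"spec": spec, "curves": curves, "truth": truth,
            "problem": problem, "results": results,
            "params_specific": specific, "bse_specific": bse_specific}


def pgi_recovery_study(seed: int = 42, noise: NoiseModel = NOISELESS,
                       ga: GAConfig | None = None, n_points: int = 40,
                       session_vf_jitter: float = 0.0) -> dict:
    """Simulate the 5-assay PGI design and refit the reversible MM law.

    Returns a dict with the scenario, generated curves, the fit problem
    and results, and the parameters converted back to specific activity
    (``params_specific``) for direct comparison with the ground truth.
    """
    spec = pgi_scenario(seed=seed, noise=noise, n_points=n_points,
                        session_vf_jitter=session_vf_jitter)
    law = ReversibleHillUni("G6P", "F6P")
    return _run_study(spec, law, {"h": 1.0}, seed, ga)


def pfk_recovery_study(seed: int = 42, noise: NoiseModel = NOISELESS,
                       ga: GAConfig | None = None, n_points: int = 40,
                       session_vf_jitter: float = 0.0) -> dict:
    """Simulate the 6-assay PFK design and refit the bi-substrate Hill law."""
    spec = pfk_scenario(seed=seed, noise=noise, n_points=n_points,
                        session_vf_jitter=session_vf_jitter)
    law = IrreversibleHillBi("F6P", "ATP", "PEP")
    return _run_study(spec, law, None, seed, ga)
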