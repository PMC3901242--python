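"""Global rate-law fitting: genetic-algorithm seeding + Levenberg–Marquardt.

The model object, :class:`GlobalRateFit`, pools rate samples from all
assays of a study — each sample an instantaneous reaction rate paired
with the full concentration vector at that moment — and fits a rate law
to them by weighted least squares.  The parameter landscape of Hill-type
laws is multimodal, so optimization is staged: a seeded genetic
algorithm searches the (log-scaled) bounded parameter box globally and
its best individual is refined with Levenberg–Marquardt.  Parameters
are optimized in log space, which enforces positivity without
constraint machinery.

:class:`GlobalFitResults` carries the estimates with their standard
errors from the residual-variance-scaled covariance matrix
cov = (JᵀJ)⁻¹ · RSS/(n−p), the Jacobian J taken with respect to the
natural (not log) parameters at the solution, plus R², a text summary
and JSON export.

:func:`truncation_scan` refits after progressively deleting the
latest (closest-to-equilibrium) samples of every assay, reporting the
standard errors under both degrees-of-freedom conventions — rescaled
to the truncated sample count, and held at the original count — to
separate the error growth due to losing data in general from that due
to losing near-equilibrium data specifically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .progress import RateSample, frame_to_samples
from .ratelaws import RateLaw, make_rate_law

__all__ = [
    "GAConfig",
    "FreeParameter",
    "GlobalRateFit",
    "GlobalFitResults",
    "TruncationStep",
    "TruncationScanResult",
    "truncation_scan",
    "goodness_of_fit",
    "load_problem_yaml",
]

log = logging.getLogger(__name__)

_PENALTY = 1e6


@dataclass
class GAConfig:
    """Knobs of the genetic global search (all overridable via config)."""

    population: int = 64
    generations: int = 200
    tournament: int = 3
    crossover_rate: float = 0.7
    mutation_sd: float = 0.15   # in log10-parameter units
    elitism: int = 2


@dataclass
class FreeParameter:
    """A parameter to be fitted, with positivity-enforcing bounds."""

    name: str
    init: float
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self):
        if self.init <= 0:
            raise ValueError(f"{self.name}: initial guess must be positive")
        if self.lo is None:
            self.lo = 1e-3 * self.init
        if self.hi is None:
            self.hi = 1e3 * self.init
        if not (0 < self.lo <= self.init <= self.hi):
            raise ValueError(f"{self.name}: need 0 < lo <= init <= hi")


def goodness_of_fit(rss: float, observed: np.ndarray) -> float:
    """Coefficient of determination R² = 1 − RSS/TSS over pooled rates."""
    observed = np.asarray(observed, dtype=float)
    tss = float(np.sum((observed - observed.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("R² undefined: observed rates have zero variance")
    return 1.0 - rss / tss


class GlobalRateFit:
    """Weighted least-squares fit of a rate law to pooled rate samples.

    Parameters
    ----------
    samples : sequence of RateSample
        Pooled dataset across assays; every sample must carry all
        species the rate law needs.
    rate_law : RateLaw
        The law to fit (from the registry or user-supplied).
    free : mapping or sequence
        Free parameters: name -> initial guess (bounds default to
        1e-3..1e3 times the guess) or :class:`FreeParameter` objects.
    fixed : mapping
        Parameters held constant (e.g. ``h=1`` for a non-cooperative
        enzyme, or a known ``keq``).
    """

    def __init__(self, samples: Sequence[RateSample], rate_law: RateLaw,
                 free: Mapping[str, float] | Sequence[FreeParameter],
                 fixed: Mapping[str, float] | None = None,
                 weights: str | np.ndarray = "unit"):
        if not samples:
            raise ValueError("dataset of rate samples is empty")
        self.rate_law = rate_law
        self.samples = list(samples)
        if isinstance(free, Mapping):
            self.free = [FreeParameter(k, float(v)) for k, v in free.items()]
        else:
            self.free = list(free)
        self.fixed = dict(fixed or {})
        names = {p.name for p in self.free} | set(self.fixed)
        missing = [n for n in rate_law.param_names if n not in names]
        if missing:
            raise ValueError(f"parameters neither free nor fixed: {missing}")

        needed = rate_law.species_needed
        for s in self.samples:
            lack = [sp for sp in needed if sp not in s.conc]
            if lack:
                raise ValueError(
                    f"sample at t={s.time} (assay {s.assay_id!r}) lacks "
                    f"species {lack} required by {rate_law!r}")
        self._conc = {sp: np.array([s.conc[sp] for s in self.samples])
                      for sp in needed}
        self.v_obs = np.array([s.rate for s in self.samples])
        if isinstance(weights, str):
            if weights == "unit":
                w = np.array([s.weight for s in self.samples])
            elif weights == "inv_v2":
                base = np.maximum(np.abs(self.v_obs), 1e-12 * max(
                    1.0, float(np.max(np.abs(self.v_obs)))))
                w = np.array([s.weight for s in self.samples]) / base ** 2
            else:
                raise ValueError(f"unknown weighting {weights!r}")
        else:
            w = np.asarray(weights, dtype=float)
        self.sqrt_w = np.sqrt(w)
        self.assay_ids = np.array([s.assay_id for s in self.samples])
        self.times = np.array([s.time for s in self.samples])

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, rate_law: RateLaw,
                       free, fixed=None, weights="unit") -> "GlobalRateFit":
        """Build from a tidy rate table (one row per sample)."""
        return cls(frame_to_samples(df), rate_law, free, fixed, weights)

    # -- objective ---------------------------------------------------------
    @property
    def nobs(self) -> int:
        return len(self.samples)

    @property
    def nfree(self) -> int:
        return len(self.free)

    def _params_dict(self, x: np.ndarray) -> dict[str, float]:
        d = dict(self.fixed)
        d.update({p.name: float(v) for p, v in zip(self.free, x)})
        return d

    def model_rates(self, params: Mapping[str, float]) -> np.ndarray:
        return np.asarray(self.rate_law.rate(self._conc, params), dtype=float)

    def residuals(self, params: Mapping[str, float] | np.ndarray) -> np.ndarray:
        """Weighted residual vector, model − observed; non-finite model
        values are replaced by a large penalty (and logged)."""
        if not isinstance(params, Mapping):
            params = self._params_dict(np.asarray(params, dtype=float))
        with np.errstate(all="ignore"):
            r = (self.model_rates(params) - self.v_obs) * self.sqrt_w
        bad = ~np.isfinite(r)
        if np.any(bad):
            log.debug("%d non-finite residuals replaced by penalty", bad.sum())
            r = np.where(bad, _PENALTY, r)
        return r

    def rss(self, params) -> float:
        return float(np.sum(self.residuals(params) ** 2))

    def _batch_rss(self, X: np.ndarray) -> np.ndarray:
        """RSS for a whole population (rows of X are parameter vectors)."""
        params = dict(self.fixed)
        for j, p in enumerate(self.free):
            params[p.name] = X[:, j][:, None]
        conc = {sp: c[None, :] for sp, c in self._conc.items()}
        with np.errstate(all="ignore"):
            v = self.rate_law.rate(conc, params)
            r = (v - self.v_obs[None, :]) * self.sqrt_w[None, :]
        r = np.where(np.isfinite(r), r, _PENALTY)
        return np.sum(r * r, axis=1)

    # -- optimizers --------------------------------------------------------
    def _ga_search(self, seed: int, ga: GAConfig
                   ) -> tuple[np.ndarray, float, np.ndarray]:
        rng = np.random.default_rng(seed)
        k = self.nfree
        lo = np.log10([p.lo for p in self.free])
        hi = np.log10([p.hi for p in self.free])
        X = rng.uniform(lo, hi, size=(ga.population, k))
        X[0] = np.log10([p.init for p in self.free])  # seed the guess
        fit = self._batch_rss(10.0 ** X)
        for _ in range(ga.generations):
            elite_idx = np.argsort(fit, kind="stable")[:ga.elitism]
            # tournament selection (lowest index wins ties via argmin)
            draws = rng.integers(0, ga.population,
                                 size=(ga.population - ga.elitism, ga.tournament))
            winners = draws[np.arange(draws.shape[0]),
                            np.argmin(fit[draws], axis=1)]
            parents = X[winners]
            partners = X[winners[rng.permutation(winners.size)]]
            # arithmetic crossover, then Gaussian mutation in log space
            mix = rng.uniform(0.0, 1.0, size=(parents.shape[0], 1))
            cross = rng.uniform(size=parents.shape[0]) < ga.crossover_rate
            children = np.where(cross[:, None],
                                mix * parents + (1 - mix) * partners, parents)
            children = children + rng.normal(0.0, ga.mutation_sd,
                                             size=children.shape)
            children = np.clip(children, lo, hi)
            X = np.vstack([X[elite_idx], children])
            fit = self._batch_rss(10.0 ** X)
        order = np.argsort(fit, kind="stable")
        best = int(order[0])
        return 10.0 ** X[best], float(fit[best]), 10.0 ** X[order]

    def _lm_refine(self, x0: np.ndarray):
        z0 = np.log(x0)
        with np.errstate(over="ignore"):
            sol = least_squares(lambda z: self.residuals(np.exp(z)), z0,
                                method="lm", xtol=1e-14, ftol=1e-14,
                                gtol=1e-14)
            x = np.exp(sol.x)
        return x, sol

    def fit(self, seed: int = 0, ga: GAConfig | None = None,
            refine: bool = True, n_refine: int = 3) -> "GlobalFitResults":
        """Run the GA + Levenberg–Marquardt pipeline (deterministic per seed).

        The ``n_refine`` best mutually distinct individuals of the final
        GA population are each polished with Levenberg–Marquardt and the
        lowest final RSS wins (first on ties): a single LM start can be
        captured by a flat valley of a multimodal Hill landscape.
        """
        ga = ga or GAConfig()
        x_ga, rss_ga, pop = self._ga_search(seed, ga)
        x, rss_best, converged = x_ga, rss_ga, False
        if refine:
            starts = [x_ga]
            for cand in pop[1:]:
                if len(starts) >= max(n_refine, 1):
                    break
                if all(np.max(np.abs(np.log10(cand) - np.log10(s))) > 0.3
                       for s in starts):
                    starts.append(cand)
            for x0 in starts:
                x_lm, sol = self._lm_refine(x0)
                rss_lm = float(np.sum(sol.fun ** 2))
                if rss_lm < rss_best:
                    x, rss_best, converged = x_lm, rss_lm, bool(sol.success)
            if rss_best >= rss_ga and not converged:
                log.warning("LM refinement did not improve on the GA best "
                            "(RSS %.3g)", rss_ga)
        return self._results(x, converged, rss_ga, seed)

    def _jacobian_natural(self, x: np.ndarray) -> np.ndarray:
        """Finite-difference Jacobian of residuals wrt natural parameters."""
        r0 = self.residuals(x)
        J = np.empty((r0.size, x.size))
        for j in range(x.size):
            step = 1e-6 * max(abs(x[j]), 1e-12)
            xp = x.copy()
            xp[j] += step
            J[:, j] = (self.residuals(xp) - r0) / step
        return J

    def _results(self, x: np.ndarray, converged: bool, rss_ga: float,
                 seed: int) -> "GlobalFitResults":
        rss = self.rss(x)
        n, p = self.nobs, self.nfree
        if n <= p:
            raise ValueError("need more samples than free parameters")
        J = self._jacobian_natural(x)
        cov, sem = _covariance(J, rss, n - p)
        names = [fp.name for fp in self.free]
        try:
            r2 = goodness_of_fit(rss, self.v_obs)
        except ValueError:
            r2 = float("nan")
        return GlobalFitResults(
            model=self, params=dict(zip(names, map(float, x))),
            bse=dict(zip(names, map(float, sem))), cov=cov, rss=rss,
            nobs=n, nfree=p, rsquared=r2, converged=converged,
            ga_rss=rss_ga, seed=seed)


def _covariance(J: np.ndarray, rss: float, dof: int):
    """(JᵀJ)⁻¹·s² via SVD; unidentifiable directions get infinite SEM."""
    s2 = rss / dof
    U, sv, Vt = np.linalg.svd(J, full_matrices=False)
    tol = max(J.shape) * np.finfo(float).eps * (sv[0] if sv.size else 0.0)
    rank_ok = sv > tol
    inv_sv2 = np.where(rank_ok, 1.0 / np.where(rank_ok, sv, 1.0) ** 2, np.inf)
    if np.all(rank_ok):
        cov = (Vt.T * inv_sv2) @ Vt * s2
        sem = np.sqrt(np.diag(cov))
    else:
        log.warning("Jacobian rank-deficient (%d/%d); flagged infinite SEM",
                    int(rank_ok.sum()), sv.size)
        cov = np.full((J.shape[1],) * 2, np.inf)
        coef = Vt.T ** 2                      # (p, k) loadings on directions
        touches_null = np.any((coef > 1e-24) & ~rank_ok[None, :], axis=1)
        finite_part = np.sum(np.where(rank_ok[None, :], coef * inv_sv2, 0.0),
                             axis=1) * s2
        sem = np.where(touches_null, np.inf, np.sqrt(finite_part))
    return cov, sem


@dataclass
class GlobalFitResults:
    """Point estimates, uncertainties and diagnostics of a global fit."""

    model: GlobalRateFit
    params: dict[str, float]
    bse: dict[str, float]
    cov: np.ndarray
    rss: float
    nobs: int
    nfree: int
    rsquared: float
    converged: bool
    ga_rss: float
    seed: int

    @property
    def df_resid(self) -> int:
        return self.nobs - self.nfree

    def all_params(self) -> dict[str, float]:
        d = dict(self.model.fixed)
        d.update(self.params)
        return d

    def predict(self, concs: Mapping[str, np.ndarray] | None = None):
        """Model rates at the fitted parameters (fit concentrations by
        default)."""
        if concs is None:
            return self.model.model_rates(self.all_params())
        return self.model.rate_law.rate(concs, self.all_params())

    def summary(self) -> str:
        lines = [
            f"Global rate-law fit: {self.model.rate_law!r}",
            f"  n samples {self.nobs}, free parameters {self.nfree}, "
            f"dof {self.df_resid}",
            f"  RSS {self.rss:.6g}   R^2 {self.rsquared:.4f}   "
            f"converged {self.converged}  (seed {self.seed})",
            f"  {'parameter':<10} {'estimate':>12} {'SEM':>12}",
        ]
        for name in self.params:
            lines.append(f"  {name:<10} {self.params[name]:>12.6g} "
                         f"{self.bse[name]:>12.3g}")
        for name, v in self.model.fixed.items():
            lines.append(f"  {name:<10} {v:>12.6g} {'(fixed)':>12}")
        return "\n".join(lines)

    def to_json(self, path=None):
        payload = {
            "rate_law": self.model.rate_law.name,
            "params": self.params, "bse": self.bse,
            "fixed": self.model.fixed,
            "cov": np.asarray(self.cov).tolist(),
            "rss": self.rss, "rsquared": self.rsquared,
            "nobs": self.nobs, "nfree": self.nfree,
            "converged": self.converged, "seed": self.seed,
        }
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def plot_fit(self, ax=None):
        """Observed vs fitted rates (lazy matplotlib import)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        v_hat = self.predict()
        ax.scatter(self.model.v_obs, v_hat, s=12)
        lim = [min(self.model.v_obs.min(), v_hat.min()),
               max(self.model.v_obs.max(), v_hat.max())]
        ax.plot(lim, lim, "k--", lw=0.8)
        ax.set_xlabel("observed rate")
        ax.set_ylabel("fitted rate")
        ax.set_title(f"R$^2$ = {self.rsquared:.3f}")
        return ax


# ---------------------------------------------------------------------------
# truncation scan
# ---------------------------------------------------------------------------

@dataclass
class TruncationStep:
    removed_per_assay: int
    removed_total: int
    result: GlobalFitResults
    bse_rescaled_dof: dict[str, float]
    bse_original_dof: dict[str, float]


@dataclass
class TruncationScanResult:
    steps: list[TruncationStep]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for st in self.steps:
            row = {"removed_per_assay": st.removed_per_assay,
                   "removed_total": st.removed_total,
                   "rss": st.result.rss}
            for name, v in st.result.params.items():
                row[name] = v
                row[f"sem_rescaled_{name}"] = st.bse_rescaled_dof[name]
                row[f"sem_original_{name}"] = st.bse_original_dof[name]
            rows.append(row)
        return pd.DataFrame(rows)


def truncation_scan(problem: GlobalRateFit, max_remove: int,
                    seed: int = 0, ga: GAConfig | None = None,
                    ) -> TruncationScanResult:
    """Refit after deleting the k latest samples of every assay, k = 0..max.

    Later times sit closer to equilibrium, so the scan probes how much
    of the parameter information lives in the near-equilibrium data.
    Standard errors are reported under both conventions: residual
    variance scaled by the truncated dof (n_k − p), and by the original
    dof (n_0 − p).  The scan stops early, with a warning, if the dof
    would drop to zero.
    """
    ids = np.unique(problem.assay_ids)
    shortest = min(np.sum(problem.assay_ids == a) for a in ids)
    if max_remove >= shortest:
        raise ValueError(f"max_remove {max_remove} >= shortest assay length "
                         f"{shortest}")
    n0, p = problem.nobs, problem.nfree
    steps = []
    for k in range(max_remove + 1):
        keep = np.ones(problem.nobs, dtype=bool)
        for a in ids:
            idx = np.nonzero(problem.assay_ids == a)[0]
            order = idx[np.argsort(problem.times[idx], kind="stable")]
            if k > 0:
                keep[order[-k:]] = False
        samples = [s for s, kp in zip(problem.samples, keep) if kp]
        if len(samples) <= p:
            log.warning("truncation stopped at k=%d: dof would be <= 0", k)
            break
        sub = GlobalRateFit(samples, problem.rate_law, self_free(problem),
                            problem.fixed)
        res = sub.fit(seed=seed, ga=ga)
        # both dof conventions for the SEM
        n_k = sub.nobs
        sem_resc = dict(res.bse)
        scale = np.sqrt((n_k - p) / (n0 - p))
        sem_orig = {name: v * scale for name, v in res.bse.items()}
        steps.append(TruncationStep(k, n0 - n_k, res, sem_resc, sem_orig))
    return TruncationScanResult(steps)


def self_free(problem: GlobalRateFit) -> list[FreeParameter]:
    return [replace(fp) for fp in problem.free]


# ---------------------------------------------------------------------------
# YAML problem configuration
# ---------------------------------------------------------------------------

def load_problem_yaml(path, data: pd.DataFrame | None = None) -> GlobalRateFit:
    """Build a :class:`GlobalRateFit` from a YAML problem file.

    Expected layout::

        law: {law: reversible_hill_uni, substrate: G6P, product: F6P}
        data: rates.csv            # optional if a frame is passed in
        weights: unit              # or inv_v2
        free:
          vf: {init: 1.0, lo: 0.01, hi: 100}
          ks: {init: 0.5}
        fixed:
          h: 1.0
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    law = make_rate_law(cfg["law"])
    if data is None:
        data = pd.read_csv(cfg["data"])
    free = []
    for name, spec in cfg.get("free", {}).items():
        if isinstance(spec, Mapping):
            free.append(FreeParameter(name, float(spec["init"]),
                                      spec.get("lo"), spec.get("hi")))
        else:
            free.append(FreeParameter(name, float(spec)))
    return GlobalRateFit.from_dataframe(data, law, free,
                                        cfg.get("fixed") or {},
                                        cfg.get("weights", "unit"))
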