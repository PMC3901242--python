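"""Progress-curve handling: splines, rates, equilibrium bookkeeping.

A progress curve is one species' concentration versus time in one
assay.  Curves are fitted *independently* with cubic smoothing splines
— mass conservation is never imposed, but the conservation defect is
available as a diagnostic — and reaction rates are obtained by
differentiating the splines at the measured time points.  Where the
reaction is observed through several species (substrate consumed,
product formed), the stoichiometry-signed derivatives are averaged.

Two further operations encode how coupled-enzyme assays are made
fittable: species hidden under overlapping resonances can be inferred
from a fast equilibrium (F6P = Keq·G6P through PGI), and data acquired
before that equilibrium is established are excluded from fitting while
being retained for model validation.

Rates from different NMR sessions or extracts are made comparable by
normalizing each session to its own maximal-rate reference assay and
rescaling once, at the end, by an externally determined Vmax.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline

from .ratelaws import ReactionScheme

__all__ = [
    "ProgressCurve",
    "AssayRun",
    "RateSample",
    "SplineModel",
    "SplineFitError",
    "EquilibrationError",
    "estimate_noise_sd",
    "fit_smoothing_spline",
    "rates_from_splines",
    "infer_equilibrium_species",
    "exclude_pre_equilibration",
    "PreEquilibrationSplit",
    "reference_maximal_rate",
    "normalize_to_reference",
    "conservation_defect",
    "read_tidy_csv",
    "write_tidy_csv",
    "samples_to_frame",
    "frame_to_samples",
]

log = logging.getLogger(__name__)


class SplineFitError(ValueError):
    """A curve cannot be spline-fitted (too few valid points)."""


class EquilibrationError(ValueError):
    """The pre-equilibration criterion is never met for an assay."""


@dataclass
class ProgressCurve:
    """Concentration (mM) of one species over time (min) in one assay."""

    assay_id: str
    species: str
    time: np.ndarray
    conc: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.time.shape != self.conc.shape or self.time.ndim != 1:
            raise ValueError("time and conc must be equal-length 1-D arrays")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError(f"{self.assay_id}/{self.species}: time must be "
                             "strictly increasing")
        if np.any(self.conc < 0):
            raise ValueError(f"{self.assay_id}/{self.species}: negative "
                             "concentrations must be clipped upstream")
        if self.valid is None:
            self.valid = np.ones_like(self.time, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def truncate(self, mask: np.ndarray) -> "ProgressCurve":
        return ProgressCurve(self.assay_id, self.species, self.time[mask],
                             self.conc[mask], self.valid[mask])


@dataclass
class AssayRun:
    """Metadata of one assay: initial mix, normalization and corrections."""

    assay_id: str
    initial_conc: dict[str, float] = field(default_factory=dict)
    reference_id: str | None = None
    protein_conc: float | None = None
    correction_factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for sp, f in self.correction_factors.items():
            if f <= 0:
                raise ValueError(f"correction factor for {sp} must be > 0")

    def effective_conc(self, species: str, conc):
        """Apply the effective-concentration correction (default 1).

        E.g. with Mg²⁺ sub-stoichiometric to ATP only a fraction of the
        added ATP is the true substrate MgATP; a factor of 0.2 encodes a
        five-fold lower effective ATP.
        """
        return np.asarray(conc, float) * self.correction_factors.get(species, 1.0)


@dataclass
class RateSample:
    """One instantaneous rate with the full concentration vector."""

    time: float
    conc: dict[str, float]
    rate: float
    source_species: str
    weight: float = 1.0
    assay_id: str = ""


def estimate_noise_sd(y: np.ndarray) -> float:
    """Noise standard deviation from second differences.

    For smooth signals the second difference is dominated by noise with
    variance 6σ²; robust against the underlying trend.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        return 0.0
    d2 = np.diff(y, n=2)
    return float(np.sqrt(np.mean(d2 ** 2) / 6.0))


@dataclass
class SplineModel:
    """A fitted cubic smoothing spline, evaluable and differentiable."""

    spline: UnivariateSpline
    t_min: float
    t_max: float
    smoothing: float
    residual_ss: float

    def __call__(self, t):
        return self.spline(t)

    def derivative(self, t):
        return self.spline.derivative()(t)

    def covers(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (t >= self.t_min) & (t <= self.t_max)


def fit_smoothing_spline(curve: ProgressCurve,
                         smoothing: float | str | None = "auto") -> SplineModel:
    """Fit a cubic smoothing spline to one progress curve.

    ``smoothing`` is scipy's residual budget ``s`` (sum of squared
    residuals allowed).  The default ``"auto"`` sets it to n·σ̂² with σ̂
    estimated from second differences, so the spline smooths at the
    noise level; 0 interpolates.
    """
    t = curve.time[curve.valid]
    c = curve.conc[curve.valid]
    if t.size < 4:
        raise SplineFitError(
            f"curve {curve.assay_id}/{curve.species}: {t.size} valid points, "
            "need at least 4 for a cubic spline")
    if smoothing == "auto" or smoothing is None:
        smoothing = t.size * estimate_noise_sd(c) ** 2
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    spl = UnivariateSpline(t, c, k=3, s=smoothing)
    rss = float(np.sum((spl(t) - c) ** 2))
    return SplineModel(spl, float(t[0]), float(t[-1]), float(smoothing), rss)


def infer_equilibrium_species(g6p, keq: float):
    """Concentration of the equilibrium partner: F6P = Keq·G6P.

    Used when a species (F6P between the FBP β-anomer peaks) cannot be
    integrated directly but sits in fast equilibrium with a quantifiable
    one through a much faster reaction.
    """
    if keq <= 0:
        raise ValueError("keq must be positive")
    g6p = np.asarray(g6p, dtype=float)
    if np.any(g6p < 0):
        raise ValueError("concentration must be non-negative")
    out = keq * g6p
    return float(out) if out.ndim == 0 else out


def rates_from_splines(assay: AssayRun,
                       splines: Mapping[str, SplineModel],
                       scheme: ReactionScheme,
                       times: Sequence[float],
                       exclude: Iterable[str] = (),
                       endpoint_weight: float = 0.5) -> list[RateSample]:
    """Reaction rates as stoichiometry-signed means of spline derivatives.

    At each requested time the rate is the average over the available,
    non-excluded reaction participants of (+d[P]/dt for products,
    −d[S]/dt for substrates).  Species consumed by side reactions (ADP
    under background hydrolysis) are excluded via ``exclude``.  The full
    concentration vector — every species with a spline, with effective-
    concentration corrections applied — is attached to each sample.

    The first and last retained time of the grid get ``endpoint_weight``
    since spline derivatives are least reliable at the boundary.
    """
    times = np.asarray(times, dtype=float)
    exclude = set(exclude)
    participants = [sp for sp in
                    list(scheme.substrates) + list(scheme.products)
                    if sp in splines and sp not in exclude]
    if not participants:
        raise ValueError("no usable reaction participant has a spline")
    samples: list[RateSample] = []
    kept_idx = []
    for i, t in enumerate(times):
        if not all(s.covers(t) for s in splines.values()):
            log.info("assay %s: t=%.3g outside spline support, skipped",
                     assay.assay_id, t)
            continue
        contribs = []
        for sp in participants:
            d = float(splines[sp].derivative(t))
            contribs.append(d if sp in scheme.products else -d)
        conc = {sp: max(float(assay.effective_conc(sp, splines[sp](t))), 0.0)
                for sp in splines}
        samples.append(RateSample(time=float(t), conc=conc,
                                  rate=float(np.mean(contribs)),
                                  source_species="+".join(participants),
                                  weight=1.0, assay_id=assay.assay_id))
        kept_idx.append(i)
    if samples:
        samples[0].weight = endpoint_weight
        samples[-1].weight = endpoint_weight
    return samples


@dataclass
class PreEquilibrationSplit:
    """Result of splitting an assay at the equilibration boundary."""

    retained: dict[str, ProgressCurve]
    withheld: dict[str, ProgressCurve]
    boundary_time: float


def exclude_pre_equilibration(curves: Mapping[str, ProgressCurve],
                              keq: float,
                              rel_tol: float = 0.05,
                              substrate: str = "G6P",
                              product: str = "F6P") -> PreEquilibrationSplit:
    """Split an assay into pre- and post-equilibration segments.

    Retains the suffix of the (shared) time grid on which the
    mass-action ratio product/substrate stays within ``rel_tol`` of
    ``keq``; the withheld prefix is preserved for model validation.
    Raises :class:`EquilibrationError` if the criterion is never met.
    """
    if substrate not in curves or product not in curves:
        raise ValueError(f"need both {substrate} and {product} curves")
    s = curves[substrate]
    p = curves[product]
    if s.time.shape != p.time.shape or np.any(s.time != p.time):
        raise ValueError("substrate and product curves must share a time grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = p.conc / s.conc
    ok = np.abs(ratio - keq) <= rel_tol * keq
    ok = np.where(np.isfinite(ratio), ok, False)
    # first index from which every later point satisfies the band
    not_ok_idx = np.nonzero(~ok)[0]
    start = 0 if not_ok_idx.size == 0 else int(not_ok_idx[-1]) + 1
    if start >= s.time.size:
        raise EquilibrationError(
            f"assay {s.assay_id}: |{product}/{substrate} - keq| never stays "
            f"within {rel_tol:.3g} of keq={keq:.4g}; nothing retained")
    mask = np.zeros(s.time.size, dtype=bool)
    mask[start:] = True
    retained = {sp: c.truncate(mask) for sp, c in curves.items()}
    withheld = {sp: c.truncate(~mask) for sp, c in curves.items()}
    return PreEquilibrationSplit(retained, withheld,
                                 boundary_time=float(s.time[start]))


def reference_maximal_rate(samples: Sequence[RateSample]) -> float:
    """Representative maximal rate of a reference assay.

    Median rate over the first quartile of the time course, where the
    substrate is saturating and the rate sits on its plateau.
    """
    if not samples:
        raise ValueError("reference assay has no rate samples")
    times = np.array([s.time for s in samples])
    rates = np.array([s.rate for s in samples])
    t_cut = times.min() + 0.25 * (times.max() - times.min())
    sel = times <= t_cut
    return float(np.median(rates[sel]))


def normalize_to_reference(samples: Sequence[RateSample],
                           reference_rate: float,
                           vmax_scale: float = 1.0) -> list[RateSample]:
    """Divide rates by a session reference rate (optionally rescale).

    After normalization the reference assay's own plateau maps to 1;
    ``vmax_scale`` re-applies an externally determined maximal rate to
    return to physical units.
    """
    if reference_rate <= 0:
        raise ValueError("reference rate must be positive")
    factor = vmax_scale / reference_rate
    return [replace(s, rate=s.rate * factor) for s in samples]


def conservation_defect(curves: Mapping[str, ProgressCurve],
                        group: Sequence[str]) -> float:
    """Relative drift of a conserved sum (diagnostic only, never enforced)."""
    total = None
    for sp in group:
        c = curves[sp].conc
        total = c.copy() if total is None else total + c
    mean = float(np.mean(total))
    if mean == 0:
        return 0.0
    return float((total.max() - total.min()) / mean)


# ---------------------------------------------------------------------------
# tidy CSV serialization
# ---------------------------------------------------------------------------

def write_tidy_csv(curves: Iterable[ProgressCurve], path) -> None:
    """Write curves as tidy CSV: assay_id, time_min, species, conc_mM, flag."""
    rows = []
    for c in curves:
        for t, conc, ok in zip(c.time, c.conc, c.valid):
            rows.append((c.assay_id, t, c.species, conc, int(ok)))
    pd.DataFrame(rows, columns=["assay_id", "time_min", "species",
                                "conc_mM", "flag"]).to_csv(path, index=False)


def read_tidy_csv(path) -> list[ProgressCurve]:
    df = pd.read_csv(path)
    curves = []
    for (assay, sp), grp in df.groupby(["assay_id", "species"], sort=False):
        grp = grp.sort_values("time_min")
        curves.append(ProgressCurve(str(assay), str(sp),
                                    grp["time_min"].to_numpy(),
                                    grp["conc_mM"].to_numpy(),
                                    grp["flag"].to_numpy().astype(bool)))
    return curves


def samples_to_frame(samples: Sequence[RateSample]) -> pd.DataFrame:
    """One row per rate sample; concentration vector as species columns."""
    rows = []
    for s in samples:
        row = {"assay_id": s.assay_id, "time_min": s.time, "rate": s.rate,
               "weight": s.weight, "source_species": s.source_species}
        row.update(s.conc)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_samples(df: pd.DataFrame) -> list[RateSample]:
    meta = {"assay_id", "time_min", "rate", "weight", "source_species"}
    species = [c for c in df.columns if c not in meta]
    out = []
    for _, row in df.iterrows():
        out.append(RateSample(time=float(row["time_min"]),
                              conc={sp: float(row[sp]) for sp in species},
                              rate=float(row["rate"]),
                              source_species=str(row.get("source_species", "")),
                              weight=float(row.get("weight", 1.0)),
                              assay_id=str(row.get("assay_id", ""))))
    return out
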