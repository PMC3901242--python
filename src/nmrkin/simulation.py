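"""Minimal ODE model of the coupled PGI–PFK assay system.

The model reproduces an in-extract NMR time course with the smallest
reaction set that matters: the reversible PGI isomerization
(G6P <-> F6P), the irreversible bi-substrate Hill PFK reaction
(F6P + ATP -> FBP + ADP, PEP inhibiting), rapid-equilibrium binding of
Mg²⁺ to ATP and ADP, and a slow first-order background hydrolysis
consuming MgADP to AMP + Pi + Mg²⁺ (adenylate-kinase-mediated net
reaction; its driver is configurable, see below).

Free Mg²⁺ is clamped (1 mM by default): the assay buffer dominates the
free-ion pool, and clamping avoids tracking total magnesium.  The
Mg-nucleotide equilibria are substituted algebraically at every
derivative evaluation rather than simulated as fast reactions, which
keeps the system non-stiff:

    MgATP = ATP_total · K·[Mg] / (1 + K·[Mg]),   K in mM⁻¹

State variables are the totals (G6P, F6P, FBP, ATP, ADP, AMP, Pi, PEP);
complexed and free nucleotide forms are derived columns of the output
trajectory.  Total adenylate (ATP+ADP+AMP) and total hexose phosphate
(G6P+F6P+FBP) are conserved by construction, which the integrator is
tested against.

The hydrolysis step is written two ways in the source material this
kind of assay follows: rate proportional to MgATP (the default here) or
an elementary first-order decay of MgADP itself; ``hydrolysis_driver``
switches between them, with k = 2e-4 min⁻¹ in either case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .progress import ProgressCurve
from .ratelaws import (IrreversibleHillBi, RateLawParameters, ReversibleHillUni,
                       irreversible_hill_bi_rate, reversible_hill_uni_rate)

__all__ = [
    "SPECIES",
    "NucleotidePools",
    "mg_partition",
    "MinimalModel",
    "SimulationTrajectory",
    "compare_to_experiment",
]

SPECIES = ("G6P", "F6P", "FBP", "ATP", "ADP", "AMP", "Pi", "PEP")


class NucleotidePools(NamedTuple):
    mgatp: np.ndarray | float
    atp_free: np.ndarray | float
    mgadp: np.ndarray | float
    adp_free: np.ndarray | float


def mg_partition(total_atp, total_adp, free_mg: float,
                 k_atp: float = 1e4, k_adp: float = 1e3) -> NucleotidePools:
    """Rapid-equilibrium speciation of the adenine nucleotides.

    Binding constants are association constants in M⁻¹ (1e4 M⁻¹ for
    MgATP, 1e3 M⁻¹ for MgADP); concentrations in mM.  For each
    nucleotide, complexed/free = K·[Mg²⁺] and complexed + free = total.
    """
    if free_mg < 0 or k_atp < 0 or k_adp < 0:
        raise ValueError("free Mg and binding constants must be >= 0")
    total_atp = np.asarray(total_atp, dtype=float)
    total_adp = np.asarray(total_adp, dtype=float)
    if np.any(total_atp < 0) or np.any(total_adp < 0):
        raise ValueError("nucleotide totals must be >= 0")
    r_atp = (k_atp / 1e3) * free_mg          # K [mM^-1] * Mg [mM]
    r_adp = (k_adp / 1e3) * free_mg
    atp_free = total_atp / (1.0 + r_atp)
    adp_free = total_adp / (1.0 + r_adp)
    return NucleotidePools(total_atp - atp_free, atp_free,
                           total_adp - adp_free, adp_free)


@dataclass
class MinimalModel:
    """Coupled PGI + PFK system with Mg speciation and MgADP hydrolysis."""

    pgi: RateLawParameters
    pfk: RateLawParameters
    k_mgatp: float = 1e4          # M^-1
    k_mgadp: float = 1e3          # M^-1
    free_mg: float = 1.0          # mM, clamped
    k_hyd: float = 2e-4           # min^-1
    hydrolysis_driver: str = "mgatp"   # or "mgadp"
    pfk_atp_pool: str = "total"   # "total" (parameters fitted on totals) or "mgatp"

    def __post_init__(self):
        self._pgi_law = ReversibleHillUni("G6P", "F6P")
        self._pfk_law = IrreversibleHillBi("F6P", "ATP", "PEP")
        self._pgi_p = self._pgi_law.params_from(self.pgi)
        self._pfk_p = self._pfk_law.params_from(self.pfk)
        self._pgi_vmm = self.pgi.vf_volumetric() / self.pgi.vf
        self._pfk_vmm = self.pfk.vf_volumetric() / self.pfk.vf
        if self.hydrolysis_driver not in ("mgatp", "mgadp"):
            raise ValueError("hydrolysis_driver must be 'mgatp' or 'mgadp'")
        if self.pfk_atp_pool not in ("total", "mgatp"):
            raise ValueError("pfk_atp_pool must be 'total' or 'mgatp'")

    def reaction_rates(self, y: np.ndarray) -> tuple[float, float, float]:
        """(v_pgi, v_pfk, v_hyd) in mM·min⁻¹ at state vector ``y``."""
        g6p, f6p, fbp, atp, adp, amp, pi_, pep = np.maximum(y, 0.0)
        pools = mg_partition(atp, adp, self.free_mg, self.k_mgatp, self.k_mgadp)
        v_pgi = self._pgi_vmm * reversible_hill_uni_rate(
            g6p, f6p, validate=False, **self._pgi_p)
        atp_eff = pools.mgatp if self.pfk_atp_pool == "mgatp" else atp
        v_pfk = self._pfk_vmm * irreversible_hill_bi_rate(
            f6p, atp_eff, pep, validate=False, **self._pfk_p)
        driver = pools.mgatp if self.hydrolysis_driver == "mgatp" else pools.mgadp
        v_hyd = self.k_hyd * driver
        return float(v_pgi), float(v_pfk), float(v_hyd)

    def rhs(self, t, y):
        v_pgi, v_pfk, v_hyd = self.reaction_rates(y)
        # hydrolysis consumes (Mg)ADP, producing AMP + Pi (+ Mg, clamped)
        return np.array([
            -v_pgi,                 # G6P
            +v_pgi - v_pfk,         # F6P
            +v_pfk,                 # FBP
            -v_pfk,                 # ATP total
            +v_pfk - v_hyd,         # ADP total
            +v_hyd,                 # AMP
            +v_hyd,                 # Pi
            0.0,                    # PEP (side reactions outside this model)
        ])

    def simulate(self, y0: Mapping[str, float], t_grid: Sequence[float],
                 method: str = "LSODA", rtol: float = 1e-8,
                 atol: float = 1e-10) -> "SimulationTrajectory":
        """Integrate from an initial concentration mapping over ``t_grid``."""
        t_grid = np.asarray(t_grid, dtype=float)
        if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
            raise ValueError("t_grid must be strictly increasing")
        y0v = np.array([float(y0.get(sp, 0.0)) for sp in SPECIES])
        if np.any(y0v < 0):
            raise ValueError("initial concentrations must be >= 0")
        sol = solve_ivp(self.rhs, (t_grid[0], t_grid[-1]), y0v,
                        t_eval=t_grid, method=method, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        conc = pd.DataFrame(sol.y.T, columns=list(SPECIES))
        pools = mg_partition(conc["ATP"].to_numpy(), conc["ADP"].to_numpy(),
                             self.free_mg, self.k_mgatp, self.k_mgadp)
        conc["MgATP"], conc["ATP_free"] = pools.mgatp, pools.atp_free
        conc["MgADP"], conc["ADP_free"] = pools.mgadp, pools.adp_free
        conc.insert(0, "time_min", t_grid)
        diag = {"method": method, "nfev": int(sol.nfev), "rtol": rtol,
                "atol": atol, "message": sol.message}
        return SimulationTrajectory(conc, diag, model=self)

    def to_json(self, path=None):
        payload = {
            "pgi": {"vf": self.pgi.vf, "half_sat": self.pgi.half_sat,
                    "h": self.pgi.h, "keq": self.pgi.keq,
                    "protein_conc": self.pgi.protein_conc},
            "pfk": {"vf": self.pfk.vf, "half_sat": self.pfk.half_sat,
                    "h": self.pfk.h, "alpha": self.pfk.alpha,
                    "protein_conc": self.pfk.protein_conc},
            "k_mgatp": self.k_mgatp, "k_mgadp": self.k_mgadp,
            "free_mg": self.free_mg, "k_hyd": self.k_hyd,
            "hydrolysis_driver": self.hydrolysis_driver,
            "pfk_atp_pool": self.pfk_atp_pool,
        }
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, source) -> "MinimalModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        pgi = RateLawParameters(**payload.pop("pgi"))
        pfk = RateLawParameters(**payload.pop("pfk"))
        return cls(pgi=pgi, pfk=pfk, **payload)


@dataclass
class SimulationTrajectory:
    """Time grid + concentration matrix (totals and Mg-speciated forms)."""

    conc: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)
    model: MinimalModel | None = None

    @property
    def time(self) -> np.ndarray:
        return self.conc["time_min"].to_numpy()

    def __getitem__(self, species: str) -> np.ndarray:
        return self.conc[species].to_numpy()

    def interp(self, species: str, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.time, self[species])

    def conserved_totals(self) -> pd.DataFrame:
        """Relative drift of the conserved pools over the trajectory."""
        out = {}
        for name, group in (("adenylate", ["ATP", "ADP", "AMP"]),
                            ("hexose_phosphate", ["G6P", "F6P", "FBP"])):
            tot = self.conc[group].sum(axis=1).to_numpy()
            ref = tot[0] if tot[0] != 0 else 1.0
            out[name] = {"initial": tot[0],
                         "max_rel_drift": float(np.max(np.abs(tot - tot[0]))
                                                / abs(ref))}
        return pd.DataFrame(out).T

    def to_csv(self, path) -> None:
        self.conc.to_csv(path, index=False)

    def plot(self, species: Sequence[str] = ("G6P", "F6P", "FBP", "ATP", "ADP"),
             ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for sp in species:
            ax.plot(self.time, self[sp], label=sp)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("concentration (mM)")
        ax.legend(frameon=False)
        return ax


def compare_to_experiment(traj: SimulationTrajectory,
                          curves: Sequence[ProgressCurve]) -> pd.DataFrame:
    """Per-species RMSE and bias of the simulation against measured curves.

    The simulation is interpolated to the data times; only the
    overlapping time support is used, and fully disjoint supports are an
    error.  The last row pools all species.
    """
    rows = {}
    pooled = []
    for c in curves:
        mask = (c.time >= traj.time[0]) & (c.time <= traj.time[-1]) & c.valid
        if not mask.any():
            raise ValueError(f"curve {c.assay_id}/{c.species}: no overlap "
                             "with the simulated time support")
        sim = traj.interp(c.species, c.time[mask])
        diff = sim - c.conc[mask]
        rows[c.species] = {"n": int(mask.sum()),
                           "rmse": float(np.sqrt(np.mean(diff ** 2))),
                           "bias": float(np.mean(diff))}
        pooled.append(diff)
    alld = np.concatenate(pooled)
    rows["pooled"] = {"n": alld.size,
                      "rmse": float(np.sqrt(np.mean(alld ** 2))),
                      "bias": float(np.mean(alld))}
    return pd.DataFrame(rows).T
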