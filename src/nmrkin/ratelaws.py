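"""Generalized Hill rate laws for progress-curve enzyme kinetics.

The central objects are the reversible Hill equation family: a minimal,
operationally parameterized description of enzyme rates covering
reversibility, cooperativity (Hill coefficient ``h``) and allosteric
modulation (modifier effect ``alpha``).  Concentrations enter scaled by
their half-saturation constants, e.g. ``sigma = S / S_0.5``; the
thermodynamic drive enters through the mass-action ratio
``Gamma = prod(P) / prod(S)`` of *unscaled* concentrations, so that the
rate vanishes exactly on the equilibrium manifold ``Gamma = Keq``.

Three concrete laws are provided:

* :func:`reversible_hill_uni_rate` — uni-uni reversible Hill; with
  ``h = 1`` it reduces to the reversible Michaelis–Menten equation used
  for phosphoglucose isomerase (PGI, G6P <-> F6P).
* :func:`irreversible_hill_bi_rate` — bi-substrate irreversible Hill
  with a hyperbolic allosteric modifier term, used for
  phosphofructokinase (PFK, F6P + ATP -> FBP + ADP, PEP inhibition).
* :func:`irreversible_mm_rate` — the textbook irreversible
  Michaelis–Menten equation (initial-rate saturation curves).

All rate functions broadcast over numpy arrays in both concentrations
and parameters, which the global fitter exploits to evaluate whole
genetic-algorithm populations at once.

Units
-----
Half-saturation constants and concentrations are in mM.  ``vf`` is a
maximal rate; as a specific activity it is µmol·min⁻¹·mg⁻¹ and converts
to a volumetric mM·min⁻¹ by multiplying with the protein concentration
in mg·mL⁻¹ (µmol·min⁻¹·mL⁻¹ == mM·min⁻¹).  ``h``, ``alpha`` and ``keq``
are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "ParameterError",
    "ReactionScheme",
    "RateLawParameters",
    "reversible_hill_uni_rate",
    "irreversible_hill_bi_rate",
    "irreversible_mm_rate",
    "haldane_reverse_vmax",
    "RateLaw",
    "ReversibleHillUni",
    "IrreversibleHillBi",
    "IrreversibleMM",
    "register_rate_law",
    "get_rate_law",
    "make_rate_law",
]


class ParameterError(ValueError):
    """A rate-law parameter violates its domain (e.g. non-positive)."""


def _check_positive(**params) -> None:
    for name, value in params.items():
        if value is None:
            raise ParameterError(f"parameter {name!r} is required but missing")
        if np.any(np.asarray(value, dtype=float) <= 0.0):
            raise ParameterError(f"parameter {name!r} must be strictly positive")


def _check_nonneg_conc(**concs) -> None:
    for name, value in concs.items():
        if np.any(np.asarray(value, dtype=float) < 0.0):
            raise ValueError(f"concentration {name!r} must be non-negative")


def _ret(x: np.ndarray):
    # return python float for scalar inputs, ndarray otherwise
    x = np.asarray(x)
    return float(x) if x.ndim == 0 else x


@dataclass(frozen=True)
class ReactionScheme:
    """Species roles of one reaction: substrates, products, modifiers.

    ``modifiers`` maps species name to effect sign (-1 inhibitor, +1
    activator); the quantitative strength lives in ``alpha`` of the
    parameter set, the sign here is declarative metadata.
    """

    substrates: tuple[str, ...]
    products: tuple[str, ...] = ()
    modifiers: Mapping[str, int] = field(default_factory=dict)
    reversible: bool = False

    def __post_init__(self):
        if len(self.substrates) == 0:
            raise ValueError("a reaction scheme needs at least one substrate")
        names = list(self.substrates) + list(self.products) + list(self.modifiers)
        if len(names) != len(set(names)):
            raise ValueError(f"species names must be unique across roles: {names}")
        if self.reversible and not self.products:
            raise ValueError("a reversible scheme needs at least one product")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.substrates) + tuple(self.products) + tuple(self.modifiers)


@dataclass
class RateLawParameters:
    """Parameter set for one reaction.

    Parameters
    ----------
    vf : float
        Maximal forward rate.  Interpreted as specific activity
        (µmol·min⁻¹·mg⁻¹) when ``protein_conc`` is set, otherwise as a
        volumetric rate (mM·min⁻¹).
    half_sat : mapping
        Species name -> half-saturation concentration (mM).
    h : float
        Hill coefficient (1 = no cooperativity).
    alpha : float
        Modifier effect; alpha < 1 inhibits, alpha > 1 activates,
        alpha = 1 renders the modifier inert.
    keq : float, optional
        Equilibrium constant (dimensionless); required for reversible
        schemes only.
    protein_conc : float, optional
        mg·mL⁻¹, converts vf to mM·min⁻¹ for simulation.
    """

    vf: float
    half_sat: dict[str, float]
    h: float = 1.0
    alpha: float = 1.0
    keq: float | None = None
    protein_conc: float | None = None

    def __post_init__(self):
        _check_positive(vf=self.vf, h=self.h, alpha=self.alpha)
        for sp, k in self.half_sat.items():
            _check_positive(**{f"half_sat[{sp}]": k})
        if self.keq is not None:
            _check_positive(keq=self.keq)
        if self.protein_conc is not None:
            _check_positive(protein_conc=self.protein_conc)

    def require_keq(self) -> float:
        if self.keq is None:
            raise ParameterError("reversible rate law requires keq")
        return self.keq

    def vf_volumetric(self) -> float:
        """Maximal rate in mM·min⁻¹ (vf × protein concentration)."""
        if self.protein_conc is None:
            return self.vf
        return self.vf * self.protein_conc


# ---------------------------------------------------------------------------
# rate-law kernels (numpy-broadcasting)
# ---------------------------------------------------------------------------

def reversible_hill_uni_rate(s, p, *, vf, ks, kp, keq, h=1.0, validate=True):
    """Uni-uni reversible Hill rate, reducing to reversible MM at h = 1.

    v = Vf·σ·(1 − Γ/Keq)·(σ+π)^(h−1) / (1 + (σ+π)^h)

    with σ = s/Ks, π = p/Kp, Γ = p/s.  The driving term is evaluated as
    σ·(1 − Γ/Keq) = (s − p/Keq)/Ks, which is algebraically identical and
    finite at s = 0; at the doubly-zero corner (s = p = 0) the rate is 0.
    """
    if validate:
        _check_positive(vf=vf, ks=ks, kp=kp, keq=keq, h=h)
        _check_nonneg_conc(s=s, p=p)
    s = np.asarray(s, dtype=float)
    p = np.asarray(p, dtype=float)
    sigma = s / ks
    pi = p / kp
    drive = (s - p / keq) / ks
    tot = sigma + pi
    with np.errstate(divide="ignore", invalid="ignore"):
        shape = np.power(tot, h - 1.0) / (1.0 + np.power(tot, h))
        v = vf * drive * shape
    return _ret(np.where(tot == 0.0, 0.0, v))


def irreversible_hill_bi_rate(s1, s2, m, *, vf, ks1, ks2, km, alpha, h,
                              validate=True):
    """Bi-substrate irreversible Hill rate with one allosteric modifier.

    v = Vf·(σ1·σ2)^h / (M + σ1^h + σ2^h + (σ1·σ2)^h),
    M = (1 + μ^h) / (1 + α·μ^h)

    σ1, σ2, μ are the substrate and modifier concentrations scaled by
    their half-saturation constants.  α < 1 makes the modifier an
    inhibitor (M grows with μ), α = 1 makes it inert (M ≡ 1).  A single
    Hill coefficient h is shared by substrates and modifier.
    """
    if validate:
        _check_positive(vf=vf, ks1=ks1, ks2=ks2, km=km, alpha=alpha, h=h)
        _check_nonneg_conc(s1=s1, s2=s2, m=m)
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    m = np.asarray(m, dtype=float)
    o1h = np.power(s1 / ks1, h)
    o2h = np.power(s2 / ks2, h)
    muh = np.power(m / km, h)
    mod = (1.0 + muh) / (1.0 + alpha * muh)
    return _ret(vf * o1h * o2h / (mod + o1h + o2h + o1h * o2h))


def irreversible_mm_rate(s, *, vf, ks, validate=True):
    """Irreversible Michaelis–Menten: v = Vf·s/(Ks + s)."""
    if validate:
        _check_positive(vf=vf, ks=ks)
        _check_nonneg_conc(s=s)
    s = np.asarray(s, dtype=float)
    return _ret(vf * s / (ks + s))


def haldane_reverse_vmax(*, vf, ks, kp, keq):
    """Reverse maximal rate from the Haldane relationship.

    For the uni-uni reversible law, thermodynamic consistency ties the
    reverse limiting rate to the forward parameters:
    Vr = Vf·Kp / (Ks·Keq).  Units follow vf.
    """
    _check_positive(vf=vf, ks=ks, kp=kp)
    if keq is None:
        raise ParameterError("Haldane relationship requires keq")
    _check_positive(keq=keq)
    return vf * kp / (ks * keq)


# ---------------------------------------------------------------------------
# pluggable rate-law objects (used by the fitter, the simulator and YAML
# configuration); the registry lets an alternative algebraic form be swapped
# in without touching the fitting machinery.
# ---------------------------------------------------------------------------

class RateLaw:
    """A named rate law bound to a reaction scheme.

    Subclasses define ``param_names`` (the flat parameter vector the
    fitter sees) and :meth:`rate`, which must broadcast over numpy
    arrays in both concentrations and parameters.
    """

    name: str = "abstract"
    param_names: tuple[str, ...] = ()

    def __init__(self, scheme: ReactionScheme):
        self.scheme = scheme

    @property
    def species_needed(self) -> tuple[str, ...]:
        return self.scheme.species

    def rate(self, concs: Mapping[str, object], params: Mapping[str, object]):
        raise NotImplementedError

    def params_from(self, p: RateLawParameters) -> dict[str, float]:
        """Flatten a :class:`RateLawParameters` into this law's vector."""
        raise NotImplementedError

    def __repr__(self):
        return (f"{type(self).__name__}({'+'.join(self.scheme.substrates)}"
                f"{' <-> ' if self.scheme.reversible else ' -> '}"
                f"{'+'.join(self.scheme.products)})")


class ReversibleHillUni(RateLaw):
    """Uni-uni reversible Hill law (PGI-style)."""

    name = "reversible_hill_uni"
    param_names = ("vf", "ks", "kp", "keq", "h")

    def __init__(self, substrate: str = "G6P", product: str = "F6P"):
        super().__init__(ReactionScheme((substrate,), (product,), reversible=True))
        self.substrate = substrate
        self.product = product

    def rate(self, concs, params):
        return reversible_hill_uni_rate(
            concs[self.substrate], concs[self.product],
            vf=params["vf"], ks=params["ks"], kp=params["kp"],
            keq=params["keq"], h=params.get("h", 1.0), validate=False)

    def params_from(self, p: RateLawParameters) -> dict[str, float]:
        return {"vf": p.vf, "ks": p.half_sat[self.substrate],
                "kp": p.half_sat[self.product], "keq": p.require_keq(),
                "h": p.h}

    def haldane_reverse_vmax(self, params: Mapping[str, float] | RateLawParameters):
        if isinstance(params, RateLawParameters):
            params = self.params_from(params)
        return haldane_reverse_vmax(vf=params["vf"], ks=params["ks"],
                                    kp=params["kp"], keq=params["keq"])


class IrreversibleHillBi(RateLaw):
    """Bi-substrate irreversible Hill law with one modifier (PFK-style)."""

    name = "irreversible_hill_bi"
    param_names = ("vf", "ks1", "ks2", "km", "alpha", "h")

    def __init__(self, s1: str = "F6P", s2: str = "ATP", modifier: str = "PEP",
                 modifier_sign: int = -1):
        super().__init__(ReactionScheme((s1, s2), ("FBP", "ADP"),
                                        modifiers={modifier: modifier_sign})
                         if {s1, s2} == {"F6P", "ATP"} else
                         ReactionScheme((s1, s2), modifiers={modifier: modifier_sign}))
        self.s1, self.s2, self.modifier = s1, s2, modifier

    @property
    def species_needed(self) -> tuple[str, ...]:
        # products do not enter the irreversible rate
        return (self.s1, self.s2, self.modifier)

    def rate(self, concs, params):
        return irreversible_hill_bi_rate(
            concs[self.s1], concs[self.s2], concs[self.modifier],
            vf=params["vf"], ks1=params["ks1"], ks2=params["ks2"],
            km=params["km"], alpha=params["alpha"], h=params["h"],
            validate=False)

    def params_from(self, p: RateLawParameters) -> dict[str, float]:
        return {"vf": p.vf, "ks1": p.half_sat[self.s1],
                "ks2": p.half_sat[self.s2], "km": p.half_sat[self.modifier],
                "alpha": p.alpha, "h": p.h}


class IrreversibleMM(RateLaw):
    """Single-substrate irreversible Michaelis–Menten law."""

    name = "irreversible_mm"
    param_names = ("vf", "ks")

    def __init__(self, substrate: str = "ATP"):
        super().__init__(ReactionScheme((substrate,)))
        self.substrate = substrate

    def rate(self, concs, params):
        return irreversible_mm_rate(concs[self.substrate],
                                    vf=params["vf"], ks=params["ks"],
                                    validate=False)

    def params_from(self, p: RateLawParameters) -> dict[str, float]:
        return {"vf": p.vf, "ks": p.half_sat[self.substrate]}


_REGISTRY: dict[str, Callable[..., RateLaw]] = {}


def register_rate_law(name: str, factory: Callable[..., RateLaw]) -> None:
    """Register a rate-law factory under ``name`` (overwrites silently)."""
    _REGISTRY[name] = factory


def get_rate_law(name: str, **kwargs) -> RateLaw:
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown rate law {name!r}; known: {sorted(_REGISTRY)}")
    return factory(**kwargs)


def make_rate_law(spec: Mapping[str, object]) -> RateLaw:
    """Build a rate law from a config mapping, e.g. loaded from YAML.

    The mapping must carry ``law`` (registry name); remaining keys are
    passed to the factory (species role names etc.).
    """
    spec = dict(spec)
    name = spec.pop("law")
    return get_rate_law(str(name), **spec)


register_rate_law(ReversibleHillUni.name, ReversibleHillUni)
register_rate_law(IrreversibleHillBi.name, IrreversibleHillBi)
register_rate_law(IrreversibleMM.name, IrreversibleMM)
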