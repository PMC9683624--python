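"""Reaction kinetics: Gierer-Meinhardt, Mimura-Murray, Gray-Scott, Wilson-Cowan.

Each model is a parameter dataclass with a pure ``reaction`` method giving
the local (per-node) rates of its two species, plus the per-species
diffusion constants used by the network integrator.  The Wilson-Cowan
neural-mass model is the non-diffusive baseline: there the network enters
as an excitatory input current rather than as mass transport.

Adopted algebra
---------------
GM (activator U, inhibitor V)::

    f = rateA * U^2 / ((1 + kappa*U^2) * V) - muA * U + sigmaA
    g = rateI * U^2 - muI * V + sigmaI

MM (prey u, predator v), the generalized Lotka-Volterra form::

    f = ((A + B*u - u^2) / C - v) * u
    g = (u - (1 + D*v)) * v

GS (substrate u, autocatalyst v)::

    f = -u*v^2 + F*(1 - u)
    g = u*v^2 - (F + k)*v

WC (excitatory E, inhibitory I), offset-subtracted logistic response::

    S_a,th(x) = 1/(1 + exp(-a*(x - th))) - 1/(1 + exp(a*th))
    dE = -E + (1 - E) * S_aE,thE(cEE*E - cEI*I + P + eta*coupling)
    dI = -I + (1 - I) * S_aI,thI(cIE*E - cII*I)
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Tuple

import numpy as np

__all__ = [
    "GMParams",
    "MMParams",
    "GSParams",
    "WCParams",
    "gm_reaction",
    "mm_reaction",
    "gs_reaction",
    "wc_sigmoid",
    "wc_rates",
    "PRESETS",
    "get_preset",
]


class ReactionDomainError(ValueError):
    """Raised when a reaction is evaluated outside its domain (e.g. GM V <= 0)."""


@dataclass(frozen=True)
class GMParams:
    """Gierer-Meinhardt activator-inhibitor parameters.

    rateA/rateI: autocatalysis and inhibitor production constants;
    muA/muI: decay rates; sigmaA/sigmaI: base production;
    kappa: activator saturation; Du/Dv: diffusion constants.
    """

    rateA: float = 0.01
    rateI: float = 0.01
    muA: float = 0.01
    muI: float = 0.01
    sigmaA: float = 0.01
    sigmaI: float = 0.0
    kappa: float = 0.0
    Du: float = 0.001
    Dv: float = 0.002

    species: Tuple[str, str] = ("U", "V")

    def __post_init__(self):
        for name in ("rateA", "rateI", "muA", "muI", "sigmaA", "sigmaI", "kappa", "Du", "Dv"):
            if getattr(self, name) < 0:
                raise ValueError(f"GM parameter {name} must be >= 0")
        if self.muI <= 0:
            raise ValueError("muI must be > 0 for a finite inhibitor fixed point")

    @property
    def diffusion(self) -> Tuple[float, float]:
        return (self.Du, self.Dv)

    def reaction(self, U, V):
        return gm_reaction(U, V, self)


@dataclass(frozen=True)
class MMParams:
    """Mimura-Murray predator-prey parameters (prey P/u, predator Q/v)."""

    A: float = 35.0
    B: float = 16.0
    C: float = 9.0
    D: float = 0.4
    dP: float = 0.1
    dQ: float = 0.01
    P0: float = 6.0
    Q0: float = 12.0

    species: Tuple[str, str] = ("P", "Q")

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.dP < 0 or self.dQ < 0:
            raise ValueError("diffusion constants must be >= 0")

    @property
    def diffusion(self) -> Tuple[float, float]:
        return (self.dP, self.dQ)

    def reaction(self, u, v):
        return mm_reaction(u, v, self)


@dataclass(frozen=True)
class GSParams:
    """Gray-Scott autocatalysis parameters: feed rate F, kill rate k."""

    F: float = 0.04
    k: float = 0.06
    Du: float = 0.2
    Dv: float = 0.1

    species: Tuple[str, str] = ("U", "V")

    def __post_init__(self):
        if self.F < 0 or self.k < 0:
            raise ValueError("F and k must be >= 0")

    @property
    def diffusion(self) -> Tuple[float, float]:
        return (self.Du, self.Dv)

    def reaction(self, u, v):
        return gs_reaction(u, v, self)


@dataclass(frozen=True)
class WCParams:
    """Wilson-Cowan neural-mass parameters for one E/I population pair.

    eta scales the network coupling added to the excitatory input;
    P is the constant external drive.
    """

    aE: float = 1.2
    aI: float = 2.0
    cEE: float = 5.0
    cII: float = 1.0
    cIE: float = 6.0
    cEI: float = 10.0
    thetaE: float = 2.0
    thetaI: float = 3.5
    eta: float = 20.0
    P: float = 0.25
    E0: float = 0.1
    I0: float = 0.1
    n_steps: int = 1000
    dt: float = 0.1

    species: Tuple[str, str] = ("E", "I")

    def __post_init__(self):
        if self.aE <= 0 or self.aI <= 0:
            raise ValueError("sigmoid slopes must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    @property
    def diffusion(self) -> Tuple[float, float]:
        # WC is not a mass-transport model; the network enters through eta.
        return (0.0, 0.0)

    def reaction(self, E, I):
        return wc_rates(E, I, 0.0, self)


def gm_reaction(U, V, p: GMParams, v_floor: float | None = None):
    """GM rates (f, g).  V must be positive; ``v_floor`` optionally clamps
    V from below (an explicit solver option, never silent)."""
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    if v_floor is not None:
        V = np.maximum(V, v_floor)
    if np.any(V <= 0):
        raise ReactionDomainError(
            "GM activator term divides by V but V <= 0 was reached; "
            "use a smaller step, an implicit solver, or set a v_floor"
        )
    U2 = U * U
    f = p.rateA * U2 / ((1.0 + p.kappa * U2) * V) - p.muA * U + p.sigmaA
    g = p.rateI * U2 - p.muI * V + p.sigmaI
    return f, g


def mm_reaction(u, v, p: MMParams):
    """Mimura-Murray rates (f, g); both vanish on the coordinate axes."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    f = ((p.A + p.B * u - u * u) / p.C - v) * u
    g = (u - (1.0 + p.D * v)) * v
    return f, g


def gs_reaction(u, v, p: GSParams):
    """Gray-Scott rates (f, g); (u, v) = (1, 0) is always an equilibrium."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    uvv = u * v * v
    f = -uvv + p.F * (1.0 - u)
    g = uvv - (p.F + p.k) * v
    return f, g


def wc_sigmoid(x, a: float, theta: float):
    """Offset-subtracted logistic response: S(0) = 0."""
    x = np.asarray(x, dtype=float)
    return 1.0 / (1.0 + np.exp(-a * (x - theta))) - 1.0 / (1.0 + np.exp(a * theta))


def wc_rates(E, I, external_input, p: WCParams):
    """Wilson-Cowan rates (dE, dI).

    ``external_input`` carries the constant drive P plus any network
    coupling term (eta * L @ E in the integrator).
    """
    E = np.asarray(E, dtype=float)
    I = np.asarray(I, dtype=float)
    dE = -E + (1.0 - E) * wc_sigmoid(
        p.cEE * E - p.cEI * I + external_input, p.aE, p.thetaE
    )
    dI = -I + (1.0 - I) * wc_sigmoid(p.cIE * E - p.cII * I, p.aI, p.thetaI)
    return dE, dI


# -- presets ----------------------------------------------------------
# "gm_bifurcation" is the simplified uncoupled system used for the
# fixed-point / linear-stability analysis (kappa = 0, sigmaI = 0,
# rateA = rateI = muI = 0.01; a = sigmaA and b = muA are the two free
# parameters, here at the stable reference point a = b = 0.01).
PRESETS = {
    "gm_bifurcation": GMParams(
        rateA=0.01, rateI=0.01, muA=0.01, muI=0.01, sigmaA=0.01, sigmaI=0.0, kappa=0.0
    ),
    # left of the stability boundary: sustained oscillation
    "gm_oscillatory": GMParams(
        rateA=0.01, rateI=0.01, muA=0.02, muI=0.01, sigmaA=0.001, sigmaI=0.0, kappa=0.0
    ),
    # center of the 4-parameter sweep range (0.004..0.016)
    "gm_sweep": GMParams(
        rateA=0.01, rateI=0.01, muA=0.01, muI=0.01, sigmaA=0.01, sigmaI=0.0, kappa=0.0
    ),
    "mm_classic": MMParams(A=35.0, B=16.0, C=9.0, D=0.4),
    # mid-grid values of the 540-combination sweep; dP = 0.1, dQ = 0.01
    "mm_sweep": MMParams(A=12.0, B=15.0, C=9.0, D=0.4, dP=0.1, dQ=0.01),
    # adopted Gray-Scott pattern-forming regime
    "gs_buric": GSParams(F=0.04, k=0.06),
    "wc_limit_cycle": WCParams(),
    # textbook strong-coupling regime with a robust single-node limit cycle
    "wc_oscillatory": WCParams(
        aE=1.3, aI=2.0, cEE=16.0, cII=3.0, cIE=15.0, cEI=12.0,
        thetaE=4.0, thetaI=3.7, P=1.25, E0=0.1, I0=0.05,
    ),
}


def get_preset(name: str):
    """Return a copy of a named parameter preset."""
    try:
        return replace(PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def params_to_dict(p) -> dict:
    import dataclasses

    d = asdict(p) if dataclasses.is_dataclass(p) else {}
    d.pop("species", None)
    d["model"] = type(p).__name__
    return d
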