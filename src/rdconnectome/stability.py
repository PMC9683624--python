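"""Fixed-point and linear-stability analysis of the simplified GM system.

The uncoupled, unsaturated Gierer-Meinhardt model with base inhibitor
production removed reduces to

    du/dt = 0.01 u^2 / v - b u + a
    dv/dt = 0.01 u^2 - 0.01 v

with the two free parameters a (base activator production, sigmaA) and
b (activator decay, muA).  The positive fixed point is closed-form:

    v* = u*^2,    u* = (0.01 + a) / b

The (a, b) plane splits into a region with a stable fixed point and a
region with sustained oscillations (a Hopf bifurcation); the boundary is
where the real part of the leading Jacobian eigenvalue vanishes.  Since
det J = 0.01 b > 0 always, the sign of the trace alone decides stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .rd_models import GMParams

__all__ = [
    "StabilityResult",
    "gm_params_for",
    "gm_fixed_point",
    "gm_jacobian",
    "gm_stability",
    "gm_boundary_curve",
]

_RATE = 0.01  # the fixed autocatalysis / inhibitor rate of the reduced system
_MARGINAL_TOL = 1e-10


@dataclass
class StabilityResult:
    """Outcome of the linear stability analysis at one (a, b) point."""

    a: float
    b: float
    fixed_point: tuple[float, float]
    jacobian: np.ndarray
    eigenvalues: np.ndarray
    classification: str  # "stable" | "oscillatory" | "marginal"

    @property
    def max_real_part(self) -> float:
        return float(np.max(self.eigenvalues.real))


def gm_params_for(a: float, b: float) -> GMParams:
    """GM parameter set realizing the reduced system (a = sigmaA, b = muA)."""
    return GMParams(
        rateA=_RATE, rateI=_RATE, muA=b, muI=_RATE, sigmaA=a, sigmaI=0.0, kappa=0.0
    )


def gm_fixed_point(a: float, b: float) -> tuple[float, float]:
    """Positive fixed point (u*, v*) of the reduced GM system.

    From dv/dt = 0: v* = u*^2; substituting into du/dt = 0 gives
    0.01 - b u* + a = 0, i.e. u* = (0.01 + a) / b.
    """
    if b <= 0:
        raise ValueError("b must be > 0 for a finite fixed point")
    u = (_RATE + a) / b
    return u, u * u


def gm_jacobian(a: float, b: float) -> np.ndarray:
    """Jacobian of the reduced GM reaction at its positive fixed point."""
    u, v = gm_fixed_point(a, b)
    return np.array(
        [
            [2 * _RATE * u / v - b, -_RATE * u * u / (v * v)],
            [2 * _RATE * u, -_RATE],
        ]
    )


def gm_stability(a: float, b: float) -> StabilityResult:
    """Classify the reduced GM fixed point by its Jacobian eigenvalues.

    Stable iff max Re(lambda) < 0; |Re| below 1e-10 is "marginal".
    """
    u, v = gm_fixed_point(a, b)
    J = gm_jacobian(a, b)
    eig = np.linalg.eigvals(J)
    r = float(np.max(eig.real))
    if abs(r) < _MARGINAL_TOL:
        cls = "marginal"
    elif r < 0:
        cls = "stable"
    else:
        cls = "oscillatory"
    return StabilityResult(
        a=a, b=b, fixed_point=(u, v), jacobian=J, eigenvalues=eig, classification=cls
    )


def _max_real_part(a: float, b: float) -> float:
    return float(np.max(np.linalg.eigvals(gm_jacobian(a, b)).real))


def gm_boundary_curve(
    a_grid, b_bracket: tuple[float, float] = (1e-4, 10.0), n_scan: int = 400
) -> np.ndarray:
    """Locate b*(a) where the leading eigenvalue's real part crosses zero.

    For each a the bracket is found by a coarse logarithmic scan in b and
    refined with Brent's method.  Returns an array of (a, b*) rows; a
    values without a sign change get b* = NaN (no boundary: for
    a >= 0.01 the fixed point is stable for every b).
    """
    a_grid = np.asarray(a_grid, dtype=float)
    if np.any(a_grid <= 0) or np.any(np.diff(a_grid) < 0):
        raise ValueError("a_grid must be positive and sorted")
    bs = np.logspace(np.log10(b_bracket[0]), np.log10(b_bracket[1]), n_scan)
    out = np.empty((a_grid.size, 2))
    for i, a in enumerate(a_grid):
        vals = np.array([_max_real_part(a, b) for b in bs])
        sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
        if sign_change.size == 0:
            out[i] = (a, np.nan)
            continue
        j = sign_change[0]
        b_star = brentq(lambda b: _max_real_part(a, b), bs[j], bs[j + 1], xtol=1e-14)
        out[i] = (a, b_star)
    return out
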