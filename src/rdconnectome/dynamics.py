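"""Time integration of coupled reaction-diffusion systems on networks.

The state is an ``(n_species, n_nodes)`` array X.  For the mass-transport
models (GM, MM, GS)::

    dX_s/dt = reaction_s(X) + D_s * (L(t) @ X_s)

where ``L(t)`` is the (possibly time-modulated) coupling operator.  For the
Wilson-Cowan model the network instead drives the excitatory sigmoid input
(``P + eta * L @ E``), with no diffusive term.

Connection-weight modulation (demyelination modelling) multiplies the
weights of a selected edge set by a schedule ``m(step)``; the coupling is
split as ``L(t) = L_rest + m(t) * L_lesion`` where ``L_lesion`` is the
conserving operator of the targeted edges alone, so mass conservation holds
at every instant.

Noise options: plain additive Gaussian noise, or a scalar coupled
Ornstein-Uhlenbeck process ``delta(t)`` applied as an extra transport kick
``U += dt * delta * (L @ U)`` on the activator after each deterministic
step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .connectome_model import (
    Connectome,
    CouplingMatrix,
    build_coupling,
)
from .rd_models import WCParams, params_to_dict

__all__ = [
    "SolverConfig",
    "Trajectory",
    "ModulationSchedule",
    "OUNoise",
    "AdditiveNoise",
    "ou_step",
    "schedule_multiplier",
    "integrate",
    "IntegrationError",
]

SOLVERS = ("euler", "rk4", "dopri_adaptive", "implicit_euler")


class IntegrationError(RuntimeError):
    """Raised on blow-up or solver failure; carries the failing step index."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


@dataclass
class SolverConfig:
    """Numerical solver settings.

    ``dt`` is the iteration step size (dimensionless; the paper's time
    axis is iteration steps).  ``record_every`` thins the stored
    trajectory.  ``v_floor`` optionally clamps the GM inhibitor from below
    (explicit opt-in; the default is a hard domain error).
    """

    method: str = "rk4"
    dt: float = 0.1
    n_steps: int = 1000
    abs_tol: float = 1e-8
    rel_tol: float = 1e-6
    record_every: int = 1
    seed: int = 0
    v_floor: float | None = None

    def __post_init__(self):
        if self.method not in SOLVERS:
            raise ValueError(f"unknown solver {self.method!r}; choose from {SOLVERS}")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")


@dataclass
class Trajectory:
    """Per-node, per-species concentration time series.

    ``states`` has shape ``(n_species, n_nodes, n_times)``; ``times`` is
    strictly increasing.
    """

    times: np.ndarray
    states: np.ndarray
    species: tuple
    nodes: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 3:
            raise ValueError("states must be (n_species, n_nodes, n_times)")
        if self.states.shape[0] != len(self.species):
            raise ValueError("species axis mismatch")
        if self.states.shape[1] != len(self.nodes):
            raise ValueError("node axis mismatch")
        if self.states.shape[2] != self.times.size:
            raise ValueError("time axis mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def get(self, species: str) -> np.ndarray:
        """(n_nodes, n_times) series of one species."""
        return self.states[self.species.index(species)]

    @property
    def n_nodes(self) -> int:
        return self.states.shape[1]


@dataclass
class ModulationSchedule:
    """Time-varying multiplier on the weights of selected edges.

    kinds:
      constant       -- multiplier 1 everywhere (identity schedule)
      step           -- 1 before ``onset`` step, ``factor`` from it on
      damped_cosine  -- max(floor, 1 - amplitude * exp(-damping*step)
                        * (1 - cos(2*pi*step/period)) / 2); oscillates
                        between 1 and ``floor`` with decaying excursions
      table          -- piecewise-constant lookup in ``values`` (last value
                        held beyond the end)

    ``edges`` selects the modulated connections; ``None`` targets all.
    The multiplier is always > 0.
    """

    kind: str = "constant"
    edges: Sequence[tuple] | None = None
    factor: float = 1.0
    onset: int = 0
    amplitude: float = 10.0
    floor: float = 0.1
    period: float = 1000.0
    damping: float = 0.0
    values: Sequence[float] | None = None

    def __post_init__(self):
        kinds = ("constant", "step", "damped_cosine", "table")
        if self.kind not in kinds:
            raise ValueError(f"unknown schedule kind {self.kind!r}; choose from {kinds}")
        if self.kind == "step" and self.factor <= 0:
            raise ValueError("step factor must be > 0")
        if self.kind == "damped_cosine" and self.floor <= 0:
            raise ValueError("damped_cosine floor must be > 0")
        if self.kind == "table" and (self.values is None or len(self.values) == 0
                                     or min(self.values) <= 0):
            raise ValueError("table schedule needs positive values")

    def multiplier(self, step: int) -> float:
        return schedule_multiplier(self, step)


def schedule_multiplier(s: ModulationSchedule, step: int) -> float:
    """Evaluate the weight multiplier of a schedule at an iteration step."""
    if step < 0:
        raise ValueError("step must be >= 0")
    if s.kind == "constant":
        return 1.0
    if s.kind == "step":
        return 1.0 if step < s.onset else s.factor
    if s.kind == "damped_cosine":
        osc = s.amplitude * math.exp(-s.damping * step) * (
            1.0 - math.cos(2.0 * math.pi * step / s.period)
        ) / 2.0
        return max(s.floor, 1.0 - osc)
    # table
    idx = min(step, len(s.values) - 1)
    return float(s.values[idx])


@dataclass
class OUNoise:
    """Coupled Ornstein-Uhlenbeck noise on the diffusion term.

    The scalar process ``delta`` mean-reverts to ``mu`` at rate ``theta``
    with volatility ``sigma``; each integrator step adds
    ``dt * delta * (L @ U)`` to the activator (both species if
    ``activator_only`` is False).
    """

    theta: float = 1.0
    sigma: float = 0.1
    mu: float = 0.0
    delta0: float = 0.0
    activator_only: bool = True

    def __post_init__(self):
        if self.theta < 0 or self.sigma < 0:
            raise ValueError("theta and sigma must be >= 0")


@dataclass
class AdditiveNoise:
    """Plain additive Gaussian noise: ``X += sigma * sqrt(dt) * xi`` per step."""

    sigma: float = 0.01
    activator_only: bool = True


def ou_step(state: float, dt: float, p: OUNoise, rng: np.random.Generator) -> float:
    """One Euler-Maruyama update of the OU process."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    xi = rng.standard_normal()
    return state + p.theta * (p.mu - state) * dt + p.sigma * math.sqrt(dt) * xi


# -- right-hand sides -------------------------------------------------

def _make_rhs(model, L: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    """Deterministic rhs X -> dX for a fixed coupling matrix."""
    if isinstance(model, WCParams):
        def rhs(X):
            E, I = X
            from .rd_models import wc_rates
            dE, dI = wc_rates(E, I, model.P + model.eta * (L @ E), model)
            return np.stack([dE, dI])
        return rhs

    Du, Dv = model.diffusion

    def rhs(X):
        u, v = X
        f, g = model.reaction(u, v)
        return np.stack([f + Du * (L @ u), g + Dv * (L @ v)])

    return rhs


def _split_coupling(
    connectome: Connectome, mode: str, schedule: ModulationSchedule | None
) -> tuple[np.ndarray, np.ndarray | None, list]:
    """Return (L_rest, L_lesion, nodes); L_lesion is None without schedule."""
    L_full = build_coupling(connectome, mode=mode)
    if schedule is None or schedule.kind == "constant":
        return L_full.matrix, None, L_full.nodes
    if schedule.edges is None:
        edges = [(s, t) for s, t, _ in connectome.edges()]
    else:
        edges = list(schedule.edges)
        for s, t in edges:
            if not connectome.graph.has_edge(s, t):
                raise ValueError(f"schedule targets missing edge {s}->{t}")
    sub = Connectome.from_edges(
        [(s, t, connectome.graph.edges[s, t]["weight"]) for s, t in edges],
        nodes=connectome.nodes,
    )
    L_lesion = build_coupling(sub, mode=mode).matrix
    return L_full.matrix - L_lesion, L_lesion, L_full.nodes


def integrate(
    model,
    connectome: Connectome | CouplingMatrix | np.ndarray,
    init: np.ndarray,
    solver: SolverConfig,
    mode: str = "out_diffusion",
    schedule: ModulationSchedule | None = None,
    noise: OUNoise | AdditiveNoise | None = None,
) -> Trajectory:
    """Integrate a two-species reaction-diffusion system on a network.

    ``init`` is ``(2, n_nodes)`` (or ``(n_nodes,)`` pairs broadcastable to
    it).  Returns the recorded :class:`Trajectory`, bitwise reproducible
    for a given (seed, solver, dt).

    Weight modulation requires a :class:`Connectome` (the lesioned edge
    subset must be rebuilt); noise requires a fixed-step solver.
    """
    # -- coupling -----------------------------------------------------
    if isinstance(connectome, Connectome):
        L_rest, L_lesion, nodes = _split_coupling(connectome, mode, schedule)
    else:
        if schedule is not None and schedule.kind != "constant":
            raise ValueError("weight modulation needs a Connectome, not a bare matrix")
        if isinstance(connectome, CouplingMatrix):
            L_rest, nodes = connectome.matrix, connectome.nodes
        else:
            L_rest = np.asarray(connectome, dtype=float)
            nodes = list(range(L_rest.shape[0]))
        L_lesion = None
    n = len(nodes)

    X = np.array(init, dtype=float)
    if X.shape != (2, n):
        raise ValueError(f"init must have shape (2, {n}), got {X.shape}")

    if noise is not None and solver.method in ("dopri_adaptive",):
        raise ValueError("stochastic runs need a fixed-step solver (euler/rk4/implicit_euler)")

    rng = np.random.default_rng(solver.seed)
    dt, n_steps, rec = solver.dt, solver.n_steps, solver.record_every

    def L_at(step: int) -> np.ndarray:
        if L_lesion is None:
            return L_rest
        return L_rest + schedule_multiplier(schedule, step) * L_lesion

    # GM inhibitor floor plumbed through the model call, not silently
    base_model = model
    if solver.v_floor is not None and hasattr(model, "kappa"):
        from .rd_models import gm_reaction

        class _Floored:
            species = base_model.species
            diffusion = base_model.diffusion

            @staticmethod
            def reaction(u, v):
                return gm_reaction(u, v, base_model, v_floor=solver.v_floor)

        model = _Floored()

    if solver.method == "dopri_adaptive":
        return _integrate_dopri(model, base_model, L_at, X, solver, nodes, schedule)

    # -- fixed-step loop ----------------------------------------------
    n_rec = n_steps // rec + 1
    times = np.empty(n_rec)
    out = np.empty((2, n, n_rec))
    times[0] = 0.0
    out[:, :, 0] = X
    delta = noise.delta0 if isinstance(noise, OUNoise) else 0.0
    ptr = 1
    for step in range(n_steps):
        L = L_at(step)
        rhs = _make_rhs(model, L)
        try:
            if solver.method == "euler":
                X = X + dt * rhs(X)
            elif solver.method == "rk4":
                k1 = rhs(X)
                k2 = rhs(X + 0.5 * dt * k1)
                k3 = rhs(X + 0.5 * dt * k2)
                k4 = rhs(X + dt * k3)
                X = X + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            else:  # implicit_euler
                X = _backward_euler_step(rhs, X, dt)
        except IntegrationError:
            raise
        except Exception as exc:  # domain errors from reactions
            raise IntegrationError(
                f"solver failed at step {step}: {exc}"
                + ("" if solver.method == "implicit_euler"
                   else " (the system may be stiff; try method='implicit_euler')"),
                step=step,
            ) from exc
        # -- noise, applied after the deterministic update ------------
        if isinstance(noise, OUNoise):
            delta = ou_step(delta, dt, noise, rng)
            kick = dt * delta * (L @ X[0])
            X[0] = X[0] + kick
            if not noise.activator_only:
                X[1] = X[1] + dt * delta * (L @ X[1])
        elif isinstance(noise, AdditiveNoise):
            X[0] = X[0] + noise.sigma * math.sqrt(dt) * rng.standard_normal(n)
            if not noise.activator_only:
                X[1] = X[1] + noise.sigma * math.sqrt(dt) * rng.standard_normal(n)
        if not np.all(np.isfinite(X)):
            raise IntegrationError(f"non-finite state (blow-up) at step {step + 1}", step=step + 1)
        if (step + 1) % rec == 0:
            times[ptr] = (step + 1) * dt
            out[:, :, ptr] = X
            ptr += 1
    times, out = times[:ptr], out[:, :, :ptr]
    return Trajectory(
        times=times,
        states=out,
        species=tuple(model.species),
        nodes=list(nodes),
        metadata=_metadata(base_model, solver, schedule, noise),
    )


def _backward_euler_step(rhs, X, dt, newton_tol=1e-10, max_iter=50):
    """Backward Euler via damped Newton with finite-difference Jacobian."""
    shape = X.shape
    m = X.size
    x0 = X.ravel()

    def G(y):
        return y - x0 - dt * rhs(y.reshape(shape)).ravel()

    y = x0 + dt * rhs(X).ravel()  # explicit predictor
    for _ in range(max_iter):
        g = G(y)
        if np.max(np.abs(g)) < newton_tol:
            break
        J = np.empty((m, m))
        h = 1e-7 * (1.0 + np.abs(y))
        for j in range(m):
            yp = y.copy()
            yp[j] += h[j]
            J[:, j] = (G(yp) - g) / h[j]
        try:
            step = np.linalg.solve(J, g)
        except np.linalg.LinAlgError as exc:
            raise IntegrationError(f"singular Newton Jacobian: {exc}") from exc
        lam = 1.0
        g_norm = np.max(np.abs(g))
        while lam > 1e-4:
            y_new = y - lam * step
            if np.max(np.abs(G(y_new))) < g_norm:
                break
            lam *= 0.5
        y = y - lam * step
    return y.reshape(shape)


def _integrate_dopri(model, base_model, L_at, X0, solver, nodes, schedule):
    """Adaptive Dormand-Prince integration via scipy's RK45.

    The schedule is evaluated at the iteration step floor(t / dt), so the
    modulated weights agree with the fixed-step solvers on the dt grid.
    """
    shape = X0.shape
    dt, n_steps = solver.dt, solver.n_steps
    t_end = n_steps * dt

    def f(t, y):
        step = min(int(t / dt), n_steps - 1)
        rhs = _make_rhs(model, L_at(step))
        return rhs(y.reshape(shape)).ravel()

    t_eval = np.arange(0, n_steps + 1, solver.record_every) * dt
    sol = solve_ivp(
        f, (0.0, t_end), X0.ravel(), method="RK45",
        t_eval=t_eval, rtol=solver.rel_tol, atol=solver.abs_tol,
    )
    if not sol.success:
        raise IntegrationError(f"adaptive solver failed: {sol.message}")
    out = sol.y.reshape(shape[0], shape[1], -1)
    return Trajectory(
        times=sol.t,
        states=out,
        species=tuple(model.species),
        nodes=list(nodes),
        metadata=_metadata(base_model, solver, schedule, None),
    )


def _metadata(model, solver, schedule, noise) -> dict:
    md = {
        "model": type(model).__name__,
        "params": params_to_dict(model),
        "solver": {
            "method": solver.method, "dt": solver.dt, "n_steps": solver.n_steps,
            "record_every": solver.record_every, "seed": solver.seed,
        },
    }
    if schedule is not None:
        md["schedule"] = {
            "kind": schedule.kind, "factor": schedule.factor, "onset": schedule.onset,
            "amplitude": schedule.amplitude, "floor": schedule.floor,
            "period": schedule.period, "damping": schedule.damping,
            "edges": None if schedule.edges is None else [list(e) for e in schedule.edges],
        }
    if noise is not None:
        md["noise"] = {k: v for k, v in vars(noise).items()}
    return md
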