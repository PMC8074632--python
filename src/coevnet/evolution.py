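"""Time-splitting integration of the scalar-field equation to steady state.

Each step performs, in order: (1) quasi-steady re-routing and accumulation of
both densities on the current h; (2) a diffusion step (explicit five/seven
point stencil under a CFL guard, or unconditionally stable backward Euler via
a cached sparse LU); (3) an implicit erosion sweep by the drained material
(sink); (4) an implicit accretion sweep by the supplied material (source),
executed as an erosion sweep on -h with the ascent routing -- the discrete
form of the ridge/valley duality. The gradient magnitude in the reaction
terms is the routing slope to the receiver, which keeps erosion aligned with
the flow path and makes the receiver-first implicit solve well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from . import _kernels
from .domain import (
    GridDomain,
    ModelParams,
    RunConfig,
    SimulationState,
    apply_fixed_faces,
)
from .routing import RoutingMap, accumulate, accumulate_mfd, route_both

__all__ = [
    "StepReport",
    "cfl_bound",
    "resolve_dt",
    "diffusion_step",
    "DiffusionSolver",
    "reaction_sweep",
    "step",
    "run_to_steady",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StepReport:
    dh_max: float
    dt_used: float
    sweeps_order: tuple[str, ...]
    newton_iters: int
    pit_count: int = 0


def cfl_bound(domain: GridDomain, D: float) -> float:
    """Explicit-diffusion stability bound spacing^2 / (2 * ndim * D)."""
    return domain.spacing**2 / (2.0 * domain.ndim * D)


def resolve_dt(domain: GridDomain, params: ModelParams, config: RunConfig) -> float:
    """Concrete time step for a run; 'auto' is 0.9x CFL (explicit) or a
    coarse L^2/(10000 D) step (implicit, reaction sweeps being implicit the
    step is limited only by splitting accuracy)."""
    if not isinstance(config.dt, str):
        return float(config.dt)
    bound = cfl_bound(domain, params.D)
    if config.diffusion == "explicit":
        return 0.9 * bound
    return max(0.9 * bound, domain.length**2 / (10_000.0 * params.D))


def _laplacian(h: np.ndarray, domain: GridDomain) -> np.ndarray:
    """Five/seven-point Laplacian with mirrored ghost cells on every face."""
    pad = np.pad(h, 1, mode="reflect")
    lap = np.zeros_like(h)
    core = (slice(1, -1),) * domain.ndim
    for ax in range(domain.ndim):
        lo = list(core)
        hi = list(core)
        lo[ax] = slice(0, -2)
        hi[ax] = slice(2, None)
        lap += pad[tuple(lo)] + pad[tuple(hi)] - 2.0 * h
    return lap / domain.spacing**2


def diffusion_step(
    h: np.ndarray,
    domain: GridDomain,
    D: float,
    dt: float,
    mode: str = "explicit",
    solver: "DiffusionSolver | None" = None,
) -> np.ndarray:
    """One diffusion sub-step; the fixed faces are left unchanged."""
    if mode == "explicit":
        bound = cfl_bound(domain, D)
        if dt > bound * (1.0 + 1e-12):
            raise ValueError(
                f"dt={dt} exceeds the explicit stability bound {bound}; "
                "use implicit diffusion or a smaller step"
            )
        h_new = h + dt * D * _laplacian(h, domain)
    elif mode == "implicit":
        if solver is None:
            solver = DiffusionSolver(domain, D, dt)
        h_new = solver.solve(h)
    else:
        raise ValueError(f"unknown diffusion mode {mode!r}")
    fixed = domain.fixed_mask()
    h_new[fixed] = h[fixed]
    return h_new


def _neumann_1d(n: int) -> sp.csr_matrix:
    T = sp.diags([np.ones(n - 1), -2.0 * np.ones(n), np.ones(n - 1)], [-1, 0, 1]).tolil()
    T[0, 1] = 2.0
    T[n - 1, n - 2] = 2.0
    return T.tocsr()


class DiffusionSolver:
    """Backward-Euler diffusion: (I - dt D Lap) h' = h, factorized once.

    The Laplacian uses the same stencil as the explicit step (mirrored ghosts
    on closed faces); rows of fixed-face cells are identity, so the Dirichlet
    values pass through exactly.
    """

    def __init__(self, domain: GridDomain, D: float, dt: float):
        self.domain = domain
        self.D = D
        self.dt = dt
        n = domain.shape
        eyes = [sp.identity(m, format="csr") for m in n]
        lap = None
        for ax in range(domain.ndim):
            T = _neumann_1d(n[ax]) / domain.spacing**2
            term = None
            for k in range(domain.ndim):
                M = T if k == ax else eyes[k]
                term = M if term is None else sp.kron(term, M, format="csr")
            lap = term if lap is None else lap + term
        free = (~domain.fixed_mask()).ravel().astype(float)
        lap = sp.diags(free) @ lap
        A = (sp.identity(domain.n_cells, format="csr") - dt * D * lap).tocsc()
        self._lu = splu(A)

    def solve(self, h: np.ndarray) -> np.ndarray:
        return self._lu.solve(h.ravel()).reshape(self.domain.shape)


def reaction_sweep(
    h: np.ndarray,
    routing: RoutingMap,
    density: np.ndarray,
    K_eff: float,
    m: float,
    n: float,
    dt: float,
    sign: int,
    domain: GridDomain,
    newton_tol: float = 1e-12,
    newton_max_iter: int = 50,
) -> tuple[np.ndarray, int]:
    """Implicit reaction sub-step (sign=-1 sink/erosion, sign=+1 source/accretion).

    The routing must have been computed with the orientation matching the
    sign (descent for the sink, ascent for the source). The source sweep runs
    the sink kernel on g = -h and negates back.
    """
    if sign not in (-1, +1):
        raise ValueError("sign must be -1 (sink) or +1 (source)")
    expected = "descent" if sign == -1 else "ascent"
    if routing.orientation != expected:
        raise ValueError(f"{expected} routing required for sign={sign}")
    fixed = domain.fixed_mask().ravel().astype(np.uint8)
    a_pow = np.ascontiguousarray(density, dtype=np.float64).ravel()
    a_pow = a_pow if m == 1.0 else a_pow**m
    g = np.ascontiguousarray(h, dtype=np.float64).ravel().copy()
    if sign == +1:
        np.negative(g, out=g)
    iters = _kernels.sink_sweep_flat(
        g,
        routing.receiver,
        routing.distance,
        a_pow,
        routing.order,
        fixed,
        dt * K_eff,
        float(n),
        newton_tol,
        newton_max_iter,
    )
    if sign == +1:
        np.negative(g, out=g)
    return g.reshape(domain.shape), iters


def step(
    state: SimulationState,
    domain: GridDomain,
    params: ModelParams,
    config: RunConfig,
    dt: float | None = None,
    solver: "DiffusionSolver | None" = None,
) -> tuple[SimulationState, StepReport]:
    """One split step: route/accumulate, diffuse, sink sweep, source sweep."""
    if dt is None:
        dt = resolve_dt(domain, params, config)
    h_old = state.h
    down, up = route_both(h_old, domain)
    if config.transport == "mfd":
        a_minus = accumulate_mfd(h_old, domain, "descent")
        a_plus = accumulate_mfd(h_old, domain, "ascent")
    else:
        a_minus = accumulate(down, domain)
        a_plus = accumulate(up, domain)
    pits = down.interior_outlet_count(domain) + up.interior_outlet_count(domain)

    h = diffusion_step(h_old, domain, params.D, dt, mode=config.diffusion, solver=solver)

    k_sink = params.K * params.r_minus**params.m_minus
    k_src = params.K * params.r_plus**params.m_plus
    sweeps = (
        ("sink", "source") if config.sweep_order == "sink_first" else ("source", "sink")
    )
    newton_iters = 0
    for name in sweeps:
        if name == "sink":
            h, it = reaction_sweep(
                h, down, a_minus, k_sink, params.m_minus, params.n_minus, dt, -1,
                domain, config.newton_tol, config.newton_max_iter,
            )
        else:
            h, it = reaction_sweep(
                h, up, a_plus, k_src, params.m_plus, params.n_plus, dt, +1,
                domain, config.newton_tol, config.newton_max_iter,
            )
        newton_iters = max(newton_iters, it)
    apply_fixed_faces(h, domain, params.H)

    dh_max = float(np.max(np.abs(h - h_old))) / dt
    new_state = SimulationState(
        h=h,
        a_plus=a_plus,
        a_minus=a_minus,
        t=state.t + dt,
        n_iter=state.n_iter + 1,
        converged=False,
        pit_count=pits,
    )
    report = StepReport(
        dh_max=dh_max, dt_used=dt, sweeps_order=sweeps,
        newton_iters=newton_iters, pit_count=pits,
    )
    return new_state, report


def run_to_steady(
    state: SimulationState,
    domain: GridDomain,
    params: ModelParams,
    config: RunConfig,
) -> tuple[SimulationState, np.ndarray]:
    """Iterate steps until max|dh|/dt < steady_tol or max_iter.

    Returns the final state (converged flag set accordingly; non-convergence
    is reported, not raised) and the trace of dh_max per step.
    """
    dt = resolve_dt(domain, params, config)
    solver = None
    if config.diffusion == "implicit":
        solver = DiffusionSolver(domain, params.D, dt)
    trace = []
    warned_pits = False
    for _ in range(config.max_iter):
        state, report = step(state, domain, params, config, dt=dt, solver=solver)
        trace.append(report.dh_max)
        if config.log_every and state.n_iter % config.log_every == 0:
            logger.info("iter=%d t=%.4g dh_max=%.4g", state.n_iter, state.t, report.dh_max)
        if report.pit_count > 0 and not warned_pits:
            logger.warning("iter=%d: %d interior routing outlets (pits); "
                           "further pit warnings suppressed for this run",
                           state.n_iter, report.pit_count)
            warned_pits = True
        if report.dh_max < config.steady_tol:
            state.converged = True
            break
    else:
        logger.warning("run_to_steady: not converged after %d iterations "
                       "(dh_max=%.4g, tol=%.4g)",
                       config.max_iter, trace[-1] if trace else float("nan"),
                       config.steady_tol)
    return state, np.asarray(trace)
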