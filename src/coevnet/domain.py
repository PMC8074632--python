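"""Grid geometry, model parameters, run controls and simulation state.

The model lives on a rectangular (2D) or parallelepiped (3D) raster. One axis
-- ``axis_flow`` -- connects the two faces with fixed values of the mediating
scalar field h: the entry face ``Omega_t`` (h = H, flow index 0) and the exit
face ``Omega_b`` (h = 0, last flow index). All remaining faces are closed
(zero-Neumann in h, no material crosses them).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "GridDomain",
    "ModelParams",
    "RunConfig",
    "SimulationState",
    "make_domain",
    "init_state",
]


@dataclass(frozen=True)
class GridDomain:
    """Raster geometry and boundary-face roles.

    Parameters
    ----------
    shape
        Grid extents, e.g. ``(100, 500)`` for a width-100, length-500
        rectangle with flow along the second axis.
    spacing
        Grid step (one unit by default; the model is run on a unit raster).
    axis_flow
        Index of the axis connecting the fixed-value faces.
    """

    shape: tuple[int, ...]
    spacing: float = 1.0
    axis_flow: int = 1

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) not in (2, 3):
            raise ValueError(f"domain must be 2D or 3D, got shape {shape}")
        if any(n < 3 for n in shape):
            raise ValueError(
                f"degenerate domain shape {shape}: need at least 3 cells along every axis"
            )
        if not 0 <= self.axis_flow < len(shape):
            raise ValueError(f"axis_flow={self.axis_flow} invalid for shape {shape}")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    @property
    def n_flow(self) -> int:
        """Number of cells along the flow axis."""
        return self.shape[self.axis_flow]

    @property
    def length(self) -> float:
        """Domain extent L along the flow axis (reference scale for CI)."""
        return self.n_flow * self.spacing

    @property
    def width(self) -> float:
        """Smallest transverse extent (used by the channel-count threshold)."""
        return min(n for ax, n in enumerate(self.shape) if ax != self.axis_flow) * self.spacing

    def face_roles(self) -> dict[str, str]:
        roles = {}
        for ax in range(self.ndim):
            if ax == self.axis_flow:
                roles[f"axis{ax}_low"] = "fixed_high"   # Omega_t, h = H
                roles[f"axis{ax}_high"] = "fixed_low"   # Omega_b, h = 0
            else:
                roles[f"axis{ax}_low"] = "closed"
                roles[f"axis{ax}_high"] = "closed"
        return roles

    def y_hat(self) -> np.ndarray:
        """Dimensionless coordinate along the flow axis, 0 on Omega_t, 1 on Omega_b."""
        n = self.n_flow
        return np.arange(n) / (n - 1)

    def fixed_mask(self) -> np.ndarray:
        """Boolean grid mask of the two fixed-value faces."""
        mask = np.zeros(self.shape, dtype=bool)
        idx_lo = [slice(None)] * self.ndim
        idx_lo[self.axis_flow] = 0
        idx_hi = [slice(None)] * self.ndim
        idx_hi[self.axis_flow] = self.shape[self.axis_flow] - 1
        mask[tuple(idx_lo)] = True
        mask[tuple(idx_hi)] = True
        return mask

    def face_index(self, which: Literal["top", "bottom"]) -> tuple:
        """Grid index tuple selecting Omega_t ("top", h=H) or Omega_b ("bottom", h=0)."""
        idx = [slice(None)] * self.ndim
        idx[self.axis_flow] = 0 if which == "top" else self.shape[self.axis_flow] - 1
        return tuple(idx)


@dataclass(frozen=True)
class ModelParams:
    """Spatially uniform coefficients of the scalar-field evolution equation.

    dh/dt = D lap(h) + K (r+ a+)^m+ |grad h|^n+  -  K (r- a-)^m- |grad h|^n-
    """

    K: float
    D: float = 1.0
    r_plus: float = 1.0
    r_minus: float = 1.0
    m_plus: float = 1.0
    m_minus: float = 1.0
    n_plus: float = 1.0
    n_minus: float = 1.0
    H: float = 1.0

    def __post_init__(self) -> None:
        if self.K <= 0 and self.K != 0.0:
            raise ValueError("K must be >= 0 (K=0 switches the feedback off)")
        if self.K < 0:
            raise ValueError("K must be non-negative")
        if self.D <= 0:
            raise ValueError("D must be positive")
        if self.H <= 0:
            raise ValueError("H must be positive")
        for name in ("m_plus", "m_minus", "n_plus", "n_minus"):
            if getattr(self, name) <= 0:
                raise ValueError(f"exponent {name} must be positive")
        for name in ("r_plus", "r_minus"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be non-negative")

    @property
    def unit_exponents(self) -> bool:
        return (self.m_plus == self.m_minus == self.n_plus == self.n_minus == 1.0)


@dataclass(frozen=True)
class RunConfig:
    """Time stepping, convergence and initial-condition controls.

    ``dt="auto"`` picks 0.9x the explicit CFL bound when ``diffusion`` is
    explicit, and a coarse L^2/(10000 D) step when it is implicit (the
    reaction sweeps are unconditionally stable, so dt is diffusion-limited).
    ``noise_amplitude`` is the dimensionless u_r: i.i.d. uniform noise on
    [0, u_r*H) added to the initial linear ramp.
    """

    dt: float | str = "auto"
    max_iter: int = 50_000
    steady_tol: float = 1e-8
    noise_amplitude: float = 1e-3
    seed: int = 0
    mode_label: Literal["problem_I", "problem_II"] = "problem_II"
    diffusion: Literal["explicit", "implicit"] = "explicit"
    transport: Literal["mfd", "d8"] = "mfd"
    sweep_order: Literal["sink_first", "source_first"] = "sink_first"
    newton_tol: float = 1e-12
    newton_max_iter: int = 50
    log_every: int = 0

    def __post_init__(self) -> None:
        if self.steady_tol <= 0:
            raise ValueError("steady_tol must be positive")
        if self.noise_amplitude < 0:
            raise ValueError("noise amplitude u_r must be >= 0")
        if isinstance(self.dt, str) and self.dt != "auto":
            raise ValueError("dt must be a positive number or 'auto'")
        if not isinstance(self.dt, str) and self.dt <= 0:
            raise ValueError("dt must be a positive number or 'auto'")
        if self.mode_label not in ("problem_I", "problem_II"):
            raise ValueError("mode_label must be 'problem_I' or 'problem_II'")
        if self.diffusion not in ("explicit", "implicit"):
            raise ValueError("diffusion must be 'explicit' or 'implicit'")
        if self.transport not in ("mfd", "d8"):
            raise ValueError("transport must be 'mfd' or 'd8'")
        if self.sweep_order not in ("sink_first", "source_first"):
            raise ValueError("sweep_order must be 'sink_first' or 'source_first'")


@dataclass
class SimulationState:
    """Fields and bookkeeping of one simulation.

    ``pit_count`` is the number of interior routing outlets (local minima of h
    for descent plus local maxima for ascent) found at the last routing pass;
    diffusion normally keeps it at zero.
    """

    h: np.ndarray
    a_plus: np.ndarray
    a_minus: np.ndarray
    t: float = 0.0
    n_iter: int = 0
    converged: bool = False
    pit_count: int = 0

    def copy(self) -> "SimulationState":
        return SimulationState(
            h=self.h.copy(),
            a_plus=self.a_plus.copy(),
            a_minus=self.a_minus.copy(),
            t=self.t,
            n_iter=self.n_iter,
            converged=self.converged,
            pit_count=self.pit_count,
        )


def make_domain(shape, spacing: float = 1.0, axis_flow: int = 1) -> GridDomain:
    """Build a validated grid domain with face roles assigned.

    The fixed-value faces sit at index 0 (h = H) and the last index (h = 0)
    of ``axis_flow``; every other face is closed.
    """
    return GridDomain(shape=tuple(shape), spacing=spacing, axis_flow=axis_flow)


def apply_fixed_faces(h: np.ndarray, domain: GridDomain, H: float) -> None:
    """Re-impose h = H on Omega_t and h = 0 on Omega_b, in place."""
    h[domain.face_index("top")] = H
    h[domain.face_index("bottom")] = 0.0


def linear_ramp(domain: GridDomain, H: float) -> np.ndarray:
    """The non-channelized reference profile h = H (1 - y_hat)."""
    prof = H * (1.0 - domain.y_hat())
    shape = [1] * domain.ndim
    shape[domain.axis_flow] = domain.n_flow
    return np.broadcast_to(prof.reshape(shape), domain.shape).copy()


def init_state(domain: GridDomain, params: ModelParams, config: RunConfig) -> SimulationState:
    """Linear ramp plus seeded uniform noise, with densities from one routing pass.

    Noise ~ U[0, u_r * H) is added at every cell except the two fixed faces,
    so the boundary values stay exact. The same (shape, seed, u_r) always
    produces a bit-identical field.
    """
    from .routing import solve_densities  # local import: routing depends on domain

    h = linear_ramp(domain, params.H)
    if config.noise_amplitude > 0:
        rng = np.random.default_rng(config.seed)
        noise = rng.uniform(0.0, config.noise_amplitude * params.H, size=domain.shape)
        noise[domain.fixed_mask()] = 0.0
        h = h + noise
    apply_fixed_faces(h, domain, params.H)
    a_plus, a_minus, pit_count = solve_densities(h, domain, method=config.transport)
    return SimulationState(h=h, a_plus=a_plus, a_minus=a_minus, pit_count=pit_count)
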