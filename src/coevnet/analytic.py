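"""Non-dimensional indices and closed-form oracles for the non-channelized state.

The behaviour of the model is governed by two dimensionless channelization
indices, one per material:

    CI_pm = K r_pm^m_pm L^(2 + m_pm - n_pm) / (D H^(1 - n_pm)),

measuring the feedback strength of each source/sink term against diffusion
over the domain scale L. Below the critical index the steady transect profile
is smooth and has the closed form (m = n = 1)

    h_hat(y) = [erf(c-) - erf((CI- y - CI+ (1-y)) / s)] / [erf(c-) + erf(c+)],

with s = sqrt(2 (CI+ + CI-)), c_pm = CI_pm / s, which solves
h'' + CI- y h' - CI+ (1-y) h' = 0 with h_hat(0)=1, h_hat(1)=0. The
non-channelized densities are a_hat+ = 1 - y, a_hat- = y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .domain import ModelParams

__all__ = [
    "DimensionlessIndices",
    "channelization_indices",
    "params_from_indices",
    "nonchannelized_densities",
    "closed_form_profile",
    "steady_residual_1d",
    "TwoFieldState",
    "two_field_reduce",
]


@dataclass(frozen=True)
class DimensionlessIndices:
    CI_plus: float
    CI_minus: float
    L: float
    H: float
    D: float

    def __post_init__(self):
        if self.CI_plus < 0 or self.CI_minus < 0:
            raise ValueError("channelization indices must be non-negative")


def channelization_indices(params: ModelParams, L: float) -> DimensionlessIndices:
    """CI+- for a parameter set and domain scale L."""
    if L <= 0:
        raise ValueError("L must be positive")
    if params.D <= 0:
        raise ValueError("D must be positive")
    ci_p = (
        params.K * params.r_plus**params.m_plus
        * L ** (2.0 + params.m_plus - params.n_plus)
        / (params.D * params.H ** (1.0 - params.n_plus))
    )
    ci_m = (
        params.K * params.r_minus**params.m_minus
        * L ** (2.0 + params.m_minus - params.n_minus)
        / (params.D * params.H ** (1.0 - params.n_minus))
    )
    return DimensionlessIndices(CI_plus=ci_p, CI_minus=ci_m, L=L, H=params.H, D=params.D)


def params_from_indices(
    ci_plus: float,
    ci_minus: float,
    L: float,
    D: float = 1.0,
    H: float = 1.0,
    m_plus: float = 1.0,
    m_minus: float = 1.0,
    n_plus: float = 1.0,
    n_minus: float = 1.0,
) -> ModelParams:
    """Dimensional parameters realizing given CI+-.

    Convention: r- = 1, so K is fixed by CI- and r+ absorbs the ratio. If
    CI- = 0, the roles swap (r+ = 1, r- = 0).
    """
    if ci_plus < 0 or ci_minus < 0:
        raise ValueError("channelization indices must be non-negative")
    if L <= 0 or D <= 0 or H <= 0:
        raise ValueError("L, D, H must be positive")
    if ci_minus > 0:
        K = ci_minus * D * H ** (1.0 - n_minus) / L ** (2.0 + m_minus - n_minus)
        r_minus = 1.0
        r_plus = (
            ci_plus * D * H ** (1.0 - n_plus) / (K * L ** (2.0 + m_plus - n_plus))
        ) ** (1.0 / m_plus)
    elif ci_plus > 0:
        K = ci_plus * D * H ** (1.0 - n_plus) / L ** (2.0 + m_plus - n_plus)
        r_plus = 1.0
        r_minus = 0.0
    else:
        K, r_plus, r_minus = 0.0, 1.0, 1.0
    return ModelParams(
        K=K, D=D, r_plus=r_plus, r_minus=r_minus, H=H,
        m_plus=m_plus, m_minus=m_minus, n_plus=n_plus, n_minus=n_minus,
    )


def nonchannelized_densities(y_hat):
    """Dimensionless smooth-state densities (a_hat+, a_hat-) = (1-y, y)."""
    y = np.asarray(y_hat, dtype=float)
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("y_hat must lie in [0, 1]")
    return 1.0 - y, y.copy()


def closed_form_profile(y_hat, ci_plus: float, ci_minus: float):
    """Closed-form smooth profile (h_hat, |h_hat'|) at y_hat for m = n = 1.

    The CI+ = CI- = 0 limit is the linear ramp (the printed formula is 0/0
    there); negative indices are rejected.
    """
    if ci_plus < 0 or ci_minus < 0:
        raise ValueError("channelization indices must be non-negative")
    y = np.asarray(y_hat, dtype=float)
    scalar = y.ndim == 0
    y = np.atleast_1d(y)
    total = ci_plus + ci_minus
    if total == 0.0:
        h = 1.0 - y
        s = np.ones_like(y)
    else:
        root = np.sqrt(2.0 * total)
        arg = (ci_minus * y - ci_plus * (1.0 - y)) / root
        denom = erf(ci_minus / root) + erf(ci_plus / root)
        h = (erf(ci_minus / root) - erf(arg)) / denom
        s = np.exp(-(arg**2)) * np.sqrt(2.0 * total / np.pi) / denom
    if scalar:
        return float(h[0]), float(s[0])
    return h, s


def steady_residual_1d(h_profile, ci_plus: float, ci_minus: float) -> np.ndarray:
    """Central-difference residual of h'' + CI- y h' - CI+ (1-y) h' = 0.

    ``h_profile`` must be sampled on a uniform y_hat grid spanning [0, 1];
    returns the residual at the interior points. The closed form converges
    to zero residual at second order under grid refinement.
    """
    h = np.asarray(h_profile, dtype=float)
    if h.ndim != 1 or h.size < 5:
        raise ValueError("h_profile must be a 1D array with at least 5 samples")
    n = h.size
    dy = 1.0 / (n - 1)
    y = np.arange(1, n - 1) * dy
    d1 = (h[2:] - h[:-2]) / (2.0 * dy)
    d2 = (h[2:] - 2.0 * h[1:-1] + h[:-2]) / dy**2
    return d2 + ci_minus * y * d1 - ci_plus * (1.0 - y) * d1


@dataclass
class TwoFieldState:
    """Signed density a* = (r+ a+ - r- a-)/(r+ + r-) and K* = K (r+ + r-).

    Valid only for unit exponents; the reduction is exact in the interior but
    its boundary conditions require the three-field solution, so it serves as
    a forward cross-check only.
    """

    a_star: np.ndarray
    K_star: float


def two_field_reduce(
    a_plus: np.ndarray,
    a_minus: np.ndarray,
    r_plus: float,
    r_minus: float,
    K: float,
    exponents: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
) -> TwoFieldState:
    """Reduce the three-field densities to the two-field (a*, K*) form."""
    if any(e != 1.0 for e in exponents):
        raise ValueError("the two-field reduction requires unit exponents m+-, n+-")
    if r_plus + r_minus <= 0:
        raise ValueError("r+ + r- must be positive")
    a_star = (r_plus * np.asarray(a_plus) - r_minus * np.asarray(a_minus)) / (
        r_plus + r_minus
    )
    return TwoFieldState(a_star=a_star, K_star=K * (r_plus + r_minus))
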