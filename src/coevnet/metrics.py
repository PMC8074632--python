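"""Pattern quantification of steady states.

Quantities reported per steady state: the total length L_i of the interface
a+ = a- separating supply- from drainage-dominated regions (marching squares
with linear interpolation, grid units); the main-channel count N_c (maximum
over the two materials of the number of boundary-originating channels longer
than half the domain width); per-face boundary signals; the transect-mean
profile; and a channelization flag based on the deviation of the mean profile
from the smooth closed form and on the transverse spread of h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import NamedTuple

import numpy as np
from scipy.signal import find_peaks
from skimage.measure import find_contours

from .analytic import DimensionlessIndices, closed_form_profile, params_from_indices
from .domain import GridDomain, RunConfig, SimulationState, init_state
from .evolution import run_to_steady
from .routing import RoutingMap, accumulate, route, route_both

__all__ = [
    "PatternReport",
    "interface_length",
    "count_main_channels",
    "mean_transect_profile",
    "detect_channelization",
    "ChannelizationResult",
    "pattern_report",
    "critical_ci_search",
    "CriticalSearchResult",
    "largest_conduit",
]


def mean_transect_profile(h: np.ndarray, domain: GridDomain) -> np.ndarray:
    """Average of h over the transverse axes, as a function of flow index."""
    axes = tuple(ax for ax in range(domain.ndim) if ax != domain.axis_flow)
    return np.asarray(h, dtype=float).mean(axis=axes)


def transverse_std_profile(h: np.ndarray, domain: GridDomain) -> np.ndarray:
    axes = tuple(ax for ax in range(domain.ndim) if ax != domain.axis_flow)
    return np.asarray(h, dtype=float).std(axis=axes)


def interface_length(
    a_plus: np.ndarray, a_minus: np.ndarray, domain: GridDomain
) -> tuple[float, list[np.ndarray]]:
    """Length of the a+ = a- interface by marching squares.

    Returns (L_i, polylines); L_i is the summed Euclidean length of all
    zero-level contour segments of a+ - a-, in grid units (spacing-scaled).
    Defined for 2D fields only.
    """
    if domain.ndim != 2:
        raise ValueError("interface length is defined for 2D domains only")
    d = np.asarray(a_plus, dtype=float) - np.asarray(a_minus, dtype=float)
    if d.min() > 0 or d.max() < 0:
        return 0.0, []
    contours = find_contours(d, 0.0)
    total = 0.0
    for poly in contours:
        seg = np.diff(poly, axis=0)
        total += float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))
    return total * domain.spacing, contours


def _face_flat_indices(domain: GridDomain, which: str) -> np.ndarray:
    ids = np.arange(domain.n_cells).reshape(domain.shape)
    return ids[domain.face_index(which)].ravel()


def _neighbors(flat: int, shape: tuple[int, ...]) -> list[tuple[int, float]]:
    idx = np.unravel_index(flat, shape)
    out = []
    for off in product((-1, 0, 1), repeat=len(shape)):
        if all(o == 0 for o in off):
            continue
        nb = tuple(i + o for i, o in zip(idx, off))
        if all(0 <= v < n for v, n in zip(nb, shape)):
            out.append(
                (int(np.ravel_multi_index(nb, shape)), float(np.sqrt(sum(o * o for o in off))))
            )
    return out


def _max_donor_trace(
    a_flat: np.ndarray,
    routing: RoutingMap,
    domain: GridDomain,
    start: int,
    a_thresh: float | None,
) -> tuple[list[int], float]:
    """Ascend the flow tree from ``start`` along maximal-donor links.

    Stops when no donor exists or (if ``a_thresh`` is set) no donor carries
    density >= a_thresh. Returns (path cells, arc length in grid units).
    """
    recv = routing.receiver
    path = [start]
    length = 0.0
    cur = start
    for _ in range(routing.n_cells):
        best = -1
        best_a = -np.inf
        best_d = 0.0
        for nb, d in _neighbors(cur, domain.shape):
            if recv[nb] != cur:
                continue
            if a_thresh is not None and a_flat[nb] < a_thresh:
                continue
            if a_flat[nb] > best_a:
                best = nb
                best_a = float(a_flat[nb])
                best_d = d
        if best < 0:
            break
        length += best_d * domain.spacing
        path.append(best)
        cur = best
    return path, length


def count_main_channels(
    a: np.ndarray,
    routing: RoutingMap,
    domain: GridDomain,
    min_length: float | None = None,
    a_thresh: float | None = None,
) -> tuple[int, list[list[int]]]:
    """Number of main channels of one material, traced from its exit face.

    Seeds are the local maxima of the boundary signal (a on the material's
    exit face) that strictly exceed the face mean. Each seed is traced up the
    flow tree along the donor with the largest density, while the donor
    density stays at or above ``a_thresh`` (default spacing * width/2, i.e.
    an upstream cell count of at least half the domain width). A trace counts
    as a main channel if its arc length exceeds ``min_length`` (default
    width/2). Deterministic given the field.
    """
    if domain.ndim != 2:
        raise ValueError("channel counting is defined for 2D domains")
    width = domain.width
    if min_length is None:
        min_length = width / 2.0
    if a_thresh is None:
        a_thresh = domain.spacing * width / 2.0
    face = "bottom" if routing.orientation == "descent" else "top"
    face_ids = _face_flat_indices(domain, face)
    a_flat = np.asarray(a, dtype=float).ravel()
    signal = a_flat[face_ids]
    if signal.max() <= 0:
        return 0, []
    mean = signal.mean()
    peaks, _ = find_peaks(signal)
    peaks = [p for p in peaks if signal[p] > mean]
    trunks = []
    count = 0
    for p in peaks:
        path, length = _max_donor_trace(a_flat, routing, domain, int(face_ids[p]), a_thresh)
        if length > min_length:
            count += 1
            trunks.append(path)
    return count, trunks


class ChannelizationResult(NamedTuple):
    channelized: bool
    deviation: float
    transverse_std: float


def detect_channelization(
    state: SimulationState,
    domain: GridDomain,
    indices: DimensionlessIndices | None = None,
    reference_profile: np.ndarray | None = None,
    eps_dev: float = 5e-3,
    eps_tr: float = 1e-2,
) -> ChannelizationResult:
    """Channelization flag for a converged state.

    ``deviation`` is the RMSE (relative to H) between the simulated
    transect-mean profile and the closed-form smooth profile (unit exponents;
    requires ``indices``) or a supplied ``reference_profile`` in h_hat units.
    The state is flagged channelized if the deviation exceeds ``eps_dev`` or
    the maximum transverse standard deviation of h/H exceeds ``eps_tr`` --
    the latter criterion needs no closed form and handles non-unit exponents.
    """
    H = float(np.asarray(state.h[domain.face_index("top")]).ravel()[0])
    mean_hat = mean_transect_profile(state.h, domain) / H
    tr = float(transverse_std_profile(state.h, domain).max()) / H
    dev = float("nan")
    if indices is not None:
        ref, _ = closed_form_profile(domain.y_hat(), indices.CI_plus, indices.CI_minus)
        dev = float(np.sqrt(np.mean((mean_hat - ref) ** 2)))
    elif reference_profile is not None:
        dev = float(np.sqrt(np.mean((mean_hat - np.asarray(reference_profile)) ** 2)))
    flag = (not np.isnan(dev) and dev > eps_dev) or tr > eps_tr
    return ChannelizationResult(flag, dev, tr)


@dataclass
class PatternReport:
    L_i: float
    N_c: int
    n_supply: int
    n_drainage: int
    boundary_signal_top: np.ndarray
    boundary_signal_bottom: np.ndarray
    mean_profile: np.ndarray
    channelized: bool
    deviation: float = float("nan")
    transverse_std: float = float("nan")
    trunks_supply: list = field(default_factory=list)
    trunks_drainage: list = field(default_factory=list)


def pattern_report(
    state: SimulationState,
    domain: GridDomain,
    indices: DimensionlessIndices | None = None,
) -> PatternReport:
    """Assemble the pattern metrics of one steady state.

    The interface and the boundary signals are computed on the partitioned
    (model) densities; channel counting runs on the single-receiver tree,
    whose upstream-count thresholding it is defined by.
    """
    down, up = route_both(state.h, domain)
    a_minus_tree = accumulate(down, domain)
    a_plus_tree = accumulate(up, domain)
    from .routing import solve_densities

    a_plus, a_minus, _ = solve_densities(state.h, domain, method="mfd")
    n_drainage, trunks_d = count_main_channels(a_minus_tree, down, domain)
    n_supply, trunks_s = count_main_channels(a_plus_tree, up, domain)
    L_i = float("nan")
    if domain.ndim == 2:
        L_i, _ = interface_length(a_plus, a_minus, domain)
    det = detect_channelization(state, domain, indices)
    top = np.asarray(a_plus[domain.face_index("top")], dtype=float).ravel()
    bottom = np.asarray(a_minus[domain.face_index("bottom")], dtype=float).ravel()
    return PatternReport(
        L_i=L_i,
        N_c=max(n_supply, n_drainage),
        n_supply=n_supply,
        n_drainage=n_drainage,
        boundary_signal_top=top,
        boundary_signal_bottom=bottom,
        mean_profile=mean_transect_profile(state.h, domain),
        channelized=det.channelized,
        deviation=det.deviation,
        transverse_std=det.transverse_std,
        trunks_supply=trunks_s,
        trunks_drainage=trunks_d,
    )


@dataclass
class CriticalSearchResult:
    ci_crit: float
    bracket: tuple[float, float]
    probes: list  # (ci, channelized, deviation, transverse_std, converged)


def critical_ci_search(
    domain: GridDomain,
    config: RunConfig,
    lo: float,
    hi: float,
    m: float = 1.0,
    n: float = 1.0,
    tol: float = 0.25,
    D: float = 1.0,
    H: float = 1.0,
    criterion: str = "amplification",
) -> CriticalSearchResult:
    """Bisection for the critical channelization index (CI+ = CI-).

    Every probe initializes the linear-ramp-plus-noise state with the same
    seed and runs to steady state. With ``criterion="amplification"`` (the
    default) a probe counts as channelized when the steady transverse spread
    of h exceeds the spread of the injected initial noise -- i.e. when the
    perturbation was amplified instead of damped, which is the instability
    itself. The transition is sharp (the steady spread jumps by orders of
    magnitude across the critical index), so the result is insensitive to
    the exact comparison level. ``criterion="threshold"`` uses the fixed
    ``detect_channelization`` levels instead. Requires the bracket endpoints
    to be non-channelized (lo) and channelized (hi); bisects until
    hi - lo <= 2 * tol and returns the midpoint with the probe trace.
    """
    probes = []
    # transverse std of U[0, u_r*H) noise relative to H; floor for u_r = 0
    noise_floor = max(config.noise_amplitude / np.sqrt(12.0), 1e-6)

    def probe(ci: float) -> bool:
        params = params_from_indices(
            ci, ci, L=domain.length, D=D, H=H,
            m_plus=m, m_minus=m, n_plus=n, n_minus=n,
        )
        state = init_state(domain, params, config)
        state, _ = run_to_steady(state, domain, params, config)
        idx = None
        if m == 1.0 and n == 1.0:
            idx = DimensionlessIndices(ci, ci, domain.length, H, D)
        det = detect_channelization(state, domain, idx)
        if criterion == "amplification":
            flag = det.transverse_std > noise_floor
        else:
            flag = det.channelized
        probes.append((ci, flag, det.deviation, det.transverse_std,
                       state.converged))
        return flag

    if probe(lo):
        raise ValueError(f"invalid bracket: CI={lo} is already channelized")
    if not probe(hi):
        raise ValueError(f"invalid bracket: CI={hi} is not channelized")
    while hi - lo > 2.0 * tol:
        mid = 0.5 * (lo + hi)
        if probe(mid):
            hi = mid
        else:
            lo = mid
    return CriticalSearchResult(
        ci_crit=0.5 * (lo + hi), bracket=(lo, hi), probes=probes
    )


def largest_conduit(
    state: SimulationState, domain: GridDomain
) -> tuple[list[int], np.ndarray]:
    """Trunk and catchment of the strongest drainage outlet.

    Picks the outlet cell with the largest a-, follows the maximal-donor path
    upstream (the conduit trunk), and returns the full upstream catchment as
    a boolean grid mask.
    """
    down = route(state.h, domain, "descent")
    a_minus = accumulate(down, domain)
    a_flat = a_minus.ravel()
    outlet_ids = np.flatnonzero(down.outlet_mask)
    outlet = int(outlet_ids[np.argmax(a_flat[outlet_ids])])
    trunk, _ = _max_donor_trace(a_flat, down, domain, outlet, a_thresh=None)
    # root of every cell via one downstream-first pass
    member = np.zeros(down.n_cells, dtype=bool)
    member[outlet] = True
    recv = down.receiver
    for c in down.order[::-1]:
        r = recv[c]
        if r != c:
            member[c] = member[r]
    return trunk, member.reshape(domain.shape)
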