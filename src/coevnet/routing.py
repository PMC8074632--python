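"""Quasi-steady transport: steepest-path routing and density accumulation.

The continuity equations for the two materials are solved instantaneously for
a given scalar field h: every cell sends its flow to the single neighbour
along the steepest descent (for the drained material a-) or steepest ascent
(for the supplied material a+, equivalently descent on -h), and the density
is the unit-rate accumulation along the resulting forest, evaluated in
upstream-first (topological) order. With unit spacing and unit rate, a is the
number of cells whose flow path passes through a cell -- the discrete
specific-density convention, so the dimensionless a_hat = a / L.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Literal

import numpy as np

from . import _kernels
from .domain import GridDomain

__all__ = [
    "RoutingMap",
    "route",
    "route_both",
    "accumulate",
    "accumulate_mfd",
    "solve_densities",
]

Orientation = Literal["descent", "ascent"]


@dataclass
class RoutingMap:
    """Receiver forest for one orientation.

    All per-cell arrays are flat (C-order raveled). ``order`` lists every
    cell before its receiver (upstream-first). ``outlet_mask`` marks cells
    that drain to themselves: the absorbing face plus interior pits (descent)
    or peaks (ascent).
    """

    receiver: np.ndarray
    slope: np.ndarray
    distance: np.ndarray
    order: np.ndarray
    orientation: Orientation
    outlet_mask: np.ndarray
    shape: tuple[int, ...]

    @property
    def n_cells(self) -> int:
        return self.receiver.shape[0]

    def interior_outlet_count(self, domain: GridDomain) -> int:
        """Outlets that are not on the orientation's absorbing face (pits/peaks)."""
        face = "bottom" if self.orientation == "descent" else "top"
        face_mask = np.zeros(domain.shape, dtype=bool)
        face_mask[domain.face_index(face)] = True
        return int(np.count_nonzero(self.outlet_mask & ~face_mask.ravel()))


def _finalize(recv, slope, dist, orientation, domain) -> RoutingMap:
    order, n_sorted = _kernels.topo_order(recv)
    if n_sorted != recv.shape[0]:
        raise RuntimeError(
            "cycle detected in receiver graph; steepest-descent routing must be acyclic"
        )
    outlet = recv == np.arange(recv.shape[0])
    return RoutingMap(
        receiver=recv,
        slope=slope,
        distance=dist,
        order=order,
        orientation=orientation,
        outlet_mask=outlet,
        shape=domain.shape,
    )


def route_both(h: np.ndarray, domain: GridDomain) -> tuple[RoutingMap, RoutingMap]:
    """Descent and ascent routing maps for h, computed in one kernel pass."""
    if not np.all(np.isfinite(h)):
        raise ValueError("h contains non-finite values")
    h = np.ascontiguousarray(h, dtype=np.float64)
    if domain.ndim == 2:
        out = _kernels.route_2d(h, domain.axis_flow, domain.spacing)
    else:
        out = _kernels.route_3d(h, domain.axis_flow, domain.spacing)
    recv_d, slope_d, dist_d, recv_a, slope_a, dist_a = out
    return (
        _finalize(recv_d, slope_d, dist_d, "descent", domain),
        _finalize(recv_a, slope_a, dist_a, "ascent", domain),
    )


def route(h: np.ndarray, domain: GridDomain, orientation: Orientation) -> RoutingMap:
    """Steepest-path receiver map for one orientation.

    Each interior cell's receiver is the 8-connected (2D) or 26-connected
    (3D) neighbour maximizing the distance-weighted drop of h (of -h for
    ascent). Cells on the absorbing face -- the flow-end face Omega_b for
    descent, the flow-start face Omega_t for ascent -- and interior cells
    with no strictly downhill neighbour are outlets.
    """
    down, up = route_both(h, domain)
    if orientation == "descent":
        return down
    if orientation == "ascent":
        return up
    raise ValueError(f"unknown orientation {orientation!r}")


def accumulate(routing: RoutingMap, domain: GridDomain, rate: float = 1.0) -> np.ndarray:
    """Unit-rate density: a_i = rate * spacing * (upstream cell count incl. i).

    Returned with the grid shape. Conservation holds exactly: the sum of a
    over outlet cells equals rate * spacing * n_cells.
    """
    a = _kernels.accumulate_flat(routing.receiver, routing.order, rate * domain.spacing)
    return a.reshape(domain.shape)


def accumulate_mfd(
    h: np.ndarray, domain: GridDomain, orientation: Orientation, rate: float = 1.0
) -> np.ndarray:
    """Partitioned (multiple-flow-direction) density for one orientation.

    Flow leaving a cell is split among all strictly downhill neighbours (of
    h for descent, of -h for ascent) in proportion to the distance-weighted
    slope. Unlike the single-receiver accumulation, the density responds
    continuously -- at first order -- to transverse perturbations of h,
    which is what carries the channelization instability; on a quantized
    single-direction tree the linearized response is identically zero. The
    transect totals are identical to the single-direction result, so the
    smooth-state profiles a_hat = 1 - y_hat, y_hat are unchanged.
    """
    if not np.all(np.isfinite(h)):
        raise ValueError("h contains non-finite values")
    if orientation == "descent":
        g = np.ascontiguousarray(h, dtype=np.float64)
        absorb_at_end = True
    elif orientation == "ascent":
        g = np.ascontiguousarray(-np.asarray(h), dtype=np.float64)
        absorb_at_end = False
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    order = np.argsort(g.ravel(), kind="stable")[::-1].copy()
    kern = _kernels.mfd_accumulate_2d if domain.ndim == 2 else _kernels.mfd_accumulate_3d
    a = kern(g, domain.axis_flow, domain.spacing, absorb_at_end, order,
             rate * domain.spacing)
    return a.reshape(domain.shape)


def solve_densities(
    h: np.ndarray,
    domain: GridDomain,
    params=None,
    rate: float = 1.0,
    method: str = "mfd",
) -> tuple[np.ndarray, np.ndarray, int]:
    """Quasi-steady material densities for the current h.

    a- accumulates along descent, a+ along ascent; the mathematics is
    identical for the counter-flow and the co-flow reading of the model (the
    two continuity formulations differ only in sign bookkeeping). By default
    the densities are the partitioned-flow (``method="mfd"``) solution used
    by the evolution equations; ``method="d8"`` gives the single-receiver
    tree view. Returns (a_plus, a_minus, pit_count) where pit_count is the
    total number of interior outlets over both orientations.
    """
    down, up = route_both(h, domain)
    if method == "mfd":
        a_minus = accumulate_mfd(h, domain, "descent", rate)
        a_plus = accumulate_mfd(h, domain, "ascent", rate)
    elif method == "d8":
        a_minus = accumulate(down, domain, rate)
        a_plus = accumulate(up, domain, rate)
    else:
        raise ValueError(f"unknown transport method {method!r}")
    pits = down.interior_outlet_count(domain) + up.interior_outlet_count(domain)
    return a_plus, a_minus, pits


def export_edge_list(routing: RoutingMap, path) -> None:
    """Write the receiver forest as CSV rows (cell_index, receiver_index, slope)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cell_index", "receiver_index", "slope"])
        for c in range(routing.n_cells):
            writer.writerow([c, int(routing.receiver[c]), float(routing.slope[c])])
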