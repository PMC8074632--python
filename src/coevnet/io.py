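"""Configuration files, state checkpoints, VTK export, and test fixtures."""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .analytic import params_from_indices
from .domain import (
    GridDomain,
    ModelParams,
    RunConfig,
    SimulationState,
    init_state,
    linear_ramp,
    make_domain,
)
from .routing import solve_densities

__all__ = [
    "load_config",
    "save_state",
    "load_state",
    "export_vtk",
    "make_fixture",
    "RunManifest",
]

_DOMAIN_KEYS = {"shape", "spacing", "axis_flow"}
_PARAM_KEYS = {
    "K", "D", "H", "r_plus", "r_minus",
    "m_plus", "m_minus", "n_plus", "n_minus",
    "ci_plus", "ci_minus",
}
_RUN_KEYS = {
    "dt", "max_iter", "steady_tol", "noise_amplitude", "seed", "mode_label",
    "diffusion", "transport", "sweep_order", "newton_tol", "newton_max_iter",
    "log_every",
}


def load_config(path) -> tuple[GridDomain, ModelParams, RunConfig]:
    """Parse a TOML config with [domain], [params], [run] sections.

    The [params] section accepts either dimensional coefficients (K, r_plus,
    r_minus, ...) or dimensionless indices (ci_plus, ci_minus) converted with
    the domain length L; giving both is an over-specification error. Unknown
    keys are rejected by name.
    """
    raw = Path(path).read_bytes()
    if not raw.strip():
        raise ValueError(f"config file {path} is empty")
    doc = tomllib.loads(raw.decode())
    for section in ("domain", "params"):
        if section not in doc:
            raise ValueError(f"missing mandatory [{section}] section")
    unknown_sections = set(doc) - {"domain", "params", "run"}
    if unknown_sections:
        raise ValueError(f"unknown config sections: {sorted(unknown_sections)}")

    dsec = doc["domain"]
    if bad := set(dsec) - _DOMAIN_KEYS:
        raise ValueError(f"unknown [domain] keys: {sorted(bad)}")
    if "shape" not in dsec:
        raise ValueError("missing mandatory key: domain.shape")
    domain = make_domain(
        tuple(dsec["shape"]),
        spacing=float(dsec.get("spacing", 1.0)),
        axis_flow=int(dsec.get("axis_flow", 1)),
    )

    psec = dict(doc["params"])
    if bad := set(psec) - _PARAM_KEYS:
        raise ValueError(f"unknown [params] keys: {sorted(bad)}")
    has_ci = "ci_plus" in psec or "ci_minus" in psec
    has_dim = "K" in psec or "r_plus" in psec or "r_minus" in psec
    if has_ci and has_dim:
        raise ValueError(
            "over-specified [params]: give either (K, r_plus, r_minus) or (ci_plus, ci_minus)"
        )
    exps = {k: float(psec.get(k, 1.0)) for k in ("m_plus", "m_minus", "n_plus", "n_minus")}
    if has_ci:
        params = params_from_indices(
            float(psec.get("ci_plus", 0.0)),
            float(psec.get("ci_minus", 0.0)),
            L=domain.length,
            D=float(psec.get("D", 1.0)),
            H=float(psec.get("H", 1.0)),
            **exps,
        )
    else:
        if "K" not in psec:
            raise ValueError("missing mandatory key: params.K (or ci_plus/ci_minus)")
        params = ModelParams(
            K=float(psec["K"]),
            D=float(psec.get("D", 1.0)),
            H=float(psec.get("H", 1.0)),
            r_plus=float(psec.get("r_plus", 1.0)),
            r_minus=float(psec.get("r_minus", 1.0)),
            **exps,
        )

    rsec = dict(doc.get("run", {}))
    if bad := set(rsec) - _RUN_KEYS:
        raise ValueError(f"unknown [run] keys: {sorted(bad)}")
    config = RunConfig(**rsec)
    return domain, params, config


def save_state(path, state: SimulationState, domain: GridDomain) -> None:
    """Checkpoint (h, a+, a-, t, ...) plus grid geometry; .npz or .nc by suffix."""
    path = Path(path)
    meta = dict(
        t=state.t, n_iter=state.n_iter, converged=int(state.converged),
        pit_count=state.pit_count, spacing=domain.spacing, axis_flow=domain.axis_flow,
    )
    if path.suffix == ".nc":
        import xarray as xr

        dims = ("x", "y", "z")[: domain.ndim]
        ds = xr.Dataset(
            {
                "h": (dims, state.h),
                "a_plus": (dims, state.a_plus),
                "a_minus": (dims, state.a_minus),
            },
            attrs=meta,
        )
        ds.to_netcdf(path, engine="scipy")
    else:
        np.savez(
            path,
            h=state.h, a_plus=state.a_plus, a_minus=state.a_minus,
            **{k: np.asarray(v) for k, v in meta.items()},
        )


def load_state(path) -> tuple[SimulationState, GridDomain]:
    """Inverse of save_state; returns the state together with its grid."""
    path = Path(path)
    try:
        if path.suffix == ".nc":
            import xarray as xr

            ds = xr.open_dataset(path, engine="scipy")
            h = np.asarray(ds["h"])
            a_plus = np.asarray(ds["a_plus"])
            a_minus = np.asarray(ds["a_minus"])
            meta = dict(ds.attrs)
            ds.close()
        else:
            with np.load(path) as z:
                h = z["h"]
                a_plus = z["a_plus"]
                a_minus = z["a_minus"]
                meta = {k: z[k][()] for k in
                        ("t", "n_iter", "converged", "pit_count", "spacing", "axis_flow")}
    except Exception as exc:  # corrupt or truncated file
        raise ValueError(f"cannot read state file {path}: {exc}") from exc
    domain = make_domain(h.shape, spacing=float(meta["spacing"]),
                         axis_flow=int(meta["axis_flow"]))
    state = SimulationState(
        h=h, a_plus=a_plus, a_minus=a_minus,
        t=float(meta["t"]), n_iter=int(meta["n_iter"]),
        converged=bool(meta["converged"]), pit_count=int(meta["pit_count"]),
    )
    return state, domain


def export_vtk(path, state: SimulationState, domain: GridDomain) -> None:
    """Legacy ASCII VTK structured-points export of h, a+, a- (2D or 3D)."""
    shape = domain.shape if domain.ndim == 3 else (*domain.shape, 1)
    # VTK varies x fastest; C-raveled arrays vary the last axis fastest.
    dims = shape[::-1]
    n = int(np.prod(shape))
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("coevnet fields\nASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {dims[0]} {dims[1]} {dims[2]}\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {domain.spacing} {domain.spacing} {domain.spacing}\n")
        fh.write(f"POINT_DATA {n}\n")
        for name, arr in (("h", state.h), ("a_plus", state.a_plus),
                          ("a_minus", state.a_minus)):
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.asarray(arr, dtype=float).ravel().tofile(fh, sep="\n", format="%.10g")
            fh.write("\n")


@dataclass
class RunManifest:
    """Provenance record written next to every CLI run's outputs."""

    config: dict
    seed: int
    package_version: str
    outputs: dict
    convergence: dict

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _carved_channel_state(domain: GridDomain, H: float, channels) -> SimulationState:
    """Synthetic channelized densities on a plane ramp (test fixture).

    The scalar field is the noise-free ramp, so routing is straight columns
    along the flow axis. The drainage density is overridden (synthetic -- not
    the accumulation of h): channel columns at transverse position ``pos``
    carry a-(flow index j) = w * (j + 1), emulating a channel that collects a
    basin of width ``w`` per unit advance; all other columns carry the plain
    single-column accumulation. With the default half-width threshold
    a_thresh = W/2, the traced channel length is (n_flow - 1) - ceil(W/(2w) - 1)
    grid units, so ``w`` controls whether a channel counts as main. The
    supply density is the mirror image.
    """
    if domain.ndim != 2:
        raise ValueError("carved_channels fixture is 2D")
    h = linear_ramp(domain, H)
    a_plus, a_minus, pits = solve_densities(h, domain, method="d8")
    flow_ax = domain.axis_flow
    nf = domain.n_flow
    ramp_idx = np.arange(nf) + 1.0
    for pos, w in channels:
        col = [slice(None)] * 2
        col[1 - flow_ax] = pos
        prof = w * ramp_idx
        a_minus[tuple(col)] = prof
        a_plus[tuple(col)] = prof[::-1]
    return SimulationState(h=h, a_plus=a_plus, a_minus=a_minus, pit_count=pits,
                           converged=True)


def make_fixture(kind: str, shape, seed: int = 0, **kwargs):
    """Deterministic synthetic states with known ground truth.

    kinds: ramp, ramp_noise, tilted_plane, carved_channels, sin_interface.
    Returns (state, domain).
    """
    axis_flow = kwargs.pop("axis_flow", 1)
    spacing = kwargs.pop("spacing", 1.0)
    H = kwargs.pop("H", 1.0)
    domain = make_domain(shape, spacing=spacing, axis_flow=axis_flow)
    params = ModelParams(K=0.0, H=H)

    if kind == "ramp" or kind == "tilted_plane":
        config = RunConfig(noise_amplitude=0.0, seed=seed, transport="d8")
        state = init_state(domain, params, config)
    elif kind == "ramp_noise":
        u_r = kwargs.pop("u_r", 1e-3)
        config = RunConfig(noise_amplitude=u_r, seed=seed, transport="d8")
        state = init_state(domain, params, config)
    elif kind == "carved_channels":
        channels = kwargs.pop("channels", [(shape[0] // 2, 10.0)])
        state = _carved_channel_state(domain, H, channels)
    elif kind == "sin_interface":
        # synthetic density difference with an analytically known zero set:
        # d = x - x0 - amp * sin(2 pi f y_hat) on a 2D grid
        if domain.ndim != 2:
            raise ValueError("sin_interface fixture is 2D")
        amp = kwargs.pop("amp", 5.0)
        freq = kwargs.pop("freq", 2.0)
        tr_ax = 1 - domain.axis_flow
        i0 = np.arange(domain.shape[0], dtype=float).reshape(-1, 1)
        i1 = np.arange(domain.shape[1], dtype=float).reshape(1, -1)
        y_hat_grid = (i1 if domain.axis_flow == 1 else i0) / (domain.n_flow - 1)
        x_grid = i0 if tr_ax == 0 else i1
        center = (domain.shape[tr_ax] - 1) / 2.0
        d = x_grid - center - amp * np.sin(2 * np.pi * freq * y_hat_grid)
        d = np.broadcast_to(d, domain.shape).copy()
        base = float(np.abs(d).max()) + 1.0
        state = SimulationState(
            h=linear_ramp(domain, H),
            a_plus=base + d / 2.0,
            a_minus=base - d / 2.0,
            converged=True,
        )
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    if kwargs:
        raise TypeError(f"unused fixture arguments: {sorted(kwargs)}")
    return state, domain
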