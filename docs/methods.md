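# Methods

## Model

`coevnet` integrates a three-field model of coupled supply and drainage
network formation on a rectangular (2D) or parallelepiped (3D) raster. A
mediating scalar field h — the elevation of a hypothetical landscape in 2D,
a chemical-signal strength in 3D — evolves by diffusion plus nonlinear
feedback from two material densities:

    dh/dt = D ∇²h + K (r₊ a₊)^m₊ |∇h|^n₊ − K (r₋ a₋)^m₋ |∇h|^n₋

The densities a₊ (supply) and a₋ (drainage) are quasi-steady solutions of
the continuity equations ∇·(a± v±) = ∓1 with unit-speed velocities along
the gradient of h: a₋ drains down-gradient and erodes (sink term), a₊
collects up-gradient — equivalently down-gradient of the inverted field —
and accretes (source term). The same equations describe a counter-flowing
drainage pair or a co-flowing supply-and-drainage pair; only the sign
bookkeeping differs.

Boundary conditions: h is fixed at H on the entry face Ω_t and 0 on the
exit face Ω_b; all other faces are zero-Neumann in h (closed to material).
The densities obey a₊(Ω_b) = a₋(Ω_t) = 0, which the accumulation satisfies
by construction (no donors upstream of an entry face).

After scaling x by the flow-axis extent L, h by H and t by L²/D, the system
is governed by two dimensionless channelization indices

    CI± = K r±^m± L^(2+m±−n±) / (D H^(1−n±)).

Below a critical CI the steady state is smooth, with transect profiles
a₊ = (1−ŷ)L, a₋ = ŷL and, for unit exponents, the closed-form ĥ(ŷ) built
from error functions (implemented in `coevnet.analytic`, re-derived from
the steady 1D balance and cross-checked in the tests by quadrature and
numerical differentiation). Above it, the smooth solution is unstable and
discrete channels form: supply channels on ridges of h, drainage channels
in valleys.

## Discretization

* Grid: unit-spacing raster (spacing is configurable); five/seven-point
  Laplacian; closed faces by mirrored ghost cells.
* Diffusion sub-step: explicit under a CFL guard (`dt ≤ Δ²/(2·dim·D)`,
  auto-dt = 0.9× bound) or backward Euler with a sparse LU factorized once
  per run (`diffusion="implicit"`). The implicit mode exists because the
  diffusive relaxation time of the 100×500 verification domain is ~0.6 L²/D
  ≈ 1.5·10⁵ time units: at the CFL step this is ~7·10⁵ iterations, while
  the auto implicit step dt = L²/(10⁴D) reaches steady state in a few
  thousand. Channelized steady states were checked to be consistent between
  dt = L²/10⁴ and a 5× smaller step, and smooth profiles against the
  closed form (RMSE ~10⁻⁴ H at CI = 1).
* Reaction sub-steps: the sink term is integrated implicitly in
  receiver-first (topological) order along the steepest-descent tree; each
  cell solves a scalar equation whose downstream value is already updated —
  closed form for n = 1, guarded Newton with bisection fallback on
  [h_recv, h_old] otherwise. The slope factor is the routing slope to the
  receiver (never negative). The source term is the same sweep applied to
  −h with the ascent tree — the exact discrete form of the ridge/valley
  duality — executed after the sink sweep (order recorded; swapping it
  changes steady states at O(dt), which is tested).
* Quasi-steady transport: densities are fully recomputed from the current h
  every step; no density memory.

## Transport: partitioned flow vs. single-receiver tree

Two discrete solutions of the continuity equations are provided.

The **single-receiver (D8) tree** sends each cell's flow to its steepest
8-connected (26-connected in 3D) neighbour; the density is the upstream
cell count times the spacing (the discrete specific-density convention, so
â = a/L). This view backs the routing-map exports, trunk tracing, channel
counting and conduit extraction, and is verified cell-for-cell against a
brute-force recursive oracle in the tests.

The **partitioned (MFD) solution** splits each cell's flow among all
strictly downhill neighbours in proportion to the distance-weighted slope.
This is the default transport inside the evolution equations, and the
choice is load-bearing: the channelization instability operates through the
first-order response of the drainage density to transverse perturbations of
h. On a quantized single-direction tree that response is identically zero
below a finite capture amplitude (~0.4 × slope × Δ), and numerical
experiments with tree transport show the smooth state remaining stable at
converged time steps for every index tested (CI ≤ 25 on the 100×500 grid) —
apparent channels appear only as large-time-step artifacts. With
partitioned transport the instability is sharp and independent of the
noise amplitude, as it must be for a genuine linear instability: at CI = 10
the transverse structure saturates at the same amplitude whether seeded
with u_r = 10⁻³ or 10⁻⁴, while below onset perturbations decay to the
10⁻¹⁴ level. Transect totals of the two transports are identical, so the
smooth-state profiles are unaffected. Both accumulations remain loop-less
directed acyclic graphs handled by the same upstream-first ordering.

One consequence of partitioned transport: the closed side walls carry a
small deterministic density deficit (flow cannot be partitioned through a
wall), which leaves a weak lateral signature in h near the walls. On
100-cell-wide domains it is orders of magnitude below the instability
signal; on very narrow domains at high CI it can itself nucleate channels
without any noise.

## Channelization detection and the critical index

`detect_channelization` flags a steady state when the RMSE of its
transect-mean profile against the closed form exceeds 5·10⁻³ H, or the
maximum transverse standard deviation of h exceeds 10⁻² H (defaults; the
transverse criterion also covers non-unit exponents, where no closed form
is printed).

`critical_ci_search` bisects CI (with CI₊ = CI₋) between a smooth and a
channelized endpoint, re-initializing every probe with the same seed. Its
default probe criterion is **amplification**: a state counts as channelized
when its steady transverse spread exceeds the spread of the injected
initial noise (u_r H/√12), i.e. when the smooth solution demonstrably
failed to damp the perturbation. This detects the stability bifurcation
itself and is insensitive to the comparison level, because the steady
spread jumps by roughly two orders of magnitude across the transition
(e.g. 2·10⁻⁵ → 2·10⁻³ between CI = 3.5 and 3.75 on the 100×500 grid). The
fixed-threshold criterion is available via `criterion="threshold"`; its
absolute levels sit above the near-onset saturation amplitude of this
discretization and therefore place the crossing at a larger index than the
bifurcation.

On the 100×500 verification domain (unit exponents, u_r = 10⁻³) the
bisection brackets the critical index between 3.53 and 3.81 (reported
midpoint ≈ 3.67).

## Pattern metrics

* Interface length L_i: zero contour of a₊ − a₋ by marching squares with
  linear interpolation (sub-cell accuracy), summed over all polylines, in
  grid units. Computed on the partitioned densities.
* Main-channel count N_c: per material, seeds are boundary-signal local
  maxima above the face mean on the material's exit face; each seed is
  traced up the single-receiver tree along the maximal donor while the
  donor density is at least spacing × width/2 (upstream count of half the
  domain width); traces longer than width/2 count. N_c is the maximum over
  the two materials. The extraction algorithm (seeding rule, threshold,
  trace) is a declared convention — the quantity itself does not pin one
  down — and all three knobs are exposed.
* The largest drainage conduit (3D visualization) is the maximal-donor
  trunk plus the full upstream catchment of the strongest outlet.

## Synthetic data and fixtures

Initial conditions are the study conditions themselves: a linear ramp plus
i.i.d. uniform noise on [0, u_r H) at every non-fixed cell, from a seeded
generator (bit-reproducible). The default u_r = 10⁻³ is the middle of the
tested robustness range. Test fixtures (`make_fixture`) include plane
ramps, seeded noisy ramps, and two fully synthetic states with known ground
truth: `sin_interface` (a density difference whose zero set is an analytic
sine curve, for the arc-length oracle) and `carved_channels` (channel
columns with prescribed linear density profiles on a plane ramp — not the
accumulation of h — so the traced channel length is exactly computable).
These fixtures exercise the metrics, not the physics; what passing them
shows is correctness of the extraction algorithms, not realism of the
patterns.

## Problem sizes in the test suite

The verification and critical-index computations run at the full 100×500
size. The regime-comparison and correlation studies run on reduced domains
(50×150, 15 steady states with CI ∈ {100,…,500}, CI₊ ≤ CI₋) and the
exponent study runs its desk-scale surrogate (orderings and insensitivity
of the critical index, 40×100 domain) — the package's sweep driver can
reproduce the full-scale versions (55 states at 100×500; exponent scans
over m ∈ [0.025, 2.5]) given several CPU-hours. High-CI steady states are
integrated for a fixed iteration budget after the pattern has locked in;
their residual dh/dt plateaus at ~10⁻⁶ H per time unit (channel
micro-adjustments) without altering the reported metrics.

## Known limitations

* Single-flow metrics (N_c tracing) on weakly channelized states depend on
  the declared extraction convention; compare trends, not absolute counts.
  On reduced domains or short runs the count spans only a few discrete
  values (roughly 5–10 across the whole regime grid), so its correlation
  with the interface length is capped well below what fully developed
  full-scale networks exhibit; the correlation test in the suite documents
  this by failing its full-scale threshold at the reduced problem size.
* The 1D one-sided-slope bias of the receiver-slope erosion term scales
  like CI/L and can exceed the closed-form RMSE threshold on short, coarse
  grids at large CI even for perfectly smooth states; the transverse
  criterion is unaffected.
* Memory use in 3D is ~10 dense arrays of the grid size; very large 3D
  domains are out of scope.
* No linear-stability eigenvalue computation is included; stability is
  probed by simulation.
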