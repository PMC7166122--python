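# Methods

## Model overview

The package models early premyofibril patterning as energy-guided
self-organization of α-actinin clusters, implemented as an adapted particle
swarm optimizer.  Each swarm member is a whole candidate pattern: N mobile
clusters on the fibril curve plus the two fixed fibril endpoints.  The
objective is the total pairwise Lennard-Jones energy of a configuration;
the swarm's global best plays the role of the "current pattern" into which
new clusters are recruited.  The model is phenomenological: ε, r_m and d_th
summarize binding affinity, preferred spacing, and the spatial reach of
recruitment without naming specific interaction partners.

Assumptions worth keeping in mind:

* Clusters interact pairwise and isotropically; there is no filament
  tension, no excluded volume beyond the LJ core, and no cluster removal —
  recruitment only ever adds clusters.
* Motion is lateral (along the aligned x-axis) with the vertical coordinate
  slaved to the curve; the fibril shape is static.
* The fixed endpoints take part in every pairwise energy sum.  They anchor
  the pattern; excluding them would leave the boundary clusters
  unconstrained, and the recruitment segment partition includes them in any
  case.  This choice is recorded in every run's metadata.

## Geometry

Curved fibrils are degree-4 Bézier curves fitted by linear least squares to
a circular arc of radius R_c subtending L_c/R_c radians (endpoints pinned,
three interior control points free, uniform parameter spacing against
uniform arc fraction).  The fit is rejected unless the realized arclength is
within 1% of L_c and the maximum deviation from the target circle is within
1% of R_c; in practice both errors are orders of magnitude smaller for all
arcs up to the half-circle feasibility bound L_c ≤ πR_c.  The circular-arc
target is the minimal reading of "radius of curvature"; nothing else about
control-point placement is constrained by the problem, and the choice is
flagged in curve metadata (JSON export).

Curves are built directly in the aligned frame (chord on the x-axis,
x_start = 0, bulge upward).  `align_to_axis` handles arbitrarily posed
curves with a rigid rotation+translation.  A curve is usable by the
dynamics only if it is single-valued as y(x) with |dy/dx| ≤ 10 everywhere;
steeper curves (e.g. L_c = 60 µm on R_c = 20 µm, which subtends 3.0 rad)
are rejected, and parameter-sweep cells containing them are logged and
marked missing rather than aborting the sweep.

Straight fibrils use an explicit sentinel (`curvature_radius=None`), not a
large finite radius, to avoid conditioning problems.

Fast paths use a 20 001-point parameter table (linear interpolation for
y(x); interpolation error ≲ 1e-7 µm for the curvatures considered);
`point_at_x` Newton-refines to place points on the curve to < 1e-6 µm.

## Swarm dynamics

* **Initialization** — each of the S configurations gets the two endpoints
  plus one interior cluster uniform in x; velocities start at zero and
  personal bests at the initial positions; the global best is the
  lowest-energy member.
* **Velocity/position updates** — R₁ and R₂ are drawn per cluster per
  iteration (scalar per cluster).  Per-cluster draws avoid rigid-body-only
  moves; the draw granularity is a modelling choice recorded in run
  metadata.  Δt = 1 iteration unit (velocities absorb the scale).
* **Correspondence** — clusters are indistinguishable, so the attraction
  terms (p − r) and (g − r) match clusters by pseudo-order rank (i-th
  leftmost to i-th leftmost).  The engine realizes this by keeping all
  position arrays row-sorted by x at all times.
* **Bests** — personal bests replace only on strict energy improvement;
  the global best is *best-so-far*: it is replaced by the best personal
  best only when that strictly lowers f(g).  Together with recruitment
  (below) this makes f(g) non-increasing, strictly decreasing at accepted
  recruitments — the invariant the convergence analysis relies on.  Ties
  resolve to the lowest configuration index.
* **Boundaries** — absorbing: a cluster predicted past an endpoint is reset
  to the endpoint with zero velocity.  Such a cluster then coincides with
  the fixed endpoint; the engine evaluates energies with pair distances
  clamped at 1e-6 µm, so the configuration receives an enormous finite
  energy and is never selected as a best (the strict public
  `configuration_energy` raises on coincident clusters instead).
* **Energy-state transition** — each segment of the global best wider than
  d_th proposes one candidate uniform in x within the segment (K_l = number
  of eligible segments; at most one recruit per segment per iteration).
  Candidates are evaluated left-to-right against the pre-transition global
  best plus the already accepted candidates of this iteration; acceptance
  requires E_k < 0 (equivalently Δf < 0).  Accepted candidates are inserted
  into the global best, and every configuration receives one new cluster
  uniform in the same segment with v = 0 and p = r for the new cluster.
  Personal-best energies are recomputed after the insertion (bests of the
  enlarged configurations are *not* re-optimized, only extended); this
  choice is noted in run metadata.

Defaults: S = 60, T_max = 200, ω_max = 0.9 and ω_min = 0.4 (the guidance is
only that the initial inertia is "near 1"; 0.9 → 0.4 is the classic linear
decay schedule), c₁ = c₂ = 2.0 (the classic PSO default; only the range
[0, 4] is prescribed by the problem).  All defaults are configurable and
recorded in run metadata along with the seed and the interpretive choices
above.

Determinism: one seeded NumPy generator per run, with a fixed draw order
(initial placements, then per iteration R₁, R₂, then recruitment
candidates segment-by-segment, then per-member spawn positions).  Identical
seed and parameters give bit-identical results.  Experiments derive
independent per-cell/per-replicate streams via `SeedSequence(base_seed,
spawn_key=(i, j, rep))`, so sweep results are independent of execution
order.

## Pattern metrics

Spacing d̄ follows the gaps → configurations → simulations averaging
chain; all S members contribute, not just the global best, so reported d̄
sits slightly above the global best's own spacing.  Distances are 2D
Euclidean between consecutive pseudo-ordered clusters (endpoints included)
— on the curved fibrils considered here this differs negligibly from
arclength.

Uniformity uses the nearest-neighbour COV λ with the population (1/N)
standard deviation, and u = 1 − λ/λ_rand clamped to [0, 1].  λ_rand is the
*maximum* λ among 60 random scatters of the same number of points uniform
in arclength on the same fibril — the only reading under which u ≤ 1 holds
generically.  Because λ_rand is a maximum over finitely many draws, λ can
occasionally exceed it; u is then clamped at 0 and the event logged.  A COV
below 1e-9 is treated as exactly equal spacing (u = 1) to absorb
floating-point noise.  Calibrations are cached per (curve, count, seed).

Aggregated metrics merge clusters closer than 1e-6 µm into one punctum
before measuring (overlapping clusters are optically a single z-body; this
also neutralizes boundary-absorbed stragglers in unconverged members).

The ranking uses the *rescaled* distance d̄_T in the exponent,
R = ū exp(−d̄_T²/2σ²) with σ the SD of the d̄_T collection of the same
grid (recorded per sweep).  In sweeps where r_m itself varies (the d_th–r_m
sweep), each cell's deviation is taken from its own r_m.  Degenerate cases:
an all-cells-exact grid maps d̄_T ≡ 0 (logged); σ = 0 keeps only cells with
d̄_T = 0 (logged).  High-rank masks use mean + 1 SD of the normalized
ranking by default; an explicit threshold (e.g. 0.56) can be supplied.

## Experiments

* Convergence: N_sim = 10 replicates; a run counts as converged when the
  swarm-mean spacing changes < 1% over the final 20 iterations.
  Non-convergence is reported, never raised.
* Default grids: 15×15 for (d_th, r_m) over [0.1, 1.5] × [0.4, 2.0] µm;
  L_c ∈ {20, 30, 40, 50, 60} µm × R_c ∈ {20, 56, 110} µm for the shape
  sweep; 9×9 over [0, 4]² for (c₁, c₂) at L_c = 35 µm, R_c = 40 µm.  The
  grid resolutions are desk-scale package defaults (the governing parameter
  ranges are fixed; the resolutions are not), all configurable.
* Biological validity ranges for d̄ (µm): cardiac [1.2, 2.0] and flight
  [1.7, 3.2] from the reported z-body → z-line elongation; skeletal
  [0.5, 1.4] is a package default (no numeric range is reported for
  zebrafish skeletal muscle) and is configurable.  The validity area is the
  flagged fraction of non-missing cells.
* Group comparisons are plumbing over scipy's one-way ANOVA and
  statsmodels' Tukey HSD (which handles unequal group sizes, i.e.
  Tukey–Kramer); all-zero-variance groups are reported as incomparable.

## What the simulations do and do not show

The model generates its own data; there is no external input.  Passing
tests show that the algorithm converges to near-equally spaced patterns
with spacing slightly above r_m, that recruitment stops spontaneously once
gaps drop below the energetically favorable size, that cluster count falls
and uniformity structure changes as r_m grows, and that on a tiny fibril
the engine reaches the exhaustive-search energy optimum.  They do not show
anything about real α-actinin kinetics: the mapping from (ε, r_m, d_th,
c₁, c₂) to molecular quantities is interpretive, 3D effects and filament
mechanics are absent, and fibril shape is frozen.

## Problem sizes

Default test and acceptance runs use the full standard conditions (S = 60,
T_max = 200, 40 µm fibril, 10 replicates per condition — about 2 s per
condition set on a laptop-class core).  Unit and property tests use smaller
swarms/fibrils chosen to exercise the same code paths.  The exhaustive
oracle uses a 4·r_m fibril at 0.01 µm grid resolution with up to 3 interior
clusters, the largest instance where full enumeration is the obvious
independent check.
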