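"""Adapted particle swarm optimizer for α-actinin cluster self-organization.

Each swarm member is a whole cluster configuration on the fibril curve.  Per
iteration the engine (i) updates velocities with a linearly decaying inertia
weight, cognitive attraction to the personal best and social attraction to
the global best, (ii) moves clusters laterally with absorbing boundaries and
re-projects them onto the curve, (iii) refreshes personal/global bests, and
(iv) runs the energy-state transition: the global best's segments wider than
the search distance d_th each propose one recruit, accepted when its energy
cost-benefit is negative, after which *every* configuration grows by one
cluster in the same segment so cluster counts stay synchronized.

Clusters within a configuration are indistinguishable; attraction toward the
bests is matched by pseudo-order rank (i-th leftmost to i-th leftmost), which
the engine realizes by keeping all position arrays sorted by x.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .curve import CurveSpec, MyofibrilCurve, build_curve
from .energy import MIN_SEPARATION, EnergyParams

logger = logging.getLogger(__name__)

#: Interpretive modelling choices recorded in every run's metadata.
INTERPRETIVE_CHOICES = {
    "endpoint_energetics": "fixed endpoints participate in all pairwise sums",
    "best_update": "global best is best-so-far (replaced only on strict improvement)",
    "random_draw_granularity": "R1, R2 drawn per cluster per iteration",
    "best_matching": "clusters matched to bests by pseudo-order rank",
    "proposal_order": "one candidate per eligible segment, evaluated left-to-right",
    "recruited_best": "personal bests gain the new cluster at its spawn position",
}


@dataclass(frozen=True)
class SwarmParams:
    """Swarm hyper-parameters.

    c1 and c2 are the cognitive (personal-best) and social (global-best)
    acceleration coefficients, both in [0, 4]; the inertia weight decays
    linearly from omega_max to omega_min over t_max iterations.
    """

    swarm_size: int = 60
    c1: float = 2.0
    c2: float = 2.0
    omega_min: float = 0.4
    omega_max: float = 0.9
    t_max: int = 200
    dt: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError(f"swarm_size must be >= 2, got {self.swarm_size}")
        for name in ("c1", "c2"):
            v = getattr(self, name)
            if not 0 <= v <= 4:
                raise ValueError(f"{name} must lie in [0, 4], got {v}")
        if not 0 < self.omega_min <= self.omega_max <= 1.2:
            raise ValueError(
                f"need 0 < omega_min <= omega_max <= 1.2, got "
                f"({self.omega_min}, {self.omega_max})"
            )
        if self.t_max < 1:
            raise ValueError(f"t_max must be >= 1, got {self.t_max}")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")

    def to_dict(self) -> dict:
        return {
            "swarm_size": self.swarm_size,
            "c1": self.c1,
            "c2": self.c2,
            "omega_min": self.omega_min,
            "omega_max": self.omega_max,
            "t_max": self.t_max,
            "dt": self.dt,
            "rng_seed": self.rng_seed,
        }


def inertia(t: float, params: SwarmParams) -> float:
    """Linearly decaying inertia weight ω(t) = ω_max − (ω_max − ω_min) t / T_max."""
    if not 0 <= t <= params.t_max:
        raise ValueError(f"iteration {t} outside [0, {params.t_max}]")
    return params.omega_max - (params.omega_max - params.omega_min) * t / params.t_max


def velocity_step(
    v: np.ndarray,
    r: np.ndarray,
    p: np.ndarray,
    g: np.ndarray,
    omega: float,
    c1: float,
    c2: float,
    r1: np.ndarray,
    r2: np.ndarray,
) -> np.ndarray:
    """One velocity update: ω v + R1 c1 (p − r) + R2 c2 (g − r)."""
    return omega * v + r1 * c1 * (p - r) + r2 * c2 * (g - r)


@dataclass
class SimulationResult:
    """Outcome of one adapted-PSO run."""

    curve: MyofibrilCurve
    energy_params: EnergyParams
    swarm_params: SwarmParams
    seed: Optional[int]
    gbest: np.ndarray                  # (M, 2) final global-best clusters, sorted
    swarm_points: np.ndarray           # (S, M, 2) final clusters of every member
    series: dict                       # t, n_clusters, f_g, mean_spacing arrays
    metadata: dict

    @property
    def final_cluster_count(self) -> int:
        return self.gbest.shape[0]

    @property
    def final_energy(self) -> float:
        return float(self.series["f_g"][-1])

    def trajectory_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.series["t"],
                "n_clusters": self.series["n_clusters"],
                "f_g": self.series["f_g"],
                "mean_spacing": self.series["mean_spacing"],
            }
        )

    def final_configuration_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x_um": self.gbest[:, 0], "y_um": self.gbest[:, 1]})

    def save(self, outdir: Union[str, Path], stem: str = "run") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.trajectory_frame().to_csv(outdir / f"{stem}_trajectory.csv", index=False)
        self.final_configuration_frame().to_csv(
            outdir / f"{stem}_final_configuration.csv", index=False
        )
        (outdir / f"{stem}_metadata.json").write_text(
            json.dumps(self.metadata, indent=2)
        )


class SwarmSimulation:
    """Stateful engine running the adapted PSO on one fibril curve.

    All per-member interior cluster x-positions live in an (S, N) array kept
    row-sorted; velocities and personal bests are carried along.  Energies are
    evaluated with the clamped Lennard-Jones kernel so boundary collisions
    yield enormous (but finite) energies rather than crashes.
    """

    def __init__(
        self,
        curve: MyofibrilCurve,
        energy_params: EnergyParams,
        swarm_params: SwarmParams,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        curve._require_single_valued()
        self.curve = curve
        self.energy = energy_params
        self.params = swarm_params
        self.rng = rng if rng is not None else np.random.default_rng(swarm_params.rng_seed)
        self.x_start = curve.x_start
        self.x_end = curve.x_end
        self._grid_x = curve.xy_grid[:, 0]
        self._grid_y = curve.xy_grid[:, 1]
        self.t = 0
        self._series: dict[str, list] = {
            "t": [],
            "n_clusters": [],
            "f_g": [],
            "mean_spacing": [],
        }
        self._pair_i: np.ndarray = np.empty(0, dtype=int)
        self._pair_j: np.ndarray = np.empty(0, dtype=int)

    # -- geometry helpers --------------------------------------------------

    def _y_of(self, x: np.ndarray) -> np.ndarray:
        return np.interp(x, self._grid_x, self._grid_y)

    def _full_points(self, x: np.ndarray) -> np.ndarray:
        """Interior x positions -> full (…, N+2, 2) point sets with endpoints."""
        x = np.asarray(x, dtype=float)
        lead = x.shape[:-1]
        xs = np.concatenate(
            [
                np.full(lead + (1,), self.x_start),
                x,
                np.full(lead + (1,), self.x_end),
            ],
            axis=-1,
        )
        return np.stack([xs, self._y_of(xs)], axis=-1)

    # -- energies ----------------------------------------------------------

    def _set_pair_index(self, m: int) -> None:
        self._pair_i, self._pair_j = np.triu_indices(m, k=1)

    def _energies(self, x: np.ndarray) -> np.ndarray:
        """Clamped pairwise energy of each row of interior positions ``x``."""
        pts = self._full_points(x)
        d = np.linalg.norm(
            pts[..., self._pair_i, :] - pts[..., self._pair_j, :], axis=-1
        )
        d = np.maximum(d, MIN_SEPARATION)
        q = (self.energy.ideal_distance / d) ** 6
        return self.energy.epsilon * np.sum(q * q - 2.0 * q, axis=-1)

    def _energy_single(self, x: np.ndarray) -> float:
        return float(self._energies(x[None, :])[0])

    # -- lifecycle ---------------------------------------------------------

    def initialize(self) -> None:
        """Seed the swarm: endpoints plus one random interior cluster each."""
        s = self.params.swarm_size
        self.x = self.rng.uniform(self.x_start, self.x_end, size=(s, 1))
        self.v = np.zeros_like(self.x)
        self.pbest = self.x.copy()
        self._set_pair_index(self.x.shape[1] + 2)
        self.f_p = self._energies(self.pbest)
        best = int(np.argmin(self.f_p))
        self.gbest = self.pbest[best].copy()
        self.f_g = float(self.f_p[best])
        self.t = 0

    def update_velocity(self, t: int) -> None:
        omega = inertia(t, self.params)
        shape = self.x.shape
        r1 = self.rng.random(shape)
        r2 = self.rng.random(shape)
        self.v = velocity_step(
            self.v, self.x, self.pbest, self.gbest[None, :],
            omega, self.params.c1, self.params.c2, r1, r2,
        )

    def update_position(self) -> None:
        self.x = self.x + self.v * self.params.dt
        below = self.x < self.x_start
        above = self.x > self.x_end
        self.x[below] = self.x_start
        self.x[above] = self.x_end
        self.v[below | above] = 0.0
        order = np.argsort(self.x, axis=1, kind="stable")
        self.x = np.take_along_axis(self.x, order, axis=1)
        self.v = np.take_along_axis(self.v, order, axis=1)

    def update_bests(self) -> None:
        f_r = self._energies(self.x)
        improved = f_r < self.f_p
        self.pbest[improved] = self.x[improved]
        self.f_p[improved] = f_r[improved]
        best = int(np.argmin(self.f_p))
        if self.f_p[best] < self.f_g:
            self.gbest = self.pbest[best].copy()
            self.f_g = float(self.f_p[best])

    def energy_state_transition(self) -> int:
        """Recruit new clusters into segments of the global best wider than d_th.

        Returns the number of clusters added (to every configuration).
        """
        g_pts = self._full_points(self.gbest)
        gaps = np.linalg.norm(np.diff(g_pts, axis=0), axis=-1)
        eligible = np.nonzero(gaps > self.energy.search_distance)[0]
        if len(eligible) == 0:
            return 0

        gx = np.concatenate([[self.x_start], self.gbest, [self.x_end]])
        accepted: list[tuple[float, float, np.ndarray]] = []  # (x1, x2, point)
        accepted_pts: list[np.ndarray] = []
        for i in eligible:
            x1, x2 = float(gx[i]), float(gx[i + 1])
            cx = self.rng.uniform(x1, x2)
            cand = np.array([cx, float(self._y_of(cx))])
            d = np.linalg.norm(g_pts - cand, axis=1)
            d = np.maximum(d, MIN_SEPARATION)
            q = (self.energy.ideal_distance / d) ** 6
            e_k = self.energy.epsilon * float(np.sum(q * q - 2.0 * q))
            for pt in accepted_pts:
                r = max(float(np.linalg.norm(pt - cand)), MIN_SEPARATION)
                qq = (self.energy.ideal_distance / r) ** 6
                e_k += self.energy.epsilon * (qq * qq - 2.0 * qq)
            if e_k < 0:
                accepted.append((x1, x2, cand))
                accepted_pts.append(cand)

        if not accepted:
            return 0

        s = self.params.swarm_size
        new_cols = np.column_stack(
            [self.rng.uniform(x1, x2, size=s) for x1, x2, _ in accepted]
        )
        self.x = np.concatenate([self.x, new_cols], axis=1)
        self.v = np.concatenate([self.v, np.zeros_like(new_cols)], axis=1)
        self.pbest = np.concatenate([self.pbest, new_cols], axis=1)
        order = np.argsort(self.x, axis=1, kind="stable")
        self.x = np.take_along_axis(self.x, order, axis=1)
        self.v = np.take_along_axis(self.v, order, axis=1)
        self.pbest = np.sort(self.pbest, axis=1)
        self.gbest = np.sort(np.concatenate([self.gbest, [c[0] for _, _, c in accepted]]))

        self._set_pair_index(self.x.shape[1] + 2)
        self.f_p = self._energies(self.pbest)
        self.f_g = self._energy_single(self.gbest)
        return len(accepted)

    def _mean_swarm_spacing(self) -> float:
        pts = self._full_points(self.x)
        gaps = np.linalg.norm(np.diff(pts, axis=-2), axis=-1)
        return float(np.mean(gaps))

    def step(self) -> None:
        """One full iteration: velocity, position, bests, recruitment, record."""
        self.update_velocity(self.t)
        self.update_position()
        self.update_bests()
        self.energy_state_transition()
        self.t += 1
        self._series["t"].append(self.t)
        self._series["n_clusters"].append(self.x.shape[1] + 2)
        self._series["f_g"].append(self.f_g)
        self._series["mean_spacing"].append(self._mean_swarm_spacing())

    def run(self) -> SimulationResult:
        self.initialize()
        for _ in range(self.params.t_max):
            self.step()
        return self._result()

    def _result(self) -> SimulationResult:
        series = {k: np.asarray(v) for k, v in self._series.items()}
        metadata = {
            "curve": self.curve.spec.to_dict(),
            "realized_length": self.curve.realized_length,
            "energy": self.energy.to_dict(),
            "swarm": self.params.to_dict(),
            "interpretive_choices": INTERPRETIVE_CHOICES,
            "final_cluster_count": int(self.x.shape[1] + 2),
        }
        return SimulationResult(
            curve=self.curve,
            energy_params=self.energy,
            swarm_params=self.params,
            seed=self.params.rng_seed,
            gbest=self._full_points(self.gbest),
            swarm_points=self._full_points(self.x),
            series=series,
            metadata=metadata,
        )


def run_simulation(
    curve: Union[CurveSpec, MyofibrilCurve],
    energy_params: Optional[EnergyParams] = None,
    swarm_params: Optional[SwarmParams] = None,
    *,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimulationResult:
    """Run one adapted-PSO simulation and return its result.

    ``seed`` (or an explicit ``rng``) overrides ``swarm_params.rng_seed``.
    Identical parameters and seed give a bit-identical result.
    """
    if isinstance(curve, CurveSpec):
        curve = build_curve(curve)
    energy_params = energy_params if energy_params is not None else EnergyParams()
    swarm_params = swarm_params if swarm_params is not None else SwarmParams()
    if rng is None:
        rng = np.random.default_rng(
            seed if seed is not None else swarm_params.rng_seed
        )
    sim = SwarmSimulation(curve, energy_params, swarm_params, rng=rng)
    result = sim.run()
    if seed is not None:
        result.metadata["seed"] = seed
        result.seed = seed
    return result
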