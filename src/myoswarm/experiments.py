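"""Experiment orchestration: convergence runs, parameter sweeps, validity, stats.

Four canonical experiments are provided, mirroring how the model is probed:

* ``convergence`` — replicate runs on a straight fibril tracking cluster
  count, global-best energy, and mean spacing over iterations.
* ``dth_rm`` — sweep of the recruitment search distance d_th against the
  ideal distance r_m on a straight fibril.
* ``shape`` — sweep of fibril length L_c against curvature radius R_c at a
  cell-type-specific r_m.
* ``behavior`` — sweep of the cognitive/social acceleration pair (c1, c2) on
  a moderately curved fibril.

Every experiment is deterministic given its base seed: each grid cell and
replicate derives an independent random stream keyed by its indices, so
results do not depend on execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .curve import CurveSpec, build_curve
from .energy import EnergyParams
from .metrics import (
    calibrate_lambda_rand,
    mean_intercluster_distance,
    ranking,
    rescaled_distance,
    uniformity_of_results,
)
from .swarm import SimulationResult, SwarmParams, run_simulation

logger = logging.getLogger(__name__)

#: Experimentally observed z-body spacing ranges (µm) per muscle cell type.
#: Cardiac and flight bounds span the reported z-body -> z-line elongation;
#: the skeletal range is a package default (no numbers are reported for
#: zebrafish skeletal muscle) and is configurable wherever it is used.
CELL_TYPE_RANGES: dict[str, tuple[float, float]] = {
    "cardiac": (1.2, 2.0),
    "flight": (1.7, 3.2),
    "skeletal": (0.5, 1.4),
}

#: Ideal inter-cluster distance r_m (µm) per muscle cell type.
CELL_TYPE_RM: dict[str, float] = {"cardiac": 1.1, "flight": 1.8, "skeletal": 0.7}


def _cell_rng(base_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=key))


# ---------------------------------------------------------------------------
# Experiment plans
# ---------------------------------------------------------------------------

CellFactory = Callable[[float, float], tuple[CurveSpec, EnergyParams, SwarmParams]]


@dataclass
class ExperimentPlan:
    """A 2-parameter sweep: grids plus a factory building each cell's config."""

    experiment: str
    p1_name: str
    p2_name: str
    p1_values: np.ndarray
    p2_values: np.ndarray
    cell_factory: CellFactory
    n_sim: int = 10

    def __post_init__(self) -> None:
        self.p1_values = np.asarray(self.p1_values, dtype=float)
        self.p2_values = np.asarray(self.p2_values, dtype=float)
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")


def dth_rm_plan(
    dth_values: Optional[Sequence[float]] = None,
    rm_values: Optional[Sequence[float]] = None,
    *,
    length: float = 40.0,
    swarm: Optional[SwarmParams] = None,
    n_sim: int = 10,
) -> ExperimentPlan:
    """Search-distance vs ideal-distance sweep on a straight fibril."""
    dth_values = np.linspace(0.1, 1.5, 15) if dth_values is None else dth_values
    rm_values = np.linspace(0.4, 2.0, 15) if rm_values is None else rm_values
    swarm = swarm if swarm is not None else SwarmParams()

    def factory(dth: float, rm: float):
        return (
            CurveSpec(length=length),
            EnergyParams(ideal_distance=rm, search_distance=dth),
            swarm,
        )

    return ExperimentPlan("dth_rm", "d_th", "r_m", dth_values, rm_values, factory, n_sim)


def shape_plan(
    cell_type: str = "cardiac",
    lengths: Optional[Sequence[float]] = None,
    radii: Optional[Sequence[float]] = None,
    *,
    d_th: float = 0.5,
    swarm: Optional[SwarmParams] = None,
    n_sim: int = 10,
) -> ExperimentPlan:
    """Fibril length vs curvature radius sweep at a cell-type-specific r_m."""
    lengths = np.array([20.0, 30.0, 40.0, 50.0, 60.0]) if lengths is None else lengths
    radii = np.array([20.0, 56.0, 110.0]) if radii is None else radii
    rm = CELL_TYPE_RM[cell_type]
    swarm = swarm if swarm is not None else SwarmParams()
    energy = EnergyParams(ideal_distance=rm, search_distance=d_th)

    def factory(length: float, radius: float):
        return (CurveSpec(length=length, curvature_radius=radius), energy, swarm)

    return ExperimentPlan("shape", "L_c", "R_c", lengths, radii, factory, n_sim)


def behavior_plan(
    cell_type: str = "cardiac",
    c1_values: Optional[Sequence[float]] = None,
    c2_values: Optional[Sequence[float]] = None,
    *,
    length: float = 35.0,
    radius: float = 40.0,
    d_th: float = 0.5,
    n_sim: int = 10,
    base_swarm: Optional[SwarmParams] = None,
) -> ExperimentPlan:
    """Cognitive/social coefficient sweep on a moderately curved fibril."""
    c1_values = np.linspace(0.0, 4.0, 9) if c1_values is None else c1_values
    c2_values = np.linspace(0.0, 4.0, 9) if c2_values is None else c2_values
    rm = CELL_TYPE_RM[cell_type]
    energy = EnergyParams(ideal_distance=rm, search_distance=d_th)
    spec = CurveSpec(length=length, curvature_radius=radius)
    base = base_swarm if base_swarm is not None else SwarmParams()

    def factory(c1: float, c2: float):
        swarm = SwarmParams(
            swarm_size=base.swarm_size,
            c1=c1,
            c2=c2,
            omega_min=base.omega_min,
            omega_max=base.omega_max,
            t_max=base.t_max,
            dt=base.dt,
        )
        return (spec, energy, swarm)

    return ExperimentPlan("behavior", "c1", "c2", c1_values, c2_values, factory, n_sim)


# ---------------------------------------------------------------------------
# Convergence experiment
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceReport:
    """Replicate-run convergence summary."""

    results: list
    converged: np.ndarray
    final_counts: np.ndarray
    final_energies: np.ndarray
    mean_distance: float
    sd_distance: float
    per_sim_distance: np.ndarray

    @property
    def n_converged(self) -> int:
        return int(self.converged.sum())


def run_convergence_experiment(
    curve_spec: Optional[CurveSpec] = None,
    energy_params: Optional[EnergyParams] = None,
    swarm_params: Optional[SwarmParams] = None,
    *,
    n_sim: int = 10,
    base_seed: int = 0,
    window: int = 20,
    rel_tol: float = 0.01,
) -> ConvergenceReport:
    """Run ``n_sim`` seeded replicate simulations and assess convergence.

    A run is flagged converged when the swarm-mean spacing changes by less
    than ``rel_tol`` (relative) over the final ``window`` iterations.
    Non-convergence is reported, not raised.
    """
    curve_spec = curve_spec if curve_spec is not None else CurveSpec(length=40.0)
    energy_params = energy_params if energy_params is not None else EnergyParams()
    swarm_params = swarm_params if swarm_params is not None else SwarmParams()
    curve = build_curve(curve_spec)

    results = [
        run_simulation(
            curve, energy_params, swarm_params, rng=_cell_rng(base_seed, i)
        )
        for i in range(n_sim)
    ]
    converged = []
    for res in results:
        spacing = res.series["mean_spacing"]
        if len(spacing) > window:
            change = abs(spacing[-1] - spacing[-1 - window]) / max(spacing[-1], 1e-12)
            converged.append(change < rel_tol)
        else:
            converged.append(False)
    metrics = mean_intercluster_distance(results)
    return ConvergenceReport(
        results=results,
        converged=np.array(converged),
        final_counts=np.array([r.final_cluster_count for r in results]),
        final_energies=np.array([r.final_energy for r in results]),
        mean_distance=metrics.mean_distance,
        sd_distance=metrics.sd_distance,
        per_sim_distance=metrics.per_sim_distance,
    )


# ---------------------------------------------------------------------------
# Grid sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Aggregated per-cell metrics of a 2-parameter sweep."""

    experiment: str
    p1_name: str
    p2_name: str
    p1_values: np.ndarray
    p2_values: np.ndarray
    dbar: np.ndarray            # (n1, n2) mean inter-cluster distance
    ubar: np.ndarray            # (n1, n2) mean uniformity
    rm: np.ndarray              # (n1, n2) ideal distance used in each cell
    dT: np.ndarray              # rescaled distance
    ranking: np.ndarray
    ranking_normalized: np.ndarray
    sigma: float
    high_rank_mask: np.ndarray
    missing: np.ndarray         # cells whose runs failed (e.g. infeasible curve)
    n_sim: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, p1 in enumerate(self.p1_values):
            for j, p2 in enumerate(self.p2_values):
                rows.append(
                    {
                        self.p1_name: p1,
                        self.p2_name: p2,
                        "dbar": self.dbar[i, j],
                        "ubar": self.ubar[i, j],
                        "dT": self.dT[i, j],
                        "ranking": self.ranking_normalized[i, j],
                        "high_rank": bool(self.high_rank_mask[i, j]),
                        "missing": bool(self.missing[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def run_grid_sweep(
    plan: ExperimentPlan,
    *,
    base_seed: int = 0,
    rank_threshold: Optional[float] = None,
) -> SweepResult:
    """Run every cell of ``plan`` with cell-index-keyed sub-seeds and aggregate.

    Failed cells (infeasible geometry, etc.) are logged, marked missing, and
    excluded from the ranking normalization; the sweep continues.
    """
    n1, n2 = len(plan.p1_values), len(plan.p2_values)
    dbar = np.full((n1, n2), np.nan)
    ubar = np.full((n1, n2), np.nan)
    rm_grid = np.full((n1, n2), np.nan)
    missing = np.zeros((n1, n2), dtype=bool)

    for i, p1 in enumerate(plan.p1_values):
        for j, p2 in enumerate(plan.p2_values):
            try:
                spec, energy, swarm = plan.cell_factory(float(p1), float(p2))
                curve = build_curve(spec)
                results = [
                    run_simulation(
                        curve, energy, swarm, rng=_cell_rng(base_seed, i, j, rep)
                    )
                    for rep in range(plan.n_sim)
                ]
                metrics = uniformity_of_results(
                    results, seed=int(_cell_rng(base_seed, i, j, 100_000).integers(2**31))
                )
                dbar[i, j] = metrics.mean_distance
                ubar[i, j] = metrics.mean_uniformity
                rm_grid[i, j] = energy.ideal_distance
            except Exception as exc:  # noqa: BLE001 - per-cell failures are survivable
                logger.warning(
                    "sweep cell (%s=%.3g, %s=%.3g) failed: %s",
                    plan.p1_name, p1, plan.p2_name, p2, exc,
                )
                missing[i, j] = True

    dT = rescaled_distance(dbar, rm_grid)
    rank = ranking(np.nan_to_num(ubar, nan=0.0), np.nan_to_num(dT, nan=0.0),
                   threshold=rank_threshold)
    mask = rank.high_rank_mask & ~missing
    return SweepResult(
        experiment=plan.experiment,
        p1_name=plan.p1_name,
        p2_name=plan.p2_name,
        p1_values=plan.p1_values,
        p2_values=plan.p2_values,
        dbar=dbar,
        ubar=ubar,
        rm=rm_grid,
        dT=dT,
        ranking=rank.ranking,
        ranking_normalized=rank.normalized,
        sigma=rank.sigma,
        high_rank_mask=mask,
        missing=missing,
        n_sim=plan.n_sim,
    )


# ---------------------------------------------------------------------------
# Biological validity
# ---------------------------------------------------------------------------

@dataclass
class ValidityReport:
    """Which sweep cells fall in the experimentally observed spacing range."""

    valid: np.ndarray
    fraction: float
    value_range: tuple[float, float]


def validity_area(
    sweep: SweepResult, value_range: tuple[float, float]
) -> ValidityReport:
    """Fraction of (non-missing) cells whose d̄ lies inside ``value_range``."""
    lo, hi = value_range
    if not lo < hi:
        raise ValueError(f"invalid range {value_range}")
    valid = (sweep.dbar >= lo) & (sweep.dbar <= hi) & ~sweep.missing
    n_usable = int((~sweep.missing).sum())
    if n_usable == 0:
        raise ValueError("all sweep cells are missing")
    fraction = float(valid.sum() / n_usable)
    return ValidityReport(valid=valid, fraction=fraction, value_range=(lo, hi))


# ---------------------------------------------------------------------------
# Group comparisons (plumbing over standard statistics)
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """One-way ANOVA plus Tukey-Kramer pairwise comparisons."""

    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame
    comparable: bool = True
    alpha: float = 0.05


def compare_groups(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> GroupComparison:
    """Compare metric vectors by group: ANOVA, then Tukey-Kramer post hoc."""
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least 2 replicates")
    if all(np.var(a) == 0 for a in arrays):
        logger.warning("all groups have zero variance; comparison is degenerate")
        return GroupComparison(
            anova_f=float("nan"),
            anova_p=float("nan"),
            pairwise=pd.DataFrame(
                columns=["group1", "group2", "meandiff", "p_adj", "significant"]
            ),
            comparable=False,
            alpha=alpha,
        )
    f_stat, p_val = stats.f_oneway(*arrays)
    values = np.concatenate(arrays)
    labels = np.concatenate([[n] * len(a) for n, a in zip(names, arrays)])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pairs = list(combinations(tukey.groupsunique, 2))
    pairwise = pd.DataFrame(
        {
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "meandiff": tukey.meandiffs,
            "p_adj": tukey.pvalues,
            "significant": tukey.reject,
        }
    )
    return GroupComparison(
        anova_f=float(f_stat), anova_p=float(p_val), pairwise=pairwise, alpha=alpha
    )
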