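"""Pattern metrics: inter-cluster spacing, uniformity, and parameter ranking.

Spacing is the mean 2D Euclidean distance between consecutive pseudo-ordered
clusters (endpoints included), averaged over gaps, then over the S swarm
configurations, then over replicate simulations.  Uniformity is an adjusted
coefficient of variation of nearest-neighbour distances, normalized by the
worst COV observed over 60 sets of randomly scattered points on the same
fibril (λ_rand), so u = 1 means perfectly even spacing and u = 0 means
random-level scatter.  Parameter sweeps are summarized by a ranking that
rewards high uniformity and spacing close to the ideal distance r_m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .curve import MyofibrilCurve
from .swarm import SimulationResult

logger = logging.getLogger(__name__)

N_CALIBRATION_DRAWS = 60  # random point sets behind the λ_rand calibration


# ---------------------------------------------------------------------------
# Spacing
# ---------------------------------------------------------------------------

def config_spacings(points: np.ndarray) -> np.ndarray:
    """Consecutive pseudo-ordered gap distances of one configuration."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 2:
        raise ValueError("a configuration needs at least 2 clusters to have a gap")
    pts = pts[np.argsort(pts[:, 0], kind="stable")]
    return np.linalg.norm(np.diff(pts, axis=0), axis=-1)


def merge_coincident(points: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Collapse clusters closer than ``tol`` (µm) into a single punctum.

    Absorbing boundaries can park a mobile cluster exactly on a fixed
    endpoint; optically such overlapping clusters are one z-body, so the
    aggregate metrics treat them as one.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    pts = pts[np.argsort(pts[:, 0], kind="stable")]
    keep = [0]
    for i in range(1, len(pts)):
        if np.linalg.norm(pts[i] - pts[keep[-1]]) > tol:
            keep.append(i)
    return pts[keep]


def _per_sim_mean_distance(result: SimulationResult) -> float:
    gaps = [
        config_spacings(merge_coincident(cfg)) for cfg in result.swarm_points
    ]
    return float(np.mean([g.mean() for g in gaps]))


@dataclass
class MetricsResult:
    """Spacing/uniformity summary over replicate simulations."""

    per_sim_distance: np.ndarray
    mean_distance: float
    sd_distance: float
    per_sim_uniformity: Optional[np.ndarray] = None
    mean_uniformity: Optional[float] = None
    n_sim: int = 0


def mean_intercluster_distance(results: Sequence[SimulationResult]) -> MetricsResult:
    """Average inter-cluster distance across replicate simulations.

    Per simulation the gap distances of all S configurations are averaged;
    the across-simulation mean and SD of those per-simulation values are
    returned.
    """
    if len(results) == 0:
        raise ValueError("need at least one simulation result")
    per_sim = np.array([_per_sim_mean_distance(r) for r in results])
    return MetricsResult(
        per_sim_distance=per_sim,
        mean_distance=float(per_sim.mean()),
        sd_distance=float(per_sim.std(ddof=0)),
        n_sim=len(results),
    )


# ---------------------------------------------------------------------------
# Uniformity
# ---------------------------------------------------------------------------

def spacing_cov(points: np.ndarray) -> float:
    """COV λ of nearest-neighbour distances: population SD over mean of γ_i."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 3:
        raise ValueError("uniformity needs at least 3 points")
    d = cdist(pts, pts)
    np.fill_diagonal(d, np.inf)
    gamma = d.min(axis=1)
    if np.any(gamma == 0):
        raise ValueError("coincident points: nearest-neighbour distance is zero")
    gbar = gamma.mean()
    return float(np.sqrt(np.mean((gamma - gbar) ** 2)) / gbar)


def uniformity(points: np.ndarray, lambda_rand: float) -> float:
    """Uniformity u = 1 − λ/λ_rand, clamped to [0, 1].

    u = 1 for perfectly evenly spaced points (λ = 0); u = 0 at random-level
    scatter.  λ can exceed λ_rand (the calibration is a max over only
    60 draws), in which case u is clamped at 0 and the event logged.
    """
    if not lambda_rand > 0:
        raise ValueError(f"lambda_rand must be positive, got {lambda_rand}")
    lam = spacing_cov(points)
    if lam < 1e-9:  # numerically exact equal spacing
        return 1.0
    u = 1.0 - lam / lambda_rand
    if u < 0:
        logger.info("spacing COV %.4g exceeded lambda_rand %.4g; clamping u to 0", lam, lambda_rand)
        return 0.0
    return float(min(u, 1.0))


def calibrate_lambda_rand(
    curve: MyofibrilCurve,
    n_points: int,
    seed: int = 0,
    n_draws: int = N_CALIBRATION_DRAWS,
) -> float:
    """Worst (largest) spacing COV over ``n_draws`` random point scatters.

    Each draw places ``n_points`` points uniformly in arclength on the curve.
    Results are cached per (curve, n_points, seed, n_draws).
    """
    if n_points < 3:
        raise ValueError("calibration needs at least 3 points")
    cache = getattr(curve, "_lambda_rand_cache", None)
    if cache is None:
        cache = {}
        curve._lambda_rand_cache = cache
    key = (n_points, seed, n_draws)
    if key not in cache:
        rng = np.random.default_rng(seed)
        s = rng.uniform(0.0, curve.realized_length, size=(n_draws, n_points))
        pts = curve.point_at_arclength(s)
        cache[key] = max(spacing_cov(pts[i]) for i in range(n_draws))
    return cache[key]


def uniformity_of_results(
    results: Sequence[SimulationResult], seed: int = 0
) -> MetricsResult:
    """Spacing and uniformity summary of replicate simulations.

    Per simulation, u is computed for each of the S configurations (with
    λ_rand calibrated for that configuration's cluster count on that curve)
    and averaged; the across-simulation mean is also reported.
    """
    base = mean_intercluster_distance(results)
    per_sim_u = []
    for res in results:
        us = []
        for cfg in res.swarm_points:
            pts = merge_coincident(cfg)
            if len(pts) < 3:
                continue  # too few distinct puncta for a COV
            lam_rand = calibrate_lambda_rand(res.curve, len(pts), seed=seed)
            us.append(uniformity(pts, lam_rand))
        if not us:
            raise ValueError("no configuration has enough distinct clusters")
        per_sim_u.append(float(np.mean(us)))
    base.per_sim_uniformity = np.array(per_sim_u)
    base.mean_uniformity = float(np.mean(per_sim_u))
    return base


# ---------------------------------------------------------------------------
# Sweep-level measures
# ---------------------------------------------------------------------------

def rescaled_distance(dbar_grid: np.ndarray, r_m) -> np.ndarray:
    """Deviation of d̄ from r_m, normalized by the grid-wide max |deviation|.

    Values lie in [−1, 1].  ``r_m`` may be a scalar or a grid (for sweeps in
    which the ideal distance itself varies).  If every cell sits exactly at
    its r_m the result is identically zero (logged).
    """
    dbar = np.asarray(dbar_grid, dtype=float)
    dev = dbar - np.asarray(r_m, dtype=float)
    denom = np.nanmax(np.abs(dev))
    if not denom > 0:
        logger.warning("all cells at the ideal distance; rescaled distance set to 0")
        return np.zeros_like(dbar)
    return dev / denom


@dataclass
class RankingResult:
    """Ranking grid with its normalization and high-rank mask."""

    ranking: np.ndarray
    normalized: np.ndarray
    sigma: float
    high_rank_mask: np.ndarray
    threshold: float


def ranking(
    ubar_grid: np.ndarray,
    dT_grid: np.ndarray,
    threshold: Optional[float] = None,
) -> RankingResult:
    """Rank parameter cells: R = ū · exp(−d̄_T² / (2σ²)).

    σ is the SD of the rescaled-distance collection of this same grid.  The
    grid is normalized to a maximum of 1; the high-rank mask flags cells whose
    normalized ranking exceeds ``threshold`` (default: grid mean plus one SD).
    """
    ubar = np.asarray(ubar_grid, dtype=float)
    dT = np.asarray(dT_grid, dtype=float)
    if ubar.shape != dT.shape:
        raise ValueError("uniformity and rescaled-distance grids must be congruent")
    sigma = float(np.nanstd(dT))
    if sigma > 0:
        r = ubar * np.exp(-(dT**2) / (2.0 * sigma**2))
    else:
        logger.warning("zero spread in rescaled distances; ranking factor set by d_T == 0")
        r = ubar * np.where(dT == 0, 1.0, 0.0)
    peak = np.nanmax(r)
    r_norm = r / peak if peak > 0 else np.zeros_like(r)
    if threshold is None:
        threshold = float(np.nanmean(r_norm) + np.nanstd(r_norm))
    mask = r_norm > threshold
    return RankingResult(
        ranking=r,
        normalized=r_norm,
        sigma=sigma,
        high_rank_mask=mask,
        threshold=float(threshold),
    )
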