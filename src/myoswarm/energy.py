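"""Energy model for α-actinin cluster configurations.

The swarm's objective is the total Lennard-Jones interaction energy of a
cluster configuration plus the cost-benefit of any clusters recruited during
the current iteration.  The Lennard-Jones well depth ε sets the energy scale
(all energies are reported in units of ε) and its minimum location r_m is the
ideal equilibrium inter-cluster distance.  The two fixed fibril endpoints
participate in all pairwise sums — they anchor the pattern — but are never
moved by the dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .curve import AxisTransform

logger = logging.getLogger(__name__)

#: Minimum evaluable pair distance (µm); guards the Lennard-Jones divergence.
MIN_SEPARATION = 1e-6


@dataclass(frozen=True)
class EnergyParams:
    """Parameters of the interaction energy.

    epsilon
        Well depth ε (energy units); scales the objective uniformly.
    ideal_distance
        r_m (µm): the pair distance at which the potential is minimal.
    search_distance
        d_th (µm): minimum segment length for cluster recruitment to be
        considered.
    """

    epsilon: float = 1.0
    ideal_distance: float = 1.1
    search_distance: float = 0.5

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if not self.ideal_distance > 0:
            raise ValueError(f"ideal_distance must be positive, got {self.ideal_distance}")
        if self.search_distance < 0:
            raise ValueError(f"search_distance must be >= 0, got {self.search_distance}")

    def to_dict(self) -> dict:
        return {
            "epsilon": self.epsilon,
            "ideal_distance": self.ideal_distance,
            "search_distance": self.search_distance,
        }


def lennard_jones(r_ij, params: EnergyParams):
    """Pairwise interaction energy ε[(r_m/r)^12 − 2 (r_m/r)^6].

    Minimal (−ε) at ``r = ideal_distance``; diverges as r -> 0, so
    non-positive distances raise.
    """
    r = np.asarray(r_ij, dtype=float)
    if np.any(r <= 0):
        raise ValueError("Lennard-Jones potential is undefined at r <= 0")
    q = (params.ideal_distance / r) ** 6
    out = params.epsilon * (q * q - 2.0 * q)
    return out if out.ndim else float(out)


def lennard_jones_clamped(r_ij, params: EnergyParams):
    """Lennard-Jones with distances clamped at :data:`MIN_SEPARATION`.

    Used on the simulation hot path, where absorbing boundaries may park a
    mobile cluster exactly on a fixed endpoint; the clamped value is a huge
    positive energy, so such configurations are simply never selected.
    """
    r = np.maximum(np.asarray(r_ij, dtype=float), MIN_SEPARATION)
    q = (params.ideal_distance / r) ** 6
    out = params.epsilon * (q * q - 2.0 * q)
    return out if out.ndim else float(out)


@dataclass
class ClusterConfiguration:
    """One swarm member: N interior clusters plus the two fixed endpoints."""

    interior: np.ndarray          # (N, 2) on-curve points, µm
    endpoints: np.ndarray         # (2, 2): fibril start and end points

    def __post_init__(self) -> None:
        self.interior = np.atleast_2d(np.asarray(self.interior, dtype=float))
        if self.interior.size == 0:
            self.interior = np.empty((0, 2))
        self.endpoints = np.asarray(self.endpoints, dtype=float)
        if self.endpoints.shape != (2, 2):
            raise ValueError("endpoints must be two planar points")

    @property
    def count(self) -> int:
        return len(self.interior)

    def all_points(self) -> np.ndarray:
        """All clusters (endpoints included) sorted by x — the pseudo-ordering."""
        pts = np.vstack([self.endpoints[:1], self.interior, self.endpoints[1:]])
        order = np.argsort(pts[:, 0], kind="stable")
        return pts[order]


def configuration_energy(config, params: EnergyParams) -> float:
    """Total pairwise Lennard-Jones energy Σ_{i<j} V(r_ij), endpoints included.

    ``config`` may be a :class:`ClusterConfiguration` or an (M, 2) point array.
    Coincident clusters (pair distance below :data:`MIN_SEPARATION`) raise.
    """
    pts = config.all_points() if isinstance(config, ClusterConfiguration) else np.atleast_2d(config)
    if len(pts) < 2:
        return 0.0
    d = pdist(pts)
    if np.any(d < MIN_SEPARATION):
        raise ValueError(
            f"coincident clusters (pair distance < {MIN_SEPARATION} µm); "
            "the Lennard-Jones energy diverges"
        )
    return float(np.sum(lennard_jones(d, params)))


@dataclass
class SegmentPartition:
    """Consecutive pseudo-ordered cluster pairs tiling the fibril extent."""

    pairs: np.ndarray        # (n_segments, 2, 2): (left point, right point)

    @property
    def x_intervals(self) -> np.ndarray:
        return self.pairs[:, :, 0]

    def __len__(self) -> int:
        return len(self.pairs)

    def segment_of(self, x: float) -> Optional[int]:
        """Index of the open segment (x1, x2) containing ``x``, or None."""
        xs = self.x_intervals
        hits = np.nonzero((x > xs[:, 0]) & (x < xs[:, 1]))[0]
        return int(hits[0]) if len(hits) else None


def partition_segments(
    config: ClusterConfiguration, transform: Optional[AxisTransform] = None
) -> SegmentPartition:
    """Segment the fibril at the pseudo-ordered clusters of ``config``.

    When a transform is given, points are mapped into the aligned frame first.
    Ties in x are broken by stable original order (and logged).
    """
    pts = np.vstack([config.endpoints[:1], config.interior, config.endpoints[1:]])
    if transform is not None:
        pts = transform.apply(pts)
    order = np.argsort(pts[:, 0], kind="stable")
    pts = pts[order]
    if np.any(np.diff(pts[:, 0]) == 0):
        logger.warning("duplicate cluster x-coordinates; tie broken by original order")
    pairs = np.stack([pts[:-1], pts[1:]], axis=1)
    return SegmentPartition(pairs=pairs)


@dataclass
class RecruitmentProposal:
    """A candidate cluster s_k with its energetic cost-benefit."""

    point: np.ndarray
    segment_index: Optional[int]
    cost_benefit: float = 0.0
    accepted: bool = False


def cost_benefit(
    s_k: np.ndarray,
    prior_proposals: Sequence[RecruitmentProposal],
    global_best: ClusterConfiguration,
    partition: SegmentPartition,
    params: EnergyParams,
) -> float:
    """Energetic cost-benefit E_k of adding candidate ``s_k``.

    E_k is the interaction energy the candidate would add: its Lennard-Jones
    couplings to every cluster of the current optimal configuration plus to
    every *accepted* earlier candidate.  The segment-occupancy indicator P
    zeroes E_k when the candidate's segment is already claimed by an earlier
    proposal (at most one recruit per segment per iteration) or when the
    candidate falls on a segment boundary.
    """
    s_k = np.asarray(s_k, dtype=float)
    seg = partition.segment_of(float(s_k[0]))
    if seg is None:
        return 0.0
    for prop in prior_proposals:
        if prop.segment_index == seg:
            return 0.0
    best_pts = global_best.all_points()
    d = np.linalg.norm(best_pts - s_k, axis=1)
    total = float(np.sum(lennard_jones_clamped(d, params)))
    for prop in prior_proposals:
        if prop.accepted:
            total += lennard_jones_clamped(
                float(np.linalg.norm(np.asarray(prop.point) - s_k)), params
            )
    return total


def objective(
    config: ClusterConfiguration,
    proposals: Sequence[RecruitmentProposal],
    params: EnergyParams,
) -> float:
    """Objective value: maintenance energy plus accepted recruitment terms."""
    total = configuration_energy(config, params)
    for prop in proposals:
        if prop.accepted:
            total += prop.cost_benefit
    return total
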