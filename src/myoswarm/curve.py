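"""Geometric substrate: planar Bézier curves standing in for premyofibrils.

A simulated premyofibril is a fourth-order (degree-4) Bézier curve with a
prescribed arclength ``L_c`` and, for curved fibrils, a prescribed radius of
curvature ``R_c``.  Curved fibrils are realized by least-squares fitting the
five control points to a circular arc of radius ``R_c`` subtending the angle
``L_c / R_c``; straight fibrils are horizontal segments.  Curves are kept in
an axis-aligned frame (both endpoints on the x-axis, start at the origin) so
that the swarm dynamics can move clusters laterally along x and recover the
vertical coordinate from the curve itself.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy.integrate import cumulative_trapezoid

logger = logging.getLogger(__name__)

#: Maximum |dy/dx| tolerated after axis alignment; steeper curves are not
#: single-valued enough for the lateral update scheme and are rejected.
MAX_SLOPE = 10.0
#: Realized arclength must match the requested length to this relative tolerance.
LENGTH_RTOL = 0.01
#: Maximum pointwise deviation from the target circular arc, relative to R_c.
RADIUS_RTOL = 0.01

_N_SAMPLES = 20001  # dense parameter grid backing x->y and arclength lookups
_N_FIT = 400        # arc samples used for the least-squares control-point fit


class CurveGeometryError(ValueError):
    """Raised for infeasible curve specifications or non-single-valued curves."""


# ---------------------------------------------------------------------------
# Bézier primitives
# ---------------------------------------------------------------------------

def _bernstein_matrix(t: np.ndarray) -> np.ndarray:
    """Degree-4 Bernstein basis evaluated at parameters ``t`` -> (len(t), 5)."""
    t = np.asarray(t, dtype=float)
    u = 1.0 - t
    return np.stack(
        [u**4, 4 * u**3 * t, 6 * (u * t) ** 2, 4 * u * t**3, t**4], axis=-1
    )


def _bezier_point(control: np.ndarray, t) -> np.ndarray:
    return _bernstein_matrix(np.atleast_1d(t)) @ control


def _bezier_derivative(control: np.ndarray, t) -> np.ndarray:
    # hodograph: derivative of a degree-4 Bézier is a degree-3 Bézier
    d = 4.0 * np.diff(control, axis=0)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    u = 1.0 - t
    basis = np.stack([u**3, 3 * u**2 * t, 3 * u * t**2, t**3], axis=-1)
    return basis @ d


def _gauss_arclength(control: np.ndarray, panels: int = 64, order: int = 10) -> float:
    """Arclength of the Bézier by composite Gauss-Legendre quadrature."""
    nodes, weights = leggauss(order)
    edges = np.linspace(0.0, 1.0, panels + 1)
    half = np.diff(edges) / 2.0
    mid = (edges[:-1] + edges[1:]) / 2.0
    t = (mid[:, None] + half[:, None] * nodes[None, :]).ravel()
    speed = np.linalg.norm(_bezier_derivative(control, t), axis=-1)
    w = (half[:, None] * weights[None, :]).ravel()
    return float(np.sum(w * speed))


# ---------------------------------------------------------------------------
# Specifications and transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurveSpec:
    """Target geometry of a simulated premyofibril.

    Parameters
    ----------
    length
        Target arclength L_c in µm.
    curvature_radius
        Radius of curvature R_c in µm, or ``None`` for a straight fibril.
        ``None`` is an explicit sentinel; do not pass a huge finite radius.
    """

    length: float
    curvature_radius: Optional[float] = None
    bezier_order: int = 4

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise CurveGeometryError(f"curve length must be positive, got {self.length}")
        if self.bezier_order != 4:
            raise CurveGeometryError("only fourth-order Bézier curves are supported")
        if self.curvature_radius is not None:
            if not self.curvature_radius > 0:
                raise CurveGeometryError(
                    f"curvature radius must be positive, got {self.curvature_radius}"
                )
            if self.length > math.pi * self.curvature_radius * (1 + 1e-12):
                raise CurveGeometryError(
                    f"infeasible curve: arclength {self.length} µm exceeds the half "
                    f"circle of radius {self.curvature_radius} µm "
                    f"(L_c must be <= pi * R_c = {math.pi * self.curvature_radius:.4g} µm)"
                )

    @property
    def is_straight(self) -> bool:
        return self.curvature_radius is None

    @classmethod
    def from_dict(cls, d: dict) -> "CurveSpec":
        radius = d.get("curvature_radius")
        if isinstance(radius, str):
            if radius.lower() in {"straight", "inf", "none"}:
                radius = None
            else:
                radius = float(radius)
        return cls(length=float(d["length"]), curvature_radius=radius)

    def to_dict(self) -> dict:
        return {
            "length": self.length,
            "curvature_radius": "straight" if self.is_straight else self.curvature_radius,
            "bezier_order": self.bezier_order,
        }


@dataclass(frozen=True)
class AxisTransform:
    """Rigid transform (rotation + translation) taking a curve onto the x-axis."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation.T + self.translation
        return out if np.ndim(points) > 1 else out[0]

    def inverse(self) -> "AxisTransform":
        rot_inv = self.rotation.T
        return AxisTransform(rotation=rot_inv, translation=-rot_inv @ self.translation)

    @classmethod
    def identity(cls) -> "AxisTransform":
        return cls(rotation=np.eye(2), translation=np.zeros(2))


# ---------------------------------------------------------------------------
# The curve object
# ---------------------------------------------------------------------------

@dataclass
class MyofibrilCurve:
    """A realized premyofibril curve with lookup tables for fast evaluation.

    ``t_grid``/``xy_grid``/``s_grid`` form a dense, monotone sampling of the
    curve used for x -> y interpolation (the swarm's hot path) and for the
    arclength -> point map used when scattering random clusters.
    """

    spec: CurveSpec
    control_points: np.ndarray
    t_grid: np.ndarray = field(repr=False)
    xy_grid: np.ndarray = field(repr=False)
    s_grid: np.ndarray = field(repr=False)
    realized_length: float = 0.0
    realized_radius: Optional[float] = None
    single_valued: bool = True
    max_slope: float = 0.0

    @property
    def x_start(self) -> float:
        return float(self.control_points[0, 0])

    @property
    def x_end(self) -> float:
        return float(self.control_points[-1, 0])

    @property
    def start_point(self) -> np.ndarray:
        return self.control_points[0].copy()

    @property
    def end_point(self) -> np.ndarray:
        return self.control_points[-1].copy()

    def _require_single_valued(self) -> None:
        if not self.single_valued:
            raise CurveGeometryError(
                "curve is not expressible as y(x) after alignment "
                f"(max |dy/dx| = {self.max_slope:.3g} exceeds {MAX_SLOPE})"
            )

    def y_at(self, x) -> np.ndarray:
        """Vertical coordinate(s) of the curve at lateral position(s) ``x``."""
        self._require_single_valued()
        return np.interp(x, self.xy_grid[:, 0], self.xy_grid[:, 1])

    def point_at_x(self, x: float, refine: bool = True) -> np.ndarray:
        """Exact on-curve point at lateral position ``x`` (Newton-refined)."""
        self._require_single_valued()
        if not (self.x_start - 1e-12 <= x <= self.x_end + 1e-12):
            raise CurveGeometryError(
                f"x={x} outside the fiber extent [{self.x_start}, {self.x_end}]"
            )
        t = float(np.interp(x, self.xy_grid[:, 0], self.t_grid))
        if refine:
            for _ in range(4):
                pt = _bezier_point(self.control_points, t)[0]
                dx = _bezier_derivative(self.control_points, t)[0, 0]
                if dx == 0:
                    break
                t = min(1.0, max(0.0, t - (pt[0] - x) / dx))
        return _bezier_point(self.control_points, t)[0]

    def point_at_arclength(self, s) -> np.ndarray:
        """Point(s) at arclength ``s`` from the start of the curve."""
        x = np.interp(s, self.s_grid, self.xy_grid[:, 0])
        y = np.interp(s, self.s_grid, self.xy_grid[:, 1])
        return np.stack([x, y], axis=-1)

    def sample(self, n: int = 200) -> np.ndarray:
        """``n`` points sampled at uniform parameter values."""
        return _bezier_point(self.control_points, np.linspace(0.0, 1.0, n))

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "control_points": self.control_points.tolist(),
                "L_c": self.spec.length,
                "R_c": "straight" if self.spec.is_straight else self.spec.curvature_radius,
                "realized_length": self.realized_length,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MyofibrilCurve":
        d = json.loads(text)
        radius = d["R_c"]
        spec = CurveSpec(
            length=d["L_c"],
            curvature_radius=None if radius == "straight" else radius,
        )
        return curve_from_control_points(np.asarray(d["control_points"]), spec)

    def polyline_frame(self, n: int = 500) -> pd.DataFrame:
        pts = self.sample(n)
        return pd.DataFrame({"x_um": pts[:, 0], "y_um": pts[:, 1]})


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def _fit_circle(xy: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kåsa) least-squares circle fit; returns (center, radius)."""
    a = np.column_stack([2 * xy[:, 0], 2 * xy[:, 1], np.ones(len(xy))])
    b = (xy**2).sum(axis=1)
    (cx, cy, c), *_ = np.linalg.lstsq(a, b, rcond=None)
    return np.array([cx, cy]), float(math.sqrt(c + cx**2 + cy**2))


def curve_from_control_points(
    control: np.ndarray,
    spec: CurveSpec,
    *,
    check_length: bool = True,
) -> MyofibrilCurve:
    """Build a :class:`MyofibrilCurve` from explicit degree-4 control points."""
    control = np.asarray(control, dtype=float)
    if control.shape != (5, 2):
        raise CurveGeometryError(f"expected 5 planar control points, got {control.shape}")
    t = np.linspace(0.0, 1.0, _N_SAMPLES)
    xy = _bezier_point(control, t)
    deriv = _bezier_derivative(control, t)
    speed = np.linalg.norm(deriv, axis=-1)
    s = cumulative_trapezoid(speed, t, initial=0.0)
    length = _gauss_arclength(control)
    if s[-1] > 0:
        s *= length / s[-1]

    monotone_x = bool(np.all(deriv[:, 0] > 0))
    if monotone_x:
        max_slope = float(np.max(np.abs(deriv[:, 1] / deriv[:, 0])))
    else:
        max_slope = math.inf
    single_valued = monotone_x and max_slope <= MAX_SLOPE
    if not single_valued:
        logger.warning(
            "curve (L_c=%.3g, R_c=%s) is not single-valued in the aligned frame "
            "(max |dy/dx| = %.3g); lateral dynamics cannot run on it",
            spec.length,
            "straight" if spec.is_straight else f"{spec.curvature_radius:.3g}",
            max_slope,
        )

    if check_length and abs(length - spec.length) > LENGTH_RTOL * spec.length:
        raise CurveGeometryError(
            f"realized arclength {length:.4f} µm deviates more than "
            f"{LENGTH_RTOL:.0%} from the requested {spec.length} µm"
        )

    realized_radius = None
    if not spec.is_straight:
        _, realized_radius = _fit_circle(xy[:: max(1, _N_SAMPLES // 500)])

    return MyofibrilCurve(
        spec=spec,
        control_points=control,
        t_grid=t,
        xy_grid=xy,
        s_grid=s,
        realized_length=length,
        realized_radius=realized_radius,
        single_valued=single_valued,
        max_slope=max_slope,
    )


def build_curve(spec: CurveSpec) -> MyofibrilCurve:
    """Construct the degree-4 Bézier realization of ``spec`` in the aligned frame.

    Straight fibrils are horizontal segments from the origin.  Curved fibrils
    are least-squares fits to the circular arc of radius ``R_c`` subtending
    ``L_c / R_c`` radians, with its chord on the x-axis and the bulge upward;
    the fit is verified to stay within 1% of both the target arclength and the
    target circle.
    """
    if spec.is_straight:
        control = np.column_stack([np.linspace(0.0, spec.length, 5), np.zeros(5)])
        return curve_from_control_points(control, spec)

    radius = spec.curvature_radius
    theta = spec.length / radius
    half = theta / 2.0
    center = np.array([radius * math.sin(half), -radius * math.cos(half)])
    phi = np.linspace(math.pi / 2 + half, math.pi / 2 - half, _N_FIT)
    target = center + radius * np.column_stack([np.cos(phi), np.sin(phi)])

    tpar = np.linspace(0.0, 1.0, _N_FIT)
    basis = _bernstein_matrix(tpar)
    rhs = target - np.outer(basis[:, 0], target[0]) - np.outer(basis[:, 4], target[-1])
    mid, *_ = np.linalg.lstsq(basis[:, 1:4], rhs, rcond=None)
    control = np.vstack([target[0], mid, target[-1]])

    curve = curve_from_control_points(control, spec)
    deviation = np.abs(
        np.linalg.norm(curve.xy_grid - center, axis=1) - radius
    ).max()
    if deviation > RADIUS_RTOL * radius:
        raise CurveGeometryError(
            f"Bézier fit deviates {deviation:.4g} µm from the target arc "
            f"(> {RADIUS_RTOL:.0%} of R_c = {radius} µm)"
        )
    return curve


def align_to_axis(curve: MyofibrilCurve) -> tuple[MyofibrilCurve, AxisTransform]:
    """Rigidly move ``curve`` so its endpoints lie on the x-axis, start at origin.

    Returns the aligned curve and the transform that achieves it.  Raises
    :class:`CurveGeometryError` when the aligned curve is not expressible as a
    single-valued function y(x).
    """
    p_start = curve.control_points[0]
    p_end = curve.control_points[-1]
    delta = p_end - p_start
    angle = math.atan2(delta[1], delta[0])
    rot = np.array(
        [[math.cos(-angle), -math.sin(-angle)], [math.sin(-angle), math.cos(-angle)]]
    )
    transform = AxisTransform(rotation=rot, translation=-rot @ p_start)
    aligned = curve_from_control_points(
        transform.apply(curve.control_points), curve.spec
    )
    aligned._require_single_valued()
    return aligned, transform


def point_on_curve(curve: MyofibrilCurve, x: float) -> np.ndarray:
    """On-curve planar point at lateral coordinate ``x`` (aligned frame)."""
    return curve.point_at_x(x)
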