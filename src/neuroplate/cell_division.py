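"""Cell division modelled by rational Bezier curves with complex weights.

The cellular cortex — the actin–myosin shell that sets a dividing cell's
shape and polarity — is represented by bundles of rational Bezier curves
arranged radially around the division centre.  Complex control weights
stand for the complex-valued fibre structure; the geometric realisation
projects the complex curve back to real coordinates.  A winding-number
routine quantifies how a closed cortex curve encircles the centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class Stage(str, Enum):
    PRE_DIVISION = "pre_division"
    POST_DIVISION = "post_division"


class Projection(str, Enum):
    REAL = "real"  # real part per coordinate (default)
    MODULUS = "modulus"  # |z| carrying the sign of the real part


@dataclass(frozen=True)
class ControlPolygon:
    """Control points P_i (3D, real) with one complex weight W_i each."""

    points: np.ndarray  # (n+1, 3) real
    weights: np.ndarray  # (n+1,) complex

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim == 1:  # scalar control points (1D worked examples)
            pts = pts[:, None]
        w = np.atleast_1d(np.asarray(self.weights, dtype=complex))
        if pts.shape[0] < 2:
            raise ValueError("need at least 2 control points")
        if pts.shape[0] != w.shape[0]:
            raise ValueError("points and weights must have equal counts")
        if np.all(np.abs(w) == 0):
            raise ValueError("weights must not all be zero")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", w)

    @property
    def degree(self) -> int:
        return self.points.shape[0] - 1


@dataclass
class CurveBundle:
    """Radially arranged sampled curves around a common division centre."""

    curves: list  # list of dicts: {t, complex_points (m,3), real_points (m,3)}
    center: np.ndarray
    stage: Stage

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        for c in self.curves:
            if len(c["t"]) < 2:
                raise ValueError("every curve needs >= 2 samples")


def bernstein(n: int, i: int, t) -> np.ndarray | float:
    """Bernstein basis polynomial b_{i,n}(t) = C(n,i) tⁱ (1−t)^{n−i}."""
    if not (0 <= i <= n):
        raise IndexError(f"index i={i} outside [0, {n}]")
    t = np.asarray(t, dtype=float)
    out = math.comb(n, i) * t**i * (1.0 - t) ** (n - i)
    return float(out) if out.ndim == 0 else out


def _project(z: np.ndarray, projection: Projection) -> np.ndarray:
    if projection is Projection.REAL:
        return z.real
    return np.abs(z) * np.sign(z.real + (z.real == 0))


def rational_bezier(
    polygon: ControlPolygon,
    t,
    projection: Projection = Projection.REAL,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the rational Bezier curve B(t) = Σ b_{i,n} P_i W_i / Σ b_{i,n} W_i.

    Complex weights make B(t) complex even for real control points.
    Returns ``(complex_point, real_projection)``; for an array of t values
    the leading axis runs over samples.  Raises if the weight denominator
    vanishes at any requested t.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any((t_arr < 0) | (t_arr > 1)):
        raise ValueError("t must lie in [0, 1]")
    n = polygon.degree
    basis = np.stack([bernstein(n, i, t_arr) for i in range(n + 1)], axis=1)
    wb = basis * polygon.weights[None, :]  # (m, n+1)
    denom = wb.sum(axis=1)
    bad = np.abs(denom) < 1e-14
    if np.any(bad):
        raise ZeroDivisionError(
            f"vanishing weight denominator at t={t_arr[bad][0]:.6g}"
        )
    num = wb @ polygon.points.astype(complex)  # (m, 3)
    pts = num / denom[:, None]
    proj = _project(pts, projection)
    if np.ndim(t) == 0:
        return pts[0], proj[0]
    return pts, proj


def _rotation_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _meridian_polygon(pinch: float) -> np.ndarray:
    """Meridian control points of a convex lobe in the x–z plane.

    ``pinch`` in [0, 1] pulls the equatorial control point toward the
    polar axis, producing the two-lobe post-division figure at large
    pinch.  Unit-ish cell size, arbitrary units.
    """
    r_eq = 1.0 - pinch
    return np.array(
        [
            [0.0, 0.0, -1.0],
            [1.0, 0.0, -1.0],
            [r_eq, 0.0, 0.0],
            [1.0, 0.0, 1.0],
            [0.0, 0.0, 1.0],
        ]
    )


def division_body(
    center,
    n_meridians: int,
    weight_schedule,
    stage: Stage = Stage.PRE_DIVISION,
    pinch: float = 0.8,
    samples: int = 64,
    projection: Projection = Projection.REAL,
) -> CurveBundle:
    """Radial bundle of rational Bezier meridians simulating a dividing cell.

    ``n_meridians`` curves share the same meridian control polygon, rotated
    about the polar (z) axis through ``center``.  ``stage=pre_division``
    yields one convex lobe; ``stage=post_division`` applies ``pinch`` to
    the equator, separating the body into two lobes.  The weight schedule
    (complex, one entry per control point) is shared by all meridians, so
    the bundle is invariant under rotation by 2π/n_meridians.
    """
    if n_meridians < 3:
        raise ValueError("n_meridians must be >= 3")
    center = np.asarray(center, dtype=float)
    eff_pinch = pinch if stage is Stage.POST_DIVISION else 0.0
    base = _meridian_polygon(eff_pinch)
    weights = np.asarray(weight_schedule, dtype=complex)
    if weights.shape[0] != base.shape[0]:
        raise ValueError(
            f"weight_schedule length {weights.shape[0]} != polygon size {base.shape[0]}"
        )
    t = np.linspace(0.0, 1.0, samples)
    curves = []
    for k in range(n_meridians):
        rot = _rotation_z(2.0 * math.pi * k / n_meridians)
        poly = ControlPolygon(base @ rot.T + center, weights)
        cpts, rpts = rational_bezier(poly, t, projection)
        curves.append({"t": t, "complex_points": cpts, "real_points": rpts})
    return CurveBundle(curves, center, stage)


def winding_number(curve: np.ndarray, point, tol: float = 1e-9) -> int:
    """Winding number of a closed planar polyline about ``point``.

    Sums signed angle increments between consecutive samples; the total
    must land within 1e−6 of an integer multiple of 2π.  The curve must
    be closed (first sample = last) and the point must not lie on it.
    """
    curve = np.asarray(curve, dtype=float)
    point = np.asarray(point, dtype=float)
    if curve.ndim != 2 or curve.shape[1] != 2:
        raise ValueError("curve must be an (m, 2) planar polyline")
    if not np.allclose(curve[0], curve[-1], atol=1e-12):
        raise ValueError("curve must be closed (first sample == last)")
    rel = curve - point
    dist = np.hypot(rel[:, 0], rel[:, 1])
    if np.any(dist < tol):
        raise ValueError("point lies on the curve (degenerate input)")
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    dang = np.diff(ang)
    dang = (dang + np.pi) % (2.0 * np.pi) - np.pi
    total = dang.sum() / (2.0 * np.pi)
    nearest = round(total)
    if abs(total - nearest) > 1e-6:
        raise ArithmeticError(
            f"winding sum {total:.8f} not within 1e-6 of an integer; "
            "curve undersampled?"
        )
    return int(nearest)


def cuboctahedral_centers(radius: float = 2.0) -> np.ndarray:
    """Plotting preset: the 12 cuboctahedral sphere centres around one cell.

    The classic 12-neighbour arrangement referenced by the kissing-number
    analogy; provided for visualisation only, no packing optimisation.
    """
    pts = []
    for a, b in [(1, 1), (1, -1), (-1, 1), (-1, -1)]:
        pts += [[a, b, 0], [a, 0, b], [0, a, b]]
    arr = np.array(pts, dtype=float)
    return radius * arr / np.sqrt(2.0)
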