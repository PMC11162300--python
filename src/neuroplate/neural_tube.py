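"""Neural-tube model: mirrored triple curves and the single-neuron unit field.

The CNS midline and the two hemispheres are represented by a triple
B = {C, S, S'} of planar curves: S and S' are mirror images of each
other about the midline C, crossing it wherever the oscillatory
envelope changes sign (a Mobius-style weave).  The envelope is derived
from the phase of the zeta field L = ζ(e^{iπxy}) on a fixed y-slice,
the stated link between the curve model and the field equation.

The single-neuron unit field is F = e^{πTxy} on a rectangular grid with
T = θ(t); the ``eq4`` variant ties t to an integer index n through the
Gram-time formula, the ``eq5`` variant takes t as a free parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .math_core import (
    GridField,
    ThetaConfig,
    ThetaMode,
    gram_time,
    riemann_siegel_theta,
    zeta_on_circle,
)


class FieldVariant(str, Enum):
    EQ4 = "eq4"  # t = gram_time(n)
    EQ5 = "eq5"  # t a free per-field constant


@dataclass
class TripleCurve:
    """Midline C with mirrored hemispheres S, S' sampled on common x values."""

    x: np.ndarray
    C: np.ndarray
    S: np.ndarray
    S_prime: np.ndarray
    crossings: list = field(default_factory=list)
    degenerate: bool = False

    def __post_init__(self) -> None:
        n = len(self.x)
        if not (len(self.C) == len(self.S) == len(self.S_prime) == n):
            raise ValueError("C, S, S' must share the x sample count")
        if np.max(np.abs(self.S + self.S_prime - 2.0 * self.C)) > 1e-9:
            raise ValueError("S and S' must mirror about C (|S + S' - 2C| < 1e-9)")


@dataclass
class NeuronUnitField:
    field: GridField
    variant: FieldVariant
    n: int | None
    t: float
    theta: float


def _zeta_phase_envelope(y_slice: float = 1.0) -> Callable[[np.ndarray], np.ndarray]:
    """Oscillatory envelope w(x) = sin(arg ζ(e^{iπ x y₀})) from the field phase.

    The phase of the zeta field restricted to the y = y₀ slice; the sine
    makes w a sign-changing envelope with zeros where the field is real.
    Vectorised with a small cache since ζ(e^{iπp}) is periodic in p.
    """
    cache: dict[float, float] = {}

    def w(x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.empty(x.shape)
        for i, xv in enumerate(x):
            p = math.remainder(xv * y_slice, 2.0)
            key = round(p, 12)
            if key not in cache:
                try:
                    cache[key] = math.sin(np.angle(zeta_on_circle(key)))
                except ZeroDivisionError:
                    cache[key] = 0.0  # pole of the field: neutral envelope
            out[i] = cache[key]
        return out

    return w


def triple_curve(
    x_range: tuple[float, float] = (0.0, 2.0 * math.pi),
    frequency: float = 1.0,
    amplitude: float = 1.0,
    midline: Callable | None = None,
    envelope: Callable | str = "sine",
    samples: int = 512,
) -> TripleCurve:
    """Build the triple {C, S, S'} with S = C + A·w(fx), S' = C − A·w(fx).

    ``envelope`` selects the oscillation w: "sine" (unit sine), "zeta"
    (phase of the zeta field on the default y-slice), or any callable.
    ``midline`` defaults to the zero function (a straight midline).
    Crossings of S and S' through C are located where w changes sign.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    x = np.linspace(x_range[0], x_range[1], samples)
    C = np.zeros_like(x) if midline is None else np.asarray(midline(x), dtype=float)
    if isinstance(envelope, str):
        if envelope == "sine":
            w_fn: Callable = lambda u: np.sin(u)  # noqa: E731
        elif envelope == "zeta":
            w_fn = _zeta_phase_envelope()
        else:
            raise ValueError(f"unknown envelope {envelope!r}")
    else:
        w_fn = envelope
    w = amplitude * np.asarray(w_fn(frequency * x), dtype=float)
    tc = TripleCurve(x, C, C + w, C - w)
    tc.degenerate = bool(np.max(np.abs(w)) < 1e-15)
    if not tc.degenerate:
        tc.crossings = crossing_points(tc)
    return tc


def crossing_points(tc: TripleCurve, tol: float = 1e-8) -> list[float]:
    """x locations where S crosses the midline C, refined by bisection.

    Sign changes of S − C between adjacent samples are refined to ``tol``
    with Brent/bisection on linear interpolation of the samples.  The
    half-open convention [x_k, x_{k+1}) reports a crossing at a shared
    sample point exactly once.  By mirror symmetry the list for S' − C
    is identical.
    """
    d = tc.S - tc.C
    if np.max(np.abs(d)) < 1e-15:
        tc.degenerate = True
        return []
    x = tc.x
    crossings: list[float] = []
    for k in range(len(x) - 1):
        a, b = d[k], d[k + 1]
        if a == 0.0:
            # exact zero at an interior sample counts once (half-open
            # convention: the domain's own endpoints are not crossings)
            if 0 < k and d[k - 1] * b < 0:
                crossings.append(float(x[k]))
            continue
        if a * b < 0:
            f = lambda u: np.interp(u, x[k : k + 2], d[k : k + 2])  # noqa: E731
            root = brentq(f, x[k], x[k + 1], xtol=tol)
            crossings.append(float(root))
    return crossings


def neuron_unit_field(
    x_range: tuple[float, float] = (-20.0, 20.0),
    y_range: tuple[float, float] = (0.1, 1.0),
    resolution: tuple[int, int] = (400, 100),
    variant: FieldVariant = FieldVariant.EQ5,
    n: int | None = None,
    t: float = 1.0,
    theta_mode: ThetaMode = ThetaMode.PRINTED,
) -> NeuronUnitField:
    """Single-neuron unit field F = e^{πTxy} with T = θ(t).

    variant eq4: t = gram_time(n) for the supplied integer n;
    variant eq5: t is the supplied per-field constant (default 1).
    Points where the printed theta is undefined (t ≤ 0) would be masked;
    with the Gram-time clock t > 0 always holds on the default n range.
    """
    if y_range[0] <= 0 or y_range[1] > 1.0:
        raise ValueError("y_range must lie within (0, 1]")
    variant = FieldVariant(variant)
    if variant is FieldVariant.EQ4:
        if n is None:
            raise ValueError("variant eq4 requires the index n")
        t_val = gram_time(n)
    else:
        t_val = float(t)
    cfg = ThetaConfig(mode=theta_mode)
    try:
        theta = riemann_siegel_theta(t_val, cfg)
    except ValueError:
        xs = np.linspace(*x_range, resolution[0])
        ys = np.linspace(*y_range, resolution[1])
        vals = np.full((len(xs), len(ys)), np.nan, dtype=complex)
        gf = GridField(xs, ys, vals, np.ones_like(vals, dtype=bool))
        return NeuronUnitField(gf, variant, n, t_val, math.nan)
    xs = np.linspace(x_range[0], x_range[1], resolution[0])
    ys = np.linspace(y_range[0], y_range[1], resolution[1])
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    F = np.exp(math.pi * theta * X * Y).astype(complex)
    gf = GridField(xs, ys, F, meta={"variant": variant.value, "t": t_val})
    return NeuronUnitField(gf, variant, n, t_val, theta)
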