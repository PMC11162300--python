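"""Shared special functions and numerical kernels.

Pascal and Hermite coefficient rows (the candidate "numerical maps" for
layered tissue growth), the principal-branch Lambert W function and the
Gram-time formula built on it, the Riemann–Siegel theta function in two
conventions, a zeta field on the unit circle, the two-stage (midpoint)
Runge–Kutta step, contour-integral Laurent coefficients, and a checked
SVD wrapper.

Arbitrary-precision evaluation (mpmath, 30 digits) backs the gamma/zeta
kernels; results are returned as ordinary floats/complex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import mpmath
import numpy as np
import sympy

_MP_DPS = 30  # internal working precision, decimal digits


class RowKind(str, Enum):
    PASCAL = "pascal"
    HERMITE = "hermite"
    CUSTOM = "custom"


@dataclass(frozen=True)
class CoefficientRow:
    """One row of a numerical map: degree-n polynomial coefficients.

    For ``pascal`` rows the coefficients are the binomial numbers
    C(n, 0..n); for ``hermite`` rows they are the physicists' Hermite
    polynomial H_n written densely from degree n down to 0.
    """

    degree: int
    coefficients: tuple
    kind: RowKind = RowKind.CUSTOM

    def __post_init__(self) -> None:
        if self.degree < 0:
            raise ValueError("degree must be non-negative")
        if len(self.coefficients) != self.degree + 1:
            raise ValueError(
                f"row of degree {self.degree} needs {self.degree + 1} "
                f"coefficients, got {len(self.coefficients)}"
            )


class ThetaMode(str, Enum):
    #: conjugate-gamma-pair form −ln(πt)/2 − (i/2)[lnΓ(1/4+it/4) − lnΓ(1/4−it/4)]
    PRINTED = "printed"
    #: textbook Riemann–Siegel theta arg Γ(1/4 + it/2) − (t/2) ln π
    STANDARD = "standard"


@dataclass(frozen=True)
class ThetaConfig:
    mode: ThetaMode = ThetaMode.PRINTED
    precision: int = _MP_DPS

    def __post_init__(self) -> None:
        if self.precision < 15:
            raise ValueError("precision must be >= 15 digits")


@dataclass
class GridField:
    """Complex field sampled on a rectangular (x, y) grid.

    ``values[i, j]`` corresponds to ``(x[i], y[j])``.  ``mask`` flags
    samples where the field is undefined (e.g. a pole); masked entries
    hold NaN and must not be interpreted as finite values.
    """

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.shape != (self.x.size, self.y.size):
            raise ValueError("values shape must be (len(x), len(y))")
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")


# ---------------------------------------------------------------------------
# coefficient rows


def pascal_row(n: int) -> CoefficientRow:
    """Row ``n`` of Pascal's triangle: binomial coefficients C(n, 0..n).

    Exact integer arithmetic for any n; rows are symmetric and sum to 2^n.
    """
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool):
        raise TypeError("n must be an integer")
    if n < 0:
        raise ValueError("n must be non-negative")
    coeffs = [math.comb(int(n), k) for k in range(int(n) + 1)]
    return CoefficientRow(int(n), tuple(coeffs), RowKind.PASCAL)


def hermite_row(n: int) -> CoefficientRow:
    """Coefficients of the physicists' Hermite polynomial H_n.

    Produced by symbolic differentiation of the Rodrigues formula
    H_n(x) = (−1)^n e^{x²} dⁿ/dxⁿ e^{−x²}; coefficients are returned
    densely from the x^n term down to the constant (zeros included),
    so the leading coefficient is 2^n.
    """
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool):
        raise TypeError("n must be an integer")
    if n < 0:
        raise ValueError("n must be non-negative")
    x = sympy.Symbol("x")
    expr = sympy.expand(
        (-1) ** n * sympy.exp(x**2) * sympy.diff(sympy.exp(-(x**2)), x, int(n))
    )
    poly = sympy.Poly(expr, x)
    coeffs = [int(c) for c in poly.all_coeffs()]
    return CoefficientRow(int(n), tuple(coeffs), RowKind.HERMITE)


# ---------------------------------------------------------------------------
# Lambert W and Gram time


def lambert_w0(x: float) -> float:
    """Principal branch W₀ of the Lambert W function for real x ≥ −1/e."""
    x = float(x)
    if x < -1.0 / math.e:
        raise ValueError(f"lambert_w0 requires x >= -1/e, got {x}")
    with mpmath.workdps(_MP_DPS):
        w = mpmath.lambertw(mpmath.mpf(x), k=0)
    return float(mpmath.re(w))


def gram_time(n: int | float) -> float:
    """Gram-style time t = 2π(n + 1/8) / W₀(e^{−n−1/8}).

    The printed one-parameter clock tying the integer index n to the
    argument of the theta function; monotone increasing in n.
    """
    nn = float(n)
    return 2.0 * math.pi * (nn + 0.125) / lambert_w0(math.exp(-nn - 0.125))


# ---------------------------------------------------------------------------
# Riemann–Siegel theta


def riemann_siegel_theta(t: float, config: ThetaConfig | None = None) -> float:
    """Riemann–Siegel theta in either the printed or the standard convention.

    printed:  −ln(πt)/2 − (i/2)[lnΓ(1/4 + it/4) − lnΓ(1/4 − it/4)]
              (conjugate-pair form, real for t > 0; requires t > 0)
    standard: arg Γ(1/4 + it/2) − (t/2) ln π   (odd in t, defined at all real t)

    Log-gamma uses mpmath's continuous branch so theta is continuous in t.
    """
    if config is None:
        config = ThetaConfig()
    t = float(t)
    with mpmath.workdps(config.precision):
        if config.mode is ThetaMode.PRINTED:
            if t <= 0:
                raise ValueError("printed-mode theta requires t > 0")
            bracket = mpmath.loggamma(mpmath.mpf("0.25") + 0.25j * t) - mpmath.loggamma(
                mpmath.mpf("0.25") - 0.25j * t
            )
            val = -mpmath.log(mpmath.pi * t) / 2 - 0.5j * bracket
            return float(mpmath.re(val))
        # standard
        lg = mpmath.loggamma(mpmath.mpf("0.25") + 0.5j * t)
        return float(mpmath.im(lg) - (t / 2) * mpmath.log(mpmath.pi))


# ---------------------------------------------------------------------------
# zeta field on the unit circle

_POLE_TOL = 1e-6


def zeta_field(
    x_range: tuple[float, float] = (-20.0, 20.0),
    y_range: tuple[float, float] = (-1.0, 1.0),
    resolution: tuple[int, int] = (81, 41),
) -> GridField:
    """L = ζ(e^{iπxy}) over a rectangular grid, poles masked.

    The argument e^{iπxy} lies on the unit circle; ζ is evaluated there by
    analytic continuation.  Grid points whose argument falls within 1e−6
    of 1 (the only pole of ζ) are masked rather than raised.
    """
    nx, ny = resolution
    if nx < 2 or ny < 2:
        raise ValueError("resolution must be >= 2 per axis")
    xs = np.linspace(x_range[0], x_range[1], nx)
    ys = np.linspace(y_range[0], y_range[1], ny)
    values = np.empty((nx, ny), dtype=complex)
    mask = np.zeros((nx, ny), dtype=bool)
    cache: dict[float, complex] = {}
    with mpmath.workdps(_MP_DPS):
        for i, xv in enumerate(xs):
            for j, yv in enumerate(ys):
                p = xv * yv
                # e^{iπp} periodic in p with period 2
                key = round(math.remainder(p, 2.0), 12)
                if key in cache:
                    z = cache[key]
                else:
                    arg = mpmath.e ** (1j * mpmath.pi * mpmath.mpf(key))
                    if abs(arg - 1) < _POLE_TOL:
                        z = complex(np.nan, np.nan)
                    else:
                        z = complex(mpmath.zeta(arg))
                    cache[key] = z
                if z != z:  # NaN marks the masked pole
                    mask[i, j] = True
                    values[i, j] = complex(np.nan, np.nan)
                else:
                    values[i, j] = z
    return GridField(
        xs, ys, values, mask, meta={"x_range": x_range, "y_range": y_range}
    )


def zeta_on_circle(p: float) -> complex:
    """ζ(e^{iπp}) at a single phase parameter p; raises at the pole p ≡ 0 (mod 2)."""
    with mpmath.workdps(_MP_DPS):
        arg = mpmath.e ** (1j * mpmath.pi * mpmath.mpf(p))
        if abs(arg - 1) < _POLE_TOL:
            raise ZeroDivisionError("zeta pole: argument equals 1")
        return complex(mpmath.zeta(arg))


# ---------------------------------------------------------------------------
# midpoint Runge–Kutta


def rk2_step(f: Callable, x: float, y, h: float):
    """One step of the two-stage midpoint Runge–Kutta scheme.

    K₁ = h·f(x, y); K₂ = h·f(x + h/2, y + K₁/2); returns y + K₂.
    Local truncation error O(h³), observed global order 2.
    """
    if h <= 0:
        raise ValueError("step size h must be positive")
    y = np.asarray(y, dtype=float) if not np.isscalar(y) else y
    k1 = h * np.asarray(f(x, y), dtype=float)
    k2 = h * np.asarray(f(x + h / 2.0, y + k1 / 2.0), dtype=float)
    if not np.all(np.isfinite(k1)) or not np.all(np.isfinite(k2)):
        raise ArithmeticError(f"non-finite rhs evaluation near x={x}")
    out = y + k2
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Laurent coefficients by contour quadrature


def laurent_coefficients(
    f: Callable[[complex], complex],
    center: complex,
    orders: Sequence[int],
    radius: float,
    samples: int = 512,
) -> list[complex]:
    """Laurent coefficients aₙ of f about ``center`` on |z − c| = radius.

    aₙ = (1/2πi) ∮ f(z)(z−c)^{−n−1} dz, evaluated by the trapezoid rule on
    ``samples`` equispaced points of the circle (spectrally accurate for f
    analytic on the contour).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    samples = max(int(samples), 256)
    th = 2.0 * np.pi * np.arange(samples) / samples
    z = center + radius * np.exp(1j * th)
    fz = np.array([f(zi) for zi in z], dtype=complex)
    if not np.all(np.isfinite(fz)):
        raise ArithmeticError("f is non-finite on the integration contour")
    out = []
    for n in orders:
        integrand = fz * (radius * np.exp(1j * th)) ** (-n)
        out.append(complex(integrand.mean()))
    return out


# ---------------------------------------------------------------------------
# SVD with reconstruction contract


def svd_factor(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """M = U Σ V* with Σ returned as a descending non-negative vector.

    Thin wrapper over LAPACK enforcing the reconstruction contract
    ‖UΣV* − M‖ < 1e−10·‖M‖.
    """
    M = np.asarray(M)
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix must be finite")
    U, s, Vh = np.linalg.svd(M, full_matrices=False)
    recon = (U * s) @ Vh
    scale = np.linalg.norm(M) or 1.0
    if np.linalg.norm(recon - M) >= 1e-10 * scale:
        raise ArithmeticError("SVD reconstruction contract violated")
    return U, s, Vh
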