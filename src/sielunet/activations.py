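"""Activation functions and the normal-approximation numerics behind SIELU.

SIELU ("Gaussian Error Linear Unit with Sigmoid") is the tanh-form GELU
rewritten through the identity tanh(y) = 2*sigmoid(2y) - 1::

    gelu_tanh(x) = 0.5*x*(1 + tanh(sqrt(2/pi)*(x + 0.044715*x**3)))
    sielu(x)     = x * sigmoid(2*sqrt(2/pi)*(x + 0.044715*x**3))

The two are mathematically identical; the sigmoid form avoids a separate
tanh evaluation.  Both approximate the exact GELU x*Phi(x), where Phi is the
standard normal CDF.  This module also implements the classical rational
approximations of the normal quantile (Hastings 1955 / Abramowitz & Stegun
26.2.22-23) and a composite-exponential approximation of Phi(z) - 0.5, plus
an ``error_scan`` harness that measures each approximation against a
high-precision scipy oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy import special

__all__ = [
    "ActivationParams",
    "NormalApproxConstants",
    "ErrorScanReport",
    "DEFAULT_PARAMS",
    "DEFAULT_CONSTANTS",
    "sigmoid",
    "tanh_act",
    "relu",
    "leaky_relu",
    "softmax",
    "gelu_tanh",
    "gelu_tanh_grad",
    "sielu",
    "sielu_grad",
    "exact_normal_cdf",
    "inverse_normal_rational",
    "hastings_inverse",
    "cdf_composite_exponential",
    "error_scan",
    "get_activation",
]

GELU_SCALE = math.sqrt(2.0 / math.pi)
GELU_CUBIC_COEFF = 0.044715


@dataclass(frozen=True)
class ActivationParams:
    """Shape parameters of the activation family.

    leaky_slope
        Negative-branch slope of LeakyReLU (dimensionless, > 0).
    gelu_cubic_coeff, gelu_scale
        The 0.044715 cubic coefficient and sqrt(2/pi) scale of the tanh-form
        GELU; fixed constants unless explicitly overridden.
    """

    leaky_slope: float = 0.01
    gelu_cubic_coeff: float = GELU_CUBIC_COEFF
    gelu_scale: float = GELU_SCALE

    def __post_init__(self) -> None:
        if not self.leaky_slope > 0:
            raise ValueError(f"leaky_slope must be > 0, got {self.leaky_slope}")


@dataclass(frozen=True)
class NormalApproxConstants:
    """Printed constants of the historical normal-distribution approximations.

    ``hastings4``/``hastings6`` are the 1955 Hastings quantile fits
    (Abramowitz & Stegun 26.2.22 and 26.2.23); ``as_inverse`` is the rational
    inverse-normal approximation with |e(p)| < 4.5e-4, which shares the
    6-constant Hastings values exactly.
    """

    hastings4: tuple[float, ...] = (2.30753, 0.27061, 0.99229, 0.04481)
    hastings6: tuple[float, ...] = (
        2.515517, 0.802853, 0.010328, 1.432788, 0.189269, 0.001308,
    )
    as_inverse: tuple[float, ...] = (
        2.515517, 0.802853, 0.010328, 1.432788, 0.189269, 0.001308,
    )


DEFAULT_PARAMS = ActivationParams()
DEFAULT_CONSTANTS = NormalApproxConstants()


@dataclass(frozen=True)
class ErrorScanReport:
    """Result of a grid scan of |approximation - oracle|."""

    grid_lo: float
    grid_hi: float
    grid_step: float
    max_abs_error: float
    argmax: float

    def to_dict(self) -> dict:
        return {
            "grid_lo": self.grid_lo,
            "grid_hi": self.grid_hi,
            "grid_step": self.grid_step,
            "max_abs_error": self.max_abs_error,
            "argmax": self.argmax,
        }


def _validated(x, name: str = "x") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(arr))
        loc = tuple(bad[0]) if bad.size else ()
        raise ValueError(
            f"non-finite value in {name} at index {loc}: "
            f"{arr[tuple(bad[0])] if bad.size else arr}"
        )
    return arr


def _like_input(out: np.ndarray, x) -> np.ndarray | float:
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


def sigmoid(x):
    """Logistic function 1/(1+exp(-x)), overflow-safe for any finite input."""
    arr = _validated(x)
    out = np.empty_like(arr)
    pos = arr >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-arr[pos]))
    ex = np.exp(arr[~pos])
    out[~pos] = ex / (1.0 + ex)
    return _like_input(out, x)


def tanh_act(x):
    """Hyperbolic tangent, equal to 2/(1+exp(-2x)) - 1."""
    return _like_input(np.tanh(_validated(x)), x)


def relu(x):
    """max(x, 0); the x >= 0 branch is the identity (0 maps to 0)."""
    arr = _validated(x)
    return _like_input(np.where(arr >= 0, arr, 0.0), x)


def leaky_relu(x, params: ActivationParams = DEFAULT_PARAMS):
    """x for x >= 0, leaky_slope*x otherwise; continuous and increasing."""
    arr = _validated(x)
    return _like_input(np.where(arr >= 0, arr, params.leaky_slope * arr), x)


def softmax(v):
    """Probability vector exp(v_j)/sum_k exp(v_k), max-shifted for stability."""
    arr = _validated(v, "v")
    if arr.size == 0:
        raise ValueError("softmax of an empty vector is undefined")
    shifted = arr - arr.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def _gelu_inner(arr: np.ndarray, params: ActivationParams) -> np.ndarray:
    return params.gelu_scale * (arr + params.gelu_cubic_coeff * arr**3)


def gelu_tanh(x, params: ActivationParams = DEFAULT_PARAMS):
    """tanh-form GELU: 0.5*x*(1 + tanh(sqrt(2/pi)*(x + 0.044715*x^3)))."""
    arr = _validated(x)
    return _like_input(0.5 * arr * (1.0 + np.tanh(_gelu_inner(arr, params))), x)


def gelu_tanh_grad(x, params: ActivationParams = DEFAULT_PARAMS):
    """Analytic derivative of :func:`gelu_tanh`."""
    arr = _validated(x)
    y = _gelu_inner(arr, params)
    t = np.tanh(y)
    dy = params.gelu_scale * (1.0 + 3.0 * params.gelu_cubic_coeff * arr**2)
    return _like_input(0.5 * (1.0 + t) + 0.5 * arr * (1.0 - t**2) * dy, x)


def sielu(x, params: ActivationParams = DEFAULT_PARAMS):
    """SIELU: x * sigmoid(2*sqrt(2/pi)*(x + 0.044715*x^3)).

    Identical to :func:`gelu_tanh` through tanh(y) = 2*sigmoid(2y) - 1.
    """
    arr = _validated(x)
    out = arr * np.asarray(sigmoid(2.0 * _gelu_inner(arr, params)))
    return _like_input(out, x)


def sielu_grad(x, params: ActivationParams = DEFAULT_PARAMS):
    """Analytic derivative of :func:`sielu`.

    With u = 2*sqrt(2/pi)*(x + c*x^3):  f'(x) = s(u) + x*s(u)*(1-s(u))*u'.
    """
    arr = _validated(x)
    u = 2.0 * _gelu_inner(arr, params)
    s = np.asarray(sigmoid(u))
    du = 2.0 * params.gelu_scale * (1.0 + 3.0 * params.gelu_cubic_coeff * arr**2)
    return _like_input(s + arr * s * (1.0 - s) * du, x)


def exact_normal_cdf(z):
    """High-precision standard normal CDF Phi(z) (scipy erf-based oracle)."""
    arr = _validated(z, "z")
    return _like_input(special.ndtr(arr), z)


def _rational_quantile(t: np.ndarray, numer: tuple, denom: tuple) -> np.ndarray:
    num = sum(c * t**i for i, c in enumerate(numer))
    den = 1.0 + sum(d * t ** (i + 1) for i, d in enumerate(denom))
    return t - num / den


def inverse_normal_rational(p, constants: NormalApproxConstants = DEFAULT_CONSTANTS):
    """Rational approximation of the upper-tail normal quantile Phi^-1(1-p).

    z = t - (C0 + C1 t + C2 t^2) / (1 + d1 t + d2 t^2 + d3 t^3) with
    t = sqrt(ln(1/p^2)); valid for 0 < p <= 0.5 with |error| < 4.5e-4.
    """
    arr = _validated(p, "p")
    if np.any((arr <= 0) | (arr > 0.5)):
        raise ValueError(f"p must lie in (0, 0.5], got {p}")
    t = np.sqrt(np.log(1.0 / arr**2))
    c = constants.as_inverse
    return _like_input(_rational_quantile(t, c[:3], c[3:]), p)


def hastings_inverse(
    q,
    constants: NormalApproxConstants = DEFAULT_CONSTANTS,
    variant: Literal["4-constant", "6-constant"] = "6-constant",
):
    """Hastings (1955) normal-quantile approximations.

    4-constant: X*(q) = eta - (a0 + a1 eta)/(1 + b1 eta + b2 eta^2);
    6-constant: the same form with the cubic denominator, numerically
    identical to :func:`inverse_normal_rational` (shared constants).
    eta = sqrt(ln(1/q^2)), for upper-tail 0 < q <= 0.5.
    """
    arr = _validated(q, "q")
    if np.any((arr <= 0) | (arr > 0.5)):
        raise ValueError(f"q must lie in (0, 0.5], got {q}")
    eta = np.sqrt(np.log(1.0 / arr**2))
    if variant == "4-constant":
        c = constants.hastings4
        out = _rational_quantile(eta, c[:2], c[2:])
    elif variant == "6-constant":
        c = constants.hastings6
        out = _rational_quantile(eta, c[:3], c[3:])
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return _like_input(out, q)


def cdf_composite_exponential(z):
    """Composite-exponential approximation of Phi(z) - 0.5 for z >= 0.

    Phi(z) - 0.5 ~= 0.5*sqrt(1 - (1/30)*[7 e^{-z^2/2} + 16 e^{-z^2(2-sqrt 2)}
    + (7 + pi z^2/4) e^{-z^2}]).  The bracket equals 30 at z = 0 (value 0) and
    vanishes as z -> inf (value 0.5).  Callers use Phi(-z) = 1 - Phi(z) for
    the lower half.
    """
    arr = _validated(z, "z")
    if np.any(arr < 0):
        raise ValueError(f"z must be >= 0 (use symmetry for z < 0), got {z}")
    z2 = arr**2
    bracket = (
        7.0 * np.exp(-z2 / 2.0)
        + 16.0 * np.exp(-z2 * (2.0 - math.sqrt(2.0)))
        + (7.0 + math.pi * z2 / 4.0) * np.exp(-z2)
    )
    inner = np.maximum(1.0 - bracket / 30.0, 0.0)
    return _like_input(0.5 * np.sqrt(inner), z)


def error_scan(
    approx_fn: Callable,
    oracle_fn: Callable,
    grid_lo: float,
    grid_hi: float,
    grid_step: float,
) -> ErrorScanReport:
    """Maximum absolute deviation of ``approx_fn`` from ``oracle_fn`` on a grid."""
    if not grid_lo < grid_hi:
        raise ValueError(f"grid_lo must be < grid_hi ({grid_lo} >= {grid_hi})")
    if not grid_step > 0:
        raise ValueError(f"grid_step must be > 0, got {grid_step}")
    n = int(np.floor((grid_hi - grid_lo) / grid_step + 1e-9)) + 1
    grid = grid_lo + grid_step * np.arange(n)
    if grid.size == 0:
        raise ValueError("empty scan grid")
    err = np.abs(np.asarray(approx_fn(grid)) - np.asarray(oracle_fn(grid)))
    k = int(np.argmax(err))
    return ErrorScanReport(
        grid_lo=float(grid_lo),
        grid_hi=float(grid_hi),
        grid_step=float(grid_step),
        max_abs_error=float(err[k]),
        argmax=float(grid[k]),
    )


_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {}


def _register() -> None:
    p = DEFAULT_PARAMS

    def d_sigmoid(x):
        s = np.asarray(sigmoid(x))
        return s * (1.0 - s)

    def d_tanh(x):
        return 1.0 - np.tanh(_validated(x)) ** 2

    def d_relu(x):
        return (np.asarray(_validated(x)) >= 0).astype(float)

    _ACTIVATIONS.update(
        {
            "sielu": (lambda x: sielu(x, p), lambda x: sielu_grad(x, p)),
            "gelu": (lambda x: gelu_tanh(x, p), lambda x: gelu_tanh_grad(x, p)),
            "relu": (relu, d_relu),
            "tanh": (tanh_act, d_tanh),
            "sigmoid": (sigmoid, d_sigmoid),
        }
    )


_register()


def get_activation(name: str) -> tuple[Callable, Callable]:
    """Return (function, derivative) for an activation name."""
    try:
        return _ACTIVATIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown activation {name!r}; choose from {sorted(_ACTIVATIONS)}"
        ) from None
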