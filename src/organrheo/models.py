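"""Closed-form responses of fractional and classical viscoelastic elements.

Three three-parameter models of soft-tissue shear response are provided:

* **S-FKV** (semi-fractional Kelvin–Voigt): a springpot (Scott–Blair
  element) in parallel with a dashpot, ``sigma = K_a * D^a[eps] + eta * deps/dt``.
* **FKV** (fractional Kelvin–Voigt): a springpot in parallel with a spring,
  ``sigma = K_a * D^a[eps] + G * eps``.
* **SLS** (standard linear solid / Zener): a spring in parallel with a
  spring–dashpot series arm.

All computation is carried out in SI units: moduli and the springpot
coefficient in Pa (Pa·s^alpha), viscosity in Pa·s, time in seconds.
kPa appears only at the reporting boundary (see :mod:`organrheo.io`).

Frequency convention
--------------------
The frequency-domain expressions are evaluated, by default, with the
oscillation frequency in ordinary Hz substituted directly for the angular
variable (``convention="hz"``).  This is the convention under which the
study's published high-frequency extrapolations are internally consistent.
``convention="rad"`` substitutes ``2*pi*f`` instead.  The flag is carried
into every fit result and report so numbers remain interpretable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import gamma as _gamma

__all__ = [
    "SFKVParams",
    "FKVParams",
    "SLSParams",
    "ComplexModulus",
    "StrainHistory",
    "GLResponse",
    "angular_argument",
    "sfkv_complex_modulus",
    "fkv_complex_modulus",
    "sls_complex_modulus",
    "sfkv_relaxation_modulus",
    "gl_stress_response",
]


class ParameterDomainError(ValueError):
    """Model parameters outside their physical domain."""


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ParameterDomainError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class SFKVParams:
    """Springpot in parallel with a dashpot.

    Parameters
    ----------
    k_alpha : float
        Coefficient of consistence of the springpot, Pa·s^alpha.  Must be > 0.
    alpha : float
        Fractional order, 0 <= alpha <= 1.  alpha = 0 degenerates to a spring
        of modulus ``k_alpha``; alpha = 1 to a dashpot of viscosity ``k_alpha``.
    eta : float
        Viscosity of the parallel dashpot, Pa·s.  Must be >= 0.
    """

    k_alpha: float
    alpha: float
    eta: float = 0.0

    def __post_init__(self) -> None:
        if _check_finite("k_alpha", self.k_alpha) <= 0:
            raise ParameterDomainError(f"k_alpha must be > 0, got {self.k_alpha}")
        if not 0.0 <= _check_finite("alpha", self.alpha) <= 1.0:
            raise ParameterDomainError(f"alpha must lie in [0, 1], got {self.alpha}")
        if _check_finite("eta", self.eta) < 0:
            raise ParameterDomainError(f"eta must be >= 0, got {self.eta}")

    @classmethod
    def from_kpa(cls, k_alpha_kpa: float, alpha: float, eta: float = 0.0) -> "SFKVParams":
        """Build from the reporting units: k_alpha in kPa·s^alpha, eta in Pa·s."""
        return cls(k_alpha=1e3 * k_alpha_kpa, alpha=alpha, eta=eta)


@dataclass(frozen=True)
class FKVParams:
    """Springpot in parallel with a spring (k_alpha Pa·s^alpha, g Pa)."""

    k_alpha: float
    alpha: float
    g: float = 0.0

    def __post_init__(self) -> None:
        if _check_finite("k_alpha", self.k_alpha) <= 0:
            raise ParameterDomainError(f"k_alpha must be > 0, got {self.k_alpha}")
        if not 0.0 <= _check_finite("alpha", self.alpha) <= 1.0:
            raise ParameterDomainError(f"alpha must lie in [0, 1], got {self.alpha}")
        if _check_finite("g", self.g) < 0:
            raise ParameterDomainError(f"g must be >= 0, got {self.g}")

    @classmethod
    def from_kpa(cls, k_alpha_kpa: float, alpha: float, g_kpa: float = 0.0) -> "FKVParams":
        return cls(k_alpha=1e3 * k_alpha_kpa, alpha=alpha, g=1e3 * g_kpa)


@dataclass(frozen=True)
class SLSParams:
    """Zener solid: spring g1 in parallel with a spring g2 + dashpot eta series arm (Pa, Pa, Pa·s)."""

    g1: float
    g2: float
    eta: float

    def __post_init__(self) -> None:
        for name in ("g1", "g2", "eta"):
            if _check_finite(name, getattr(self, name)) < 0:
                raise ParameterDomainError(f"{name} must be >= 0")
        if self.g2 == 0 and self.eta > 0:
            raise ParameterDomainError(
                "g2 = 0 with eta > 0 leaves the series arm's relaxation time undefined"
            )

    @classmethod
    def from_kpa(cls, g1_kpa: float, g2_kpa: float, eta: float) -> "SLSParams":
        return cls(g1=1e3 * g1_kpa, g2=1e3 * g2_kpa, eta=eta)


@dataclass(frozen=True)
class ComplexModulus:
    """Storage and loss moduli (Pa) at one or more frequencies (Hz)."""

    frequency: np.ndarray
    storage: np.ndarray
    loss: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "frequency", np.atleast_1d(np.asarray(self.frequency, float)))
        object.__setattr__(self, "storage", np.atleast_1d(np.asarray(self.storage, float)))
        object.__setattr__(self, "loss", np.atleast_1d(np.asarray(self.loss, float)))


@dataclass(frozen=True)
class StrainHistory:
    """A shear-strain trajectory eps(t) sampled at non-negative, increasing times.

    ``step`` builds the step history ``eps0 * H(t)`` used in relaxation tests.
    """

    times: np.ndarray
    strains: np.ndarray
    strain_amplitude: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, float)
        strains = np.asarray(self.strains, float)
        if times.ndim != 1 or times.shape != strains.shape:
            raise ValueError("times and strains must be 1-D arrays of equal length")
        if times[0] < 0 or np.any(np.diff(times) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "strains", strains)

    @classmethod
    def step(cls, strain_amplitude: float, t_end: float, n: int = 2) -> "StrainHistory":
        times = np.linspace(0.0, t_end, n)
        return cls(times=times, strains=np.full(n, strain_amplitude), strain_amplitude=strain_amplitude)


class GLResponse(NamedTuple):
    times: np.ndarray
    stress: np.ndarray  # Pa


def angular_argument(frequency, convention: str = "hz"):
    """Frequency argument entering the model formulas under the chosen convention."""
    f = np.asarray(frequency, float)
    if np.any(f <= 0):
        raise ValueError("frequency must be > 0")
    if convention == "hz":
        return f
    if convention == "rad":
        return 2.0 * np.pi * f
    raise ValueError(f"unknown frequency convention {convention!r}")


def sfkv_complex_modulus(params: SFKVParams, frequency, convention: str = "hz") -> ComplexModulus:
    """S-FKV complex modulus.

    G' = K_a w^a cos(a pi/2);  G'' = K_a w^a sin(a pi/2) + eta w,
    with w the frequency argument under ``convention`` (Hz by default).
    """
    w = angular_argument(frequency, convention)
    half = 0.5 * np.pi * params.alpha
    wa = w**params.alpha
    storage = params.k_alpha * wa * np.cos(half)
    loss = params.k_alpha * wa * np.sin(half) + params.eta * w
    return ComplexModulus(frequency=np.asarray(frequency, float), storage=storage, loss=loss)


def fkv_complex_modulus(params: FKVParams, frequency, convention: str = "hz") -> ComplexModulus:
    """FKV complex modulus: G' = K_a w^a cos(a pi/2) + G;  G'' = K_a w^a sin(a pi/2)."""
    w = angular_argument(frequency, convention)
    half = 0.5 * np.pi * params.alpha
    wa = w**params.alpha
    storage = params.k_alpha * wa * np.cos(half) + params.g
    loss = params.k_alpha * wa * np.sin(half)
    return ComplexModulus(frequency=np.asarray(frequency, float), storage=storage, loss=loss)


def sls_complex_modulus(params: SLSParams, frequency, convention: str = "hz") -> ComplexModulus:
    """Zener complex modulus with relaxation time tau = eta / g2.

    G' = g1 + g2 (w tau)^2 / (1 + (w tau)^2);  G'' = g2 w tau / (1 + (w tau)^2).
    With g2 = 0 (and necessarily eta = 0) the model is a pure spring g1.
    """
    w = angular_argument(frequency, convention)
    if params.g2 == 0:
        z = np.zeros_like(w)
        return ComplexModulus(
            frequency=np.asarray(frequency, float),
            storage=np.full_like(w, params.g1),
            loss=z,
        )
    wt = w * params.eta / params.g2
    denom = 1.0 + wt**2
    storage = params.g1 + params.g2 * wt**2 / denom
    loss = params.g2 * wt / denom
    return ComplexModulus(frequency=np.asarray(frequency, float), storage=storage, loss=loss)


def sfkv_relaxation_modulus(params: SFKVParams, t):
    """S-FKV relaxation modulus G(t) = K_a t^(-alpha) / Gamma(1 - alpha), Pa, for t > 0.

    The dashpot contributes an impulsive term ``eta * delta(t)`` at t = 0 only;
    it is excluded here, so the expression is valid strictly for t > 0.
    Strictly decreasing in t for 0 < alpha < 1; constant K_a for alpha = 0.
    """
    t = np.asarray(t, float)
    if np.any(t <= 0):
        raise ValueError("relaxation modulus is defined for t > 0 only")
    return params.k_alpha * t ** (-params.alpha) / _gamma(1.0 - params.alpha)


def _gl_weights(alpha: float, n: int) -> np.ndarray:
    # w_j = (-1)^j C(alpha, j), built by the stable recursion w_j = w_{j-1} (j-1-alpha)/j
    w = np.empty(n)
    w[0] = 1.0
    for j in range(1, n):
        w[j] = w[j - 1] * (j - 1.0 - alpha) / j
    return w


def gl_stress_response(params: SFKVParams, history: StrainHistory, dt: float) -> GLResponse:
    """Numerical S-FKV stress via the Grünwald–Letnikov fractional derivative.

    The strain history is resampled onto a uniform grid of spacing ``dt`` and

        sigma(t_n) = K_a dt^(-alpha) sum_j w_j eps(t_{n-j}) + eta (eps_n - eps_{n-1}) / dt

    with full-memory first-order GL weights (histories here are <= 1e4 steps,
    so the O(N^2) convolution is acceptable).  For a step strain the response
    divided by the step amplitude converges to :func:`sfkv_relaxation_modulus`
    as dt -> 0.  Strain before t = 0 is taken as zero, so the backward
    difference at the first sample approximates the dashpot's impulse.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    spacing = np.diff(history.times)
    if spacing.size and dt > spacing.min() * (1 + 1e-9):
        raise ValueError(
            f"dt = {dt} exceeds the finest spacing of the history ({spacing.min()}); "
            "refine dt below the evaluation-time resolution"
        )
    t_end = history.times[-1]
    n = int(round(t_end / dt)) + 1
    times = np.arange(n) * dt
    eps = np.interp(times, history.times, history.strains)

    w = _gl_weights(params.alpha, n)
    frac = np.convolve(eps, w)[:n] * dt ** (-params.alpha)
    prev = np.concatenate(([0.0], eps[:-1]))
    rate = (eps - prev) / dt
    return GLResponse(times=times, stress=params.k_alpha * frac + params.eta * rate)
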