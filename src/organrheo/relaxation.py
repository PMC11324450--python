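"""Time-domain relaxation prediction and high-frequency extrapolation.

A frequency-domain S-FKV fit implies a power-law relaxation modulus
``G(t) = K_a t^(-alpha) / Gamma(1-alpha)`` (the dashpot's impulsive
contribution at t = 0 is excluded; comparisons start at t = 1 s, the first
sampled point of the step-strain protocol).  This module predicts that
response, quantifies its mismatch against a measured trace, and evaluates
the fitted storage modulus at arbitrary — typically elastography-range —
frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .models import SFKVParams, sfkv_complex_modulus, sfkv_relaxation_modulus

__all__ = [
    "RelaxationTrace",
    "RelaxationComparison",
    "ExtrapolationResult",
    "predict_relaxation",
    "compare_relaxation",
    "extrapolate_storage",
    "round_half_up",
]


def round_half_up(x, ndigits: int = 2):
    """Decimal round-half-up (0.005 -> 0.01), elementwise; used for table parity."""
    scale = 10.0**ndigits
    return np.floor(np.asarray(x, float) * scale + 0.5) / scale


@dataclass(frozen=True)
class RelaxationTrace:
    """Relaxation modulus (Pa) vs time (s) after a step shear strain."""

    times: np.ndarray
    relaxation_modulus: np.ndarray
    strain_step: float = 0.001  # dimensionless (0.1 %)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        g = np.asarray(self.relaxation_modulus, float)
        if t.ndim != 1 or t.shape != g.shape:
            raise ValueError("times and relaxation_modulus must be 1-D of equal length")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be positive and strictly increasing")
        if np.any(g <= 0):
            raise ValueError("relaxation moduli must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "relaxation_modulus", g)


@dataclass(frozen=True)
class RelaxationComparison:
    """Prediction-vs-measurement summary on the common time grid.

    ``initial_discrepancy`` is the signed percentage
    (predicted - measured) / measured x 100 at the earliest common time
    (1 s under the study protocol): negative means the prediction
    undershoots.  ``decay_shape_distance`` is the maximum relative deviation
    (in %) between the two curves after each is divided by its own value at
    that first time — zero means identical decay kinetics regardless of
    amplitude.
    """

    times: np.ndarray
    predicted: np.ndarray
    measured: np.ndarray
    initial_discrepancy: float
    decay_shape_distance: float


def predict_relaxation(params: SFKVParams, times) -> np.ndarray:
    """Pointwise S-FKV relaxation modulus (Pa) at the given times (s, > 0)."""
    return sfkv_relaxation_modulus(params, times)


def compare_relaxation(predicted: RelaxationTrace, measured: RelaxationTrace) -> RelaxationComparison:
    """Compare predicted and measured relaxation traces on their common times."""
    common, ip, im = np.intersect1d(predicted.times, measured.times, return_indices=True)
    if common.size == 0:
        raise ValueError("predicted and measured traces share no time points")
    p = predicted.relaxation_modulus[ip]
    m = measured.relaxation_modulus[im]
    initial = (p[0] - m[0]) / m[0] * 100.0
    p_hat, m_hat = p / p[0], m / m[0]
    shape = float(np.max(np.abs(p_hat - m_hat) / m_hat) * 100.0)
    return RelaxationComparison(
        times=common, predicted=p, measured=m,
        initial_discrepancy=float(initial), decay_shape_distance=shape,
    )


@dataclass(frozen=True)
class ExtrapolationResult:
    """Fitted storage modulus evaluated at requested frequencies, in kPa.

    ``storage_kpa`` is rounded half-up to 2 decimals (reporting boundary);
    ``range_kpa`` is the (value at min f, value at max f) endpoint pair, the
    form frequency-range predictions are tabulated in.  For an S-FKV solid
    the storage modulus is monotone in frequency, so the endpoints bound the
    whole interval.
    """

    frequencies: np.ndarray
    storage_kpa: np.ndarray
    range_kpa: tuple[float, float]
    convention: str


def extrapolate_storage(params: SFKVParams, frequencies, convention: str = "hz") -> ExtrapolationResult:
    """Evaluate the S-FKV storage modulus at each frequency (Hz), report in kPa."""
    f = np.atleast_1d(np.asarray(frequencies, float))
    mod = sfkv_complex_modulus(params, f, convention=convention)
    kpa = round_half_up(mod.storage / 1e3, 2)
    lo, hi = kpa[int(np.argmin(f))], kpa[int(np.argmax(f))]
    return ExtrapolationResult(
        frequencies=f, storage_kpa=kpa, range_kpa=(float(lo), float(hi)), convention=convention,
    )
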