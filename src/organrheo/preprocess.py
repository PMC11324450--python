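"""Data-quality stages applied to rheometer sweeps before model fitting.

Three checks mirror standard oscillatory-shear practice on soft tissue:

1. **LVE detection** — from an amplitude (strain) sweep, find the largest
   strain amplitude over which the storage modulus stays within a tolerance
   of its low-strain plateau.  Fits are only meaningful inside this linear
   viscoelastic region (about 0.1 % shear strain for the organs studied).
2. **Inertial-bandwidth truncation** — instrument inertia produces a
   characteristic dip in G' (and rise in G'') at high oscillation frequency;
   points at and above the dip are excluded from fitting rather than
   corrected.
3. **Contact-state conversion** — the axial pre-compression is set by a
   contact force; dividing by the platen area and the sample's elastic
   modulus gives the axial pre-strain at which the shear moduli were taken.

Moduli are handled in Pa throughout; strain amplitudes in % shear strain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "StrainSweep",
    "FrequencySweep",
    "SampleGeometry",
    "InsufficientDataError",
    "detect_lve_limit",
    "detect_inertial_cutoff",
    "truncate_at_cutoff",
    "contact_axial_state",
]


class InsufficientDataError(ValueError):
    """Too few sweep points for the requested detection."""


def _as_sorted_positive(name, values):
    arr = np.asarray(values, float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D array")
    return arr


@dataclass(frozen=True)
class StrainSweep:
    """Amplitude sweep at fixed frequency: moduli (Pa) vs strain amplitude (%)."""

    strain_amplitudes: np.ndarray
    storage: np.ndarray
    loss: np.ndarray
    frequency: float = 1.0

    def __post_init__(self) -> None:
        amp = _as_sorted_positive("strain_amplitudes", self.strain_amplitudes)
        if np.any(np.diff(amp) <= 0):
            raise ValueError("strain_amplitudes must be strictly increasing")
        storage = _as_sorted_positive("storage", self.storage)
        loss = _as_sorted_positive("loss", self.loss)
        if not (amp.size == storage.size == loss.size):
            raise ValueError("strain_amplitudes, storage and loss must have equal length")
        if np.any(storage <= 0) or np.any(loss < 0):
            raise ValueError("moduli must be positive")
        for name, arr in (("strain_amplitudes", amp), ("storage", storage), ("loss", loss)):
            object.__setattr__(self, name, arr)


@dataclass(frozen=True)
class FrequencySweep:
    """Frequency sweep at fixed strain amplitude: moduli (Pa) vs frequency (Hz).

    ``axial_strain`` (%) and ``contact_force`` (N) describe the compressive
    pre-load state under which the sweep was taken, when known.
    """

    frequencies: np.ndarray
    storage: np.ndarray
    loss: np.ndarray
    strain_amplitude: float = 0.1
    contact_force: Optional[float] = None
    axial_strain: Optional[float] = None

    def __post_init__(self) -> None:
        f = _as_sorted_positive("frequencies", self.frequencies)
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be positive and strictly increasing")
        storage = _as_sorted_positive("storage", self.storage)
        loss = _as_sorted_positive("loss", self.loss)
        if not (f.size == storage.size == loss.size):
            raise ValueError("frequencies, storage and loss must have equal length")
        if np.any(storage <= 0) or np.any(loss < 0):
            raise ValueError("moduli must be positive")
        for name, arr in (("frequencies", f), ("storage", storage), ("loss", loss)):
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return int(self.frequencies.size)


@dataclass(frozen=True)
class SampleGeometry:
    """Disc-sample geometry and contact state.

    elastic_modulus is in kPa (the unit organ stiffness is tabulated in);
    contact_axial_state converts internally to Pa.
    """

    diameter: float  # mm
    thickness: float  # mm
    organ: str = ""
    elastic_modulus: float = float("nan")  # kPa
    contact_force: float = 0.0  # N
    temperature: float = 20.0  # deg C

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.thickness <= 0:
            raise ValueError("diameter and thickness must be > 0")


def detect_lve_limit(sweep: StrainSweep, tolerance: float = 0.05) -> Optional[float]:
    """Largest strain amplitude (%) still inside the linear viscoelastic region.

    The low-strain reference is the mean storage modulus of the first three
    points; the limit is the largest amplitude such that every storage value
    up to and including it deviates from the reference by less than
    ``tolerance`` (fractional).  G' alone drives the decision: it dominates
    the response and is less noisy than G''.  Returns the maximum amplitude
    if no point deviates, and None in the degenerate case where even the
    first point is outside tolerance.
    """
    if sweep.strain_amplitudes.size < 4:
        raise InsufficientDataError("LVE detection needs at least 4 strain-sweep points")
    if not 0.0 < tolerance < 0.5:
        raise ValueError("tolerance must lie in (0, 0.5)")
    ref = sweep.storage[:3].mean()
    deviating = np.abs(sweep.storage - ref) / ref >= tolerance
    if not deviating.any():
        return float(sweep.strain_amplitudes[-1])
    first = int(np.argmax(deviating))
    if first == 0:
        return None
    return float(sweep.strain_amplitudes[first - 1])


def detect_inertial_cutoff(sweep: FrequencySweep, drop_tolerance: float = 0.05) -> Optional[float]:
    """Lowest frequency (Hz) at which G' drops below its running maximum by
    more than ``drop_tolerance`` (fractional), or None for monotone sweeps.

    Points at and above the returned frequency carry the inertial artifact and
    should be excluded from fitting (see :func:`truncate_at_cutoff`).
    """
    if len(sweep) < 5:
        raise InsufficientDataError("inertial detection needs at least 5 frequency-sweep points")
    if not 0.0 < drop_tolerance < 1.0:
        raise ValueError("drop_tolerance must lie in (0, 1)")
    running_max = np.maximum.accumulate(sweep.storage)
    dropped = sweep.storage < (1.0 - drop_tolerance) * running_max
    # instrument inertia only worsens with frequency, so a genuine cutoff is a
    # drop that persists to the end of the sweep; isolated noise dips are not
    # flagged
    persistent = np.logical_and.accumulate(dropped[::-1])[::-1]
    if not persistent.any():
        return None
    return float(sweep.frequencies[int(np.argmax(persistent))])


def truncate_at_cutoff(sweep: FrequencySweep, cutoff: Optional[float]) -> FrequencySweep:
    """Return the sweep restricted to frequencies strictly below ``cutoff``."""
    if cutoff is None:
        return sweep
    keep = sweep.frequencies < cutoff
    if not keep.any():
        raise ValueError("cutoff excludes every point of the sweep")
    return replace(
        sweep,
        frequencies=sweep.frequencies[keep],
        storage=sweep.storage[keep],
        loss=sweep.loss[keep],
    )


def contact_axial_state(geom: SampleGeometry, nominal_rounding: bool = True) -> tuple[float, float]:
    """Axial (stress Pa, strain %) produced by the contact force on the disc.

    stress = F / (pi (d/2)^2); strain = stress / E x 100 %.  With
    ``nominal_rounding`` (default) the stress is rounded to one significant
    figure before dividing by E, matching how pre-strains are conventionally
    quoted from a nominal contact stress (0.1 N on a 25 mm disc -> 203.7 Pa
    exactly, 200 Pa nominal).
    """
    if geom.contact_force < 0:
        raise ValueError("contact force must be >= 0")
    if geom.contact_force == 0:
        return 0.0, 0.0
    if not (geom.elastic_modulus > 0):
        raise ValueError("elastic_modulus (kPa) must be > 0 to convert stress to strain")
    radius_m = geom.diameter * 1e-3 / 2.0
    area = math.pi * radius_m**2
    if area == 0:
        raise ZeroDivisionError("zero contact area")
    stress = geom.contact_force / area
    if nominal_rounding:
        exponent = math.floor(math.log10(stress))
        stress = round(stress / 10**exponent) * 10.0**exponent
    strain = stress / (geom.elastic_modulus * 1e3) * 100.0
    return float(stress), float(strain)
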