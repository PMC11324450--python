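"""Default per-organ parameter profiles for the synthetic-data generator.

Each profile bundles the quantities the study's measurements exhibit for one
porcine organ: the fitted S-FKV parameters at the reference pre-compression,
the linear law relating the springpot coefficient to axial pre-strain,
the drift of the fractional order and viscosity with pre-strain, the extent
of the linear viscoelastic region, the frequency at which instrument inertia
corrupts the sweep, and the elastic modulus used for contact-state
conversion.

All four organ defaults carry the study's published values; the profiles are
the "stated world" every synthetic dataset is drawn from.

Note on the anchor strain: the fitted S-FKV parameters are anchored at a
common reference axial strain of 0.5 % (the first row of the published
per-strain drift table), and the springpot coefficient at other pre-strains
follows K_a(eps) = K_ref * (1 + b*eps) / (1 + b*eps_ref).  Using the
published (k0, b) regression directly would contradict the anchored values
at the reference strain, because that regression does not pass exactly
through its own anchor point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import SFKVParams

__all__ = ["OrganProfile", "PROFILES", "get_profile", "ORGANS"]

#: axial strains (%) at which per-strain alpha/eta drift values are tabulated
DRIFT_STRAINS = np.array([0.5, 2.5, 4.5, 6.5, 8.5, 10.5])

#: reference axial strain (%) at which profile.params hold exactly
REFERENCE_STRAIN = 0.5


@dataclass(frozen=True)
class OrganProfile:
    """Ground-truth generative description of one organ's shear rheology."""

    organ: str
    params: SFKVParams  # S-FKV parameters at the reference axial strain (Pa units)
    k0: float  # springpot coefficient at zero axial strain, Pa·s^alpha
    b: float  # fractional stiffening per % axial strain
    drift_alpha: np.ndarray  # alpha at DRIFT_STRAINS
    drift_eta: np.ndarray  # eta (Pa·s) at DRIFT_STRAINS
    lve_limit: float = 0.1  # % shear strain
    inertial_onset: float = 9.5  # Hz
    noise_cv: float = 0.03  # multiplicative lognormal coefficient of variation
    elastic_modulus: float = 44.0  # kPa, for contact-state conversion
    contact_strain: float = 0.5  # % axial strain at the 0.1 N contact force
    thickness: float = 5.5  # mm
    diameter: float = 25.0  # mm

    def params_at(self, axial_strain: float, drift: bool = True) -> SFKVParams:
        """S-FKV parameters at an axial pre-strain (%).

        The springpot coefficient scales linearly in pre-strain relative to
        the reference; alpha and eta follow the tabulated drift (linear
        interpolation, clamped at the table ends) when ``drift`` is on.
        """
        scale = (1.0 + self.b * axial_strain) / (1.0 + self.b * REFERENCE_STRAIN)
        if drift:
            alpha = float(np.interp(axial_strain, DRIFT_STRAINS, self.drift_alpha))
            eta = float(np.interp(axial_strain, DRIFT_STRAINS, self.drift_eta))
        else:
            alpha, eta = self.params.alpha, self.params.eta
        return SFKVParams(k_alpha=self.params.k_alpha * scale, alpha=alpha, eta=eta)


def _profile(organ, k_kpa, alpha, eta, k0_kpa, b, drift_alpha, drift_eta,
             inertial_onset, elastic_modulus, contact_strain, thickness):
    return OrganProfile(
        organ=organ,
        params=SFKVParams.from_kpa(k_kpa, alpha, eta),
        k0=1e3 * k0_kpa,
        b=b,
        drift_alpha=np.asarray(drift_alpha, float),
        drift_eta=np.asarray(drift_eta, float),
        inertial_onset=inertial_onset,
        elastic_modulus=elastic_modulus,
        contact_strain=contact_strain,
        thickness=thickness,
    )


PROFILES: dict[str, OrganProfile] = {
    "heart": _profile(
        "heart", 2.00, 0.13, 10.3, 1.94, 0.10,
        [0.13, 0.11, 0.11, 0.11, 0.11, 0.10],
        [10.3, 18.4, 17.6, 21.2, 20.6, 25.6],
        inertial_onset=9.5, elastic_modulus=110.0, contact_strain=0.2, thickness=5.9,
    ),
    "kidney": _profile(
        "kidney", 0.88, 0.12, 7.58, 0.69, 0.23,
        [0.12, 0.11, 0.10, 0.10, 0.09, 0.09],
        [7.58, 10.9, 13.5, 14.3, 20.1, 22.1],
        inertial_onset=9.5, elastic_modulus=44.0, contact_strain=0.5, thickness=5.3,
    ),
    "liver": _profile(
        "liver", 0.27, 0.16, 9.70, 0.26, 0.12,
        [0.16, 0.14, 0.14, 0.13, 0.13, 0.13],
        [9.70, 13.1, 13.4, 16.1, 14.6, 17.5],
        inertial_onset=4.2, elastic_modulus=17.5, contact_strain=1.1, thickness=5.3,
    ),
    "brain": _profile(
        "brain", 0.25, 0.16, 10.5, 0.13, 0.07,
        [0.16, 0.15, 0.15, 0.15, 0.15, 0.15],
        [10.5, 13.2, 13.0, 13.2, 12.4, 12.3],
        inertial_onset=2.8, elastic_modulus=1.5, contact_strain=13.3, thickness=5.5,
    ),
}

ORGANS = tuple(PROFILES)


def get_profile(organ: str) -> OrganProfile:
    try:
        return PROFILES[organ.lower()]
    except KeyError:
        raise KeyError(f"unknown organ {organ!r}; choose from {', '.join(PROFILES)}") from None


#: Frequencies (Hz) at which published elastography / shear-testing studies
#: report shear moduli for each organ, as (technique label, (f_min, f_max))
#: bands; single-frequency reports have f_min == f_max.  These are the
#: frequencies the fitted storage modulus is extrapolated to for comparison.
LITERATURE_BANDS: dict[str, list[tuple[str, tuple[float, float]]]] = {
    "heart": [
        ("MRE, porcine heart", (80.0, 80.0)),
        ("MRE, porcine heart", (40.0, 500.0)),
    ],
    "kidney": [
        ("rheometry, porcine kidney", (0.1, 4.0)),
        ("rheometry, porcine kidney", (0.01, 20.0)),
        ("MRE, porcine kidney", (75.0, 300.0)),
        ("SDUV, porcine kidney", (50.0, 500.0)),
    ],
    "liver": [
        ("SWE, porcine liver", (100.0, 200.0)),
        ("MRE, porcine liver", (75.0, 300.0)),
        ("rotational rheometer, porcine liver", (0.1, 0.1)),
        ("rheological tests, porcine liver", (0.1, 10.0)),
        ("dynamic mechanical testing, human liver", (1.0, 30.0)),
    ],
    "brain": [
        ("rheometry TTS, porcine brain", (589.0, 589.0)),
        ("oscillatory shear, porcine brain", (20.0, 200.0)),
        ("oscillatory shear TTS, porcine brain", (260.0, 1000.0)),
        ("rotational rheometry, porcine brain", (1.0, 10.0)),
        ("rotational shear, porcine brain", (0.04, 16.0)),
        ("custom shear testing, porcine brain", (20.0, 200.0)),
        ("MRE, human brain", (25.0, 62.5)),
        ("dynamic shear testing, human brain", (9.0, 10.0)),
        ("dynamic torsion testing, human brain", (2.0, 10.0)),
        ("MRE, human brain", (50.0, 50.0)),
    ],
}
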