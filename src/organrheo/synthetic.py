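"""Synthetic rheometer datasets with the statistical structure of real sweeps.

Every generator draws from an :class:`~organrheo.profiles.OrganProfile` and a
seed, and is bit-reproducible for the same (profile, seed).  Noise is
multiplicative lognormal with unit mean — rheometer modulus errors scale
with the modulus — at a default coefficient of variation of 3 %.

Structure emulated (and nothing more):

* frequency sweeps follow the S-FKV power law, with the springpot
  coefficient scaled linearly by axial pre-strain;
* above the organ's inertial-onset frequency, the storage modulus is
  multiplicatively suppressed and the loss modulus inflated, mimicking the
  instrument-inertia artifact (the shape is a stand-in, not physics);
* strain sweeps are flat below the LVE limit and soften smoothly
  (Kraus-type decay) above it;
* relaxation traces follow the S-FKV power-law relaxation modulus, with an
  optional amplitude bias emulating the <= 30 % initial-value mismatch seen
  between frequency-domain fits and measured relaxation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import sfkv_complex_modulus, sfkv_relaxation_modulus
from .preprocess import FrequencySweep, SampleGeometry, StrainSweep
from .profiles import REFERENCE_STRAIN, OrganProfile
from .relaxation import RelaxationTrace

__all__ = [
    "gen_frequency_sweep",
    "gen_strain_sweep",
    "gen_relaxation_trace",
    "gen_dataset",
    "SyntheticDataset",
]

CONTACT_FORCE = 0.1  # N, the study's pre-load


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    s2 = np.log1p(cv**2)
    return rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2), size=size)


def gen_frequency_sweep(
    profile: OrganProfile,
    axial_strain: float | None = None,
    n_points: int = 20,
    f_range: tuple[float, float] = (0.1, 9.5),
    seed: int = 0,
    noise_cv: float | None = None,
    drift: bool = True,
    convention: str = "hz",
) -> FrequencySweep:
    """Log-spaced frequency sweep at one axial pre-strain.

    The inertial artifact applies strictly above ``profile.inertial_onset``:
    G' is suppressed by 1 / (1 + (f/f_onset)^4) and G'' inflated by a term
    growing as f^2, both continuous at the onset.
    """
    if n_points < 5:
        raise ValueError("n_points must be >= 5")
    lo, hi = f_range
    if not 0 < lo < hi:
        raise ValueError("f_range must be positive and increasing")
    eps = REFERENCE_STRAIN if axial_strain is None else float(axial_strain)
    params = profile.params_at(eps, drift=drift)
    f = np.geomspace(lo, hi, n_points)
    mod = sfkv_complex_modulus(params, f, convention=convention)
    storage, loss = mod.storage.copy(), mod.loss.copy()

    beyond = f > profile.inertial_onset
    if beyond.any():
        x = f[beyond] / profile.inertial_onset
        storage[beyond] /= 0.5 * (1.0 + x**4)  # == 1 at onset, dips beyond
        loss_onset = sfkv_complex_modulus(params, profile.inertial_onset, convention=convention).loss[0]
        loss[beyond] += loss_onset * (x**2 - 1.0)

    cv = profile.noise_cv if noise_cv is None else noise_cv
    rng = np.random.default_rng(seed)
    storage = storage * _lognormal_factor(rng, cv, f.size)
    loss = loss * _lognormal_factor(rng, cv, f.size)
    return FrequencySweep(
        frequencies=f, storage=storage, loss=loss,
        strain_amplitude=0.1, contact_force=CONTACT_FORCE, axial_strain=eps,
    )


def gen_strain_sweep(
    profile: OrganProfile,
    n_points: int = 25,
    strain_range: tuple[float, float] = (0.01, 10.0),
    seed: int = 0,
    noise_cv: float | None = None,
    frequency: float = 1.0,
) -> StrainSweep:
    """Amplitude sweep: flat plateau below the LVE limit, Kraus-type softening above.

    Above the limit gamma_L the storage modulus decays as
    ``G'_plateau / (1 + ((gamma - gamma_L)/gamma_L)^m)`` with m = 0.8 — a
    shape chosen to look like measured amplitude sweeps, not claimed physical.
    The loss modulus softens with half the exponent (it decays more slowly).
    """
    lo, hi = strain_range
    if not 0 < lo < profile.lve_limit < hi:
        raise ValueError("strain_range must span the profile's LVE limit")
    gamma = np.geomspace(lo, hi, n_points)
    mod = sfkv_complex_modulus(profile.params, frequency)
    m = 0.8
    above = gamma > profile.lve_limit
    soft = np.ones(n_points)
    soft[above] = 1.0 / (1.0 + ((gamma[above] - profile.lve_limit) / profile.lve_limit) ** m)
    cv = profile.noise_cv if noise_cv is None else noise_cv
    rng = np.random.default_rng(seed)
    storage = mod.storage[0] * soft * _lognormal_factor(rng, cv, n_points)
    loss = mod.loss[0] * np.sqrt(soft) * _lognormal_factor(rng, cv, n_points)
    return StrainSweep(strain_amplitudes=gamma, storage=storage, loss=loss, frequency=frequency)


def gen_relaxation_trace(
    profile: OrganProfile,
    times=None,
    strain_step: float = 0.001,
    seed: int = 0,
    noise_cv: float | None = None,
    bias: float = 1.0,
) -> RelaxationTrace:
    """Step-strain relaxation trace sampled, by default, every 1 s for 10 s.

    ``bias`` multiplies the whole trace: bias = 1.29 emulates a tissue whose
    measured relaxation amplitude exceeds the frequency-domain prediction by
    29 % while sharing its decay exponent.
    """
    t = np.arange(1.0, 11.0) if times is None else np.asarray(times, float)
    if np.any(t <= 0):
        raise ValueError("relaxation times must be > 0")
    g = sfkv_relaxation_modulus(profile.params, t) * bias
    cv = profile.noise_cv if noise_cv is None else noise_cv
    rng = np.random.default_rng(seed)
    g = g * _lognormal_factor(rng, cv, t.size)
    return RelaxationTrace(times=t, relaxation_modulus=g, strain_step=strain_step)


@dataclass(frozen=True)
class SyntheticDataset:
    """One organ's full synthetic measurement session."""

    organ: str
    strain_sweep: StrainSweep
    frequency_sweeps: dict[float, FrequencySweep]  # keyed by axial strain (%)
    relaxation: RelaxationTrace
    geometry: SampleGeometry
    seed: int


def gen_dataset(
    profile: OrganProfile,
    seed: int = 0,
    axial_strains=(0.5, 2.5, 4.5, 6.5, 8.5, 10.5),
    relaxation_bias: float = 1.0,
) -> SyntheticDataset:
    """Strain sweep + frequency sweeps at several pre-strains + relaxation trace.

    Child seeds are spawned deterministically from ``seed``, so regenerating
    with the same seed and profile is bit-identical.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.generate_state(2 + len(axial_strains)) % (2**31)
    sweeps = {
        float(eps): gen_frequency_sweep(profile, axial_strain=eps, seed=int(children[i]))
        for i, eps in enumerate(axial_strains)
    }
    return SyntheticDataset(
        organ=profile.organ,
        strain_sweep=gen_strain_sweep(profile, seed=int(children[-2])),
        frequency_sweeps=sweeps,
        relaxation=gen_relaxation_trace(profile, seed=int(children[-1]), bias=relaxation_bias),
        geometry=SampleGeometry(
            diameter=profile.diameter, thickness=profile.thickness, organ=profile.organ,
            elastic_modulus=profile.elastic_modulus, contact_force=CONTACT_FORCE,
        ),
        seed=seed,
    )
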