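"""Least-squares fitting of frequency sweeps and the pre-strain stiffening law.

The three candidate models (S-FKV, FKV, SLS) each have three parameters,
fitted jointly to the storage and loss moduli by minimising the sum of
squared *relative* residuals — both moduli constrain the fractional order,
and relative weighting keeps the (much larger) storage modulus from
dominating.  Optimisation uses box-constrained trust-region least squares
with a deterministic, data-derived initial point, so a fit is a pure
function of the sweep.

Goodness of fit is the coefficient of determination r² computed over the
concatenation of the storage and loss moduli on a logarithmic scale, the
natural normalisation for power-law moduli spanning unequal magnitudes
(recorded in every result as ``r2``; the formula lives in ``_r_squared``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import statsmodels.api as sm
from scipy.optimize import least_squares

from .models import (
    FKVParams,
    SFKVParams,
    SLSParams,
    fkv_complex_modulus,
    sfkv_complex_modulus,
    sls_complex_modulus,
)
from .preprocess import FrequencySweep

__all__ = [
    "FitResult",
    "FitError",
    "StrainDependence",
    "MODEL_IDS",
    "fit_sweep",
    "compare_models",
    "fit_strain_dependence",
    "make_parameter_table",
]

MODEL_IDS = ("SFKV", "FKV", "SLS")

ModelParams = Union[SFKVParams, FKVParams, SLSParams]


class FitError(RuntimeError):
    """Optimizer failed to converge; message carries the solver diagnostics."""


@dataclass(frozen=True)
class FitResult:
    model_id: str
    params: ModelParams
    r2: float
    residual_norm: float
    n_points: int
    convention: str
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.r2 > 1 + 1e-12:
            raise ValueError("r2 cannot exceed 1")
        if self.n_points < 3:
            raise ValueError("need at least as many points as parameters (3)")


@dataclass(frozen=True)
class StrainDependence:
    """Linear stiffening law K_a(eps_A) = k0 (1 + b eps_A), eps_A in % axial strain.

    Obtained as an ordinary least-squares line K_a = c0 + c1 eps_A with
    k0 = c0 and b = c1 / c0; ``k0`` carries the units of the input K_a.
    """

    k0: float
    b: float
    fit_r2: float

    def __post_init__(self) -> None:
        if not self.k0 > 0:
            raise ValueError("k0 must be > 0 (tissue has positive stiffness at zero pre-strain)")


def _log_slope(f: np.ndarray, g: np.ndarray) -> float:
    return float(np.polyfit(np.log(f), np.log(g), 1)[0])


def _predict(model_id: str, x: np.ndarray, f: np.ndarray, convention: str):
    if model_id == "SFKV":
        mod = sfkv_complex_modulus(SFKVParams(*x), f, convention)
    elif model_id == "FKV":
        mod = fkv_complex_modulus(FKVParams(*x), f, convention)
    elif model_id == "SLS":
        mod = sls_complex_modulus(SLSParams(*x), f, convention)
    else:
        raise ValueError(f"unknown model {model_id!r}; choose from {MODEL_IDS}")
    return mod.storage, mod.loss


def _initial_guess(model_id: str, sweep: FrequencySweep) -> np.ndarray:
    """Deterministic data-derived starting point (no random restarts)."""
    f, gp, gl = sweep.frequencies, sweep.storage, sweep.loss
    alpha0 = float(np.clip(_log_slope(f, gp), 0.02, 0.95))
    half = 0.5 * np.pi * alpha0
    if model_id == "SFKV":
        k0 = float(np.median(gp / (f**alpha0 * np.cos(half))))
        resid_loss = gl[-1] - k0 * f[-1] ** alpha0 * np.sin(half)
        eta0 = max(float(resid_loss / f[-1]), 1e-9)
        return np.array([max(k0, 1e-9), alpha0, eta0])
    if model_id == "FKV":
        g0 = 0.5 * float(gp.min())
        k0 = float(np.median(np.maximum(gp - g0, 1e-12) / (f**alpha0 * np.cos(half))))
        return np.array([max(k0, 1e-9), alpha0, g0])
    # SLS: low-f plateau g1, high-f increment g2, relaxation time ~ mid-band
    g1 = float(gp.min())
    g2 = max(float(gp.max() - gp.min()), 0.05 * g1 + 1e-9)
    tau = 1.0 / float(np.sqrt(f[0] * f[-1]))
    return np.array([g1, g2, g2 * tau])


_BOUNDS = {
    "SFKV": (np.array([1e-12, 0.0, 0.0]), np.array([np.inf, 1.0, np.inf])),
    "FKV": (np.array([1e-12, 0.0, 0.0]), np.array([np.inf, 1.0, np.inf])),
    "SLS": (np.array([0.0, 1e-12, 0.0]), np.array([np.inf, np.inf, np.inf])),
}


def _loss_floor(sweep: FrequencySweep) -> np.ndarray:
    # relative-residual denominator; floor guards degenerate zero-loss data
    return np.maximum(sweep.loss, 1e-6 * sweep.storage.max())


def _r_squared(sweep: FrequencySweep, fit_p: np.ndarray, fit_l: np.ndarray) -> float:
    # r2 = 1 - SS_res/SS_tot over the concatenated (G', G'') vector on a log
    # scale: both moduli enter dimensionless and equally weighted (the same
    # normalisation the fit objective uses), which is the natural scale for
    # power-law moduli.  A common floor guards degenerate zero-loss sweeps.
    floor = 1e-6 * float(sweep.storage.max())
    y = np.log(np.maximum(np.concatenate([sweep.storage, sweep.loss]), floor))
    yhat = np.log(np.maximum(np.concatenate([fit_p, fit_l]), floor))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - yhat) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res < 1e-20 else -np.inf
    return 1.0 - ss_res / ss_tot


def fit_sweep(sweep: FrequencySweep, model_id: str = "SFKV", convention: str = "hz") -> FitResult:
    """Fit one model to a cleaned frequency sweep (inertial points excluded).

    Raises :class:`FitError` on solver failure.  Constant (degenerate) moduli
    yield a boundary solution with a warning rather than an error.
    """
    if len(sweep) < 5:
        raise ValueError("fit_sweep needs at least 5 frequencies")
    f = sweep.frequencies
    dl = _loss_floor(sweep)

    def residuals(x):
        mp, ml = _predict(model_id, x, f, convention)
        return np.concatenate([(mp - sweep.storage) / sweep.storage, (ml - sweep.loss) / dl])

    x0 = _initial_guess(model_id, sweep)
    lo, hi = _BOUNDS[model_id]
    x0 = np.clip(x0, lo + 1e-12, None)
    sol = least_squares(
        residuals, x0, bounds=(lo, hi), method="trf",
        x_scale=np.maximum(np.abs(x0), 1e-9), xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not sol.success:
        raise FitError(f"{model_id} fit did not converge: {sol.message}")

    warns = []
    if np.ptp(sweep.storage) / sweep.storage.mean() < 1e-12:
        warns.append("degenerate sweep: constant storage modulus; boundary solution allowed")
    at_bound = (np.abs(sol.x - lo) < 1e-10 * np.maximum(1, np.abs(lo))) | (
        np.isfinite(hi) & (np.abs(sol.x - hi) < 1e-10)
    )
    if at_bound.any():
        warns.append(f"parameters at bounds: indices {np.flatnonzero(at_bound).tolist()}")

    mp, ml = _predict(model_id, sol.x, f, convention)
    params = {"SFKV": SFKVParams, "FKV": FKVParams, "SLS": SLSParams}[model_id](*sol.x)
    return FitResult(
        model_id=model_id,
        params=params,
        r2=_r_squared(sweep, mp, ml),
        residual_norm=float(np.linalg.norm(residuals(sol.x))),
        n_points=len(sweep),
        convention=convention,
        warnings=tuple(warns),
    )


def compare_models(sweep: FrequencySweep, convention: str = "hz") -> list[FitResult]:
    """Fit all three models and rank by r² (ties broken by residual norm).

    A model whose fit fails is dropped from the ranking with a warning; the
    remaining models are still returned.
    """
    results = []
    for model_id in MODEL_IDS:
        try:
            results.append(fit_sweep(sweep, model_id, convention))
        except (FitError, ValueError) as exc:  # pragma: no cover - defensive
            warnings.warn(f"{model_id} fit failed and is excluded from ranking: {exc}")
    if not results:
        raise FitError("all model fits failed")
    return sorted(results, key=lambda r: (-r.r2, r.residual_norm))


def fit_strain_dependence(pairs: Sequence[tuple[float, float]]) -> StrainDependence:
    """OLS fit of the springpot coefficient against axial pre-strain (%).

    ``pairs`` are (axial strain %, K_a) tuples; at least 3 strain levels.
    """
    arr = np.asarray(pairs, float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (axial_strain, k_alpha) pairs")
    eps, k = arr[:, 0], arr[:, 1]
    res = sm.OLS(k, sm.add_constant(eps)).fit()
    c0, c1 = res.params
    return StrainDependence(k0=float(c0), b=float(c1 / c0), fit_r2=float(res.rsquared))


def make_parameter_table(fits: dict[str, Sequence[FitResult]]):
    """Across-sample summary table of S-FKV parameters per organ.

    Reports mean ± sample sd (sd = 0 for a single fit) of K_a (kPa·s^alpha),
    alpha, and eta (Pa·s), plus the coefficient of variation of K_a in %,
    all rounded half-up to 2 decimals at this reporting boundary.
    """
    import pandas as pd

    from .relaxation import round_half_up

    rows = []
    for organ, organ_fits in fits.items():
        if not organ_fits:
            continue
        k = np.array([fr.params.k_alpha for fr in organ_fits]) / 1e3  # kPa
        a = np.array([fr.params.alpha for fr in organ_fits])
        e = np.array([fr.params.eta for fr in organ_fits])
        sd = lambda v: float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        rows.append(
            {
                "organ": organ,
                "n": int(k.size),
                "k_alpha_kpa_mean": k.mean(),
                "k_alpha_kpa_sd": sd(k),
                "alpha_mean": a.mean(),
                "alpha_sd": sd(a),
                "eta_pas_mean": e.mean(),
                "eta_pas_sd": sd(e),
                "k_alpha_cv_pct": 100.0 * sd(k) / k.mean(),
            }
        )
    if not rows:
        raise ValueError("no fits supplied")
    table = pd.DataFrame(rows)
    num = table.columns.drop(["organ", "n"])
    table[num] = round_half_up(table[num].to_numpy(), 2)
    return table
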