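"""Sweep fitting: round-trips, the grid-search oracle, and model ranking."""

import numpy as np
import pytest

from organrheo.fitting import (
    FitResult,
    compare_models,
    fit_strain_dependence,
    fit_sweep,
    make_parameter_table,
)
from organrheo.models import (
    FKVParams,
    SFKVParams,
    SLSParams,
    fkv_complex_modulus,
    sfkv_complex_modulus,
    sls_complex_modulus,
)
from organrheo.preprocess import FrequencySweep
from organrheo.synthetic import gen_frequency_sweep

FORWARD = {"SFKV": sfkv_complex_modulus, "FKV": fkv_complex_modulus, "SLS": sls_complex_modulus}


def sweep_from_params(model_id, params, f=None, noise_cv=0.0, seed=0):
    f = np.geomspace(0.1, 9.5, 20) if f is None else f
    mod = FORWARD[model_id](params, f)
    storage, loss = mod.storage.copy(), np.maximum(mod.loss, 1e-9)
    if noise_cv:
        rng = np.random.default_rng(seed)
        s2 = np.log1p(noise_cv**2)
        storage = storage * rng.lognormal(-s2 / 2, np.sqrt(s2), f.size)
        loss = loss * rng.lognormal(-s2 / 2, np.sqrt(s2), f.size)
    return FrequencySweep(frequencies=f, storage=storage, loss=loss)


class TestFitSweep:
    @pytest.mark.parametrize(
        "model_id, params",
        [
            ("SFKV", SFKVParams.from_kpa(0.88, 0.12, 7.58)),
            ("FKV", FKVParams.from_kpa(0.88, 0.12, 0.30)),
            ("SLS", SLSParams.from_kpa(0.60, 0.35, 60.0)),
        ],
    )
    def test_noiseless_round_trip(self, model_id, params):
        sweep = sweep_from_params(model_id, params)
        fr = fit_sweep(sweep, model_id)
        for name, truth in vars(params).items():
            if truth > 0:
                assert getattr(fr.params, name) == pytest.approx(truth, rel=1e-6)
        assert fr.r2 > 1 - 1e-10

    def test_noisy_kidney_fit_quality(self, kidney):
        sweep = gen_frequency_sweep(kidney, seed=11)  # 3% noise default
        fr = fit_sweep(sweep)
        assert fr.r2 >= 0.99
        assert fr.params.k_alpha == pytest.approx(kidney.params.k_alpha, rel=0.15)
        assert fr.params.alpha == pytest.approx(kidney.params.alpha, rel=0.15)

    def test_optimizer_beats_coarse_grid_oracle(self, kidney):
        # brute-force 20x20x20 grid on 5 frequencies must not beat the optimizer
        f = np.geomspace(0.2, 8.0, 5)
        sweep = sweep_from_params("SFKV", kidney.params, f=f, noise_cv=0.05, seed=4)

        def objective(k, a, e):
            mod = sfkv_complex_modulus(SFKVParams(k, a, e), f)
            dl = np.maximum(sweep.loss, 1e-6 * sweep.storage.max())
            return np.sum(((mod.storage - sweep.storage) / sweep.storage) ** 2) + np.sum(
                ((mod.loss - sweep.loss) / dl) ** 2
            )

        grid_best = min(
            objective(k, a, e)
            for k in np.linspace(400, 1400, 20)
            for a in np.linspace(0.02, 0.4, 20)
            for e in np.linspace(0.0, 30.0, 20)
        )
        fr = fit_sweep(sweep, "SFKV")
        assert objective(fr.params.k_alpha, fr.params.alpha, fr.params.eta) <= grid_best

    def test_too_few_points(self, kidney):
        sweep = sweep_from_params("SFKV", kidney.params, f=np.array([0.5, 1.0, 2.0, 4.0]))
        with pytest.raises(ValueError):
            fit_sweep(sweep)

    def test_degenerate_constant_moduli_warn(self):
        f = np.geomspace(0.1, 10, 8)
        sweep = FrequencySweep(f, np.full(8, 1000.0), np.zeros(8))
        fr = fit_sweep(sweep, "SFKV")
        assert any("degenerate" in w for w in fr.warnings)
        assert fr.params.k_alpha == pytest.approx(1000.0, rel=1e-4)


class TestCompareModels:
    def test_sfkv_wins_on_sfkv_data(self, kidney):
        wins = sum(
            compare_models(gen_frequency_sweep(kidney, seed=s))[0].model_id == "SFKV"
            for s in range(20)
        )
        assert wins >= 19

    def test_fkv_outranks_sls_on_fkv_data(self):
        params = FKVParams.from_kpa(0.8, 0.15, 0.2)  # frequency-independent loss shape
        ranks = []
        for s in range(10):
            sweep = sweep_from_params("FKV", params, noise_cv=0.03, seed=s)
            order = [r.model_id for r in compare_models(sweep)]
            ranks.append(order.index("FKV") < order.index("SLS"))
        assert np.mean(ranks) >= 0.9

    def test_pure_spring_data_ties_all_models(self):
        f = np.geomspace(0.1, 10, 10)
        sweep = FrequencySweep(f, np.full(10, 2000.0), np.zeros(10))
        results = compare_models(sweep)
        assert len(results) == 3
        assert all(r.r2 == pytest.approx(1.0, abs=1e-6) for r in results)


class TestStrainDependence:
    def test_exact_line_round_trip(self):
        # points generated exactly on the kidney stiffening law k0=0.69, b=0.23
        eps = np.array([0.5, 2.5, 4.5, 6.5, 8.5, 10.5])
        k = 0.69 * (1 + 0.23 * eps)
        dep = fit_strain_dependence(list(zip(eps, k)))
        assert dep.k0 == pytest.approx(0.69, rel=1e-12)
        assert dep.b == pytest.approx(0.23, rel=1e-12)
        assert dep.fit_r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_k_gives_zero_slope(self):
        eps = np.array([0.5, 2.5, 4.5, 6.5])
        dep = fit_strain_dependence(list(zip(eps, np.full(4, 0.88))))
        assert dep.b == pytest.approx(0.0, abs=1e-12)

    def test_noisy_recovery_of_slope(self, rng):
        # 5% noise, 6 strain levels: mean recovered b within 10% of truth
        eps = np.array([0.5, 2.5, 4.5, 6.5, 8.5, 10.5])
        truth_b = 0.23
        recovered = []
        for _ in range(100):
            k = 0.69 * (1 + truth_b * eps) * (1 + 0.05 * rng.standard_normal(6))
            recovered.append(fit_strain_dependence(list(zip(eps, k))).b)
        assert np.mean(recovered) == pytest.approx(truth_b, rel=0.10)

    def test_too_few_levels(self):
        with pytest.raises(ValueError):
            fit_strain_dependence([(0.5, 0.8), (2.5, 0.9)])


class TestParameterTable:
    def _fit(self, k_kpa, alpha=0.12, eta=7.58):
        return FitResult(
            model_id="SFKV", params=SFKVParams.from_kpa(k_kpa, alpha, eta),
            r2=0.999, residual_norm=0.01, n_points=20, convention="hz",
        )

    def test_single_fit_row_equals_params(self):
        table = make_parameter_table({"kidney": [self._fit(0.88)]})
        row = table.iloc[0]
        assert row["k_alpha_kpa_mean"] == 0.88
        assert row["k_alpha_kpa_sd"] == 0.0
        assert row["alpha_mean"] == 0.12
        assert row["eta_pas_mean"] == 7.58

    def test_identical_fits_have_zero_sd(self):
        table = make_parameter_table({"kidney": [self._fit(0.88), self._fit(0.88)]})
        assert table.iloc[0]["k_alpha_kpa_sd"] == 0.0

    def test_reports_coefficient_of_variation(self):
        # dispersion across samples is reported as sd/mean in %
        ks = [0.88, 0.63, 1.13, 0.75, 1.01]
        table = make_parameter_table({"kidney": [self._fit(k) for k in ks]})
        expect = 100 * np.std(ks, ddof=1) / np.mean(ks)
        assert table.iloc[0]["k_alpha_cv_pct"] == pytest.approx(expect, abs=0.005)
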