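"""Deflection-surface regression, Young's modulus and hysteresis."""

import numpy as np
import pytest
from sklearn.base import clone

from carrypole.config import GRAVITY
from carrypole.deflection import (
    DeflectionRecord,
    DeflectionSurfaceRegressor,
    build_loop_curves,
    fit_deflection_surface,
    hysteresis,
    young_modulus,
)
from carrypole.dynamics import spring_constant, spring_constant_from_coefficient
from carrypole.synthetic import (
    SyntheticPoleSpec,
    gen_deflection_dataset,
    hysteresis_offset_for,
)


@pytest.fixture
def noiseless_dataset(pole_spec):
    return gen_deflection_dataset(pole_spec, noise_sd=0.0)


class TestSurfaceFit:
    def test_noiseless_exact_recovery(self, noiseless_dataset):
        d = noiseless_dataset
        fit = fit_deflection_surface(d.records, x_L=d.x_L)
        assert fit.a == pytest.approx(d.a, rel=1e-9)
        assert fit.a_ci95[1] - fit.a_ci95[0] == pytest.approx(0.0, abs=1e-12 * d.a)

    def test_recovery_of_reported_coefficient_scale(self):
        # coefficient of the stiffest surveyed pole order of magnitude
        spec = SyntheticPoleSpec(seed=1)
        a_true = 7.29e-4
        d = gen_deflection_dataset(spec, a=a_true, noise_sd=0.0)
        fit = fit_deflection_surface(d.records, x_L=d.x_L)
        assert fit.a == pytest.approx(a_true, rel=1e-7)

    def test_noisy_ci_covers_truth(self, pole_spec):
        hits = 0
        for seed in range(50):
            d = gen_deflection_dataset(
                pole_spec, noise_sd=5e-4, rng=np.random.default_rng(seed)
            )
            fit = fit_deflection_surface(d.records, x_L=d.x_L)
            hits += fit.a_ci95[0] <= d.a <= fit.a_ci95[1]
        assert hits >= 45  # ~95% nominal coverage

    def test_degenerate_designs_rejected(self):
        recs = [
            DeflectionRecord(load_mass=m, marker_distance=0.0, deflection=0.0)
            for m in (2.0, 4.0, 6.0)
        ]
        with pytest.raises(ValueError, match="rank-deficient|degenerate"):
            fit_deflection_surface(recs, x_L=0.7)

    def test_order_invariance(self, noiseless_dataset):
        d = noiseless_dataset
        fwd = fit_deflection_surface(d.records, x_L=d.x_L)
        rev = fit_deflection_surface(list(d.records)[::-1], x_L=d.x_L)
        assert fwd.a == pytest.approx(rev.a, rel=1e-12)

    def test_ci_shrinks_with_replication(self, pole_spec):
        rng = np.random.default_rng(3)
        datasets = [
            gen_deflection_dataset(pole_spec, noise_sd=5e-4, rng=rng)
            for _ in range(4)
        ]

        def design(ds):
            X = np.array([[r.load_mass, r.marker_distance] for d in ds for r in d.records])
            y = np.array([r.deflection for d in ds for r in d.records])
            return X, y

        x_L = datasets[0].x_L
        reg1 = DeflectionSurfaceRegressor(x_L=x_L).fit(*design(datasets[:1]))
        reg4 = DeflectionSurfaceRegressor(x_L=x_L).fit(*design(datasets))
        # standard error shrinks roughly as 1/sqrt(replicates)
        assert reg4.a_se_ == pytest.approx(reg1.a_se_ / 2.0, rel=0.35)

    def test_sklearn_estimator_contract(self):
        reg = DeflectionSurfaceRegressor(x_L=0.65)
        params = reg.get_params()
        assert params["x_L"] == 0.65
        cloned = clone(reg)
        assert cloned.get_params() == params

    def test_tip_deflection_matches_cantilever_closed_form(self, pole_spec):
        d = gen_deflection_dataset(pole_spec, noise_sd=0.0)
        fit = fit_deflection_surface(d.records, x_L=d.x_L)
        m = 10.0
        EI = fit.flexural_rigidity
        X = np.array([[m, d.x_L]])
        reg = DeflectionSurfaceRegressor(x_L=d.x_L).fit(
            np.array([[r.load_mass, r.marker_distance] for r in d.records]),
            np.array([r.deflection for r in d.records]),
        )
        tip = reg.predict(X)[0]
        assert tip == pytest.approx(m * GRAVITY * d.x_L**3 / (3 * EI), rel=1e-9)


class TestYoungModulus:
    @pytest.mark.parametrize(
        "a, I, expected_gpa",
        [(7.29e-4, 1.028e-8, 22.2), (3.98e-4, 2.740e-8, 15.3)],
    )
    def test_reported_pairs(self, a, I, expected_gpa):
        assert young_modulus(a, I) / 1e9 == pytest.approx(expected_gpa, abs=0.05)

    def test_identity(self):
        I = 3.7e-8
        assert young_modulus(1.0 / (6.0 * I), I) == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            young_modulus(0.0, 1e-8)
        with pytest.raises(ValueError):
            young_modulus(1e-4, -1e-8)


class TestHysteresis:
    def test_identical_curves_no_loss(self):
        curve = np.column_stack([np.linspace(0, 0.1, 20), np.linspace(0, 200, 20)])
        h = hysteresis(curve, curve)
        assert h.hysteresis == pytest.approx(0.0, abs=1e-12)
        assert h.resilience == pytest.approx(1.0)

    def test_scaled_unloading_triangle_ratio(self):
        delta = np.linspace(0, 0.1, 50)
        loading = np.column_stack([delta, 2000.0 * delta])
        unloading = np.column_stack([delta, 0.9 * 2000.0 * delta])
        assert hysteresis(loading, unloading).hysteresis == pytest.approx(0.10, abs=1e-9)

    def test_total_loss(self):
        delta = np.linspace(0, 0.1, 50)
        loading = np.column_stack([delta, 2000.0 * delta])
        unloading = np.column_stack([delta, np.zeros_like(delta)])
        assert hysteresis(loading, unloading).hysteresis == pytest.approx(1.0)

    def test_zero_energy_rejected(self):
        delta = np.linspace(0, 0.1, 10)
        flat = np.column_stack([delta, np.zeros_like(delta)])
        with pytest.raises(ValueError):
            hysteresis(flat, flat)


class TestLoopCurves:
    def test_linear_pole_loading_slope(self, pole_spec):
        d = gen_deflection_dataset(pole_spec, noise_sd=0.0)
        loading, _ = build_loop_curves(d.records, x_L=d.x_L)
        slope = np.polyfit(loading[:, 0], loading[:, 1], 1)[0]
        k_expected = spring_constant_from_coefficient(d.a, d.x_L)
        assert slope == pytest.approx(k_expected, rel=1e-9)

    def test_missing_phase_raises(self, pole_spec):
        d = gen_deflection_dataset(pole_spec, noise_sd=0.0)
        loading_only = [r for r in d.records if r.phase == "loading"]
        with pytest.raises(ValueError, match="unloading"):
            build_loop_curves(loading_only, x_L=d.x_L)

    def test_generated_loop_area_matches_analytic(self, pole_spec):
        target = 0.05
        d = gen_deflection_dataset(
            pole_spec, noise_sd=0.0, hysteresis_offset=hysteresis_offset_for(target)
        )
        loading, unloading = build_loop_curves(d.records, x_L=d.x_L)
        h = hysteresis(loading, unloading)
        assert h.hysteresis == pytest.approx(target, abs=0.002)

    def test_stiffness_consistency_with_spring_constant(self, pole_spec):
        # k from E, I equals the tip load-deflection slope on noiseless data
        d = gen_deflection_dataset(pole_spec, noise_sd=0.0)
        fit = fit_deflection_surface(d.records, x_L=d.x_L)
        I = pole_spec.I_zzc_nominal_m4
        E = young_modulus(fit.a, I)
        k_beam = spring_constant(E, I, d.x_L)
        loading, _ = build_loop_curves(d.records, x_L=d.x_L)
        slope = np.polyfit(loading[:, 0], loading[:, 1], 1)[0]
        assert k_beam == pytest.approx(slope, rel=1e-3)
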