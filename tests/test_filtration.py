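"""Carman-Kozeny resistance, compressibility fit, forward simulation, Darcy fit."""

import math
from dataclasses import replace

import numpy as np
import pytest

from isowash import (
    CakeProperties,
    ParticlePopulation,
    alpha_at_pressure,
    carman_kozeny_alpha,
    darcy_fit,
    dryland_state,
    fit_compressibility,
    make_scenario,
    predict_volumes,
    simulate_filtration,
)
from isowash.errors import (
    InvalidArgumentError,
    InvalidSeriesError,
    InvalidStateError,
)
from isowash.filtration import _hydraulics, classify_compressibility

SPHERES_100UM = ParticlePopulation(
    x10=50, x50=100, x90=150, d43=100.0, sphericity=1.0, sd=30
)


class TestCarmanKozeny:
    def test_hand_evaluated_reference_value(self):
        # psi=1, eps=0.5, x=100 um, rho_s=1000 -> 180*0.5/(1000*1e-8*0.125)
        alpha = carman_kozeny_alpha(SPHERES_100UM, 0.5, 1000.0)
        assert alpha == pytest.approx(7.2e7, rel=1e-12)

    def test_doubling_size_quarters_alpha(self):
        big = replace(SPHERES_100UM, x90=400, d43=200.0, mean_size_um=200.0)
        assert carman_kozeny_alpha(SPHERES_100UM, 0.5, 1000.0) == pytest.approx(
            4.0 * carman_kozeny_alpha(big, 0.5, 1000.0)
        )

    def test_porosity_bounds_enforced(self):
        with pytest.raises(InvalidArgumentError):
            carman_kozeny_alpha(SPHERES_100UM, 1.0, 1000.0)

    def test_order_of_magnitude_matches_measured_cake_resistance(self):
        # diglyme-water/cyclohexane system: psi=0.4964, eps=0.5258,
        # x=94 um, rho_s=1260 vs the measured 1.01e8 m/kg
        particles = ParticlePopulation(
            x10=39.03, x50=86.95, x90=176.48, d43=94.0, sphericity=0.4964,
            sd=174.0,
        )
        alpha = carman_kozeny_alpha(particles, 0.5258, 1260.0)
        assert 1e7 < alpha < 1e9  # same order of magnitude as 1.01e8


class TestAlphaAtPressure:
    def test_incompressible_is_pressure_independent(self):
        props = CakeProperties(porosity=0.5, sphericity=0.8,
                               compressibility_index=0.0, alpha_ref=1e8)
        assert alpha_at_pressure(props, 5e4) == 1e8
        assert alpha_at_pressure(props, 5e5) == 1e8

    def test_unit_index_is_linear_in_pressure(self):
        props = CakeProperties(porosity=0.5, sphericity=0.8,
                               compressibility_index=1.0,
                               reference_pressure=1e5, alpha_ref=1e8)
        assert alpha_at_pressure(props, 2e5) == pytest.approx(2e8)

    def test_two_point_slope_reproduces_measured_pair(self):
        # alpha_ref = 9.84e7 at 100 mbar, n from the 100/600 mbar pair,
        # evaluated at 600 mbar must hit 1.84e9
        n = math.log(1.84e9 / 9.84e7) / math.log(6.0)
        props = CakeProperties(porosity=0.5, sphericity=0.8,
                               compressibility_index=n,
                               reference_pressure=1e4, alpha_ref=9.84e7)
        assert alpha_at_pressure(props, 6e4) == pytest.approx(1.84e9, rel=1e-9)


class TestFitCompressibility:
    def test_two_point_slope_matches_hand_formula(self):
        fit = fit_compressibility([(1e4, 9.84e7), (6e4, 1.84e9)])
        expected = math.log(1.84e9 / 9.84e7) / math.log(6.0)
        assert fit.n == pytest.approx(expected, rel=1e-12)
        assert fit.label == "high"
        assert fit.identifiable

    def test_flat_line_is_incompressible(self):
        fit = fit_compressibility([(1e4, 5e8), (6e4, 5e8)])
        assert fit.n == pytest.approx(0.0, abs=1e-12)
        assert fit.label == "low/moderate"

    def test_collinear_points_recovered_to_machine_precision(self):
        n_true, a0 = 0.73, 3.1e8
        pairs = [(p, a0 * (p / 1e5) ** n_true) for p in (1e4, 5e4, 2e5)]
        fit = fit_compressibility(pairs)
        assert fit.n == pytest.approx(n_true, rel=1e-12)
        assert fit.alpha_ref == pytest.approx(a0, rel=1e-10)

    def test_single_pressure_flags_unidentifiable(self):
        fit = fit_compressibility([(1e5, 1e8), (1e5, 2e8)])
        assert not fit.identifiable
        assert fit.n == 0.0

    def test_classification_bands(self):
        assert classify_compressibility(0.3) == "low/moderate"
        assert classify_compressibility(1.3) == "high"
        assert classify_compressibility(50.0) == "extreme"


class TestSimulateFiltration:
    def test_matches_analytic_closed_form(self, mfa2):
        """t = (mu/(A dP)) (alpha w V^2 / 2A + Rm V) at every grid time."""
        res = simulate_filtration(mfa2)
        h = _hydraulics(mfa2)
        area = mfa2.filter.area
        dp = mfa2.conditions.driving_force
        v = res.filtrate_volumes
        t_exact = (h.mu / (area * dp)) * (
            h.alpha * h.w * v**2 / (2 * area)
            + mfa2.filter.medium_resistance * v
        )
        assert np.allclose(res.times, t_exact, rtol=1e-3)

    def test_volume_series_monotone_and_concave(self, mfa2):
        res = simulate_filtration(mfa2)
        t, v = res.times, res.filtrate_volumes
        assert np.all(np.diff(v) >= 0)
        rates = np.diff(v) / np.diff(t)
        assert np.all(np.diff(rates) <= 1e-12)  # decelerating flow

    def test_zero_solids_gives_pure_medium_darcy_flow(self, mfa2):
        susp = replace(mfa2.suspension, solid_mass=0.0)
        scen = replace(mfa2, suspension=susp)
        res = simulate_filtration(scen)
        slope = (
            mfa2.conditions.driving_force * mfa2.filter.area
            / (res.viscosity * mfa2.filter.medium_resistance)
        )
        keep = res.times > 0
        assert np.allclose(
            res.filtrate_volumes[keep] / res.times[keep], slope, rtol=1e-9
        )

    def test_mass_balance_closes_at_every_time(self, mfa2):
        res = simulate_filtration(mfa2)
        susp = mfa2.suspension
        filtrate = res.filtrate_volumes * res.filtrate_density
        # wet cake mass (solids deposited so far + liquor everywhere else)
        wet = susp.total_mass - filtrate
        total = filtrate + wet
        assert np.allclose(total, susp.total_mass, rtol=1e-12)
        # and at dryland, the explicit cake state closes the balance
        end = res.end_state
        assert (
            res.filtrate_mass + end.solid_mass + end.liquor_mass
        ) == pytest.approx(susp.total_mass, rel=1e-8)

    def test_max_time_truncates_before_dryland(self, mfa2):
        full = simulate_filtration(mfa2)
        res = simulate_filtration(mfa2, max_time=float(full.times[-1]) / 4)
        assert res.stopped_at == "max_time"
        assert res.filtrate_volumes[-1] < full.filtrate_volumes[-1]
        with pytest.raises(InvalidStateError):
            dryland_state(res)


class TestDrylandState:
    def test_geometry_identities(self, mfa2_cake):
        cake = mfa2_cake
        assert cake.void_volume == pytest.approx(
            cake.porosity * cake.bulk_volume, rel=1e-12
        )
        assert cake.height == pytest.approx(
            cake.solid_volume / ((1 - cake.porosity) * cake.area), rel=1e-12
        )
        assert cake.saturation == 1.0

    def test_retained_liquor_fills_voids(self, mfa2, mfa2_cake):
        res = simulate_filtration(mfa2)
        assert mfa2_cake.liquor_mass == pytest.approx(
            mfa2_cake.void_volume * res.filtrate_density, rel=1e-12
        )
        assert mfa2_cake.liquor.mass_fractions == pytest.approx(
            mfa2.suspension.liquor.mass_fractions
        )

    def test_retained_solvent_mass_near_reported_value(self, mfa2_cake):
        # displacement-model reference for this experiment: 7.18 g
        solvent_g = mfa2_cake.species_masses()["diglyme_water"] * 1e3
        assert solvent_g == pytest.approx(7.18, rel=0.20)


class TestDarcyFit:
    def test_round_trip_recovers_simulator_parameters(self, mfa2):
        res = simulate_filtration(mfa2)
        fit = darcy_fit(
            res.times, res.filtrate_volumes, mfa2.filter.area,
            mfa2.conditions.driving_force, res.viscosity,
            res.solids_per_volume,
        )
        assert fit.alpha == pytest.approx(res.alpha_used, rel=1e-2)
        assert fit.medium_resistance == pytest.approx(
            mfa2.filter.medium_resistance, rel=1e-2
        )
        assert not fit.negative_medium_resistance

    def test_two_points_rejected(self, mfa2):
        with pytest.raises(InvalidSeriesError):
            darcy_fit(
                np.array([0.0, 1.0, 2.0]), np.array([0.0, 1e-6, 2e-6]),
                mfa2.filter.area, 6e4, 1e-3, 100.0,
            )

    def test_non_monotone_volumes_rejected(self, mfa2):
        with pytest.raises(InvalidSeriesError):
            darcy_fit(
                np.array([1.0, 2.0, 3.0]), np.array([2e-6, 1e-6, 3e-6]),
                mfa2.filter.area, 6e4, 1e-3, 100.0,
            )

    def test_negative_intercept_reported_with_flag(self):
        # synthetic series with a negative t/V intercept (pre-settled cake)
        v = np.linspace(1e-6, 1e-5, 20)
        t = 1e11 * v**2 - 1e4 * v
        fit = darcy_fit(t, v, 5e-4, 6e4, 1e-3, 100.0)
        assert fit.negative_medium_resistance
        assert fit.medium_resistance < 0
        assert fit.warnings()

    def test_noisy_recovery_within_ten_percent_median(self, mfa2):
        res = simulate_filtration(mfa2, n_points=50)
        rng = np.random.default_rng(42)
        errors = []
        for _ in range(100):
            noisy = res.filtrate_volumes[1:] * (
                1 + 0.01 * rng.standard_normal(49)
            )
            order = np.argsort(noisy)
            v, t = noisy[order], res.times[1:][order]
            keep = np.concatenate([[True], np.diff(v) > 0])
            fit = darcy_fit(
                t[keep], v[keep], mfa2.filter.area,
                mfa2.conditions.driving_force, res.viscosity,
                res.solids_per_volume,
            )
            errors.append(abs(fit.alpha - res.alpha_used) / res.alpha_used)
        assert np.median(errors) < 0.10


def test_predict_volumes_caps_at_dryland(mfa2):
    res = simulate_filtration(mfa2)
    t_end = float(res.times[-1])
    v = predict_volumes(mfa2, np.array([t_end, 2 * t_end, 10 * t_end]))
    assert np.allclose(v, res.filtrate_volumes[-1], rtol=1e-12)
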