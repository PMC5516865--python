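"""One-compartment saturable-clearance PK: simulation, fits, summaries."""

import numpy as np
import pytest

from erbbqsp.pkpd import (
    DoseSchedule,
    PKInputError,
    PKParams,
    SerumProfile,
    default_pk_params,
    drug_mass_balance,
    fit_pk,
    simulate_pk,
    terminal_half_life,
    trough_concentration,
    ug_per_ml_to_nmol_per_l,
)

PRINTED_TIMES = np.array([1.0, 4.0, 8.0, 24.0, 48.0, 72.0, 96.0, 168.0])


class TestUnitBridge:
    def test_trough_goal_in_molar_units(self):
        # 100 µg/ml of a 150 kDa IgG = 667 nmol/l
        assert ug_per_ml_to_nmol_per_l(100.0) == pytest.approx(666.67, abs=0.5)

    def test_linear_in_concentration(self):
        assert ug_per_ml_to_nmol_per_l(50.0) == pytest.approx(
            0.5 * ug_per_ml_to_nmol_per_l(100.0))


class TestSimulatePK:
    def test_no_elimination_conserves_dose(self):
        params = PKParams(ka=1.0, V=2.0, Vmax=1e-12, Km=50.0)
        profile = simulate_pk(params, DoseSchedule.single(600.0, 500.0), [500.0])
        assert profile.concentrations[0] == pytest.approx(600.0 / 2.0, rel=1e-4)

    def test_linear_limit_matches_bateman_solution(self):
        """Km >> C: reduces to first-order elimination with CL = Vmax/Km;
        closed-form Bateman equation is the oracle."""
        ka, V, Vmax, Km = 0.5, 2.0, 10.0, 1e6
        ke = Vmax / Km / V
        params = PKParams(ka, V, Vmax, Km)
        dose = 100.0
        t = np.linspace(1.0, 96.0, 20)
        profile = simulate_pk(params, DoseSchedule.single(dose, 100.0), t)
        bateman = dose * ka / (V * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))
        np.testing.assert_allclose(profile.concentrations, bateman, rtol=1e-3)

    def test_half_life_increases_with_dose(self):
        params = default_pk_params()
        half_lives = []
        for dose in (150.0, 300.0, 600.0):
            profile = simulate_pk(params, DoseSchedule.single(dose), PRINTED_TIMES)
            half_lives.append(terminal_half_life(profile).hours)
        assert half_lives[0] < half_lives[1] < half_lives[2]

    def test_clearance_accelerates_below_km(self):
        params = default_pk_params()
        # instantaneous clearance Vmax/(Km+C) is larger at low C
        cl = lambda c: params.Vmax / (params.Km + c)
        assert cl(10.0) > cl(params.Km) > cl(300.0)
        # visible in the profile: log-slope steepens once C < Km
        profile = simulate_pk(params, DoseSchedule.single(600.0, 200.0),
                              np.linspace(10.0, 200.0, 96))
        logc = np.log(profile.concentrations)
        slopes = np.diff(logc) / np.diff(profile.times)
        above = profile.concentrations[:-1] > 2 * params.Km
        below = profile.concentrations[:-1] < 0.5 * params.Km
        assert np.mean(np.abs(slopes[below])) > 2 * np.mean(np.abs(slopes[above]))

    def test_mass_balance(self):
        params = default_pk_params()
        schedule = DoseSchedule(((0.0, 600.0), (72.0, 600.0)), 200.0)
        total, dosed = drug_mass_balance(params, schedule, 150.0)
        assert total == pytest.approx(dosed, rel=1e-6)


class TestTerminalHalfLife:
    def test_pure_exponential(self):
        t = np.array([10.0, 20.0, 30.0, 40.0])
        profile = SerumProfile(t, 50.0 * np.exp(-0.1 * t), 100.0)
        est = terminal_half_life(profile)
        assert est.hours == pytest.approx(np.log(2) / 0.1, rel=1e-9)
        assert est.monotone

    def test_scale_invariance(self):
        t = np.array([10.0, 20.0, 30.0, 40.0])
        a = terminal_half_life(SerumProfile(t, 50.0 * np.exp(-0.1 * t), 1.0))
        b = terminal_half_life(SerumProfile(t, 100.0 * np.exp(-0.1 * t), 1.0))
        assert a.hours == pytest.approx(b.hours, rel=1e-12)

    def test_low_dose_window_matches_analytic_linear_limit(self):
        params = default_pk_params()
        profile = simulate_pk(params, DoseSchedule.single(20.0, 200.0),
                              np.linspace(40.0, 80.0, 5))
        est = terminal_half_life(profile, window=5)
        assert est.hours == pytest.approx(params.linear_half_life(), rel=0.10)

    def test_non_monotone_window_flagged(self):
        t = np.array([0.0, 10.0, 20.0, 30.0])
        c = np.array([10.0, 4.0, 6.0, 2.0])
        est = terminal_half_life(SerumProfile(t, c, 1.0))
        assert not est.monotone

    def test_too_few_points_rejected(self):
        with pytest.raises(PKInputError):
            terminal_half_life(SerumProfile(np.array([1.0, 2.0]),
                                            np.array([5.0, 3.0]), 1.0))


class TestFitPK:
    def test_noiseless_recovery_within_5_percent(self):
        truth = default_pk_params()
        profiles = [
            simulate_pk(truth, DoseSchedule.single(dose), PRINTED_TIMES)
            for dose in (150.0, 300.0, 600.0)
        ]
        fit, diag = fit_pk(profiles, seed=1)
        for name in ("ka", "V", "Vmax", "Km"):
            assert getattr(fit, name) == pytest.approx(getattr(truth, name), rel=0.05)
        assert not diag["weakly_identified"]

    def test_single_low_dose_group_flagged_weakly_identified(self):
        truth = default_pk_params()
        profile = simulate_pk(truth, DoseSchedule.single(20.0), PRINTED_TIMES[:6])
        _, diag = fit_pk([profile], seed=2, n_starts=4)
        assert diag["weakly_identified"]

    def test_all_zero_rejected(self):
        profile = SerumProfile(PRINTED_TIMES, np.zeros(len(PRINTED_TIMES)), 150.0)
        with pytest.raises(PKInputError):
            fit_pk([profile])

    def test_too_few_points_rejected(self):
        profile = SerumProfile(np.array([1.0, 4.0, 8.0]), np.array([1.0, 2.0, 1.5]), 150.0)
        with pytest.raises(PKInputError):
            fit_pk([profile])


class TestTrough:
    def test_monotone_in_dose(self):
        params = default_pk_params()
        troughs = [
            trough_concentration(params, DoseSchedule.repeating(dose, 72.0, 20)).trough_ug_ml
            for dose in (300.0, 600.0, 900.0)
        ]
        assert troughs[0] <= troughs[1] <= troughs[2]

    def test_no_elimination_flagged_non_stationary(self):
        params = PKParams(ka=0.3, V=2.0, Vmax=1e-12, Km=50.0)
        result = trough_concentration(params, DoseSchedule.repeating(600.0, 72.0, 8))
        assert not result.stationary

    def test_q3d_600ug_meets_trough_goal(self):
        result = trough_concentration(
            default_pk_params(), DoseSchedule.repeating(600.0, 72.0, 20))
        assert result.stationary
        assert result.meets_goal
        assert result.trough_ug_ml > 100.0

    def test_non_repeating_schedule_rejected(self):
        params = default_pk_params()
        schedule = DoseSchedule(
            ((0.0, 600.0), (72.0, 300.0), (144.0, 600.0), (216.0, 600.0), (288.0, 600.0)),
            400.0)
        with pytest.raises(PKInputError):
            trough_concentration(params, schedule)

    def test_too_few_cycles_rejected(self):
        with pytest.raises(PKInputError):
            trough_concentration(default_pk_params(),
                                 DoseSchedule.repeating(600.0, 72.0, 3))
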