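"""Growth-linked model: simulation limits, DT50 extraction, fitting,
unit conversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from atrakin import (ApplicationSchedule, GrowthLinkedParams,
                     ResidueObservations, degrader_size, dt50_from_series,
                     fit_growth_linked, percent_dose_to_micromolar,
                     simulate_growth_linked)
from atrakin.growth_model import (InvalidParameterError, InvalidSettingsError,
                                  SimulationSettings, UnderDeterminedError)
from atrakin.synth import NoiseModel, SoilScenario, generate_dissipation

from conftest import sfo_observations


def monod_halving_time(A0, A, Ks, NV):
    """Implicit solution of dA/dt = -NV*A/(A+Ks): t(A)."""
    return ((A0 - A) + Ks * math.log(A0 / A)) / NV


class TestSimulate:
    def test_no_removal_terms_residue_constant(self, single_dose):
        p = GrowthLinkedParams(k1=0.1, Y=0, N0=0, mu=0.2, V=0.7, Ks=75)
        s = simulate_growth_linked(p, single_dose,
                                   SimulationSettings(0.01, 28))
        assert np.allclose(s.atr, 100.0)

    def test_chemical_only_limit_matches_exponential(self, single_dose):
        p = GrowthLinkedParams(k1=0.1, Y=100, N0=0, mu=0, V=0, Ks=75)
        s = simulate_growth_linked(p, single_dose,
                                   SimulationSettings(0.01, 60))
        err = np.max(np.abs(s.atr - 100 * np.exp(-0.1 * s.times)))
        assert err < 0.5
        assert s.interp_atr(math.log(2) / 0.1) == pytest.approx(50, abs=0.5)

    def test_chemical_limit_error_shrinks_with_step(self, single_dose):
        p = GrowthLinkedParams(k1=0.1, Y=100, N0=0, mu=0, V=0, Ks=75)
        errs = []
        for step in (0.1, 0.05, 0.01):
            s = simulate_growth_linked(p, single_dose,
                                       SimulationSettings(step, 60))
            errs.append(np.max(np.abs(s.atr - 100 * np.exp(-0.1 * s.times))))
        assert errs[0] > errs[1] > errs[2]

    def test_biological_only_limit_matches_implicit_monod(self, single_dose):
        p = GrowthLinkedParams(k1=0, Y=0, N0=100, mu=0, V=0.7, Ks=75)
        s = simulate_growth_linked(p, single_dose,
                                   SimulationSettings(0.01, 30))
        t_star = monod_halving_time(100, 50, 75, 100 * 0.7)
        t_sim = dt50_from_series(s, single_dose, 1)
        assert abs(t_sim - t_star) / t_star < 0.005
        # a second checkpoint deeper into the decay
        t_star25 = monod_halving_time(100, 25, 75, 100 * 0.7)
        assert s.interp_atr(t_star25) == pytest.approx(25, rel=0.01)

    def test_adapting_soil_fast_later_applications(self, adapting_params,
                                                   schedule, settings):
        s = simulate_growth_linked(adapting_params, schedule, settings)
        dt50s = [dt50_from_series(s, schedule, a) for a in (1, 2, 3)]
        assert dt50s[0] > 20
        assert dt50s[1] < 3 and dt50s[2] < 3

    def test_mass_balance_and_nonnegativity(self, adapting_params, schedule,
                                            settings):
        s = simulate_growth_linked(adapting_params, schedule, settings)
        assert np.all(s.atr >= 0)
        total_removed = 300.0 - s.atr[-1]
        assert total_removed <= 300.0 + 1e-9
        # non-increasing between application events (the only positive jumps
        # sit between the duplicated pre/post-dose nodes, where dt == 0)
        jumps = np.diff(s.atr)
        within_window = np.diff(s.times) > 0
        assert np.all(jumps[within_window] <= 1e-12)

    def test_degraders_nondecreasing_and_capped(self, adapting_params,
                                                schedule, settings):
        s = simulate_growth_linked(adapting_params, schedule, settings)
        assert np.all(np.diff(s.degraders) >= 0)
        assert np.all(s.degraders <= 100.0 + 1e-12)

    def test_reapplication_accumulates_when_not_degrading(self, schedule):
        p = GrowthLinkedParams(k1=0.014, Y=40, N0=0, mu=0, V=0.7, Ks=75)
        s = simulate_growth_linked(p, schedule, SimulationSettings(0.01, 116))
        after_third = s.interp_atr(88.01)
        assert after_third > 100.0

    def test_chem_pool_clock_resets_at_application(self, adapting_params,
                                                   schedule, settings):
        s = simulate_growth_linked(adapting_params, schedule, settings)
        at60 = np.nonzero(s.times == 60.0)[0]
        assert len(at60) == 2                       # pre- and post-dose nodes
        assert s.chem_pool_clock[at60[1]] == 0.0    # clock reset on dosing
        assert s.chem_pool_clock[at60[0]] > 59

    def test_invalid_inputs_raise(self, single_dose):
        with pytest.raises(InvalidParameterError):
            GrowthLinkedParams(k1=math.nan, Y=50, N0=0.1, mu=0.2, V=0.7)
        with pytest.raises(InvalidParameterError):
            GrowthLinkedParams(k1=0.1, Y=150, N0=0.1, mu=0.2, V=0.7)
        with pytest.raises(InvalidSettingsError):
            SimulationSettings(step=-0.01, horizon=60)
        with pytest.raises(InvalidSettingsError):
            p = GrowthLinkedParams(k1=0.1, Y=50, N0=0.1, mu=0.2, V=0.7)
            simulate_growth_linked(p, ApplicationSchedule((0, 60, 88)),
                                   SimulationSettings(0.01, 80))


class TestDegraderSize:
    @pytest.mark.parametrize("n0,mu,t,expected", [
        (0.03, 0.0, 50.0, 0.03),             # zero growth
        (0.03, 0.2, 60.0, 100.0),            # 0.03*e^12 ~ 4883, capped
        (100.0, 0.2, 0.0, 100.0),            # starts at the cap
        (0.0, 0.5, 100.0, 0.0),              # nothing grows from nothing
    ])
    def test_values(self, n0, mu, t, expected):
        p = GrowthLinkedParams(k1=0, Y=0, N0=n0, mu=mu, V=0, Ks=75)
        assert degrader_size(p, t) == pytest.approx(expected)

    @given(t1=st.floats(0, 200), t2=st.floats(0, 200))
    @hsettings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_time(self, t1, t2):
        p = GrowthLinkedParams(k1=0, Y=0, N0=0.01, mu=0.2, V=0, Ks=75)
        lo, hi = sorted((t1, t2))
        assert degrader_size(p, lo) <= degrader_size(p, hi) + 1e-12

    def test_negative_time_rejected(self):
        p = GrowthLinkedParams(k1=0, Y=0, N0=0.01, mu=0.2, V=0, Ks=75)
        with pytest.raises(ValueError):
            degrader_size(p, -1.0)


class TestDt50FromSeries:
    def test_pure_exponential_half_life(self, single_dose):
        p = GrowthLinkedParams(k1=0.1, Y=100, N0=0, mu=0, V=0, Ks=75)
        s = simulate_growth_linked(p, single_dose,
                                   SimulationSettings(0.01, 60))
        assert dt50_from_series(s, single_dose, 1) == pytest.approx(
            math.log(2) / 0.1, rel=0.01)

    def test_constant_series_is_infinite(self, single_dose):
        p = GrowthLinkedParams(k1=0.1, Y=0, N0=0, mu=0, V=0, Ks=75)
        s = simulate_growth_linked(p, single_dose,
                                   SimulationSettings(0.01, 60))
        assert dt50_from_series(s, single_dose, 1) == math.inf

    def test_higher_growth_rate_never_slows_second_application(
            self, schedule, settings):
        dt50s = []
        for mu in (0.155, 0.19, 0.225):
            p = GrowthLinkedParams(k1=0.1, Y=40, N0=0.001, mu=mu, V=0.65,
                                   Ks=75)
            s = simulate_growth_linked(p, schedule, settings)
            dt50s.append(dt50_from_series(s, schedule, 2))
        assert dt50s[0] >= dt50s[1] >= dt50s[2]

    def test_out_of_range_application(self, single_dose, adapting_params):
        s = simulate_growth_linked(adapting_params, single_dose,
                                   SimulationSettings(0.01, 60))
        with pytest.raises(IndexError):
            dt50_from_series(s, single_dose, 2)


class TestFitGrowthLinked:
    def test_noise_free_parameter_recovery(self, noise_free_obs, schedule,
                                           adapting_params):
        fit = fit_growth_linked(noise_free_obs, schedule, n_starts=12, seed=0)
        assert fit.sse < 1e-6
        p, t = fit.params, adapting_params
        assert p.k1 == pytest.approx(t.k1, rel=0.05)
        assert p.Y == pytest.approx(t.Y, rel=0.05)
        assert p.mu == pytest.approx(t.mu, rel=0.05)
        assert p.V == pytest.approx(t.V, rel=0.05)
        assert p.N0 == pytest.approx(t.N0, rel=0.5)

    def test_sfo_truth_collapses_biological_term(self, schedule):
        # data from the pure chemical pool: fitted biological removal must
        # be negligible relative to the chemical removal
        truth = GrowthLinkedParams(k1=0.05, Y=100, N0=0, mu=0, V=0, Ks=75)
        scen = SoilScenario("SFO", truth, adapting=False, replicate_cv=0.0,
                            n_replicates=1)
        obs = generate_dissipation(scen, schedule,
                                   noise=NoiseModel(cv=0.0, seed=0))
        fit = fit_growth_linked(obs, schedule, n_starts=8, seed=0)
        from atrakin.growth_model import SimulationSettings as SS
        s = simulate_growth_linked(fit.params, schedule, SS(0.01, 116))
        bio_rate = (s.degraders * fit.params.V * s.atr / (s.atr + 75))
        chem_rate = (fit.params.Y * fit.params.k1
                     * np.exp(-fit.params.k1 * s.chem_pool_clock))
        assert bio_rate.sum() < 0.01 * (bio_rate.sum() + chem_rate.sum())

    def test_noisy_dt50_recovery_within_20_percent(self, adapting_params,
                                                   schedule):
        scen = SoilScenario("S1", adapting_params, adapting=True,
                            replicate_cv=0.05, n_replicates=4)
        obs = generate_dissipation(scen, schedule,
                                   noise=NoiseModel(cv=0.05, seed=7))
        fit = fit_growth_linked(obs, schedule, n_starts=4, seed=0)
        s_true = simulate_growth_linked(adapting_params, schedule,
                                        SimulationSettings(0.01, 116))
        s_fit = simulate_growth_linked(fit.params, schedule,
                                       SimulationSettings(0.01, 116))
        for a in (2, 3):
            truth = dt50_from_series(s_true, schedule, a)
            got = dt50_from_series(s_fit, schedule, a)
            assert got == pytest.approx(truth, rel=0.2)

    def test_empty_observations_rejected(self, schedule):
        empty = ResidueObservations(np.array([]), np.array([], dtype=int),
                                    np.array([]), np.array([]), np.array([]))
        with pytest.raises(UnderDeterminedError):
            fit_growth_linked(empty, schedule)

    def test_single_time_rejected(self, schedule):
        obs = sfo_observations(days=(3,), n_reps=4)
        with pytest.raises(UnderDeterminedError):
            fit_growth_linked(obs, schedule)


class TestUnitConversion:
    def test_half_saturation_in_micromolar(self):
        # 75% of a 6 ug/mL dose at 215.68 g/mol is the TrzN Km scale
        assert percent_dose_to_micromolar(75, 6, 215.68) == pytest.approx(
            20.9, abs=0.05)

    @pytest.mark.parametrize("percent,conc,mm,expected", [
        (100, 215.68, 215.68, 1000.0),   # one molar mass per mL = 1 mM
        (50, 6, 215.68, 13.91),
    ])
    def test_arithmetic(self, percent, conc, mm, expected):
        assert percent_dose_to_micromolar(percent, conc, mm) == pytest.approx(
            expected, abs=0.005)

    def test_invalid_molar_mass(self):
        with pytest.raises(ValueError):
            percent_dose_to_micromolar(75, 6, -1)
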