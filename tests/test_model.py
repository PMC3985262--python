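import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import patchpk as pk
from patchpk import (
    ConcentrationSeries,
    EventKind,
    InstabilityError,
    PatchEvent,
    Regimen,
    SimulationGrid,
    absorption_rate,
    elimination_rate,
    simulate_analytic,
    simulate_difference,
)


class TestRates:
    def test_absorption_rate_matches_k_o_over_vd(self, ngmn):
        r0 = absorption_rate(ngmn, patch_age=0.0, area_fraction=1.0)
        assert r0 * 24 == pytest.approx(0.464, rel=1e-3)  # ng/mL per day
        # exponential attenuation with patch age, scaled by attached area
        r = absorption_rate(ngmn, patch_age=100.0, area_fraction=0.5)
        assert r == pytest.approx(0.5 * r0 * math.exp(-ngmn.decay_const * 100))
        assert absorption_rate(ngmn, 10.0, 0.0) == 0.0

    def test_absorption_rate_decays_monotonically(self, ngmn):
        ages = np.linspace(0, 5000, 50)
        rates = [absorption_rate(ngmn, a, 1.0) for a in ages]
        assert all(x > y for x, y in zip(rates, rates[1:]))
        assert rates[-1] < 1e-3 * rates[0] or rates[-1] < rates[0]

    def test_absorption_rate_rejects_bad_inputs(self, ngmn):
        with pytest.raises(ValueError):
            absorption_rate(ngmn, -1.0, 1.0)
        with pytest.raises(ValueError):
            absorption_rate(ngmn, 1.0, 1.5)

    def test_elimination_rate_is_first_order(self, ngmn, ee):
        assert elimination_rate(ngmn, 1.0) == pytest.approx(0.0244)
        assert elimination_rate(ee, 50.0) == pytest.approx(1.925)
        assert elimination_rate(ngmn, 0.0) == 0.0
        with pytest.raises(ValueError):
            elimination_rate(ngmn, -0.1)


class TestGridAndSeries:
    def test_grid_validation(self):
        with pytest.raises(ValueError):
            SimulationGrid(dt=0.0, horizon=10)
        with pytest.raises(ValueError):
            SimulationGrid(dt=2.0, horizon=10)  # dt capped at 1 h
        with pytest.raises(ValueError):
            SimulationGrid(dt=0.3, horizon=10)  # not a multiple
        g = SimulationGrid(dt=0.5, horizon=10)
        assert g.n_steps == 20 and g.times()[-1] == 10

    def test_series_invariants(self):
        with pytest.raises(ValueError):
            ConcentrationSeries([0, 1], [1.0, -0.5], "ng/mL")
        with pytest.raises(ValueError):
            ConcentrationSeries([0, 0], [1.0, 1.0], "ng/mL")
        with pytest.raises(ValueError):
            ConcentrationSeries([0, 1, 2], [1.0, 1.0], "ng/mL")

    def test_csv_round_trip(self, ngmn, std_regimen, tmp_path):
        s = simulate_difference(ngmn, std_regimen, SimulationGrid(0.5, 600))
        path = tmp_path / "traj.csv"
        s.to_csv(path)
        header = path.read_text().splitlines()
        assert header[0] == "# unit: ng/mL"
        assert header[2] == "time_h,concentration"
        back = ConcentrationSeries.from_csv(path)
        assert back.unit == "ng/mL" and back.name == "NGMN"
        assert np.allclose(back.values, s.values, rtol=1e-5)


class TestDifferenceScheme:
    def test_no_patch_is_pure_exponential_decay(self, ngmn):
        reg = Regimen([PatchEvent(0, EventKind.APPLY_NEW, 1.0),
                       PatchEvent(1e-9, EventKind.REMOVE, 0.0)], horizon=200)
        s = simulate_difference(ngmn.with_k_o(1e-300), reg,
                                SimulationGrid(0.1, 200), c0=2.0)
        expected = 2.0 * (1 - ngmn.k_elim * 0.1) ** np.arange(len(s))
        assert np.allclose(s.values, expected, rtol=1e-9)

    def test_zero_horizon_returns_initial_point(self, ngmn, std_regimen):
        s = simulate_difference(ngmn, std_regimen, SimulationGrid(0.1, 0.0), c0=0.0)
        assert len(s) == 1 and s.values[0] == 0.0

    def test_rejects_negative_c0_and_overlong_grid(self, ngmn, std_regimen):
        with pytest.raises(ValueError):
            simulate_difference(ngmn, std_regimen, c0=-1.0)
        with pytest.raises(ValueError):
            simulate_difference(ngmn, std_regimen, SimulationGrid(1.0, 1000))

    def test_unstable_step_raises_rather_than_clips(self, ngmn):
        # k_elim * dt > 1 makes forward Euler overshoot below zero
        bad = pk.DrugParams(**{**ngmn.__dict__, "k_elim": 1.5, "t_half": math.log(2) / 1.5})
        reg = pk.standard_cycle()
        with pytest.raises(InstabilityError):
            simulate_difference(bad, reg, SimulationGrid(1.0, 600), c0=1.0)


class TestOracleEquivalence:
    """The closed-form piecewise solution is the accuracy oracle."""

    def test_difference_tracks_analytic_on_standard_cycle(self, ngmn, std_regimen):
        grid = SimulationGrid(0.01, std_regimen.horizon)
        d = simulate_difference(ngmn, std_regimen, grid)
        a = simulate_analytic(ngmn, std_regimen, grid)
        assert np.max(np.abs(d.values - a.values)) < 1e-3

    def test_first_order_convergence(self, ngmn, std_regimen):
        devs = {}
        for dt in (0.1, 0.05):
            grid = SimulationGrid(dt, std_regimen.horizon)
            d = simulate_difference(ngmn, std_regimen, grid)
            a = simulate_analytic(ngmn, std_regimen, grid)
            devs[dt] = np.max(np.abs(d.values - a.values))
        ratio = devs[0.1] / devs[0.05]
        assert 1.6 < ratio < 2.4  # halving dt halves the error

    def test_analytic_decay_only_and_steady_state(self, ngmn):
        # f = 0 throughout: C = c0 exp(-k t)
        reg = Regimen([PatchEvent(0, EventKind.APPLY_NEW, 1.0),
                       PatchEvent(1e-9, EventKind.REMOVE, 0.0)], horizon=300)
        t = np.linspace(1, 300, 40)
        c = pk.analytic_concentrations(ngmn, reg, t, c0=1.7)
        assert np.allclose(c, 1.7 * np.exp(-ngmn.k_elim * t), rtol=1e-9, atol=1e-12)

        # constant input (zero attenuation): C -> (k_o/V_d)/k
        flat = ngmn.with_decay_const(0.0)
        reg2 = Regimen([PatchEvent(0, EventKind.APPLY_NEW, 1.0)], horizon=5000)
        c_inf = pk.analytic_concentrations(flat, reg2, [5000.0])[0]
        assert c_inf == pytest.approx(flat.input_rate / flat.k_elim, rel=1e-9)

    def test_confluent_limit_when_k_equals_decay_const(self, ngmn):
        conf = ngmn.with_decay_const(ngmn.k_elim)
        reg = Regimen([PatchEvent(0, EventKind.APPLY_NEW, 1.0)], horizon=600)
        t = np.linspace(0, 600, 200)
        c = pk.analytic_concentrations(conf, reg, t)
        expected = conf.input_rate * t * np.exp(-conf.k_elim * t)
        assert np.allclose(c, expected, rtol=1e-9, atol=1e-15)
        # and a nearby non-confluent value agrees continuously
        near = ngmn.with_decay_const(ngmn.k_elim * (1 + 1e-7))
        c2 = pk.analytic_concentrations(near, reg, t)
        assert np.allclose(c, c2, rtol=1e-5)


class TestStructuralProperties:
    def test_linearity_in_dose(self, ngmn, std_regimen, std_grid):
        base = simulate_difference(ngmn, std_regimen, std_grid)
        double = simulate_difference(ngmn.with_k_o(2 * ngmn.k_o), std_regimen, std_grid)
        assert np.allclose(double.values, 2 * base.values, rtol=1e-12)

    def test_area_scaling(self, ngmn):
        full = Regimen([PatchEvent(0, EventKind.APPLY_NEW, 1.0)], horizon=300)
        half = Regimen([PatchEvent(0, EventKind.APPLY_NEW, 1.0),
                        PatchEvent(0.0, EventKind.DETACH, 0.5)], horizon=300)
        grid = SimulationGrid(0.1, 300)
        s_full = simulate_difference(ngmn, full, grid)
        s_half = simulate_difference(ngmn, half, grid)
        assert np.allclose(s_half.values[1:], 0.5 * s_full.values[1:], rtol=1e-9)

    def test_post_removal_log_slope_is_minus_kelim(self, ngmn, std_regimen):
        grid = SimulationGrid(0.1, std_regimen.horizon)
        a = simulate_analytic(ngmn, std_regimen, grid)
        tail = a.slice(510, 600)
        slope = np.polyfit(tail.times, np.log(tail.values), 1)[0]
        assert slope == pytest.approx(-ngmn.k_elim, rel=1e-9)
        d = simulate_difference(ngmn, std_regimen, grid)
        tail_d = d.slice(510, 600)
        slope_d = np.polyfit(tail_d.times, np.log(tail_d.values), 1)[0]
        assert slope_d == pytest.approx(-ngmn.k_elim, rel=5e-3)  # grid tolerance

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        k_o=st.floats(1.0, 500.0),
        decay_per_day=st.floats(0.0, 0.5),
        c0=st.floats(0.0, 3.0),
        dt=st.sampled_from([0.1, 0.25, 0.5, 1.0]),
    )
    def test_nonnegativity_and_oracle_agreement(self, k_o, decay_per_day, c0, dt):
        """Both solvers stay non-negative and agree to first order for any
        physically plausible parameter draw."""
        p = pk.load_preset("table1-verbatim")["NGMN"].with_k_o(k_o)
        p = p.with_decay_const(decay_per_day / 24.0)
        reg = pk.standard_cycle()
        grid = SimulationGrid(dt, reg.horizon)
        d = simulate_difference(p, reg, grid, c0=c0)
        a = simulate_analytic(p, reg, grid, c0=c0)
        assert np.all(d.values >= 0) and np.all(a.values >= 0)
        scale = max(1.0, np.max(a.values))
        assert np.max(np.abs(d.values - a.values)) < 0.05 * scale * dt / 0.1
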