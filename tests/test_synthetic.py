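import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.linalg import null_space

from hydratherm.constants import GAS_CONSTANT
from hydratherm.exceptions import ConfigurationError, DomainError
from hydratherm.synthetic import (
    CellConditions,
    KineticScheme,
    build_rate_matrix,
    equilibrium_ratio_from_thermo,
    simulate_atds,
    simulate_k_series,
    stationary_distribution,
)
from hydratherm.thermo import vant_hoff_k
from hydratherm.vanthoff import vant_hoff_fit


def conditions_at(temperature=298.0, water_pressure=1000.0, carrier=2000.0, **kw):
    return CellConditions(
        temperature=temperature,
        carrier_pressure=carrier,
        water_pressure=water_pressure,
        **kw,
    )


class TestEquilibriumRatio:
    def test_identity_case(self):
        # K = 1 at P = P_o when dH = dS = 0
        assert equilibrium_ratio_from_thermo(0.0, 0.0, conditions_at()) == pytest.approx(1.0)

    def test_thymine_sodium_first_water_value(self):
        # independent closed form: r = exp((61.1e3 - 298*66.1) / (R*298)) at P = P_o
        expected = math.exp((61.1e3 - 298.0 * 66.1) / (GAS_CONSTANT * 298.0))
        got = equilibrium_ratio_from_thermo(-61.1, -66.1, conditions_at())
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(math.exp(16.710), rel=1e-3)

    def test_linear_in_pressure(self):
        full = equilibrium_ratio_from_thermo(-50.0, -90.0, conditions_at(water_pressure=0.2, carrier=10.0))
        half = equilibrium_ratio_from_thermo(-50.0, -90.0, conditions_at(water_pressure=0.1, carrier=10.0))
        assert half == pytest.approx(full / 2.0, rel=1e-12)

    def test_nonphysical_temperature_rejected(self):
        with pytest.raises(DomainError):
            conditions_at(temperature=-5.0)
        with pytest.raises(DomainError):
            vant_hoff_k(-50.0, -90.0, 0.0)


class TestRateMatrix:
    def test_column_sums_vanish(self, two_step_scheme, warm_conditions):
        q = build_rate_matrix(two_step_scheme, warm_conditions)
        assert np.allclose(q.sum(axis=0), 0.0, atol=1e-15)

    def test_two_state_detailed_balance(self):
        # pick conditions so r_1 = 2 exactly, then p1/p0 must equal 2
        dh, ds, temp = -60.0, -90.0, 420.0
        k = vant_hoff_k(dh, ds, temp)
        pressure = 2.0 * 1000.0 / k
        cond = CellConditions(temperature=temp, water_pressure=pressure,
                              carrier_pressure=10 * pressure + 10)
        scheme = KineticScheme(max_n=1, forward_pseudo_rates=(0.01,),
                               true_thermo=((dh, ds),))
        p = stationary_distribution(scheme, cond)
        assert p[1] / p[0] == pytest.approx(2.0, rel=1e-12)

    def test_stationary_matches_null_space(self, two_step_scheme, warm_conditions):
        q = build_rate_matrix(two_step_scheme, warm_conditions)
        ns = null_space(q)
        assert ns.shape[1] == 1
        p_ns = ns[:, 0] / ns[:, 0].sum()
        p = stationary_distribution(two_step_scheme, warm_conditions)
        assert np.allclose(p, p_ns, rtol=1e-10, atol=1e-12)

    def test_stationary_matches_long_time_ode(self, two_step_scheme, warm_conditions):
        # brute-force oracle: integrate dp/dt = Q p far beyond the slowest
        # relaxation time and compare componentwise
        q = build_rate_matrix(two_step_scheme, warm_conditions)
        eigvals = np.linalg.eigvals(q)
        rates = sorted(abs(ev.real) for ev in eigvals if abs(ev) > 1e-12)
        t_end = 100.0 / rates[0]
        p0 = np.zeros(q.shape[0])
        p0[0] = 1.0
        sol = solve_ivp(lambda t, p: q @ p, (0.0, t_end), p0,
                        rtol=1e-12, atol=1e-14)
        p_ode = sol.y[:, -1]
        p = stationary_distribution(two_step_scheme, warm_conditions)
        assert np.allclose(p, p_ode, atol=1e-9)

    @given(
        dh=st.floats(min_value=-80.0, max_value=-30.0),
        ds=st.floats(min_value=-120.0, max_value=-60.0),
        temp=st.floats(min_value=300.0, max_value=550.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_detailed_balance_property(self, dh, ds, temp):
        cond = CellConditions(temperature=temp, water_pressure=0.1)
        scheme = KineticScheme(max_n=2, forward_pseudo_rates=(0.02, 0.02),
                               true_thermo=((dh, ds), (dh + 3.0, ds)))
        p = stationary_distribution(scheme, cond)
        for step, (h, s) in enumerate(scheme.true_thermo, start=1):
            r = equilibrium_ratio_from_thermo(h, s, cond)
            assert p[step] / p[step - 1] == pytest.approx(r, rel=1e-10)

    def test_nonfinite_ratio_rejected(self, warm_conditions):
        scheme = KineticScheme(max_n=1, forward_pseudo_rates=(0.01,),
                               true_thermo=((1e6, 0.0),))  # underflows to r = 0
        with pytest.raises(ConfigurationError):
            build_rate_matrix(scheme, warm_conditions)


class TestSimulateATDs:
    def test_deterministic_for_fixed_seed(self, two_step_scheme, warm_conditions):
        a = simulate_atds(two_step_scheme, warm_conditions, seed=7)
        b = simulate_atds(two_step_scheme, warm_conditions, seed=7)
        for x, y in zip(a.atds, b.atds):
            assert np.array_equal(x.counts, y.counts)
        c = simulate_atds(two_step_scheme, warm_conditions, seed=8)
        assert any(
            not np.array_equal(x.counts, y.counts) for x, y in zip(a.atds, c.atds)
        )

    def test_expected_counts_linear_in_n_pulses(self, two_step_scheme):
        base = CellConditions(temperature=400.0, n_pulses=1000)
        double = CellConditions(temperature=400.0, n_pulses=2000)
        a = simulate_atds(two_step_scheme, base, seed=0, poisson=False)
        b = simulate_atds(two_step_scheme, double, seed=0, poisson=False)
        for x, y in zip(a.atds, b.atds):
            assert np.allclose(y.counts, 2.0 * x.counts, rtol=1e-12)

    def test_channel_summed_ratio_near_stationary(self, two_step_scheme, warm_conditions):
        # relaxation time << drift time, so the closed-form stationary ratio
        # is the oracle for the channel-summed count ratio
        p = stationary_distribution(two_step_scheme, warm_conditions)
        data = simulate_atds(two_step_scheme, warm_conditions, seed=42)
        totals = [atd.total_counts for atd in data.atds]
        for n in (1, 2):
            r_true = p[n] / p[n - 1]
            r_obs = totals[n] / totals[n - 1]
            se = r_obs * math.sqrt(1.0 / totals[n] + 1.0 / totals[n - 1])
            assert abs(r_obs - r_true) <= 3.0 * se

    def test_poisson_fidelity_one_channel(self, two_step_scheme, warm_conditions):
        # mean/variance ratio of a single channel over replicates stays near 1
        channel = int(warm_conditions.drift_time_mean)
        draws = [
            simulate_atds(two_step_scheme, warm_conditions, seed=s).atds[0].counts[channel]
            for s in range(250)
        ]
        draws = np.asarray(draws)
        ratio = draws.var(ddof=1) / draws.mean()
        assert 0.8 <= ratio <= 1.2

    def test_atds_carry_conditions(self, two_step_scheme, warm_conditions):
        data = simulate_atds(two_step_scheme, warm_conditions, seed=3)
        for atd in data.atds:
            assert atd.temperature == warm_conditions.temperature
            assert atd.water_pressure == warm_conditions.water_pressure
        assert data.seed == 3


class TestSimulateKSeries:
    def test_noiseless_is_exactly_linear(self):
        temps = np.linspace(350.0, 550.0, 8)
        series = simulate_k_series(-61.1, -66.1, temps, 0.0, seed=0)
        t, k, s = series.arrays()
        x, y = 1.0 / t, np.log(k)
        slope = (y[-1] - y[0]) / (x[-1] - x[0])
        assert np.allclose(y, y[0] + slope * (x - x[0]), rtol=1e-12)
        assert np.all(s == 0.0)

    def test_bulk_sodium_closed_form_value(self):
        # dG(298) = -52.7 + 298*0.1004 = -22.7808 kJ/mol for this step
        series = simulate_k_series(-52.7, -100.4, [298.0], 0.0, seed=0)
        _, k, _ = series.arrays()
        expected = math.exp(22.7808e3 / (GAS_CONSTANT * 298.0))
        assert k[0] == pytest.approx(expected, rel=1e-9)

    def test_seed_contract(self):
        temps = [350.0, 400.0, 450.0]
        a = simulate_k_series(-60.0, -90.0, temps, 0.05, seed=1)
        b = simulate_k_series(-60.0, -90.0, temps, 0.05, seed=1)
        c = simulate_k_series(-60.0, -90.0, temps, 0.05, seed=2)
        assert a.points == b.points
        assert a.points != c.points

    def test_zero_noise_roundtrip_through_fit(self):
        # end-to-end recovery invariant at machine precision
        temps = np.linspace(340.0, 560.0, 9)
        series = simulate_k_series(-57.7, -69.0, temps, 0.0, seed=0)
        result = vant_hoff_fit(series)
        assert result.dH == pytest.approx(-57.7, rel=1e-9)
        assert result.dS == pytest.approx(-69.0, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(DomainError):
            simulate_k_series(-60.0, -90.0, [300.0, -10.0], 0.0, seed=0)
        with pytest.raises(DomainError):
            simulate_k_series(-60.0, -90.0, [300.0], -0.1, seed=0)
        with pytest.raises(DomainError):
            simulate_k_series(-60.0, -90.0, [], 0.0, seed=0)
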