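"""Device core: tunneling law, closed-form usage, discrete decay, energy."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

from fnsynapse.device import (
    SynapseState,
    apply_input_pulse,
    apply_pulse,
    decay_alpha,
    decay_rate_r,
    junction_pulse,
    optimal_flow,
    tunneling_slew,
    wc_closed_form,
    write_energy,
)
from fnsynapse.params import DeviceParams


class TestTunnelingSlew:
    def test_vanishes_at_low_potential(self, params):
        assert tunneling_slew(0.05, params) < 1e-300

    def test_algebraic_value_at_w_equals_k2(self, params):
        expected = params.k1 * params.k2 / math.e
        assert tunneling_slew(params.k2, params) == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing(self, params):
        w = np.linspace(1.0, 12.0, 400)
        assert np.all(np.diff(tunneling_slew(w, params)) > 0)

    def test_rejects_nonpositive_potential(self, params):
        with pytest.raises(ValueError):
            tunneling_slew(0.0, params)

    def test_matches_derivative_of_closed_form(self, params):
        """-J(Wc(t)) equals dWc/dt: the slew is the closed form's generator."""
        for t in (1.0, 1e2, 1e4, 1e6):
            h = t * 1e-4
            num = (wc_closed_form(t + h, params) - wc_closed_form(t - h, params)) / (2 * h)
            ana = -tunneling_slew(wc_closed_form(t, params), params)
            assert ana == pytest.approx(num, rel=1e-6)


class TestWcClosedForm:
    def test_initial_condition(self, params):
        assert wc_closed_form(0.0, params) == pytest.approx(params.Wc0, rel=1e-12)

    def test_monotone_decreasing(self, params):
        t = np.logspace(-2, 8, 200)
        assert np.all(np.diff(wc_closed_form(t, params)) < 0)

    def test_rejects_negative_time(self, params):
        with pytest.raises(ValueError):
            wc_closed_form(-1.0, params)

    def test_agrees_with_ode_integration(self, params):
        """RK integration of dWc/dt = -J(Wc) reproduces the closed form."""
        sol = solve_ivp(
            lambda t, w: -tunneling_slew(w[0], params),
            (0.0, 1e4),
            [params.Wc0],
            rtol=1e-11,
            atol=1e-12,
            dense_output=True,
        )
        t_eval = np.logspace(0, 4, 40)
        err = np.abs(sol.sol(t_eval)[0] - wc_closed_form(t_eval, params))
        assert err.max() < 1e-6


class TestDecayAlpha:
    def test_bounded_and_increasing(self, params):
        n = np.arange(1, 10_001)
        a = decay_alpha(n, params)
        assert np.all((a > 0) & (a < 1))
        assert np.all(np.diff(a) > 0)

    def test_rejects_n_below_one(self, params):
        with pytest.raises(ValueError):
            decay_alpha(0, params)

    def test_short_pulse_limit_is_unity(self, params):
        """gamma -> infinity (dt -> 0): no decay per update."""
        p = params.replace(dt_pulse=1e-9)
        assert decay_alpha(1, p) > 1 - 1e-8
        assert decay_alpha(10_000, p) > 1 - 1e-8

    def test_asymptotic_decay_scale(self, params):
        """(1 - alpha(n)) * (n + gamma) -> 1 + 2/ln(k1 dt n + k0) ~ 1."""
        n = 10_000_000
        lhs = (1 - decay_alpha(n, params)) * (n + params.gamma())
        expected = 1 + 2 / math.log(params.k1 * params.dt_pulse * n + params.k0)
        assert lhs == pytest.approx(expected, rel=1e-9)
        assert lhs == pytest.approx(1.0, abs=0.06)


class TestApplyPulse:
    def test_zero_input_keeps_zero_weight_and_ages_usage(self, params):
        s = SynapseState.fresh(params)
        wcs = [s.wc]
        for _ in range(10):
            s = apply_pulse(s, 0.0, 0.0, params)
            wcs.append(s.wc)
        assert s.wd == 0.0
        assert np.all(np.diff(wcs) < 0)
        assert s.n_updates == 10

    def test_usage_decreases_for_either_polarity(self, params):
        for sign in (+1.0, -1.0):
            s = SynapseState.fresh(params)
            wc_prev = s.wc
            for _ in range(50):
                s = apply_input_pulse(s, sign * 1.15, params)
                assert s.wc < wc_prev
                wc_prev = s.wc

    def test_short_width_limit_is_pure_random_walk(self, params, rng):
        """alpha == 1 degenerates the recursion to a running sum."""
        steps = rng.choice([-1.0, 1.0], size=200) * 1e-3
        s = SynapseState.fresh(params)
        for x in steps:
            s = apply_pulse(s, x, 0.0, params, width=1e-12)
        assert s.wd == pytest.approx(np.sum(steps), rel=1e-9)

    def test_recursion_matches_unrolled_weighted_sum(self, params, rng):
        """n pulses from empty state equal the closed weighted sum over inputs."""
        n = 500
        vin = rng.choice([-1.0, 1.0], size=n + 1)  # vin[1..n]
        vin[0] = 0.0
        s = SynapseState.fresh(params)
        for k in range(1, n + 1):
            s = apply_pulse(s, vin[k] - vin[k - 1], 0.0, params)
        a = np.concatenate([[np.nan], decay_alpha(np.arange(1, n + 1), params)])
        # suffix products prod_{j=i+2}^{n} alpha(j)
        total = vin[n] + (a[n] - 1) * vin[n - 1]
        suffix = 1.0
        for i in range(n - 2, 0, -1):
            suffix *= a[i + 2]
            total += (a[i + 1] - 1) * suffix * vin[i]
        assert s.wd == pytest.approx(total, abs=1e-12)

    def test_metaplasticity_under_repeated_potentiation(self, params):
        """100 identical pulses: write size strictly shrinks with usage."""
        s = SynapseState.fresh(params)
        deltas = []
        for _ in range(100):
            prev = s.wd
            s = apply_input_pulse(s, 1.15, params)
            deltas.append(abs(s.wd - prev))
        assert np.all(np.diff(deltas) < 0)

    def test_junction_pulse_write_grows_exponentially_with_magnitude(self, params):
        mags = np.linspace(2.0, 6.0, 9)
        dwd = np.array(
            [abs(junction_pulse(SynapseState.fresh(params), m, params, width=0.1)[0].wd)
             for m in mags]
        )
        # log of the dominant-junction drop should be close to linear in x
        assert np.all(np.diff(dwd) > 0)
        slope = np.diff(np.log(dwd))
        assert slope.std() / slope.mean() < 0.25


class TestDecayRate:
    def test_exponential_trajectory_gives_constant_rate(self):
        a = 0.37
        t = np.linspace(1.0, 10.0, 400)
        ti, r = decay_rate_r(t, np.exp(-a * t))
        assert np.allclose(r, a, rtol=1e-4)

    def test_fn_trajectory_has_optimal_one_over_t_rate(self, params):
        """t * r(t) -> 1 at large usage: the optimality criterion."""
        t = np.logspace(2, 7, 3000)
        ti, r = decay_rate_r(t, wc_closed_form(t, params))
        mask = ti >= 100 * params.k0 / params.k1
        assert np.abs(ti[mask] * r[mask] - 1).max() < 0.05

    def test_matches_symbolic_rate_for_inverse_log_family(self):
        """Wc = beta/log t  =>  r = (1/t) (1 + 2/log t) exactly."""
        beta = 5.0
        t = np.logspace(1, 6, 4000)
        ti, r = decay_rate_r(t, beta / np.log(t))
        expected = (1 + 2 / np.log(ti)) / ti
        assert np.max(np.abs(r / expected - 1)) < 1e-4

    def test_input_validation(self):
        with pytest.raises(ValueError):
            decay_rate_r(np.arange(4.0), np.arange(4.0))
        with pytest.warns(RuntimeWarning):
            decay_rate_r(np.arange(9.0) + 1, np.sin(np.arange(9.0)))


class TestOptimalFlow:
    def test_substitution(self):
        assert optimal_flow(1.0, 1.0) == pytest.approx(math.exp(-1))

    def test_same_functional_form_as_tunneling(self):
        beta = 3.0
        p = DeviceParams(k1=1.0, k2=beta, k0=math.exp(beta), Wc0=1.0)
        w = np.linspace(0.5, 5.0, 50)
        assert np.allclose(optimal_flow(w, beta), tunneling_slew(w, p), rtol=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            optimal_flow(-1.0, 1.0)
        with pytest.raises(ValueError):
            optimal_flow(1.0, 0.0)

    def test_ode_trajectory_recovers_beta_by_fit(self):
        """Integrating the flow gives Wc = beta/log(t + c); fitted beta ~ input."""
        beta = 4.0
        w0 = 1.0
        sol = solve_ivp(
            lambda t, w: -optimal_flow(w[0], beta),
            (0.0, 5e4),
            [w0],
            rtol=1e-10,
            atol=1e-12,
            dense_output=True,
        )
        t = np.logspace(2, np.log10(5e4), 60)
        w = sol.sol(t)[0]
        popt, _ = curve_fit(lambda t, b, c: b / np.log(t + c), t, w, p0=(1.0, 10.0))
        assert popt[0] == pytest.approx(beta, rel=0.01)


class TestWriteEnergy:
    def test_fabricated_device_operating_point(self):
        # 200 fF coupling cap, 2 V input change -> 400 fJ per capacitor
        assert write_energy(200e-15, 2.0) == pytest.approx(400e-15, rel=1e-12)

    def test_differential_pulse_doubles(self):
        # 4 V differential pulse = +/-2 V on two 200 fF caps -> 800 fJ total
        assert 2 * write_energy(200e-15, 4.0 / 2) == pytest.approx(800e-15, rel=1e-12)

    def test_zero_input(self):
        assert write_energy(200e-15, 0.0) == 0.0

    def test_rejects_nonpositive_capacitance(self):
        with pytest.raises(ValueError):
            write_energy(0.0, 1.0)


class TestStateSerialization:
    def test_json_roundtrip_scalar_and_array(self, params, tmp_path):
        s = SynapseState.fresh(params)
        s = apply_input_pulse(s, 1.15, params)
        text = s.to_json()
        back = SynapseState.from_json(text)
        assert back.w_plus == s.w_plus and back.w_minus == s.w_minus
        assert back.n_updates == s.n_updates

        arr = SynapseState.fresh(params, shape=(3,))
        arr = apply_input_pulse(arr, np.array([1.0, -1.0, 0.5]), params)
        path = tmp_path / "state.json"
        arr.to_json(path)
        back = SynapseState.from_json(path)
        np.testing.assert_array_equal(back.w_plus, arr.w_plus)
        np.testing.assert_array_equal(back.w_minus, arr.w_minus)
        # full precision: the payload must carry exact float round-trips
        assert json.loads(path.read_text())["w_plus"][0] == arr.w_plus[0]


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    v=st.floats(min_value=-4.0, max_value=4.0, allow_nan=False),
    n_pulses=st.integers(min_value=1, max_value=30),
)
def test_weight_stays_bounded_and_usage_monotone(v, n_pulses):
    """Input pulses can never drive |Wd| beyond the pulse amplitude, and
    usage decreases by exactly one pulse of closed-form decay per update."""
    p = DeviceParams()
    s = SynapseState.fresh(p)
    for _ in range(n_pulses):
        s = apply_input_pulse(s, v, p)
    assert abs(s.wd) <= abs(v) + 1e-12
    assert s.wc == pytest.approx(wc_closed_form(n_pulses * p.dt_pulse, p), rel=1e-12)
    assert s.n_updates == n_pulses
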