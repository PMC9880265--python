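"""Single-electron Poisson model: rates, bookkeeping, concentration."""

import numpy as np
import pytest

from fnsynapse.device import SynapseState, junction_pulse
from fnsynapse.params import DeviceParams, preset
from fnsynapse.stochastic import (
    compare_to_deterministic,
    expected_electrons,
    run_pulse_train,
    stochastic_step,
)


class TestExpectedElectrons:
    def test_rate_times_quantum_recovers_deterministic_drop(self, params):
        s = SynapseState(w_plus=7.8, w_minus=7.6)
        lam_p, lam_m = expected_electrons(s, params, x_pulse=4.0)
        _, drop_p, drop_m = junction_pulse(s, 4.0, params)
        q_over_ct = params.q / params.CT
        assert lam_p * q_over_ct == pytest.approx(drop_p, abs=1e-12)
        assert lam_m * q_over_ct == pytest.approx(drop_m, abs=1e-12)

    def test_voltage_quantum_is_tenth_of_microvolt(self, params):
        # CT = 1.6 pF: one electron moves the node by q/CT = 0.1 uV
        assert params.q / params.CT == pytest.approx(1.0014e-7, rel=1e-3)

    def test_millivolt_drop_is_ten_thousand_electrons(self, params):
        # lambda = CT * dW / q: 1 mV at 1.6 pF -> ~1e4 electrons
        lam = params.CT * 1e-3 / params.q
        assert lam == pytest.approx(1e4, rel=2e-3)

    def test_subthreshold_nodes_have_negligible_rate(self, params):
        s = SynapseState(w_plus=4.0, w_minus=4.0)
        lam_p, lam_m = expected_electrons(s, params, x_pulse=1.0)
        assert lam_p < 1e-6 and lam_m < 1e-6


class TestStochasticStep:
    def test_zero_rate_leaves_potentials_unchanged(self, params):
        s = SynapseState(w_plus=4.0, w_minus=4.0)
        new, rec = stochastic_step(s, 1.0, 123, params)
        assert rec.e_plus == 0 and rec.e_minus == 0
        assert new.w_plus == s.w_plus and new.w_minus == s.w_minus

    def test_single_electron_moves_weight_tenth_microvolt(self, params):
        s = SynapseState(w_plus=7.0, w_minus=7.0)
        quantum = params.q / params.CT
        # one electron on one junction shifts Wd by half a quantum
        new = SynapseState(w_plus=s.w_plus - quantum, w_minus=s.w_minus)
        assert abs(new.wd - s.wd) == pytest.approx(quantum / 2, rel=1e-9)
        assert quantum == pytest.approx(1e-7, rel=2e-3)

    def test_seeded_reproducibility(self, params):
        s = SynapseState(w_plus=7.9, w_minus=7.9)
        a = stochastic_step(s, 4.0, 77, params)[1]
        b = stochastic_step(s, 4.0, 77, params)[1]
        assert a.e_plus == b.e_plus and a.e_minus == b.e_minus

    def test_mean_of_many_steps_matches_deterministic(self, params, rng):
        """Law of large numbers: 1e4 one-pulse outcomes average to the
        deterministic update within 3 standard errors."""
        n = 10_000
        s = SynapseState(
            w_plus=np.full(n, 8.0), w_minus=np.full(n, 8.0),
            n_updates=np.zeros(n, dtype=np.int64),
        )
        new, rec = stochastic_step(s, 4.0, rng, params)
        det, drop_p, drop_m = junction_pulse(
            SynapseState(w_plus=8.0, w_minus=8.0), 4.0, params
        )
        dwd_det = float(det.wd)
        dwd_mc = new.wd  # array of per-run realized updates
        se = dwd_mc.std(ddof=1) / np.sqrt(n)
        assert abs(dwd_mc.mean() - dwd_det) < 3 * se

    def test_charge_bookkeeping_is_exact(self, params):
        """Cumulative sampled charge equals CT * total potential loss."""
        s0 = SynapseState(w_plus=7.9, w_minus=7.9)
        s = s0
        rng = np.random.default_rng(5)
        tot_p = tot_m = 0
        for k in range(50):
            s, rec = stochastic_step(s, 4.0 * (-1) ** k, rng, params)
            tot_p += rec.e_plus
            tot_m += rec.e_minus
        # exact up to float accumulation of the potentials (~1e-27 C here)
        assert params.q * tot_p == pytest.approx(params.CT * (s0.w_plus - s.w_plus), rel=1e-9)
        assert params.q * tot_m == pytest.approx(params.CT * (s0.w_minus - s.w_minus), rel=1e-9)


class TestDeterministicAgreement:
    def test_larger_capacitance_concentrates_the_trajectory(self):
        """Scaling CT up shrinks the electron quantum: Poisson concentration."""
        base = DeviceParams()
        big = base.replace(Cfg=base.Cfg * 100)  # CT ~ x100, quantum /100
        dev_base = np.median([compare_to_deterministic(50, base, s, wc_init=7.5) for s in range(5)])
        dev_big = np.median([compare_to_deterministic(50, big, s, wc_init=7.5) for s in range(5)])
        assert dev_big < dev_base / 3

    def test_ensemble_mean_converges_like_inverse_sqrt_runs(self, params):
        """Error of the run-averaged trajectory falls ~ 1/sqrt(runs)."""
        n_pulses = 20
        rng = np.random.default_rng(9)
        signs = rng.choice([-1.0, 1.0], size=n_pulses)
        det, _ = run_pulse_train(n_pulses, params, 0, 4.0, 7.8, stochastic=False, signs=signs)
        errs = []
        for runs in (100, 1000, 10_000):
            s = SynapseState(
                w_plus=np.full(runs, 7.8), w_minus=np.full(runs, 7.8),
                n_updates=np.zeros(runs, dtype=np.int64),
            )
            r = np.random.default_rng(11)
            traj = [0.0]
            for k in range(n_pulses):
                s, _ = stochastic_step(s, 4.0 * signs[k], r, params)
                traj.append(float(s.wd.mean()))
            errs.append(np.max(np.abs(np.asarray(traj) - det)))
        ratio = errs[0] / errs[2]  # expect ~ sqrt(100) = 10
        assert 3 < ratio < 35

    def test_high_regime_deviation_is_small(self, params):
        devs = [compare_to_deterministic(100, params, s, wc_init=7.0) for s in range(5)]
        assert max(devs) < 200e-6


class TestLowRegimeConsolidation:
    def test_few_electron_updates_keep_power_law_but_lower_snr(self, params):
        """With only a few electrons per update the SNR curve drops below the
        continuous model's sqrt(N/n) but keeps the ~ n^-1/2 falloff."""
        N, n_pat, runs = 100, 40, 400
        wc_init = 7.0  # a handful of electrons per pulse at 4 V drive
        rng = np.random.default_rng(42)
        shape = (runs, N)
        s = SynapseState(
            w_plus=np.full(shape, wc_init), w_minus=np.full(shape, wc_init),
            n_updates=np.zeros(shape, dtype=np.int64),
        )
        lam_probe = expected_electrons(
            SynapseState(w_plus=wc_init, w_minus=wc_init), params, 4.0
        )
        assert max(float(lam_probe[0]), float(lam_probe[1])) < 10

        V = rng.choice(np.array([-1.0, 1.0]), size=(runs, N, n_pat))
        q1 = np.empty((n_pat, runs))
        for k in range(n_pat):
            s, _ = stochastic_step(s, 4.0 * V[:, :, k], rng, params)
            q1[k] = (s.wd * V[:, :, 0]).mean(axis=1)
        s_mc = q1.mean(axis=1)
        var = q1.var(axis=1, ddof=1)
        snr = np.abs(s_mc) / np.sqrt(var + s_mc**2 / N)
        ns = np.arange(1, n_pat + 1)
        mask = ns >= 5
        analytic = np.sqrt(N / ns[mask])
        # shifted down on average ...
        assert np.mean(snr[mask] / analytic) < 0.95
        # ... but still a power law of slope ~ -1/2
        slope = np.polyfit(np.log(ns[mask]), np.log(snr[mask]), 1)[0]
        assert -0.8 < slope < -0.25
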