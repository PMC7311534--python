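"""Forward model and SPGR signal conversion."""

import numpy as np
import pytest
from scipy.signal import lfilter

from liverperf import (
    AcquisitionParams,
    InputFunctions,
    PerfusionParams,
    RateConstants,
    concentration_from_signal,
    forward_model,
    params_to_rates,
    rates_to_params,
    spgr_signal,
)
from liverperf.model import check_times, exp_conv


def euler_reference(params, inputs, dt=1e-3):
    """Independent forward-Euler integration of the compartment ODE at 1 ms."""
    r = params_to_rates(params)
    t = inputs.times
    ca, cp = inputs.plasma()
    fine = np.arange(0.0, t[-1] + dt / 2, dt)
    u = r.k1a * np.interp(fine, t, ca) + r.k1p * np.interp(fine, t, cp)
    # C_{n+1} = C_n (1 - k2 dt) + dt u_n, as a first-order IIR recursion
    c = lfilter([dt], [1.0, -(1.0 - r.k2 * dt)], u)
    c = np.concatenate([[0.0], c[:-1]])
    return c[np.round(t / dt).astype(int)]


class TestParameterConversion:
    @pytest.mark.parametrize(
        "params, rates",
        [
            ((0.30, 0.30, 30.0), (0.003, 0.007, 1.0 / 30.0)),
            ((0.0, 0.5, 10.0), (0.0, 0.05, 0.1)),
        ],
    )
    def test_known_values(self, params, rates):
        r = params_to_rates(PerfusionParams(*params))
        assert (r.k1a, r.k1p, r.k2) == pytest.approx(rates)

    def test_pure_arterial_supply_has_no_portal_rate(self):
        assert params_to_rates(PerfusionParams(1.0, 0.4, 20.0)).k1p == 0.0

    def test_round_trip(self, rng):
        for _ in range(20):
            p = PerfusionParams(rng.uniform(0, 1), rng.uniform(0.01, 1), rng.uniform(0.1, 100))
            q = rates_to_params(params_to_rates(p))
            assert q.as_array() == pytest.approx(p.as_array(), rel=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            params_to_rates(PerfusionParams(0.3, 0.3, 0.0))
        with pytest.raises(ValueError):
            params_to_rates(PerfusionParams(1.2, 0.3, 10.0))
        with pytest.raises(ValueError):
            rates_to_params(RateConstants(0.0, 0.0, 0.1))


class TestForwardModel:
    def test_zero_inputs_give_zero_curve(self, times):
        silent = InputFunctions(times=times, aif=np.zeros_like(times), pvif=np.zeros_like(times))
        c = forward_model(PerfusionParams(0.3, 0.3, 30.0), silent)
        assert np.all(c == 0.0)

    def test_constant_arterial_input_matches_step_response(self):
        # C_A = c for t >= 0, C_P = 0: C_L(t) = k1A c (1 - exp(-k2 t)) / k2
        t = np.arange(0.0, 200.0, 2.0)
        const = InputFunctions(times=t, aif=np.full(t.size, 2.0), pvif=np.zeros(t.size),
                               hematocrit=0.0)
        p = PerfusionParams(1.0, 0.4, 25.0)
        r = params_to_rates(p)
        expected = r.k1a * 2.0 * (1.0 - np.exp(-r.k2 * t)) / r.k2
        assert forward_model(p, const) == pytest.approx(expected, abs=1e-12)

    def test_equilibrium_approaches_dv_times_input(self):
        t = np.arange(0.0, 3000.0, 3.0)
        const = InputFunctions(times=t, aif=np.full(t.size, 1.5), pvif=np.full(t.size, 1.5),
                               hematocrit=0.0)
        p = PerfusionParams(0.4, 0.55, 12.0)
        c = forward_model(p, const)
        assert c[-1] == pytest.approx(p.dv * 1.5, rel=1e-10)

    def test_matches_forward_euler_oracle(self, inputs, rng):
        for _ in range(20):
            p = PerfusionParams(rng.uniform(0, 1), rng.uniform(0.05, 1), rng.uniform(1, 100))
            analytic = forward_model(p, inputs)
            reference = euler_reference(p, inputs)
            scale = np.abs(reference).max()
            assert np.abs(analytic - reference).max() / scale < 1e-4

    def test_linearity_in_dv(self, inputs):
        base = forward_model(PerfusionParams(0.3, 0.2, 30.0), inputs)
        scaled = forward_model(PerfusionParams(0.3, 0.6, 30.0), inputs)
        assert scaled == pytest.approx(3.0 * base, rel=1e-12)

    def test_superposition_of_inputs(self, inputs, times):
        p = PerfusionParams(0.4, 0.5, 20.0)
        zeros = np.zeros_like(times)
        art_only = InputFunctions(times=times, aif=inputs.aif, pvif=zeros,
                                  hematocrit=inputs.hematocrit)
        port_only = InputFunctions(times=times, aif=zeros, pvif=inputs.pvif,
                                   hematocrit=inputs.hematocrit)
        total = forward_model(p, inputs)
        assert total == pytest.approx(
            forward_model(p, art_only) + forward_model(p, port_only), rel=1e-12
        )

    def test_exp_conv_vectorizes_over_rates(self, inputs, times):
        k2s = np.array([0.01, 0.1, 1.0])
        batch = exp_conv(times, inputs.aif, k2s)
        for i, k2 in enumerate(k2s):
            assert batch[i] == pytest.approx(exp_conv(times, inputs.aif, k2))

    def test_time_grid_validation(self):
        with pytest.raises(ValueError):
            check_times(np.array([0.0, 2.0, 1.0]))
        with pytest.raises(ValueError):
            check_times(np.array([5.0]))


class TestSpgrSignal:
    def test_baseline_matches_closed_form(self, acq):
        a = np.deg2rad(acq.flip_deg)
        e0 = np.exp(-acq.tr_ms / acq.t10_ms)
        expected = 1000.0 * np.sin(a) * (1 - e0) / (1 - np.cos(a) * e0)
        assert spgr_signal(np.zeros(5), acq, m0=1000.0) == pytest.approx(expected)

    def test_signal_increases_with_concentration(self, acq, rng):
        c1 = np.sort(rng.uniform(0, 5, 50))
        s = spgr_signal(c1, acq)
        assert np.all(np.diff(s) > 0)

    def test_round_trip_recovers_concentration(self, acq, inputs):
        conc = forward_model(PerfusionParams(0.3, 0.3, 30.0), inputs)
        sig = spgr_signal(conc, acq, m0=512.0)
        back, valid = concentration_from_signal(sig, acq)
        assert valid.all()
        assert back == pytest.approx(conc, abs=1e-10)

    def test_baseline_only_signal_maps_to_zero_concentration(self, acq):
        sig = spgr_signal(np.zeros(20), acq, m0=100.0)
        conc, valid = concentration_from_signal(sig, acq)
        assert valid.all()
        assert conc == pytest.approx(np.zeros(20), abs=1e-10)

    def test_saturated_frames_are_flagged(self, acq):
        sig = spgr_signal(np.zeros(20), acq, m0=100.0)
        sig[10] = 100.0 * np.sin(np.deg2rad(acq.flip_deg)) * 1.5  # beyond the asymptote
        conc, valid = concentration_from_signal(sig, acq)
        assert not valid[10] and np.isnan(conc[10])
        assert valid[[i for i in range(20) if i != 10]].all()

    def test_zero_baseline_rejected(self, acq):
        with pytest.raises(ValueError):
            concentration_from_signal(np.zeros(20), acq)

    def test_acquisition_validation(self):
        with pytest.raises(ValueError):
            AcquisitionParams(flip_deg=95.0).validate()
        with pytest.raises(ValueError):
            AcquisitionParams(tr_ms=-1.0).validate()
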