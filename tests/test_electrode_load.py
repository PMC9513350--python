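"""Electrode-electrolyte RC interface: impedance, compliance clamping,
inrush suppression and shorting to reference."""

import math

import numpy as np
import pytest

from icmsim.current_generator import CurrentWaveform, GeneratorSettings, PulseSpec, synthesize_pulse
from icmsim.electrode_load import (
    InterfaceModel,
    bench_load,
    fit_parallel_resistance,
    impedance_magnitude,
    inrush_peak,
    short_to_reference,
    simulate_drive,
)

MODEL = InterfaceModel(r_series_ohm=1e3, r_parallel_ohm=30e3, c_parallel_f=2e-9)


def rectangle(i_uA: float, dur_us: float, dt_us: float = 0.1) -> CurrentWaveform:
    n = int(round(dur_us / dt_us))
    return CurrentWaveform(np.arange(n + 1) * dt_us, np.r_[np.full(n, i_uA), 0.0])


class TestImpedance:
    def test_dc_limit_is_series_plus_parallel(self):
        assert impedance_magnitude(MODEL, 0.0) == pytest.approx(31e3)

    def test_high_frequency_limit_is_series_resistance(self):
        assert impedance_magnitude(MODEL, 1e12) == pytest.approx(1e3, rel=1e-6)

    def test_negligible_capacitance_gives_resistive_divider(self):
        m = InterfaceModel(1e3, 30e3, 1e-18)
        for f in (0, 1e3, 1e6):
            assert impedance_magnitude(m, f) == pytest.approx(31e3)

    def test_monotone_nonincreasing_in_frequency(self):
        freqs = np.logspace(0, 7, 50)
        z = [impedance_magnitude(MODEL, f) for f in freqs]
        assert all(a >= b - 1e-9 for a, b in zip(z, z[1:]))

    @pytest.mark.parametrize("name,z_target", [("metal_33k7", 33.7e3), ("small_tip_325k", 325e3)])
    def test_bench_fixtures_reproduce_their_1kHz_impedance(self, name, z_target):
        model = bench_load(name)
        assert model.r_series_ohm == 1e3
        assert impedance_magnitude(model, 1000.0) == pytest.approx(z_target, rel=1e-9)

    def test_fit_recovers_target_impedance(self):
        m = fit_parallel_resistance(50e3, c_parallel_f=1e-9)
        assert impedance_magnitude(m, 1000.0) == pytest.approx(50e3, rel=1e-9)

    def test_fit_rejects_unreachable_target(self):
        with pytest.raises(ValueError, match="unreachable"):
            fit_parallel_resistance(33.7e3, c_parallel_f=10e-9)


class TestSimulateDrive:
    def test_small_current_matches_command_and_steady_state(self):
        # 10 uA into 31 kOhm -> 0.31 V steady state, far from the 2.42 V limit
        wf = rectangle(10.0, 2000.0)
        res = simulate_drive(MODEL, wf)
        assert np.array_equal(res.actual_uA, res.commanded_uA)
        assert res.clamped_intervals_us == ()
        assert res.terminal_voltage_V[-2] == pytest.approx(10e-6 * 31e3, rel=1e-3)

    def test_unclamped_matches_closed_form_rc_response(self):
        # dVc/dt = (I - Vc/Rp)/Cp with constant I:
        # Vout(t) = I*Rs + I*Rp*(1 - exp(-t/RpCp))
        tau_us = MODEL.tau_source_s * 1e6  # 60 us
        wf = rectangle(10.0, 300.0, dt_us=tau_us / 100)
        res = simulate_drive(MODEL, wf)
        t_s = res.sample_times_us[:-1] * 1e-6
        i = 10e-6
        v_exact = i * 1e3 + i * 30e3 * (1 - np.exp(-t_s / MODEL.tau_source_s))
        err = np.abs(res.terminal_voltage_V[:-1] - v_exact) / np.abs(v_exact).max()
        assert err.max() < 1e-3

    def test_charge_conservation_against_analytic_rc(self):
        # delivered charge = stored capacitor charge + charge through Rp
        tau_us = MODEL.tau_source_s * 1e6
        wf = rectangle(10.0, 300.0, dt_us=tau_us / 100)
        res = simulate_drive(MODEL, wf)
        dt_s = tau_us / 100 * 1e-6
        q_in = np.sum(res.actual_uA[:-1] * 1e-6) * dt_s
        vc = res.capacitor_voltage_V
        q_cap = MODEL.c_parallel_f * vc[-1]
        q_rp = np.trapezoid(vc, dx=dt_s) / MODEL.r_parallel_ohm
        assert q_in == pytest.approx(q_cap + q_rp, rel=1e-3)

    def test_clamp_signature_on_high_impedance_load(self):
        # ~80 uA command into the small-tip load: current holds at command,
        # then the terminal hits -2.42 V and the current decays monotonically
        load = bench_load("small_tip_325k")
        wf = synthesize_pulse(PulseSpec(80, 80, 200, 200), GeneratorSettings())
        res = simulate_drive(load, wf)
        assert res.clamped_intervals_us  # the limit is reached
        assert res.actual_uA[0] == pytest.approx(-79.6875)
        t0, t1 = res.clamped_intervals_us[0]
        sel = (res.sample_times_us >= t0) & (res.sample_times_us < t1)
        i_clamped = res.actual_uA[sel]
        assert np.all(np.diff(np.abs(i_clamped)) <= 1e-12)
        assert np.all(np.abs(i_clamped) <= np.abs(res.actual_uA[0]) + 1e-9)

    def test_clamped_current_matches_closed_form_decay(self):
        # while clamped: I(t) = (Vclamp - Vc(t))/Rs with Vc relaxing toward
        # Vclamp*Rp/(Rs+Rp) at tau = (Rs||Rp)*Cp
        load = bench_load("small_tip_325k")
        wf = rectangle(-80.0, 200.0)
        res = simulate_drive(load, wf)
        t0, t1 = res.clamped_intervals_us[0]
        sel = np.nonzero((res.sample_times_us >= t0) & (res.sample_times_us < t1))[0]
        k0 = sel[0]
        vc0 = res.capacitor_voltage_V[k0]
        vclamp = -load.v_limit_v
        rs, rp = load.r_series_ohm, load.r_parallel_ohm
        vc_inf = vclamp * rp / (rs + rp)
        t_rel = (res.sample_times_us[sel] - res.sample_times_us[k0]) * 1e-6
        vc_exact = vc_inf + (vc0 - vc_inf) * np.exp(-t_rel / load.tau_clamp_s)
        i_exact = (vclamp - vc_exact) / rs * 1e6
        assert np.abs(res.actual_uA[sel] - i_exact).max() < 1e-3 * np.abs(i_exact).max()

    def test_terminal_voltage_never_exceeds_limit(self):
        load = bench_load("small_tip_325k")
        wf = synthesize_pulse(PulseSpec(90, 90, 300, 300), GeneratorSettings())
        res = simulate_drive(load, wf)
        assert np.abs(res.terminal_voltage_V).max() <= load.v_limit_v + 1e-3

    def test_in_compliance_current_independent_of_load(self):
        # ideal current source: sweeping Rp a decade changes the delivered
        # current not at all while the voltage stays inside the limit
        wf = rectangle(5.0, 100.0)
        traces = []
        for rp in (10e3, 30e3, 100e3):
            m = InterfaceModel(1e3, rp, 2e-9)
            traces.append(simulate_drive(m, wf).actual_uA)
        assert np.array_equal(traces[0], traces[1])
        assert np.array_equal(traces[0], traces[2])


class TestInrush:
    def test_no_mismatch_no_inrush(self):
        assert inrush_peak(MODEL, 0.0, suppression_on=False) == 0.0

    def test_ohms_law_peak_without_suppression(self):
        assert inrush_peak(MODEL, 0.1, suppression_on=False) == pytest.approx(100.0)

    def test_suppression_removes_transient(self):
        assert inrush_peak(MODEL, 0.5, suppression_on=True) == 0.0


class TestShortToReference:
    def test_zero_duration_unchanged(self):
        assert short_to_reference(MODEL, 0.8, 0.0) == 0.8

    def test_five_time_constants_leave_under_0_7_percent(self):
        tau = MODEL.r_series_ohm * MODEL.c_parallel_f
        resid = short_to_reference(MODEL, 1.0, 5 * tau)
        assert resid < 0.007
        assert resid == pytest.approx(math.exp(-5))

    def test_shorting_bounds_accumulation_in_imbalanced_train(self):
        # forced 1-LSB anodic excess: without shorting, Vc grows monotonically
        # across pulses; with per-pulse shorting it stays bounded.
        # A near-blocking interface (very large charge-transfer resistance)
        # retains the residual charge between pulses.
        model = InterfaceModel(1e3, 1e9, 2e-9)
        spec = PulseSpec(29.6875, 29.6875 + 1.5625, 100, 100)
        wf = synthesize_pulse(spec, GeneratorSettings(), dt_us=0.5)
        tau_short = model.r_series_ohm * model.c_parallel_f

        def run_train(n_pulses: int, short: bool) -> list[float]:
            vc, ends = 0.0, []
            for _ in range(n_pulses):
                res = simulate_drive(model, wf, vc0_V=vc)
                # settle through Rp between pulses (5 ms inter-pulse interval)
                vc = res.capacitor_voltage_V[-1] * math.exp(-5e-3 / model.tau_source_s)
                if short:
                    vc = short_to_reference(model, vc, 10 * tau_short)
                ends.append(vc)
            return ends

        no_short = run_train(8, short=False)
        assert all(b > a for a, b in zip(no_short, no_short[1:]))
        shorted = run_train(8, short=True)
        assert max(abs(v) for v in shorted) < 0.01 * max(no_short)
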