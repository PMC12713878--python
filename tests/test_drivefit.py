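"""Chemoreflex model: response dynamics, fitting, loop gain."""

import math

import numpy as np
import pytest
from scipy.optimize import nnls as scipy_nnls

from conftest import make_breaths, ode_drive_oracle
from pup_endotype.drivefit import (
    ChemoreflexParams,
    FitSettings,
    chemoreflex_response,
    filtered_disturbance,
    fit_drive_model,
    fit_drive_span,
    lg1_lgn,
    loop_gain_magnitude,
    natural_frequency,
    nnls_intercept,
    nnls_two_columns,
)
from pup_endotype.errors import AnalysisError, InputError, InsufficientDataError
from pup_endotype.signals import AnnotationSet, Epoch, RespEvent


class TestChemoreflexResponse:
    def test_sustained_apnea_reaches_steady_state_gain(self):
        params = ChemoreflexParams(gain_G=0.5, tau_s=20.0, delay_s=0.0)
        breaths = make_breaths(np.zeros(200))  # apnea held for 800 s >> tau
        drive = chemoreflex_response(breaths, params)
        assert drive[-1] == pytest.approx(150.0, abs=0.01)

    def test_eupneic_input_gives_eupneic_drive(self):
        params = ChemoreflexParams(gain_G=3.0, tau_s=60.0, delay_s=10.0)
        breaths = make_breaths(np.full(100, 100.0))
        assert np.allclose(chemoreflex_response(breaths, params), 100.0)

    def test_non_monotone_times_rejected(self):
        breaths = make_breaths(np.full(5, 100.0))
        breaths[2].t_start = breaths[1].t_start - 8.0
        with pytest.raises(InputError):
            chemoreflex_response(breaths, ChemoreflexParams(1.0, 30.0, 5.0))

    @pytest.mark.parametrize("tau,delay", [(15.0, 5.0), (60.0, 10.0), (120.0, 25.0)])
    def test_matches_fine_step_ode_integration(self, tau, delay):
        rng = np.random.default_rng(42)
        vent = np.clip(100.0 + 25.0 * rng.standard_normal(150), 0.0, None)
        breaths = make_breaths(vent)
        gain = 2.5
        u_hat = filtered_disturbance(
            np.array([b.t_start for b in breaths]),
            np.array([b.t_end for b in breaths]),
            vent,
            np.array([tau]),
            delay,
        )[0]
        ref = ode_drive_oracle(
            np.array([b.t_start for b in breaths]), vent, gain, tau, delay, 4.0
        )
        scale = np.max(np.abs(ref)) or 1.0
        assert np.max(np.abs(gain * u_hat - ref)) / scale < 1e-3

    def test_linearity_of_deviations(self):
        rng = np.random.default_rng(5)
        dev = 10.0 * rng.standard_normal(120)
        params = ChemoreflexParams(gain_G=2.0, tau_s=45.0, delay_s=8.0)
        d1 = chemoreflex_response(make_breaths(100.0 + dev), params) - 100.0
        d2 = chemoreflex_response(make_breaths(100.0 + 2 * dev), params) - 100.0
        assert np.allclose(d2, 2 * d1, atol=1e-9)

    def test_sinusoid_amplitude_and_phase_match_transfer_function(self):
        # fine breath grid so zero-order-hold effects stay below tolerance
        period, gain, tau, delay = 0.1, 3.0, 60.0, 10.0
        f = 1.0 / 120.0
        n = int(900 / period)
        t = np.arange(n) * period
        a_in = 10.0
        vent = 100.0 + a_in * np.sin(2 * np.pi * f * (t + period / 2))
        u_hat = filtered_disturbance(t, t + period, vent, np.array([tau]), delay)[0]
        out = gain * u_hat
        # least-squares sinusoid fit on the steady-state tail
        tail = t > 5 * tau
        X = np.column_stack([np.sin(2 * np.pi * f * t[tail]), np.cos(2 * np.pi * f * t[tail])])
        (a, b), *_ = np.linalg.lstsq(X, out[tail], rcond=None)
        amp = math.hypot(a, b)
        # out = -amp*sin(2*pi*f*t - phase) => a = -amp*cos(phase), b = amp*sin(phase)
        phase = math.atan2(b, -a) % (2 * math.pi)
        amp_expected = a_in * gain / math.sqrt(1 + (2 * math.pi * f * tau) ** 2)
        phase_expected = math.atan(2 * math.pi * f * tau) + 2 * math.pi * f * delay
        assert abs(amp - amp_expected) / amp_expected < 0.01
        assert abs(phase - phase_expected) / phase_expected < 0.01


class TestNNLS:
    @pytest.mark.parametrize("seed", range(8))
    def test_two_column_solver_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        u = rng.standard_normal(60)
        a = (rng.random(60) < 0.3).astype(float)
        y = rng.standard_normal(60) * 5
        G, g, sse = nnls_two_columns(u, a, y)
        X = np.column_stack([u, a])
        ref, _ = scipy_nnls(X, y)
        r = y - X @ ref
        assert G == pytest.approx(ref[0], abs=1e-8)
        assert g == pytest.approx(ref[1], abs=1e-8)
        assert sse == pytest.approx(float(r @ r), rel=1e-6, abs=1e-9)

    def test_intercept_solver_reduces_to_centered_problem(self):
        rng = np.random.default_rng(1)
        u = rng.standard_normal(50)
        a = (rng.random(50) < 0.4).astype(float)
        y = 7.0 + 2.0 * u + 3.0 * a + 0.01 * rng.standard_normal(50)
        b, G, g, sse = nnls_intercept(u, a, y)
        assert b == pytest.approx(7.0, abs=0.05)
        assert G == pytest.approx(2.0, abs=0.05)
        assert g == pytest.approx(3.0, abs=0.05)


def _self_consistent_night(gain=3.0, tau=60.0, delta=10.0, gamma=20.0, n=400, seed=0):
    """Ventilation generated by the fit model's own equations.

    Non-event breaths satisfy vent = 100 + G*u_hat + gamma*A exactly;
    event breaths carry reduced ventilation.
    """
    rng = np.random.default_rng(seed)
    period = 4.0
    t0 = np.arange(n) * period
    vent = np.full(n, 100.0)
    in_event = np.zeros(n, dtype=bool)
    in_arousal = np.zeros(n, dtype=bool)
    i = 10
    while i < n - 12:
        run = rng.integers(4, 8)
        in_event[i : i + run] = True
        vent[i : i + run] = rng.uniform(20.0, 50.0)
        in_arousal[i + run : i + run + 2] = True
        i += run + int(rng.integers(8, 15))
    # iterate the causal model to a fixed point: each sweep propagates
    # consistency forward by roughly delta seconds, so n*period/delta
    # sweeps reach the end of the record
    for _ in range(int(n * period / max(delta, period)) + 5):
        u_hat = filtered_disturbance(t0, t0 + period, vent, np.array([tau]), delta)[0]
        target = 100.0 + gain * u_hat + gamma * in_arousal
        new = np.where(in_event, vent, target)
        if np.max(np.abs(new - vent)) < 1e-12:
            vent = new
            break
        vent = new
    u_hat = filtered_disturbance(t0, t0 + period, vent, np.array([tau]), delta)[0]
    target = 100.0 + gain * u_hat + gamma * in_arousal
    assert np.max(np.abs(np.where(in_event, vent, target) - vent)) < 1e-9
    breaths = make_breaths(vent, in_event=in_event, in_arousal=in_arousal)
    return breaths, vent


class TestFitDriveSpan:
    def test_recovers_parameters_exactly_on_self_consistent_data(self):
        breaths, _ = _self_consistent_night(gain=3.0, tau=60.0, delta=10.0, gamma=20.0)
        settings = FitSettings(taus=(30.0, 60.0, 90.0), deltas=(6.0, 10.0, 14.0))
        res = fit_drive_span(breaths, settings)
        assert res.params.tau_s == 60.0
        assert res.params.delay_s == 10.0
        assert res.params.gain_G == pytest.approx(3.0, abs=1e-6)
        assert res.params.arousal_gamma == pytest.approx(20.0, abs=1e-6)
        assert res.sse < 1e-9
        assert res.identifiable

    def test_truth_has_lowest_sse_on_the_grid(self):
        breaths, _ = _self_consistent_night()
        settings = FitSettings(
            taus=tuple(range(20, 130, 10)), deltas=(2.0, 6.0, 10.0, 14.0, 18.0)
        )
        res = fit_drive_span(breaths, settings)
        best = min(res.grid_trace, key=lambda r: r[2])
        assert best[:2] == (60.0, 10.0)

    def test_flat_input_flagged_unidentifiable(self):
        breaths = make_breaths(np.full(200, 100.0))
        res = fit_drive_span(breaths, FitSettings(taus=(30.0, 60.0), deltas=(4.0, 8.0)))
        assert res.identifiable is False

    def test_all_event_breaths_rejected(self):
        breaths = make_breaths(np.full(50, 80.0), in_event=np.ones(50, dtype=bool))
        with pytest.raises(InsufficientDataError):
            fit_drive_span(breaths, FitSettings(taus=(30.0,), deltas=(4.0,)))

    def test_event_breaths_never_enter_the_residual_set(self):
        breaths, vent = _self_consistent_night()
        res = fit_drive_span(breaths, FitSettings(taus=(60.0,), deltas=(10.0,)))
        flagged = {i for i, b in enumerate(breaths) if b.in_event}
        assert flagged.isdisjoint(set(res.fit_index.tolist()))
        # corrupting event-breath ventilation changes u_hat but not which
        # breaths are scored
        vent2 = vent.copy()
        vent2[[i for i in flagged][:5]] -= 10.0
        breaths2 = make_breaths(
            vent2,
            in_event=np.array([b.in_event for b in breaths]),
            in_arousal=np.array([b.in_arousal for b in breaths]),
        )
        res2 = fit_drive_span(breaths2, FitSettings(taus=(60.0,), deltas=(10.0,)))
        assert np.array_equal(res.fit_index, res2.fit_index)


class TestFitDriveModel:
    def test_windowed_fit_recovers_parameters_on_model_data(self):
        breaths, _ = _self_consistent_night(n=500)
        epochs = [Epoch(onset=30.0 * k, stage="N2") for k in range(67)]
        events = []
        start = None
        for b in breaths + [None]:
            if b is not None and b.in_event:
                start = b.t_start if start is None else start
                end = b.t_end
            elif start is not None:
                events.append(RespEvent(onset=start, duration=end - start, kind="hypopnea"))
                start = None
        ann = AnnotationSet(resp_events=events, epochs=epochs)
        settings = FitSettings(taus=(30.0, 60.0, 90.0), deltas=(6.0, 10.0, 14.0))
        fit = fit_drive_model(breaths, ann, settings)
        assert fit.params.tau_s == 60.0
        assert fit.params.gain_G == pytest.approx(3.0, abs=0.05)
        assert len(fit.windows) > 3

    def test_no_events_means_no_analyzable_window(self):
        breaths = make_breaths(np.full(300, 100.0))
        ann = AnnotationSet(epochs=[Epoch(onset=30.0 * k, stage="N2") for k in range(40)])
        with pytest.raises(InsufficientDataError):
            fit_drive_model(breaths, ann, FitSettings(taus=(60.0,), deltas=(10.0,)))


class TestLoopGain:
    def test_dc_limit_is_the_steady_state_gain(self):
        p = ChemoreflexParams(gain_G=3.0, tau_s=60.0, delay_s=10.0)
        assert loop_gain_magnitude(p, 1e-9) == pytest.approx(3.0, rel=1e-6)

    def test_closed_form_at_one_cycle_per_minute(self):
        p = ChemoreflexParams(gain_G=3.0, tau_s=60.0, delay_s=10.0)
        assert loop_gain_magnitude(p, 1.0 / 60.0) == pytest.approx(
            3.0 / math.sqrt(1.0 + 4.0 * math.pi**2), rel=1e-9
        )

    def test_magnitude_strictly_decreasing_in_frequency(self):
        p = ChemoreflexParams(gain_G=2.0, tau_s=45.0, delay_s=8.0)
        for f in [0.005, 0.01, 0.02, 0.05]:
            assert loop_gain_magnitude(p, 2 * f) < loop_gain_magnitude(p, f)

    def test_natural_frequency_zeroes_the_phase_equation(self):
        p = ChemoreflexParams(gain_G=3.0, tau_s=60.0, delay_s=10.0)
        fn_hz = natural_frequency(p) / 60.0
        residual = math.atan(2 * math.pi * fn_hz * p.tau_s) + 2 * math.pi * fn_hz * p.delay_s - math.pi
        assert abs(residual) < 1e-9

    def test_longer_delay_lowers_the_natural_frequency(self):
        base = ChemoreflexParams(gain_G=3.0, tau_s=60.0, delay_s=10.0)
        doubled = ChemoreflexParams(gain_G=3.0, tau_s=60.0, delay_s=20.0)
        assert natural_frequency(doubled) < natural_frequency(base)

    def test_zero_delay_has_no_phase_crossing(self):
        with pytest.raises(AnalysisError):
            natural_frequency(ChemoreflexParams(gain_G=3.0, tau_s=60.0, delay_s=0.0))

    def test_lgn_below_lg1_when_natural_frequency_above_1cpm(self):
        p = ChemoreflexParams(gain_G=3.0, tau_s=60.0, delay_s=10.0)
        lg1, lgn = lg1_lgn(p)
        assert natural_frequency(p) > 1.0
        assert lgn < lg1
        assert lg1 == pytest.approx(3.0 / math.sqrt(1.0 + 4.0 * math.pi**2), rel=1e-9)

    def test_vanishing_lag_recovers_pure_gain(self):
        p = ChemoreflexParams(gain_G=3.0, tau_s=1e-6, delay_s=10.0)
        assert lg1_lgn(p)[0] == pytest.approx(3.0, rel=1e-6)
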