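"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from pup_endotype.signals import BreathRecord, FlowTrace


def make_sine_flow(
    n_cycles: int = 150, period: float = 4.0, amp: float = 0.5, fs: float = 25.0
) -> FlowTrace:
    """Full-sine breathing: half-sine inspiration then mirrored expiration."""
    t = np.arange(int(round(n_cycles * period * fs))) / fs
    return FlowTrace(samples=amp * np.sin(2 * np.pi * t / period), sampling_rate=fs)


def make_breaths(
    vent_pct: np.ndarray,
    period: float = 4.0,
    vent_abs: np.ndarray | None = None,
    in_event: np.ndarray | None = None,
    in_arousal: np.ndarray | None = None,
    stage: str = "N2",
) -> list[BreathRecord]:
    """Breath list on a uniform grid with prescribed ventilation."""
    vent_pct = np.asarray(vent_pct, dtype=float)
    n = vent_pct.size
    out = []
    for i in range(n):
        b = BreathRecord(
            t_start=i * period,
            t_insp_end=i * period + period / 2,
            t_end=(i + 1) * period,
            tidal_volume=max(0.0, vent_pct[i] * period / 6000.0),
        )
        b.ventilation_pct = float(vent_pct[i])
        b.ventilation_abs = float(vent_abs[i]) if vent_abs is not None else vent_pct[i] * 0.075
        b.in_event = bool(in_event[i]) if in_event is not None else False
        b.in_arousal = bool(in_arousal[i]) if in_arousal is not None else False
        b.stage = stage
        out.append(b)
    return out


def ode_drive_oracle(
    t_starts: np.ndarray,
    vent_pct: np.ndarray,
    gain: float,
    tau: float,
    delay: float,
    period: float,
    dt: float = 0.01,
) -> np.ndarray:
    """Fine-step RK4 integration of tau*y' + y = G*u, u = 100 - vent(t - delay).

    Independent oracle for the breath-domain exponential update: the ODE
    is integrated with classical 4th-order Runge-Kutta steps of at most
    ``dt`` on a grid that includes every discontinuity of the delayed
    piecewise-constant input.  Returns the chemical-drive deviation y
    sampled at breath starts.
    """
    t_starts = np.asarray(t_starts, dtype=float)
    vent = np.asarray(vent_pct, dtype=float)
    t_end = t_starts[-1] + period
    breakpoints = np.concatenate([t_starts, t_starts + delay, [t_end]])
    grid = np.union1d(np.arange(t_starts[0], t_end, dt), breakpoints)
    grid = grid[(grid >= t_starts[0]) & (grid <= t_end)]
    mid = grid[:-1] + np.diff(grid) / 2.0
    idx = np.searchsorted(t_starts, mid - delay, side="right") - 1
    u = np.where(idx >= 0, 100.0 - vent[np.clip(idx, 0, vent.size - 1)], 0.0)
    h = np.diff(grid)
    # RK4 on y' = (G*u - y)/tau with u constant per sub-interval reduces to
    # y_{k+1} = a_k*y_k + (1 - a_k)*G*u_k with a_k the 4th-order Taylor
    # polynomial of exp(-h_k/tau)
    z = -h / tau
    a = 1.0 + z + z**2 / 2.0 + z**3 / 6.0 + z**4 / 24.0
    y = np.empty(grid.size)
    y[0] = 0.0
    for k in range(h.size):
        y[k + 1] = a[k] * y[k] + (1.0 - a[k]) * gain * u[k]
    pick = np.searchsorted(grid, t_starts)
    return y[np.clip(pick, 0, y.size - 1)]


@pytest.fixture(scope="session")
def moderate_night():
    """One reproducible simulated night with recurrent obstructive events."""
    from pup_endotype.simulate import SimConfig, simulate_night

    cfg = SimConfig(
        duration_s=1800.0,
        vpassive_true=55.0,
        threshold_true=150.0,
        comp_slope=0.1,
        gain_G=4.0,
        tau_s=45.0,
        delay_s=8.0,
        arousal_gamma=20.0,
        noise_sd=0.05,
        seed=11,
    )
    return cfg, simulate_night(cfg)
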