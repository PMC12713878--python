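"""Closed-loop ventilatory-control simulator with known ground-truth traits.

Generates a full synthetic night — airflow trace, scored annotations and
a per-breath truth table — from a mechanistic model of obstructive sleep
apnea:

* a chemoreflex controller (gain G, time constant tau, circulatory delay
  delta) turns the history of achieved ventilation into ventilatory
  drive, using exactly the same delayed first-order dynamics as the
  estimator;
* a collapsible airway converts drive D into achieved ventilation:
  V = Vpassive + comp_slope * (D - 100) for D >= 100 (floored at 0) and
  V = min(D, Vpassive) below eupneic drive (the airway can always
  deliver up to its passive capacity);
* an arousal fires when chemical drive reaches a threshold, adds a
  wakefulness drive gamma for its duration and opens the airway
  (V = D) for the arousal plus a short recovery;
* multiplicative lognormal breath-level noise perturbs the achieved
  ventilation, and the noisy ventilation both feeds back through the
  chemoreflex and is emitted as flow — breath-to-breath variability is
  the physiological excitation that makes the loop dynamics
  identifiable from spontaneous breathing.

Respiratory events are auto-scored from the pre-noise airway output
(the deterministic ventilation the airway admits at the current drive)
with a configurable hypopnea/apnea rule, emulating a human scorer on
crisp event boundaries.  Everything is seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drivefit import ChemoreflexParams, lg1_lgn
from .errors import InputError, UnstableConfigError
from .signals import EPOCH_S, AnnotationSet, Arousal, Epoch, FlowTrace, RespEvent


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated night."""

    duration_s: float = 7200.0
    breath_period_s: float = 4.0
    # chemoreflex
    gain_G: float = 3.5
    tau_s: float = 60.0
    delay_s: float = 8.0
    arousal_gamma: float = 20.0
    # airway
    vpassive_true: float = 60.0
    comp_slope: float = 0.1
    # arousal
    threshold_true: float = 150.0
    arousal_duration_s: float = 10.0
    post_arousal_airway_open_s: float = 5.0
    # measurement
    noise_sd: float = 0.05
    eupneic_ventilation_abs: float = 7.5
    sampling_rate: float = 25.0
    stage_schedule: tuple[tuple[float, str], ...] = ((0.0, "N2"),)
    # auto-scoring
    hypopnea_frac: float = 0.7
    apnea_frac: float = 0.1
    min_event_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.breath_period_s <= 0:
            raise InputError("durations must be positive")
        if self.vpassive_true < 0:
            raise InputError("vpassive_true must be >= 0")
        if not -1.0 <= self.comp_slope <= 1.0:
            raise InputError("comp_slope must lie in [-1, 1]")
        if np.isfinite(self.threshold_true) and self.threshold_true < 100:
            raise InputError("arousal threshold must be >= 100 %eupnea")
        if 1.0 + self.gain_G * self.comp_slope <= 0 and not np.isfinite(self.threshold_true):
            raise UnstableConfigError(
                "drive diverges: comp_slope <= -1/gain_G with no arousal bound"
            )

    @property
    def chemoreflex(self) -> ChemoreflexParams:
        return ChemoreflexParams(
            gain_G=self.gain_G,
            tau_s=self.tau_s,
            delay_s=self.delay_s,
            arousal_gamma=self.arousal_gamma,
        )


@dataclass
class GroundTruth:
    """Programmed trait values underlying a simulated night."""

    vpassive: float
    compensation: float
    vactive: float
    arousal_threshold: float
    lg1: float
    lgn: float
    n_events_scored: int = 0
    n_arousals: int = 0

    def __post_init__(self) -> None:
        if abs(self.vactive - (self.vpassive + self.compensation)) > 1e-9:
            raise InputError("ground truth must satisfy vactive = vpassive + compensation")


def ground_truth_from_config(cfg: SimConfig) -> GroundTruth:
    comp = cfg.comp_slope * (cfg.threshold_true - 100.0)
    lg1, lgn = lg1_lgn(cfg.chemoreflex)
    return GroundTruth(
        vpassive=cfg.vpassive_true,
        compensation=comp,
        vactive=cfg.vpassive_true + comp,
        arousal_threshold=cfg.threshold_true,
        lg1=lg1,
        lgn=lgn,
    )


def score_events(
    t_starts: np.ndarray,
    durations: np.ndarray,
    vent_pct: np.ndarray,
    hypopnea_frac: float = 0.7,
    apnea_frac: float = 0.1,
    min_event_s: float = 10.0,
) -> list[RespEvent]:
    """Emulated human scoring of respiratory events from breath ventilation.

    Maximal runs of breaths with ventilation below ``hypopnea_frac`` x 100
    lasting at least ``min_event_s`` become events; a run whose minimum
    drops below ``apnea_frac`` x 100 is an (obstructive) apnea, otherwise
    a hypopnea.
    """
    below = np.asarray(vent_pct) < hypopnea_frac * 100.0
    events: list[RespEvent] = []
    i = 0
    n = below.size
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j < n and below[j]:
            j += 1
        dur = float(np.sum(durations[i:j]))
        if dur >= min_event_s:
            kind = (
                "obstructive_apnea"
                if float(np.min(vent_pct[i:j])) < apnea_frac * 100.0
                else "hypopnea"
            )
            events.append(RespEvent(onset=float(t_starts[i]), duration=dur, kind=kind))
        i = j
    return events


def simulate_night(
    cfg: SimConfig,
) -> tuple[FlowTrace, AnnotationSet, GroundTruth, pd.DataFrame]:
    """Run the closed loop breath by breath and synthesize the recording.

    Returns the flow trace, auto-scored annotations, the programmed
    ground truth, and a per-breath truth table with columns
    ``t_start, chemical_drive, total_drive, aroused, airway_open,
    vent_true, vent_noisy, stage, scored_event``.
    """
    T = cfg.breath_period_s
    n = int(round(cfg.duration_s / T))
    if n < 2:
        raise InputError("duration too short for the breath period")
    starts = np.arange(n) * T
    rng = np.random.default_rng(cfg.seed)

    sched_on = [s for s, _ in cfg.stage_schedule]
    sched_st = [st for _, st in cfg.stage_schedule]
    stage_of = lambda t: sched_st[int(np.searchsorted(sched_on, t, side="right")) - 1]

    tau, G, delay, gamma = cfg.tau_s, cfg.gain_G, cfg.delay_s, cfg.arousal_gamma
    y = 0.0  # filter state (drive deviation under unit input scaling)
    u = 0.0  # current delayed disturbance, 100 - V
    t_cur = 0.0
    pending: list[tuple[float, float]] = []  # (time, new u) input changes
    p_head = 0
    arousal_until = -np.inf
    open_until = -np.inf

    chem_arr = np.empty(n)
    total_arr = np.empty(n)
    aroused_arr = np.zeros(n, dtype=bool)
    open_arr = np.zeros(n, dtype=bool)
    v_true = np.empty(n)
    v_noisy = np.empty(n)
    stages = []
    arousal_list: list[Arousal] = []

    for i in range(n):
        t_i = float(starts[i])
        while p_head < len(pending) and pending[p_head][0] <= t_i:
            tc, uval = pending[p_head]
            p_head += 1
            if tc > t_cur:
                y = u + (y - u) * np.exp(-(tc - t_cur) / tau)
                t_cur = tc
            u = uval
        if t_i > t_cur:
            y = u + (y - u) * np.exp(-(t_i - t_cur) / tau)
            t_cur = t_i

        chem = max(0.0, 100.0 + G * y)
        mid = t_i + T / 2.0
        # the arousal drive applies to breaths lying within the margins of
        # the scored arousal (midpoint rule, same as the estimator)
        aroused = mid < arousal_until
        if not aroused and t_i >= arousal_until and chem >= cfg.threshold_true:
            aroused = True
            arousal_until = t_i + cfg.arousal_duration_s
            open_until = arousal_until + cfg.post_arousal_airway_open_s
            arousal_list.append(Arousal(onset=t_i, duration=cfg.arousal_duration_s))
        stage = stage_of(t_i)
        airway_open = aroused or mid < open_until or stage == "W"
        D = chem + (gamma if aroused else 0.0)

        if airway_open:
            V = D
        elif D >= 100.0:
            V = max(0.0, cfg.vpassive_true + cfg.comp_slope * (D - 100.0))
        else:
            V = min(D, cfg.vpassive_true)

        V_noisy = V * rng.lognormal(mean=0.0, sigma=cfg.noise_sd) if cfg.noise_sd > 0 else V

        chem_arr[i] = chem
        total_arr[i] = D
        aroused_arr[i] = aroused
        open_arr[i] = airway_open
        v_true[i] = V
        v_noisy[i] = V_noisy
        stages.append(stage)
        pending.append((t_i + delay, 100.0 - V_noisy))

    durations = np.full(n, T)
    events = score_events(
        starts, durations, v_true, cfg.hypopnea_frac, cfg.apnea_frac, cfg.min_event_s
    )

    flow = _synthesize_flow(cfg, starts, v_noisy)

    n_epochs = int(np.ceil(cfg.duration_s / EPOCH_S))
    epochs = [Epoch(onset=k * EPOCH_S, stage=stage_of(k * EPOCH_S)) for k in range(n_epochs)]
    annotations = AnnotationSet(resp_events=events, arousals=arousal_list, epochs=epochs)

    truth = ground_truth_from_config(cfg)
    truth.n_events_scored = len(events)
    truth.n_arousals = len(arousal_list)

    in_ev = np.zeros(n, dtype=bool)
    for e in events:
        in_ev |= (starts < e.end) & (starts + T > e.onset)
    table = pd.DataFrame(
        {
            "t_start": starts,
            "chemical_drive": chem_arr,
            "total_drive": total_arr,
            "aroused": aroused_arr,
            "airway_open": open_arr,
            "vent_true": v_true,
            "vent_noisy": v_noisy,
            "stage": stages,
            "scored_event": in_ev,
        }
    )
    return flow, annotations, truth, table


def _synthesize_flow(cfg: SimConfig, starts: np.ndarray, vent_pct: np.ndarray) -> FlowTrace:
    """Half-sine inspiration/expiration flow with per-breath tidal volume."""
    T = cfg.breath_period_s
    fs = cfg.sampling_rate
    n_samp = int(round(cfg.duration_s * fs))
    t = np.arange(n_samp) / fs
    idx = np.minimum((t // T).astype(int), starts.size - 1)
    tr = t - starts[idx]
    ti = T / 2.0  # inspiratory time
    vt = (vent_pct / 100.0) * cfg.eupneic_ventilation_abs * T / 60.0  # units*s
    amp = vt * np.pi / (2.0 * ti)
    insp = tr < ti
    flow = np.where(
        insp,
        amp[idx] * np.sin(np.pi * tr / ti),
        -amp[idx] * np.sin(np.pi * (tr - ti) / (T - ti)),
    )
    return FlowTrace(samples=flow, sampling_rate=fs, t0=0.0)


def stable_config(**overrides) -> SimConfig:
    """A non-collapsible, low-loop-gain night (no events expected)."""
    base = dict(
        vpassive_true=100.0,
        comp_slope=0.0,
        gain_G=2.0,
        tau_s=60.0,
        delay_s=8.0,
        noise_sd=0.0,
        threshold_true=160.0,
    )
    base.update(overrides)
    return SimConfig(**base)


def unstable_config(**overrides) -> SimConfig:
    """A strongly collapsible, high-loop-gain night with recurrent events."""
    base = dict(
        vpassive_true=30.0,
        comp_slope=0.0,
        gain_G=4.0,
        tau_s=45.0,
        delay_s=8.0,
        noise_sd=0.0,
        threshold_true=150.0,
    )
    base.update(overrides)
    return SimConfig(**base)
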