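"""Breath-level processing of a polysomnographic airflow signal.

Turns a raw single-channel airflow trace (inspiration positive, already
linearized) plus scored annotations into a list of context-tagged
breaths.  Each breath carries its tidal volume (integral of inspiratory
flow), absolute ventilation (tidal volume per minute) and ventilation
expressed as a percentage of a local eupneic baseline, defined as the
time-weighted mean ventilation over a centered 7-minute window.  On that
scale 0% is a complete apnea, 100% is eupneic breathing and values above
100% are hyperpnea.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import FlatSignalError, InputError, NoBreathsError

STAGES = ("W", "N1", "N2", "N3", "R")
NREM_STAGES = ("N1", "N2", "N3")
EVENT_TYPES = ("obstructive_apnea", "central_apnea", "mixed_apnea", "hypopnea")
APNEA_TYPES = ("obstructive_apnea", "central_apnea", "mixed_apnea")
EPOCH_S = 30.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class FlowTrace:
    """Single-channel airflow time series in arbitrary linear units."""

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InputError("flow samples must be one-dimensional")
        if not self.sampling_rate > 0:
            raise InputError("sampling_rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration


@dataclass(frozen=True)
class RespEvent:
    """A scored respiratory event, half-open interval [onset, onset+duration)."""

    onset: float
    duration: float
    kind: str

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InputError(f"respiratory event duration must be > 0, got {self.duration}")
        if self.kind not in EVENT_TYPES:
            raise InputError(f"unknown respiratory event type {self.kind!r}")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class Arousal:
    """A scored cortical arousal, half-open interval [onset, onset+duration)."""

    onset: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InputError(f"arousal duration must be > 0, got {self.duration}")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class Epoch:
    """One 30-s sleep-staging epoch."""

    onset: float
    stage: str

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise InputError(f"unknown sleep stage {self.stage!r}")


@dataclass
class AnnotationSet:
    """Scored respiratory events, arousals and sleep stages for one night."""

    resp_events: list[RespEvent] = field(default_factory=list)
    arousals: list[Arousal] = field(default_factory=list)
    epochs: list[Epoch] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.resp_events = sorted(self.resp_events, key=lambda e: e.onset)
        self.arousals = sorted(self.arousals, key=lambda a: a.onset)
        self.epochs = sorted(self.epochs, key=lambda e: e.onset)
        onsets = np.array([e.onset for e in self.epochs])
        if onsets.size:
            if np.any(np.diff(onsets) <= 0):
                raise InputError("epoch onsets must be strictly increasing (no overlap)")
            grid = (onsets - onsets[0]) / EPOCH_S
            if not np.allclose(grid, np.round(grid), atol=1e-6):
                raise InputError("epoch onsets must lie on a 30-s grid")

    def stage_at(self, t: float) -> str | None:
        """Stage of the epoch containing time ``t``, or None if unstaged."""
        onsets = [e.onset for e in self.epochs]
        i = int(np.searchsorted(onsets, t, side="right")) - 1
        if i < 0:
            return None
        if t < self.epochs[i].onset + EPOCH_S:
            return self.epochs[i].stage
        return None

    def total_sleep_time_s(self) -> float:
        return sum(EPOCH_S for e in self.epochs if e.stage != "W")

    def stage_time_s(self, stages: tuple[str, ...]) -> float:
        return sum(EPOCH_S for e in self.epochs if e.stage in stages)


@dataclass
class BreathRecord:
    """One segmented breath with timing, volume and scoring context."""

    t_start: float
    t_insp_end: float
    t_end: float
    tidal_volume: float
    ventilation_abs: float = np.nan
    ventilation_pct: float = np.nan
    stage: str | None = None
    in_event: bool = False
    in_arousal: bool = False

    def __post_init__(self) -> None:
        if not (self.t_start < self.t_insp_end <= self.t_end):
            raise InputError(
                f"breath timing must satisfy t_start < t_insp_end <= t_end, "
                f"got ({self.t_start}, {self.t_insp_end}, {self.t_end})"
            )
        if self.tidal_volume < 0:
            raise InputError("tidal_volume must be non-negative")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


def breath_arrays(breaths: list[BreathRecord]) -> dict[str, np.ndarray]:
    """Column view of a breath list for vectorized numerics."""
    return {
        "t_start": np.array([b.t_start for b in breaths]),
        "t_end": np.array([b.t_end for b in breaths]),
        "tidal_volume": np.array([b.tidal_volume for b in breaths]),
        "ventilation_abs": np.array([b.ventilation_abs for b in breaths]),
        "ventilation_pct": np.array([b.ventilation_pct for b in breaths]),
        "in_event": np.array([b.in_event for b in breaths], dtype=bool),
        "in_arousal": np.array([b.in_arousal for b in breaths], dtype=bool),
        "stage": np.array([b.stage if b.stage is not None else "?" for b in breaths]),
    }


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def segment_breaths(
    flow: FlowTrace,
    min_breath_s: float = 1.5,
    max_breath_s: float = 12.0,
    smooth_s: float = 2.0,
) -> list[BreathRecord]:
    """Delimit breaths at inspiratory onsets and integrate tidal volumes.

    Inspiration onsets are negative-to-positive zero crossings of a
    moving-average-smoothed copy of the flow; tidal volume is the
    trapezoidal integral of the positive raw flow over the breath.
    Crossings that would close a breath shorter than ``min_breath_s`` are
    merged into the previous breath; spans longer than ``max_breath_s``
    (apneic gaps) are split into zero-volume pseudo-breaths of nominal
    duration so that apneas remain represented as 0% ventilation.
    """
    x = flow.samples
    if not np.all(np.isfinite(x)):
        raise InputError("flow contains non-finite samples (NaN/inf)")
    if flow.sampling_rate < 10:
        raise InputError(f"sampling rate {flow.sampling_rate} Hz < 10 Hz minimum")
    fs = flow.sampling_rate
    t = flow.times
    if x.size < int(2 * min_breath_s * fs):
        raise NoBreathsError("record too short to contain breaths")

    w = max(1, int(round(smooth_s * fs)))
    smooth = np.convolve(x, np.ones(w) / w, mode="same")

    pos = smooth > 0.0
    up = np.flatnonzero(~pos[:-1] & pos[1:])  # smooth[i] <= 0 < smooth[i+1]
    if up.size == 0:
        raise NoBreathsError("no breaths detected")
    # two-stage detection: the heavily smoothed signal finds one crossing
    # per breath; each onset is then refined to the nearest crossing of a
    # lightly smoothed copy, otherwise the wide kernel drags boundaries
    # toward the larger neighbouring breath and jitters breath durations
    fine_w = max(1, int(round(0.25 * fs)))
    fine = np.convolve(x, np.ones(fine_w) / fine_w, mode="same")
    fpos = fine > 0.0
    fup = np.flatnonzero(~fpos[:-1] & fpos[1:])
    onsets = []
    half = int(round(1.0 * fs))
    for i in up:
        j = i
        if fup.size:
            k = int(np.argmin(np.abs(fup - i)))
            if abs(int(fup[k]) - i) <= half:
                j = int(fup[k])
        sig = fine if j != i else smooth
        denom = sig[j + 1] - sig[j]
        frac = -sig[j] / denom if denom != 0 else 0.0
        onsets.append(t[j] + frac / fs)
    onsets = np.asarray(onsets)

    kept = [onsets[0]]
    for o in onsets[1:]:
        if o - kept[-1] >= min_breath_s:
            kept.append(float(o))
    onsets = np.asarray(kept)

    diffs = np.diff(onsets)
    normal = diffs[diffs <= max_breath_s]
    nominal = float(np.median(normal)) if normal.size else 4.0

    spans: list[tuple[float, float, bool]] = []  # (start, end, pseudo)

    def fill_gap(a: float, b: float) -> None:
        """Split an apneic span into zero-volume pseudo-breaths."""
        if b - a < min_breath_s:
            if spans:  # absorb a sliver into the previous breath
                s0, _, p0 = spans[-1]
                spans[-1] = (s0, b, p0)
            return
        k = max(1, int(np.ceil((b - a) / nominal)))
        edges = np.linspace(a, b, k + 1)
        for lo, hi in zip(edges[:-1], edges[1:]):
            spans.append((float(lo), float(hi), True))

    def add_breath(a: float, b: float) -> None:
        if b - a <= max_breath_s:
            spans.append((a, b, False))
        else:
            spans.append((a, a + nominal, False))
            fill_gap(a + nominal, b)

    # leading segment: an inspiration may already be in progress at t0
    if onsets[0] - flow.t0 >= min_breath_s:
        if onsets[0] - flow.t0 <= max_breath_s:
            spans.append((flow.t0, float(onsets[0]), False))
        else:
            fill_gap(flow.t0, float(onsets[0]))
    for a, b in zip(onsets[:-1], onsets[1:]):
        add_breath(float(a), float(b))
    # trailing segment after the last onset
    if flow.t_end - onsets[-1] >= min_breath_s:
        add_breath(float(onsets[-1]), flow.t_end)

    if not spans:
        raise NoBreathsError("no breaths detected")

    pos_flow = np.clip(x, 0.0, None)
    breaths: list[BreathRecord] = []
    for a, b, pseudo in spans:
        if pseudo:
            breaths.append(
                BreathRecord(t_start=a, t_insp_end=0.5 * (a + b), t_end=b, tidal_volume=0.0)
            )
            continue
        i0 = int(np.searchsorted(t, a, side="left"))
        i1 = int(np.searchsorted(t, b, side="left"))
        i1 = min(i1, x.size)
        insp_end = _first_down_crossing(smooth, fine, t, i0, i1, half)
        if insp_end is None or not (a < insp_end <= b):
            insp_end = 0.5 * (a + b)
        # integrate the inspiratory phase only: positive flow later in the
        # span belongs to the next breath when onset detection jitters
        j1 = min(int(np.searchsorted(t, insp_end, side="left")) + 1, x.size)
        if j1 - i0 >= 2:
            vt = float(np.trapezoid(pos_flow[i0:j1], dx=1.0 / fs))
        else:
            vt = 0.0
        breaths.append(BreathRecord(t_start=a, t_insp_end=insp_end, t_end=b, tidal_volume=vt))
    return breaths


def _first_down_crossing(
    smooth: np.ndarray,
    fine: np.ndarray,
    t: np.ndarray,
    i0: int,
    i1: int,
    refine_half: int,
) -> float | None:
    """End of inspiration: first smoothed down-crossing, refined on ``fine``."""
    seg = smooth[i0:i1]
    if seg.size < 2:
        return None
    pos = seg > 0.0
    down = np.flatnonzero(pos[:-1] & ~pos[1:])
    if down.size == 0:
        return None
    j = i0 + int(down[0])
    fseg = fine[max(0, j - refine_half) : min(fine.size - 1, j + refine_half)]
    fpos = fseg > 0.0
    fdown = np.flatnonzero(fpos[:-1] & ~fpos[1:])
    sig = smooth
    if fdown.size:
        k = int(np.argmin(np.abs(fdown + max(0, j - refine_half) - j)))
        j = max(0, j - refine_half) + int(fdown[k])
        sig = fine
    denom = sig[j + 1] - sig[j]
    frac = sig[j] / -denom if denom != 0 else 0.0
    return float(t[j] + frac * (t[1] - t[0]))


def compute_ventilation(breaths: list[BreathRecord]) -> list[BreathRecord]:
    """Set ventilation_abs = tidal_volume x 60 / breath duration (units/min)."""
    for b in breaths:
        if b.duration <= 0:
            raise AssertionError("zero-duration breath violates segmentation contract")
        b.ventilation_abs = b.tidal_volume * 60.0 / b.duration
    return breaths


def normalize_to_eupnea(breaths: list[BreathRecord], window_s: float = 420.0) -> list[BreathRecord]:
    """Express each breath's ventilation as % of a local eupneic baseline.

    The baseline is the time-weighted mean of ventilation_abs over a
    window of ``window_s`` centered on the breath midpoint, truncated at
    the record edges (never padded).  All breaths, including those inside
    scored events, contribute to the baseline.
    """
    if not breaths:
        return breaths
    starts = np.array([b.t_start for b in breaths])
    ends = np.array([b.t_end for b in breaths])
    vent = np.array([b.ventilation_abs for b in breaths])
    if np.any(np.isnan(vent)):
        raise InputError("ventilation_abs must be computed before normalization")
    rec0, rec1 = float(starts[0]), float(ends[-1])
    if rec1 - rec0 < window_s:
        raise InputError(
            f"record ({rec1 - rec0:.0f} s) shorter than the eupnea window ({window_s:.0f} s)"
        )
    half = window_s / 2.0
    for i, b in enumerate(breaths):
        c = b.midpoint
        lo, hi = max(rec0, c - half), min(rec1, c + half)
        j0 = int(np.searchsorted(ends, lo, side="right"))
        j1 = int(np.searchsorted(starts, hi, side="left"))
        wts = np.minimum(ends[j0:j1], hi) - np.maximum(starts[j0:j1], lo)
        wts = np.clip(wts, 0.0, None)
        denom = float(np.dot(vent[j0:j1], wts))
        total = float(wts.sum())
        if total <= 0 or denom <= 0:
            raise FlatSignalError("flat signal: local eupnea baseline is zero")
        b.ventilation_pct = 100.0 * b.ventilation_abs / (denom / total)
    return breaths


def assign_context(breaths: list[BreathRecord], annotations: AnnotationSet) -> list[BreathRecord]:
    """Tag each breath with sleep stage, event overlap and arousal membership.

    ``in_event`` is true iff [t_start, t_end) overlaps any scored
    respiratory event; ``in_arousal`` is true iff the breath midpoint lies
    inside a scored arousal; the stage is that of the epoch containing the
    breath midpoint (breaths outside the staged period are treated as wake,
    with a warning).
    """
    ev_on = np.array([e.onset for e in annotations.resp_events])
    ev_off = np.array([e.end for e in annotations.resp_events])
    ar_on = np.array([a.onset for a in annotations.arousals])
    ar_off = np.array([a.end for a in annotations.arousals])
    unstaged = 0
    for b in breaths:
        b.in_event = bool(np.any((ev_on < b.t_end) & (ev_off > b.t_start))) if ev_on.size else False
        mid = b.midpoint
        b.in_arousal = bool(np.any((ar_on <= mid) & (mid < ar_off))) if ar_on.size else False
        stage = annotations.stage_at(mid)
        if stage is None:
            stage = "W"
            unstaged += 1
        b.stage = stage
    if unstaged:
        warnings.warn(
            f"{unstaged} breath(es) outside the staged period; treated as wake",
            stacklevel=2,
        )
    return breaths
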