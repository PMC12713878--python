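"""Chemoreflex model fitting: from %eupnea ventilation to ventilatory drive.

The ventilatory controller is modelled as a first-order lag with a pure
delay.  Writing the chemical-drive deviation d(t) = drive(t) - 100 and
the disturbance u(t) = 100 - ventilation(t - delay), the dynamics are

    tau * d'(t) + d(t) = G * u(t)

with steady-state (loop) gain G, time constant tau and circulatory delay
delta.  Ventilation is piecewise constant per breath, so the ODE is
integrated exactly breath interval by breath interval (exponential
update); the per-breath drive is the state at the breath START, i.e. the
drive commanding that breath.  During scored arousals an additional
wakefulness drive gamma is added to the chemical drive.

Fitting inverts this model: over a grid of (tau, delta) the unit-gain
filtered disturbance u_hat is computed once, and (G, gamma) are obtained
by non-negative linear least squares of

    ventilation ~ 100 + G * u_hat + gamma * A      (A = arousal indicator)

restricted to breaths outside scored respiratory events, where the
airway is assumed open and achieved ventilation reveals drive.  Loop
gain is then read off the fitted transfer function: LG1 at 1 cycle/min
and LGn at the natural frequency where the loop phase reaches -180 deg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import AnalysisError, InputError, InsufficientDataError
from .signals import NREM_STAGES, AnnotationSet, BreathRecord

__all__ = [
    "ChemoreflexParams",
    "DriveSeries",
    "FitResult",
    "NightDriveFit",
    "FitSettings",
    "filtered_disturbance",
    "chemoreflex_response",
    "fit_drive_span",
    "fit_drive_model",
    "loop_gain_magnitude",
    "natural_frequency",
    "lg1_lgn",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChemoreflexParams:
    """Fitted chemoreflex model: gain, time constant, delay, arousal drive."""

    gain_G: float
    tau_s: float
    delay_s: float
    arousal_gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.gain_G < 0:
            raise InputError("gain_G must be >= 0")
        if not self.tau_s > 0:
            raise InputError("tau_s must be > 0")
        if self.delay_s < 0:
            raise InputError("delay_s must be >= 0")
        if self.arousal_gamma < 0:
            raise InputError("arousal_gamma must be >= 0")


@dataclass
class DriveSeries:
    """Per-breath chemical and total ventilatory drive, %eupnea.

    total = chemical + arousal term on breaths within a scored arousal;
    both clamped at 0.
    """

    chemical: np.ndarray
    total: np.ndarray

    def __post_init__(self) -> None:
        self.chemical = np.asarray(self.chemical, dtype=float)
        self.total = np.asarray(self.total, dtype=float)
        if self.chemical.shape != self.total.shape:
            raise InputError("chemical and total drive must have equal length")
        if np.any(self.total < self.chemical - 1e-9):
            raise InputError("total drive must be >= chemical drive")

    def __len__(self) -> int:
        return self.chemical.size


@dataclass
class FitResult:
    """Outcome of fitting the chemoreflex model on one span of breaths."""

    params: ChemoreflexParams
    drive: DriveSeries
    sse: float
    n_fit_breaths: int
    identifiable: bool
    grid_trace: list[tuple[float, float, float]]  # (tau, delta, sse)
    t_start: float = np.nan
    t_end: float = np.nan
    fit_index: np.ndarray | None = None
    #: window-local eupneic ventilation (units/min) the fit was scaled to
    eupnea_abs: float = np.nan
    #: full-night ventilation on the window-local %eupnea scale
    vent_scaled: np.ndarray | None = None


@dataclass
class NightDriveFit:
    """Windowed night-level fit: per-window results plus median parameters."""

    params: ChemoreflexParams
    drive: DriveSeries
    windows: list[FitResult]
    n_fit_breaths: int
    identifiable: bool

    @property
    def sse(self) -> float:
        return float(sum(w.sse for w in self.windows))


@dataclass(frozen=True)
class FitSettings:
    """Grid, windowing and identifiability settings for the drive fit."""

    taus: tuple[float, ...] = tuple(float(v) for v in range(10, 185, 5))
    deltas: tuple[float, ...] = tuple(float(v) for v in range(2, 32, 2))
    window_length_s: float = 420.0
    window_step_s: float = 210.0
    min_fit_breaths: int = 10
    max_wake_fraction: float = 0.5
    tol_flat: float = 0.01
    var_min: float = 1.0
    f1_cpm: float = 1.0
    #: iterations of one-sided censoring of covertly obstructed breaths
    censor_iters: int = 5
    #: residual threshold (in upper-residual RMS units) below which a
    #: breath is treated as obstructed and dropped from the fit
    censor_k: float = 0.5


# ---------------------------------------------------------------------------
# the delayed first-order filter
# ---------------------------------------------------------------------------


def filtered_disturbance(
    t_starts: np.ndarray,
    t_ends: np.ndarray,
    vent_pct: np.ndarray,
    taus: np.ndarray,
    delay: float,
) -> np.ndarray:
    """Unit-gain filtered disturbance u_hat at breath starts.

    u(t) = 100 - vent(t - delay) with vent piecewise constant per breath
    and eupneic (100%) before the record, filtered through
    tau*y' + y = u by exact exponential updates.  Vectorized over ``taus``;
    returns an array of shape (len(taus), n_breaths).
    """
    t_starts = np.asarray(t_starts, dtype=float)
    t_ends = np.asarray(t_ends, dtype=float)
    vent = np.asarray(vent_pct, dtype=float)
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    n = t_starts.size
    if n == 0:
        return np.zeros((taus.size, 0))
    if np.any(np.diff(t_starts) <= 0) or np.any(t_ends <= t_starts):
        raise InputError("breath times must be strictly increasing and non-overlapping")
    if delay < 0:
        raise InputError("delay must be >= 0")

    # input step changes, shifted by the delay; u returns to 0 (eupnea)
    # across gaps between breaths and after the last breath
    change_t: list[float] = []
    change_u: list[float] = []
    for j in range(n):
        change_t.append(t_starts[j] + delay)
        change_u.append(100.0 - vent[j])
        gap = (j == n - 1) or (t_starts[j + 1] - t_ends[j] > 1e-9)
        if gap:
            change_t.append(t_ends[j] + delay)
            change_u.append(0.0)

    # merge queries (breath starts) and input changes in time order;
    # at ties the query is served first (y is continuous, u right-continuous)
    events = sorted(
        [(tq, 0, qi, 0.0) for qi, tq in enumerate(t_starts)]
        + [(tc, 1, -1, uc) for tc, uc in zip(change_t, change_u)]
    )
    out = np.zeros((taus.size, n))
    y = np.zeros(taus.size)
    u = 0.0
    t_cur = events[0][0]
    last_query = t_starts[-1]
    for tev, kind, qi, uval in events:
        if tev > last_query and kind == 1:
            break
        h = tev - t_cur
        if h > 0:
            y = u + (y - u) * np.exp(-h / taus)
            t_cur = tev
        if kind == 0:
            out[:, qi] = y
        else:
            u = uval
    return out


def chemoreflex_response(breaths: list[BreathRecord], params: ChemoreflexParams) -> np.ndarray:
    """Chemical drive (%eupnea) per breath under the delayed first-order model.

    The returned value for breath i is the model state at the breath
    start, clamped at 0.
    """
    t0 = np.array([b.t_start for b in breaths])
    t1 = np.array([b.t_end for b in breaths])
    v = np.array([b.ventilation_pct for b in breaths])
    if np.any(np.isnan(v)):
        raise InputError("ventilation_pct must be set on all breaths")
    u_hat = filtered_disturbance(t0, t1, v, np.array([params.tau_s]), params.delay_s)[0]
    return np.maximum(0.0, 100.0 + params.gain_G * u_hat)


def drive_series(
    breaths: list[BreathRecord], params: ChemoreflexParams, clamp: bool = True
) -> DriveSeries:
    """Chemical and total drive for a breath list under ``params``."""
    t0 = np.array([b.t_start for b in breaths])
    t1 = np.array([b.t_end for b in breaths])
    v = np.array([b.ventilation_pct for b in breaths])
    a = np.array([b.in_arousal for b in breaths], dtype=float)
    u_hat = filtered_disturbance(t0, t1, v, np.array([params.tau_s]), params.delay_s)[0]
    chem = 100.0 + params.gain_G * u_hat
    total = chem + params.arousal_gamma * a
    if clamp:
        chem = np.maximum(0.0, chem)
        total = np.maximum(0.0, total)
    return DriveSeries(chemical=chem, total=np.maximum(total, chem))


# ---------------------------------------------------------------------------
# non-negative least squares on two columns (exact active-set enumeration)
# ---------------------------------------------------------------------------


def nnls_intercept(
    u: np.ndarray, a: np.ndarray, y: np.ndarray
) -> tuple[float, float, float, float]:
    """Minimize ||y - b - G*u - g*a||^2 with G >= 0, g >= 0, b free.

    The unconstrained intercept is concentrated out by centering, leaving
    an exact two-variable non-negative least-squares problem; returns
    (b, G, g, sse).
    """
    um, am, ym = u.mean(), a.mean(), y.mean()
    G, g, sse = nnls_two_columns(u - um, a - am, y - ym)
    b = float(ym - G * um - g * am)
    return b, G, g, sse


def nnls_two_columns(u: np.ndarray, a: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Minimize ||y - G*u - g*a||^2 subject to G >= 0, g >= 0.

    With two variables the exact optimum is found by enumerating the four
    possible active sets; returns (G, g, sse).
    """
    yy = float(np.dot(y, y))
    best = (0.0, 0.0, yy)
    uu, aa, ua = float(np.dot(u, u)), float(np.dot(a, a)), float(np.dot(u, a))
    uy, ay = float(np.dot(u, y)), float(np.dot(a, y))
    cands: list[tuple[float, float]] = []
    det = uu * aa - ua * ua
    if det > 1e-12 * max(uu * aa, 1e-300):
        cands.append(((aa * uy - ua * ay) / det, (uu * ay - ua * uy) / det))
    if uu > 0:
        cands.append((uy / uu, 0.0))
    if aa > 0:
        cands.append((0.0, ay / aa))
    for G, g in cands:
        if G < 0 or g < 0:
            continue
        sse = yy - 2 * (G * uy + g * ay) + G * G * uu + 2 * G * g * ua + g * g * aa
        sse = max(0.0, sse)
        if sse < best[2] - 1e-12:
            best = (G, g, sse)
    return best


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _fit_arrays(breaths: list[BreathRecord]):
    t0 = np.array([b.t_start for b in breaths])
    t1 = np.array([b.t_end for b in breaths])
    v = np.array([b.ventilation_pct for b in breaths])
    a = np.array([b.in_arousal for b in breaths], dtype=float)
    if np.any(np.isnan(v)):
        raise InputError("ventilation_pct must be set on all breaths")
    return t0, t1, v, a


def fit_drive_span(
    breaths: list[BreathRecord],
    settings: FitSettings = FitSettings(),
    fit_mask: np.ndarray | None = None,
    u_grid: np.ndarray | None = None,
) -> FitResult:
    """Fit (G, tau, delta, gamma) on one span of breaths.

    The residual is scored only on breaths where ``fit_mask`` is true (by
    default: breaths not flagged ``in_event``); all breaths feed the
    filtered disturbance through their ventilation values.  ``u_grid`` may
    carry a precomputed disturbance grid of shape (n_delta, n_tau, n).
    """
    t0, t1, v, a = _fit_arrays(breaths)
    n = len(breaths)
    if fit_mask is None:
        fit_mask = ~np.array([b.in_event for b in breaths], dtype=bool)
    fit_mask = np.asarray(fit_mask, dtype=bool)
    m = int(fit_mask.sum())
    if m == 0:
        raise InsufficientDataError("insufficient unobstructed breaths (all breaths in events)")

    taus = np.asarray(settings.taus, dtype=float)
    deltas = np.asarray(settings.deltas, dtype=float)
    if u_grid is None:
        u_grid = disturbance_grid(t0, t1, v, settings)

    y = v[fit_mask] - 100.0
    a_fit = a[fit_mask]
    trace: list[tuple[float, float, float]] = []
    best = None  # (sse, di, ti, G, g)
    for di, delta in enumerate(deltas):
        for ti, tau in enumerate(taus):
            u_fit = u_grid[di, ti][fit_mask]
            G, g, sse = nnls_two_columns(u_fit, a_fit, y)
            trace.append((float(tau), float(delta), float(sse)))
            if best is None or sse < best[0] - 1e-12:
                best = (sse, di, ti, G, g)
    assert best is not None
    sse, di, ti, G, g = best
    params = ChemoreflexParams(
        gain_G=float(G),
        tau_s=float(taus[ti]),
        delay_s=float(deltas[di]),
        arousal_gamma=float(g),
    )
    u_best = u_grid[di, ti]
    chem = 100.0 + params.gain_G * u_best
    total = chem + params.arousal_gamma * a
    drive = DriveSeries(
        chemical=np.maximum(0.0, chem), total=np.maximum(np.maximum(0.0, total), np.maximum(0.0, chem))
    )

    sses = np.array([s for _, _, s in trace])
    flat = (sses.max() - sses.min()) < settings.tol_flat * max(sses.min(), 1e-12)
    low_var = float(np.var(u_best[fit_mask])) < settings.var_min
    return FitResult(
        params=params,
        drive=drive,
        sse=float(sse),
        n_fit_breaths=m,
        identifiable=not (flat or low_var),
        grid_trace=trace,
        t_start=float(t0[0]),
        t_end=float(t1[-1]),
        fit_index=np.flatnonzero(fit_mask),
    )


def disturbance_grid(
    t0: np.ndarray, t1: np.ndarray, v: np.ndarray, settings: FitSettings
) -> np.ndarray:
    """Precompute u_hat for every (delta, tau) grid point: (n_delta, n_tau, n)."""
    taus = np.asarray(settings.taus, dtype=float)
    deltas = np.asarray(settings.deltas, dtype=float)
    out = np.empty((deltas.size, taus.size, t0.size))
    for di, delta in enumerate(deltas):
        out[di] = filtered_disturbance(t0, t1, v, taus, float(delta))
    return out


def nrem_windows(
    annotations: AnnotationSet, settings: FitSettings
) -> list[tuple[float, float]]:
    """7-min analysis windows advanced by half a window over contiguous NREM."""
    from .signals import EPOCH_S

    segs: list[tuple[float, float]] = []
    cur: tuple[float, float] | None = None
    for ep in annotations.epochs:
        if ep.stage in NREM_STAGES:
            if cur is not None and abs(ep.onset - cur[1]) < 1e-6:
                cur = (cur[0], ep.onset + EPOCH_S)
            else:
                if cur is not None:
                    segs.append(cur)
                cur = (ep.onset, ep.onset + EPOCH_S)
        else:
            if cur is not None:
                segs.append(cur)
                cur = None
    if cur is not None:
        segs.append(cur)

    L, step = settings.window_length_s, settings.window_step_s
    windows: list[tuple[float, float]] = []
    for s0, s1 in segs:
        start = s0
        while start + L <= s1 + 1e-6:
            windows.append((start, start + L))
            start += step
    return windows


def fit_drive_model(
    breaths: list[BreathRecord],
    annotations: AnnotationSet,
    settings: FitSettings = FitSettings(),
) -> NightDriveFit:
    """Windowed night-level drive fit.

    Contiguous NREM sleep is split into overlapping windows; a window is
    fitted when it contains at least one scored respiratory event, at
    least ``min_fit_breaths`` unobstructed breaths and less than 50% wake.

    Each window's regression carries a free eupneic intercept b
    (ventilation ~ b + G*u_hat + gamma*A), which absorbs the local
    baseline and, inverted through the model, yields the window's
    implied true-eupnea scale mu = 100*(1+G)/(b+100*G); ventilation and
    drive are rescaled by mu so traits refer to model-implied eupnea
    rather than the raw local mean.  Because achieved ventilation can
    only fall below intended ventilation, breaths whose residual is
    strongly negative (covert flow limitation without a scorable event)
    are iteratively censored and the window refitted — an upper-envelope
    fit.  Night-level parameters are the medians of the per-window
    parameters and the night drive series is computed from them.
    """
    t0 = np.array([b.t_start for b in breaths])
    t1 = np.array([b.t_end for b in breaths])
    vabs = np.array([b.ventilation_abs for b in breaths])
    a = np.array([b.in_arousal for b in breaths], dtype=float)
    if np.any(np.isnan(vabs)):
        raise InputError("ventilation_abs must be set on all breaths")
    mids = 0.5 * (t0 + t1)
    durs = t1 - t0
    # fit eligibility: a breath is scored against the model when the
    # majority of it (its midpoint) lies outside every scored event; a
    # breath that merely brushes an event boundary is still informative
    # (the first recovery breath carries most of the dynamic signal)
    in_event = np.zeros(len(breaths), dtype=bool)
    for e in annotations.resp_events:
        in_event |= (mids >= e.onset) & (mids < e.end)

    # night-scale ventilation and its filtered disturbance, computed once;
    # the free per-window intercept absorbs any constant rescaling, so the
    # same disturbance grid serves every window
    m_night = float(np.dot(vabs, durs) / durs.sum())
    if m_night <= 0:
        raise InputError("mean ventilation is zero; nothing to fit")
    q = 100.0 * vabs / m_night
    taus = np.asarray(settings.taus, dtype=float)
    deltas = np.asarray(settings.deltas, dtype=float)
    u_grid = disturbance_grid(t0, t1, q, settings)

    windows = nrem_windows(annotations, settings)
    ev_iv = [(e.onset, e.end) for e in annotations.resp_events]
    results: list[FitResult] = []
    for w0, w1 in windows:
        idx = (mids >= w0) & (mids < w1)
        has_event = any(on < w1 and off > w0 for on, off in ev_iv)
        fit_mask0 = idx & ~in_event
        m0 = int(fit_mask0.sum())
        if not has_event or m0 < settings.min_fit_breaths or not idx.any():
            continue
        fit_mask = fit_mask0
        trace: list[tuple[float, float, float]] = []
        best = None
        for it in range(max(1, settings.censor_iters)):
            a_fit = a[fit_mask]
            y_fit = q[fit_mask]
            trace = []
            best = None
            for di in range(deltas.size):
                for ti in range(taus.size):
                    b, G, g, sse = nnls_intercept(u_grid[di, ti][fit_mask], a_fit, y_fit)
                    trace.append((float(taus[ti]), float(deltas[di]), float(sse)))
                    if best is None or sse < best[0] - 1e-12:
                        best = (sse, di, ti, b, G, g)
            sse, di, ti, b, G, g = best
            if it == settings.censor_iters - 1:
                break
            # censor covertly obstructed breaths: achieved ventilation can
            # only fall below intended, so strongly negative residuals mark
            # flow limitation that was never scored as an event
            r = q - (b + G * u_grid[di, ti] + g * a)
            pos = r[fit_mask][r[fit_mask] > 0]
            sigma = float(np.sqrt(np.mean(pos**2))) if pos.size > 3 else float(np.std(r[fit_mask]))
            new_mask = fit_mask0 & (r > -settings.censor_k * max(sigma, 1e-6))
            if int(new_mask.sum()) < settings.min_fit_breaths or np.array_equal(new_mask, fit_mask):
                break
            fit_mask = new_mask
        sse, di, ti, b, G, g = best
        # the free eupneic intercept implies the true-eupnea scale: if the
        # night mean sits at a fraction mu of true eupnea, the model gives
        # b = 100*(1 + G*(1 - mu))/mu, hence mu = 100*(1+G)/(b + 100*G)
        denom = b + 100.0 * G
        mu = 100.0 * (1.0 + G) / denom if denom > 0 else 1.0
        mu = float(np.clip(mu, 0.4, 2.5))
        params = ChemoreflexParams(
            gain_G=float(G),
            tau_s=float(taus[ti]),
            delay_s=float(deltas[di]),
            arousal_gamma=float(mu * g),
        )
        chem = mu * (b + G * u_grid[di, ti])  # estimated true %eupnea
        total = chem + params.arousal_gamma * a
        drive = DriveSeries(
            chemical=np.maximum(0.0, chem),
            total=np.maximum(np.maximum(0.0, total), np.maximum(0.0, chem)),
        )
        sses = np.array([s for _, _, s in trace])
        flat = (sses.max() - sses.min()) < settings.tol_flat * max(sses.min(), 1e-12)
        low_var = float(np.var(u_grid[di, ti][fit_mask])) < settings.var_min
        results.append(
            FitResult(
                params=params,
                drive=drive,
                sse=float(sse),
                n_fit_breaths=int(fit_mask.sum()),
                identifiable=not (flat or low_var),
                grid_trace=trace,
                t_start=w0,
                t_end=w1,
                fit_index=np.flatnonzero(fit_mask),
                eupnea_abs=m_night / mu,
                vent_scaled=mu * q,
            )
        )
    if not results:
        raise InsufficientDataError(
            "insufficient unobstructed breaths: no analyzable NREM window "
            f"(of {len(windows)} candidate windows)"
        )

    med = lambda xs: float(np.median(np.asarray(xs)))
    night_params = ChemoreflexParams(
        gain_G=med([r.params.gain_G for r in results]),
        tau_s=med([r.params.tau_s for r in results]),
        delay_s=med([r.params.delay_s for r in results]),
        arousal_gamma=med([r.params.arousal_gamma for r in results]),
    )
    night_drive = drive_series(breaths, night_params)
    return NightDriveFit(
        params=night_params,
        drive=night_drive,
        windows=results,
        n_fit_breaths=int(sum(r.n_fit_breaths for r in results)),
        identifiable=any(r.identifiable for r in results),
    )


# ---------------------------------------------------------------------------
# loop gain
# ---------------------------------------------------------------------------


def loop_gain_magnitude(params: ChemoreflexParams, f_hz: float) -> float:
    """|G / (1 + i 2 pi f tau)| — amplitude ratio of drive to ventilation."""
    if not f_hz > 0:
        raise InputError("frequency must be > 0")
    return params.gain_G / math.sqrt(1.0 + (2.0 * math.pi * f_hz * params.tau_s) ** 2)


def natural_frequency(params: ChemoreflexParams) -> float:
    """Frequency (cycles/min) where the loop phase lag reaches 180 degrees.

    Solves arctan(2 pi f tau) + 2 pi f delta = pi; the left side is
    strictly increasing in f so the root is unique.  Requires delay > 0
    (a pure first-order lag never reaches -180 deg).
    """
    if params.delay_s <= 0:
        raise AnalysisError("no phase crossing: delay_s must be > 0")
    tau, delta = params.tau_s, params.delay_s

    def phase_deficit(f: float) -> float:
        return math.atan(2 * math.pi * f * tau) + 2 * math.pi * f * delta - math.pi

    hi = 0.5 / delta  # 2 pi f delta = pi, so phase_deficit(hi) >= 0
    fn_hz = brentq(phase_deficit, 1e-12, hi, xtol=1e-16, rtol=4 * np.finfo(float).eps)
    return float(fn_hz) * 60.0


def lg1_lgn(params: ChemoreflexParams, f1_cpm: float = 1.0) -> tuple[float, float]:
    """Loop gain at ``f1_cpm`` cycles/min (LG1) and at the natural frequency (LGn)."""
    lg1 = loop_gain_magnitude(params, f1_cpm / 60.0)
    fn_cpm = natural_frequency(params)
    lgn = loop_gain_magnitude(params, fn_cpm / 60.0)
    return lg1, lgn
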