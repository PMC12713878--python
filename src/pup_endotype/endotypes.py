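"""Endogram construction and the four endotypic traits.

The endogram summarizes pharyngeal behaviour over a study as a curve of
median ventilation versus median ventilatory drive, built by binning
breaths into equal-count drive-percentile bins.  From it the traits are
read: Vpassive (ventilation at eupneic, 100%, drive — collapsibility),
Vactive (ventilation at the arousal-threshold drive), compensation
(Vactive - Vpassive), and Vmin (median ventilation in the lowest drive
decile, a collapsibility measure insensitive to systematic drive bias).
The arousal threshold itself is the chemical drive immediately preceding
scored arousals, and loop gain (LG1/LGn) comes from the fitted
chemoreflex model.  Night-level values are medians across analysis
windows with bootstrap confidence intervals, and can be classified
against published cohort tertiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .drivefit import DriveSeries, FitResult, lg1_lgn
from .errors import AnalysisError, InputError
from .signals import APNEA_TYPES, NREM_STAGES, AnnotationSet, Arousal, BreathRecord

TRAITS = ("vpassive", "vmin", "vactive", "compensation", "arousal_threshold", "lg1", "lgn")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Endogram:
    """Binned median ventilation-vs-drive curve (drive-percentile bins)."""

    drive_median: np.ndarray
    vent_median: np.ndarray
    n_breaths: np.ndarray

    def __post_init__(self) -> None:
        self.drive_median = np.asarray(self.drive_median, dtype=float)
        self.vent_median = np.asarray(self.vent_median, dtype=float)
        self.n_breaths = np.asarray(self.n_breaths, dtype=int)
        if not (self.drive_median.size == self.vent_median.size == self.n_breaths.size):
            raise InputError("endogram columns must have equal length")
        if self.drive_median.size and np.any(np.diff(self.drive_median) <= 0):
            raise InputError("endogram drive medians must be strictly increasing")

    def __len__(self) -> int:
        return self.drive_median.size


@dataclass
class EndotypeSet:
    """The endotypic traits for one window or one night (all %eupnea except LG)."""

    vpassive: float = np.nan
    vmin: float = np.nan
    vactive: float = np.nan
    compensation: float = np.nan
    arousal_threshold: float = np.nan
    lg1: float = np.nan
    lgn: float = np.nan
    flags: list[str] = field(default_factory=list)
    per_window: list["EndotypeSet"] | None = None
    ci95: dict[str, tuple[float, float]] | None = None

    def as_dict(self) -> dict[str, float]:
        return {t: float(getattr(self, t)) for t in TRAITS}


@dataclass(frozen=True)
class ReferenceTertiles:
    """Published 33rd/66th percentile trait boundaries for a cohort."""

    cohort: str
    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for trait, (p33, p66) in self.bounds.items():
            if p33 > p66:
                raise InputError(f"{self.cohort}/{trait}: p33 must be <= p66")


@dataclass
class SurrogateIndices:
    """Simple polysomnography-report surrogates of the endotypic traits."""

    ahi: float
    f_hypopnea: float
    mean_oa_duration: float
    nrem_oai_over_nrem_ahi: float
    rem_ahi_over_nrem_ahi: float
    flags: list[str] = field(default_factory=list)


@dataclass
class ArousalThresholdResult:
    """Median pre-arousal chemical drive with per-arousal values."""

    value: float
    per_arousal: np.ndarray
    n_used: int
    defined: bool


# ---------------------------------------------------------------------------
# endogram
# ---------------------------------------------------------------------------


def default_n_bins(n_breaths: int, n_bins: int = 100) -> int:
    """Centile bins for >= 1000 breaths, else coarser equal-count bins."""
    if n_breaths >= 1000:
        return n_bins
    return max(1, min(n_breaths, max(10, n_breaths // 10)))


def build_endogram(
    vent_pct: np.ndarray,
    total_drive: np.ndarray,
    n_bins: int | None = None,
) -> Endogram:
    """Bin breaths into equal-count drive bins; median (drive, vent) per bin.

    Breaths are ordered lexicographically by (drive, ventilation) so the
    endogram is invariant under permutation of the input, including ties.
    Adjacent bins with identical drive medians are merged.
    """
    vent = np.asarray(vent_pct, dtype=float)
    drive = np.asarray(total_drive, dtype=float)
    if vent.size != drive.size:
        raise InputError("ventilation and drive must be aligned")
    n = vent.size
    if n == 0:
        raise AnalysisError("empty endogram: no breaths in scope")
    if n_bins is None:
        n_bins = default_n_bins(n)
    n_bins = min(n_bins, n)

    order = np.lexsort((vent, drive))
    d_sorted, v_sorted = drive[order], vent[order]
    chunks = np.array_split(np.arange(n), n_bins)

    dm = [float(np.median(d_sorted[c])) for c in chunks]
    vm = [float(np.median(v_sorted[c])) for c in chunks]
    counts = [int(c.size) for c in chunks]

    # merge bins whose drive medians coincide (ties in drive)
    out_d: list[float] = []
    out_v: list[float] = []
    out_n: list[int] = []
    members: list[np.ndarray] = []
    for c, d in zip(chunks, dm):
        if out_d and d <= out_d[-1]:
            members[-1] = np.concatenate([members[-1], c])
            out_d[-1] = float(np.median(d_sorted[members[-1]]))
            out_v[-1] = float(np.median(v_sorted[members[-1]]))
            out_n[-1] = int(members[-1].size)
        else:
            members.append(c)
            out_d.append(d)
            out_v.append(float(np.median(v_sorted[c])))
            out_n.append(int(c.size))
    return Endogram(np.array(out_d), np.array(out_v), np.array(out_n))


def ventilation_at_drive(endogram: Endogram, drive_level: float) -> tuple[float, bool]:
    """Interpolate the endogram at a drive level; clamp and flag outside it."""
    if len(endogram) == 0:
        raise AnalysisError("empty endogram")
    value = float(np.interp(drive_level, endogram.drive_median, endogram.vent_median))
    extrapolated = bool(
        drive_level < endogram.drive_median[0] or drive_level > endogram.drive_median[-1]
    )
    return value, extrapolated


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------


def arousal_threshold(
    drive: DriveSeries,
    breaths: list[BreathRecord],
    arousals: list[Arousal],
    min_arousals: int = 5,
    max_gap_s: float = 30.0,
) -> ArousalThresholdResult:
    """Median chemical drive immediately preceding scored arousals.

    For each arousal the drive is read from the breath containing the
    arousal onset (the per-breath drive is attributed at the breath start,
    i.e. before the onset); if no breath contains it, the last breath
    ending within ``max_gap_s`` before the onset is used, otherwise the
    arousal is skipped.  The trait is undefined (flagged) with fewer than
    ``min_arousals`` usable arousals.
    """
    if len(drive) != len(breaths):
        raise InputError("drive series and breath list must be aligned")
    starts = np.array([b.t_start for b in breaths])
    ends = np.array([b.t_end for b in breaths])
    values: list[float] = []
    for ar in arousals:
        i = int(np.searchsorted(starts, ar.onset, side="right")) - 1
        if i >= 0 and ends[i] > ar.onset:
            values.append(float(drive.chemical[i]))
            continue
        # fallback: last breath fully ending before the onset
        j = int(np.searchsorted(ends, ar.onset, side="right")) - 1
        if j >= 0 and ar.onset - ends[j] <= max_gap_s:
            values.append(float(drive.chemical[j]))
    arr = np.asarray(values, dtype=float)
    defined = arr.size >= min_arousals
    return ArousalThresholdResult(
        value=float(np.median(arr)) if defined else float("nan"),
        per_arousal=arr,
        n_used=int(arr.size),
        defined=defined,
    )


def compute_traits(
    endogram: Endogram,
    arth: ArousalThresholdResult,
    drive: DriveSeries,
    vent_pct: np.ndarray,
    fit: FitResult | None = None,
    vmin_quantile: float = 0.10,
    f1_cpm: float = 1.0,
) -> EndotypeSet:
    """Assemble one EndotypeSet from an endogram, drive and fitted model.

    vactive = vpassive + compensation holds exactly by construction.
    """
    vent = np.asarray(vent_pct, dtype=float)
    flags: list[str] = []

    vpassive, ex_p = ventilation_at_drive(endogram, 100.0)
    if ex_p:
        flags.append("vpassive extrapolated beyond endogram range")

    if arth.defined:
        vactive, ex_a = ventilation_at_drive(endogram, arth.value)
        vactive = max(0.0, vactive)
        if ex_a:
            flags.append("vactive extrapolated beyond endogram range")
        compensation = vactive - vpassive
    else:
        vactive = float("nan")
        compensation = float("nan")
        flags.append(f"arousal threshold undefined ({arth.n_used} usable arousals)")

    # Vmin: median ventilation within the lowest drive decile
    k = max(1, int(np.ceil(vmin_quantile * len(drive))))
    low = np.argsort(drive.total, kind="stable")[:k]
    vmin = float(np.median(vent[low]))

    lg1 = lgn = float("nan")
    if fit is not None:
        if not fit.identifiable:
            flags.append("drive model not identifiable; loop gain undefined")
        elif fit.params.delay_s > 0:
            lg1, lgn = lg1_lgn(fit.params, f1_cpm=f1_cpm)
        else:
            flags.append("no natural frequency: fitted delay is zero")

    return EndotypeSet(
        vpassive=float(vpassive),
        vmin=vmin,
        vactive=float(vactive),
        compensation=float(compensation),
        arousal_threshold=float(arth.value),
        lg1=float(lg1),
        lgn=float(lgn),
        flags=flags,
    )


def aggregate_night(
    window_sets: list[EndotypeSet],
    seed: int = 0,
    n_boot: int = 1000,
) -> EndotypeSet:
    """Night-level traits: per-trait median over valid windows, bootstrap CI.

    The confidence interval is the 2.5/97.5 percentile of the bootstrap
    distribution (windows resampled with replacement) of the median.
    Night compensation is recomputed as vactive - vpassive so the trait
    identity holds exactly after aggregation.
    """
    if not window_sets:
        raise AnalysisError("no valid analysis windows: cannot aggregate night")
    rng = np.random.default_rng(seed)
    night = EndotypeSet(per_window=window_sets, ci95={})
    flags: list[str] = []
    for trait in TRAITS:
        vals = np.array(
            [getattr(w, trait) for w in window_sets if np.isfinite(getattr(w, trait))]
        )
        if vals.size == 0:
            flags.append(f"{trait} undefined in all windows")
            night.ci95[trait] = (float("nan"), float("nan"))
            continue
        med = float(np.median(vals))
        setattr(night, trait, med)
        if vals.size == 1:
            night.ci95[trait] = (med, med)
            flags.append(f"{trait}: single window, degenerate confidence interval")
        else:
            boots = np.median(
                vals[rng.integers(0, vals.size, size=(n_boot, vals.size))], axis=1
            )
            lo, hi = np.percentile(boots, [2.5, 97.5])
            night.ci95[trait] = (float(lo), float(hi))
    if np.isfinite(night.vactive) and np.isfinite(night.vpassive):
        night.compensation = night.vactive - night.vpassive
    night.flags = flags
    return night


def classify_traits(night: EndotypeSet, ref: ReferenceTertiles) -> dict[str, str]:
    """Label each trait low/moderate/high against cohort tertiles.

    Values exactly at a boundary are moderate; undefined traits are "n/a".
    """
    labels: dict[str, str] = {}
    for trait in TRAITS:
        value = getattr(night, trait)
        if trait not in ref.bounds or not np.isfinite(value):
            labels[trait] = "n/a"
            continue
        p33, p66 = ref.bounds[trait]
        if value < p33:
            labels[trait] = "low"
        elif value <= p66:
            labels[trait] = "moderate"
        else:
            labels[trait] = "high"
    return labels


# ---------------------------------------------------------------------------
# polysomnography-report surrogates
# ---------------------------------------------------------------------------


def surrogate_indices(
    annotations: AnnotationSet, total_sleep_time_s: float | None = None
) -> SurrogateIndices:
    """AHI, F_hypopnea, obstructive-apnea duration and stage-restricted ratios.

    Events are attributed to REM or NREM by their larger epoch overlap.
    Low F_hypopnea and long obstructive apneas indicate greater
    collapsibility; a high NREM/REM AHI ratio indicates higher loop gain.
    """
    from .signals import EPOCH_S

    if total_sleep_time_s is None:
        total_sleep_time_s = annotations.total_sleep_time_s()
    if not total_sleep_time_s > 0:
        raise InputError("total sleep time must be > 0")
    tst_h = total_sleep_time_s / 3600.0
    flags: list[str] = []

    events = annotations.resp_events
    n_ap = sum(1 for e in events if e.kind in APNEA_TYPES)
    n_hyp = sum(1 for e in events if e.kind == "hypopnea")
    n_tot = n_ap + n_hyp
    ahi = n_tot / tst_h
    if n_tot > 0:
        f_hyp = n_hyp / n_tot
    else:
        f_hyp = float("nan")
        flags.append("no respiratory events: F_hypopnea undefined")

    oa_durs = [e.duration for e in events if e.kind == "obstructive_apnea"]
    if oa_durs:
        mean_oa = float(np.mean(oa_durs))
    else:
        mean_oa = float("nan")
        flags.append("no obstructive apneas: mean duration undefined")

    def overlap_with(event: "RespEvent", stages: tuple[str, ...]) -> float:  # noqa: F821
        total = 0.0
        for ep in annotations.epochs:
            if ep.stage in stages:
                total += max(
                    0.0, min(event.end, ep.onset + EPOCH_S) - max(event.onset, ep.onset)
                )
        return total

    nrem_h = annotations.stage_time_s(NREM_STAGES) / 3600.0
    rem_h = annotations.stage_time_s(("R",)) / 3600.0
    nrem_ev = nrem_oa = rem_ev = 0
    for e in events:
        in_nrem = overlap_with(e, NREM_STAGES)
        in_rem = overlap_with(e, ("R",))
        if in_rem > in_nrem:
            rem_ev += 1
        else:
            nrem_ev += 1
            if e.kind == "obstructive_apnea":
                nrem_oa += 1

    nrem_ahi = nrem_ev / nrem_h if nrem_h > 0 else float("nan")
    nrem_oai = nrem_oa / nrem_h if nrem_h > 0 else float("nan")
    rem_ahi = rem_ev / rem_h if rem_h > 0 else float("nan")

    if np.isfinite(nrem_ahi) and nrem_ahi > 0:
        oai_ratio = nrem_oai / nrem_ahi
    else:
        oai_ratio = float("nan")
        flags.append("NREM AHI zero or undefined: OAI/AHI ratio undefined")
    if rem_h > 0 and np.isfinite(nrem_ahi) and nrem_ahi > 0:
        rem_ratio = rem_ahi / nrem_ahi
    else:
        rem_ratio = float("nan")
        flags.append("no REM sleep or zero NREM AHI: REM/NREM AHI ratio undefined")

    return SurrogateIndices(
        ahi=float(ahi),
        f_hypopnea=float(f_hyp),
        mean_oa_duration=mean_oa,
        nrem_oai_over_nrem_ahi=float(oai_ratio),
        rem_ahi_over_nrem_ahi=float(rem_ratio),
        flags=flags,
    )
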