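"""End-to-end analysis: flow + annotations -> night endotype report.

The pipeline chains the modules: breath segmentation and ventilation
normalization (signals), windowed chemoreflex-model fitting (drivefit),
endogram construction, trait extraction and night aggregation
(endotypes), and optional classification against a reference cohort.
The run is deterministic given the inputs, the configuration and the
seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .drivefit import DriveSeries, FitSettings, drive_series, fit_drive_model
from .endotypes import (
    EndotypeSet,
    TRAITS,
    arousal_threshold,
    build_endogram,
    classify_traits,
    compute_traits,
    surrogate_indices,
)
from .errors import InputError
from .io import read_annotations, read_flow, sha256_of
from .reference import COHORT_TERTILES
from .signals import (
    NREM_STAGES,
    AnnotationSet,
    FlowTrace,
    assign_context,
    compute_ventilation,
    normalize_to_eupnea,
    segment_breaths,
)

logger = logging.getLogger("pup_endotype")


@dataclass(frozen=True)
class AnalysisParams:
    """All tunable analysis parameters with their defaults."""

    smooth_s: float = 2.0
    min_breath_s: float = 1.5
    max_breath_s: float = 12.0
    eupnea_window_s: float = 420.0
    fit: FitSettings = field(default_factory=FitSettings)
    n_bins: int = 100
    vmin_quantile: float = 0.10
    min_arousals: int = 5
    min_arousals_window: int = 3
    post_arousal_exclusion_s: float = 10.0
    n_boot: int = 1000

    @classmethod
    def from_config(cls, cfg: dict) -> "AnalysisParams":
        """Build from a (possibly nested) configuration mapping.

        Recognized nested keys: ``grid.tau_s``, ``grid.delay_s``,
        ``window.length_s``, ``window.step_s``, ``window.min_fit_breaths``,
        ``lg.f1_cpm`` plus any flat field name of this dataclass.
        """
        fit_kwargs = {}
        grid = cfg.get("grid", {})
        if "tau_s" in grid:
            fit_kwargs["taus"] = tuple(float(v) for v in grid["tau_s"])
        if "delay_s" in grid:
            fit_kwargs["deltas"] = tuple(float(v) for v in grid["delay_s"])
        window = cfg.get("window", {})
        if "length_s" in window:
            fit_kwargs["window_length_s"] = float(window["length_s"])
        if "step_s" in window:
            fit_kwargs["window_step_s"] = float(window["step_s"])
        if "min_fit_breaths" in window:
            fit_kwargs["min_fit_breaths"] = int(window["min_fit_breaths"])
        lg = cfg.get("lg", {})
        if "f1_cpm" in lg:
            fit_kwargs["f1_cpm"] = float(lg["f1_cpm"])
        flat = {
            k: v
            for k, v in cfg.items()
            if k in {f for f in cls.__dataclass_fields__ if f != "fit"}
        }
        return cls(fit=FitSettings(**fit_kwargs), **flat)


@dataclass
class RunConfig:
    """One pipeline run: input paths, cohort, seed and parameter overrides."""

    flow_path: str | Path
    annotations_path: str | Path
    cohort: str | None = None
    flow_channel: str = "Flow"
    check_filters: bool = False
    seed: int = 0
    params: AnalysisParams = field(default_factory=AnalysisParams)
    config_echo: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cohort is not None and self.cohort not in COHORT_TERTILES:
            raise InputError(
                f"unknown cohort {self.cohort!r}; choose one of {sorted(COHORT_TERTILES)}"
            )


@dataclass
class Report:
    """The analysis result as a JSON-serializable night report."""

    body: dict

    def to_json(self) -> str:
        return json.dumps(self.body, indent=2, sort_keys=True, allow_nan=False)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _round(x: float, nd: int = 1):
    """Round for the report; non-finite values serialize as null."""
    if x is None or not np.isfinite(x):
        return None
    return round(float(x), nd)


def analyze_recording(
    flow: FlowTrace,
    annotations: AnnotationSet,
    params: AnalysisParams = AnalysisParams(),
    seed: int = 0,
    cohort: str | None = None,
) -> dict:
    """Run the full analysis on in-memory inputs; returns the report body."""
    warnings_out: list[str] = []

    breaths = segment_breaths(
        flow,
        min_breath_s=params.min_breath_s,
        max_breath_s=params.max_breath_s,
        smooth_s=params.smooth_s,
    )
    compute_ventilation(breaths)
    normalize_to_eupnea(breaths, window_s=params.eupnea_window_s)
    assign_context(breaths, annotations)
    logger.info("segmented %d breaths", len(breaths))

    night_fit = fit_drive_model(breaths, annotations, params.fit)
    logger.info(
        "fitted %d window(s); night params G=%.2f tau=%.0f delay=%.0f gamma=%.1f",
        len(night_fit.windows),
        night_fit.params.gain_G,
        night_fit.params.tau_s,
        night_fit.params.delay_s,
        night_fit.params.arousal_gamma,
    )

    mids = np.array([b.midpoint for b in breaths])
    vent = np.array([b.ventilation_pct for b in breaths])
    nrem = np.array([b.stage in NREM_STAGES for b in breaths], dtype=bool)

    # endogram scope: sleeping breaths only — outside scored arousals and
    # outside the brief post-arousal recovery during which the airway is
    # still held open by the preceding arousal (hyperpneic, V tracks drive)
    in_arousal = np.array([b.in_arousal for b in breaths], dtype=bool)
    post_ar = np.zeros(len(breaths), dtype=bool)
    for ar in annotations.arousals:
        post_ar |= (mids >= ar.end) & (mids < ar.end + params.post_arousal_exclusion_s)
    sleeping = ~in_arousal & ~post_ar

    window_sets: list[EndotypeSet] = []
    window_rows: list[dict] = []
    for wfit in night_fit.windows:
        idx = (mids >= wfit.t_start) & (mids < wfit.t_end) & nrem
        w_breaths = [b for b, keep in zip(breaths, idx) if keep]
        if not w_breaths:
            continue
        # ventilation and drive on the window-local %eupnea scale of the fit
        w_drive = DriveSeries(
            chemical=wfit.drive.chemical[idx], total=wfit.drive.total[idx]
        )
        w_vent = wfit.vent_scaled[idx]
        asleep = sleeping[idx]
        if not asleep.any():
            continue
        endo = build_endogram(w_vent[asleep], w_drive.total[asleep])
        w_arousals = [
            a for a in annotations.arousals if wfit.t_start <= a.onset < wfit.t_end
        ]
        arth = arousal_threshold(
            w_drive, w_breaths, w_arousals, min_arousals=params.min_arousals_window
        )
        traits = compute_traits(
            endo,
            arth,
            DriveSeries(chemical=w_drive.chemical[asleep], total=w_drive.total[asleep]),
            w_vent[asleep],
            fit=wfit,
            vmin_quantile=params.vmin_quantile,
            f1_cpm=params.fit.f1_cpm,
        )
        window_sets.append(traits)
        window_rows.append(
            {
                "t_start": wfit.t_start,
                "t_end": wfit.t_end,
                "traits": {t: _round(getattr(traits, t), 3) for t in TRAITS},
                "fit": {
                    "gain_G": round(wfit.params.gain_G, 4),
                    "tau_s": wfit.params.tau_s,
                    "delay_s": wfit.params.delay_s,
                    "arousal_gamma": round(wfit.params.arousal_gamma, 4),
                    "sse": round(wfit.sse, 4),
                    "n_fit_breaths": wfit.n_fit_breaths,
                    "identifiable": wfit.identifiable,
                },
                "flags": traits.flags,
            }
        )

    from .endotypes import aggregate_night

    night = aggregate_night(window_sets, seed=seed, n_boot=params.n_boot)
    warnings_out.extend(night.flags)

    # whole-night NREM endogram (sleeping breaths) under the night-median
    # parameters
    scope = nrem & sleeping
    if scope.any():
        nrem_breaths = [b for b, keep in zip(breaths, scope) if keep]
        night_drive = drive_series(nrem_breaths, night_fit.params)
        night_endo = build_endogram(vent[scope], night_drive.total, n_bins=params.n_bins)
        endo_rows = [
            {"drive_median": round(d, 2), "vent_median": round(v, 2), "n": int(c)}
            for d, v, c in zip(
                night_endo.drive_median, night_endo.vent_median, night_endo.n_breaths
            )
        ]
    else:
        endo_rows = []
        warnings_out.append("no NREM breaths: night endogram empty")

    labels = None
    if cohort is not None:
        labels = classify_traits(night, COHORT_TERTILES[cohort])

    surr = surrogate_indices(annotations)
    warnings_out.extend(surr.flags)

    lg_decimals = 3
    night_traits = {
        t: _round(getattr(night, t), lg_decimals if t in ("lg1", "lgn") else 1)
        for t in TRAITS
    }
    ci95 = {
        t: [
            _round(night.ci95[t][0], lg_decimals if t in ("lg1", "lgn") else 1),
            _round(night.ci95[t][1], lg_decimals if t in ("lg1", "lgn") else 1),
        ]
        for t in TRAITS
    }

    return {
        "metadata": {"version": __version__, "seed": seed, "config": {}, "inputs": {}},
        "night": {
            "traits": night_traits,
            "ci95": ci95,
            "labels": labels,
            "cohort": cohort,
            "fit_params": {
                "gain_G": round(night_fit.params.gain_G, 4),
                "tau_s": night_fit.params.tau_s,
                "delay_s": night_fit.params.delay_s,
                "arousal_gamma": round(night_fit.params.arousal_gamma, 4),
                "identifiable": night_fit.identifiable,
            },
        },
        "per_window": window_rows,
        "endogram": endo_rows,
        "surrogate_indices": {
            "ahi": _round(surr.ahi, 2),
            "f_hypopnea": _round(surr.f_hypopnea, 3),
            "mean_oa_duration": _round(surr.mean_oa_duration, 1),
            "nrem_oai_over_nrem_ahi": _round(surr.nrem_oai_over_nrem_ahi, 3),
            "rem_ahi_over_nrem_ahi": _round(surr.rem_ahi_over_nrem_ahi, 3),
        },
        "warnings": warnings_out,
    }


def run_pipeline(cfg: RunConfig) -> Report:
    """File-based entry point: read inputs, analyze, assemble the report."""
    flow = read_flow(cfg.flow_path, channel=cfg.flow_channel, check_filters=cfg.check_filters)
    annotations = read_annotations(cfg.annotations_path)
    body = analyze_recording(
        flow, annotations, params=cfg.params, seed=cfg.seed, cohort=cfg.cohort
    )
    body["metadata"]["config"] = cfg.config_echo
    body["metadata"]["inputs"] = {
        "flow": {"path": str(cfg.flow_path), "sha256": sha256_of(cfg.flow_path)},
        "annotations": {
            "path": str(cfg.annotations_path),
            "sha256": sha256_of(cfg.annotations_path),
        },
    }
    return Report(body=body)
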