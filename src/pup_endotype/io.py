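"""Readers and writers: flow (CSV/EDF), annotations CSV, endogram CSV, report JSON.

CSV is the canonical text format: a flow file has columns ``time_s,flow``
on a uniform time grid, an annotation file has columns
``onset_s,duration_s,kind,label`` with kind one of resp_event / arousal /
stage.  EDF recordings are read through ``mne`` (optional dependency);
the channel is selected by label.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InputError
from .signals import (
    EPOCH_S,
    EVENT_TYPES,
    STAGES,
    AnnotationSet,
    Arousal,
    Epoch,
    FlowTrace,
    RespEvent,
)
from .endotypes import Endogram

ANNOTATION_COLUMNS = ["onset_s", "duration_s", "kind", "label"]
ANNOTATION_KINDS = ("resp_event", "arousal", "stage")
MIN_LOWPASS_HZ = 12.5  # flow low-pass filtering below this degrades waveform analysis


# ---------------------------------------------------------------------------
# flow
# ---------------------------------------------------------------------------


def read_flow_csv(path: str | Path, jitter_tol: float = 0.01) -> FlowTrace:
    """Read a two-column ``time_s,flow`` CSV on a uniform time grid."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"flow file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in ("time_s", "flow") if c not in df.columns]
    if missing:
        raise InputError(f"flow CSV {path} missing column(s): {', '.join(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    x = df["flow"].to_numpy(dtype=float)
    if t.size < 2:
        raise InputError("flow CSV must contain at least two samples")
    dt = np.diff(t)
    step = float(np.median(dt))
    if step <= 0:
        raise InputError("flow CSV time column must be strictly increasing")
    if float(np.max(np.abs(dt - step))) > jitter_tol * step:
        raise InputError(
            f"non-uniform flow time grid: step jitter exceeds {jitter_tol:.0%} of {step:.6g} s"
        )
    return FlowTrace(samples=x, sampling_rate=1.0 / step, t0=float(t[0]))


def read_flow_edf(
    path: str | Path, channel: str = "Flow", check_filters: bool = False
) -> FlowTrace:
    """Read one channel from an EDF recording (requires the ``mne`` package)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"flow file not found: {path}")
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on optional extra
        raise InputError("reading EDF requires the 'mne' package (pip install mne)") from exc
    raw = mne.io.read_raw_edf(str(path), preload=False, verbose="error")
    if channel not in raw.ch_names:
        raise InputError(
            f"channel {channel!r} not found in {path.name}; available: {', '.join(raw.ch_names)}"
        )
    raw = raw.pick([channel]).load_data(verbose="error")
    if check_filters:
        lowpass = raw.info.get("lowpass")
        if lowpass is not None and lowpass < MIN_LOWPASS_HZ:
            warnings.warn(
                f"EDF channel {channel!r} low-pass filtered at {lowpass:g} Hz "
                f"(< {MIN_LOWPASS_HZ} Hz); flow-waveform fidelity may be degraded",
                stacklevel=2,
            )
    data = raw.get_data()[0]
    return FlowTrace(samples=data, sampling_rate=float(raw.info["sfreq"]), t0=0.0)


def read_flow(
    path: str | Path, channel: str = "Flow", check_filters: bool = False
) -> FlowTrace:
    """Dispatch on file extension: ``.edf`` via mne, anything else as CSV."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_flow_edf(path, channel=channel, check_filters=check_filters)
    return read_flow_csv(path)


def write_flow_csv(flow: FlowTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": flow.times, "flow": flow.samples}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def read_annotations(path: str | Path) -> AnnotationSet:
    """Parse and validate an ``onset_s,duration_s,kind,label`` CSV."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"annotation CSV {path} missing column(s): {', '.join(missing)}")

    events: list[RespEvent] = []
    arousals: list[Arousal] = []
    epochs: list[Epoch] = []
    for row in df.itertuples():
        rownum = row.Index + 2  # 1-based, after the header
        onset, duration = float(row.onset_s), float(row.duration_s)
        kind, label = str(row.kind), str(row.label)
        if duration <= 0:
            raise InputError(f"row {rownum}: duration must be > 0, got {duration}")
        if kind == "resp_event":
            if label not in EVENT_TYPES:
                raise InputError(f"row {rownum}: unknown respiratory event label {label!r}")
            events.append(RespEvent(onset=onset, duration=duration, kind=label))
        elif kind == "arousal":
            arousals.append(Arousal(onset=onset, duration=duration))
        elif kind == "stage":
            if label not in STAGES:
                raise InputError(f"row {rownum}: unknown stage label {label!r}")
            if abs(duration / EPOCH_S - round(duration / EPOCH_S)) > 1e-6:
                raise InputError(f"row {rownum}: stage duration must be a multiple of 30 s")
            for k in range(int(round(duration / EPOCH_S))):
                epochs.append(Epoch(onset=onset + k * EPOCH_S, stage=label))
        else:
            raise InputError(f"row {rownum}: unknown kind {kind!r}")
    return AnnotationSet(resp_events=events, arousals=arousals, epochs=epochs)


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    """Write annotations in the canonical CSV schema (stages as 30-s rows)."""
    rows = (
        [(e.onset, e.duration, "resp_event", e.kind) for e in annotations.resp_events]
        + [(a.onset, a.duration, "arousal", "arousal") for a in annotations.arousals]
        + [(ep.onset, EPOCH_S, "stage", ep.stage) for ep in annotations.epochs]
    )
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    df = df.sort_values(["onset_s", "kind"], kind="stable").reset_index(drop=True)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# endogram / config / report
# ---------------------------------------------------------------------------


def write_endogram_csv(endogram: Endogram, path: str | Path) -> None:
    pd.DataFrame(
        {
            "drive_median": endogram.drive_median,
            "vent_median": endogram.vent_median,
            "n": endogram.n_breaths,
        }
    ).to_csv(path, index=False)


def load_config_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise InputError(f"config file {path} must contain a mapping")
    return data


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def report_schema() -> dict:
    """The JSON schema the report body conforms to (shipped with the package)."""
    text = resources.files("pup_endotype").joinpath("report_schema.json").read_text()
    return json.loads(text)


def validate_report(report: dict, schema: dict | None = None, _path: str = "$") -> None:
    """Structural validation against the shipped schema.

    Supports the subset of JSON Schema the report schema uses: ``type``,
    ``required``, ``properties``, ``items`` and ``enum``.  Raises
    ``InputError`` naming the offending path.
    """
    if schema is None:
        schema = report_schema()
    typ = schema.get("type")
    type_map = {
        "object": dict,
        "array": list,
        "string": str,
        "number": (int, float),
        "integer": int,
        "boolean": bool,
        "null": type(None),
    }
    if typ is not None:
        allowed = typ if isinstance(typ, list) else [typ]
        if not any(isinstance(report, type_map[t]) for t in allowed):
            raise InputError(f"report schema violation at {_path}: expected {typ}")
        if "boolean" not in allowed and isinstance(report, bool):
            raise InputError(f"report schema violation at {_path}: expected {typ}")
    if "enum" in schema and report not in schema["enum"]:
        raise InputError(f"report schema violation at {_path}: {report!r} not in enum")
    if isinstance(report, dict):
        for key in schema.get("required", []):
            if key not in report:
                raise InputError(f"report schema violation at {_path}: missing key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in report:
                validate_report(report[key], sub, f"{_path}.{key}")
    if isinstance(report, list) and "items" in schema:
        for i, item in enumerate(report):
            validate_report(item, schema["items"], f"{_path}[{i}]")
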