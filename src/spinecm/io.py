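"""File formats: trace CSV + sidecar metadata, profile JSON, rating tables.

Traces travel as a two-column CSV (``t_s,angle_deg``) with a JSON sidecar
(``<stem>.meta.json``) carrying plane, posture, device rate, calibration
offset and subject/rater/session identifiers.  Normalized profiles are a
JSON array plus metadata block.  Rating tables are CSV in either wide
form (``subject_id`` + one column per measurement) or long form
(``subject_id,rater_id,session,value_deg``), which is pivoted.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import RatingTable
from .core import AngularTrace, NormalizedProfile, Plane, Posture
from .landmarks import ClinicalOutcome, LandmarkSet

__all__ = [
    "meta_path_for",
    "write_trace",
    "read_trace",
    "write_profile",
    "read_profile",
    "read_rating_table",
    "write_rating_table",
    "outcome_to_dict",
    "write_json_report",
]

_LONG_COLUMNS = {"subject_id", "value_deg"}


def meta_path_for(trace_path: str | Path) -> Path:
    """Sidecar metadata path for a trace CSV: <stem>.meta.json."""
    p = Path(trace_path)
    return p.with_suffix(".meta.json")


def write_trace(path: str | Path, trace: AngularTrace, metadata: dict | None = None) -> None:
    """Write a trace CSV plus its JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame({"t_s": trace.t, "angle_deg": trace.angle})
    df.to_csv(path, index=False)
    meta = {
        "plane": trace.plane.value,
        "posture": trace.posture.value,
        "device_rate_hz": trace.device_rate_hint,
        "calibration_offset_deg": trace.calibration_offset,
    }
    if metadata:
        meta.update(metadata)
    meta_path_for(path).write_text(json.dumps(meta, indent=2))


def read_trace(path: str | Path, meta_path: str | Path | None = None) -> tuple[AngularTrace, dict]:
    """Read a trace CSV and its sidecar; returns (trace, full metadata dict)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"t_s", "angle_deg"}.issubset(df.columns):
        raise ValueError(f"{path}: trace CSV requires columns t_s,angle_deg")
    meta_path = Path(meta_path) if meta_path else meta_path_for(path)
    meta: dict = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    trace = AngularTrace(
        t=df["t_s"].to_numpy(float),
        angle=df["angle_deg"].to_numpy(float),
        plane=Plane(meta.get("plane", "transverse")),
        posture=Posture(meta.get("posture", "adams")),
        device_rate_hint=meta.get("device_rate_hz"),
        calibration_offset=float(meta.get("calibration_offset_deg", 0.0)),
    )
    return trace, meta


def write_profile(path: str | Path, profile: NormalizedProfile, metadata: dict | None = None) -> None:
    """Serialize a normalized profile as JSON (values + metadata block)."""
    payload = {
        "n_points": profile.n_points,
        "plane": profile.plane.value,
        "posture": profile.posture.value,
        "values_deg": [float(v) for v in profile.values],
    }
    if metadata:
        payload["metadata"] = metadata
    Path(path).write_text(json.dumps(payload, indent=2))


def read_profile(path: str | Path) -> NormalizedProfile:
    payload = json.loads(Path(path).read_text())
    return NormalizedProfile(
        values=np.asarray(payload["values_deg"], dtype=float),
        plane=Plane(payload["plane"]),
        posture=Posture(payload["posture"]),
    )


def read_rating_table(path: str | Path) -> RatingTable:
    """Read a rating table CSV, accepting wide or long layout.

    Long layout (``subject_id,rater_id[,session],value_deg``) is pivoted
    to subjects x (rater, session) columns; duplicated cells raise.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cols = set(df.columns)
    if _LONG_COLUMNS.issubset(cols):
        keys = [c for c in ("rater_id", "session") if c in cols]
        if not keys:
            raise ValueError("long-format table needs a rater_id and/or session column")
        wide = df.pivot_table(
            index="subject_id", columns=keys, values="value_deg", aggfunc="first", sort=True
        )
        if wide.isna().any().any():
            raise ValueError("long-format table is incomplete (missing cells)")
        col_names = tuple(
            "_".join(str(part) for part in (c if isinstance(c, tuple) else (c,)))
            for c in wide.columns
        )
        return RatingTable(
            values=wide.to_numpy(float),
            subject_ids=tuple(str(s) for s in wide.index),
            columns=col_names,
        )
    if "subject_id" not in cols:
        raise ValueError("rating table needs a subject_id column")
    measure_cols = [c for c in df.columns if c != "subject_id"]
    if len(measure_cols) < 2:
        raise ValueError("wide-format table needs >= 2 measurement columns")
    return RatingTable(
        values=df[measure_cols].to_numpy(float),
        subject_ids=tuple(str(s) for s in df["subject_id"]),
        columns=tuple(measure_cols),
    )


def write_rating_table(path: str | Path, table: RatingTable) -> None:
    df = pd.DataFrame(table.values, columns=list(table.columns))
    df.insert(0, "subject_id", list(table.subject_ids))
    df.to_csv(path, index=False)


def _landmark_set_to_dict(lm: LandmarkSet | None):
    if lm is None:
        return None
    return {
        name: {"index": getattr(lm, name).index, "value_deg": getattr(lm, name).value}
        for name in ("n1", "n2", "n3")
    }


def outcome_to_dict(outcome: ClinicalOutcome) -> dict:
    """JSON-ready clinical report for one scan."""
    return {
        "plane": outcome.plane.value,
        "posture": outcome.posture.value,
        "atr_deg": outcome.atr,
        "hump_right_deg": outcome.hump_right,
        "hump_left_deg": outcome.hump_left,
        "kyphosis_deg": outcome.kyphosis,
        "lordosis_deg": outcome.lordosis,
        "apexes_s": {
            "hump_right": outcome.hump_right_apex_s,
            "hump_left": outcome.hump_left_apex_s,
            "kyphosis": outcome.kyphosis_apex_s,
            "lordosis": outcome.lordosis_apex_s,
        },
        "transition_s": outcome.transition_s,
        "var1_deg": outcome.var1,
        "var2_deg": outcome.var2,
        "degenerate": outcome.degenerate,
        "landmarks": {
            "poli": _landmark_set_to_dict(outcome.landmarks_poli),
            "orig": _landmark_set_to_dict(outcome.landmarks_orig),
        },
    }


def write_json_report(path: str | Path, payload) -> None:
    """Write any report object (dataclass or dict) as indented JSON."""
    if dataclasses.is_dataclass(payload) and not isinstance(payload, type):
        payload = dataclasses.asdict(payload)

    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default))
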