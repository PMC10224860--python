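"""Reading and writing of trace and cohort files.

All on-disk formats are plain text. A trace is a CSV with header
``time_s,head_vel_dps,eye_vel_dps`` and one row per sample; its optional
ground-truth sidecar (``*.truth.csv``) lists one simulated impulse per row
keyed by onset time. A cohort is a CSV with one row per participant.
Trace samples are written with the full (shortest exact) decimal
representation so read-back is lossless; derived tables use 9 significant
digits. Both formats are deterministic, so a rerun with the same
configuration and seed reproduces every file byte for byte.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS, Cohort
from .errors import TraceFormatError, ValidationError
from .synthetic import ImpulseKinematics, VelocityTrace

TRACE_COLUMNS = ["time_s", "head_vel_dps", "eye_vel_dps"]
# traces round-trip exactly (shortest exact decimal for a double); derived
# tables use 9 significant digits
TRACE_FLOAT_FMT = "%.17g"
FLOAT_FMT = "%.9g"


def write_trace(trace: VelocityTrace, path: str | Path) -> Path:
    """Write a trace as CSV; if ground truth is attached, also write the
    ``<stem>.truth.csv`` sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": trace.timestamps,
            "head_vel_dps": trace.head_velocity,
            "eye_vel_dps": trace.eye_velocity,
        }
    )
    df.to_csv(path, index=False, float_format=TRACE_FLOAT_FMT)
    if trace.ground_truth is not None:
        truth = pd.DataFrame(
            {
                "onset_time_s": [k.onset_time for k in trace.ground_truth],
                "direction": [k.direction for k in trace.ground_truth],
                "peak_head_vel_dps": [k.peak_head_velocity for k in trace.ground_truth],
                "duration_s": [k.duration for k in trace.ground_truth],
            }
        )
        truth.to_csv(_truth_path(path), index=False, float_format=TRACE_FLOAT_FMT)
    return path


def _truth_path(path: Path) -> Path:
    return path.with_suffix(".truth.csv")


def read_trace(path: str | Path) -> VelocityTrace:
    """Read and validate a trace CSV.

    The sampling rate is inferred from the timestamps (which must be uniform
    to within 1e-9 s). If a ground-truth sidecar exists next to the file it
    is loaded too. Format violations raise :class:`TraceFormatError` naming
    the offending row where possible.
    """
    path = Path(path)
    if not path.exists():
        raise TraceFormatError(f"no such trace file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise TraceFormatError(f"{path}: cannot parse as CSV ({exc})") from exc
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing columns {missing}")
    if len(df) < 2:
        raise TraceFormatError(f"{path}: a trace needs at least two samples")
    values = df[TRACE_COLUMNS].to_numpy(dtype=float)
    bad = np.where(~np.isfinite(values).all(axis=1))[0]
    if bad.size:
        # +2: header line plus 1-based numbering
        raise TraceFormatError(
            f"{path}: non-finite value at line {int(bad[0]) + 2}"
        )
    t = values[:, 0]
    dt = np.diff(t)
    if np.any(dt <= 0) or np.max(np.abs(dt - dt[0])) > 1e-9:
        j = int(np.argmax(np.abs(dt - dt[0])))
        raise TraceFormatError(
            f"{path}: non-uniform sampling near line {j + 2}"
        )
    fs = 1.0 / float(np.mean(dt))
    truth = None
    sidecar = _truth_path(path)
    if sidecar.exists():
        tdf = pd.read_csv(sidecar)
        truth = [
            ImpulseKinematics(
                peak_head_velocity=float(r.peak_head_vel_dps),
                duration=float(r.duration_s),
                direction=str(r.direction),
                onset_time=float(r.onset_time_s),
            )
            for r in tdf.itertuples(index=False)
        ]
    try:
        return VelocityTrace(
            timestamps=t,
            head_velocity=values[:, 1],
            eye_velocity=values[:, 2],
            sampling_rate=fs,
            ground_truth=truth,
        )
    except ValidationError as exc:
        raise TraceFormatError(f"{path}: {exc}") from exc


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    path = Path(path)
    df = cohort.to_frame()
    df["susceptible"] = df["susceptible"].map({True: "true", False: "false"})
    df["symptomatic"] = df["symptomatic"].map({True: "true", False: "false"})
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


_BOOL_STRINGS = {"true": True, "false": False}


def read_cohort(path: str | Path) -> Cohort:
    """Read and validate a cohort CSV (strict boolean parsing, unique ids,
    nausea on the 0-10 scale)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such cohort file: {path}")
    df = pd.read_csv(path, dtype={"participant_id": str})
    if len(df) == 0:
        raise ValidationError(f"{path}: empty cohort table")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    for col in ("susceptible", "symptomatic"):
        raw = df[col].astype(str).str.strip().str.lower()
        unknown = sorted(set(raw) - set(_BOOL_STRINGS))
        if unknown:
            raise ValidationError(
                f"{path}: column {col!r} has non-boolean values {unknown}; "
                "use 'true' or 'false'"
            )
        df[col] = raw.map(_BOOL_STRINGS)
    return Cohort.from_frame(df)
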