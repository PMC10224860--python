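"""Head-impulse detection, per-impulse VOR gain and per-participant metrics.

The analysis chain mirrors standard clinical vHIT processing:

1. detect impulses as excursions of |head velocity| above a search threshold,
   backtracking to the last sub-threshold sample for the onset;
2. compute each impulse's VOR gain as minus the ratio of mean eye to mean
   head velocity in a fixed 10 ms window centered 60 ms after onset;
3. keep impulses whose peak head velocity exceeds 100 deg/s ("valid");
4. per direction, average the gains of the five fastest valid impulses
   (at least five are required, else the direction — and participant — is
   excluded);
5. pool left/right gains and compute the asymmetry index
   ``100 * (gL - gR) / (gL + gR)`` (percent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    GainWindowError,
    InsufficientImpulsesError,
    TraceFormatError,
    UndefinedAsymmetryError,
    ValidationError,
)
from .synthetic import Direction, VelocityTrace

VALIDITY_PEAK_DPS = 100.0  # impulses must exceed this peak head velocity
MIN_VALID_PER_DIRECTION = 5
GAIN_WINDOW = (0.055, 0.065)  # s after onset, half-open [start, stop)
MIN_WINDOW_HEAD_DPS = 1.0  # below this mean head velocity the ratio is junk


@dataclass
class DetectionParams:
    """Thresholds of the impulse detector.

    ``search_threshold`` triggers an event; the onset is the last sample
    before the crossing with |head| below ``onset_threshold`` (looking back at
    most ``max_rise_time``). Events within ``refractory`` of the previous
    onset are suppressed. The defaults guarantee that every valid impulse
    (peak > 100 deg/s) is detectable.
    """

    search_threshold: float = 50.0
    onset_threshold: float = 20.0
    refractory: float = 0.5
    max_rise_time: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.onset_threshold < self.search_threshold:
            raise ValidationError(
                "need 0 < onset_threshold < search_threshold; got "
                f"{self.onset_threshold} / {self.search_threshold}"
            )
        if self.refractory <= 0:
            raise ValidationError("refractory must be positive")
        if self.max_rise_time <= 0:
            raise ValidationError("max_rise_time must be positive")


@dataclass
class HeadImpulse:
    """One detected head impulse and its derived metrics."""

    onset_index: int
    onset_time: float
    direction: Direction
    peak_head_velocity: float
    peak_head_acceleration: float
    gain: float | None = None
    valid: bool = True

    def __post_init__(self) -> None:
        if self.peak_head_velocity <= 0:
            raise ValidationError("peak_head_velocity must be positive")


@dataclass
class ParticipantVHIT:
    """Per-session summary of one participant's vHIT metrics.

    Direction gains, the pooled gain and the asymmetry index are populated
    only when both directions have at least five valid impulses; otherwise
    ``excluded`` is set and ``exclusion_reason`` explains which direction
    fell short.
    """

    impulses: list[HeadImpulse] = field(default_factory=list)
    n_valid_left: int = 0
    n_valid_right: int = 0
    gain_left: float | None = None
    gain_right: float | None = None
    gain_pooled: float | None = None
    asymmetry_signed: float | None = None
    asymmetry_abs: float | None = None
    excluded: bool = False
    exclusion_reason: str | None = None


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_impulses(
    trace: VelocityTrace, params: DetectionParams | None = None
) -> list[HeadImpulse]:
    """Segment a trace into head impulses (gains left unset).

    One impulse is emitted per excursion of |head velocity| above the search
    threshold; its onset is the last sample before the crossing where |head|
    is below the onset threshold, its direction the sign of head velocity at
    the peak. Peak velocity and acceleration are measured on the excursion
    (acceleration by finite differences).
    """
    params = params or DetectionParams()
    t = trace.timestamps
    dt = np.diff(t)
    if np.max(np.abs(dt - dt[0])) > 1e-9:
        raise TraceFormatError("non-uniform timestamps")
    h = trace.head_velocity
    absh = np.abs(h)
    fs = trace.sampling_rate
    refractory_n = int(round(params.refractory * fs))
    max_back = int(round(params.max_rise_time * fs))

    impulses: list[HeadImpulse] = []
    last_onset = -refractory_n - 1
    i = 1
    n = len(h)
    while i < n:
        if absh[i] >= params.search_threshold and absh[i - 1] < params.search_threshold:
            # backtrack to the onset: last sub-threshold sample, then follow
            # the monotone descent to the foot of the velocity rise
            onset = None
            floor = max(0, i - 1 - max_back)
            for j in range(i - 1, floor - 1, -1):
                if absh[j] < params.onset_threshold:
                    onset = j
                    break
            if onset is not None:
                while onset > floor and absh[onset - 1] < absh[onset]:
                    onset -= 1
            if onset is None or onset - last_onset < refractory_n:
                i += 1
                continue
            # walk forward to the end of the excursion
            j = i
            while j + 1 < n and absh[j + 1] >= params.onset_threshold:
                j += 1
            seg = slice(onset, min(j + 2, n))
            seg_h = h[seg]
            peak_idx = int(np.argmax(np.abs(seg_h)))
            accel = np.gradient(seg_h, 1.0 / fs)
            impulses.append(
                HeadImpulse(
                    onset_index=onset,
                    onset_time=float(t[onset]),
                    direction="right" if seg_h[peak_idx] > 0 else "left",
                    peak_head_velocity=float(np.abs(seg_h[peak_idx])),
                    peak_head_acceleration=float(np.max(np.abs(accel))),
                )
            )
            last_onset = onset
            i = j + 1
        i += 1
    return impulses


# ---------------------------------------------------------------------------
# per-impulse gain
# ---------------------------------------------------------------------------

def compute_gain(trace: VelocityTrace, impulse: HeadImpulse) -> float:
    """VOR gain of one impulse.

    Gain is minus the ratio of mean eye velocity to mean head velocity over
    the half-open window [onset + 55 ms, onset + 65 ms) — a 10 ms window
    centered 60 ms after impulse onset; the sign flip makes compensatory
    responses positive. At 220 Hz the window holds 2-3 samples.

    Raises
    ------
    GainWindowError
        If the window extends past the trace, or the mean head velocity in
        the window is below 1 deg/s (degenerate ratio; the impulse is also
        marked invalid).
    """
    t0 = trace.timestamps[0]
    dt = trace.dt
    start = impulse.onset_time + GAIN_WINDOW[0]
    stop = impulse.onset_time + GAIN_WINDOW[1]
    # half-open membership on the uniform sample grid
    i0 = int(math.ceil((start - t0) / dt - 1e-9))
    i1 = int(math.ceil((stop - t0) / dt - 1e-9))
    if i0 < 0 or i1 > len(trace):
        raise GainWindowError(
            f"gain window [{start:.3f}, {stop:.3f}) s falls outside the trace"
        )
    if i1 <= i0:
        raise GainWindowError("gain window contains no samples")
    mean_head = float(np.mean(trace.head_velocity[i0:i1]))
    mean_eye = float(np.mean(trace.eye_velocity[i0:i1]))
    if abs(mean_head) < MIN_WINDOW_HEAD_DPS:
        impulse.valid = False
        raise GainWindowError(
            f"mean head velocity {mean_head:.2f} deg/s in the gain window is "
            "too small for a meaningful ratio"
        )
    gain = -mean_eye / mean_head
    impulse.gain = gain
    return gain


def attach_gains(
    trace: VelocityTrace, impulses: list[HeadImpulse]
) -> list[HeadImpulse]:
    """Compute gains for all impulses, marking failures invalid instead of
    raising."""
    for imp in impulses:
        try:
            compute_gain(trace, imp)
        except GainWindowError:
            imp.valid = False
            imp.gain = None
    return impulses


# ---------------------------------------------------------------------------
# validity filter and aggregation
# ---------------------------------------------------------------------------

def filter_valid(
    impulses: list[HeadImpulse], peak_threshold: float = VALIDITY_PEAK_DPS
) -> list[HeadImpulse]:
    """Keep impulses with peak head velocity strictly above the threshold and
    a defined, finite gain; order is preserved."""
    return [
        imp
        for imp in impulses
        if imp.valid
        and imp.peak_head_velocity > peak_threshold
        and imp.gain is not None
        and math.isfinite(imp.gain)
    ]


def aggregate_direction_gain(
    valid_impulses: list[HeadImpulse], direction: Direction | None = None
) -> tuple[float, int]:
    """Mean gain of the five fastest valid impulses of one direction.

    Impulses are ranked by peak head velocity (ties broken by earlier
    onset); the gains of the top five are averaged. Returns
    ``(gain, n_used)``.

    Raises
    ------
    InsufficientImpulsesError
        If fewer than five valid impulses are supplied.
    """
    if len(valid_impulses) < MIN_VALID_PER_DIRECTION:
        name = direction or "requested"
        raise InsufficientImpulsesError(
            f"{len(valid_impulses)} valid impulses in the {name} direction; "
            f"at least {MIN_VALID_PER_DIRECTION} are required"
        )
    ranked = sorted(
        valid_impulses, key=lambda imp: (-imp.peak_head_velocity, imp.onset_time)
    )
    top = ranked[:MIN_VALID_PER_DIRECTION]
    return float(np.mean([imp.gain for imp in top])), len(top)


def asymmetry_index(gain_left: float, gain_right: float) -> tuple[float, float]:
    """Left/right VOR gain asymmetry in percent.

    Signed value ``100 * (gL - gR) / (gL + gR)`` and its magnitude. Positive
    means the leftward gain is larger.
    """
    s = gain_left + gain_right
    if s <= 0:
        raise UndefinedAsymmetryError(
            f"gain sum {s:.3f} is non-positive; asymmetry undefined"
        )
    signed = 100.0 * (gain_left - gain_right) / s
    return signed, abs(signed)


# ---------------------------------------------------------------------------
# per-participant summary
# ---------------------------------------------------------------------------

def summarize_session(
    trace: VelocityTrace,
    params: DetectionParams | None = None,
    *,
    pooling: str = "direction-mean",
    strict: bool = True,
) -> ParticipantVHIT:
    """Run detect -> gain -> filter -> aggregate on one session.

    ``pooling`` selects how the pooled gain is formed: ``"direction-mean"``
    (unweighted mean of the two direction gains, the default) or
    ``"all-impulses"`` (mean over the five fastest of both directions
    together, 10 impulses). With ``strict=False``, a direction with fewer
    than five valid impulses flags the session excluded instead of raising.
    """
    if pooling not in ("direction-mean", "all-impulses"):
        raise ValidationError(f"unknown pooling mode {pooling!r}")
    impulses = attach_gains(trace, detect_impulses(trace, params))
    valid = filter_valid(impulses)
    by_dir: dict[Direction, list[HeadImpulse]] = {"left": [], "right": []}
    for imp in valid:
        by_dir[imp.direction].append(imp)
    out = ParticipantVHIT(
        impulses=impulses,
        n_valid_left=len(by_dir["left"]),
        n_valid_right=len(by_dir["right"]),
    )
    short = [d for d in ("left", "right") if len(by_dir[d]) < MIN_VALID_PER_DIRECTION]
    if short:
        reason = (
            "insufficient valid impulses: "
            + ", ".join(f"{d} has {len(by_dir[d])}" for d in short)
            + f" (minimum {MIN_VALID_PER_DIRECTION})"
        )
        if strict:
            raise InsufficientImpulsesError(reason)
        out.excluded = True
        out.exclusion_reason = reason
        return out
    gl, _ = aggregate_direction_gain(by_dir["left"], "left")
    gr, _ = aggregate_direction_gain(by_dir["right"], "right")
    out.gain_left, out.gain_right = gl, gr
    if pooling == "direction-mean":
        out.gain_pooled = 0.5 * (gl + gr)
    else:
        ranked = sorted(
            valid, key=lambda imp: (-imp.peak_head_velocity, imp.onset_time)
        )
        top = ranked[: 2 * MIN_VALID_PER_DIRECTION]
        out.gain_pooled = float(np.mean([imp.gain for imp in top]))
    out.asymmetry_signed, out.asymmetry_abs = asymmetry_index(gl, gr)
    return out


def summarize_participant(
    trace_pre: VelocityTrace,
    trace_post: VelocityTrace,
    params: DetectionParams | None = None,
    *,
    pooling: str = "direction-mean",
    strict: bool = True,
) -> tuple[ParticipantVHIT, ParticipantVHIT]:
    """Summaries for the pre and post sessions of one participant.

    Insufficient-data errors are re-raised with the session name attached so
    the caller can log which recording failed.
    """
    out = []
    for session, trace in (("pre", trace_pre), ("post", trace_post)):
        try:
            out.append(
                summarize_session(trace, params, pooling=pooling, strict=strict)
            )
        except InsufficientImpulsesError as exc:
            raise InsufficientImpulsesError(f"{session} session: {exc}") from exc
    return out[0], out[1]
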