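"""Ground-truthed synthetic vHIT recordings and study cohorts.

The video head impulse test (vHIT) measures the high-frequency horizontal
vestibulo-ocular reflex (VOR): an examiner delivers brief, passive,
unpredictable head rotations in yaw while the participant fixates a target,
and a combined eye/head tracker records synchronized angular-velocity traces
(here at 220 Hz). The simulator in this module produces such traces with
known ("ground truth") impulse kinematics and gains, plus study cohorts with
a configurable pre/post gain correlation, so the whole downstream pipeline is
testable without access to recorded data.

Physical conventions
--------------------
* Positive angular velocity = rightward (clockwise from above) rotation.
* A compensatory eye movement opposes the head, so the raw eye velocity has
  the opposite sign; the VOR gain of a healthy participant is ~+1 after the
  sign flip applied by the analysis.
* Head impulses are raised-cosine velocity pulses. For a pulse of peak
  velocity ``p`` and duration ``T``, the peak acceleration is ``pi*p/T`` and
  the total displacement ``p*T/2`` — closed forms used to enforce the
  physical envelope of a hand-delivered impulse: displacement at most 20 deg
  and acceleration at most 4700 deg/s^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.stats import norm

from .cohort import Cohort, ParticipantRecord
from .errors import BoundViolationError, CapacityError, ValidationError

MAX_DISPLACEMENT_DEG = 20.0
MAX_ACCELERATION_DPS2 = 4700.0

Direction = Literal["left", "right"]


# ---------------------------------------------------------------------------
# impulse kinematics and single-pulse synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImpulseKinematics:
    """Kinematic description of one head impulse.

    ``peak_head_velocity`` is unsigned (deg/s); ``direction`` carries the
    sign. The implied peak acceleration (``pi*peak/duration``) and implied
    displacement (``peak*duration/2``) of the raised-cosine envelope must
    stay inside the physical bounds of a hand-delivered impulse.
    """

    peak_head_velocity: float
    duration: float
    direction: Direction
    onset_time: float = 0.0

    def __post_init__(self) -> None:
        if self.peak_head_velocity <= 0:
            raise BoundViolationError("peak_head_velocity must be positive")
        if self.duration <= 0:
            raise BoundViolationError("duration must be positive")
        if self.direction not in ("left", "right"):
            raise ValidationError(f"unknown direction {self.direction!r}")
        acc = self.peak_acceleration
        if acc > MAX_ACCELERATION_DPS2:
            raise BoundViolationError(
                f"implied peak acceleration {acc:.0f} deg/s^2 exceeds "
                f"{MAX_ACCELERATION_DPS2:.0f} deg/s^2"
            )
        disp = self.displacement
        if disp > MAX_DISPLACEMENT_DEG:
            raise BoundViolationError(
                f"implied displacement {disp:.1f} deg exceeds "
                f"{MAX_DISPLACEMENT_DEG:.0f} deg"
            )

    @property
    def peak_acceleration(self) -> float:
        """Closed-form max |dv/dt| of the raised-cosine pulse (deg/s^2)."""
        return math.pi * self.peak_head_velocity / self.duration

    @property
    def displacement(self) -> float:
        """Closed-form integral of the pulse (deg)."""
        return self.peak_head_velocity * self.duration / 2.0

    @property
    def sign(self) -> int:
        return 1 if self.direction == "right" else -1


def simulate_impulse_profile(
    kin: ImpulseKinematics, sampling_rate: float
) -> np.ndarray:
    """Sample the signed raised-cosine velocity pulse of one impulse.

    Returns head-velocity samples at ``t = k / sampling_rate`` for
    ``0 <= t <= duration``. The sampled peak equals the configured peak up to
    quantization of the peak instant onto the sample grid.
    """
    if sampling_rate <= 0:
        raise ValidationError("sampling_rate must be positive")
    n = int(math.floor(kin.duration * sampling_rate)) + 1
    t = np.arange(n) / sampling_rate
    v = 0.5 * kin.peak_head_velocity * (1.0 - np.cos(2.0 * np.pi * t / kin.duration))
    return kin.sign * v


# ---------------------------------------------------------------------------
# full trace synthesis
# ---------------------------------------------------------------------------

@dataclass
class TraceConfig:
    """Configuration of one synthetic vHIT session.

    Defaults mirror a standard clinical session: 220 Hz sampling, ~10
    impulses per direction with peak velocities well above the 100 deg/s
    validity cut, true gain ~1, broadband eye-tracker noise of a few deg/s
    and occasional catch-up saccades.

    Parameters
    ----------
    true_gain_left, true_gain_right:
        VOR gain applied to leftward / rightward impulses.
    vor_latency:
        Delay (s) of the eye response relative to the head; 0 by default so
        the fixed analysis window is unbiased (the analysis applies no
        latency compensation).
    noise_sd:
        SD (deg/s) of white measurement noise added to the eye channel.
    saccade_probability:
        Per-impulse probability of an additive catch-up saccade transient
        shortly after impulse offset (outside the gain window).
    peak_velocity_range:
        Uniform sampling range (deg/s) for impulse peak velocities. With the
        0.15 s default duration, peaks up to ~220 deg/s respect both the
        acceleration and the displacement envelope.
    duration:
        Total trace length in seconds, or None to size the trace to fit the
        requested impulses exactly.
    """

    sampling_rate: float = 220.0
    n_impulses_per_direction: int = 10
    true_gain_left: float = 1.04
    true_gain_right: float = 1.04
    vor_latency: float = 0.0
    noise_sd: float = 5.0
    saccade_probability: float = 0.2
    peak_velocity_range: tuple[float, float] = (150.0, 220.0)
    impulse_duration: float = 0.15
    min_quiescence: float = 0.5
    duration: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if self.n_impulses_per_direction < 0:
            raise ValidationError("n_impulses_per_direction must be >= 0")
        if self.true_gain_left <= 0 or self.true_gain_right <= 0:
            raise ValidationError("true gains must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0.0 <= self.saccade_probability <= 1.0:
            raise ValidationError("saccade_probability must lie in [0, 1]")
        lo, hi = self.peak_velocity_range
        if not 0 < lo <= hi:
            raise ValidationError("peak_velocity_range must satisfy 0 < lo <= hi")
        if self.min_quiescence <= 0:
            raise ValidationError("min_quiescence must be positive")


@dataclass
class VelocityTrace:
    """Synchronized head/eye angular-velocity time series.

    ``ground_truth`` is populated by the simulator and absent for traces read
    from disk without a sidecar.
    """

    timestamps: np.ndarray
    head_velocity: np.ndarray
    eye_velocity: np.ndarray
    sampling_rate: float
    ground_truth: list[ImpulseKinematics] | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.head_velocity = np.asarray(self.head_velocity, dtype=float)
        self.eye_velocity = np.asarray(self.eye_velocity, dtype=float)
        n = len(self.timestamps)
        if len(self.head_velocity) != n or len(self.eye_velocity) != n:
            raise ValidationError("timestamps, head and eye series differ in length")
        if n < 2:
            raise ValidationError("a trace needs at least two samples")
        dt = np.diff(self.timestamps)
        if np.any(dt <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-9:
            raise ValidationError("timestamps must be uniform to within 1e-9 s")
        for name, arr in (
            ("timestamps", self.timestamps),
            ("head_velocity", self.head_velocity),
            ("eye_velocity", self.eye_velocity),
        ):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite values")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def __len__(self) -> int:
        return len(self.timestamps)


def simulate_trace(cfg: TraceConfig) -> VelocityTrace:
    """Simulate one vHIT session.

    Impulses alternate in randomized direction order and are separated by at
    least ``min_quiescence`` seconds of rest, mimicking the unpredictable
    timing the examiner uses to defeat anticipation. The eye channel is
    ``-true_gain(direction) * head``, delayed by ``vor_latency``, plus white
    noise and optional catch-up saccade transients. Identical configuration
    (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate
    k = cfg.n_impulses_per_direction

    directions: list[Direction] = ["left"] * k + ["right"] * k
    rng.shuffle(directions)  # type: ignore[arg-type]
    lo, hi = cfg.peak_velocity_range
    peaks = rng.uniform(lo, hi, size=2 * k)
    gaps = cfg.min_quiescence + rng.uniform(0.0, 0.5, size=2 * k)
    saccade_draws = rng.uniform(size=2 * k)
    saccade_delays = rng.uniform(0.02, 0.06, size=2 * k)
    saccade_amps = rng.uniform(30.0, 80.0, size=2 * k)

    # lay impulses down sequentially; snap onsets to the sample grid so the
    # recorded ground truth is exact
    onset_times = []
    t_cursor = gaps[0] if k else cfg.min_quiescence
    for j in range(2 * k):
        if j > 0:
            t_cursor += gaps[j]
        onset_idx = int(round(t_cursor * fs))
        onset_times.append(onset_idx / fs)
        t_cursor = onset_times[-1] + cfg.impulse_duration

    needed = (t_cursor + cfg.min_quiescence) if k else 2 * cfg.min_quiescence
    total = cfg.duration if cfg.duration is not None else needed
    if total < needed:
        raise CapacityError(
            f"{2 * k} impulses need {needed:.2f} s but the trace is limited "
            f"to {total:.2f} s"
        )

    n_samples = int(round(total * fs)) + 1
    t = np.arange(n_samples) / fs
    head = np.zeros(n_samples)
    eye = np.zeros(n_samples)
    lat_samples = int(round(cfg.vor_latency * fs))
    truth: list[ImpulseKinematics] = []

    for j, (direction, peak, onset_time) in enumerate(
        zip(directions, peaks, onset_times)
    ):
        kin = ImpulseKinematics(
            peak_head_velocity=float(peak),
            duration=cfg.impulse_duration,
            direction=direction,
            onset_time=float(onset_time),
        )
        truth.append(kin)
        pulse = simulate_impulse_profile(kin, fs)
        i0 = int(round(onset_time * fs))
        _add_segment(head, pulse, i0)
        gain = cfg.true_gain_right if direction == "right" else cfg.true_gain_left
        _add_segment(eye, -gain * pulse, i0 + lat_samples)
        if saccade_draws[j] < cfg.saccade_probability:
            # catch-up saccade: brief transient in the compensatory direction
            sac_kin_t = np.arange(int(0.030 * fs) + 1) / fs
            sac = (
                0.5
                * saccade_amps[j]
                * (1.0 - np.cos(2.0 * np.pi * sac_kin_t / 0.030))
            )
            sac_i0 = int(round((onset_time + cfg.impulse_duration + saccade_delays[j]) * fs))
            _add_segment(eye, -kin.sign * sac, sac_i0)

    if cfg.noise_sd > 0:
        eye = eye + rng.normal(0.0, cfg.noise_sd, size=n_samples)

    return VelocityTrace(
        timestamps=t,
        head_velocity=head,
        eye_velocity=eye,
        sampling_rate=fs,
        ground_truth=truth,
    )


def _add_segment(target: np.ndarray, segment: np.ndarray, start: int) -> None:
    """Add ``segment`` into ``target`` starting at ``start``, clipping at the
    trace end."""
    if start >= len(target):
        return
    stop = min(start + len(segment), len(target))
    target[start:stop] += segment[: stop - start]


# ---------------------------------------------------------------------------
# cohort synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubgroupSpec:
    """Generative parameters for one susceptibility-by-symptom subgroup."""

    n: int
    age_mean: float
    age_sd: float
    mssq_mean: float
    mssq_sd: float
    nausea_range: tuple[int, int]
    gain_pre_mean: float
    gain_pre_sd: float
    gain_post_mean: float
    gain_post_sd: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValidationError("subgroup count must be >= 0")
        for name in ("age_sd", "mssq_sd", "gain_pre_sd", "gain_post_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        lo, hi = self.nausea_range
        if not 0 <= lo <= hi <= 10:
            raise ValidationError("nausea_range must lie within [0, 10]")


def _default_subgroups() -> dict[str, SubgroupSpec]:
    # descriptive statistics of a small healthy cohort split by self-reported
    # susceptibility (rows) and nausea outcome during provocation (columns)
    return {
        "nonsusceptible_symptomatic": SubgroupSpec(
            n=2, age_mean=46.5, age_sd=6.4, mssq_mean=10.1, mssq_sd=14.3,
            nausea_range=(1, 1),
            gain_pre_mean=1.03, gain_pre_sd=0.07,
            gain_post_mean=1.03, gain_post_sd=0.04,
        ),
        "susceptible_symptomatic": SubgroupSpec(
            n=6, age_mean=33.5, age_sd=10.5, mssq_mean=19.7, mssq_sd=9.3,
            nausea_range=(2, 4),
            gain_pre_mean=1.04, gain_pre_sd=0.03,
            gain_post_mean=1.03, gain_post_sd=0.04,
        ),
        "nonsusceptible_asymptomatic": SubgroupSpec(
            n=4, age_mean=35.8, age_sd=19.2, mssq_mean=2.7, mssq_sd=3.7,
            nausea_range=(0, 0),
            gain_pre_mean=1.04, gain_pre_sd=0.03,
            gain_post_mean=1.03, gain_post_sd=0.03,
        ),
        "susceptible_asymptomatic": SubgroupSpec(
            n=5, age_mean=33.6, age_sd=17.8, mssq_mean=10.5, mssq_sd=2.8,
            nausea_range=(0, 0),
            gain_pre_mean=1.01, gain_pre_sd=0.09,
            gain_post_mean=1.02, gain_post_sd=0.10,
        ),
    }


@dataclass
class CohortConfig:
    """Configuration of a simulated study cohort.

    Pre and post gains of a participant are drawn from a bivariate normal
    with the subgroup's means/SDs and ``pre_post_correlation`` (repeated
    vHIT gains in the same person are strongly correlated; 0.7 is the
    planning value used for the study design this simulator emulates).
    Questionnaire (MSSQ) scores and nausea ratings share a Gaussian-copula
    latent variable with weight ``mssq_nausea_coupling`` so their rank
    correlation is tunable.
    """

    subgroups: dict[str, SubgroupSpec] = field(default_factory=_default_subgroups)
    pre_post_correlation: float = 0.7
    mssq_nausea_coupling: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.pre_post_correlation <= 1.0:
            raise ValidationError(
                "pre_post_correlation must lie in [-1, 1]; got "
                f"{self.pre_post_correlation}"
            )
        if not -1.0 <= self.mssq_nausea_coupling <= 1.0:
            raise ValidationError(
                "mssq_nausea_coupling must lie in [-1, 1]; got "
                f"{self.mssq_nausea_coupling}"
            )
        for key in self.subgroups:
            sus, sym = _parse_subgroup_key(key)
            lo, hi = self.subgroups[key].nausea_range
            if sym and lo < 1:
                raise ValidationError(
                    f"symptomatic subgroup {key!r} must have nausea >= 1"
                )
            if not sym and hi > 0:
                raise ValidationError(
                    f"asymptomatic subgroup {key!r} must have nausea 0"
                )


def _parse_subgroup_key(key: str) -> tuple[bool, bool]:
    try:
        sus_s, sym_s = key.split("_")
        susceptible = {"susceptible": True, "nonsusceptible": False}[sus_s]
        symptomatic = {"symptomatic": True, "asymptomatic": False}[sym_s]
    except (ValueError, KeyError) as exc:
        raise ValidationError(
            f"subgroup key {key!r} must be "
            "'(non)susceptible_(a)symptomatic'"
        ) from exc
    return susceptible, symptomatic


def simulate_cohort(cfg: CohortConfig) -> Cohort:
    """Simulate a study cohort, one record per participant.

    Asymptomatic participants get nausea 0; symptomatic participants get an
    integer rating inside the subgroup's range, coupled to the MSSQ score
    through the shared latent variable. Seed-reproducible.
    """
    rng = np.random.default_rng(cfg.seed)
    rho = cfg.pre_post_correlation
    w = cfg.mssq_nausea_coupling
    records: list[ParticipantRecord] = []
    pid = 0
    for key in sorted(cfg.subgroups):
        spec = cfg.subgroups[key]
        susceptible, symptomatic = _parse_subgroup_key(key)
        for _ in range(spec.n):
            pid += 1
            z1, z2 = rng.standard_normal(2)
            pre = spec.gain_pre_mean + spec.gain_pre_sd * z1
            post = spec.gain_post_mean + spec.gain_post_sd * (
                rho * z1 + math.sqrt(1.0 - rho * rho) * z2
            )
            latent = rng.standard_normal()
            e_m, e_n = rng.standard_normal(2)
            sq = math.sqrt(1.0 - w * w)
            mssq = max(
                0.0, spec.mssq_mean + spec.mssq_sd * (w * latent + sq * e_m)
            )
            lo_n, hi_n = spec.nausea_range
            if symptomatic:
                u = norm.cdf(w * latent + sq * e_n)
                nausea = min(10, lo_n + int(u * (hi_n - lo_n + 1)))
            else:
                nausea = 0
            age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 18.0, 80.0))
            records.append(
                ParticipantRecord(
                    participant_id=f"p{pid:03d}",
                    susceptible=susceptible,
                    symptomatic=symptomatic,
                    age=round(age, 1),
                    mssq_short=round(mssq, 2),
                    nausea_max=nausea,
                    gain_pre=float(pre),
                    gain_post=float(post),
                )
            )
    return Cohort(records)
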