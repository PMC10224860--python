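"""End-to-end reproducible runs: config, seed fan-out, stages, manifest.

A run ties the stages together in the order of the study it emulates:
simulate a cohort with latent true gains, simulate a pre and a post vHIT
session per participant whose true gain is that participant's latent gain,
process every trace through the impulse pipeline, merge the measured pooled
gains back into the cohort, run the mixed-design inference and the power
curve, and record every artifact in a manifest. Identical (config, seed)
reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .cohort import Cohort, ParticipantRecord
from .errors import ConfigError, ConstantInputError, InsufficientImpulsesError, VhitError
from .io import write_cohort, write_trace
from .pipeline import DetectionParams, summarize_participant
from .stats import PowerSpec, mixed_anova_2x2, power_by_simulation, spearman
from .synthetic import CohortConfig, TraceConfig, simulate_cohort, simulate_trace

log = logging.getLogger("vhitkit")

# allowed configuration keys per block; anything else is rejected so a typo
# cannot silently fall back to a default
_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "trace", "cohort", "detection", "stats"},
    "trace": {
        "sampling_rate",
        "n_impulses_per_direction",
        "noise_sd",
        "vor_latency",
        "saccade_probability",
        "impulse_duration",
        "peak_velocity_range",
        "min_quiescence",
        "duration",
    },
    "cohort": {"pre_post_correlation", "mssq_nausea_coupling"},
    "detection": {
        "search_threshold",
        "onset_threshold",
        "refractory",
        "max_rise_time",
    },
    "stats": {"alpha", "power_n_grid", "power_reps", "pooling"},
}

# stage indices used in the seed fan-out; fixed so stages can be rerun in
# isolation with the same child seed
_STAGE_COHORT = 0
_STAGE_TRACES = 1
_STAGE_POWER = 2


@dataclass
class RunConfig:
    """Validated top-level configuration of an end-to-end run."""

    seed: int = 0
    trace: dict[str, Any] = field(default_factory=dict)
    cohort: dict[str, Any] = field(default_factory=dict)
    detection: dict[str, Any] = field(default_factory=dict)
    stats: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, raw: dict[str, Any]) -> "RunConfig":
        _check_keys(raw, "")
        for block in ("trace", "cohort", "detection", "stats"):
            _check_keys(raw.get(block, {}) or {}, block)
        return cls(
            seed=int(raw.get("seed", 0)),
            trace=dict(raw.get("trace", {}) or {}),
            cohort=dict(raw.get("cohort", {}) or {}),
            detection=dict(raw.get("detection", {}) or {}),
            stats=dict(raw.get("stats", {}) or {}),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_mapping(raw)


def _check_keys(block: dict[str, Any], name: str) -> None:
    if not isinstance(block, dict):
        raise ConfigError(f"config block {name or '<root>'!r} must be a mapping")
    unknown = sorted(set(block) - _SCHEMA[name])
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {unknown} in block {name or '<root>'!r}; "
            f"allowed: {sorted(_SCHEMA[name])}"
        )


def child_seed(seed: int, stage: int, *sub: int) -> int:
    """Deterministic per-stage seed derived from the global seed.

    Uses numpy's SeedSequence with ``spawn_key = (stage, *sub)`` and folds
    the first generated word into [0, 2^31).
    """
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(stage, *sub))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunManifest:
    """Record of one end-to-end run: config checksum, package version,
    per-stage artifacts (with checksums) and the exclusion log."""

    config_sha256: str
    version: str
    seed: int
    stages: dict[str, list[dict[str, str]]] = field(default_factory=dict)
    exclusions: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "config_sha256": self.config_sha256,
            "version": self.version,
            "seed": self.seed,
            "stages": self.stages,
            "exclusions": self.exclusions,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fmt(x: float | None) -> float | None:
    # fixed 9-significant-digit rounding for reproducible text output
    return None if x is None else float(f"{x:.9g}")


def run_end_to_end(config: RunConfig, out_dir: str | Path) -> RunManifest:
    """Execute the full simulate -> process -> analyze -> power workflow.

    Any stage failure is re-raised with the stage name attached. Returns the
    manifest, which is also written to ``<out_dir>/manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_blob = json.dumps(
        {
            "seed": config.seed,
            "trace": config.trace,
            "cohort": config.cohort,
            "detection": config.detection,
            "stats": config.stats,
        },
        sort_keys=True,
    ).encode()
    manifest = RunManifest(
        config_sha256=hashlib.sha256(config_blob).hexdigest(),
        version=__version__,
        seed=config.seed,
    )

    # --- stage: cohort simulation ------------------------------------------
    try:
        cohort_cfg = CohortConfig(
            seed=child_seed(config.seed, _STAGE_COHORT), **config.cohort
        )
        cohort = simulate_cohort(cohort_cfg)
        cohort_path = out / "cohort_latent.csv"
        write_cohort(cohort, cohort_path)
    except VhitError as exc:
        raise type(exc)(f"stage 'simulate-cohort': {exc}") from exc
    manifest.stages["simulate-cohort"] = [_artifact(out, cohort_path)]

    # --- stage: trace simulation + processing ------------------------------
    trace_dir = out / "traces"
    trace_dir.mkdir(exist_ok=True)
    params = DetectionParams(**config.detection)
    pooling = config.stats.get("pooling", "direction-mean")
    metrics_rows: list[dict[str, Any]] = []
    measured: list[ParticipantRecord] = []
    trace_artifacts: list[dict[str, str]] = []
    try:
        for i, rec in enumerate(cohort):
            summaries = {}
            for s_idx, (session, true_gain) in enumerate(
                (("pre", rec.gain_pre), ("post", rec.gain_post))
            ):
                cfg = TraceConfig(
                    true_gain_left=true_gain,
                    true_gain_right=true_gain,
                    seed=child_seed(config.seed, _STAGE_TRACES, i, s_idx),
                    **config.trace,
                )
                trace = simulate_trace(cfg)
                p = trace_dir / f"{rec.participant_id}_{session}.csv"
                write_trace(trace, p)
                trace_artifacts.append(_artifact(out, p))
                summaries[session] = trace
            pre_sum, post_sum = summarize_participant(
                summaries["pre"], summaries["post"], params,
                pooling=pooling, strict=False,
            )
            for session, summ in (("pre", pre_sum), ("post", post_sum)):
                metrics_rows.append(
                    {
                        "participant_id": rec.participant_id,
                        "session": session,
                        "gain_left": _fmt(summ.gain_left),
                        "gain_right": _fmt(summ.gain_right),
                        "gain_pooled": _fmt(summ.gain_pooled),
                        "asym_abs": _fmt(summ.asymmetry_abs),
                        "n_valid_left": summ.n_valid_left,
                        "n_valid_right": summ.n_valid_right,
                    }
                )
                if summ.excluded:
                    msg = (
                        f"{rec.participant_id} {session}: {summ.exclusion_reason}"
                    )
                    manifest.exclusions.append(msg)
                    log.warning("excluded %s", msg)
            if not (pre_sum.excluded or post_sum.excluded):
                measured.append(
                    replace(
                        rec,
                        gain_pre=float(pre_sum.gain_pooled),
                        gain_post=float(post_sum.gain_pooled),
                    )
                )
    except VhitError as exc:
        raise type(exc)(f"stage 'process': {exc}") from exc

    import pandas as pd

    metrics_path = out / "metrics.csv"
    pd.DataFrame(metrics_rows).to_csv(metrics_path, index=False)
    measured_path = out / "cohort_measured.csv"
    if measured:
        write_cohort(Cohort(measured), measured_path)
    manifest.stages["process"] = trace_artifacts + [
        _artifact(out, metrics_path)
    ] + ([_artifact(out, measured_path)] if measured else [])

    # --- stage: inference ---------------------------------------------------
    try:
        if len(measured) < 4:
            raise InsufficientImpulsesError(
                f"only {len(measured)} participants survived processing; "
                "too few for the mixed-design analysis"
            )
        analysis_cohort = Cohort(measured)
        report = mixed_anova_2x2(analysis_cohort)
        df = analysis_cohort.to_frame()
        try:
            rho, p_rho = spearman(df["mssq_short"], df["nausea_max"])
            spearman_block: dict[str, Any] = {
                "rho": _fmt(rho),
                "p": _fmt(p_rho),
                "n": int(len(df)),
            }
        except ConstantInputError as exc:
            spearman_block = {"rho": None, "p": None, "note": str(exc)}
        report_payload = {
            "n_per_group": report.n_per_group,
            "effects": {
                name: {
                    "F": _fmt(e.F),
                    "df1": e.df1,
                    "df2": e.df2,
                    "p": _fmt(e.p),
                    "BF10": _fmt(e.bf10),
                    "evidence": e.evidence,
                }
                for name, e in report.effects.items()
            },
            "spearman_mssq_vs_nausea": spearman_block,
        }
        report_path = out / "report.yaml"
        report_path.write_text(
            yaml.safe_dump(report_payload, sort_keys=True, default_flow_style=False)
        )
    except VhitError as exc:
        raise type(exc)(f"stage 'analyze': {exc}") from exc
    manifest.stages["analyze"] = [_artifact(out, report_path)]

    # --- stage: power curve -------------------------------------------------
    try:
        spec = PowerSpec(
            alpha=float(config.stats.get("alpha", 0.05)),
            n_reps=int(config.stats.get("power_reps", 1000)),
            seed=child_seed(config.seed, _STAGE_POWER),
        )
        grid = config.stats.get("power_n_grid", [10, 15, 20])
        rows = []
        for total_n in grid:
            res = power_by_simulation(spec, int(total_n))
            rows.append(
                {
                    "total_n": res.total_n,
                    "power": _fmt(res.power),
                    "ci_low": _fmt(res.ci_low),
                    "ci_high": _fmt(res.ci_high),
                }
            )
        power_path = out / "power_curve.csv"
        pd.DataFrame(rows).to_csv(power_path, index=False)
    except VhitError as exc:
        raise type(exc)(f"stage 'power': {exc}") from exc
    manifest.stages["power"] = [_artifact(out, power_path)]

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _artifact(root: Path, path: Path) -> dict[str, str]:
    return {"path": str(path.relative_to(root)), "sha256": _sha256(path)}
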