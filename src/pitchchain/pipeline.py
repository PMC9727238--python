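"""End-to-end orchestration: trials → per-pitch metrics → condition contrasts.

The pipeline is a pure function of its inputs and configuration: identical
trial files and config produce byte-identical outputs.  Each trial passes
through qualification, gap filling, zero-lag filtering, segment-frame
construction, event detection, inverse dynamics and peak extraction; the
per-pitch metrics table then feeds the GEE condition contrasts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dynamics, events, kinematics, stats
from .preprocess import FilterSpec, preprocess_trial
from .trial_io import (
    ExclusionRecord,
    THROWING_ARM_MARKERS,
    Trial,
    mirror_left_handed,
    qualify_trial,
    read_trial_c3d,
    read_trial_csv,
)

__all__ = [
    "PipelineConfig",
    "compute_pitch_metrics",
    "run_pipeline",
    "convert_units",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = (
    "subject_id", "condition", "ball_speed_mph", "sep_time_ms",
    "peak_omega_pelvis_degs", "peak_omega_trunk_degs",
    "peak_omega_upper_arm_degs", "peak_omega_forearm_degs",
    "peak_M_elbow_Nm", "peak_M_shoulder_Nm",
    "peak_P_elbow_W", "peak_P_shoulder_W",
    "mer_time_s", "flags",
)


@dataclass
class PipelineConfig:
    """Resolved pipeline settings; defaults match the module-level choices."""

    cutoff_hz: float = 12.5
    filter_order_effective: int = 4
    filter_order_is_per_pass: bool = False
    max_gap_frames: int = 20
    mer_window_pre_ms: float = 100.0
    mer_window_post_ms: float = 50.0
    peak_onset_deg_s: float = 50.0
    peak_post_mer_ms: float = 100.0
    ball_mass_kg: float = 0.0  # arm-only analysis by default
    alpha: float = 0.05
    seed: int = 0
    input_dir: str | None = None
    output_dir: str | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def filter_spec(self, rate: float) -> FilterSpec:
        return FilterSpec(
            cutoff=self.cutoff_hz,
            order_effective=self.filter_order_effective,
            rate=rate,
            order_is_per_pass=self.filter_order_is_per_pass,
        )


def compute_pitch_metrics(
    trial: Trial,
    config: PipelineConfig | None = None,
    filter_enabled: bool = True,
) -> dict | ExclusionRecord:
    """Reduce one pitch to its outcome row, or return the exclusion record."""
    config = config or PipelineConfig()
    qualified = qualify_trial(trial, THROWING_ARM_MARKERS, config.max_gap_frames)
    if isinstance(qualified, ExclusionRecord):
        return qualified
    trial = mirror_left_handed(qualified)
    trial = preprocess_trial(
        trial, config.filter_spec(trial.rate), config.max_gap_frames,
        filter_enabled=filter_enabled,
    )

    frames = kinematics.build_segment_frames(trial)
    omegas = {s: kinematics.angular_velocity(frames[s]) for s in kinematics.SEGMENTS}

    angle, gimbal = kinematics.external_rotation_angle(frames["upper_arm"], frames["trunk"])
    mer_frame, mer_time = events.detect_mer(angle, trial.rate)
    window = events.peak_search_window(
        omegas["trunk"], mer_frame,
        onset_deg_s=config.peak_onset_deg_s,
        post_mer_s=config.peak_post_mer_ms / 1000.0,
    )

    peaks = {s: events.refine_peak(omegas[s], window)
             for s in ("pelvis", "trunk", "upper_arm", "forearm")}
    sep = events.separation_time(peaks["pelvis"], peaks["trunk"])

    hand_distal = trial.markers["MC3"].positions
    lengths = dynamics.segment_lengths(frames, hand_distal)
    params = dynamics.zatsiorsky_params(trial.subject, lengths)
    loads = dynamics.inverse_dynamics_topdown(
        frames, omegas, params, hand_distal, ball_mass=config.ball_mass_kg,
        release_frame=mer_frame + int(round(0.010 * trial.rate))
        if config.ball_mass_kg > 0 else None,
    )
    powers = {
        "elbow": dynamics.joint_power(loads["elbow"], omegas["upper_arm"], omegas["forearm"]),
        "shoulder": dynamics.joint_power(loads["shoulder"], omegas["trunk"], omegas["upper_arm"]),
    }
    mer_peaks = dynamics.extract_peaks_at_mer(
        loads, powers, mer_time, trial.rate,
        window_pre_s=config.mer_window_pre_ms / 1000.0,
        window_post_s=config.mer_window_post_ms / 1000.0,
    )

    flags = []
    if gimbal.any():
        flags.append(f"gimbal:{int(gimbal.sum())}")
    for s, pk in peaks.items():
        if pk.fallback:
            flags.append(f"peak_fallback:{s}")
    if mer_peaks["window_clipped"]:
        flags.append("mer_window_clipped")

    return {
        "subject_id": trial.subject.subject_id,
        "condition": trial.condition,
        "ball_speed_mph": trial.ball_speed,
        "sep_time_ms": sep.dt_ms,
        "peak_omega_pelvis_degs": peaks["pelvis"].value_peak,
        "peak_omega_trunk_degs": peaks["trunk"].value_peak,
        "peak_omega_upper_arm_degs": peaks["upper_arm"].value_peak,
        "peak_omega_forearm_degs": peaks["forearm"].value_peak,
        "peak_M_elbow_Nm": mer_peaks["peak_M_elbow"],
        "peak_M_shoulder_Nm": mer_peaks["peak_M_shoulder"],
        "peak_P_elbow_W": mer_peaks["peak_P_elbow"],
        "peak_P_shoulder_W": mer_peaks["peak_P_shoulder"],
        "mer_time_s": mer_time,
        "flags": ";".join(flags),
    }


def _load_trials(input_dir: Path) -> list[tuple[str, Trial]]:
    trials: list[tuple[str, Trial]] = []
    for path in sorted(input_dir.glob("*.csv")):
        trials.append((path.name, read_trial_csv(path)))
    for path in sorted(input_dir.glob("*.c3d")):
        sidecar = path.with_suffix(".meta.yaml")
        meta = {}
        if sidecar.exists():
            with sidecar.open("r", encoding="utf-8") as fh:
                meta = yaml.safe_load(fh) or {}
        trials.append((path.name, read_trial_c3d(path, meta)))
    return trials


def run_pipeline(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process every trial in ``config.input_dir`` and fit the contrasts.

    Writes ``metrics.csv``, ``stats_summary.csv``, ``emm_table.csv``,
    ``run.log`` and ``resolved_config.yaml`` under ``config.output_dir`` and
    returns ``(metrics, stats_summary)``.
    """
    if not config.input_dir or not config.output_dir:
        raise ValueError("config must set input_dir and output_dir")
    input_dir, out = Path(config.input_dir), Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows, log_lines = [], []
    for name, trial in _load_trials(input_dir):
        result = compute_pitch_metrics(trial, config)
        if isinstance(result, ExclusionRecord):
            log_lines.append(
                f"{name}\texcluded\tmarker={result.marker}\t{result.reason}"
            )
            continue
        log_lines.append(
            f"{name}\tqualified\tmer={result['mer_time_s']:.4f}s"
            f"\tflags={result['flags'] or '-'}"
        )
        rows.append(result)

    metrics = pd.DataFrame(rows, columns=list(METRIC_COLUMNS))
    metrics.to_csv(out / "metrics.csv", index=False, float_format="%.6g")
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    with (out / "resolved_config.yaml").open("w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)

    if metrics.empty:
        raise RuntimeError(
            "no qualified trials; see run.log for exclusion reasons"
        )
    if metrics["subject_id"].nunique() >= 2 and metrics["condition"].nunique() == 2:
        summary, emm = stats.condition_summary(metrics, alpha=config.alpha)
        summary.to_csv(out / "stats_summary.csv", index=False, float_format="%.6g")
        emm.to_csv(out / "emm_table.csv", index=False, float_format="%.6g")
    else:
        summary = pd.DataFrame()
    return metrics, summary


_UNIT_FACTORS = {
    ("mph", "m/s"): 0.44704,
    ("m/s", "mph"): 1.0 / 0.44704,
    ("deg", "rad"): np.pi / 180.0,
    ("rad", "deg"): 180.0 / np.pi,
    ("ms", "s"): 1e-3,
    ("s", "ms"): 1e3,
}


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Exact-factor unit conversion (mph↔m/s, deg↔rad, ms↔s)."""
    if from_unit == to_unit:
        return value
    try:
        return value * _UNIT_FACTORS[(from_unit, to_unit)]
    except KeyError:
        raise ValueError(f"unsupported unit conversion {from_unit!r} -> {to_unit!r}")
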