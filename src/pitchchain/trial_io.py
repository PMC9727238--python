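"""Canonical data model for pitching trials and marker-trajectory I/O.

A trial is one fastball pitch: a set of 3-D marker trajectories sampled at a
common rate (400 frames/s by default), subject anthropometry, the experimental
condition, and the radar ball speed.  Positions are metres in a global frame
with +x to the pitcher's right, +y along the throwing direction and +z up.

Two on-disk representations are supported: a plain-text CSV dialect (used for
fixtures and archival) and the C3D motion-capture container (point data only).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MarkerTrajectory",
    "SubjectRecord",
    "Trial",
    "ExclusionRecord",
    "SEGMENT_MARKERS",
    "THROWING_ARM_MARKERS",
    "PLUGIN_GAIT_ALIASES",
    "read_trial_csv",
    "write_trial_csv",
    "read_trial_c3d",
    "write_trial_c3d",
    "qualify_trial",
    "mirror_left_handed",
]

#: Canonical marker labels per segment, sufficient to build all five
#: ISB-convention segment frames.
SEGMENT_MARKERS: dict[str, tuple[str, ...]] = {
    "pelvis": ("LASI", "RASI", "LPSI", "RPSI"),
    "trunk": ("IJ", "PX", "C7", "T8"),
    "upper_arm": ("ACR", "LEL", "MEL"),
    "forearm": ("LEL", "MEL", "RS", "US"),
    "hand": ("RS", "US", "MC3", "HND2"),
}

#: Markers that are indispensable for the throwing-arm analysis; a pitch with
#: an unfillable gap in any of these is excluded.
THROWING_ARM_MARKERS: tuple[str, ...] = ("ACR", "LEL", "MEL", "RS", "US", "MC3", "HND2")

#: Mapping from (throwing-side-specific) plug-in-gait labels to canonical ones.
PLUGIN_GAIT_ALIASES: dict[str, dict[str, str]] = {
    "right": {
        "CLAV": "IJ", "STRN": "PX", "C7": "C7", "T10": "T8",
        "RSHO": "ACR", "RELB": "LEL", "RELBM": "MEL", "RMEL": "MEL",
        "RWRA": "RS", "RWRB": "US", "RFIN": "MC3", "RHND": "HND2",
    },
    "left": {
        "CLAV": "IJ", "STRN": "PX", "C7": "C7", "T10": "T8",
        "LSHO": "ACR", "LELB": "LEL", "LELBM": "MEL", "LMEL": "MEL",
        "LWRA": "RS", "LWRB": "US", "LFIN": "MC3", "LHND": "HND2",
    },
}


@dataclass
class MarkerTrajectory:
    """One marker's global-frame positions over time.

    Parameters
    ----------
    name : str
        Anatomical landmark label (e.g. ``"LASI"``).
    positions : (T, 3) ndarray
        Global-frame coordinates in metres.  Rows where ``valid_mask`` is
        False hold placeholder values and must not be used.
    valid_mask : (T,) bool ndarray
        False marks occluded / missing samples.
    """

    name: str
    positions: np.ndarray
    valid_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError(f"marker {self.name!r}: positions must be (T, 3)")
        if self.positions.shape[0] < 2:
            raise ValueError(f"marker {self.name!r}: need at least 2 samples")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.positions.shape[0], dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != (self.positions.shape[0],):
            raise ValueError(f"marker {self.name!r}: valid_mask length mismatch")
        if not np.all(np.isfinite(self.positions[self.valid_mask])):
            raise ValueError(f"marker {self.name!r}: non-finite valid positions")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def invalid_runs(self) -> list[tuple[int, int]]:
        """Contiguous invalid stretches as half-open ``[start, stop)`` pairs."""
        runs: list[tuple[int, int]] = []
        invalid = ~self.valid_mask
        start = None
        for i, bad in enumerate(invalid):
            if bad and start is None:
                start = i
            elif not bad and start is not None:
                runs.append((start, i))
                start = None
        if start is not None:
            runs.append((start, len(invalid)))
        return runs


@dataclass(frozen=True)
class SubjectRecord:
    """Per-pitcher anthropometry."""

    subject_id: str
    body_mass: float  # kg
    body_height: float  # m
    throwing_side: str = "right"

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError("body_mass must be > 0")
        if self.body_height <= 0:
            raise ValueError("body_height must be > 0")
        if self.throwing_side not in ("right", "left"):
            raise ValueError("throwing_side must be 'right' or 'left'")


CONDITIONS = ("unimpeded", "impeded")


@dataclass
class Trial:
    """One pitch: marker set + metadata."""

    subject: SubjectRecord
    condition: str
    markers: dict[str, MarkerTrajectory]
    rate: float = 400.0
    ball_speed: float | None = None  # mph, radar; may be absent pre-synthesis
    qualified: bool = True

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        lengths = {m.n_frames for m in self.markers.values()}
        if len(lengths) > 1:
            raise ValueError(f"markers disagree on frame count: {sorted(lengths)}")

    @property
    def n_frames(self) -> int:
        return next(iter(self.markers.values())).n_frames

    def times(self) -> np.ndarray:
        """Frame times in seconds, t = frame / rate (frames are 0-based)."""
        return np.arange(self.n_frames) / self.rate

    def with_markers(self, markers: dict[str, MarkerTrajectory]) -> "Trial":
        return replace(self, markers=markers)


@dataclass(frozen=True)
class ExclusionRecord:
    """Why a pitch was dropped from the analysis."""

    subject_id: str
    condition: str
    marker: str
    reason: str
    run_length: int | None = None


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_CSV_POS_FMT = "%.6f"


def write_trial_csv(trial: Trial, path: str | Path) -> None:
    """Write a trial in the package CSV dialect.

    Header comment lines carry rate / subject / condition / ball speed /
    anthropometry; the body is ``frame,<label>_x,<label>_y,<label>_z,...``
    with empty cells for invalid samples.  Positions in metres, 6 decimals.
    """
    path = Path(path)
    labels = list(trial.markers)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# rate={trial.rate:g}\n")
        fh.write(f"# subject={trial.subject.subject_id}\n")
        fh.write(f"# condition={trial.condition}\n")
        bs = "NA" if trial.ball_speed is None else f"{trial.ball_speed:.4f}"
        fh.write(f"# ball_speed_mph={bs}\n")
        fh.write(f"# body_mass_kg={trial.subject.body_mass:g}\n")
        fh.write(f"# body_height_m={trial.subject.body_height:g}\n")
        fh.write(f"# throwing_side={trial.subject.throwing_side}\n")
        cols = ["frame"]
        for lab in labels:
            cols += [f"{lab}_x", f"{lab}_y", f"{lab}_z"]
        fh.write(",".join(cols) + "\n")
        T = trial.n_frames
        for t in range(T):
            row = [str(t)]
            for lab in labels:
                traj = trial.markers[lab]
                if traj.valid_mask[t]:
                    row += [_CSV_POS_FMT % v for v in traj.positions[t]]
                else:
                    row += ["", "", ""]
            fh.write(",".join(row) + "\n")


def read_trial_csv(path: str | Path) -> Trial:
    """Read a trial written by :func:`write_trial_csv` (lossless round trip)."""
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines) and lines[i].startswith("#"):
        key, _, val = lines[i][1:].strip().partition("=")
        meta[key.strip()] = val.strip()
        i += 1
    if i >= len(lines):
        raise ValueError(f"{path}: no header row found")
    header = lines[i].split(",")
    if header[0] != "frame":
        raise ValueError(f"{path}: malformed header, first column {header[0]!r} (expected 'frame')")
    if (len(header) - 1) % 3 != 0:
        raise ValueError(f"{path}: position columns not in x/y/z triples")
    labels: list[str] = []
    for j in range(1, len(header), 3):
        base = header[j]
        if not base.endswith("_x"):
            raise ValueError(f"{path}: malformed header column {base!r} (expected *_x)")
        lab = base[:-2]
        if header[j + 1] != f"{lab}_y" or header[j + 2] != f"{lab}_z":
            raise ValueError(f"{path}: malformed header around column {base!r}")
        labels.append(lab)

    body = lines[i + 1:]
    T = len(body)
    pos = np.zeros((len(labels), T, 3))
    mask = np.ones((len(labels), T), dtype=bool)
    for t, line in enumerate(body):
        cells = line.split(",")
        for k in range(len(labels)):
            trio = cells[1 + 3 * k: 4 + 3 * k]
            if any(c == "" for c in trio):
                mask[k, t] = False
            else:
                pos[k, t] = [float(c) for c in trio]

    subject = SubjectRecord(
        subject_id=meta.get("subject", "unknown"),
        body_mass=float(meta.get("body_mass_kg", "80.6")),
        body_height=float(meta.get("body_height_m", "1.87")),
        throwing_side=meta.get("throwing_side", "right"),
    )
    bs = meta.get("ball_speed_mph", "NA")
    markers = {
        lab: MarkerTrajectory(lab, pos[k], mask[k]) for k, lab in enumerate(labels)
    }
    return Trial(
        subject=subject,
        condition=meta.get("condition", "unimpeded"),
        markers=markers,
        rate=float(meta.get("rate", "400")),
        ball_speed=None if bs.upper() == "NA" else float(bs),
    )


# ---------------------------------------------------------------------------
# C3D (delegates to the minimal reader/writer in pitchchain.c3d)
# ---------------------------------------------------------------------------

def write_trial_c3d(trial: Trial, path: str | Path) -> None:
    """Write point data + residual validity flags to a C3D file."""
    from . import c3d

    labels = list(trial.markers)
    T = trial.n_frames
    pts = np.zeros((T, len(labels), 3))
    valid = np.ones((T, len(labels)), dtype=bool)
    for k, lab in enumerate(labels):
        pts[:, k, :] = trial.markers[lab].positions
        valid[:, k] = trial.markers[lab].valid_mask
    c3d.write_c3d(path, labels, pts, valid, rate=trial.rate, units="m")


def read_trial_c3d(
    path: str | Path,
    meta: Mapping[str, object] | None = None,
    required_markers: Sequence[str] = (),
) -> Trial:
    """Read a trial from a C3D file plus a subject/condition sidecar mapping.

    ``meta`` keys: subject_id, body_mass, body_height, throwing_side,
    condition, ball_speed (all optional; anthropometry defaults to the cohort
    means).  ``valid_mask`` is False wherever the file marks a point invalid.
    """
    from . import c3d

    path = Path(path)
    if not path.exists():
        raise IOError(f"C3D file not found: {path}")
    labels, pts, valid, rate = c3d.read_c3d(path)
    meta = dict(meta or {})
    missing = [m for m in required_markers if m not in labels]
    if missing:
        raise ValueError(f"{path}: required markers absent: {missing}")
    markers = {
        lab: MarkerTrajectory(lab, pts[:, k, :], valid[:, k])
        for k, lab in enumerate(labels)
    }
    subject = SubjectRecord(
        subject_id=str(meta.get("subject_id", "unknown")),
        body_mass=float(meta.get("body_mass", 80.6)),
        body_height=float(meta.get("body_height", 1.87)),
        throwing_side=str(meta.get("throwing_side", "right")),
    )
    bs = meta.get("ball_speed")
    return Trial(
        subject=subject,
        condition=str(meta.get("condition", "unimpeded")),
        markers=markers,
        rate=rate,
        ball_speed=None if bs is None else float(bs),
    )


# ---------------------------------------------------------------------------
# Qualification
# ---------------------------------------------------------------------------

def qualify_trial(
    trial: Trial,
    required_markers: Sequence[str] = THROWING_ARM_MARKERS,
    max_gap: int = 20,
) -> Trial | ExclusionRecord:
    """Apply the pitch-qualification rule.

    A pitch is excluded when any indispensable marker is entirely missing or
    has a contiguous invalid run longer than ``max_gap`` frames (boundary
    inclusive: a run of exactly ``max_gap`` still qualifies).  The default of
    20 frames is 50 ms at 400 Hz, beyond which cubic interpolation of a fast
    throwing arm is unreliable.
    """
    if not required_markers:
        raise ValueError("required_markers must be nonempty")
    for lab in sorted(required_markers):
        traj = trial.markers.get(lab)
        if traj is None or not traj.valid_mask.any():
            return ExclusionRecord(
                trial.subject.subject_id, trial.condition, lab,
                "marker entirely missing", None,
            )
        for start, stop in traj.invalid_runs():
            if stop - start > max_gap:
                return ExclusionRecord(
                    trial.subject.subject_id, trial.condition, lab,
                    f"invalid run of {stop - start} frames exceeds max_gap={max_gap}",
                    stop - start,
                )
    return replace(trial, qualified=True)


def mirror_left_handed(trial: Trial) -> Trial:
    """Mirror the global x-axis so a left-handed pitch can be analysed with
    the right-handed throwing convention.  No-op for right-handed trials."""
    if trial.subject.throwing_side == "right":
        return trial
    markers = {}
    for lab, traj in trial.markers.items():
        pos = traj.positions.copy()
        pos[:, 0] = -pos[:, 0]
        markers[lab] = MarkerTrajectory(lab, pos, traj.valid_mask.copy())
    subject = replace(trial.subject, throwing_side="right")
    return replace(trial, markers=markers, subject=subject)
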