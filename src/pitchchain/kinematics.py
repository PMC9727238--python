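"""Segment coordinate frames and angular velocities.

Five segments are modelled — pelvis, trunk, upper arm, forearm, hand — with
local frames following the International Society of Biomechanics convention
(Y along the segment long axis pointing proximally/superiorly, X anterior,
Z to the right, right-handed).  Orientation matrices store the local axes as
columns expressed in the global frame.

Joint centres are deterministic marker constructions: the glenohumeral centre
is the acromion marker offset 7% of body height inferiorly along the trunk
long axis, the elbow centre is the epicondyle midpoint, and the wrist centre
is the styloid midpoint.

Angular velocity is extracted from the rotation matrices via the
skew-symmetric matrix Ω = Ṙ Rᵀ (global frame), with Ṙ from central
differences; its magnitude is the Euclidean norm of the vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .trial_io import Trial, SEGMENT_MARKERS

__all__ = [
    "SegmentFrameSeries",
    "AngularVelocitySeries",
    "build_segment_frames",
    "angular_velocity",
    "external_rotation_angle",
    "SEGMENTS",
]

SEGMENTS = ("pelvis", "trunk", "upper_arm", "forearm", "hand")

#: Glenohumeral centre depth below the acromion, as a fraction of body height.
GH_OFFSET_FRACTION = 0.07

_DEGENERATE_TOL = 1e-9
_ORTHO_TOL = 1e-6


@dataclass
class SegmentFrameSeries:
    """Time series of a segment's orientation and origin.

    ``R`` is (T, 3, 3) with columns = local axes in the global frame
    (orthonormal, det +1); ``origin`` is (T, 3) in metres and coincides with
    the segment's proximal joint centre.
    """

    segment: str
    R: np.ndarray
    origin: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.R.ndim != 3 or self.R.shape[1:] != (3, 3):
            raise ValueError("R must be (T, 3, 3)")
        if self.origin.shape != (self.R.shape[0], 3):
            raise ValueError("origin must be (T, 3)")

    @property
    def n_frames(self) -> int:
        return self.R.shape[0]

    def check_orthonormal(self, tol: float = _ORTHO_TOL) -> None:
        err = np.abs(np.einsum("tij,tik->tjk", self.R, self.R) - np.eye(3)).max()
        if err > tol:
            raise ValueError(
                f"{self.segment}: orientation matrices not orthonormal "
                f"(max deviation {err:.2e})"
            )
        if np.any(np.linalg.det(self.R) < 0):
            raise ValueError(f"{self.segment}: left-handed orientation matrix")


@dataclass
class AngularVelocitySeries:
    """Global-frame segment angular velocity and its magnitude trace."""

    segment: str
    omega: np.ndarray  # (T, 3) rad/s
    rate: float

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)

    @property
    def omega_norm(self) -> np.ndarray:
        """Euclidean norm of the angular velocity vector, rad/s."""
        return np.linalg.norm(self.omega, axis=1)

    @property
    def omega_norm_deg(self) -> np.ndarray:
        return np.degrees(self.omega_norm)

    @property
    def n_frames(self) -> int:
        return self.omega.shape[0]


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    bad = np.flatnonzero(n[..., 0] < _DEGENERATE_TOL)
    if bad.size:
        raise ValueError(f"degenerate marker geometry ({what}) at frame {bad[0]}")
    return v / n


def _frames_from_axes(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    R = np.stack([x, y, z], axis=-1)
    return R


def _positions(trial: Trial, label: str) -> np.ndarray:
    traj = trial.markers.get(label)
    if traj is None:
        raise ValueError(f"required marker {label!r} missing from trial")
    if not traj.valid_mask.all():
        raise ValueError(f"marker {label!r} has invalid samples; preprocess first")
    return traj.positions


def build_segment_frames(trial: Trial) -> dict[str, SegmentFrameSeries]:
    """Construct all five segment frame series from a preprocessed trial."""
    p = {lab: _positions(trial, lab)
         for seg in SEGMENT_MARKERS for lab in SEGMENT_MARKERS[seg]}
    rate = trial.rate
    out: dict[str, SegmentFrameSeries] = {}

    # pelvis: Z along the ASIS line (to the right), X anterior in the plane of
    # the ASISes and the mid-PSIS point, Y superior.
    mid_asis = 0.5 * (p["LASI"] + p["RASI"])
    mid_psis = 0.5 * (p["LPSI"] + p["RPSI"])
    z = _unit(p["RASI"] - p["LASI"], "pelvis ASIS line")
    v = mid_asis - mid_psis
    x = _unit(v - np.sum(v * z, axis=1, keepdims=True) * z, "pelvis anterior axis")
    y = np.cross(z, x)
    out["pelvis"] = SegmentFrameSeries("pelvis", _frames_from_axes(x, y, z), mid_asis, rate)

    # trunk (thorax): Y from mid(PX, T8) up to mid(IJ, C7), X anterior.
    y = _unit(0.5 * (p["IJ"] + p["C7"]) - 0.5 * (p["PX"] + p["T8"]), "trunk long axis")
    w = p["IJ"] - p["C7"]
    x = _unit(w - np.sum(w * y, axis=1, keepdims=True) * y, "trunk anterior axis")
    z = np.cross(x, y)
    out["trunk"] = SegmentFrameSeries("trunk", _frames_from_axes(x, y, z), p["IJ"], rate)
    trunk_y = y

    # upper arm: Y from the elbow centre up to the glenohumeral centre,
    # anterior axis perpendicular to the epicondyle line.
    gh = p["ACR"] - GH_OFFSET_FRACTION * trial.subject.body_height * trunk_y
    ejc = 0.5 * (p["LEL"] + p["MEL"])
    y = _unit(gh - ejc, "upper arm long axis")
    w = p["LEL"] - p["MEL"]
    x = _unit(np.cross(y, w), "upper arm epicondyle plane")
    z = np.cross(x, y)
    out["upper_arm"] = SegmentFrameSeries("upper_arm", _frames_from_axes(x, y, z), gh, rate)

    # forearm: Y from the wrist centre up to the elbow centre.
    wjc = 0.5 * (p["RS"] + p["US"])
    y = _unit(ejc - wjc, "forearm long axis")
    w = p["RS"] - p["US"]
    x = _unit(np.cross(y, w), "forearm styloid plane")
    z = np.cross(x, y)
    out["forearm"] = SegmentFrameSeries("forearm", _frames_from_axes(x, y, z), ejc, rate)

    # hand: Y from the third metacarpal head up to the wrist centre; the
    # dorsal marker fixes the plane.
    y = _unit(wjc - p["MC3"], "hand long axis")
    d = p["HND2"] - 0.5 * (wjc + p["MC3"])
    x = _unit(np.cross(y, d), "hand dorsal plane")
    z = np.cross(x, y)
    out["hand"] = SegmentFrameSeries("hand", _frames_from_axes(x, y, z), wjc, rate)

    for series in out.values():
        series.check_orthonormal()
    return out


def _matrix_derivative(R: np.ndarray, rate: float) -> np.ndarray:
    """Entry-wise central differences; one-sided at the ends."""
    Rdot = np.empty_like(R)
    Rdot[1:-1] = (R[2:] - R[:-2]) * (rate / 2.0)
    Rdot[0] = (R[1] - R[0]) * rate
    Rdot[-1] = (R[-1] - R[-2]) * rate
    return Rdot


def angular_velocity(frames: SegmentFrameSeries) -> AngularVelocitySeries:
    """Segment angular velocity from the rotation-matrix time series.

    ω is the axial vector of Ω = Ṙ Rᵀ.  Ω is explicitly antisymmetrised as
    (Ω − Ωᵀ)/2 to suppress numerical asymmetry before vector extraction.
    """
    if frames.n_frames < 3:
        raise ValueError("need at least 3 frames for angular velocity")
    frames.check_orthonormal()
    Rdot = _matrix_derivative(frames.R, frames.rate)
    Omega = np.einsum("tij,tkj->tik", Rdot, frames.R)  # Ṙ Rᵀ
    Omega = 0.5 * (Omega - np.swapaxes(Omega, 1, 2))
    omega = np.stack(
        [Omega[:, 2, 1], Omega[:, 0, 2], Omega[:, 1, 0]], axis=1
    )
    return AngularVelocitySeries(frames.segment, omega, frames.rate)


def external_rotation_angle(
    upper_arm: SegmentFrameSeries,
    trunk: SegmentFrameSeries,
    gimbal_tol: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Humerothoracic axial-rotation angle (degrees), external positive.

    The humerus orientation relative to the thorax is decomposed with the ISB
    shoulder Y-X-Y sequence (plane of elevation, elevation, axial rotation);
    the third angle is returned, unwrapped over time.  Frames whose elevation
    is within ``gimbal_tol`` rad of the degenerate poles are flagged and the
    angle there is interpolated from neighbouring frames.

    Returns ``(angle_deg, gimbal_flags)``.
    """
    if upper_arm.n_frames != trunk.n_frames or upper_arm.rate != trunk.rate:
        raise ValueError("upper arm and trunk series must share T and rate")
    import warnings

    R_rel = np.einsum("tji,tjk->tik", trunk.R, upper_arm.R)  # trunkᵀ · upper_arm
    rot = Rotation.from_matrix(R_rel)
    with warnings.catch_warnings():
        # degenerate poles are handled explicitly below via the flags
        warnings.simplefilter("ignore", UserWarning)
        ang = rot.as_euler("YXY")  # intrinsic Y-X-Y, radians
    elevation = ang[:, 1]
    axial = ang[:, 2].copy()
    flags = np.minimum(np.abs(elevation), np.abs(np.pi - np.abs(elevation))) < gimbal_tol
    if flags.all():
        # Degenerate throughout (e.g. identical frames): axial rotation and
        # plane of elevation are indistinguishable; report their sum, which
        # is 0 for identical frames.
        axial = ang[:, 0] + ang[:, 2]
        return np.degrees(axial), flags
    if flags.any():
        good = np.flatnonzero(~flags)
        axial[flags] = np.interp(np.flatnonzero(flags), good, axial[good])
    axial = np.unwrap(axial)
    return np.degrees(axial), flags
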