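"""Inertial parameters and top-down inverse dynamics for the throwing arm.

Segment masses, centre-of-mass locations and transverse moments of inertia
come from the de Leva-adjusted Zatsiorsky anthropometric tables (male values);
the moment of inertia about each segment's longitudinal axis is treated as
negligible and set to zero.

Net joint forces and moments are obtained by a distal-to-proximal
Newton–Euler recursion starting at the free hand (no distal load), expressed
in the global frame.  The convention is proximal-on-distal: the returned load
at a joint is what the proximal segment exerts on the distal one.  Joint
power is the dot product of the net joint moment with the angular velocity
difference across the joint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import AngularVelocitySeries, SegmentFrameSeries

__all__ = [
    "InertialParams",
    "JointLoadSeries",
    "JointPowerSeries",
    "ZATSIORSKY_DELEVA_MALE",
    "zatsiorsky_params",
    "segment_lengths",
    "inverse_dynamics_topdown",
    "joint_power",
    "extract_peaks_at_mer",
]

GRAVITY = 9.81  # m/s², along −z global

#: de Leva-adjusted Zatsiorsky table, male: mass fraction of body mass,
#: CoM position from the proximal end as a fraction of segment length, and
#: radii of gyration (sagittal, transverse) as fractions of segment length.
#: The longitudinal radius is omitted because the longitudinal moment of
#: inertia is set to zero throughout.
ZATSIORSKY_DELEVA_MALE: dict[str, dict[str, float]] = {
    "upper_arm": {"mass_frac": 0.0271, "com_frac": 0.5772,
                  "r_sagittal": 0.285, "r_transverse": 0.269},
    "forearm": {"mass_frac": 0.0162, "com_frac": 0.4574,
                "r_sagittal": 0.276, "r_transverse": 0.265},
    "hand": {"mass_frac": 0.0061, "com_frac": 0.7900,
             "r_sagittal": 0.628, "r_transverse": 0.513},
}

ARM_SEGMENTS = ("upper_arm", "forearm", "hand")


@dataclass(frozen=True)
class InertialParams:
    """Per-segment inertial parameters.

    Moments of inertia are about the centre of mass: ``I_coronal`` about the
    segment's anterior (local x) axis, ``I_sagittal`` about the lateral
    (local z) axis, and ``I_longitudinal`` about the long (local y) axis,
    fixed at zero.
    """

    segment: str
    mass: float  # kg
    com_fraction: float  # from the proximal end
    length: float  # m
    I_coronal: float  # kg·m²
    I_sagittal: float  # kg·m²
    I_longitudinal: float = 0.0

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be > 0")
        if not 0 < self.com_fraction < 1:
            raise ValueError("com_fraction must lie in (0, 1)")
        if self.I_longitudinal != 0.0:
            raise ValueError("I_longitudinal is fixed at 0 in this analysis")

    def inertia_local(self) -> np.ndarray:
        """Inertia tensor in the segment frame (x anterior, y long, z right)."""
        return np.diag([self.I_coronal, self.I_longitudinal, self.I_sagittal])


@dataclass
class JointLoadSeries:
    """Net force and moment at a joint, global frame, proximal-on-distal."""

    joint: str
    F: np.ndarray  # (T, 3) N
    M: np.ndarray  # (T, 3) Nm
    rate: float

    @property
    def M_norm(self) -> np.ndarray:
        return np.linalg.norm(self.M, axis=1)


@dataclass
class JointPowerSeries:
    """Mechanical joint power P = M · (ω_distal − ω_proximal), watts."""

    joint: str
    P: np.ndarray  # (T,)
    rate: float


def zatsiorsky_params(
    subject, seg_lengths: dict[str, float]
) -> dict[str, InertialParams]:
    """Inertial parameters for the three arm segments.

    mass = table fraction × body mass; I = mass · (radius fraction × length)²
    about the transverse axes at the CoM; longitudinal inertia zero.
    """
    out: dict[str, InertialParams] = {}
    for seg in ARM_SEGMENTS:
        L = float(seg_lengths[seg])
        if not 0.05 <= L <= 0.6:
            raise ValueError(
                f"{seg}: implausible segment length {L:.3f} m (must be 0.05–0.6 m)"
            )
        row = ZATSIORSKY_DELEVA_MALE[seg]
        m = row["mass_frac"] * subject.body_mass
        out[seg] = InertialParams(
            segment=seg,
            mass=m,
            com_fraction=row["com_frac"],
            length=L,
            I_coronal=m * (row["r_transverse"] * L) ** 2,
            I_sagittal=m * (row["r_sagittal"] * L) ** 2,
        )
    return out


def _endpoints(
    frames: dict[str, SegmentFrameSeries], hand_distal: np.ndarray
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """(proximal, distal) joint-point series per arm segment.

    Origins coincide with proximal joint centres; the hand's distal endpoint
    is the third metacarpal head trajectory.
    """
    return {
        "upper_arm": (frames["upper_arm"].origin, frames["forearm"].origin),
        "forearm": (frames["forearm"].origin, frames["hand"].origin),
        "hand": (frames["hand"].origin, np.asarray(hand_distal, dtype=float)),
    }


def segment_lengths(
    frames: dict[str, SegmentFrameSeries], hand_distal: np.ndarray
) -> dict[str, float]:
    """Mean proximal-to-distal endpoint distance per arm segment."""
    ends = _endpoints(frames, hand_distal)
    return {
        seg: float(np.linalg.norm(d - p, axis=1).mean())
        for seg, (p, d) in ends.items()
    }


def _second_derivative(x: np.ndarray, rate: float) -> np.ndarray:
    """Double central difference; end frames copy their neighbours."""
    a = np.empty_like(x)
    a[1:-1] = (x[2:] - 2 * x[1:-1] + x[:-2]) * rate**2
    a[0] = a[1]
    a[-1] = a[-2]
    return a


def _first_derivative(x: np.ndarray, rate: float) -> np.ndarray:
    d = np.empty_like(x)
    d[1:-1] = (x[2:] - x[:-2]) * (rate / 2.0)
    d[0] = (x[1] - x[0]) * rate
    d[-1] = (x[-1] - x[-2]) * rate
    return d


def inverse_dynamics_topdown(
    frames: dict[str, SegmentFrameSeries],
    omegas: dict[str, AngularVelocitySeries],
    inertial: dict[str, InertialParams],
    hand_distal: np.ndarray,
    gravity: float = GRAVITY,
    ball_mass: float = 0.0,
    release_frame: int | None = None,
) -> dict[str, JointLoadSeries]:
    """Newton–Euler recursion hand → forearm → upper arm.

    For each segment (distal load F_d, M_d known, zero at the free hand):

        F_p = m (a_com − g) + F_d
        M_p = I ω̇ + ω × (I ω) + (r_com − r_p) × F_p − (r_com − r_d) × F_d + M_d

    all in the global frame, g = −gravity ẑ.  Returns loads keyed by
    ``wrist``, ``elbow`` and ``shoulder``.  ``ball_mass`` optionally adds a
    point mass at the hand CoM up to ``release_frame`` (exclusive); by
    default the analysis is arm-only (free hand).
    """
    ends = _endpoints(frames, hand_distal)
    T = frames["hand"].n_frames
    if T < 5:
        raise ValueError("need at least 5 frames for CoM accelerations")
    rate = frames["hand"].rate
    g_vec = np.array([0.0, 0.0, -gravity])

    joint_of = {"hand": "wrist", "forearm": "elbow", "upper_arm": "shoulder"}
    loads: dict[str, JointLoadSeries] = {}
    F_d = np.zeros((T, 3))
    M_d = np.zeros((T, 3))
    r_d: np.ndarray | None = None  # distal joint point of the current segment

    for seg in ("hand", "forearm", "upper_arm"):
        par = inertial[seg]
        prox, dist = ends[seg]
        com = prox + par.com_fraction * (dist - prox)
        a_com = _second_derivative(com, rate)
        if not np.all(np.isfinite(a_com)):
            bad = np.flatnonzero(~np.isfinite(a_com).all(axis=1))
            raise ValueError(
                f"{seg}: non-finite CoM acceleration at frames "
                f"[{bad[0]}, {bad[-1] + 1})"
            )
        mass = np.full(T, par.mass)
        if seg == "hand" and ball_mass > 0:
            extra = np.full(T, ball_mass)
            if release_frame is not None:
                extra[release_frame:] = 0.0
            mass = mass + extra

        omega = omegas[seg].omega
        omega_dot = _first_derivative(omega, rate)
        R = frames[seg].R
        I_glob = np.einsum("tij,jk,tlk->til", R, par.inertia_local(), R)
        I_omega = np.einsum("tij,tj->ti", I_glob, omega)
        euler = np.einsum("tij,tj->ti", I_glob, omega_dot) + np.cross(omega, I_omega)

        F_p = mass[:, None] * (a_com - g_vec) + F_d
        M_p = euler + np.cross(com - prox, F_p) + M_d
        if r_d is not None:
            M_p -= np.cross(com - r_d, F_d)
        loads[joint_of[seg]] = JointLoadSeries(joint_of[seg], F_p, M_p, rate)
        F_d, M_d, r_d = F_p, M_p, prox

    return loads


def joint_power(
    load: JointLoadSeries,
    omega_prox: AngularVelocitySeries,
    omega_dist: AngularVelocitySeries,
) -> JointPowerSeries:
    """P = M · (ω_distal − ω_proximal), watts."""
    if not (omega_prox.n_frames == omega_dist.n_frames == load.M.shape[0]):
        raise ValueError("joint power inputs must share the frame count")
    omega_joint = omega_dist.omega - omega_prox.omega
    P = np.einsum("ti,ti->t", load.M, omega_joint)
    return JointPowerSeries(load.joint, P, load.rate)


def extract_peaks_at_mer(
    loads: dict[str, JointLoadSeries],
    powers: dict[str, JointPowerSeries],
    mer_time: float,
    rate: float,
    window_pre_s: float = 0.100,
    window_post_s: float = 0.050,
) -> dict[str, float | bool]:
    """Peak moment magnitude and peak power around MER.

    Maxima of ‖M‖ and P over [t_MER − pre, t_MER + post] for the elbow and
    shoulder.  When the window is clipped by the trial bounds the result is
    flagged (``window_clipped``) and computed on the clipped range.
    """
    T = next(iter(loads.values())).M.shape[0]
    lo = int(np.floor((mer_time - window_pre_s) * rate))
    hi = int(np.ceil((mer_time + window_post_s) * rate)) + 1
    clipped = lo < 0 or hi > T
    lo, hi = max(0, lo), min(T, hi)
    if hi <= lo:
        raise ValueError("MER extraction window is empty")
    out: dict[str, float | bool] = {"window_clipped": clipped}
    for joint in ("elbow", "shoulder"):
        out[f"peak_M_{joint}"] = float(loads[joint].M_norm[lo:hi].max())
        out[f"peak_P_{joint}"] = float(powers[joint].P[lo:hi].max())
    return out
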