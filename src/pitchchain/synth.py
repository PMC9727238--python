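"""Synthetic pitching trials with known ground truth.

The generator emulates the delivery phase of a fastball pitch as a 5-segment
chain.  Pelvis and trunk rotate about the global vertical axis with Gaussian
angular-velocity pulses whose peak times are offset by a configurable
separation time; the humerus carries an axial external-rotation bump peaking
at a prescribed MER instant; elbow extension and a wrist snap follow.  All
segment orientations are closed-form products of elementary rotations, so
angular velocities, peak values and times, MER, and marker positions are known
analytically — the generated trial plus its truth record lets every pipeline
stage be verified without motion-capture data.

Marker placement inverts the frame constructions used by the analysis: the
rest pose is calibrated through :func:`~pitchchain.kinematics.build_segment_frames`
itself, so for noise-free trials the recovered frames equal the generating
ones exactly.

Default pulse magnitudes are calibrated to the scales reported for elite
adolescent pitchers (pelvis peak ≈ 675 deg/s, trunk ≈ 1000 deg/s, separation
time ≈ 32.7 ms); they are a calibration, not ground truth about any athlete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .kinematics import SEGMENTS, build_segment_frames
from .trial_io import MarkerTrajectory, SubjectRecord, Trial

__all__ = [
    "PitchProfile",
    "TruthRecord",
    "AnalyticCase",
    "generate_trial",
    "generate_cohort",
    "analytic_cases",
    "COHORT_MEANS",
    "COHORT_BETWEEN_SD",
    "COHORT_WITHIN_SD",
    "STUDY_SCALE_EFFECTS",
    "OUTCOME_COLUMNS",
]

MPH_PER_MS = 1.0 / 0.44704


@dataclass(frozen=True)
class PitchProfile:
    """Parameters of one synthetic pitch.

    Angular-velocity pulse amplitudes are in deg/s, times in seconds from
    trial start, widths are Gaussian σ in seconds.  ``sep_time_ms`` is the
    pelvis→trunk peak-time offset (the ground-truth separation time).
    """

    rate: float = 400.0
    duration: float = 1.5
    pelvis_amp_degs: float = 675.0
    pelvis_peak_time: float = 0.60
    pelvis_width: float = 0.050
    trunk_amp_degs: float = 1000.0
    sep_time_ms: float = 32.7
    trunk_width: float = 0.045
    mer_time: float = 0.72
    er_amplitude_deg: float = 120.0
    er_width: float = 0.055
    elbow_amp_degs: float = 900.0
    elbow_peak_time: float = 0.75
    elbow_width: float = 0.030
    wrist_amp_degs: float = 400.0
    wrist_peak_time: float = 0.76
    wrist_width: float = 0.025
    upper_arm_length: float = 0.30
    forearm_length: float = 0.27
    hand_length: float = 0.08
    noise_sigma: float = 0.0  # m, marker-level Gaussian noise
    release_offset_s: float = 0.010  # ball release after MER
    ball_speed_noise_mph: float = 0.5
    n_gaps: int = 0  # intermittent occlusion gaps to inject
    gap_length: int = 5  # frames per gap
    seed: int = 0

    def __post_init__(self) -> None:
        for w in (self.pelvis_width, self.trunk_width, self.er_width,
                  self.elbow_width, self.wrist_width):
            if w <= 0:
                raise ValueError("pulse widths must be > 0")
        if self.duration * self.rate < 64:
            raise ValueError("trial too short")

    @property
    def trunk_peak_time(self) -> float:
        return self.pelvis_peak_time + self.sep_time_ms / 1000.0


@dataclass
class TruthRecord:
    """Ground truth of a generated pitch, consistent by construction."""

    peak_omega_degs: dict[str, float]
    peak_omega_time: dict[str, float]
    sep_time_ms: float
    mer_time: float
    ball_speed_mph: float  # noise-free hand-speed-derived value
    markers_clean: dict[str, np.ndarray]
    omega: dict[str, np.ndarray]  # (T, 3) rad/s on the trial grid
    R: dict[str, np.ndarray]  # (T, 3, 3) on the trial grid


# ---------------------------------------------------------------------------
# Rest pose and calibration
# ---------------------------------------------------------------------------

def _rest_markers(profile: PitchProfile, straight_arm: bool = False) -> dict[str, np.ndarray]:
    """Plausible standing rest pose, right-handed thrower facing +y.

    Arm abducted along +x; forearm vertical (elbow flexed) by default or
    straight along +x when ``straight_arm``.
    """
    Lu, Lf, Lh = profile.upper_arm_length, profile.forearm_length, profile.hand_length
    m: dict[str, np.ndarray] = {
        "LASI": [-0.12, 0.09, 1.00], "RASI": [0.12, 0.09, 1.00],
        "LPSI": [-0.05, -0.10, 1.02], "RPSI": [0.05, -0.10, 1.02],
        "IJ": [0.00, 0.09, 1.43], "PX": [0.00, 0.11, 1.28],
        "C7": [0.00, -0.05, 1.46], "T8": [0.00, -0.07, 1.28],
        "ACR": [0.19, 0.00, 1.50],
    }
    # The GH centre implied by the construction (trunk long axis is +z here).
    gh = np.array([0.19, 0.00, 1.50 - 0.07 * 1.87])
    ejc = gh + np.array([Lu, 0.0, 0.0])
    m["LEL"] = ejc + np.array([0.0, 0.035, 0.0])
    m["MEL"] = ejc - np.array([0.0, 0.035, 0.0])
    fore_dir = np.array([1.0, 0.0, 0.0]) if straight_arm else np.array([0.0, 0.0, 1.0])
    wjc = ejc + Lf * fore_dir
    m["RS"] = wjc + np.array([0.0, 0.03, 0.0])
    m["US"] = wjc - np.array([0.0, 0.03, 0.0])
    mc3 = wjc + Lh * fore_dir
    m["MC3"] = mc3
    m["HND2"] = wjc + 0.5 * Lh * fore_dir + np.array([0.025, 0.02, 0.0])
    return {k: np.asarray(v, dtype=float) for k, v in m.items()}


def _calibrate_rest(markers: dict[str, np.ndarray], subject: SubjectRecord):
    """Run the analysis frame construction on the rest pose.

    Returns ``(R0, o0)`` dicts per segment; the generator then moves these
    frames analytically, guaranteeing generator/analyzer closure.
    """
    two = {k: MarkerTrajectory(k, np.stack([v, v]), np.ones(2, bool))
           for k, v in markers.items()}
    trial = Trial(subject=subject, condition="unimpeded", markers=two, rate=400.0)
    frames = build_segment_frames(trial)
    R0 = {s: frames[s].R[0] for s in SEGMENTS}
    o0 = {s: frames[s].origin[0] for s in SEGMENTS}
    return R0, o0


def _rz(phi: np.ndarray) -> np.ndarray:
    c, s = np.cos(phi), np.sin(phi)
    R = np.zeros(phi.shape + (3, 3))
    R[..., 0, 0], R[..., 0, 1] = c, -s
    R[..., 1, 0], R[..., 1, 1] = s, c
    R[..., 2, 2] = 1.0
    return R


def _ry(phi: np.ndarray) -> np.ndarray:
    c, s = np.cos(phi), np.sin(phi)
    R = np.zeros(phi.shape + (3, 3))
    R[..., 0, 0], R[..., 0, 2] = c, s
    R[..., 2, 0], R[..., 2, 2] = -s, c
    R[..., 1, 1] = 1.0
    return R


def _gauss(t: np.ndarray, t0: float, s: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - t0) / s) ** 2)


def _gauss_integral(t: np.ndarray, amp: float, t0: float, s: float) -> np.ndarray:
    """∫ amp·exp(−(u−t0)²/2s²) du from −∞ to t."""
    return amp * s * math.sqrt(2 * math.pi) * ndtr((t - t0) / s)


def _chain_state(profile: PitchProfile, t: np.ndarray,
                 R0: dict[str, np.ndarray], o0: dict[str, np.ndarray],
                 subject: SubjectRecord,
                 markers_rest: dict[str, np.ndarray]):
    """Closed-form segment orientations, origins, angular velocities and
    marker positions on an arbitrary time grid."""
    d2r = math.pi / 180.0
    Ap, At = profile.pelvis_amp_degs * d2r, profile.trunk_amp_degs * d2r
    tp, tt = profile.pelvis_peak_time, profile.trunk_peak_time
    sp, st = profile.pelvis_width, profile.trunk_width

    phi_p = _gauss_integral(t, Ap, tp, sp)
    phi_t = _gauss_integral(t, At, tt, st)
    dphi_p = Ap * _gauss(t, tp, sp)
    dphi_t = At * _gauss(t, tt, st)

    gam_amp = profile.er_amplitude_deg * d2r
    gam = gam_amp * _gauss(t, profile.mer_time, profile.er_width)
    dgam = gam * (-(t - profile.mer_time) / profile.er_width**2)

    Be = profile.elbow_amp_degs * d2r
    beta = _gauss_integral(t, Be, profile.elbow_peak_time, profile.elbow_width)
    dbeta = Be * _gauss(t, profile.elbow_peak_time, profile.elbow_width)

    Bw = profile.wrist_amp_degs * d2r
    delta = _gauss_integral(t, Bw, profile.wrist_peak_time, profile.wrist_width)
    ddelta = Bw * _gauss(t, profile.wrist_peak_time, profile.wrist_width)

    zhat = np.array([0.0, 0.0, 1.0])
    pivot = o0["pelvis"]

    R = {}
    R["pelvis"] = _rz(phi_p) @ R0["pelvis"]
    R["trunk"] = _rz(phi_t) @ R0["trunk"]
    K1 = R0["trunk"].T @ R0["upper_arm"]
    R["upper_arm"] = R["trunk"] @ K1 @ _ry(gam)
    K2 = R0["upper_arm"].T @ R0["forearm"]
    R["forearm"] = R["upper_arm"] @ _rz(beta) @ K2
    K3 = R0["forearm"].T @ R0["hand"]
    R["hand"] = R["forearm"] @ _rz(delta) @ K3

    def tr_map(x):  # trunk-rigid points rotate about the vertical axis
        return np.einsum("tij,j->ti", _rz(phi_t), x - pivot) + pivot

    def pel_map(x):
        return np.einsum("tij,j->ti", _rz(phi_p), x - pivot) + pivot

    origin = {
        "pelvis": pel_map(o0["pelvis"]),
        "trunk": tr_map(o0["trunk"]),
        "upper_arm": tr_map(o0["upper_arm"]),  # GH rigid in the trunk
    }
    A_ua = R["upper_arm"] @ R0["upper_arm"].T
    origin["forearm"] = np.einsum(
        "tij,j->ti", A_ua, o0["forearm"] - o0["upper_arm"]) + origin["upper_arm"]
    A_fa = R["forearm"] @ R0["forearm"].T
    origin["hand"] = np.einsum(
        "tij,j->ti", A_fa, o0["hand"] - o0["forearm"]) + origin["forearm"]
    A_h = R["hand"] @ R0["hand"].T

    omega = {
        "pelvis": dphi_p[:, None] * zhat,
        "trunk": dphi_t[:, None] * zhat,
    }
    omega["upper_arm"] = omega["trunk"] + dgam[:, None] * R["upper_arm"][:, :, 1]
    omega["forearm"] = omega["upper_arm"] + dbeta[:, None] * R["upper_arm"][:, :, 2]
    omega["hand"] = omega["forearm"] + ddelta[:, None] * R["forearm"][:, :, 2]

    markers = {}
    for lab in ("LASI", "RASI", "LPSI", "RPSI"):
        markers[lab] = pel_map(markers_rest[lab])
    for lab in ("IJ", "PX", "C7", "T8"):
        markers[lab] = tr_map(markers_rest[lab])
    markers["ACR"] = origin["upper_arm"] + (
        0.07 * subject.body_height) * R["trunk"][:, :, 1]
    for lab in ("LEL", "MEL"):
        markers[lab] = np.einsum(
            "tij,j->ti", A_ua, markers_rest[lab] - o0["upper_arm"]) + origin["upper_arm"]
    for lab in ("RS", "US"):
        markers[lab] = np.einsum(
            "tij,j->ti", A_fa, markers_rest[lab] - o0["forearm"]) + origin["forearm"]
    for lab in ("MC3", "HND2"):
        markers[lab] = np.einsum(
            "tij,j->ti", A_h, markers_rest[lab] - o0["hand"]) + origin["hand"]
    return R, origin, omega, markers


DEFAULT_SUBJECT = SubjectRecord("synthetic", body_mass=80.6, body_height=1.87)


def generate_trial(
    profile: PitchProfile | None = None,
    subject: SubjectRecord | None = None,
) -> tuple[Trial, TruthRecord]:
    """Generate one synthetic pitch and its ground-truth record.

    Deterministic under a fixed ``profile.seed``.  Noise and occlusion gaps
    are applied to the returned trial only; the truth record keeps the clean
    markers and the analytic kinematics.
    """
    profile = profile or PitchProfile()
    subject = subject or DEFAULT_SUBJECT
    rng = np.random.default_rng(profile.seed)

    rest = _rest_markers(profile)
    R0, o0 = _calibrate_rest(rest, subject)

    T = int(round(profile.duration * profile.rate))
    t = np.arange(T) / profile.rate
    R, origin, omega, markers = _chain_state(profile, t, R0, o0, subject, rest)

    # Integration-stability guard: per-frame rotation increments must be small.
    max_step = max(np.linalg.norm(w, axis=1).max() for w in omega.values()) / profile.rate
    if max_step > 0.2:
        raise ValueError(
            f"angle step {max_step:.3f} rad/frame exceeds 0.2; use a higher rate"
        )

    # Ground truth on a dense grid (10× rate) from the same closed forms.
    td = np.arange(0, profile.duration, 1.0 / (10 * profile.rate))
    _, _, omega_d, markers_d = _chain_state(profile, td, R0, o0, subject, rest)
    peak_val, peak_time = {}, {}
    for seg in SEGMENTS:
        norm = np.degrees(np.linalg.norm(omega_d[seg], axis=1))
        k = int(np.argmax(norm))
        peak_val[seg], peak_time[seg] = float(norm[k]), float(td[k])

    # Ball speed: hand-marker (MC3) speed at release, radar-style in mph.
    release_t = profile.mer_time + profile.release_offset_s
    kr = int(round(release_t * 10 * profile.rate))
    kr = min(max(kr, 1), len(td) - 2)
    v = (markers_d["MC3"][kr + 1] - markers_d["MC3"][kr - 1]) * (10 * profile.rate / 2)
    ball_truth = float(np.linalg.norm(v)) * MPH_PER_MS

    trajs: dict[str, MarkerTrajectory] = {}
    for lab, pos in markers.items():
        noisy = pos + rng.normal(0.0, profile.noise_sigma, pos.shape) \
            if profile.noise_sigma > 0 else pos.copy()
        trajs[lab] = MarkerTrajectory(lab, noisy, np.ones(T, bool))
    if profile.n_gaps > 0:
        labels = sorted(trajs)
        for _ in range(profile.n_gaps):
            lab = labels[rng.integers(len(labels))]
            start = int(rng.integers(2, T - profile.gap_length - 2))
            trajs[lab].valid_mask[start:start + profile.gap_length] = False

    ball = ball_truth + (rng.normal(0.0, profile.ball_speed_noise_mph)
                         if profile.ball_speed_noise_mph > 0 else 0.0)
    trial = Trial(subject=subject, condition="unimpeded", markers=trajs,
                  rate=profile.rate, ball_speed=ball)
    truth = TruthRecord(
        peak_omega_degs=peak_val,
        peak_omega_time=peak_time,
        sep_time_ms=peak_time["trunk"] * 1000 - peak_time["pelvis"] * 1000,
        mer_time=profile.mer_time,
        ball_speed_mph=ball_truth,
        markers_clean=markers,
        omega=omega,
        R=R,
    )
    return trial, truth


# ---------------------------------------------------------------------------
# Outcome-level cohort generator (for the statistics stage)
# ---------------------------------------------------------------------------

OUTCOME_COLUMNS = (
    "ball_speed_mph", "sep_time_ms",
    "peak_omega_pelvis_degs", "peak_omega_trunk_degs",
    "peak_omega_upper_arm_degs", "peak_omega_forearm_degs",
    "peak_M_elbow_Nm", "peak_M_shoulder_Nm",
    "peak_P_elbow_W", "peak_P_shoulder_W",
)

#: Grand means under the unimpeded condition, calibrated to the scales
#: reported for elite adolescent fastball pitching.
COHORT_MEANS: dict[str, float] = {
    "ball_speed_mph": 76.6, "sep_time_ms": 32.7,
    "peak_omega_pelvis_degs": 675.0, "peak_omega_trunk_degs": 1050.0,
    "peak_omega_upper_arm_degs": 1700.0, "peak_omega_forearm_degs": 2200.0,
    "peak_M_elbow_Nm": 54.8, "peak_M_shoulder_Nm": 75.9,
    "peak_P_elbow_W": 950.0, "peak_P_shoulder_W": 1200.0,
}

#: Between-pitcher SDs (cluster-level heterogeneity).
COHORT_BETWEEN_SD: dict[str, float] = {
    "ball_speed_mph": 2.6, "sep_time_ms": 18.0,
    "peak_omega_pelvis_degs": 92.0, "peak_omega_trunk_degs": 140.0,
    "peak_omega_upper_arm_degs": 220.0, "peak_omega_forearm_degs": 280.0,
    "peak_M_elbow_Nm": 8.7, "peak_M_shoulder_Nm": 8.5,
    "peak_P_elbow_W": 250.0, "peak_P_shoulder_W": 350.0,
}

#: Within-pitcher (pitch-to-pitch) SDs.
COHORT_WITHIN_SD: dict[str, float] = {
    "ball_speed_mph": 2.0, "sep_time_ms": 45.0,
    "peak_omega_pelvis_degs": 118.0, "peak_omega_trunk_degs": 180.0,
    "peak_omega_upper_arm_degs": 280.0, "peak_omega_forearm_degs": 350.0,
    "peak_M_elbow_Nm": 6.5, "peak_M_shoulder_Nm": 14.0,
    "peak_P_elbow_W": 260.0, "peak_P_shoulder_W": 347.0,
}

#: Impeded-minus-unimpeded shifts at the scale observed when pelvis–trunk
#: mobility is taped: slightly slower ball, shorter separation time, higher
#: pelvic angular velocity, small non-significant load/power decreases.
STUDY_SCALE_EFFECTS: dict[str, float] = {
    "ball_speed_mph": -0.6, "sep_time_ms": -12.4,
    "peak_omega_pelvis_degs": 45.0, "peak_omega_trunk_degs": 0.0,
    "peak_omega_upper_arm_degs": 0.0, "peak_omega_forearm_degs": 0.0,
    "peak_M_elbow_Nm": -0.9, "peak_M_shoulder_Nm": -1.8,
    "peak_P_elbow_W": -51.0, "peak_P_shoulder_W": -36.0,
}


def generate_cohort(
    n_subjects: int = 11,
    pitches_per_condition: int = 22,
    effects: dict[str, float] | None = None,
    between_sd: dict[str, float] | None = None,
    within_sd: dict[str, float] | None = None,
    means: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Hierarchical outcome-level cohort for the statistics stage.

    Subject means are drawn Normal(grand mean, between-SD); pitch outcomes
    Normal(subject mean + condition shift, within-SD).  Returns a tidy frame
    with one row per pitch (``subject_id``, ``condition`` and one column per
    outcome).
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    effects = {**{k: 0.0 for k in OUTCOME_COLUMNS}, **(effects or {})}
    between_sd = between_sd or COHORT_BETWEEN_SD
    within_sd = within_sd or COHORT_WITHIN_SD
    means = means or COHORT_MEANS
    for d, name in ((between_sd, "between_sd"), (within_sd, "within_sd")):
        if any(v < 0 for v in d.values()):
            raise ValueError(f"{name} must be nonnegative")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        sid = f"P{s + 1:02d}"
        subj_mean = {
            k: means[k] + rng.normal(0.0, between_sd[k]) for k in OUTCOME_COLUMNS
        }
        for cond in ("unimpeded", "impeded"):
            shift = 1.0 if cond == "impeded" else 0.0
            for _ in range(pitches_per_condition):
                row = {"subject_id": sid, "condition": cond}
                for k in OUTCOME_COLUMNS:
                    row[k] = subj_mean[k] + shift * effects[k] + rng.normal(
                        0.0, within_sd[k])
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Analytic oracle cases for the dynamics stage
# ---------------------------------------------------------------------------

@dataclass
class AnalyticCase:
    """A trial whose joint loads have a closed form."""

    name: str
    trial: Trial
    #: expected(loads_inputs) -> dict of expected arrays/values; see each case
    expected: dict


def _static_trial(markers: dict[str, np.ndarray], T: int, rate: float,
                  subject: SubjectRecord) -> Trial:
    trajs = {k: MarkerTrajectory(k, np.tile(v, (T, 1)), np.ones(T, bool))
             for k, v in markers.items()}
    return Trial(subject=subject, condition="unimpeded", markers=trajs, rate=rate)


def analytic_cases(T: int = 120, rate: float = 400.0) -> list[AnalyticCase]:
    """Closed-form dynamics oracles.

    * ``static_horizontal_arm`` — straight arm held horizontally: shoulder
      moment magnitude is Σ mᵢ g dᵢ with dᵢ the horizontal CoM distances
      (expected key ``shoulder_M_norm(params, frames, hand_distal)``).
    * ``free_fall`` — whole chain accelerating at g with no rotation: all
      joint forces and moments vanish.
    * ``constant_rotation_pendulum`` — rigid straight arm rotating at
      constant rate about a horizontal axis through the shoulder: with zero
      longitudinal inertia the shoulder moment reduces to the gravity term
      −Σ mᵢ (rᵢ − r_GH) × g (key ``shoulder_M(params, frames, hand_distal)``).
    """
    profile = PitchProfile()
    subject = DEFAULT_SUBJECT
    rest = _rest_markers(profile, straight_arm=True)
    cases: list[AnalyticCase] = []

    def _com_positions(params, frames, hand_distal):
        from .dynamics import _endpoints

        ends = _endpoints(frames, hand_distal)
        return {
            seg: p + params[seg].com_fraction * (d - p)
            for seg, (p, d) in ends.items()
        }

    # (a) static horizontal arm
    def static_expected(params, frames, hand_distal):
        g = 9.81
        gh = frames["upper_arm"].origin
        coms = _com_positions(params, frames, hand_distal)
        total = np.zeros(gh.shape[0])
        for seg, com in coms.items():
            d = np.linalg.norm((com - gh)[:, :2], axis=1)
            total += params[seg].mass * g * d
        return total

    cases.append(AnalyticCase(
        "static_horizontal_arm",
        _static_trial(rest, T, rate, subject),
        {"shoulder_M_norm": static_expected},
    ))

    # (b) free fall: markers translate with a = g, no rotation
    t = np.arange(T) / rate
    drop = -0.5 * 9.81 * t**2 + 2.0  # start high enough to stay meaningful
    ff_markers = {
        k: v[None, :] + np.stack([np.zeros(T), np.zeros(T), drop], axis=1)
        for k, v in rest.items()
    }
    trajs = {k: MarkerTrajectory(k, p, np.ones(T, bool)) for k, p in ff_markers.items()}
    cases.append(AnalyticCase(
        "free_fall",
        Trial(subject=subject, condition="unimpeded", markers=trajs, rate=rate),
        {"all_loads_zero": True},
    ))

    # (c) rigid straight arm swinging at constant rate about the horizontal
    # +y axis through the shoulder (arm sweeps the x–z plane, so the segment
    # long axes stay perpendicular to the rotation axis)
    Omega = math.radians(200.0)  # constant rate, 200 deg/s
    gh0 = np.array([0.19, 0.00, 1.50 - 0.07 * 1.87])
    ang = Omega * t
    c, s = np.cos(ang), np.sin(ang)
    Ry = np.zeros((T, 3, 3))
    Ry[:, 1, 1] = 1.0
    Ry[:, 0, 0], Ry[:, 0, 2] = c, s
    Ry[:, 2, 0], Ry[:, 2, 2] = -s, c
    arm_labels = ("LEL", "MEL", "RS", "US", "MC3", "HND2")
    pend_markers = {k: np.tile(v, (T, 1)) for k, v in rest.items()
                    if k not in arm_labels}
    for k in arm_labels:
        pend_markers[k] = np.einsum("tij,j->ti", Ry, rest[k] - gh0) + gh0
    # ACR must keep implying a fixed GH: trunk is static, so a constant ACR
    # works (the rest pose already satisfies GH = ACR − 0.07 h ŷ_trunk).
    trajs = {k: MarkerTrajectory(k, p.copy(), np.ones(T, bool))
             for k, p in pend_markers.items()}

    def pendulum_expected(params, frames, hand_distal):
        g_vec = np.array([0.0, 0.0, -9.81])
        gh = frames["upper_arm"].origin
        coms = _com_positions(params, frames, hand_distal)
        M = np.zeros((gh.shape[0], 3))
        for seg, com in coms.items():
            M -= params[seg].mass * np.cross(com - gh, g_vec)
        return M

    cases.append(AnalyticCase(
        "constant_rotation_pendulum",
        Trial(subject=subject, condition="unimpeded", markers=trajs, rate=rate),
        {"shoulder_M": pendulum_expected, "rate_deg_s": 200.0},
    ))
    return cases
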