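"""Pitch events: sub-sample angular-velocity peaks, MER, separation time.

Peak instants are refined by least-squares fitting a second-order polynomial
to 11 samples (five on each side of the discrete maximum); the vertex gives
the sub-sample peak time and value.  Maximal external rotation (MER) is the
first frame at which the humerothoracic axial-rotation angle attains its
maximum.  Separation time is the interval between the pelvis and trunk peak
angular velocities, positive when the trunk peaks later (proximal-to-distal
order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import AngularVelocitySeries

__all__ = [
    "PeakEvent",
    "SeparationTime",
    "refine_peak",
    "detect_mer",
    "separation_time",
    "peak_search_window",
]

_HALF_WINDOW = 5  # samples on each side of the discrete maximum


@dataclass(frozen=True)
class PeakEvent:
    """A refined angular-velocity peak."""

    segment: str
    t_peak: float  # s, sub-sample
    value_peak: float  # deg/s
    window: tuple[int, int]  # frame range of the 11-point fit, half-open
    fallback: bool = False  # True when the parabola vertex was rejected


@dataclass(frozen=True)
class SeparationTime:
    """Pelvis–trunk peak interval; positive = trunk peaks after pelvis."""

    dt_ms: float
    pelvis_t: float
    trunk_t: float


def peak_search_window(
    trunk_omega: AngularVelocitySeries,
    mer_frame: int | None = None,
    onset_deg_s: float = 50.0,
    post_mer_s: float = 0.100,
) -> tuple[int, int]:
    """Restrict the peak search to the delivery phase.

    Start: first frame where the trunk angular-velocity magnitude exceeds
    ``onset_deg_s`` (a stride-foot-contact proxy); end: 100 ms after MER when
    an MER frame is given, else the end of the trial.  Half-open range.
    """
    norm = trunk_omega.omega_norm_deg
    above = np.flatnonzero(norm > onset_deg_s)
    start = int(above[0]) if above.size else 0
    if mer_frame is not None:
        stop = min(len(norm), mer_frame + int(round(post_mer_s * trunk_omega.rate)) + 1)
    else:
        stop = len(norm)
    if stop - start < 2 * _HALF_WINDOW + 1:
        start, stop = 0, len(norm)
    return start, stop


def refine_peak(
    series: AngularVelocitySeries,
    window: tuple[int, int] | None = None,
) -> PeakEvent:
    """Sub-sample peak of the angular-velocity magnitude (deg/s).

    A parabola is least-squares fitted to the 11 samples centred on the
    discrete maximum (earliest frame on plateau ties).  The vertex is used
    when it is concave and lies within ±1 frame of the discrete maximum;
    otherwise the discrete maximum is returned with ``fallback=True``.
    """
    y = series.omega_norm_deg
    T = len(y)
    if T < 2 * _HALF_WINDOW + 1:
        raise ValueError(f"need at least {2 * _HALF_WINDOW + 1} samples, got {T}")
    lo, hi = window if window is not None else (0, T)
    lo, hi = max(0, lo), min(T, hi)
    k = lo + int(np.argmax(y[lo:hi]))  # argmax returns the earliest tie
    rate = series.rate

    a0, b0 = k - _HALF_WINDOW, k + _HALF_WINDOW + 1
    if a0 < 0 or b0 > T:
        # Discrete maximum too close to the trial bounds for an 11-point fit.
        return PeakEvent(series.segment, k / rate, float(y[k]), (max(a0, 0), min(b0, T)), True)

    idx = np.arange(a0, b0)
    t = idx / rate
    tc = t - t[_HALF_WINDOW]  # centre for conditioning
    coeff = np.polynomial.polynomial.polyfit(tc, y[idx], deg=2)  # c0 + c1 t + c2 t²
    c0, c1, c2 = coeff
    if c2 < 0:
        t_vertex = -c1 / (2 * c2)
        if abs(t_vertex) <= 1.0 / rate:  # within ±1 frame of the discrete max
            v = c0 + c1 * t_vertex + c2 * t_vertex**2
            return PeakEvent(series.segment, t_vertex + t[_HALF_WINDOW], float(v), (a0, b0), False)
    return PeakEvent(series.segment, k / rate, float(y[k]), (a0, b0), True)


def detect_mer(angle_deg: np.ndarray, rate: float) -> tuple[int, float]:
    """First frame at which the external-rotation angle is maximal.

    Returns ``(frame_index, time_s)``.  An all-constant series carries no
    event and raises.
    """
    angle_deg = np.asarray(angle_deg, dtype=float)
    if angle_deg.size == 0 or not np.all(np.isfinite(angle_deg)):
        raise ValueError("angle series must be nonempty and finite")
    if np.ptp(angle_deg) == 0:
        raise ValueError("external-rotation angle is constant; no MER event")
    k = int(np.argmax(angle_deg))  # argmax picks the first of exact ties
    return k, k / rate


def separation_time(pelvis_peak: PeakEvent, trunk_peak: PeakEvent) -> SeparationTime:
    """Trunk peak time minus pelvis peak time, in milliseconds."""
    dt = (trunk_peak.t_peak - pelvis_peak.t_peak) * 1000.0
    return SeparationTime(dt, pelvis_peak.t_peak, trunk_peak.t_peak)
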