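"""Gap filling and zero-lag low-pass filtering of marker trajectories.

Occlusion gaps are filled with a cubic polynomial through the nearest valid
neighbours, then each coordinate is low-pass filtered with a zero-lag
(forward-backward) Butterworth filter.  The default is a second-order filter
run in both directions — a fourth-order zero-phase cascade — with the cutoff
corrected so the −3 dB point of the cascade sits at the nominal frequency
(12.5 Hz by default), the dominant convention in motion-capture processing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .trial_io import MarkerTrajectory, Trial

__all__ = ["FilterSpec", "fill_gaps", "lowpass_zero_lag", "preprocess_trial"]


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass filter settings.

    ``order_effective`` is the order of the zero-phase cascade (forward plus
    backward pass); 4 means a second-order Butterworth applied twice.  Set
    ``order_is_per_pass=True`` to instead interpret the order as that of each
    single pass (a fourth-order filter run twice, net order 8).
    """

    cutoff: float = 12.5  # Hz, −3 dB point of the cascade
    order_effective: int = 4
    rate: float = 400.0
    order_is_per_pass: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.cutoff < self.rate / 2:
            raise ValueError("cutoff must lie in (0, rate/2)")
        if self.order_effective < 2 or self.order_effective % 2:
            raise ValueError("order_effective must be an even integer >= 2")

    @property
    def per_pass_order(self) -> int:
        if self.order_is_per_pass:
            return self.order_effective
        return self.order_effective // 2

    @property
    def corrected_cutoff(self) -> float:
        """Single-pass cutoff giving a cascade −3 dB point at ``cutoff``.

        Two identical Butterworth passes of order n attenuate to 1/2 at the
        frequency where each pass gives 1/sqrt(2); the single-pass cutoff must
        therefore be raised by (2**(1/2) − 1)**(−1/(2n)).
        """
        n = self.per_pass_order
        return self.cutoff / (2 ** 0.5 - 1) ** (1.0 / (2 * n))


def fill_gaps(traj: MarkerTrajectory, max_gap: int = 20) -> MarkerTrajectory:
    """Fill interior occlusion gaps with a third-order (cubic) polynomial.

    Each invalid run is interpolated from the two nearest valid samples on
    each side (four points determine the cubic exactly); when fewer than two
    exist on a side, a least-squares cubic over all valid samples within a
    ±10-frame window is used.  Leading/trailing gaps cannot be interpolated
    and raise; so do runs longer than ``max_gap``.
    """
    if traj.valid_mask.all():
        return traj
    T = traj.n_frames
    runs = traj.invalid_runs()
    for start, stop in runs:
        if start == 0 or stop == T:
            raise ValueError(
                f"marker {traj.name!r}: leading/trailing gap [{start}, {stop}) "
                "cannot be interpolated; trim the trial first"
            )
        if stop - start > max_gap:
            raise ValueError(
                f"marker {traj.name!r}: gap of {stop - start} frames exceeds "
                f"max_gap={max_gap}"
            )
    pos = traj.positions.copy()
    valid_idx = np.flatnonzero(traj.valid_mask)
    for start, stop in runs:
        left = valid_idx[valid_idx < start][-2:]
        right = valid_idx[valid_idx >= stop][:2]
        support = np.concatenate([left, right])
        if len(left) < 2 or len(right) < 2:
            lo, hi = max(0, start - 10), min(T, stop + 10)
            support = valid_idx[(valid_idx >= lo) & (valid_idx < hi)]
        if len(support) < 4:
            raise ValueError(
                f"marker {traj.name!r}: insufficient valid support around gap "
                f"[{start}, {stop})"
            )
        # Centre the abscissa for conditioning; degree-3 fit is exact with
        # 4 support points.
        t0 = support.mean()
        for axis in range(3):
            coeff = np.polynomial.polynomial.polyfit(
                support - t0, pos[support, axis], deg=3
            )
            gap = np.arange(start, stop) - t0
            pos[start:stop, axis] = np.polynomial.polynomial.polyval(gap, coeff)
    return MarkerTrajectory(traj.name, pos, np.ones(T, dtype=bool))


def lowpass_zero_lag(traj: MarkerTrajectory, spec: FilterSpec | None = None) -> MarkerTrajectory:
    """Zero-lag Butterworth low-pass, applied independently per coordinate.

    The trajectory must be fully valid (run :func:`fill_gaps` first).  Edge
    effects are handled by ``sosfiltfilt``'s odd reflection padding with
    padlen = 3 × (order + 1) samples.
    """
    spec = spec or FilterSpec()
    if not traj.valid_mask.all():
        raise ValueError(f"marker {traj.name!r}: fill gaps before filtering")
    n = spec.per_pass_order
    padlen = 3 * (n + 1)
    if traj.n_frames <= max(6 * n, padlen):
        raise ValueError(
            f"marker {traj.name!r}: need more than {max(6 * n, padlen)} samples "
            f"to filter (got {traj.n_frames})"
        )
    sos = butter(n, spec.corrected_cutoff, btype="low", fs=spec.rate, output="sos")
    pos = sosfiltfilt(sos, traj.positions, axis=0, padlen=padlen)
    return MarkerTrajectory(traj.name, np.ascontiguousarray(pos), traj.valid_mask.copy())


def preprocess_trial(trial: Trial, spec: FilterSpec | None = None,
                     max_gap: int = 20, filter_enabled: bool = True) -> Trial:
    """Fill gaps and filter every marker of a trial."""
    spec = spec or FilterSpec(rate=trial.rate)
    out = {}
    for lab, traj in trial.markers.items():
        filled = fill_gaps(traj, max_gap=max_gap)
        out[lab] = lowpass_zero_lag(filled, spec) if filter_enabled else filled
    return trial.with_markers(out)
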