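"""Gait-event and turn detection from shank angular velocity.

The detector keys on the sagittal-plane shank angular velocity (gyro_y): the
high positive peak in each gait cycle is the mid-swing, and the troughs
immediately before and after it are toe-off and heel-strike.  The turn in a
walk-turn-walk trial appears as a gap in threshold-passing mid-swings on both
legs; the first post-gap swing peak, smaller than the other leg's following
peak, closes the turn.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from ..core_io import ValidationError
from ..preprocess import FilterSpec, butterworth_lowpass

__all__ = ["GaitEventParams", "GaitEvents", "DetectionError", "detect_gait_events", "detect_turn"]


class DetectionError(ValueError):
    """Event or turn detection failed (with diagnostics in the message)."""


@dataclass(frozen=True)
class GaitEventParams:
    #: low-pass cutoff applied to gyro_y before peak picking, Hz
    smooth_cutoff_hz: float = 10.0
    #: absolute floor for the mid-swing amplitude threshold, deg/s
    min_peak_amp: float = 50.0
    #: adaptive threshold as a fraction of the global |gyro_y| maximum
    rel_peak_frac: float = 0.4
    #: minimum peak separation as a fraction of the median inter-peak interval
    min_sep_frac: float = 0.4
    #: a merged-timeline gap this many times the median step gap marks the turn
    turn_gap_factor: float = 1.75


@dataclass
class LegEvents:
    mid_swing: np.ndarray      # times, s
    toe_off: np.ndarray
    heel_strike: np.ndarray
    mid_swing_amp: np.ndarray  # filtered gyro_y value at each mid-swing


@dataclass
class GaitEvents:
    left: LegEvents
    right: LegEvents
    turn_start: Optional[float] = None
    turn_end: Optional[float] = None

    def validate(self) -> None:
        for leg in (self.left, self.right):
            if not (np.all(leg.toe_off < leg.mid_swing) and np.all(leg.mid_swing < leg.heel_strike)):
                raise ValidationError("event ordering violated: need toe_off < mid_swing < heel_strike")
            if np.any(np.diff(leg.mid_swing) <= 0):
                raise ValidationError("mid-swing times must be strictly increasing")
        if self.turn_start is not None and self.turn_end is not None:
            if not self.turn_start < self.turn_end:
                raise ValidationError("turn_start must precede turn_end")
            for leg in (self.left, self.right):
                inside = (leg.mid_swing > self.turn_start) & (leg.mid_swing < self.turn_end)
                if np.any(inside):
                    raise ValidationError("mid-swing detected inside the turn window")

    def with_turn(self, turn_start: float, turn_end: float) -> "GaitEvents":
        """Return a copy with the turn window set; mid-swings strictly inside
        the window (and their flanking events) are dropped."""
        def prune(leg: LegEvents) -> LegEvents:
            keep = ~((leg.mid_swing > turn_start) & (leg.mid_swing < turn_end))
            return LegEvents(
                leg.mid_swing[keep], leg.toe_off[keep],
                leg.heel_strike[keep], leg.mid_swing_amp[keep],
            )
        out = GaitEvents(prune(self.left), prune(self.right), turn_start, turn_end)
        out.validate()
        return out


def _detect_leg(gyro_y, rate: float, params: GaitEventParams, leg_name: str) -> LegEvents:
    from scipy.signal import find_peaks

    y = butterworth_lowpass(
        np.asarray(gyro_y, dtype=float),
        FilterSpec(order=4, cutoff_hz=params.smooth_cutoff_hz),
        rate,
    )
    span = float(np.max(np.abs(y))) if y.size else 0.0
    height = max(params.rel_peak_frac * span, params.min_peak_amp)
    peaks, _ = find_peaks(y, height=height)
    if peaks.size >= 3:
        med_sep = float(np.median(np.diff(peaks)))
        peaks, _ = find_peaks(y, height=height, distance=max(1, int(params.min_sep_frac * med_sep)))
    if peaks.size < 2:
        raise DetectionError(
            f"{leg_name} leg: found {peaks.size} mid-swing candidate(s) above "
            f"{height:.1f} deg/s (signal span {span:.1f} deg/s); need >= 2"
        )
    med_sep = float(np.median(np.diff(peaks)))
    half = max(2, int(round(0.5 * med_sep)))

    n = y.size
    toe_idx = np.empty(peaks.size, dtype=int)
    heel_idx = np.empty(peaks.size, dtype=int)
    for k, p in enumerate(peaks):
        lo = max(0, p - half)
        toe_idx[k] = lo + int(np.argmin(y[lo:p])) if p > lo else max(0, p - 1)
        hi = min(n, p + half + 1)
        heel_idx[k] = p + 1 + int(np.argmin(y[p + 1:hi])) if hi > p + 1 else min(n - 1, p + 1)

    dt = 1.0 / rate
    return LegEvents(
        mid_swing=peaks * dt,
        toe_off=toe_idx * dt,
        heel_strike=heel_idx * dt,
        mid_swing_amp=y[peaks],
    )


def detect_gait_events(
    left_gyro_y,
    right_gyro_y,
    rate: float,
    params: GaitEventParams = GaitEventParams(),
) -> GaitEvents:
    """Detect per-leg mid-swing / toe-off / heel-strike from shank gyro_y.

    The turn window is left unset; apply :func:`detect_turn` afterwards.
    """
    left = _detect_leg(left_gyro_y, rate, params, "left")
    right = _detect_leg(right_gyro_y, rate, params, "right")
    events = GaitEvents(left=left, right=right)
    events.validate()
    return events


def detect_turn(
    events: GaitEvents,
    low_back_yaw_rate=None,
    rate: float = 100.0,
    params: GaitEventParams = GaitEventParams(),
) -> tuple[float, float]:
    """Locate the turn as the gap in threshold-passing mid-swings.

    turn_start is the last mid-swing before the gap (the earliest time after
    which neither leg swings above threshold); turn_end is the first post-gap
    mid-swing, preferring the leg whose peak is smaller than the other leg's
    next peak.  Raises :class:`DetectionError` when no gap stands out.
    ``low_back_yaw_rate`` is accepted for API symmetry/diagnostics; the
    decision is made from the gait events.
    """
    times = np.concatenate([events.left.mid_swing, events.right.mid_swing])
    legs = np.concatenate([
        np.zeros(events.left.mid_swing.size, dtype=int),
        np.ones(events.right.mid_swing.size, dtype=int),
    ])
    amps = np.concatenate([events.left.mid_swing_amp, events.right.mid_swing_amp])
    order = np.argsort(times)
    times, legs, amps = times[order], legs[order], amps[order]
    if times.size < 4:
        raise DetectionError("too few mid-swings on the merged timeline to locate a turn")

    gaps = np.diff(times)
    med_gap = float(np.median(gaps))
    k = int(np.argmax(gaps))
    if gaps[k] <= params.turn_gap_factor * med_gap:
        raise DetectionError(
            f"no turn found: largest mid-swing gap {gaps[k]:.3f} s does not exceed "
            f"{params.turn_gap_factor} x median step gap {med_gap:.3f} s"
        )
    turn_start = float(times[k])

    # candidate turn-end peaks: the first post-gap mid-swing of each leg
    post = np.arange(k + 1, times.size)
    candidates = []
    for leg in (0, 1):
        idx = post[legs[post] == leg]
        if idx.size:
            candidates.append(idx[0])
    chosen = None
    for c in sorted(candidates):
        other = [i for i in post if legs[i] != legs[c] and times[i] > times[c]]
        if other and amps[c] < amps[other[0]]:
            chosen = c
            break
    if chosen is None:
        chosen = min(candidates)
    return turn_start, float(times[chosen])
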