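"""Per-subtest measure computations built on the signal primitives."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..core_io import AppLog, Location, SensorRecording, ValidationError
from ..preprocess import FilterSpec, butterworth_lowpass, derivative, tilt_angles
from .events import GaitEvents
from .measures import jerk_measure, rms

__all__ = [
    "STSTransitions",
    "CycleCountError",
    "gait_measures",
    "sts5_measures",
    "los_measures",
    "knee_rom",
    "crt_measures",
    "fes_score",
]


class CycleCountError(ValueError):
    """Sit-to-stand segmentation found the wrong number of cycles."""


# ---------------------------------------------------------------------------
# TUG
# ---------------------------------------------------------------------------

def _same_foot_intervals(times: np.ndarray, turn_start: float, turn_end: float) -> np.ndarray:
    """Consecutive same-foot event intervals, dropping any that span the turn."""
    if times.size < 2:
        return np.empty(0)
    d = np.diff(times)
    spans_turn = (times[:-1] < turn_end) & (times[1:] > turn_start)
    return d[~spans_turn]


def _pooled_rms(segments: list[np.ndarray]) -> float:
    """RMS over several mean-removed segments (pooled mean square)."""
    sq = [np.square(s - s.mean()) for s in segments if s.size]
    if not sq:
        raise ValidationError("no samples for pooled RMS")
    return float(np.sqrt(np.concatenate(sq).mean()))


def gait_measures(
    events: GaitEvents,
    low_back: SensorRecording,
    walkway_distance_m: float,
    filter_spec: FilterSpec = FilterSpec(),
) -> dict[str, float]:
    """Walk- and turn-phase measures for a walk-turn-walk trial.

    step_time follows the same-foot definition (interval between consecutive
    toe-offs of one foot); the conventional alternating-foot interval is also
    emitted as step_time_alt.  Distances assume the walkway is covered twice
    (out and back): step_length = 2*distance / n_steps and gait_velocity =
    2*distance / walk_time, with walk_time the first-toe-off-to-last-
    heel-strike span minus the turning time.
    """
    if walkway_distance_m <= 0:
        raise ValidationError("walkway_distance must be positive")
    if events.turn_start is None or events.turn_end is None:
        raise ValidationError("gait_measures requires events with a detected turn window")
    ts, te = events.turn_start, events.turn_end
    turn_time = te - ts

    ms_all = np.sort(np.concatenate([events.left.mid_swing, events.right.mid_swing]))
    # steps outside the open turn window (the boundary swings count as steps)
    n_steps = int(np.sum((ms_all <= ts) | (ms_all >= te)))
    if n_steps == 0:
        raise ValidationError("zero steps detected outside the turn")

    to_all = np.concatenate([events.left.toe_off, events.right.toe_off])
    hs_all = np.concatenate([events.left.heel_strike, events.right.heel_strike])
    walk_time = (hs_all.max() - to_all.min()) - turn_time
    if walk_time <= 0:
        raise ValidationError("non-positive walking time")

    stride_intervals = np.concatenate([
        _same_foot_intervals(events.left.toe_off, ts, te),
        _same_foot_intervals(events.right.toe_off, ts, te),
    ])
    step_time = float(stride_intervals.mean()) if stride_intervals.size else float("nan")
    alt = np.diff(ms_all)
    alt = alt[alt < turn_time]  # drop the turn gap itself
    step_time_alt = float(alt.mean()) if alt.size else float("nan")

    out = {
        "n_steps": float(n_steps),
        "step_time": step_time,
        "step_time_alt": step_time_alt,
        "step_length": 2.0 * walkway_distance_m / n_steps,
        "walk_time": float(walk_time),
        "gait_velocity": 2.0 * walkway_distance_m / walk_time,
        "turn_time": float(turn_time),
    }

    t = low_back.time - low_back.time[0]
    rate = low_back.sampling_rate
    acc = butterworth_lowpass(low_back.acc, filter_spec, rate)
    gyro = butterworth_lowpass(low_back.gyro, filter_spec, rate)

    walk_masks = [
        (t >= to_all.min()) & (t <= ts),
        (t >= te) & (t <= hs_all.max()),
    ]
    for i, direction in enumerate(("ap", "ml", "v")):
        out[f"walk_rms_acc_{direction}"] = _pooled_rms([acc[m, i] for m in walk_masks])
        out[f"walk_rms_gyro_{direction}"] = _pooled_rms([gyro[m, i] for m in walk_masks])
        out[f"walk_jerk_acc_{direction}"] = _segment_jerk([acc[m, i] for m in walk_masks], rate)
        out[f"walk_jerk_gyro_{direction}"] = _segment_jerk([gyro[m, i] for m in walk_masks], rate)

    turn_mask = (t >= ts) & (t <= te)
    yaw = gyro[turn_mask, 2]
    if yaw.size == 0:
        raise ValidationError("turn window contains no low-back samples")
    # the turn is a one-sided pulse, so its RMS is taken about zero, not the mean
    out["turn_gyro_rms"] = float(np.sqrt(np.mean(yaw**2)))
    out["turn_gyro_max"] = float(np.max(np.abs(yaw)))
    return out


def _segment_jerk(segments: list[np.ndarray], rate: float) -> float:
    """Pooled RMS of the mean-removed derivative across disjoint segments."""
    derivs = [derivative(s, rate) for s in segments if s.size >= 3]
    if not derivs:
        raise ValidationError("no segment long enough for jerk")
    return _pooled_rms(derivs)


# ---------------------------------------------------------------------------
# STS5
# ---------------------------------------------------------------------------

@dataclass
class STSTransitions:
    """Five sit-stand-sit cycles with interpolated threshold-crossing bounds."""

    cycles: list[dict] = field(default_factory=list)  # keys: sit_stand, stand_sit -> (t0, t1)

    @property
    def sit_stand_durations(self) -> np.ndarray:
        return np.array([c["sit_stand"][1] - c["sit_stand"][0] for c in self.cycles])

    @property
    def stand_sit_durations(self) -> np.ndarray:
        return np.array([c["stand_sit"][1] - c["stand_sit"][0] for c in self.cycles])

    @property
    def sit_stand_sit_durations(self) -> np.ndarray:
        return np.array([c["stand_sit"][1] - c["sit_stand"][0] for c in self.cycles])

    def validate(self, expected_cycles: int = 5) -> None:
        if len(self.cycles) != expected_cycles:
            raise CycleCountError(
                f"expected {expected_cycles} sit-to-stand cycles, found {len(self.cycles)}"
            )
        for c in self.cycles:
            if not c["sit_stand"][0] < c["sit_stand"][1] <= c["stand_sit"][0] < c["stand_sit"][1]:
                raise ValidationError("sit_stand must precede stand_sit within a cycle")


def _threshold_regions(t, y, thr, min_duration_s=0.2):
    """Contiguous regions where y > thr, with linearly interpolated edges."""
    above = y > thr
    if not np.any(above):
        return []
    edges = np.diff(above.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0])
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(y) - 1)
    regions = []
    for s, e in zip(starts, ends):
        t0 = t[s]
        if s > 0:
            t0 = t[s - 1] + (thr - y[s - 1]) / (y[s] - y[s - 1]) * (t[s] - t[s - 1])
        t1 = t[e]
        if e < len(y) - 1:
            t1 = t[e] + (thr - y[e]) / (y[e + 1] - y[e]) * (t[e + 1] - t[e])
        if t1 - t0 >= min_duration_s:
            regions.append((float(t0), float(t1), s, e))
    return regions


def sts5_measures(
    upper_leg: SensorRecording,
    expected_cycles: int = 5,
    onset_frac: float = 0.1,
    filter_spec: FilterSpec = FilterSpec(),
) -> tuple[STSTransitions, dict[str, float]]:
    """Segment five sit-stand-sit cycles from thigh gyro_y and derive measures.

    Each cycle is a biphasic pulse: a positive sit->stand lobe followed by a
    negative stand->sit lobe.  Lobe boundaries are crossings of
    ``onset_frac`` x the global peak amplitude.
    """
    if upper_leg.location not in (Location.LEFT_UPPER_LEG, Location.RIGHT_UPPER_LEG):
        raise ValidationError("sts5_measures needs an upper-leg recording")
    rate = upper_leg.sampling_rate
    t = upper_leg.time - upper_leg.time[0]
    y = butterworth_lowpass(upper_leg.gyro[:, 1], filter_spec, rate)
    thr = onset_frac * float(np.max(np.abs(y)))
    if thr <= 0:
        raise CycleCountError("flat thigh angular velocity; no cycles found")

    pos = _threshold_regions(t, y, thr)
    neg = _threshold_regions(t, -y, thr)

    cycles = []
    j = 0
    for p0, p1, _, _ in pos:
        while j < len(neg) and neg[j][0] < p1:
            j += 1
        if j < len(neg):
            n0, n1, _, _ = neg[j]
            cycles.append({"sit_stand": (p0, p1), "stand_sit": (n0, n1)})
            j += 1
    transitions = STSTransitions(cycles)
    transitions.validate(expected_cycles)

    def region_stats(t0, t1):
        m = (t >= t0) & (t <= t1)
        seg = y[m]
        mean_av = float(np.mean(np.abs(seg)))
        jerk = jerk_measure(seg, rate) if seg.size >= 3 else float("nan")
        return mean_av, jerk

    accum = {k: {"mean_gyro": [], "jerk": []} for k in ("sit_stand", "stand_sit", "sit_stand_sit")}
    for c in transitions.cycles:
        for key, (t0, t1) in (
            ("sit_stand", c["sit_stand"]),
            ("stand_sit", c["stand_sit"]),
            ("sit_stand_sit", (c["sit_stand"][0], c["stand_sit"][1])),
        ):
            mean_av, jerk = region_stats(t0, t1)
            accum[key]["mean_gyro"].append(mean_av)
            accum[key]["jerk"].append(jerk)

    measures = {
        "sit_stand_duration": float(transitions.sit_stand_durations.mean()),
        "stand_sit_duration": float(transitions.stand_sit_durations.mean()),
        "sit_stand_sit_duration": float(transitions.sit_stand_sit_durations.mean()),
        "total_time": float(
            transitions.cycles[-1]["stand_sit"][1] - transitions.cycles[0]["sit_stand"][0]
        ),
    }
    for key in ("sit_stand", "stand_sit", "sit_stand_sit"):
        measures[f"{key}_mean_gyro"] = float(np.mean(accum[key]["mean_gyro"]))
        measures[f"{key}_jerk"] = float(np.mean(accum[key]["jerk"]))
    return transitions, measures


# ---------------------------------------------------------------------------
# LOS, MF, CRT, FES
# ---------------------------------------------------------------------------

def los_measures(
    low_back: SensorRecording,
    reach_distance_m: float | None = None,
    height_cm: float | None = None,
    filter_spec: FilterSpec = FilterSpec(),
) -> dict[str, float]:
    """Forward-reach measures from the low-back sensor.

    The reach distance is passed through when externally measured; otherwise
    it is estimated as height * sin(peak trunk-pitch excursion) when the
    height is known (method recorded under ``reach_method``).
    """
    rate = low_back.sampling_rate
    gyro = butterworth_lowpass(low_back.gyro, filter_spec, rate)
    out = {
        "rms_gyro_ap": rms(gyro[:, 0]),
        "rms_gyro_ml": rms(gyro[:, 1]),
        "jerk_gyro_ap": jerk_measure(gyro[:, 0], rate),
        "jerk_gyro_ml": jerk_measure(gyro[:, 1], rate),
    }
    if reach_distance_m is not None:
        out["reach_distance"] = float(reach_distance_m)
        out["reach_method"] = "measured"
    elif height_cm is not None:
        theta_ap, _ = tilt_angles(low_back)
        excursion = float(theta_ap.max() - theta_ap.min())
        out["reach_distance"] = (height_cm / 100.0) * math.sin(math.radians(excursion))
        out["reach_method"] = "estimated"
    else:
        out["reach_distance"] = float("nan")
        out["reach_method"] = "missing"
    return out


def _segment_angle(rec: SensorRecording) -> np.ndarray:
    """Sagittal segment angle (deg): orientation pitch when present, else
    drift-corrected (linearly detrended) integration of gyro_y."""
    if rec.orientation is not None:
        return rec.orientation[:, 1].astype(float)
    from scipy.signal import detrend

    gy = rec.gyro[:, 1]
    if not np.all(np.isfinite(gy)):
        raise ValidationError("no usable orientation or angular-velocity data for segment angle")
    angle = np.concatenate([[0.0], np.cumsum((gy[1:] + gy[:-1]) / 2.0)]) / rec.sampling_rate
    return detrend(angle)


def knee_rom(
    upper_leg: SensorRecording,
    lower_leg: SensorRecording,
    filter_spec: FilterSpec = FilterSpec(),
) -> float:
    """Knee range of motion (deg) as the span of lower-minus-upper-leg pitch."""
    knee = _segment_angle(lower_leg) - _segment_angle(upper_leg)
    knee = butterworth_lowpass(knee, filter_spec, lower_leg.sampling_rate)
    return float(knee.max() - knee.min())


def crt_measures(log: AppLog) -> tuple[float, float]:
    """(information processing speed bit/s, simple reaction time s).

    Simple reaction time averages correct single-alternative trials.  The
    processing speed is log2(alternatives) / mean correct reaction time,
    averaged over the distinct multi-alternative block sizes.
    """
    if log.kind != "CRT":
        raise ValidationError("crt_measures needs a CRT log")
    simple = [t.reaction_time for t in log.crt_trials if t.n_alternatives == 1 and t.correct]
    if not simple:
        raise ValidationError("no correct single-alternative trials")
    srt = float(np.mean(simple))

    blocks: dict[int, list[float]] = {}
    for t in log.crt_trials:
        if t.n_alternatives > 1 and t.correct:
            blocks.setdefault(t.n_alternatives, []).append(t.reaction_time)
    if not blocks:
        raise ValidationError("no correct multi-alternative trials")
    ips = float(np.mean([math.log2(n) / np.mean(rts) for n, rts in sorted(blocks.items())]))
    return ips, srt


def fes_score(log: AppLog) -> float:
    """Falls-efficacy score: sum of item scores (higher = greater fear)."""
    if log.kind != "FES":
        raise ValidationError("fes_score needs a FES log")
    if len(log.fes_items) != log.fes_n_items:
        missing = sorted(set(range(1, log.fes_n_items + 1)) - set(range(1, len(log.fes_items) + 1)))
        raise ValidationError(
            f"FES log has {len(log.fes_items)} of {log.fes_n_items} items; missing {missing}"
        )
    return float(sum(log.fes_items))
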