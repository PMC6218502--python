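"""Synthetic IMU sessions with ground truth and feature-level cohorts.

Signal generators emit :class:`~fallkit.core_io.Session` objects whose key
scalars (event times, transition durations, realized RMS) are recorded in a
:class:`GroundTruth`, so every downstream extractor can be validated without
recorded data.  The cohort generator draws labelled feature tables from
per-group normal distributions.

Seeding: every generator takes one master seed; independent substreams are
derived with ``numpy.random.SeedSequence([seed, *counters])`` so individual
subjects and channels are reproducible in isolation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .core_io import (
    AppLog,
    CRTTrial,
    FallStatus,
    Location,
    SensorRecording,
    Session,
    Subtest,
    ValidationError,
)
from .preprocess import FilterSpec, butterworth_lowpass
from .features.catalogue import measure_catalogue

__all__ = [
    "GaitProfile",
    "SwayProfile",
    "GroundTruth",
    "CohortSpec",
    "simulate_tug",
    "simulate_sway",
    "simulate_sts5",
    "simulate_los",
    "simulate_mf",
    "simulate_crt_log",
    "simulate_fes_log",
    "simulate_battery",
    "simulate_cohort_features",
    "table3_cohort_spec",
    "faller_gait_profile",
    "nonfaller_gait_profile",
]

GRAVITY = 9.81
RATE = 100.0


@dataclass
class GroundTruth:
    """Scheduled event times and true scalar values for a generated session."""

    gait_events: Optional[dict] = None      # {"left"/"right": {"mid_swing": [...], ...}}
    turn_start: Optional[float] = None
    turn_end: Optional[float] = None
    sts_cycles: list = field(default_factory=list)  # per cycle: dict of boundary times
    measures: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        def convert(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            raise TypeError(f"not JSON serializable: {type(obj)}")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, default=convert)


# ---------------------------------------------------------------------------
# TUG
# ---------------------------------------------------------------------------

@dataclass
class GaitProfile:
    n_steps: int = 12
    stride_time: float = 1.04          # same-foot interval, s
    stride_time_sd: float = 0.0
    swing_peak_amp: float = 300.0      # deg/s
    swing_peak_amp_sd: float = 0.0
    toe_off_trough_amp: float = 120.0  # magnitude, deg/s
    heel_strike_trough_amp: float = 120.0
    turn_duration: float = 2.11        # s; 0 disables the turn
    turn_yaw_rate: float = 110.0       # deg/s
    walkway_distance: float = 3.0      # m (walked twice)
    noise_sd: float = 0.0              # deg/s, added to every gyro channel

    def validate(self) -> None:
        if self.n_steps < 4:
            raise ValidationError("need at least 4 steps")
        if self.stride_time <= 0:
            raise ValidationError("stride_time must be positive")
        if self.swing_peak_amp <= max(self.toe_off_trough_amp, self.heel_strike_trough_amp):
            raise ValidationError("swing peak must exceed trough magnitudes")
        if self.turn_duration < 0:
            raise ValidationError("turn_duration must be >= 0")


def _gauss_lobe(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def simulate_tug(profile: GaitProfile, seed: int = 0,
                 subject_id: str = "sim") -> tuple[Session, GroundTruth]:
    """Simulate a walk-turn-walk (TUG) session.

    Each shank's gyro_y is a train of positive Gaussian mid-swing lobes
    flanked by negative toe-off/heel-strike lobes, legs alternating by half a
    stride.  The turn is a gap in swing lobes on both legs during which the
    low-back yaw rate carries a flat-topped pulse; the first post-turn swing
    has reduced amplitude so turn-end detection has the documented signature.
    """
    profile.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB0]))

    n = profile.n_steps
    n_out = (n + 1) // 2
    half = profile.stride_time / 2.0
    half_sd = profile.stride_time_sd / 2.0

    intervals = np.full(n - 1, half)
    if half_sd > 0:
        intervals = intervals + rng.standard_normal(n - 1) * half_sd
    intervals = np.maximum(intervals, 0.3 * half)
    lead_in = 1.5
    ms_times = lead_in + np.concatenate([[0.0], np.cumsum(intervals)])
    turn = profile.turn_duration
    walking_span = float(ms_times[-1] - ms_times[0])
    if turn > 0:
        if turn >= walking_span:
            raise ValidationError("turn longer than the total walking trial")
        if turn <= 1.5 * half:
            raise ValidationError("turn_duration must exceed the normal step interval")
        # shift the return steps so the first post-turn mid-swing falls exactly
        # turn_duration after the last outbound mid-swing
        ms_times[n_out:] += turn - intervals[n_out - 1]
        turn_start = float(ms_times[n_out - 1])
        turn_end = float(ms_times[n_out])
    else:
        turn_start = turn_end = None

    legs = np.arange(n) % 2  # 0 = left, 1 = right
    amps = np.full(n, profile.swing_peak_amp)
    if profile.swing_peak_amp_sd > 0:
        amps = amps + rng.standard_normal(n) * profile.swing_peak_amp_sd
    amps = np.maximum(amps, 0.5 * profile.swing_peak_amp)
    if turn > 0:
        amps[n_out] *= 0.75  # the turn-closing step is slower

    to_lead = 0.20 * profile.stride_time
    hs_lag = 0.20 * profile.stride_time
    sigma_sw = 0.05 * profile.stride_time
    sigma_tr = 0.04 * profile.stride_time

    duration = float(ms_times[-1] + hs_lag + 1.5)
    t = np.arange(int(round(duration * RATE))) / RATE

    events = {"left": {"mid_swing": [], "toe_off": [], "heel_strike": []},
              "right": {"mid_swing": [], "toe_off": [], "heel_strike": []}}
    shank_y = {"left": np.zeros_like(t), "right": np.zeros_like(t)}
    for i in range(n):
        leg = "left" if legs[i] == 0 else "right"
        ms, amp = ms_times[i], amps[i]
        to, hs = ms - to_lead, ms + hs_lag
        shank_y[leg] += (
            amp * _gauss_lobe(t, ms, sigma_sw)
            - profile.toe_off_trough_amp * _gauss_lobe(t, to, sigma_tr)
            - profile.heel_strike_trough_amp * _gauss_lobe(t, hs, sigma_tr)
        )
        events[leg]["mid_swing"].append(float(ms))
        events[leg]["toe_off"].append(float(to))
        events[leg]["heel_strike"].append(float(hs))

    # low-back yaw pulse with a flat top across the turn window
    yaw = np.zeros_like(t)
    if turn > 0:
        ramp = min(0.25 * turn, 0.4)
        rise = np.clip((t - turn_start) / ramp, 0.0, 1.0)
        fall = np.clip((turn_end - t) / ramp, 0.0, 1.0)
        envelope = np.minimum(rise, fall)
        smooth = 0.5 * (1 - np.cos(np.pi * np.clip(envelope, 0, 1)))
        yaw = profile.turn_yaw_rate * smooth

    def noisy(base: np.ndarray, key: int) -> np.ndarray:
        sub = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB1, key]))
        return base + (sub.standard_normal(t.size) * profile.noise_sd if profile.noise_sd > 0 else 0.0)

    def make_rec(loc: Location, gyro_y: np.ndarray, gyro_z: np.ndarray, key: int) -> SensorRecording:
        gyro = np.column_stack([noisy(np.zeros_like(t), key),
                                noisy(gyro_y, key + 1),
                                noisy(gyro_z, key + 2)])
        acc = np.column_stack([np.zeros_like(t), np.zeros_like(t), np.full_like(t, GRAVITY)])
        acc += np.random.default_rng(
            np.random.SeedSequence([int(seed), 0xB2, key])
        ).standard_normal((t.size, 3)) * (0.02 if profile.noise_sd > 0 else 0.0)
        return SensorRecording(location=loc, time=t, acc=acc, gyro=gyro, sampling_rate=RATE)

    recordings = {
        Location.LEFT_LOWER_LEG: make_rec(Location.LEFT_LOWER_LEG, shank_y["left"], np.zeros_like(t), 10),
        Location.RIGHT_LOWER_LEG: make_rec(Location.RIGHT_LOWER_LEG, shank_y["right"], np.zeros_like(t), 20),
        Location.LOW_BACK: make_rec(Location.LOW_BACK, np.zeros_like(t), yaw, 30),
    }
    session = Session(subject_id=subject_id, subtest=Subtest.TUG, recordings=recordings,
                      metadata={"walkway_distance_m": profile.walkway_distance})

    gt = GroundTruth(
        gait_events={leg: {k: np.asarray(v) for k, v in ev.items()} for leg, ev in events.items()},
        turn_start=turn_start, turn_end=turn_end,
    )
    to_all = np.sort(np.concatenate([events["left"]["toe_off"], events["right"]["toe_off"]]))
    hs_all = np.sort(np.concatenate([events["left"]["heel_strike"], events["right"]["heel_strike"]]))
    strides = []
    for leg in ("left", "right"):
        tos = np.asarray(events[leg]["toe_off"])
        d = np.diff(tos)
        if turn > 0:
            spans = (tos[:-1] < turn_end) & (tos[1:] > turn_start)
            d = d[~spans]
        strides.append(d)
    strides = np.concatenate(strides)
    walk_time = float(hs_all[-1] - to_all[0] - (turn if turn > 0 else 0.0))
    gt.measures = {
        "n_steps": float(n),
        "step_time": float(strides.mean()),
        "step_length": 2.0 * profile.walkway_distance / n,
        "walk_time": walk_time,
        "gait_velocity": 2.0 * profile.walkway_distance / walk_time,
        "turn_time": float(turn) if turn > 0 else float("nan"),
        "turn_gyro_max": profile.turn_yaw_rate if turn > 0 else float("nan"),
    }
    return session, gt


def nonfaller_gait_profile(**overrides) -> GaitProfile:
    base = dict(n_steps=16, stride_time=1.04, stride_time_sd=0.08, turn_duration=2.11,
                turn_yaw_rate=113.78, walkway_distance=3.12)
    base.update(overrides)
    return GaitProfile(**base)


def faller_gait_profile(**overrides) -> GaitProfile:
    base = dict(n_steps=17, stride_time=1.08, stride_time_sd=0.13, turn_duration=2.43,
                turn_yaw_rate=104.93, walkway_distance=3.06)
    base.update(overrides)
    return GaitProfile(**base)


# ---------------------------------------------------------------------------
# Quiet-standing sway
# ---------------------------------------------------------------------------

@dataclass
class SwayProfile:
    rms_acc_ap: float = 0.015   # m/s^2
    rms_acc_ml: float = 0.006
    rms_gyro_ap: float = 1.4    # deg/s
    rms_gyro_ml: float = 1.1
    jerk_scale: float = 1.0     # reserved shaping factor; realized jerk is recorded
    bandwidth: float = 1.0      # Hz
    duration: float = 30.0      # s

    def validate(self) -> None:
        if self.duration < 10:
            raise ValidationError("sway duration must be >= 10 s")
        if self.bandwidth <= 0 or self.bandwidth >= RATE / 2:
            raise ValidationError("bandwidth must lie in (0, Nyquist)")
        for name in ("rms_acc_ap", "rms_acc_ml", "rms_gyro_ap", "rms_gyro_ml"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


def _band_limited_unit(rng, n: int, bandwidth: float) -> np.ndarray:
    """Gaussian noise with all spectral content at or below ``bandwidth``."""
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / RATE)
    spec[freqs > bandwidth] = 0.0
    y = np.fft.irfft(spec, n=n)
    sd = y.std()
    return y / sd if sd > 0 else y


def _scaled_channel(rng, n: int, bandwidth: float, target_rms: float,
                    filter_spec: FilterSpec) -> np.ndarray:
    """Band-limited noise scaled so the default-filtered, mean-removed RMS of
    the emitted channel equals ``target_rms`` exactly (filtering is linear)."""
    if target_rms == 0:
        return np.zeros(n)
    u = _band_limited_unit(rng, n, bandwidth)
    f = butterworth_lowpass(u, filter_spec, RATE)
    f = f - f.mean()
    realized = float(np.sqrt(np.mean(f * f)))
    return u * (target_rms / realized)


def simulate_sway(profile: SwayProfile, condition: Subtest = Subtest.SIT_EO_FIRM,
                  seed: int = 0, subject_id: str = "sim",
                  filter_spec: FilterSpec = FilterSpec()) -> tuple[Session, GroundTruth]:
    """Simulate quiet standing: low-back sway with exactly prescribed RMS.

    AP/ML acceleration channels are band-limited Gaussian processes rescaled
    so the extraction-pipeline RMS (after the default low-pass) reproduces the
    profile values to machine precision; the vertical channel closes the
    gravity vector so tilt angles follow from inclination.
    """
    profile.validate()
    condition = Subtest(condition)
    if not condition.value.startswith("SIT"):
        raise ValidationError("simulate_sway generates SIT conditions")
    n = int(round(profile.duration * RATE))
    t = np.arange(n) / RATE

    def rng_for(k: int):
        return np.random.default_rng(np.random.SeedSequence([int(seed), 0x5A, k]))

    acc_x = _scaled_channel(rng_for(1), n, profile.bandwidth, profile.rms_acc_ap, filter_spec)
    acc_y = _scaled_channel(rng_for(2), n, profile.bandwidth, profile.rms_acc_ml, filter_spec)
    gyro_x = _scaled_channel(rng_for(3), n, profile.bandwidth, profile.rms_gyro_ap, filter_spec)
    gyro_y = _scaled_channel(rng_for(4), n, profile.bandwidth, profile.rms_gyro_ml, filter_spec)

    acc_z = np.sqrt(np.maximum(GRAVITY**2 - acc_x**2 - acc_y**2, 0.0))
    acc = np.column_stack([acc_x, acc_y, acc_z])
    gyro = np.column_stack([gyro_x, gyro_y, np.zeros(n)])

    rec = SensorRecording(location=Location.LOW_BACK, time=t, acc=acc, gyro=gyro,
                          sampling_rate=RATE)
    session = Session(subject_id=subject_id, subtest=condition,
                      recordings={Location.LOW_BACK: rec},
                      metadata={"surface": "foam" if "FOAM" in condition.value else "firm",
                                "eyes": "closed" if "EC" in condition.value else "open"})

    theta_ap = np.degrees(np.arctan2(acc_x, acc_z))
    theta_ml = np.degrees(np.arctan2(acc_y, acc_z))
    facc = butterworth_lowpass(acc, filter_spec, RATE)
    fgyro = butterworth_lowpass(gyro, filter_spec, RATE)
    from .features.measures import jerk_measure
    gt = GroundTruth(measures={
        "rms_acc_ap": profile.rms_acc_ap,
        "rms_acc_ml": profile.rms_acc_ml,
        "rms_gyro_ap": profile.rms_gyro_ap,
        "rms_gyro_ml": profile.rms_gyro_ml,
        "jerk_acc_ap": jerk_measure(facc[:, 0], RATE),
        "jerk_acc_ml": jerk_measure(facc[:, 1], RATE),
        "jerk_gyro_ap": jerk_measure(fgyro[:, 0], RATE),
        "jerk_gyro_ml": jerk_measure(fgyro[:, 1], RATE),
        "tilt_ap": theta_ap,
        "tilt_ml": theta_ml,
    })
    return session, gt


# ---------------------------------------------------------------------------
# STS5
# ---------------------------------------------------------------------------

def _cosine_edge_lobe(t: np.ndarray, t0: float, t1: float, amp: float, ramp: float,
                      onset_frac: float = 0.1) -> np.ndarray:
    """Flat-topped lobe whose ``onset_frac`` threshold crossings sit exactly at
    t0 and t1 (raised-cosine edges of width ``ramp``)."""
    # crossing offset of a raised-cosine edge through onset_frac
    xc = math.acos(1.0 - 2.0 * onset_frac) / math.pi  # fraction of the ramp
    rise_start = t0 - xc * ramp
    fall_end = t1 + xc * ramp
    up = np.clip((t - rise_start) / ramp, 0.0, 1.0)
    down = np.clip((fall_end - t) / ramp, 0.0, 1.0)
    envelope = np.minimum(up, down)
    return amp * 0.5 * (1 - np.cos(np.pi * envelope))


def simulate_sts5(transition_durations, seed: int = 0, amp: float = 100.0,
                  noise_sd: float = 0.0, subject_id: str = "sim",
                  n_cycles_expected: int = 5) -> tuple[Session, GroundTruth]:
    """Simulate five sit-stand-sit cycles on the thigh gyro.

    ``transition_durations`` gives each cycle's full sit-stand-sit span (s).
    Within a cycle the positive sit->stand lobe covers the first 45%, a quiet
    gap 10%, and the negative stand->sit lobe the final 45%; lobe edges are
    placed so the 10%-of-peak crossings land exactly on the scheduled
    boundaries.
    """
    durations = [float(d) for d in transition_durations]
    if any(d <= 0 for d in durations):
        raise ValidationError("cycle durations must be positive")
    rest = 1.2
    lead = 1.0
    cycles = []
    start = lead
    for d in durations:
        a, b = start, start + 0.45 * d
        c, e = start + 0.55 * d, start + d
        if cycles and a - cycles[-1]["stand_sit"][1] < 0.5:
            raise ValidationError("scheduled cycles overlap")
        cycles.append({"sit_stand": (a, b), "stand_sit": (c, e)})
        start = e + rest

    total = start + 1.0
    n = int(round(total * RATE))
    t = np.arange(n) / RATE
    y = np.zeros(n)
    for cyc in cycles:
        d = cyc["stand_sit"][1] - cyc["sit_stand"][0]
        ramp = min(0.1, 0.2 * 0.45 * d)
        y += _cosine_edge_lobe(t, *cyc["sit_stand"], amp, ramp)
        y -= _cosine_edge_lobe(t, *cyc["stand_sit"], amp, ramp)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x57]))
    gyro_y = y + (rng.standard_normal(n) * noise_sd if noise_sd > 0 else 0.0)
    gyro = np.column_stack([np.zeros(n), gyro_y, np.zeros(n)])
    acc = np.column_stack([np.zeros(n), np.zeros(n), np.full(n, GRAVITY)])

    rec = SensorRecording(location=Location.RIGHT_UPPER_LEG, time=t, acc=acc, gyro=gyro,
                          sampling_rate=RATE)
    session = Session(subject_id=subject_id, subtest=Subtest.STS5,
                      recordings={Location.RIGHT_UPPER_LEG: rec})
    gt = GroundTruth(
        sts_cycles=cycles,
        measures={
            "sit_stand_sit_duration": float(np.mean(durations)),
            "sit_stand_duration": float(np.mean([0.45 * d for d in durations])),
            "stand_sit_duration": float(np.mean([0.45 * d for d in durations])),
            "total_time": float(cycles[-1]["stand_sit"][1] - cycles[0]["sit_stand"][0]),
        },
    )
    return session, gt


# ---------------------------------------------------------------------------
# LOS and MF
# ---------------------------------------------------------------------------

def _sweep(t: np.ndarray, t0: float, t1: float, peak: float) -> np.ndarray:
    """Smooth 0 -> peak -> 0 angle sweep over [t0, t1] (raised cosine)."""
    phase = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
    return peak * 0.5 * (1 - np.cos(2 * np.pi * phase))


def simulate_los(peak_pitch_deg: float = 12.0, duration: float = 8.0, seed: int = 0,
                 noise_sd: float = 0.0, subject_id: str = "sim") -> tuple[Session, GroundTruth]:
    """Simulate a forward-reach trial: a smooth trunk-pitch excursion."""
    n = int(round(duration * RATE))
    t = np.arange(n) / RATE
    pitch = _sweep(t, 1.0, duration - 1.0, peak_pitch_deg)
    gyro_y = np.gradient(pitch, 1.0 / RATE)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x10]))
    noise = rng.standard_normal((n, 3)) * noise_sd if noise_sd > 0 else np.zeros((n, 3))
    gyro = np.column_stack([np.zeros(n), gyro_y, np.zeros(n)]) + noise
    rad = np.radians(pitch)
    acc = np.column_stack([GRAVITY * np.sin(rad), np.zeros(n), GRAVITY * np.cos(rad)])
    orientation = np.column_stack([np.zeros(n), pitch, np.zeros(n)])

    rec = SensorRecording(location=Location.LOW_BACK, time=t, acc=acc, gyro=gyro,
                          sampling_rate=RATE, orientation=orientation)
    session = Session(subject_id=subject_id, subtest=Subtest.LOS,
                      recordings={Location.LOW_BACK: rec})
    gt = GroundTruth(measures={"peak_pitch_deg": peak_pitch_deg})
    return session, gt


def simulate_mf(task: str, rom_deg: float, duration: float = 8.0, seed: int = 0,
                noise_sd: float = 0.0, subject_id: str = "sim",
                with_orientation: bool = True) -> tuple[Session, GroundTruth]:
    """Simulate a knee flexion/extension trial on both legs.

    The thigh stays level while each shank pitch sweeps 0 -> rom -> 0; both
    the orientation channels and gyro_y are emitted consistently so either
    extraction route (orientation difference or gyro integration) applies.
    """
    if task not in ("flexion", "extension"):
        raise ValidationError("task must be 'flexion' or 'extension'")
    n = int(round(duration * RATE))
    t = np.arange(n) / RATE
    sweep = _sweep(t, 1.0, duration - 1.0, rom_deg)
    zero = np.zeros(n)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x3F]))

    def rec(loc: Location, pitch: np.ndarray, key: int) -> SensorRecording:
        gyro_y = np.gradient(pitch, 1.0 / RATE)
        noise = (np.random.default_rng(np.random.SeedSequence([int(seed), 0x3F, key]))
                 .standard_normal((n, 3)) * noise_sd if noise_sd > 0 else np.zeros((n, 3)))
        gyro = np.column_stack([zero, gyro_y, zero]) + noise
        rad = np.radians(pitch)
        acc = np.column_stack([GRAVITY * np.sin(rad), zero, GRAVITY * np.cos(rad)])
        ori = np.column_stack([zero, pitch, zero]) if with_orientation else None
        return SensorRecording(location=loc, time=t, acc=acc, gyro=gyro,
                               sampling_rate=RATE, orientation=ori)

    recordings = {
        Location.LEFT_UPPER_LEG: rec(Location.LEFT_UPPER_LEG, zero, 1),
        Location.LEFT_LOWER_LEG: rec(Location.LEFT_LOWER_LEG, sweep, 2),
        Location.RIGHT_UPPER_LEG: rec(Location.RIGHT_UPPER_LEG, zero, 3),
        Location.RIGHT_LOWER_LEG: rec(Location.RIGHT_LOWER_LEG, sweep, 4),
    }
    subtest = Subtest.MF_FLEXION if task == "flexion" else Subtest.MF_EXTENSION
    session = Session(subject_id=subject_id, subtest=subtest, recordings=recordings)
    return session, GroundTruth(measures={"rom_deg": rom_deg})


# ---------------------------------------------------------------------------
# App logs and full batteries
# ---------------------------------------------------------------------------

def simulate_crt_log(mean_srt: float = 0.30, mean_choice_rt: float = 0.30,
                     n_alternatives: int = 4, n_trials: int = 10, rt_sd: float = 0.02,
                     seed: int = 0) -> AppLog:
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC7]))
    trials = []
    for _ in range(n_trials):
        trials.append(CRTTrial(1, max(0.05, mean_srt + rng.standard_normal() * rt_sd), True))
    for _ in range(n_trials):
        trials.append(CRTTrial(n_alternatives,
                               max(0.05, mean_choice_rt + rng.standard_normal() * rt_sd), True))
    return AppLog(kind="CRT", crt_trials=trials)


def simulate_fes_log(total_score: int = 10, n_items: int = 7,
                     item_range: tuple[int, int] = (1, 4), seed: int = 0) -> AppLog:
    """FES items summing exactly to ``total_score`` within the item range."""
    lo, hi = item_range
    if not n_items * lo <= total_score <= n_items * hi:
        raise ValidationError(f"total {total_score} not achievable with {n_items} items in [{lo},{hi}]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xFE]))
    items = [lo] * n_items
    budget = total_score - n_items * lo
    while budget > 0:
        i = int(rng.integers(n_items))
        if items[i] < hi:
            items[i] += 1
            budget -= 1
    return AppLog(kind="FES", fes_items=items, fes_item_range=item_range, fes_n_items=n_items)


def simulate_battery(seed: int = 0, subject_id: str = "sim", faller_like: bool = False
                     ) -> tuple[dict[Subtest, Session], dict[str, AppLog], dict]:
    """A complete seven-subtest battery for one subject, with ground truths."""
    gait = faller_gait_profile(noise_sd=10.0) if faller_like else nonfaller_gait_profile(noise_sd=10.0)
    truths: dict = {}
    sessions: dict[Subtest, Session] = {}

    sessions[Subtest.TUG], truths["TUG"] = simulate_tug(gait, seed=seed, subject_id=subject_id)

    sway_scale = 1.4 if faller_like else 1.0
    for k, cond in enumerate(
        (Subtest.SIT_EO_FIRM, Subtest.SIT_EC_FIRM, Subtest.SIT_EO_FOAM, Subtest.SIT_EC_FOAM)
    ):
        prof = SwayProfile(
            rms_acc_ap=0.01 * (1 + 0.4 * k) * sway_scale,
            rms_acc_ml=0.005 * (1 + 0.4 * k) * sway_scale,
            rms_gyro_ap=1.2 * (1 + 0.3 * k) * sway_scale,
            rms_gyro_ml=1.0 * (1 + 0.3 * k) * sway_scale,
            bandwidth=1.0, duration=30.0,
        )
        sessions[cond], truths[cond.value] = simulate_sway(prof, cond, seed=seed + k + 1,
                                                           subject_id=subject_id)

    mean_cycle = 2.44 if faller_like else 2.05
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBA]))
    durations = np.maximum(mean_cycle + rng.standard_normal(5) * 0.1, 0.8)
    sessions[Subtest.STS5], truths["STS5"] = simulate_sts5(durations, seed=seed,
                                                           noise_sd=2.0, subject_id=subject_id)

    sessions[Subtest.LOS], truths["LOS"] = simulate_los(
        peak_pitch_deg=10.0 if faller_like else 13.0, seed=seed, noise_sd=0.5,
        subject_id=subject_id)
    # height lets the extractor estimate reach from the pitch excursion
    sessions[Subtest.LOS].metadata["height_cm"] = 154.4 if faller_like else 154.8

    flex = 124.95 if faller_like else 131.73
    ext = 3.69 if faller_like else 4.29
    sessions[Subtest.MF_FLEXION], truths["MF_FLEXION"] = simulate_mf(
        "flexion", flex, seed=seed, subject_id=subject_id)
    sessions[Subtest.MF_EXTENSION], truths["MF_EXTENSION"] = simulate_mf(
        "extension", ext, seed=seed, subject_id=subject_id)

    logs = {
        "CRT": simulate_crt_log(mean_choice_rt=(math.log2(4) / (5.82 if faller_like else 7.09)),
                                seed=seed),
        "FES": simulate_fes_log(total_score=15 if faller_like else 10, seed=seed),
    }
    return sessions, logs, truths


# ---------------------------------------------------------------------------
# Feature-level cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Per-measure, per-group normal parameters for a synthetic cohort.

    ``measures`` maps measure_id -> ((mean_nf, sd_nf), (mean_f, sd_f)).
    """

    n_nonfaller: int
    n_faller: int
    measures: dict[str, tuple[tuple[float, float], tuple[float, float]]]
    correlation: Optional[np.ndarray] = None
    seed: int = 0
    check_catalogue: bool = True

    def validate(self) -> None:
        if self.n_nonfaller < 1 or self.n_faller < 1:
            raise ValidationError("group sizes must be >= 1")
        if self.check_catalogue:
            cat = set(measure_catalogue()["measure_id"])
            unknown = [m for m in self.measures if m not in cat]
            if unknown:
                raise ValidationError(f"measures absent from catalogue: {unknown}")
        for m, ((_, sd_nf), (_, sd_f)) in self.measures.items():
            if sd_nf <= 0 or sd_f <= 0:
                raise ValidationError(f"SDs must be > 0 for {m}")
        if self.correlation is not None:
            r = np.asarray(self.correlation, dtype=float)
            d = len(self.measures)
            if r.shape != (d, d):
                raise ValidationError(f"correlation must be {d}x{d}")
            if not np.allclose(r, r.T):
                raise ValidationError("correlation matrix must be symmetric")
            if np.min(np.linalg.eigvalsh(r)) < -1e-10:
                raise ValidationError("correlation matrix must be positive semi-definite")


def simulate_cohort_features(spec: CohortSpec) -> pd.DataFrame:
    """Draw a labelled feature table from per-group normal distributions.

    Subjects are deterministic individually: subject ``i`` of group ``g``
    (0 = non-faller, 1 = faller) uses the stream
    ``SeedSequence([seed, g, i])``.
    """
    spec.validate()
    ids = list(spec.measures)
    d = len(ids)
    chol = None
    if spec.correlation is not None:
        r = np.asarray(spec.correlation, dtype=float)
        chol = np.linalg.cholesky(r + 1e-12 * np.eye(d))

    rows = []
    for g, (status, n_group) in enumerate(
        ((FallStatus.NON_FALLER, spec.n_nonfaller), (FallStatus.FALLER, spec.n_faller))
    ):
        means = np.array([spec.measures[m][g][0] for m in ids])
        sds = np.array([spec.measures[m][g][1] for m in ids])
        for i in range(n_group):
            rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), g, i]))
            z = rng.standard_normal(d)
            if chol is not None:
                z = chol @ z
            row = dict(zip(ids, means + sds * z))
            row["subject_id"] = f"{'F' if g else 'NF'}{i:04d}"
            row["fall_status"] = status.value
            rows.append(row)
    df = pd.DataFrame(rows)
    return df[["subject_id", *ids, "fall_status"]]


def table3_cohort_spec(n_nonfaller: int = 114, n_faller: int = 82, seed: int = 0) -> CohortSpec:
    """Cohort spec for the ten headline measures with their published
    per-group means and SDs (non-faller group first)."""
    measures = {
        "fes_score": ((9.73, 2.98), (14.96, 4.92)),
        "crt_ips": ((7.09, 1.28), (5.82, 1.27)),
        "tug_step_length": ((0.39, 0.04), (0.36, 0.04)),
        "tug_gait_velocity": ((0.77, 0.11), (0.68, 0.12)),
        "sts5_stand_sit_jerk": ((1507.23, 519.93), (1318.21, 650.68)),
        "mf_extension_rom": ((4.29, 1.55), (3.69, 1.82)),
        "sts5_sit_stand_sit_jerk": ((1592.92, 553.47), (1341.82, 651.17)),
        "tug_turn_gyro_max": ((113.78, 10.89), (104.93, 16.31)),
        "sit_vis_es_ml": ((89.1, 4.3), (87.0, 5.2)),
        "mf_flexion_rom": ((131.73, 13.38), (124.95, 12.99)),
    }
    return CohortSpec(n_nonfaller=n_nonfaller, n_faller=n_faller, measures=measures, seed=seed)
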