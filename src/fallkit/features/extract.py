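"""Battery-level extraction: one MeasureVector per subject."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ..core_io import AppLog, Location, Session, SubjectRecord, Subtest, ValidationError
from ..preprocess import FilterSpec, butterworth_lowpass, tilt_angles
from .catalogue import SIT_CONDITIONS, measure_catalogue
from .events import GaitEventParams, detect_gait_events, detect_turn
from .measures import (
    DEFAULT_THETA_LIMIT_DEG,
    equilibrium_score,
    frequency_measures,
    jerk_measure,
    rms,
    sensory_system_scores,
)
from .subtests import crt_measures, fes_score, gait_measures, knee_rom, los_measures, sts5_measures

__all__ = ["MeasureVector", "extract_all", "ExtractionConfig"]

#: sensor locations each subtest requires
SENSOR_MAP = {
    Subtest.SIT_EO_FIRM: [Location.LOW_BACK],
    Subtest.SIT_EC_FIRM: [Location.LOW_BACK],
    Subtest.SIT_EO_FOAM: [Location.LOW_BACK],
    Subtest.SIT_EC_FOAM: [Location.LOW_BACK],
    Subtest.LOS: [Location.LOW_BACK],
    Subtest.STS5: [Location.RIGHT_UPPER_LEG],
    Subtest.TUG: [Location.LOW_BACK, Location.LEFT_LOWER_LEG, Location.RIGHT_LOWER_LEG],
    Subtest.MF_FLEXION: [
        Location.LEFT_UPPER_LEG, Location.LEFT_LOWER_LEG,
        Location.RIGHT_UPPER_LEG, Location.RIGHT_LOWER_LEG,
    ],
    Subtest.MF_EXTENSION: [
        Location.LEFT_UPPER_LEG, Location.LEFT_LOWER_LEG,
        Location.RIGHT_UPPER_LEG, Location.RIGHT_LOWER_LEG,
    ],
}


@dataclass(frozen=True)
class ExtractionConfig:
    filter_spec: FilterSpec = FilterSpec()
    gravity_cutoff_hz: float = 0.5
    theta_limit_deg: float = DEFAULT_THETA_LIMIT_DEG
    gait_params: GaitEventParams = GaitEventParams()
    walkway_distance_m: float = 3.0
    sts5_onset_frac: float = 0.1


@dataclass
class MeasureVector:
    """Named scalar measures for one subject; missing entries are flagged."""

    subject_id: str
    values: dict[str, float] = field(default_factory=dict)
    missing: set[str] = field(default_factory=set)
    notes: dict[str, str] = field(default_factory=dict)

    def set(self, measure_id: str, value: float) -> None:
        if value is None or (isinstance(value, float) and not math.isfinite(value)):
            self.missing.add(measure_id)
        else:
            self.values[measure_id] = float(value)

    def flag_missing(self, measure_id: str) -> None:
        self.missing.add(measure_id)

    @property
    def n_populated(self) -> int:
        return len(self.values)

    def to_series(self) -> pd.Series:
        cat = measure_catalogue()["measure_id"]
        return pd.Series(
            {m: self.values.get(m, np.nan) for m in cat}, name=self.subject_id, dtype=float
        )


def _sit_condition_measures(vec: MeasureVector, cond: str, session: Session,
                            config: ExtractionConfig) -> Optional[dict[str, float]]:
    rec = session.recording(Location.LOW_BACK)
    rate = rec.sampling_rate
    acc = butterworth_lowpass(rec.acc, config.filter_spec, rate)
    gyro = butterworth_lowpass(rec.gyro, config.filter_spec, rate)
    theta_ap, theta_ml = tilt_angles(rec, config.gravity_cutoff_hz)
    tilt = {"ap": theta_ap, "ml": theta_ml}

    es = {}
    for i, d in enumerate(("ap", "ml")):
        es[d] = equilibrium_score(tilt[d], config.theta_limit_deg)
        vec.set(f"sit_{cond}_es_{d}", es[d])
        vec.set(f"sit_{cond}_rms_acc_{d}", rms(acc[:, i]))
        vec.set(f"sit_{cond}_rms_gyro_{d}", rms(gyro[:, i]))
        vec.set(f"sit_{cond}_jerk_acc_{d}", jerk_measure(acc[:, i], rate))
        vec.set(f"sit_{cond}_jerk_gyro_{d}", jerk_measure(gyro[:, i], rate))
        vec.set(f"sit_{cond}_rms_tilt_{d}", rms(tilt[d]))
        vec.set(f"sit_{cond}_range_tilt_{d}", float(tilt[d].max() - tilt[d].min()))
        for ch, series in (("acc", acc[:, i]), ("gyro", gyro[:, i])):
            med, cen, power = frequency_measures(series, rate)
            vec.set(f"sit_{cond}_medfreq_{ch}_{d}", med)
            vec.set(f"sit_{cond}_cenfreq_{ch}_{d}", cen)
            vec.set(f"sit_{cond}_psd_{ch}_{d}", power)
    return es


def _tug_measures(vec: MeasureVector, session: Session, config: ExtractionConfig) -> None:
    left = session.recording(Location.LEFT_LOWER_LEG)
    right = session.recording(Location.RIGHT_LOWER_LEG)
    low_back = session.recording(Location.LOW_BACK)
    events = detect_gait_events(left.gyro[:, 1], right.gyro[:, 1],
                                left.sampling_rate, config.gait_params)
    ts, te = detect_turn(events, low_back.gyro[:, 2], low_back.sampling_rate,
                         config.gait_params)
    events = events.with_turn(ts, te)
    distance = float(session.metadata.get("walkway_distance_m", config.walkway_distance_m))
    gm = gait_measures(events, low_back, distance, config.filter_spec)
    rename = {
        "gait_velocity": "tug_gait_velocity",
        "step_time": "tug_step_time",
        "step_time_alt": "tug_step_time_alt",
        "step_length": "tug_step_length",
        "walk_time": "tug_walk_time",
        "n_steps": "tug_n_steps",
        "turn_time": "tug_turn_time",
        "turn_gyro_rms": "tug_turn_gyro_rms",
        "turn_gyro_max": "tug_turn_gyro_max",
    }
    for key, value in gm.items():
        vec.set(rename.get(key, f"tug_{key}"), value)


def _sts5(vec: MeasureVector, session: Session, config: ExtractionConfig) -> None:
    loc = (Location.RIGHT_UPPER_LEG
           if Location.RIGHT_UPPER_LEG in session.recordings
           else Location.LEFT_UPPER_LEG)
    _, measures = sts5_measures(session.recording(loc),
                                onset_frac=config.sts5_onset_frac,
                                filter_spec=config.filter_spec)
    for key, value in measures.items():
        vec.set(f"sts5_{key}", value)


def _mf(vec: MeasureVector, task: str, session: Session, config: ExtractionConfig) -> None:
    roms = []
    for side, upper, lower in (
        ("left", Location.LEFT_UPPER_LEG, Location.LEFT_LOWER_LEG),
        ("right", Location.RIGHT_UPPER_LEG, Location.RIGHT_LOWER_LEG),
    ):
        rom = knee_rom(session.recording(upper), session.recording(lower), config.filter_spec)
        vec.set(f"mf_{task}_rom_{side}", rom)
        roms.append(rom)
    vec.set(f"mf_{task}_rom", float(np.mean(roms)))


def extract_all(
    sessions: dict[Subtest, Session],
    logs: Optional[dict[str, AppLog]] = None,
    subject: Optional[SubjectRecord] = None,
    config: Optional[ExtractionConfig] = None,
) -> MeasureVector:
    """Extract every catalogue measure computable from the supplied sessions.

    Partial batteries are allowed: measures from absent subtests (or failing
    detections) are flagged missing rather than raising, and the reason is
    kept in ``notes``.  A complete battery populates the full catalogue.
    """
    config = config or ExtractionConfig()
    logs = logs or {}
    sessions = {Subtest(k): v for k, v in sessions.items()}
    subject_id = subject.subject_id if subject else (
        next(iter(sessions.values())).subject_id if sessions else "unknown"
    )
    vec = MeasureVector(subject_id=subject_id)

    for subtest, needed in SENSOR_MAP.items():
        if subtest in sessions:
            missing_locs = [loc for loc in needed if loc not in sessions[subtest].recordings]
            if missing_locs and subtest != Subtest.STS5:
                raise ValidationError(
                    f"{subtest.value} session lacks required sensor(s): "
                    f"{[loc.value for loc in missing_locs]}"
                )

    condition_es: dict[str, dict[str, float]] = {}
    for cond in SIT_CONDITIONS:
        subtest = Subtest(f"SIT_{cond.upper()}")
        if subtest in sessions:
            try:
                es = _sit_condition_measures(vec, cond, sessions[subtest], config)
                condition_es[cond] = es
            except ValueError as exc:
                vec.notes[subtest.value] = str(exc)

    for d in ("ap", "ml"):
        if all(cond in condition_es for cond in SIT_CONDITIONS):
            som, vis, vest = sensory_system_scores(
                condition_es["eo_firm"][d], condition_es["ec_firm"][d],
                condition_es["eo_foam"][d], condition_es["ec_foam"][d],
            )
            vec.set(f"sit_som_es_{d}", som)
            vec.set(f"sit_vis_es_{d}", vis)
            vec.set(f"sit_vest_es_{d}", vest)

    stage_runs = []
    if Subtest.TUG in sessions:
        stage_runs.append(("TUG", lambda: _tug_measures(vec, sessions[Subtest.TUG], config)))
    if Subtest.STS5 in sessions:
        stage_runs.append(("STS5", lambda: _sts5(vec, sessions[Subtest.STS5], config)))
    if Subtest.LOS in sessions:
        def _los():
            session = sessions[Subtest.LOS]
            reach = session.metadata.get("reach_distance_m")
            height = subject.height_cm if subject else session.metadata.get("height_cm")
            out = los_measures(session.recording(Location.LOW_BACK),
                               None if reach is None else float(reach),
                               None if height is None else float(height),
                               config.filter_spec)
            vec.notes["los_reach_method"] = out.pop("reach_method")
            for key, value in out.items():
                vec.set(f"los_{key}", value)
        stage_runs.append(("LOS", _los))
    for task, subtest in (("flexion", Subtest.MF_FLEXION), ("extension", Subtest.MF_EXTENSION)):
        if subtest in sessions:
            stage_runs.append(
                (subtest.value, lambda t=task, s=subtest: _mf(vec, t, sessions[s], config))
            )
    if "CRT" in logs:
        def _crt():
            ips, srt = crt_measures(logs["CRT"])
            vec.set("crt_ips", ips)
            vec.set("crt_srt", srt)
        stage_runs.append(("CRT", _crt))
    if "FES" in logs:
        stage_runs.append(("FES", lambda: vec.set("fes_score", fes_score(logs["FES"]))))

    for stage, run in stage_runs:
        try:
            run()
        except ValueError as exc:
            vec.notes[stage] = str(exc)

    for measure_id in measure_catalogue()["measure_id"]:
        if measure_id not in vec.values:
            vec.flag_missing(measure_id)
    return vec
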