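"""Declarative measure catalogue driving the extraction pipeline.

The catalogue enumerates every scalar the battery produces: 155 measures over
the seven subtests (the four quiet-standing conditions count as one subtest).
A 38-entry screened reference list names the measures that pass both the
group t-test and the ROC criterion and feed the classifiers by default.
"""

from __future__ import annotations

from functools import lru_cache

import pandas as pd

__all__ = ["measure_catalogue", "screened_reference", "CATALOGUE_SIZE", "SCREENED_SIZE"]

CATALOGUE_SIZE = 155
SCREENED_SIZE = 38

SIT_CONDITIONS = ("eo_firm", "ec_firm", "eo_foam", "ec_foam")
_DIRS_2 = ("ap", "ml")
_DIRS_3 = ("ap", "ml", "v")


def _rows():
    rows = []

    def add(measure_id, subtest, sensor, direction, statistic, units, domain):
        rows.append(
            dict(measure_id=measure_id, subtest=subtest, sensor=sensor,
                 direction=direction, statistic=statistic, units=units, domain=domain)
        )

    # --- SIT: 26 measures per condition x 4 conditions + 6 sensory scores = 110
    for cond in SIT_CONDITIONS:
        sub = f"SIT_{cond.upper()}"
        for d in _DIRS_2:
            add(f"sit_{cond}_es_{d}", sub, "low_back", d, "equilibrium_score", "score", "time")
            add(f"sit_{cond}_rms_acc_{d}", sub, "low_back", d, "rms_acc", "m/s^2", "time")
            add(f"sit_{cond}_rms_gyro_{d}", sub, "low_back", d, "rms_gyro", "deg/s", "time")
            add(f"sit_{cond}_jerk_acc_{d}", sub, "low_back", d, "jerk_acc", "m/s^3", "time")
            add(f"sit_{cond}_jerk_gyro_{d}", sub, "low_back", d, "jerk_gyro", "deg/s^2", "time")
            add(f"sit_{cond}_rms_tilt_{d}", sub, "low_back", d, "rms_tilt", "deg", "time")
            add(f"sit_{cond}_range_tilt_{d}", sub, "low_back", d, "range_tilt", "deg", "time")
            for ch, unit in (("acc", "m/s^2"), ("gyro", "deg/s")):
                add(f"sit_{cond}_medfreq_{ch}_{d}", sub, "low_back", d,
                    f"median_freq_{ch}", "Hz", "frequency")
                add(f"sit_{cond}_cenfreq_{ch}_{d}", sub, "low_back", d,
                    f"centroid_freq_{ch}", "Hz", "frequency")
                add(f"sit_{cond}_psd_{ch}_{d}", sub, "low_back", d,
                    f"psd_power_{ch}", f"({unit})^2", "frequency")
    for system in ("som", "vis", "vest"):
        for d in _DIRS_2:
            add(f"sit_{system}_es_{d}", "SIT", "low_back", d,
                f"{system}_equilibrium_score", "score", "score")

    # --- TUG: 21
    for mid, stat, units in (
        ("tug_gait_velocity", "gait_velocity", "m/s"),
        ("tug_step_time", "step_time_same_foot", "s"),
        ("tug_step_time_alt", "step_time_alternating", "s"),
        ("tug_step_length", "step_length", "m"),
        ("tug_walk_time", "walk_time", "s"),
        ("tug_n_steps", "n_steps", "count"),
    ):
        add(mid, "TUG", "lower_legs", "", stat, units, "time")
    for d in _DIRS_3:
        add(f"tug_walk_rms_acc_{d}", "TUG", "low_back", d, "walk_rms_acc", "m/s^2", "time")
        add(f"tug_walk_rms_gyro_{d}", "TUG", "low_back", d, "walk_rms_gyro", "deg/s", "time")
        add(f"tug_walk_jerk_acc_{d}", "TUG", "low_back", d, "walk_jerk_acc", "m/s^3", "time")
        add(f"tug_walk_jerk_gyro_{d}", "TUG", "low_back", d, "walk_jerk_gyro", "deg/s^2", "time")
    add("tug_turn_time", "TUG", "lower_legs", "", "turn_time", "s", "time")
    add("tug_turn_gyro_rms", "TUG", "low_back", "v", "turn_rms_gyro", "deg/s", "time")
    add("tug_turn_gyro_max", "TUG", "low_back", "v", "turn_max_gyro", "deg/s", "time")

    # --- STS5: 10
    for phase in ("sit_stand", "stand_sit", "sit_stand_sit"):
        add(f"sts5_{phase}_duration", "STS5", "upper_leg", "", f"{phase}_duration", "s", "time")
        add(f"sts5_{phase}_mean_gyro", "STS5", "upper_leg", "", f"{phase}_mean_gyro", "deg/s", "time")
        add(f"sts5_{phase}_jerk", "STS5", "upper_leg", "", f"{phase}_jerk", "deg/s^2", "time")
    add("sts5_total_time", "STS5", "upper_leg", "", "total_time", "s", "time")

    # --- LOS: 5
    add("los_reach_distance", "LOS", "low_back", "", "forward_reach", "m", "time")
    for d in _DIRS_2:
        add(f"los_rms_gyro_{d}", "LOS", "low_back", d, "rms_gyro", "deg/s", "time")
        add(f"los_jerk_gyro_{d}", "LOS", "low_back", d, "jerk_gyro", "deg/s^2", "time")

    # --- MF: 6
    for task in ("flexion", "extension"):
        for side in ("left", "right"):
            add(f"mf_{task}_rom_{side}", f"MF_{task.upper()}", "upper+lower_leg", side,
                f"knee_{task}_rom", "deg", "time")
        add(f"mf_{task}_rom", f"MF_{task.upper()}", "upper+lower_leg", "both",
            f"knee_{task}_rom_mean", "deg", "time")

    # --- CRT: 2, FES: 1
    add("crt_ips", "CRT", "app", "", "information_processing_speed", "bit/s", "score")
    add("crt_srt", "CRT", "app", "", "simple_reaction_time", "s", "score")
    add("fes_score", "FES", "app", "", "falls_efficacy_score", "score", "score")
    return rows


@lru_cache(maxsize=1)
def measure_catalogue() -> pd.DataFrame:
    """The full measure catalogue as a DataFrame (one row per measure)."""
    df = pd.DataFrame(_rows())
    assert df["measure_id"].is_unique
    assert len(df) == CATALOGUE_SIZE, f"catalogue has {len(df)} rows, expected {CATALOGUE_SIZE}"
    return df


#: measures significant in both the t-test and the ROC criterion on the study
#: cohort; used as the default predictor set for the classifiers.
_SCREENED = [
    "fes_score",
    "crt_ips",
    "tug_step_length",
    "tug_gait_velocity",
    "sts5_stand_sit_jerk",
    "mf_extension_rom",
    "sts5_sit_stand_sit_jerk",
    "tug_turn_gyro_max",
    "sit_vis_es_ml",
    "mf_flexion_rom",
    "tug_step_time",
    "tug_turn_time",
    "tug_turn_gyro_rms",
    "tug_walk_rms_gyro_ap",
    "tug_walk_rms_gyro_ml",
    "tug_walk_rms_gyro_v",
    "tug_walk_rms_acc_v",
    "sts5_sit_stand_duration",
    "sts5_stand_sit_duration",
    "sts5_sit_stand_sit_duration",
    "sts5_sit_stand_mean_gyro",
    "sts5_stand_sit_mean_gyro",
    "sts5_sit_stand_sit_mean_gyro",
    "sts5_sit_stand_jerk",
    "sts5_total_time",
    "los_jerk_gyro_ml",
    "sit_vest_es_ml",
    "sit_eo_foam_es_ml",
    "sit_eo_foam_rms_acc_ap",
    "sit_eo_foam_rms_acc_ml",
    "sit_eo_foam_rms_gyro_ap",
    "sit_eo_foam_jerk_acc_ap",
    "sit_eo_foam_jerk_acc_ml",
    "sit_eo_foam_jerk_gyro_ap",
    "sit_eo_firm_jerk_acc_ap",
    "sit_ec_firm_jerk_acc_ap",
    "sit_ec_foam_es_ml",
    "sit_ec_foam_rms_acc_ap",
]


def screened_reference() -> list[str]:
    """IDs of the screened predictor measures (all present in the catalogue)."""
    cat = set(measure_catalogue()["measure_id"])
    missing = [m for m in _SCREENED if m not in cat]
    assert not missing, f"screened reference ids missing from catalogue: {missing}"
    assert len(_SCREENED) == SCREENED_SIZE
    return list(_SCREENED)
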