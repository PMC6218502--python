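"""Scalar signal measures: RMS, jerk, spectral summaries, equilibrium scores."""

from __future__ import annotations

import numpy as np
from scipy import signal as sp_signal

from ..core_io import ValidationError
from ..preprocess import derivative

__all__ = [
    "rms",
    "jerk_measure",
    "frequency_measures",
    "equilibrium_score",
    "sensory_system_scores",
]

#: theoretical stability limit for the equilibrium score, degrees of tilt range
DEFAULT_THETA_LIMIT_DEG = 12.5


def rms(series) -> float:
    """Root-mean-square of the mean-removed series (sway convention)."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValidationError("rms of an empty series")
    x = x - x.mean()
    return float(np.sqrt(np.mean(x * x)))


def jerk_measure(series, rate: float, mean_removed: bool = True) -> float:
    """RMS of the time derivative of the series (units/s).

    Applied to acceleration this is jerk; applied to angular velocity it is
    the RMS angular acceleration.  By default the derivative is mean-removed
    before the RMS, matching the sway convention of :func:`rms`; set
    ``mean_removed=False`` to keep a constant drift term.
    """
    d = derivative(series, rate)
    if mean_removed:
        return rms(d)
    return float(np.sqrt(np.mean(np.asarray(d, float) ** 2)))


def frequency_measures(series, rate: float, nperseg: int = 256) -> tuple[float, float, float]:
    """(median frequency Hz, centroid frequency Hz, total PSD power).

    Computed from a Welch averaged periodogram of the mean-removed series.
    Median frequency splits the cumulative power in half; the centroid is the
    power-weighted mean frequency; total power integrates the density.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 256:
        raise ValidationError(f"frequency_measures needs >= 256 samples, got {x.size}")
    x = x - x.mean()
    freqs, psd = sp_signal.welch(x, fs=rate, nperseg=min(nperseg, x.size))
    power = psd.sum()
    if power <= 0:
        return 0.0, 0.0, 0.0
    cum = np.cumsum(psd)
    median_freq = float(np.interp(0.5 * power, cum, freqs))
    centroid_freq = float((freqs * psd).sum() / power)
    total_power = float(np.trapezoid(psd, freqs))
    return median_freq, centroid_freq, total_power


def equilibrium_score(tilt_deg, theta_limit_deg: float = DEFAULT_THETA_LIMIT_DEG) -> float:
    """0-100 postural stability score from a tilt-angle series.

    100 * (1 - tilt range / theta_limit), clamped to [0, 100]; 100 means no
    sway, 0 means the sway range reached the stability limit.
    """
    if theta_limit_deg <= 0:
        raise ValidationError("theta_limit must be positive")
    x = np.asarray(tilt_deg, dtype=float)
    if x.size == 0:
        raise ValidationError("equilibrium_score of an empty series")
    score = 100.0 * (1.0 - (x.max() - x.min()) / theta_limit_deg)
    return float(np.clip(score, 0.0, 100.0))


def sensory_system_scores(
    es_eo_firm: float, es_ec_firm: float, es_eo_foam: float, es_ec_foam: float
) -> tuple[float, float, float]:
    """(somatosensory, visual, vestibular) scores from the four condition
    equilibrium scores, as condition-to-baseline ratios scaled to 100 and
    capped at 100.  Baseline is eyes-open on the firm surface.

    Returns NaN for all three when the baseline score is zero (flagged
    missing upstream).
    """
    if es_eo_firm == 0:
        return float("nan"), float("nan"), float("nan")
    som = min(100.0, 100.0 * es_ec_firm / es_eo_firm)
    vis = min(100.0, 100.0 * es_eo_foam / es_eo_firm)
    vest = min(100.0, 100.0 * es_ec_foam / es_eo_firm)
    return som, vis, vest
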