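"""Noise filtering and basic signal derivations shared by the feature extractors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import Location, SensorRecording, ValidationError

__all__ = ["FilterSpec", "butterworth_lowpass", "derivative", "tilt_angles"]


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth, applied zero-phase (two effective passes)."""

    order: int = 4
    cutoff_hz: float = 20.0

    def validate(self, rate: float) -> None:
        if self.order < 1:
            raise ValidationError("filter order must be >= 1")
        if not 0 < self.cutoff_hz < rate / 2:
            raise ValidationError(
                f"cutoff {self.cutoff_hz} Hz must lie in (0, Nyquist={rate / 2} Hz)"
            )


def butterworth_lowpass(series, spec: FilterSpec = FilterSpec(), rate: float = 100.0):
    """Zero-phase low-pass Butterworth filter.

    Implemented by frequency sampling: the (real) spectrum is scaled by the
    squared analog Butterworth magnitude 1 / (1 + (f/fc)^(2*order)), the exact
    response of a forward-backward pass, with no phase shift at any frequency.
    A bilinear-transform IIR run through ``filtfilt`` warps the response near
    Nyquist away from this documented contract, which is why the filter is
    applied spectrally.  The series is reflect-padded before the transform to
    suppress edge transients, then trimmed.

    Works on 1-D series or (n, k) arrays (filtered column-wise).
    """
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n = x.shape[0]
    spec.validate(rate)
    if n <= 3 * spec.order:
        raise ValidationError(f"series length {n} too short for order-{spec.order} filter")

    # reflect-pad by ~3 filter time constants (bounded by the series itself)
    pad = int(min(n - 1, max(3 * spec.order, round(3 * rate / spec.cutoff_hz))))
    xp = np.concatenate([x[pad:0:-1], x, x[-2:-pad - 2:-1]], axis=0)

    freqs = np.fft.rfftfreq(xp.shape[0], d=1.0 / rate)
    gain = 1.0 / (1.0 + (freqs / spec.cutoff_hz) ** (2 * spec.order))
    y = np.fft.irfft(np.fft.rfft(xp, axis=0) * gain[:, None], n=xp.shape[0], axis=0)
    y = y[pad:pad + n]
    return y[:, 0] if squeeze else y


def derivative(series, rate: float):
    """Time derivative: central differences inside, one-sided at the edges.

    Exact for linear series (a ramp of slope k maps to the constant k).
    """
    x = np.asarray(series, dtype=float)
    if x.shape[0] < 3:
        raise ValidationError("derivative needs at least 3 samples")
    return np.gradient(x, 1.0 / rate, axis=0)


def tilt_angles(
    low_back: SensorRecording,
    gravity_cutoff_hz: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Anteroposterior and mediolateral trunk tilt, in degrees.

    Uses the orientation channels when present (theta_AP = pitch,
    theta_ML = roll).  Otherwise the gravity direction is isolated with a
    ``gravity_cutoff_hz`` low-pass on acceleration and the inclination is
    theta_AP = atan2(acc_x, acc_z), theta_ML = atan2(acc_y, acc_z).
    """
    if low_back.location != Location.LOW_BACK:
        raise ValidationError(
            f"tilt_angles requires the low_back recording, got {low_back.location.value}"
        )
    if low_back.orientation is not None:
        return low_back.orientation[:, 1].copy(), low_back.orientation[:, 0].copy()
    g = butterworth_lowpass(
        low_back.acc, FilterSpec(order=4, cutoff_hz=gravity_cutoff_hz), low_back.sampling_rate
    )
    theta_ap = np.degrees(np.arctan2(g[:, 0], g[:, 2]))
    theta_ml = np.degrees(np.arctan2(g[:, 1], g[:, 2]))
    return theta_ap, theta_ml
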