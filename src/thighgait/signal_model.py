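"""Raw and derived signals from a thigh-mounted IMU.

This module owns the axis conventions of the six-channel recording, the
dominant-frequency estimate of the vertical acceleration, and the two
Butterworth feature filters that feed the event detector:

* ``az_bp`` — vertical acceleration band-passed around its dominant (step)
  frequency ± a half width;
* ``gy_lp3`` — pitch angular velocity low-passed at 3 Hz.

Internal units are m/s² and rad/s throughout; readers convert declared
source units at load time (:mod:`thighgait.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import signal as sps
from scipy.fft import next_fast_len, rfft, rfftfreq

__all__ = [
    "ImuRecording",
    "FeatureSignals",
    "estimate_main_frequency",
    "bandpass_az",
    "lowpass_gyro",
    "compute_features",
]

#: default search band (Hz) for the dominant gait frequency
DEFAULT_SEARCH_BAND = (0.5, 3.0)

#: target spectral bin width (Hz) before parabolic refinement
_FREQ_RESOLUTION = 0.05


def _as_series(x: Any, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise ValueError(f"{name} contains a non-finite value at sample {bad}")
    return arr


@dataclass
class ImuRecording:
    """A uniformly sampled six-axis thigh-IMU trace.

    Axis convention: X = anterior–posterior, Y = medial–lateral,
    Z = superior–inferior.  ``gyro_pitch`` is the rotation rate about the
    medial–lateral axis, with positive = thigh flexion (forward rotation);
    for left-side sensors the raw Y rate is negated at load so the same
    detector applies to both legs.

    The time base is implicit and uniform: sample ``i`` occurs at
    ``i / sample_rate`` seconds.
    """

    sample_rate: float
    acc_ap: np.ndarray
    acc_ml: np.ndarray
    acc_v: np.ndarray
    gyro_roll: np.ndarray
    gyro_pitch: np.ndarray
    gyro_yaw: np.ndarray
    side: str = "right"
    units_declared: dict = field(default_factory=lambda: {"acc": "m_s2", "gyro": "rad_s"})

    def __post_init__(self) -> None:
        if self.sample_rate <= 6.0:
            raise ValueError(
                f"sample_rate must exceed 6 Hz (Nyquist above the 3 Hz low-pass "
                f"cutoff), got {self.sample_rate}"
            )
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        names = ("acc_ap", "acc_ml", "acc_v", "gyro_roll", "gyro_pitch", "gyro_yaw")
        series = []
        for name in names:
            arr = _as_series(getattr(self, name), name)
            setattr(self, name, arr)
            series.append(arr)
        n = series[0].size
        if n < 2:
            raise ValueError("recording must contain at least 2 samples")
        if any(s.size != n for s in series):
            raise ValueError("all six axis series must have the same length")

    @property
    def n_samples(self) -> int:
        return int(self.acc_v.size)

    @property
    def duration(self) -> float:
        """Recording span in seconds."""
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


@dataclass
class FeatureSignals:
    """Feature signals consumed by the event-detection rules."""

    acc_x: np.ndarray  # anterior–posterior acceleration (source reference)
    acc_z: np.ndarray  # vertical acceleration (source reference)
    gyro_y: np.ndarray  # pitch angular velocity (source reference)
    az_bp: np.ndarray  # band-passed vertical acceleration
    gy_lp3: np.ndarray  # low-passed pitch angular velocity
    main_freq_az: float
    sample_rate: float

    def __post_init__(self) -> None:
        n = self.acc_z.size
        if self.az_bp.size != n or self.gy_lp3.size != n:
            raise ValueError("filtered series must match source length")
        nyq = self.sample_rate / 2.0
        if not (0.5 < self.main_freq_az < nyq):
            raise ValueError(
                f"main_freq_az = {self.main_freq_az} Hz outside (0.5, {nyq}) Hz"
            )
        rms = float(np.sqrt(np.mean(self.az_bp**2)))
        if rms > 0 and abs(float(np.mean(self.az_bp))) > 0.01 * rms:
            raise ValueError("az_bp mean exceeds 1% of its RMS; band-pass failed")


def estimate_main_frequency(
    series: np.ndarray,
    sample_rate: float,
    search_band: tuple[float, float] = DEFAULT_SEARCH_BAND,
) -> float:
    """Dominant spectral frequency of an acceleration series.

    The mean-removed series is zero-padded to a spectral bin width of at
    most 0.05 Hz; the peak magnitude bin inside ``search_band`` is refined
    by parabolic interpolation over its two neighbours.  The estimate is
    invariant to scaling and constant offsets, and deterministic.

    Parameters
    ----------
    series
        Uniformly sampled acceleration, at least 4 s long.
    sample_rate
        Sampling frequency in Hz.
    search_band
        ``(low, high)`` frequency window, within (0, Nyquist).

    Returns
    -------
    float
        Peak frequency in Hz.
    """
    x = _as_series(series, "series")
    fs = float(sample_rate)
    if x.size < 4 * fs:
        raise ValueError(
            f"series too short for frequency estimation: {x.size} samples "
            f"< 4 s at {fs} Hz"
        )
    lo, hi = float(search_band[0]), float(search_band[1])
    nyq = fs / 2.0
    if not (0.0 < lo < hi < nyq):
        raise ValueError(f"search_band {search_band} outside (0, Nyquist={nyq})")

    x = x - x.mean()
    if not np.any(x):
        raise ValueError("degenerate input: series has no spectral content")

    nfft = next_fast_len(max(x.size, int(np.ceil(fs / _FREQ_RESOLUTION))))
    mag = np.abs(rfft(x, nfft))
    freqs = rfftfreq(nfft, 1.0 / fs)
    band = (freqs >= lo) & (freqs <= hi)
    if not np.any(band) or not np.any(mag[band] > 0):
        raise ValueError("no spectral peak inside the search band")

    k = int(np.flatnonzero(band)[np.argmax(mag[band])])
    # parabolic refinement around the peak bin
    if 0 < k < mag.size - 1:
        a, b, c = mag[k - 1], mag[k], mag[k + 1]
        denom = a - 2 * b + c
        delta = 0.0 if denom == 0 else 0.5 * (a - c) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return float((k + delta) * fs / nfft)


def _butter_sos(order: int, wn, btype: str, fs: float):
    return sps.butter(order, wn, btype=btype, fs=fs, output="sos")


def _apply(sos, x: np.ndarray, causal: bool) -> np.ndarray:
    if causal:
        return sps.sosfilt(sos, x)
    # forward–backward: zero phase, default edge padding of 3x section length
    return sps.sosfiltfilt(sos, x)


def bandpass_az(
    acc_v: np.ndarray,
    sample_rate: float,
    main_freq: float,
    half_width: float = 0.5,
    causal: bool = False,
) -> np.ndarray:
    """Second-order Butterworth band-pass around ``main_freq`` ± ``half_width``.

    Applied zero-phase (forward–backward) by default, so passband peaks are
    not shifted in time; effective attenuation is doubled relative to a
    single causal pass.
    """
    x = _as_series(acc_v, "acc_v")
    fs = float(sample_rate)
    lo = float(main_freq) - float(half_width)
    hi = float(main_freq) + float(half_width)
    if lo <= 0 or hi >= fs / 2.0:
        raise ValueError(
            f"band edges [{lo}, {hi}] Hz invalid for sample rate {fs} Hz"
        )
    sos = _butter_sos(2, (lo, hi), "bandpass", fs)
    return _apply(sos, x, causal)


def lowpass_gyro(
    gyro_pitch: np.ndarray,
    sample_rate: float,
    cutoff: float = 3.0,
    causal: bool = False,
) -> np.ndarray:
    """Second-order Butterworth low-pass (zero-phase by default)."""
    x = _as_series(gyro_pitch, "gyro_pitch")
    fs = float(sample_rate)
    if not (0.0 < cutoff < fs / 2.0):
        raise ValueError(f"cutoff {cutoff} Hz outside (0, Nyquist) for fs={fs}")
    sos = _butter_sos(2, cutoff, "lowpass", fs)
    return _apply(sos, x, causal)


def compute_features(recording: ImuRecording, config) -> FeatureSignals:
    """Assemble the feature signals for a recording.

    ``config`` is any object exposing ``main_freq`` (``"auto"`` or a fixed
    Hz value), ``bandpass_half_width_hz``, ``lowpass_cutoff_hz`` and
    ``causal`` — typically a :class:`thighgait.event_detection.DetectionConfig`.

    The side-dependent sign flip of the pitch rate is applied when the
    recording is loaded from file, not here; recordings constructed in
    memory (e.g. by the simulator) are already in the canonical convention.
    """
    fs = recording.sample_rate
    main_freq = getattr(config, "main_freq", "auto")
    if isinstance(main_freq, str):
        if main_freq != "auto":
            raise ValueError(f"main_freq must be 'auto' or a number, got {main_freq!r}")
        main_freq = estimate_main_frequency(recording.acc_v, fs)
    main_freq = float(main_freq)

    half_width = float(getattr(config, "bandpass_half_width_hz", 0.5))
    cutoff = float(getattr(config, "lowpass_cutoff_hz", 3.0))
    causal = bool(getattr(config, "causal", False))

    az_bp = bandpass_az(recording.acc_v, fs, main_freq, half_width, causal=causal)
    gy_lp3 = lowpass_gyro(recording.gyro_pitch, fs, cutoff, causal=causal)
    return FeatureSignals(
        acc_x=recording.acc_ap,
        acc_z=recording.acc_v,
        gyro_y=recording.gyro_pitch,
        az_bp=az_bp,
        gy_lp3=gy_lp3,
        main_freq_az=main_freq,
        sample_rate=fs,
    )
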