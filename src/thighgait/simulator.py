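"""Synthetic thigh-IMU gait signals with exact ground-truth event times.

The generator is a specification-by-construction of the waveform
morphology the detector relies on, not a biomechanical model:

* pitch angular velocity — a monotone piecewise-cubic interpolant through
  per-stride anchors, guaranteeing a unique local peak at the OTO phase, a
  descending zero crossing at the OIC phase, and a unique sub-threshold
  local minimum at the TO phase;
* vertical acceleration — a two-per-stride cosine (so the band-passed
  signal's minima bracket each IC) plus Gaussian impact pulses at IC and
  smaller ones at OIC;
* anterior–posterior acceleration — IC impact pulses plus a weak
  one-per-stride oscillation.

Everything is seeded and reproducible; unused axes carry noise only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.stats import truncnorm

from .evaluation import GroundTruth
from .signal_model import ImuRecording

__all__ = [
    "SimulationSpec",
    "generate_timeline",
    "synthesize_gyro",
    "synthesize_acc",
    "simulate",
    "with_relative_noise",
]

#: fraction of the stride minimum relative to the peak amplitude
_TO_DEPTH = 0.9


@dataclass(frozen=True)
class SimulationSpec:
    """Parametric stride timeline and waveform amplitudes.

    Event phases are fractions of the stride with IC at phase 0;
    ``asymmetry_shift`` is added to the OIC phase (negative = earlier
    contralateral contact).  ``pad_s`` is lead-in/lead-out padding added
    around the stride train by :func:`simulate` (default 0.6 stride) so
    the first and last ICs remain detectable; ``None`` selects the
    default.
    """

    n_strides: int = 20
    stride_mean: float = 1.2
    stride_sd: float = 0.0
    oto_phase: float = 0.12
    oic_phase: float = 0.50
    to_phase: float = 0.62
    gyro_amp: float = 3.0
    accz_amp: float = 1.0
    impact_amp_ic: float = 3.0
    # mid-stride acc_v peak = accz_amp + impact_amp_oic; keep it below the
    # default IC threshold so only true ICs fire
    impact_amp_oic: float = 0.4
    impact_width: float = 0.03
    noise_acc_sd: float = 0.0
    noise_gyro_sd: float = 0.0
    asymmetry_shift: float = 0.0
    sample_rate: float = 100.0
    seed: int = 0
    pad_s: float | None = None

    def __post_init__(self) -> None:
        oic = self.oic_phase + self.asymmetry_shift
        if not (0.0 < self.oto_phase < oic < self.to_phase < 1.0):
            raise ValueError(
                f"event phases must satisfy 0 < OTO < OIC < TO < 1, got "
                f"OTO={self.oto_phase}, OIC={oic}, TO={self.to_phase}"
            )
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")
        if self.stride_mean <= 0 or self.stride_sd < 0:
            raise ValueError("stride_mean must be > 0 and stride_sd >= 0")
        for name in ("gyro_amp", "accz_amp", "impact_amp_ic", "impact_amp_oic",
                     "noise_acc_sd", "noise_gyro_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.impact_width <= 0:
            raise ValueError("impact_width must be > 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")

    @property
    def pad(self) -> float:
        return 0.6 * self.stride_mean if self.pad_s is None else self.pad_s


def _rng(spec: SimulationSpec, stream: int) -> np.random.Generator:
    # independent, reproducible streams per signal component
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), stream]))


def _stride_durations(spec: SimulationSpec) -> np.ndarray:
    if spec.stride_sd == 0:
        return np.full(spec.n_strides, spec.stride_mean)
    # truncated normal, bounded below at half the mean stride
    a = (0.5 * spec.stride_mean - spec.stride_mean) / spec.stride_sd
    dist = truncnorm(a, np.inf, loc=spec.stride_mean, scale=spec.stride_sd)
    return dist.rvs(size=spec.n_strides, random_state=_rng(spec, 0))


def generate_timeline(spec: SimulationSpec) -> GroundTruth:
    """True event times for a seeded stride train, first IC at t = 0.

    The IC list has ``n_strides + 1`` entries (the closing IC of the last
    stride included); OTO/OIC/TO have ``n_strides`` each.
    """
    d = _stride_durations(spec)
    ics = np.concatenate(([0.0], np.cumsum(d)))
    oic = spec.oic_phase + spec.asymmetry_shift
    return GroundTruth(
        events={
            "IC": ics,
            "OTO": ics[:-1] + spec.oto_phase * d,
            "OIC": ics[:-1] + oic * d,
            "TO": ics[:-1] + spec.to_phase * d,
        },
        source="simulator",
    )


def _extended_ics(timeline: GroundTruth) -> np.ndarray:
    """IC boundaries with one virtual stride prepended and appended.

    The virtual strides reuse the first/last real stride duration so the
    waveforms continue naturally into any padding.
    """
    ics = timeline.events["IC"]
    if ics.size < 2:
        raise ValueError("timeline must contain at least one full stride")
    return np.concatenate(([ics[0] - (ics[1] - ics[0])], ics,
                           [ics[-1] + (ics[-1] - ics[-2])]))


def _phase(t_grid: np.ndarray, ics: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continuous stride phase of each grid time (stride index + fraction)."""
    k = np.clip(np.searchsorted(ics, t_grid, side="right") - 1, 0, ics.size - 2)
    d = ics[k + 1] - ics[k]
    frac = (t_grid - ics[k]) / d
    return k, frac


def synthesize_gyro(
    timeline: GroundTruth, spec: SimulationSpec, t_grid: np.ndarray
) -> np.ndarray:
    """Pitch angular-velocity series on ``t_grid``.

    Monotone piecewise-cubic interpolation through per-stride anchors —
    (OTO, +amp), (OIC, 0), (TO, −0.9·amp), (mid-swing, 0) — so between
    anchors the waveform is monotone and every detection trigger is
    unique and exactly placed (noiseless case).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if spec.gyro_amp == 0 and spec.noise_gyro_sd == 0:
        return np.zeros_like(t_grid)
    ics = _extended_ics(timeline)
    oto = spec.oto_phase
    oic = spec.oic_phase + spec.asymmetry_shift
    to = spec.to_phase
    mid = (to + 1.0) / 2.0  # ascending zero between TO and next IC
    amp = spec.gyro_amp
    # shoulder anchors sharpen the OTO peak so its location stays put under
    # additive noise; the descent through OIC is antisymmetric about the
    # zero so the 3 Hz low-pass does not bias the crossing.  Widths shrink
    # near tight phase layouts to keep the anchors strictly ordered.
    w_oto = min(0.06, 0.45 * oto, 0.45 * (oic - oto))
    wc2 = min(0.10, 0.45 * (oic - (oto + w_oto)), 0.85 * (to - oic))
    wc1 = wc2 / 2.0
    phases = np.array(
        [oto - w_oto, oto, oto + w_oto,
         oic - wc2, oic - wc1, oic, oic + wc1, oic + wc2,
         to, mid]
    )
    values = np.array(
        [0.4 * amp, amp, 0.4 * amp,
         0.38 * amp, 0.2 * amp, 0.0, -0.2 * amp, -0.38 * amp,
         -_TO_DEPTH * amp, 0.0]
    )

    starts = ics[:-1]
    durs = np.diff(ics)
    anchor_t = (starts[:, None] + phases[None, :] * durs[:, None]).ravel()
    anchor_v = np.tile(values, starts.size)
    order = np.argsort(anchor_t)
    clean = PchipInterpolator(anchor_t[order], anchor_v[order], extrapolate=True)(t_grid)
    if spec.noise_gyro_sd > 0:
        clean = clean + _rng(spec, 1).normal(0.0, spec.noise_gyro_sd, t_grid.size)
    return clean


def _pulses(t_grid: np.ndarray, centers: np.ndarray, amp: float, width: float) -> np.ndarray:
    if amp == 0 or centers.size == 0:
        return np.zeros_like(t_grid)
    out = np.zeros_like(t_grid)
    for c in centers:
        out += amp * np.exp(-0.5 * ((t_grid - c) / width) ** 2)
    return out


def synthesize_acc(
    timeline: GroundTruth, spec: SimulationSpec, t_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Anterior–posterior and vertical acceleration series on ``t_grid``.

    The vertical channel is ``accz_amp·cos(4π·phase)`` — minima at stride
    phases 0.25 and 0.75, so the band-passed minima bracket each IC — plus
    impact pulses at IC and OIC.  The AP channel carries IC pulses plus a
    weak one-per-stride sine.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    ics = _extended_ics(timeline)
    k, frac = _phase(t_grid, ics)

    oic = spec.oic_phase + spec.asymmetry_shift
    durs = np.diff(ics)
    ic_centers = ics  # includes the virtual boundary ICs
    oic_centers = ics[:-1] + oic * durs

    acc_v = (
        spec.accz_amp * np.cos(4.0 * np.pi * frac)
        + _pulses(t_grid, ic_centers, spec.impact_amp_ic, spec.impact_width)
        + _pulses(t_grid, oic_centers, spec.impact_amp_oic, spec.impact_width)
    )
    acc_ap = (
        _pulses(t_grid, ic_centers, spec.impact_amp_ic, spec.impact_width)
        + 0.3 * spec.accz_amp * np.sin(2.0 * np.pi * frac)
    )
    if spec.noise_acc_sd > 0:
        acc_v = acc_v + _rng(spec, 2).normal(0.0, spec.noise_acc_sd, t_grid.size)
        acc_ap = acc_ap + _rng(spec, 3).normal(0.0, spec.noise_acc_sd, t_grid.size)
    return acc_ap, acc_v


def simulate(spec: SimulationSpec) -> tuple[ImuRecording, GroundTruth]:
    """Full six-axis recording plus the matching ground truth.

    The stride train is shifted by the lead-in padding so the recording
    time base starts at 0; ground-truth times are on the recording clock.
    Unused axes (medial–lateral acceleration, roll/yaw rates) carry noise
    only.
    """
    base = generate_timeline(spec)
    pad = spec.pad
    shifted = GroundTruth(
        events={k: v + pad for k, v in base.events.items()}, source="simulator"
    )
    total = shifted.events["IC"][-1] + pad
    n = int(np.floor(total * spec.sample_rate)) + 1
    t_grid = np.arange(n) / spec.sample_rate

    gyro_pitch = synthesize_gyro(shifted, spec, t_grid)
    acc_ap, acc_v = synthesize_acc(shifted, spec, t_grid)

    def _noise(stream: int, sd: float) -> np.ndarray:
        if sd == 0:
            return np.zeros(n)
        return _rng(spec, stream).normal(0.0, sd, n)

    recording = ImuRecording(
        sample_rate=spec.sample_rate,
        acc_ap=acc_ap,
        acc_ml=_noise(4, spec.noise_acc_sd),
        acc_v=acc_v,
        gyro_roll=_noise(5, spec.noise_gyro_sd),
        gyro_pitch=gyro_pitch,
        gyro_yaw=_noise(6, spec.noise_gyro_sd),
        side="right",
    )
    return recording, shifted


def with_relative_noise(spec: SimulationSpec, fraction: float) -> SimulationSpec:
    """Spec copy whose noise SDs are ``fraction`` of the noiseless RMS.

    RMS is measured per channel family (vertical acceleration, pitch rate)
    on a noiseless rendering of the same spec.
    """
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    clean = replace(spec, noise_acc_sd=0.0, noise_gyro_sd=0.0)
    rec, _ = simulate(clean)
    rms_acc = float(np.sqrt(np.mean(rec.acc_v**2)))
    rms_gyro = float(np.sqrt(np.mean(rec.gyro_pitch**2)))
    return replace(
        spec,
        noise_acc_sd=fraction * rms_acc,
        noise_gyro_sd=fraction * rms_gyro,
    )
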