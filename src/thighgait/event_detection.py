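"""Threshold- and zero-crossing-based detection of the four gait events.

The detector works from three thigh-IMU feature signals
(:class:`~thighgait.signal_model.FeatureSignals`):

* TO  — sub-threshold local minimum of the raw pitch rate;
* IC  — supra-threshold vertical-acceleration peak inside a window bounded
  by two adjacent minima of the band-passed vertical acceleration, gated
  by the anterior–posterior acceleration when that channel also spikes;
* OTO — first pitch-rate local peak after IC plus a configurable delay;
* OIC — first (+)→(−) zero crossing of the low-passed pitch rate after OTO.

Thresholds ship with smoke-test defaults but the documented workflow is to
calibrate them with :func:`calibrate_thresholds` against reference events.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks

from .signal_model import FeatureSignals, ImuRecording, compute_features

__all__ = [
    "DetectionConfig",
    "GaitEvent",
    "GaitCycle",
    "find_local_extrema",
    "detect_to",
    "ic_windows",
    "detect_ic",
    "detect_oto",
    "detect_oic",
    "detect_events",
    "calibrate_thresholds",
    "CalibrationResult",
]

EVENT_KINDS = ("IC", "OTO", "OIC", "TO")


@dataclass
class DetectionConfig:
    """Tunable parameters of the detector and its feature filters.

    Thresholds are in internal units (m/s², rad/s); ``oto_delay`` and
    ``min_peak_separation`` are fractions of the estimated cycle duration.
    """

    th_to_gyro: float = -0.5  # rad/s, negative: TO local-minimum gate
    th_acc_x: float = 1.5  # m/s² above gravity-removed baseline
    th_acc_z: float = 1.5  # m/s² above gravity-removed baseline
    oto_delay: float = 0.05
    min_peak_separation: float = 0.25
    main_freq: float | str = "auto"  # "auto" or fixed Hz
    bandpass_half_width_hz: float = 0.5
    lowpass_cutoff_hz: float = 3.0
    causal: bool = False
    sample_rate_hz: float = 100.0
    acc_units: str = "m_s2"
    gyro_units: str = "rad_s"
    side: str = "right"

    def __post_init__(self) -> None:
        if self.th_to_gyro >= 0:
            raise ValueError("th_to_gyro must be negative")
        if self.th_acc_x <= 0 or self.th_acc_z <= 0:
            raise ValueError("acceleration thresholds must be positive")
        if not (0.0 < self.oto_delay < 0.5):
            raise ValueError("oto_delay must lie in (0, 0.5)")
        if not (0.0 < self.min_peak_separation < 0.5):
            raise ValueError("min_peak_separation must lie in (0, 0.5)")


@dataclass(frozen=True)
class GaitEvent:
    kind: str
    sample_index: int
    time: float

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class GaitCycle:
    """One stride: IC → OTO → OIC → TO → next IC.

    ``valid`` is False when any event is missing or the temporal ordering
    is violated; ``edge`` flags the first/last cycle of a recording, which
    are excluded from parameter statistics by default.
    """

    ic: GaitEvent | None
    oto: GaitEvent | None
    oic: GaitEvent | None
    to: GaitEvent | None
    next_ic: GaitEvent | None = None
    edge: bool = False
    valid: bool = False

    @property
    def duration(self) -> float | None:
        if self.ic is None or self.next_ic is None:
            return None
        return self.next_ic.time - self.ic.time

    def events(self) -> list[GaitEvent]:
        return [e for e in (self.ic, self.oto, self.oic, self.to) if e is not None]


def _dedup_extrema(indices: np.ndarray, values: np.ndarray, min_separation: int) -> np.ndarray:
    """Keep the more extreme of any two candidates closer than min_separation.

    ``values`` must already be oriented so that larger = more extreme.
    Greedy by extremeness, ties broken by earlier index (deterministic).
    """
    if indices.size == 0 or min_separation <= 1:
        return indices
    order = np.lexsort((indices, -values))
    kept: list[int] = []
    for i in order:
        idx = int(indices[i])
        if all(abs(idx - k) >= min_separation for k in kept):
            kept.append(idx)
    return np.array(sorted(kept), dtype=int)


def find_local_extrema(
    series: np.ndarray, mode: str, min_separation: int = 1
) -> np.ndarray:
    """Indices of strict local extrema, plateau-aware.

    A sample qualifies when it is strictly beyond both distinct neighbours;
    plateaus contribute their first sample.  Among extrema closer than
    ``min_separation`` samples, only the more extreme survives.  Endpoints
    never qualify.  Returns sorted indices (empty for degenerate input).
    """
    if mode not in ("min", "max"):
        raise ValueError(f"mode must be 'min' or 'max', got {mode!r}")
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        return np.array([], dtype=int)
    y = -x if mode == "min" else x
    _, props = find_peaks(y, plateau_size=(1, None))
    idx = props["left_edges"].astype(int)
    return _dedup_extrema(idx, y[idx], int(min_separation))


def detect_to(
    gyro_y: np.ndarray, th_to_gyro: float, min_separation: int = 1
) -> np.ndarray:
    """TO candidates: local minima of the raw pitch rate below threshold."""
    if th_to_gyro >= 0:
        raise ValueError("th_to_gyro must be negative")
    x = np.asarray(gyro_y, dtype=float)
    idx = find_local_extrema(x, "min", 1)
    idx = idx[x[idx] < th_to_gyro]
    return _dedup_extrema(idx, -x[idx], int(min_separation))


def ic_windows(az_bp: np.ndarray, min_separation: int = 1) -> list[tuple[int, int]]:
    """Half-open IC-search windows between adjacent band-passed-AccZ minima."""
    minima = find_local_extrema(az_bp, "min", min_separation)
    return [(int(a), int(b)) for a, b in zip(minima[:-1], minima[1:])]


def detect_ic(
    acc_x: np.ndarray,
    acc_z: np.ndarray,
    window: tuple[int, int],
    th_acc_x: float,
    th_acc_z: float,
    min_separation: int = 1,
) -> int | None:
    """IC inside one window, or ``None``.

    Branch A (anterior–posterior channel spikes inside the window): the
    earliest supra-threshold vertical-acceleration local maximum at or
    after the first supra-threshold AP sample.  Branch B (no AP spike):
    the largest supra-threshold vertical-acceleration local maximum.
    """
    a, b = int(window[0]), int(window[1])
    if b <= a:
        raise ValueError(f"window {window} is empty")
    z = np.asarray(acc_z, dtype=float)
    x = np.asarray(acc_x, dtype=float)
    seg = z[a:b]
    peaks = a + find_local_extrema(seg, "max", min_separation)
    peaks = peaks[z[peaks] > th_acc_z]
    if peaks.size == 0:
        return None
    gate = np.flatnonzero(x[a:b] > th_acc_x)
    if gate.size:  # branch A
        first = a + int(gate[0])
        after = peaks[peaks >= first]
        return int(after[0]) if after.size else None
    # branch B: most prominent supra-threshold peak
    return int(peaks[np.argmax(z[peaks])])


def detect_oto(
    gyro_y: np.ndarray,
    ic_index: int,
    delay: int,
    search_end: int,
    min_separation: int = 1,
) -> int | None:
    """First pitch-rate local peak in ``[ic_index + delay, search_end)``."""
    start = int(ic_index) + int(delay)
    end = int(search_end)
    if start >= end:
        return None
    x = np.asarray(gyro_y, dtype=float)
    seg = x[start:end]
    peaks = start + find_local_extrema(seg, "max", min_separation)
    return int(peaks[0]) if peaks.size else None


def detect_oic(gy_lp3: np.ndarray, oto_index: int, search_end: int) -> int | None:
    """First (+) → (−) zero crossing after ``oto_index``.

    Returns the first index ``i > oto_index`` with
    ``gy_lp3[i-1] > 0 >= gy_lp3[i]``; an exact-zero sample is attributed
    to the crossing.  ``None`` when no crossing occurs before ``search_end``.
    """
    s = int(oto_index)
    e = int(search_end)
    if s >= e:
        return None
    x = np.asarray(gy_lp3, dtype=float)
    seg = x[s : min(e, x.size)]
    hits = np.flatnonzero((seg[:-1] > 0) & (seg[1:] <= 0))
    return int(s + hits[0] + 1) if hits.size else None


def _event(kind: str, index: int | None, fs: float) -> GaitEvent | None:
    if index is None:
        return None
    return GaitEvent(kind, int(index), int(index) / fs)


def detect_events(
    recording: ImuRecording,
    config: DetectionConfig,
    features: FeatureSignals | None = None,
) -> list[GaitCycle]:
    """Run the full four-event detection pipeline on one recording.

    Cycles are assembled from consecutive detected ICs; OTO/OIC searches
    are bounded by the next detected TO (falling back to the next IC when
    the TO is missing), preventing cross-cycle capture.  A cycle missing
    any event or violating IC < OTO < OIC < TO ordering is returned with
    ``valid=False``.  First and last cycles are flagged ``edge``.
    """
    feats = features if features is not None else compute_features(recording, config)
    fs = recording.sample_rate
    cycle_est = 2.0 / feats.main_freq_az  # seconds; step freq is 2 per stride
    if recording.duration < 3.0 * cycle_est:
        raise ValueError(
            f"recording too short: {recording.duration:.2f} s < 3 estimated "
            f"strides ({3 * cycle_est:.2f} s)"
        )
    min_sep = max(1, int(round(config.min_peak_separation * cycle_est * fs)))

    to_idx = detect_to(feats.gyro_y, config.th_to_gyro, min_sep)
    windows = ic_windows(feats.az_bp, min_sep)
    ics = [
        i
        for w in windows
        if (i := detect_ic(feats.acc_x, feats.acc_z, w, config.th_acc_x,
                           config.th_acc_z, min_sep)) is not None
    ]

    cycles: list[GaitCycle] = []
    for k in range(len(ics) - 1):
        ic_i, nic_i = ics[k], ics[k + 1]
        in_cycle = to_idx[(to_idx > ic_i) & (to_idx < nic_i)]
        to_i = int(in_cycle[0]) if in_cycle.size else None
        bound = to_i if to_i is not None else nic_i
        delay = max(1, int(round(config.oto_delay * (nic_i - ic_i))))
        oto_i = detect_oto(feats.gyro_y, ic_i, delay, bound, min_sep)
        oic_i = detect_oic(feats.gy_lp3, oto_i, bound) if oto_i is not None else None

        cyc = GaitCycle(
            ic=_event("IC", ic_i, fs),
            oto=_event("OTO", oto_i, fs),
            oic=_event("OIC", oic_i, fs),
            to=_event("TO", to_i, fs),
            next_ic=_event("IC", nic_i, fs),
            edge=(k == 0 or k == len(ics) - 2),
        )
        cyc.valid = (
            None not in (oto_i, oic_i, to_i)
            and ic_i < oto_i < oic_i < to_i < nic_i
        )
        cycles.append(cyc)
    return cycles


# ---------------------------------------------------------------------------
# threshold calibration

@dataclass
class CalibrationResult:
    config: DetectionConfig
    f1: float
    mean_abs_error_ms: float
    table: list[dict] = field(repr=False, default_factory=list)


def _score_point(
    recordings: Sequence[ImuRecording],
    references: Sequence["GroundTruth"],
    config: DetectionConfig,
    tolerance: float,
    features: Sequence[FeatureSignals] | None = None,
) -> tuple[float, float]:
    """Pooled event-matching F1 and mean |error| (ms) over all recordings."""
    from .evaluation import match_events  # local import: avoid cycle

    tp = fp = fn = 0
    abs_errs: list[float] = []
    for i, (rec, ref) in enumerate(zip(recordings, references)):
        try:
            cycles = detect_events(
                rec, config, features=None if features is None else features[i]
            )
        except ValueError:
            cycles = []
        detected = cycles_to_event_times(cycles)
        result = match_events(detected, ref, tolerance)
        for kind in EVENT_KINDS:
            m = result[kind]
            tp += len(m.pairs)
            fp += len(m.spurious)
            fn += len(m.missed)
            abs_errs.extend(abs(d - r) * 1000.0 for d, r in m.pairs)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    mean_abs = float(np.mean(abs_errs)) if abs_errs else float("inf")
    return f1, mean_abs


def cycles_to_event_times(cycles: Iterable[GaitCycle]) -> dict[str, np.ndarray]:
    """Collect per-kind sorted event times from assembled cycles.

    The closing IC of the last cycle is included so that n strides yield
    n+1 IC times.
    """
    out: dict[str, list[float]] = {k: [] for k in EVENT_KINDS}
    last_next = None
    for c in cycles:
        for e in c.events():
            out[e.kind].append(e.time)
        last_next = c.next_ic
    if last_next is not None:
        out["IC"].append(last_next.time)
    return {k: np.unique(np.asarray(v, dtype=float)) for k, v in out.items()}


def calibrate_thresholds(
    recordings: Sequence[ImuRecording],
    references: Sequence["GroundTruth"],
    grid: dict[str, Sequence[float]],
    base_config: DetectionConfig | None = None,
    tolerance: float = 0.05,
) -> CalibrationResult:
    """Exhaustive grid search over detector thresholds.

    ``grid`` maps a subset of ``{"th_to_gyro", "th_acc_x", "th_acc_z",
    "oto_delay"}`` to candidate values.  The objective is lexicographic:
    maximise pooled event-matching F1 at ``±tolerance`` seconds, then
    minimise mean |error| in ms, then prefer the grid point closest to the
    grid centre (Euclidean distance in grid-index space) — a deterministic
    tie-break that is invariant to the order of the input recordings.
    """
    allowed = ("th_to_gyro", "th_acc_x", "th_acc_z", "oto_delay")
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty on every axis")
    unknown = set(grid) - set(allowed)
    if unknown:
        raise ValueError(f"unknown grid parameters: {sorted(unknown)}")
    if len(recordings) == 0 or len(recordings) != len(references):
        raise ValueError("need >= 1 recording, each with a reference")

    base = base_config if base_config is not None else DetectionConfig()
    # feature signals are threshold-independent: compute once per recording
    feats = [compute_features(rec, base) for rec in recordings]
    names = [n for n in allowed if n in grid]
    axes = [list(grid[n]) for n in names]
    centre = np.array([(len(a) - 1) / 2.0 for a in axes])

    best = None
    table: list[dict] = []
    for idx in itertools.product(*(range(len(a)) for a in axes)):
        point = {n: axes[i][j] for i, (n, j) in enumerate(zip(names, idx))}
        config = replace(base, **point)
        f1, mean_abs = _score_point(recordings, references, config, tolerance,
                                    features=feats)
        dist = float(np.linalg.norm(np.array(idx) - centre))
        table.append({**point, "f1": f1, "mean_abs_error_ms": mean_abs})
        key = (-f1, mean_abs, dist, idx)  # lexicographic, fully deterministic
        if best is None or key < best[0]:
            best = (key, config, f1, mean_abs)

    assert best is not None
    return CalibrationResult(config=best[1], f1=best[2], mean_abs_error_ms=best[3],
                             table=table)
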