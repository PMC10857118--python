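"""Scoring of detected gait events and parameters against reference tables.

Reference events come from force-plate tables or from the simulator's
ground truth.  Event errors follow the detected-minus-reference sign
convention (negative = early detection); the error rate expresses the
error as a percentage of the enclosing reference gait-cycle duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GroundTruth",
    "MatchResult",
    "EventErrorReport",
    "match_events",
    "event_errors",
    "parameter_errors",
]

EVENT_KINDS = ("IC", "OTO", "OIC", "TO")

#: box-plot outlier rule: beyond 3x the IQR from the quartiles
OUTLIER_IQR_FACTOR = 3.0


@dataclass
class GroundTruth:
    """Ordered reference event times per kind, in seconds."""

    events: dict[str, np.ndarray]
    source: str = "force_plate"

    def __post_init__(self) -> None:
        if self.source not in ("force_plate", "simulator"):
            raise ValueError(f"unknown source {self.source!r}")
        clean: dict[str, np.ndarray] = {}
        for kind, times in self.events.items():
            if kind not in EVENT_KINDS:
                raise ValueError(f"unknown event kind {kind!r}")
            t = np.asarray(times, dtype=float)
            if np.any(np.diff(t) < 0):
                raise ValueError(f"{kind} reference times are not ascending")
            clean[kind] = t
        self.events = clean

    def cycle_durations(self) -> np.ndarray:
        ics = self.events.get("IC", np.array([]))
        return np.diff(ics)

    def median_cycle(self) -> float:
        d = self.cycle_durations()
        if d.size == 0:
            raise ValueError("reference has fewer than two ICs; no cycle duration")
        return float(np.median(d))

    def enclosing_cycle(self, time: float) -> float:
        """Duration of the reference IC→IC interval containing ``time``.

        Falls back to the median cycle for times outside the covered span.
        """
        ics = self.events.get("IC", np.array([]))
        if ics.size >= 2 and ics[0] <= time < ics[-1]:
            j = int(np.searchsorted(ics, time, side="right")) - 1
            return float(ics[j + 1] - ics[j])
        return self.median_cycle()


@dataclass
class MatchResult:
    """Matched pairs plus leftovers for one event kind."""

    kind: str
    pairs: list[tuple[float, float]]  # (detected_time, reference_time)
    spurious: list[float]  # detected with no reference partner
    missed: list[float]  # reference with no detected partner


def match_events(
    detected: Mapping[str, Sequence[float]],
    reference: GroundTruth,
    tolerance: float | None = None,
) -> dict[str, MatchResult]:
    """Greedy nearest-neighbour pairing of detected to reference events.

    Candidate pairs within ``tolerance`` seconds are accepted in order of
    increasing |Δt| (ties broken by reference then detected index, so the
    result is deterministic); each event is used at most once.  The
    default tolerance is half the median reference cycle.
    """
    if tolerance is None:
        tolerance = reference.median_cycle() / 2.0
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")

    out: dict[str, MatchResult] = {}
    for kind in EVENT_KINDS:
        det = np.asarray(detected.get(kind, ()), dtype=float)
        ref = reference.events.get(kind, np.array([]))
        cand = [
            (abs(d - r), j, i, d, r)
            for i, d in enumerate(det)
            for j, r in enumerate(ref)
            if abs(d - r) <= tolerance
        ]
        cand.sort()
        used_d: set[int] = set()
        used_r: set[int] = set()
        pairs: list[tuple[float, float]] = []
        for _, j, i, d, r in cand:
            if i in used_d or j in used_r:
                continue
            used_d.add(i)
            used_r.add(j)
            pairs.append((d, r))
        pairs.sort(key=lambda p: p[1])
        out[kind] = MatchResult(
            kind=kind,
            pairs=pairs,
            spurious=[float(d) for i, d in enumerate(det) if i not in used_d],
            missed=[float(r) for j, r in enumerate(ref) if j not in used_r],
        )
    return out


@dataclass
class EventErrorReport:
    """Per-pair errors and per-kind summary statistics.

    ``pairs`` columns: kind, detected_time, reference_time, error_ms,
    error_pct_gc, outlier.  ``summary`` is indexed by kind with mean/SD of
    both metrics and the bookkeeping counts.
    """

    pairs: pd.DataFrame
    summary: pd.DataFrame = field(repr=False)

    def mean_abs_error_rate(self) -> pd.Series:
        """Mean |error rate| (%GC) per event kind."""
        if self.pairs.empty:
            return pd.Series(dtype=float)
        return self.pairs.groupby("kind")["error_pct_gc"].apply(
            lambda s: float(np.mean(np.abs(s)))
        )


def _iqr_outliers(values: np.ndarray) -> np.ndarray:
    """Boolean mask of values beyond 3x IQR outside the quartiles."""
    if values.size == 0:
        return np.zeros(0, dtype=bool)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo = q1 - OUTLIER_IQR_FACTOR * iqr
    hi = q3 + OUTLIER_IQR_FACTOR * iqr
    return (values < lo) | (values > hi)


def event_errors(
    matches: Mapping[str, MatchResult], reference: GroundTruth
) -> EventErrorReport:
    """Timing errors and error rates for matched event pairs.

    error_ms = (detected − reference)·1000; error_pct_gc normalises by the
    enclosing reference IC→IC duration.  Outliers (per kind, on error_ms)
    are flagged beyond 3×IQR from the quartiles.
    """
    rows = []
    for kind in EVENT_KINDS:
        m = matches.get(kind)
        if m is None:
            continue
        for det, ref in m.pairs:
            err_ms = (det - ref) * 1000.0
            cycle_ms = reference.enclosing_cycle(ref) * 1000.0
            rows.append(
                {
                    "kind": kind,
                    "detected_time": det,
                    "reference_time": ref,
                    "error_ms": err_ms,
                    "error_pct_gc": err_ms / cycle_ms * 100.0,
                }
            )
    pairs = pd.DataFrame(
        rows,
        columns=["kind", "detected_time", "reference_time", "error_ms", "error_pct_gc"],
    )
    pairs["outlier"] = False
    for kind in EVENT_KINDS:
        sel = pairs["kind"] == kind
        if sel.any():
            pairs.loc[sel, "outlier"] = _iqr_outliers(pairs.loc[sel, "error_ms"].to_numpy())

    srows = []
    for kind in EVENT_KINDS:
        m = matches.get(kind)
        sub = pairs[pairs["kind"] == kind]
        n = len(sub)
        srows.append(
            {
                "kind": kind,
                "mean_error_ms": sub["error_ms"].mean() if n else np.nan,
                "sd_error_ms": sub["error_ms"].std(ddof=1) if n > 1 else (0.0 if n else np.nan),
                "mean_error_pct_gc": sub["error_pct_gc"].mean() if n else np.nan,
                "sd_error_pct_gc": sub["error_pct_gc"].std(ddof=1) if n > 1 else (0.0 if n else np.nan),
                "n_matched": n,
                "n_missed": len(m.missed) if m else 0,
                "n_spurious": len(m.spurious) if m else 0,
                "n_outliers": int(sub["outlier"].sum()),
            }
        )
    summary = pd.DataFrame(srows).set_index("kind")
    return EventErrorReport(pairs=pairs, summary=summary)


def parameter_errors(
    calculated: pd.DataFrame, measured: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Calculated-minus-measured parameter differences, per cycle.

    Both tables must be aligned row-for-row (same length, same columns).
    Returns ``(per_cycle, summary)`` where the summary holds mean and
    sample SD of the differences for every shared numeric column.
    """
    if len(calculated) != len(measured):
        raise ValueError(
            f"tables misaligned: {len(calculated)} calculated vs "
            f"{len(measured)} measured cycles"
        )
    cols = [
        c
        for c in calculated.columns
        if c in measured.columns and c != "cycle_index"
        and np.issubdtype(calculated[c].dtype, np.number)
    ]
    if not cols:
        raise ValueError("tables share no numeric parameter columns")
    diff = calculated[cols].reset_index(drop=True) - measured[cols].reset_index(drop=True)
    n = len(diff)
    sd = diff.std(ddof=1) if n > 1 else pd.Series(0.0, index=diff.columns)
    summary = pd.DataFrame({"mean": diff.mean(), "sd": sd, "n": n})
    summary.index.name = "parameter"
    return diff, summary
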