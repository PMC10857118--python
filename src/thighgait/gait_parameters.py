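"""Temporal gait parameters derived from the four events of each stride.

All percentages are of the gait cycle (IC to next ipsilateral IC).  The
reported double-limb-support value is the mean of the initial (IC→OTO) and
terminal (OIC→TO) periods, so that stance = SLS + 2·DLS holds exactly; a
flag exposes the total instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .event_detection import GaitCycle

__all__ = ["TemporalParameters", "cycle_parameters", "aggregate_parameters", "PARAMETER_FIELDS"]

PARAMETER_FIELDS = (
    "stride_time",
    "stance_pct",
    "swing_pct",
    "symmetry_pct",
    "sls_pct",
    "dls_initial_pct",
    "dls_terminal_pct",
    "dls_pct",
    "cadence",
)


@dataclass(frozen=True)
class TemporalParameters:
    """Per-cycle temporal parameters (percentages of the gait cycle)."""

    stride_time: float
    stance_pct: float
    swing_pct: float
    symmetry_pct: float
    sls_pct: float
    dls_initial_pct: float
    dls_terminal_pct: float
    dls_pct: float
    cadence: float

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in PARAMETER_FIELDS}


def cycle_parameters(
    cycle: GaitCycle, total_dls: bool = False
) -> TemporalParameters:
    """Compute temporal parameters for one complete cycle.

    With ``T`` the stride duration: stance = (TO−IC)/T, symmetry =
    (OIC−IC)/T, single limb support = (OIC−OTO)/T, initial/terminal double
    limb support = (OTO−IC)/T and (TO−OIC)/T, all ×100; swing = 100 −
    stance; cadence = 120/T steps/min (one contralateral step per stride).

    ``total_dls=True`` reports the summed double-support instead of the
    mean of the two periods.

    Raises ``ValueError`` for an incomplete or mis-ordered cycle or a
    non-positive duration.  The degenerate boundary TO = next IC (stance
    100 %) is allowed.
    """
    ev = (cycle.ic, cycle.oto, cycle.oic, cycle.to, cycle.next_ic)
    if any(e is None for e in ev):
        raise ValueError("cycle is incomplete; cannot compute parameters")
    ic, oto, oic, to, nic = (e.time for e in ev)  # type: ignore[union-attr]
    T = nic - ic
    if T <= 0:
        raise ValueError(f"non-positive cycle duration {T}")
    if not (ic < oto < oic < to <= nic):
        raise ValueError("cycle violates IC < OTO < OIC < TO <= next IC ordering")

    stance = (to - ic) / T * 100.0
    swing = 100.0 - stance
    symmetry = (oic - ic) / T * 100.0
    dls_i = (oto - ic) / T * 100.0
    sls = (oic - oto) / T * 100.0
    dls_t = (to - oic) / T * 100.0
    dls = dls_i + dls_t if total_dls else (dls_i + dls_t) / 2.0
    return TemporalParameters(
        stride_time=T,
        stance_pct=stance,
        swing_pct=swing,
        symmetry_pct=symmetry,
        sls_pct=sls,
        dls_initial_pct=dls_i,
        dls_terminal_pct=dls_t,
        dls_pct=dls,
        cadence=120.0 / T,
    )


def parameters_table(
    cycles: Iterable[GaitCycle],
    include_edge: bool = False,
    total_dls: bool = False,
) -> pd.DataFrame:
    """One row of parameters per usable cycle.

    Cycles that are invalid, incomplete, or (by default) edge-flagged are
    skipped; the original cycle index is preserved in the ``cycle_index``
    column.
    """
    rows = []
    for i, c in enumerate(cycles):
        if not c.valid or (c.edge and not include_edge):
            continue
        p = cycle_parameters(c, total_dls=total_dls)
        rows.append({"cycle_index": i, **p.as_dict()})
    return pd.DataFrame(rows, columns=["cycle_index", *PARAMETER_FIELDS])


def aggregate_parameters(
    cycles: Iterable[GaitCycle],
    include_edge: bool = False,
    total_dls: bool = False,
) -> pd.DataFrame:
    """Mean ± sample SD of each parameter over valid interior cycles.

    Returns a frame indexed by parameter with columns ``mean``, ``sd`` and
    ``n``; SD is reported as 0 when only one cycle is available.
    """
    table = parameters_table(cycles, include_edge=include_edge, total_dls=total_dls)
    if table.empty:
        raise ValueError("no valid interior cycles to aggregate")
    data = table[list(PARAMETER_FIELDS)]
    n = len(data)
    sd = data.std(ddof=1) if n > 1 else pd.Series(0.0, index=data.columns)
    out = pd.DataFrame({"mean": data.mean(), "sd": sd})
    out["n"] = n
    out.index.name = "parameter"
    return out
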