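"""Dominance epochs and their serialization.

A dominance epoch is the interval during which one percept's activity
peak exceeds the other's. Epochs are delimited by debounced switch
events; the sequence of epochs tiles the interval between the first and
last committed switch after burn-in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .params import DEFAULT_TIME_UNIT_MS

CSV_COLUMNS = ["percept", "t_on", "duration", "duration_s"]


@dataclass(frozen=True)
class DominanceRecord:
    """One dominance epoch.

    percept : "L"/"R" for two-percept models, "1"/"2"/"3" for three.
    t_on : onset time in model units.
    duration : dominance time T in model units.
    duration_s : the same in seconds.
    """

    percept: str
    t_on: float
    duration: float
    duration_s: float


def records_from_switches(
    switch_times: np.ndarray,
    switch_from: np.ndarray,
    labels: Sequence[str],
    burn_in: float,
    time_unit_ms: float = DEFAULT_TIME_UNIT_MS,
) -> list[DominanceRecord]:
    """Convert committed switch events into dominance epochs.

    ``switch_from[i]`` is the integer label of the percept that *ended*
    at ``switch_times[i]``. The epoch between switches i and i+1 belongs
    to the percept that ended at switch i+1. Epochs starting before
    ``burn_in`` are discarded, which also drops the (truncated) epoch in
    progress when burn-in ends.
    """
    switch_times = np.asarray(switch_times, dtype=float)
    switch_from = np.asarray(switch_from, dtype=np.int64)
    out: list[DominanceRecord] = []
    for i in range(len(switch_times) - 1):
        t_on = switch_times[i]
        if t_on < burn_in:
            continue
        dur = switch_times[i + 1] - switch_times[i]
        lab = labels[switch_from[i + 1]]
        out.append(
            DominanceRecord(lab, float(t_on), float(dur), float(dur * time_unit_ms / 1000.0))
        )
    return out


def records_to_dataframe(records: Iterable[DominanceRecord]) -> pd.DataFrame:
    rows = [(r.percept, r.t_on, r.duration, r.duration_s) for r in records]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def records_to_csv(records: Iterable[DominanceRecord], path: str) -> None:
    records_to_dataframe(records).to_csv(path, index=False, float_format="%.10g")

def records_from_csv(path: str) -> list[DominanceRecord]:
    df = pd.read_csv(path, dtype={"percept": str})
    return [
        DominanceRecord(r.percept, float(r.t_on), float(r.duration), float(r.duration_s))
        for r in df.itertuples()
    ]


def durations(records: Iterable[DominanceRecord], percept: str | None = None) -> np.ndarray:
    """Durations in model units, optionally for a single percept."""
    return np.array(
        [r.duration for r in records if percept is None or r.percept == percept], dtype=float
    )
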