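"""Personalized physiological baseline quantization.

Standard threshold alerts compare a frail resident's vitals against
population norms and misfire under high inter-subject variability. The
basal quantizer instead maintains, per resident and channel, an expanding
historical set ``H_t = {x_1, ..., x_{t-1}}`` of that resident's own healthy
values and recursively updates its empirical quartiles (q25, q50, q75).
Each new observation is mapped to a categorical state

    Q = 1 if x <= q25;  2 if q25 < x <= q50;  3 if q50 < x <= q75;  4 otherwise

and to its day-to-day first difference dQ = Q_t - Q_{t-1}. The (Q, dQ)
stream is a non-linear filter: it smooths high-frequency noise, preserves
genuine state transitions, and is invariant to any strictly increasing
affine transform of the raw series — so downstream classifiers learn a
universal deviation signature instead of memorizing individual baselines.

Days labeled infected are quantized but never absorbed into the history, so
the baseline cannot drift toward the pathological state.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Observed values required before quartiles (and hence Q) are defined.
DEFAULT_MIN_HISTORY = 4


@dataclass
class BasalState:
    """Per-resident, per-channel history and current quartiles.

    ``history`` is a multiset (kept sorted internally for exact O(1)
    quartile recomputation after each insert).
    """

    resident_id: str
    channel: str
    min_history: int = DEFAULT_MIN_HISTORY
    history: list = field(default_factory=list)
    q25: Optional[float] = None
    q50: Optional[float] = None
    q75: Optional[float] = None
    last_q: Optional[int] = None

    @property
    def n_obs(self) -> int:
        return len(self.history)

    @property
    def ready(self) -> bool:
        return self.n_obs >= self.min_history


@dataclass(frozen=True)
class QuantizedReading:
    """Categorical state and its first difference; None while warming up."""

    q: Optional[int]
    delta_q: Optional[int]


def _quartile_sorted(values: list, p: float) -> float:
    # Linear interpolation on the sorted history ("type 7" convention).
    h = (len(values) - 1) * p
    lo = math.floor(h)
    hi = min(lo + 1, len(values) - 1)
    return values[lo] + (values[hi] - values[lo]) * (h - lo)


def _quartiles(sorted_values: list) -> tuple[float, float, float]:
    return (
        _quartile_sorted(sorted_values, 0.25),
        _quartile_sorted(sorted_values, 0.50),
        _quartile_sorted(sorted_values, 0.75),
    )


def quantize(state: BasalState, x: float) -> QuantizedReading:
    """Map ``x`` onto the state's historical quartile bins.

    Ties go to the lower bin (closed-left bins). Returns ``(None, None)``
    while fewer than ``min_history`` values have been absorbed. ``delta_q``
    is relative to the last defined state, 0 when there is no predecessor.
    The state itself is not modified.
    """
    if not (isinstance(x, (int, float, np.floating, np.integer)) and math.isfinite(x)):
        raise ValueError(f"non-finite vital value {x!r}")
    if not state.ready:
        return QuantizedReading(None, None)
    if x <= state.q25:
        q = 1
    elif x <= state.q50:
        q = 2
    elif x <= state.q75:
        q = 3
    else:
        q = 4
    delta = 0 if state.last_q is None else q - state.last_q
    return QuantizedReading(q, delta)


def update_basal(state: BasalState, x: float, is_event_day: bool = False) -> BasalState:
    """Absorb ``x`` into the history unless the day is an infection day.

    On non-event days the value is appended and the quartiles recomputed
    exactly from the full history (histories stay small — a few hundred
    points — so streaming approximations are unnecessary). On event days
    the state is returned unchanged: pathological values must not shift
    the personal baseline.
    """
    if not math.isfinite(x):
        raise ValueError(f"non-finite vital value {x!r}")
    if is_event_day:
        return state
    bisect.insort(state.history, float(x))
    if state.ready:
        state.q25, state.q50, state.q75 = _quartiles(state.history)
    return state


def run_basal_stream(
    series: pd.DataFrame,
    labels: Optional[pd.DataFrame] = None,
    min_history: int = DEFAULT_MIN_HISTORY,
) -> pd.DataFrame:
    """Quantize one resident-channel series day by day.

    ``series`` has columns (date, value), sorted by date, one resident and
    one channel; ``labels`` optionally carries (date, status) infection
    labels. Each observed day is quantized against the state *before* that
    day's value is incorporated, then the state is updated (gated on the
    label). Null days yield undefined readings and no update.
    """
    dates = pd.to_datetime(series["date"])
    if not dates.is_monotonic_increasing:
        raise ValueError("series must be sorted by date")
    event_days: set = set()
    if labels is not None and len(labels):
        infected = labels.loc[labels["status"] == "INFECTED", "date"]
        event_days = set(pd.to_datetime(infected))

    rid = str(series["resident_id"].iloc[0]) if "resident_id" in series else ""
    ch = str(series["channel"].iloc[0]) if "channel" in series else ""
    state = BasalState(rid, ch, min_history=min_history)
    qs: list = []
    dqs: list = []
    for date, value in zip(dates, series["value"]):
        if pd.isna(value):
            qs.append(None)
            dqs.append(None)
            continue
        reading = quantize(state, float(value))
        qs.append(reading.q)
        dqs.append(reading.delta_q)
        if reading.q is not None:
            state.last_q = reading.q
        update_basal(state, float(value), is_event_day=date in event_days)
    out = series[["date"]].copy()
    out["Q"] = pd.array(qs, dtype="Int64")
    out["delta_Q"] = pd.array(dqs, dtype="Int64")
    return out


def quantize_cohort(
    vitals: pd.DataFrame,
    diagnoses: Optional[pd.DataFrame] = None,
    min_history: int = DEFAULT_MIN_HISTORY,
) -> pd.DataFrame:
    """Run the basal stream over every resident-channel series of a cohort.

    Returns a long table (resident_id, date, channel, Q, delta_Q); null
    vitals days carry undefined readings.
    """
    label_groups = {}
    if diagnoses is not None and len(diagnoses):
        label_groups = {rid: g for rid, g in diagnoses.groupby("resident_id")}
    frames = []
    for (rid, channel), group in vitals.sort_values("date").groupby(
        ["resident_id", "channel"], sort=True
    ):
        res = run_basal_stream(group, label_groups.get(rid), min_history=min_history)
        res.insert(0, "resident_id", rid)
        res.insert(2, "channel", channel)
        frames.append(res)
    if not frames:
        return pd.DataFrame(columns=["resident_id", "date", "channel", "Q", "delta_Q"])
    return pd.concat(frames, ignore_index=True)
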