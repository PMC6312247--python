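"""Clock-hour pattern detection and participant-level prevalence tables.

Only hourly clock intervals are considered (1:00-1:59, never 1:30-2:29),
matching how the nonwear rule's hourly allowance is audited.  An A-type
pattern is a clock hour classified entirely nonwear yet carrying at least T
pre-classification counts; a B-type pattern is a clock hour classified
entirely wear carrying between 1 and T counts.  Mixed hours qualify as
neither.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import (
    MINUTES_PER_DAY,
    MINUTES_PER_HOUR,
    CountSeries,
    WearLabels,
    _aligned_hour_starts,
)

__all__ = [
    "HourSummary",
    "summarize_hours",
    "detect_a_type",
    "detect_b_type",
    "prevalence_table",
    "DEFAULT_A_THRESHOLDS",
    "DEFAULT_B_THRESHOLDS",
]

#: A-type prevalence is surveyed for T from 10 to 500 counts/hour.
DEFAULT_A_THRESHOLDS: tuple[int, ...] = tuple(range(10, 501, 10))
#: B-type prevalence is surveyed for T from 1 to 60 counts/hour.
DEFAULT_B_THRESHOLDS: tuple[int, ...] = tuple(range(1, 61))


@dataclass(frozen=True)
class HourSummary:
    """Counts and classification status of one complete clock hour."""

    participant_id: str
    day_index: int
    hour_index: int
    start_minute: int
    total_counts: int
    all_nonwear: bool
    all_wear: bool


def summarize_hours(series: CountSeries, labels: WearLabels) -> list[HourSummary]:
    """One summary per complete clock hour; partial edge hours are omitted."""
    if labels.n_minutes != series.n_minutes:
        raise ValueError("labels not aligned to series")
    out: list[HourSummary] = []
    for h in _aligned_hour_starts(series):
        block = slice(h, h + MINUTES_PER_HOUR)
        w = labels.wear[block]
        clock_minute = series.start_offset_minutes + h
        out.append(
            HourSummary(
                participant_id=series.participant_id,
                day_index=clock_minute // MINUTES_PER_DAY,
                hour_index=(clock_minute // MINUTES_PER_HOUR) % 24,
                start_minute=h,
                total_counts=int(series.counts[block].sum()),
                all_nonwear=not bool(w.any()),
                all_wear=bool(w.all()),
            )
        )
    return out


def _check_threshold(threshold: int) -> int:
    t = int(threshold)
    if t < 1:
        raise ValueError("pattern detection requires threshold >= 1")
    return t


def detect_a_type(
    summaries: Iterable[HourSummary], threshold: int
) -> list[HourSummary]:
    """Hours classified entirely nonwear with >= ``threshold`` counts."""
    t = _check_threshold(threshold)
    return [s for s in summaries if s.all_nonwear and s.total_counts >= t]


def detect_b_type(
    summaries: Iterable[HourSummary], threshold: int
) -> list[HourSummary]:
    """Hours classified entirely wear with between 1 and ``threshold`` counts."""
    t = _check_threshold(threshold)
    return [s for s in summaries if s.all_wear and 1 <= s.total_counts <= t]


def prevalence_table(
    summaries_by_participant: Mapping[str, Sequence[HourSummary]],
    a_thresholds: Sequence[int] = DEFAULT_A_THRESHOLDS,
    b_thresholds: Sequence[int] = DEFAULT_B_THRESHOLDS,
) -> pd.DataFrame:
    """Number and percent of participants with >= 1 qualifying hour, per T.

    A participant is counted once per threshold regardless of how many
    qualifying hours they have; the percent denominator is the full cohort
    passed in.  Returns a tidy frame with columns ``pattern`` ("A"/"B"),
    ``threshold``, ``n_participants`` and ``percent``.
    """
    if not summaries_by_participant:
        raise ValueError("empty cohort")
    n_total = len(summaries_by_participant)
    # Per participant: the largest fully-nonwear hour total determines A-type
    # membership at every T at once; the smallest positive fully-wear hour
    # total does the same for B-type.
    max_nonwear: list[int] = []
    min_wear_pos: list[int] = []
    for summaries in summaries_by_participant.values():
        nw = [s.total_counts for s in summaries if s.all_nonwear]
        wp = [s.total_counts for s in summaries if s.all_wear and s.total_counts >= 1]
        max_nonwear.append(max(nw) if nw else -1)
        min_wear_pos.append(min(wp) if wp else np.iinfo(np.int64).max)
    max_nonwear_arr = np.asarray(max_nonwear)
    min_wear_arr = np.asarray(min_wear_pos)

    rows = []
    for t in a_thresholds:
        t = _check_threshold(t)
        n = int((max_nonwear_arr >= t).sum())
        rows.append(("A", t, n, 100.0 * n / n_total))
    for t in b_thresholds:
        t = _check_threshold(t)
        n = int((min_wear_arr <= t).sum())
        rows.append(("B", t, n, 100.0 * n / n_total))
    return pd.DataFrame(
        rows, columns=["pattern", "threshold", "n_participants", "percent"]
    )
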