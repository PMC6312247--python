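"""Valid-day summaries and the nonwear-threshold sensitivity sweep.

A *valid day* is a midnight-to-midnight calendar day with at least 10 hours
(600 minutes) of classified wear.  Participant-level counts-per-minute (CPM)
is the pooled ratio over valid days: total counts during wear divided by
total wear minutes.  Minutes at or above the 2,020 counts/min cut-point — the
adult moderate-to-vigorous activity boundary — are averaged over valid days.

The sensitivity sweep re-runs only the hourly reclassification (never bout
detection) for each threshold T, tallying cohort size, mean CPM and mean
cut-point minutes in the >=1 and >=4 valid-day strata, with absolute and
percent differences from the no-reclassification baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .classifier import (
    MINUTES_PER_DAY,
    ClassifierParams,
    CountSeries,
    ReclassParams,
    WearLabels,
    classify_wear,
    reclassify_nonwear,
)

__all__ = [
    "AnalysisParams",
    "DayMetrics",
    "ParticipantMetrics",
    "ExclusionFlags",
    "StratumSummary",
    "SensitivityRow",
    "ScenarioSummary",
    "DEFAULT_T_SWEEP",
    "day_metrics",
    "participant_metrics",
    "apply_exclusions",
    "sensitivity_table",
    "summarize_scenario",
]

#: Reclassification thresholds surveyed by default (plus the baseline row).
DEFAULT_T_SWEEP: tuple[int, ...] = (
    500, 400, 350, 300, 250, 200, 150, 100, 90, 80,
    75, 70, 60, 50, 25, 10, 5, 3, 1, 0,
)


@dataclass(frozen=True)
class AnalysisParams:
    """Valid-day and activity cut-point settings."""

    min_wear_minutes_per_valid_day: int = 600
    valid_day_thresholds: tuple[int, ...] = (1, 4)
    mvpa_cutpoint: int = 2020
    t_sweep: tuple[int, ...] = DEFAULT_T_SWEEP

    def __post_init__(self) -> None:
        if not 0 < self.min_wear_minutes_per_valid_day <= MINUTES_PER_DAY:
            raise ValueError("min_wear_minutes_per_valid_day must be in (0, 1440]")
        if self.mvpa_cutpoint < 0:
            raise ValueError("mvpa_cutpoint must be >= 0")
        if any(k < 1 for k in self.valid_day_thresholds):
            raise ValueError("valid-day thresholds must be >= 1")
        if any(t < 0 for t in self.t_sweep):
            raise ValueError("reclassification thresholds must be >= 0")


@dataclass(frozen=True)
class DayMetrics:
    """Wear tallies for one complete calendar day."""

    participant_id: str
    day_index: int
    wear_minutes: int
    counts_during_wear: int
    minutes_at_or_above_cutpoint: int
    valid: bool


@dataclass(frozen=True)
class ParticipantMetrics:
    """Pooled summaries over a participant's valid days."""

    participant_id: str
    n_valid_days: int
    cpm: float
    mean_mvpa_minutes: float


@dataclass(frozen=True)
class ExclusionFlags:
    """Inclusion decision for one participant (>=24 h recorded, calibrated)."""

    participant_id: str
    recorded_minutes: int
    calibration_ok: bool

    @property
    def included(self) -> bool:
        return self.recorded_minutes >= MINUTES_PER_DAY and self.calibration_ok


@dataclass(frozen=True)
class StratumSummary:
    """Cohort summary for one valid-day stratum (>= k valid days)."""

    k_valid: int
    n_participants: int
    mean_cpm: float
    mean_mvpa_minutes: float
    n_diff: int = 0
    n_pct_diff: float = 0.0
    cpm_diff: float = 0.0
    cpm_pct_diff: float = 0.0
    mvpa_diff: float = 0.0
    mvpa_pct_diff: float = 0.0


@dataclass(frozen=True)
class SensitivityRow:
    """One row of the threshold sweep; ``threshold`` is None for the baseline."""

    threshold: int | None
    strata: tuple[StratumSummary, ...]

    def stratum(self, k_valid: int) -> StratumSummary:
        for s in self.strata:
            if s.k_valid == k_valid:
                return s
        raise KeyError(f"no stratum for k_valid={k_valid}")


def day_metrics(
    series: CountSeries, labels: WearLabels, params: AnalysisParams | None = None
) -> list[DayMetrics]:
    """Score every complete midnight-aligned 1,440-minute day.

    Partial first/last calendar days are not scored.  Counts are summed over
    wear minutes only; cut-point minutes are wear minutes with counts at or
    above the cut-point (inclusive).
    """
    p = params or AnalysisParams()
    if labels.n_minutes != series.n_minutes:
        raise ValueError("labels not aligned to series")
    first = (-series.start_offset_minutes) % MINUTES_PER_DAY
    out: list[DayMetrics] = []
    for d0 in range(first, series.n_minutes - MINUTES_PER_DAY + 1, MINUTES_PER_DAY):
        block = slice(d0, d0 + MINUTES_PER_DAY)
        w = labels.wear[block]
        c = series.counts[block]
        wear_minutes = int(w.sum())
        out.append(
            DayMetrics(
                participant_id=series.participant_id,
                day_index=(series.start_offset_minutes + d0) // MINUTES_PER_DAY,
                wear_minutes=wear_minutes,
                counts_during_wear=int(c[w].sum()),
                minutes_at_or_above_cutpoint=int((w & (c >= p.mvpa_cutpoint)).sum()),
                valid=wear_minutes >= p.min_wear_minutes_per_valid_day,
            )
        )
    return out


def participant_metrics(
    days: Sequence[DayMetrics], k_valid: int
) -> ParticipantMetrics | None:
    """Pooled participant summary, or None if fewer than ``k_valid`` valid days.

    CPM is the pooled ratio (total wear counts / total wear minutes over
    valid days), not a mean of daily ratios; cut-point minutes are averaged
    over valid days.
    """
    if k_valid < 1:
        raise ValueError("k_valid must be >= 1")
    valid = [d for d in days if d.valid]
    if len(valid) < k_valid:
        return None
    wear_minutes = sum(d.wear_minutes for d in valid)
    counts = sum(d.counts_during_wear for d in valid)
    mvpa = [d.minutes_at_or_above_cutpoint for d in valid]
    return ParticipantMetrics(
        participant_id=valid[0].participant_id,
        n_valid_days=len(valid),
        cpm=counts / wear_minutes,
        mean_mvpa_minutes=float(np.mean(mvpa)),
    )


def apply_exclusions(
    cohort: Iterable[CountSeries],
) -> tuple[list[CountSeries], list[ExclusionFlags]]:
    """Drop participants with under 24 h recorded or failed calibration."""
    kept: list[CountSeries] = []
    flags: list[ExclusionFlags] = []
    for series in cohort:
        f = ExclusionFlags(
            participant_id=series.participant_id,
            recorded_minutes=series.n_minutes,
            calibration_ok=series.calibration_ok,
        )
        flags.append(f)
        if f.included:
            kept.append(series)
    return kept, flags


def _stratum_summary(
    per_participant: Sequence[ParticipantMetrics | None],
    k_valid: int,
    baseline: StratumSummary | None,
) -> StratumSummary:
    included = [m for m in per_participant if m is not None]
    n = len(included)
    cpm = float(np.mean([m.cpm for m in included])) if n else float("nan")
    mvpa = float(np.mean([m.mean_mvpa_minutes for m in included])) if n else float("nan")
    if baseline is None:
        return StratumSummary(k_valid, n, cpm, mvpa)

    def pct(delta: float, base: float) -> float:
        return 100.0 * delta / base if base else float("nan")

    return StratumSummary(
        k_valid=k_valid,
        n_participants=n,
        mean_cpm=cpm,
        mean_mvpa_minutes=mvpa,
        n_diff=n - baseline.n_participants,
        n_pct_diff=pct(n - baseline.n_participants, baseline.n_participants),
        cpm_diff=cpm - baseline.mean_cpm,
        cpm_pct_diff=pct(cpm - baseline.mean_cpm, baseline.mean_cpm),
        mvpa_diff=mvpa - baseline.mean_mvpa_minutes,
        mvpa_pct_diff=pct(mvpa - baseline.mean_mvpa_minutes, baseline.mean_mvpa_minutes),
    )


def sensitivity_table(
    cohort: Sequence[CountSeries],
    classifier_params: ClassifierParams | None = None,
    analysis_params: AnalysisParams | None = None,
) -> list[SensitivityRow]:
    """Baseline row plus one row per threshold in ``analysis_params.t_sweep``.

    Bout detection runs once per participant; each threshold row edits the
    baseline labels via hourly reclassification and re-tallies the day and
    participant metrics.  The cohort is assumed to have passed
    :func:`apply_exclusions`.
    """
    if not cohort:
        raise ValueError("empty cohort")
    cp = classifier_params or ClassifierParams()
    ap = analysis_params or AnalysisParams()
    base_labels = [classify_wear(s, cp) for s in cohort]

    def metrics_for(labels: Sequence[WearLabels], k: int) -> list[ParticipantMetrics | None]:
        return [
            participant_metrics(day_metrics(s, lab, ap), k)
            for s, lab in zip(cohort, labels)
        ]

    baseline_strata = tuple(
        _stratum_summary(metrics_for(base_labels, k), k, baseline=None)
        for k in ap.valid_day_thresholds
    )
    rows = [SensitivityRow(threshold=None, strata=baseline_strata)]
    for t in ap.t_sweep:
        relabeled = [
            reclassify_nonwear(s, lab, ReclassParams(t))
            for s, lab in zip(cohort, base_labels)
        ]
        strata = tuple(
            _stratum_summary(metrics_for(relabeled, k), k, baseline=base)
            for k, base in zip(ap.valid_day_thresholds, baseline_strata)
        )
        rows.append(SensitivityRow(threshold=int(t), strata=strata))
    return rows


@dataclass(frozen=True)
class ScenarioSummary:
    """Before/after classification tallies for a single scenario day."""

    participant_id: str
    total_minutes: int
    total_counts: int
    cpm_before: float
    wear_minutes: int
    wear_counts: int
    excluded_minutes: int
    excluded_counts: int

    @property
    def wear_percent(self) -> float:
        return 100.0 * self.wear_minutes / self.total_minutes

    @property
    def excluded_percent(self) -> float:
        return 100.0 * self.excluded_minutes / self.total_minutes


def summarize_scenario(series: CountSeries, labels: WearLabels) -> ScenarioSummary:
    """Tally total/wear/excluded minutes and counts for a classified series."""
    if labels.n_minutes != series.n_minutes:
        raise ValueError("labels not aligned to series")
    total_counts = series.total_counts()
    wear_counts = int(series.counts[labels.wear].sum())
    return ScenarioSummary(
        participant_id=series.participant_id,
        total_minutes=series.n_minutes,
        total_counts=total_counts,
        cpm_before=total_counts / series.n_minutes,
        wear_minutes=labels.wear_minutes,
        wear_counts=wear_counts,
        excluded_minutes=labels.nonwear_minutes,
        excluded_counts=total_counts - wear_counts,
    )
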