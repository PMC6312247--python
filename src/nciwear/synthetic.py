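"""Corner-case scenario construction and synthetic cohort simulation.

Two exact hour-long count patterns drive the corner-case audit of the NCI
nonwear rule:

* Pattern A — ``(0, 100, 100)`` repeated 20 times: 4,000 counts in an hour,
  every nonzero minute an admissible allowance minute, so a day of it is
  classified almost entirely nonwear.
* Pattern B — ``(1, 1, 1)`` followed by 57 zeros: 3 counts in an hour, but
  the three consecutive allowance minutes break every candidate bout below
  the 60-minute window, so a day of it is classified entirely wear.

Repeating a pattern for 24 hours from midnight yields Scenario A (96,000
counts, ~0.1% wear) and Scenario B (72 counts, 100% wear).

The cohort simulator emulates the structure the survey analysis assumes —
midnight-aligned multi-day minute series, a contiguous daytime wear period
per day, zero-dominated overnight nonwear with sparse low-count noise — and
plants A-type / B-type corner-case hours at known positions so that
detection can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .classifier import MINUTES_PER_DAY, MINUTES_PER_HOUR, CountSeries

__all__ = [
    "PATTERN_A",
    "PATTERN_B",
    "HourPatternSpec",
    "SyntheticConfig",
    "SimulatedParticipant",
    "build_pattern",
    "build_scenario",
    "simulate_cohort",
]

#: One minute of 0 counts followed by two minutes of 100 counts, twenty times.
PATTERN_A: tuple[int, ...] = (0, 100, 100) * 20
#: Three minutes of 1 count each, then 57 minutes of 0 counts.
PATTERN_B: tuple[int, ...] = (1, 1, 1) + (0,) * 57


@dataclass(frozen=True)
class HourPatternSpec:
    """An hour-long (60-minute) template of per-minute counts."""

    pattern_id: str
    minute_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.minute_counts) != MINUTES_PER_HOUR:
            raise ValueError("an hourly pattern must have exactly 60 minute counts")
        if any(int(c) < 0 for c in self.minute_counts):
            raise ValueError("pattern counts must be nonnegative")

    def total_counts(self) -> int:
        return int(sum(self.minute_counts))


def build_pattern(pattern_id: str) -> HourPatternSpec:
    """Return the named corner-case hourly pattern ("A" or "B")."""
    pid = str(pattern_id).upper()
    if pid == "A":
        return HourPatternSpec("A", PATTERN_A)
    if pid == "B":
        return HourPatternSpec("B", PATTERN_B)
    raise ValueError(f"unknown pattern id {pattern_id!r}; expected 'A' or 'B'")


def build_scenario(pattern: HourPatternSpec, hours: int = 24) -> CountSeries:
    """Concatenate an hourly pattern into a midnight-aligned scenario series."""
    if hours < 1:
        raise ValueError("hours must be >= 1")
    counts = np.tile(np.asarray(pattern.minute_counts, dtype=np.int64), hours)
    return CountSeries(
        participant_id=f"scenario-{pattern.pattern_id}",
        counts=counts,
        start_offset_minutes=0,
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions for the synthetic cohort.

    Each participant contributes ``n_days`` midnight-aligned 1,440-minute
    days.  Each day has one contiguous wear period from ``wear_start_hours``
    to ``wear_end_hours`` (clock hours drawn uniformly, inclusive bounds).
    Wear-minute counts come from a three-part mixture over the strata the
    nonwear rule distinguishes: zero, low (1-100, uniform), and high (>100,
    shifted exponential).  Nonwear minutes are zero apart from sparse
    isolated low-count noise.  ``a_type_rate`` / ``b_type_rate`` are the
    expected numbers of planted corner-case hours per participant (Poisson).
    """

    n_participants: int = 200
    n_days: int = 7
    seed: int = 0
    wear_start_hours: tuple[int, int] = (6, 9)
    wear_end_hours: tuple[int, int] = (20, 23)
    p_wear_zero: float = 0.10
    p_wear_low: float = 0.30
    high_count_scale: float = 500.0
    nonwear_noise_per_hour: float = 0.1
    a_type_rate: float = 0.5
    b_type_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_days < 1:
            raise ValueError("n_participants and n_days must be >= 1")
        for p in (self.p_wear_zero, self.p_wear_low):
            if not 0.0 <= p <= 1.0:
                raise ValueError("mixture probabilities must lie in [0, 1]")
        if self.p_wear_zero + self.p_wear_low > 1.0:
            raise ValueError("p_wear_zero + p_wear_low must be <= 1")
        for r in (self.nonwear_noise_per_hour, self.a_type_rate, self.b_type_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")
        ws_lo, ws_hi = self.wear_start_hours
        we_lo, we_hi = self.wear_end_hours
        if not (0 <= ws_lo <= ws_hi < we_lo <= we_hi <= 24):
            raise ValueError(
                "wear hour ranges must satisfy 0 <= start <= ... < end <= 24"
            )
        if self.high_count_scale <= 0:
            raise ValueError("high_count_scale must be > 0")


@dataclass(frozen=True)
class SimulatedParticipant:
    """A simulated count series plus the generator's ground truth.

    ``true_wear`` marks the minutes during which the (simulated) monitor was
    on the body.  Planted A-type hours are true-wear hours the classifier
    will call nonwear; planted B-type hours are true-nonwear hours it will
    call wear.  Both are recorded by their start minute index.
    """

    series: CountSeries
    true_wear: np.ndarray
    planted_a_hours: tuple[int, ...]
    planted_b_hours: tuple[int, ...]


def _simulate_participant(
    pid: str, cfg: SyntheticConfig, rng: np.random.Generator
) -> SimulatedParticipant:
    n = cfg.n_days * MINUTES_PER_DAY
    counts = np.zeros(n, dtype=np.int64)
    true_wear = np.zeros(n, dtype=bool)

    wear_starts = rng.integers(cfg.wear_start_hours[0], cfg.wear_start_hours[1] + 1,
                               size=cfg.n_days)
    wear_ends = rng.integers(cfg.wear_end_hours[0], cfg.wear_end_hours[1] + 1,
                             size=cfg.n_days)
    for d in range(cfg.n_days):
        day0 = d * MINUTES_PER_DAY
        true_wear[day0 + wear_starts[d] * 60 : day0 + wear_ends[d] * 60] = True

    # Wear counts: zero / low (1-100) / high (>100) mixture.
    widx = np.flatnonzero(true_wear)
    u = rng.random(widx.size)
    low = (u >= cfg.p_wear_zero) & (u < cfg.p_wear_zero + cfg.p_wear_low)
    high = u >= cfg.p_wear_zero + cfg.p_wear_low
    counts[widx[low]] = rng.integers(1, 101, size=int(low.sum()))
    counts[widx[high]] = 101 + np.floor(
        rng.exponential(cfg.high_count_scale, size=int(high.sum()))
    ).astype(np.int64)

    # Sparse low-count noise during nonwear.
    nidx = np.flatnonzero(~true_wear)
    noisy = rng.random(nidx.size) < cfg.nonwear_noise_per_hour / MINUTES_PER_HOUR
    counts[nidx[noisy]] = rng.integers(1, 101, size=int(noisy.sum()))

    # Plant B-type hours in the last nonwear clock hour before a day's wear
    # onset: the three leading allowance minutes break any bout arriving
    # from the night, and the wear period terminates the 57-zero tail below
    # the 60-minute window, so the hour is classified all-wear.
    eligible_b = [
        d * MINUTES_PER_DAY + (int(wear_starts[d]) - 1) * 60
        for d in range(cfg.n_days)
        if wear_starts[d] >= 1
    ]
    n_b = min(int(rng.poisson(cfg.b_type_rate)), len(eligible_b))
    planted_b = sorted(
        int(h) for h in rng.choice(eligible_b, size=n_b, replace=False)
    ) if n_b else []
    for h in planted_b:
        counts[h : h + MINUTES_PER_HOUR] = PATTERN_B

    # Plant A-type hours strictly inside nonwear spans: the hour and the
    # minute after it must be true nonwear, so the bout runs past the hour
    # boundary and the whole clock hour is classified nonwear.  Hours
    # directly preceding a planted B hour are excluded — the B hour's
    # leading allowance minutes would extend the A hour's trailing run and
    # break the bout before the hour's end.
    b_starts = set(planted_b)
    eligible_a = [
        h
        for h in range(0, n - MINUTES_PER_HOUR, MINUTES_PER_HOUR)
        if not true_wear[h : h + MINUTES_PER_HOUR + 1].any()
        and h not in b_starts
        and h + MINUTES_PER_HOUR not in b_starts
    ]
    n_a = min(int(rng.poisson(cfg.a_type_rate)), len(eligible_a))
    planted_a = sorted(
        int(h) for h in rng.choice(eligible_a, size=n_a, replace=False)
    ) if n_a else []
    for h in planted_a:
        counts[h : h + MINUTES_PER_HOUR] = PATTERN_A
        counts[h + MINUTES_PER_HOUR] = 0  # keep the bout running past the hour
        true_wear[h : h + MINUTES_PER_HOUR] = True

    series = CountSeries(participant_id=pid, counts=counts, start_offset_minutes=0)
    true_wear.setflags(write=False)
    return SimulatedParticipant(
        series=series,
        true_wear=true_wear,
        planted_a_hours=tuple(planted_a),
        planted_b_hours=tuple(planted_b),
    )


def simulate_cohort(config: SyntheticConfig) -> list[SimulatedParticipant]:
    """Simulate a cohort; fully reproducible for a fixed ``config.seed``.

    Per-participant random substreams are spawned deterministically from the
    single global seed, so the output for participant *i* does not depend on
    the number of participants requested after it.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_participants)
    width = len(str(config.n_participants))
    return [
        _simulate_participant(f"sim-{i:0{width}d}", config, np.random.default_rng(child))
        for i, child in enumerate(children)
    ]
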