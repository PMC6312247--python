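"""Rule-based wear/nonwear classification for minute-epoch accelerometer counts.

Implements the National Cancer Institute nonwear rule (NCINW) as applied to
uniaxial ActiGraph data integrated into 1-minute epochs: nonwear is an
interval of at least 60 consecutive minutes of zero activity counts, with an
allowance for up to 2 consecutive minutes of 1-100 counts; the interval is
terminated by any minute above 100 counts or by 3 consecutive minutes in the
1-100 band.  A nonwear bout begins and ends on zero-count minutes: allowance
minutes trailing the last zero belong to wear.

The module also provides the hourly reclassification used in threshold
sensitivity analyses (fully-nonwear clock hours carrying at least T counts
are re-designated wear), a brute-force interval-enumeration oracle used for
verification, and a search for the maximum count total a nonwear clock hour
can carry.

All operations here are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CountSeries",
    "ClassifierParams",
    "ReclassParams",
    "WearLabels",
    "classify_wear",
    "nonwear_oracle",
    "reclassify_nonwear",
    "max_nonwear_hour_counts",
]

MINUTES_PER_HOUR = 60
MINUTES_PER_DAY = 1440


def _as_count_array(counts: Sequence[int] | np.ndarray) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if arr.size == 0:
        raise ValueError("count series is empty")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if not np.all(np.mod(arr, 1) == 0):
            raise ValueError("counts must be integral (counts are integer-valued)")
    arr = arr.astype(np.int64)
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    return arr


@dataclass(frozen=True)
class CountSeries:
    """One participant's minute-epoch vertical-axis activity counts.

    Parameters
    ----------
    participant_id
        Opaque identifier, carried through all downstream tables.
    counts
        Nonnegative integer counts, one value per 1-minute epoch.
    start_offset_minutes
        Clock minute-of-day of the first epoch (0 = midnight). Clock hours
        and calendar days downstream are derived from this offset.
    calibration_ok
        Whether the device passed its post-study calibration check; used by
        the cohort exclusion filter.
    """

    participant_id: str
    counts: np.ndarray
    start_offset_minutes: int = 0
    calibration_ok: bool = True

    def __post_init__(self) -> None:
        arr = _as_count_array(self.counts)
        arr.setflags(write=False)
        object.__setattr__(self, "counts", arr)
        off = int(self.start_offset_minutes)
        if not 0 <= off < MINUTES_PER_DAY:
            raise ValueError(
                f"start_offset_minutes must be in [0, {MINUTES_PER_DAY - 1}], got {off}"
            )
        object.__setattr__(self, "start_offset_minutes", off)

    @property
    def n_minutes(self) -> int:
        return int(self.counts.size)

    def total_counts(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ClassifierParams:
    """Constants of the nonwear rule.

    Defaults reproduce the NCI algorithm: a >=60-minute window of zeros,
    tolerating at most 2 consecutive "allowance" minutes of 1-100 counts,
    terminated by any minute above 100 counts (strictly) or by a third
    consecutive allowance minute.
    """

    window_minutes: int = 60
    max_consecutive_allowance: int = 2
    allowance_min_counts: int = 1
    allowance_max_counts: int = 100
    terminate_above_counts: int = 100

    def __post_init__(self) -> None:
        if self.window_minutes < 1:
            raise ValueError("window_minutes must be >= 1")
        if not 0 <= self.max_consecutive_allowance < self.window_minutes:
            raise ValueError("max_consecutive_allowance must be in [0, window_minutes)")
        if not (
            self.allowance_min_counts
            <= self.allowance_max_counts
            <= self.terminate_above_counts
        ):
            raise ValueError(
                "require allowance_min_counts <= allowance_max_counts"
                " <= terminate_above_counts"
            )


@dataclass(frozen=True)
class ReclassParams:
    """Hourly reclassification threshold T (counts per clock hour).

    At T >= 1, every fully-nonwear clock hour whose pre-classification count
    total is >= T is re-designated wear.  T = 0 disables nonwear exclusion
    entirely: all minutes become wear.
    """

    threshold: int

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")


@dataclass(frozen=True)
class WearLabels:
    """Per-minute wear labels aligned to a :class:`CountSeries`.

    ``wear`` is a boolean vector (True = wear); ``bouts`` are the maximal
    nonwear runs as half-open ``(start, end)`` index pairs, sorted and
    disjoint — exactly the False-runs of ``wear``.
    """

    wear: np.ndarray
    bouts: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        arr = np.asarray(self.wear, dtype=bool)
        arr.setflags(write=False)
        object.__setattr__(self, "wear", arr)

    @classmethod
    def from_wear(cls, wear: np.ndarray) -> "WearLabels":
        """Build labels from a boolean vector, recomputing bouts as False-runs."""
        w = np.asarray(wear, dtype=bool)
        padded = np.concatenate(([True], w, [True]))
        edges = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(edges == -1)
        ends = np.flatnonzero(edges == 1)
        bouts = tuple((int(s), int(e)) for s, e in zip(starts, ends))
        return cls(wear=w, bouts=bouts)

    @property
    def n_minutes(self) -> int:
        return int(self.wear.size)

    @property
    def wear_minutes(self) -> int:
        return int(self.wear.sum())

    @property
    def nonwear_minutes(self) -> int:
        return self.n_minutes - self.wear_minutes


def classify_wear(
    series: CountSeries, params: ClassifierParams | None = None
) -> WearLabels:
    """Label each minute wear/nonwear under the NCI nonwear rule.

    A candidate nonwear bout starts at a zero-count minute and extends over
    subsequent minutes that are zero or allowance minutes (counts in
    ``[allowance_min_counts, allowance_max_counts]``), provided no more than
    ``max_consecutive_allowance`` allowance minutes occur in a row.  The
    candidate stops before any minute above ``terminate_above_counts`` and
    before the first minute of a too-long allowance run; it then ends at the
    last zero-count minute it reached (trailing allowance minutes are wear).
    Candidates shorter than ``window_minutes`` are discarded: their minutes
    stay wear.

    Nonzero counts below ``allowance_min_counts`` (impossible at the default
    of 1) are treated as terminators.
    """
    p = params or ClassifierParams()
    c = series.counts
    n = c.size
    wear = np.ones(n, dtype=bool)
    i = 0
    while i < n:
        if c[i] != 0:
            i += 1
            continue
        last_zero = i
        run = 0
        k = i
        while k < n:
            v = c[k]
            if v == 0:
                last_zero = k
                run = 0
            elif p.allowance_min_counts <= v <= p.allowance_max_counts:
                run += 1
                if run > p.max_consecutive_allowance:
                    break
            else:
                break
            k += 1
        end = last_zero + 1
        if end - i >= p.window_minutes:
            wear[i:end] = False
        # No zero between `last_zero` and the terminating minute can seed a
        # new candidate, so resuming at `end` loses nothing.
        i = end
    return WearLabels.from_wear(wear)


def nonwear_oracle(
    series: CountSeries,
    params: ClassifierParams | None = None,
    max_minutes: int = 2000,
) -> WearLabels:
    """Brute-force reference classifier: enumerate valid intervals, take their union.

    For every start index ``i`` with a zero count, every end index ``j`` is
    examined; ``[i, j+1)`` is a valid nonwear interval when it ends on a zero,
    contains no minute above the termination threshold, contains no run of
    more than ``max_consecutive_allowance`` allowance minutes, and spans at
    least ``window_minutes``.  The union of all valid intervals is nonwear.

    Quadratic in series length; intended as an independent test oracle, hence
    the ``max_minutes`` cap.
    """
    p = params or ClassifierParams()
    c = series.counts
    n = c.size
    if n > max_minutes:
        raise ValueError(f"oracle capped at {max_minutes} minutes, got {n}")
    nonwear = np.zeros(n, dtype=bool)
    for i in range(n):
        if c[i] != 0:
            continue
        run = 0
        furthest_valid_end = -1
        for j in range(i, n):
            v = int(c[j])
            if v == 0:
                run = 0
                if j + 1 - i >= p.window_minutes:
                    furthest_valid_end = j + 1
            elif p.allowance_min_counts <= v <= p.allowance_max_counts:
                run += 1
                if run > p.max_consecutive_allowance:
                    break
            else:
                break
        if furthest_valid_end > 0:
            nonwear[i:furthest_valid_end] = True
    return WearLabels.from_wear(~nonwear)


def _aligned_hour_starts(series: CountSeries) -> range:
    """Start indices of complete clock hours (60-minute blocks on the hour)."""
    first = (-series.start_offset_minutes) % MINUTES_PER_HOUR
    return range(first, series.n_minutes - MINUTES_PER_HOUR + 1, MINUTES_PER_HOUR)


def reclassify_nonwear(
    series: CountSeries, labels: WearLabels, params: ReclassParams
) -> WearLabels:
    """Re-designate high-count fully-nonwear clock hours as wear.

    For ``threshold >= 1``, every complete clock hour whose 60 minutes are
    all labelled nonwear and whose pre-classification count total is at least
    the threshold has all 60 minutes relabelled wear.  ``threshold == 0``
    relabels every nonwear minute wear (no nonwear exclusion at all).

    Bouts of the result are recomputed from the edited labels with no
    minimum-length constraint; bout detection itself is not re-run.
    """
    if labels.n_minutes != series.n_minutes:
        raise ValueError(
            f"labels ({labels.n_minutes} min) not aligned to series"
            f" ({series.n_minutes} min)"
        )
    wear = np.array(labels.wear, dtype=bool)
    if params.threshold == 0:
        wear[:] = True
        return WearLabels.from_wear(wear)
    for h in _aligned_hour_starts(series):
        block = slice(h, h + MINUTES_PER_HOUR)
        if not wear[block].any() and int(series.counts[block].sum()) >= params.threshold:
            wear[block] = True
    return WearLabels.from_wear(wear)


def max_nonwear_hour_counts(
    params: ClassifierParams | None = None, hour_minutes: int = MINUTES_PER_HOUR
) -> int:
    """Maximum count total a clock hour lying wholly inside a nonwear bout can carry.

    Searches over admissible minute patterns by dynamic programming: each
    minute is either zero or a nonzero allowance minute, and no run of more
    than ``max_consecutive_allowance`` nonzero minutes may occur.  The sum is
    maximised by setting every nonzero minute to ``allowance_max_counts``
    (any admissible pattern with smaller values is dominated).  Runs touching
    the hour boundary are admissible because the hour can always be embedded
    in a longer bout padded with zero-count minutes on both sides, which
    also satisfies the minimum bout length.

    At the default parameters the optimum is the repeating (0, 100, 100)
    pattern: 40 allowance minutes of 100 counts.
    """
    p = params or ClassifierParams()
    cap = p.allowance_max_counts
    max_run = p.max_consecutive_allowance
    neg = -1  # unreachable marker
    # dp[r] = best sum so far with a trailing run of r consecutive nonzero minutes
    dp = [neg] * (max_run + 1)
    dp[0] = 0
    for _ in range(hour_minutes):
        nxt = [neg] * (max_run + 1)
        nxt[0] = max(dp)  # a zero-count minute resets the run
        for r in range(max_run):
            if dp[r] >= 0:
                cand = dp[r] + cap
                if cand > nxt[r + 1]:
                    nxt[r + 1] = cand
        dp = nxt
    return max(dp)
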