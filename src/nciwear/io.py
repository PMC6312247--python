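"""Reading and writing count tables, reports and configuration.

The canonical exchange format is a plain delimited per-minute table with one
row per participant-minute and columns::

    participant_id, day_index, minute_of_day, counts, calibration_ok

``minute_of_day`` is 0-based (0 = midnight); minutes must be contiguous per
participant.  An optional NHANES SAS-transport (XPT) dialect reads the
PAXRAW-style per-minute layout (SEQN / PAXSTAT / PAXCAL / PAXN / PAXINTEN),
mapping the device status and calibration flags into the exclusion filter.

Report writers render the sensitivity sweep (counts as integers, CPM to one
decimal, minutes and percents to two decimals) and the prevalence table as
delimited text with a deterministic column order.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .classifier import MINUTES_PER_DAY, ClassifierParams, CountSeries, WearLabels
from .metrics import AnalysisParams, ExclusionFlags, SensitivityRow
from .synthetic import SimulatedParticipant, SyntheticConfig

__all__ = [
    "COUNT_TABLE_COLUMNS",
    "read_count_table",
    "write_count_table",
    "write_labels",
    "sensitivity_frame",
    "write_report",
    "load_config",
    "format_hhmm",
]

COUNT_TABLE_COLUMNS = (
    "participant_id",
    "day_index",
    "minute_of_day",
    "counts",
    "calibration_ok",
)


def format_hhmm(minutes: int) -> str:
    """Render a duration in whole minutes as HH:MM (24 h -> ``24:00``)."""
    if minutes < 0:
        raise ValueError("duration must be >= 0")
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


def write_count_table(
    cohort: Iterable[CountSeries | SimulatedParticipant],
    path: str | Path,
    sep: str = ",",
) -> None:
    """Serialize a cohort to the canonical per-minute delimited table."""
    frames = []
    for item in cohort:
        series = item.series if isinstance(item, SimulatedParticipant) else item
        absolute = series.start_offset_minutes + np.arange(series.n_minutes)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": series.participant_id,
                    "day_index": absolute // MINUTES_PER_DAY,
                    "minute_of_day": absolute % MINUTES_PER_DAY,
                    "counts": series.counts,
                    "calibration_ok": int(series.calibration_ok),
                }
            )
        )
    if not frames:
        raise ValueError("empty cohort")
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def _series_from_group(pid: str, group: pd.DataFrame) -> CountSeries:
    absolute = (
        group["day_index"].to_numpy(np.int64) * MINUTES_PER_DAY
        + group["minute_of_day"].to_numpy(np.int64)
    )
    gaps = np.flatnonzero(np.diff(absolute) != 1)
    if gaps.size:
        pos = int(gaps[0])
        raise ValueError(
            f"participant {pid!r}: non-contiguous minutes at row {pos + 1}"
            f" (minute {int(absolute[pos])} followed by {int(absolute[pos + 1])})"
        )
    calib = group["calibration_ok"].to_numpy()
    return CountSeries(
        participant_id=str(pid),
        counts=group["counts"].to_numpy(np.int64),
        start_offset_minutes=int(absolute[0] % MINUTES_PER_DAY),
        calibration_ok=bool(np.all(calib.astype(bool))),
    )


def _read_plain(path: str | Path, sep: str) -> list[CountSeries]:
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in COUNT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    return [
        _series_from_group(pid, g) for pid, g in df.groupby("participant_id", sort=False)
    ]


def _read_nhanes_xpt(path: str | Path) -> list[CountSeries]:
    # PAXRAW-style layout: SEQN participant id, PAXN 1-based sequential
    # minute from midnight of day 1, PAXINTEN vertical-axis counts,
    # PAXSTAT data-reliability flag and PAXCAL calibration flag (1 = good).
    df = pd.read_sas(path, format="xport")
    df.columns = [c.upper() for c in df.columns]
    required = ["SEQN", "PAXN", "PAXINTEN"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"XPT file missing PAXRAW variables: {missing}")
    out: list[CountSeries] = []
    for seqn, g in df.groupby("SEQN", sort=True):
        g = g.sort_values("PAXN")
        seq = g["PAXN"].to_numpy(np.int64)
        if np.any(np.diff(seq) != 1):
            raise ValueError(f"participant {seqn}: non-contiguous PAXN sequence")
        calibrated = True
        for flag in ("PAXCAL", "PAXSTAT"):
            if flag in g.columns:
                calibrated = calibrated and bool((g[flag].to_numpy() == 1).all())
        counts = np.clip(g["PAXINTEN"].to_numpy(np.float64), 0, None).astype(np.int64)
        out.append(
            CountSeries(
                participant_id=str(int(seqn)),
                counts=counts,
                start_offset_minutes=int((seq[0] - 1) % MINUTES_PER_DAY),
                calibration_ok=calibrated,
            )
        )
    return out


def read_count_table(
    path: str | Path, dialect: str = "plain", sep: str = ","
) -> tuple[list[CountSeries], list[ExclusionFlags]]:
    """Read a cohort plus per-participant exclusion flags.

    ``dialect`` is ``"plain"`` (delimited per-minute table) or
    ``"nhanes-xpt"`` (SAS transport, PAXRAW variable layout).
    """
    if dialect == "plain":
        cohort = _read_plain(path, sep)
    elif dialect == "nhanes-xpt":
        cohort = _read_nhanes_xpt(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    flags = [
        ExclusionFlags(s.participant_id, s.n_minutes, s.calibration_ok) for s in cohort
    ]
    return cohort, flags


def write_labels(
    cohort: Sequence[CountSeries],
    labels: Sequence[WearLabels],
    path: str | Path,
    sep: str = ",",
) -> None:
    """Write per-minute wear labels (1 = wear) alongside the raw counts."""
    frames = []
    for series, lab in zip(cohort, labels):
        absolute = series.start_offset_minutes + np.arange(series.n_minutes)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": series.participant_id,
                    "day_index": absolute // MINUTES_PER_DAY,
                    "minute_of_day": absolute % MINUTES_PER_DAY,
                    "counts": series.counts,
                    "wear": lab.wear.astype(int),
                }
            )
        )
    if not frames:
        raise ValueError("empty cohort")
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def sensitivity_frame(rows: Sequence[SensitivityRow]) -> pd.DataFrame:
    """Flatten sensitivity rows into a wide table, one column group per stratum.

    Numbers are formatted to the report precision: participant counts as
    integers, CPM to one decimal, minutes and percent differences to two
    decimals.
    """
    if not rows:
        raise ValueError("no sensitivity rows")
    records = []
    for row in rows:
        label = "default" if row.threshold is None else f"T>={row.threshold}"
        rec: dict[str, object] = {"criteria": label}
        for s in row.strata:
            k = f"k{s.k_valid}"
            rec[f"{k}_n"] = s.n_participants
            rec[f"{k}_cpm"] = f"{s.mean_cpm:.1f}"
            rec[f"{k}_mvpa_min"] = f"{s.mean_mvpa_minutes:.2f}"
            rec[f"{k}_n_diff"] = s.n_diff
            rec[f"{k}_n_pct_diff"] = f"{s.n_pct_diff:.2f}"
            rec[f"{k}_cpm_diff"] = f"{s.cpm_diff:.1f}"
            rec[f"{k}_cpm_pct_diff"] = f"{s.cpm_pct_diff:.2f}"
            rec[f"{k}_mvpa_diff"] = f"{s.mvpa_diff:.2f}"
            rec[f"{k}_mvpa_pct_diff"] = f"{s.mvpa_pct_diff:.2f}"
        records.append(rec)
    return pd.DataFrame.from_records(records)


def write_report(frame: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a report frame as delimited text with a stable column order."""
    if frame.empty:
        raise ValueError("refusing to write an empty report")
    frame.to_csv(path, sep=sep, index=False)


def load_config(path: str | Path) -> dict[str, object]:
    """Load a YAML key/value config into parameter objects.

    Recognised top-level sections: ``classifier``, ``analysis``,
    ``synthetic``; each maps field names of the corresponding parameter
    dataclass to values.  Missing sections fall back to the defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping of sections")

    def build(cls, section):
        values = raw.get(section, {}) or {}
        if not isinstance(values, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        values = {
            k: tuple(v) if isinstance(v, list) else v for k, v in values.items()
        }
        return cls(**values)

    return {
        "classifier": build(ClassifierParams, "classifier"),
        "analysis": build(AnalysisParams, "analysis"),
        "synthetic": build(SyntheticConfig, "synthetic"),
    }
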