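"""Actigraphy preprocessing: epoch aggregation and valid-day quality control.

Wrist-accelerometer recordings arrive as vector-magnitude (milli-g) epoch
series, typically at 5-s or 1-min resolution.  Analysis operates on 1-min
series restricted to *valid* days: calendar days with a complete set of
1,440 minute slots and less than 4 hours of imputed data.  Participants
with fewer than 3 valid days are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440
IMPUTED_HOURS_LIMIT = 4.0
DEFAULT_MIN_VALID_DAYS = 3


class AlignmentError(ValueError):
    """Epoch series does not start on a minute boundary."""


@dataclass
class EpochSeries:
    """One participant's timestamped activity series with an imputation mask.

    Attributes
    ----------
    participant_id : str
    start : pd.Timestamp
        Timestamp of the first epoch.
    epoch_seconds : int
        Epoch duration; must divide 60 or equal 60.
    values : np.ndarray
        Vector-magnitude activity in milli-g; nonnegative, finite.
    imputed : np.ndarray
        Boolean mask, True where the value was imputed upstream.
    """

    participant_id: str
    start: pd.Timestamp
    epoch_seconds: int
    values: np.ndarray
    imputed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.values = np.asarray(self.values, dtype=float)
        if self.imputed is None:
            self.imputed = np.zeros(self.values.shape, dtype=bool)
        self.imputed = np.asarray(self.imputed, dtype=bool)
        if self.values.shape != self.imputed.shape:
            raise ValueError("values and imputed must have equal length")
        if not (60 % self.epoch_seconds == 0):
            raise ValueError(f"epoch_seconds must divide 60, got {self.epoch_seconds}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activity values must be finite")
        if np.any(self.values < 0):
            raise ValueError("activity values must be nonnegative")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(
            np.arange(len(self.values)) * self.epoch_seconds, unit="s"
        )

    def minute_of_day(self) -> np.ndarray:
        """Minute-of-day index (0..1439) for each epoch; requires 1-min epochs."""
        if self.epoch_seconds != 60:
            raise ValueError("minute_of_day requires a 1-min series")
        start_min = self.start.hour * 60 + self.start.minute
        return (start_min + np.arange(len(self.values))) % MINUTES_PER_DAY

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "value_mg": self.values,
                "imputed": self.imputed.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, participant_id: str | None = None) -> "EpochSeries":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        if len(df) < 2:
            raise ValueError("epoch file must contain at least two rows")
        step = int((df["timestamp"].iloc[1] - df["timestamp"].iloc[0]).total_seconds())
        pid = participant_id if participant_id is not None else str(path)
        return cls(
            participant_id=pid,
            start=df["timestamp"].iloc[0],
            epoch_seconds=step,
            values=df["value_mg"].to_numpy(),
            imputed=df["imputed"].to_numpy().astype(bool),
        )


@dataclass
class DayQC:
    """Quality-control record for one calendar day of a 1-min series."""

    calendar_day: date
    complete: bool
    imputed_hours: float

    @property
    def valid(self) -> bool:
        return self.complete and self.imputed_hours < IMPUTED_HOURS_LIMIT


def aggregate_to_minutes(series: EpochSeries) -> EpochSeries:
    """Aggregate a sub-minute epoch series to a 1-min series.

    Each minute is the arithmetic mean of its constituent epochs and is
    flagged imputed if any constituent epoch was imputed.  Idempotent on
    1-min input.  The series must start on a minute boundary.
    """
    if series.epoch_seconds == 60:
        return series
    if series.start.second != 0 or series.start.microsecond != 0:
        raise AlignmentError(
            f"series start {series.start} is not aligned to a minute boundary"
        )
    per_min = 60 // series.epoch_seconds
    n = len(series.values)
    n_minutes = -(-n // per_min)  # ceil
    padded = np.full(n_minutes * per_min, np.nan)
    padded[:n] = series.values
    pad_imp = np.zeros(n_minutes * per_min, dtype=bool)
    pad_imp[:n] = series.imputed
    with np.errstate(invalid="ignore"):
        minute_values = np.nanmean(padded.reshape(n_minutes, per_min), axis=1)
    minute_imputed = pad_imp.reshape(n_minutes, per_min).any(axis=1)
    return EpochSeries(
        participant_id=series.participant_id,
        start=series.start,
        epoch_seconds=60,
        values=minute_values,
        imputed=minute_imputed,
    )


def day_qc(series: EpochSeries) -> list[DayQC]:
    """Per-calendar-day QC of a 1-min series.

    A day is *complete* when all 1,440 minute slots are present;
    imputed_hours counts imputed minutes / 60.  Validity combines both:
    complete and < 4 h imputed.
    """
    if series.epoch_seconds != 60:
        raise ValueError("day_qc requires a 1-min series")
    ts = series.timestamps
    days = ts.normalize()
    out: list[DayQC] = []
    for day, idx in pd.Series(np.arange(len(ts)), index=days).groupby(level=0):
        sel = idx.to_numpy()
        n_minutes = len(sel)
        imputed_minutes = int(series.imputed[sel].sum())
        out.append(
            DayQC(
                calendar_day=day.date(),
                complete=(n_minutes == MINUTES_PER_DAY),
                imputed_hours=imputed_minutes / 60.0,
            )
        )
    return out


def valid_day_mask(series: EpochSeries) -> np.ndarray:
    """Boolean mask over minutes belonging to valid days."""
    qc = day_qc(series)
    valid_days = {rec.calendar_day for rec in qc if rec.valid}
    days = series.timestamps.normalize()
    return np.array([d.date() in valid_days for d in days])


def filter_participants(
    qc_by_participant: dict[str, list[DayQC]],
    min_valid_days: int = DEFAULT_MIN_VALID_DAYS,
) -> pd.DataFrame:
    """Inclusion decisions from per-participant day QC.

    A participant is included iff at least ``min_valid_days`` days are valid.
    Returns a frame with participant_id, valid_days, included and reason.
    """
    if min_valid_days < 1:
        raise ValueError("min_valid_days must be >= 1")
    rows = []
    for pid, qcs in qc_by_participant.items():
        n_valid = sum(rec.valid for rec in qcs)
        included = n_valid >= min_valid_days
        rows.append(
            {
                "participant_id": pid,
                "valid_days": n_valid,
                "included": included,
                "reason": "" if included else f"fewer than {min_valid_days} valid days",
            }
        )
    return pd.DataFrame(rows).sort_values("participant_id").reset_index(drop=True)
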