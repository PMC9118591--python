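"""Accelerometer count processing: from per-minute traces to a 24-h composition.

Subjects wear a hip accelerometer for 7 consecutive days; the device records
activity counts per minute (CPM).  The processing chain implemented here:

1. non-wear detection — runs of zero counts spanning at least 60 min, allowing
   up to two brief interruption episodes (each 1–2 consecutive minutes below
   100 CPM);
2. sleep estimation — per night, the longest non-wear gap that starts in the
   evening window and ends in the morning window is counted as sleep (removal
   at night until refit in the morning) and excluded from daytime non-wear;
3. intensity classification of worn minutes — sedentary < 100 CPM, light
   100–2295 CPM, moderate-to-vigorous >= 2296 CPM;
4. day validity (>= 10 h wear) and subject validity (>= 4 valid days, at least
   one of them a weekend day);
5. weekly weighting (5/7 weekday, 2/7 weekend group means) and closure of the
   four behaviour durations to a 1440-min day.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import Composition, DEFAULT_PARTS, closure, zero_replace

__all__ = [
    "SB_CUTOFF_CPM",
    "MVPA_CUTOFF_CPM",
    "MIN_WEAR_MINUTES",
    "MIN_VALID_DAYS",
    "EpochSeries",
    "WearMask",
    "DaySummary",
    "BehaviourDurations",
    "detect_nonwear",
    "classify_intensity",
    "classify_counts",
    "estimate_sleep",
    "summarize_days",
    "subject_valid",
    "weekly_weighted_means",
    "to_composition",
    "process_subject",
    "process_epoch_table",
]

SB_CUTOFF_CPM = 100       # below: sedentary
MVPA_CUTOFF_CPM = 2296    # at or above: MVPA; between: light activity
MIN_WEAR_MINUTES = 600    # >= 10 h wear for a valid day
MIN_VALID_DAYS = 4

# Sleep search windows (minutes since midnight): the overnight gap must start
# between 18:00 and 03:00 (next day) and end between 03:00 and 12:00.
EVENING_START_MIN = 18 * 60
MORNING_START_MIN = 3 * 60
MORNING_END_MIN = 12 * 60


@dataclass
class EpochSeries:
    """Per-minute count trace for one subject."""

    subject_id: str
    timestamps: pd.DatetimeIndex
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.counts = np.asarray(self.counts)
        if len(self.timestamps) != len(self.counts):
            raise ValueError("timestamps and counts length mismatch")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        diffs = np.diff(self.timestamps.asi8)
        if np.any(diffs <= 0):
            raise ValueError("timestamps must be strictly increasing")
        same_day = self.timestamps.normalize()[:-1] == self.timestamps.normalize()[1:]
        if np.any(diffs[np.asarray(same_day)] != 60_000_000_000):
            raise ValueError("epochs must be 60 s apart within a day")

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class WearMask:
    """Boolean worn/not-worn mask plus the detected non-wear intervals."""

    worn: np.ndarray
    intervals: list[tuple[int, int]] = field(default_factory=list)
    """Half-open epoch-index intervals [start, stop) of non-wear."""


@dataclass
class DaySummary:
    date: dt.date
    wear_minutes: int
    sleep_minutes: float | None
    sb_minutes: int
    lpa_minutes: int
    mvpa_minutes: int
    is_weekend: bool
    is_valid: bool


@dataclass
class BehaviourDurations:
    """Weekly-weighted behaviour minutes, before and after closure."""

    subject_id: str
    weighted_minutes: dict[str, float]
    composition: Composition


def detect_nonwear(series: EpochSeries, window_min: int = 60,
                   allowance_max_run: int = 2,
                   allowance_cpm: int = SB_CUTOFF_CPM,
                   max_allowances: int = 2) -> WearMask:
    """Flag non-wear: >= ``window_min`` minutes of zeros with small allowances.

    A candidate window starts and ends on zero-count epochs and may contain at
    most ``max_allowances`` interruption episodes, each of at most
    ``allowance_max_run`` consecutive minutes with counts below
    ``allowance_cpm``.  Any minute at or above ``allowance_cpm``, or a longer
    interruption, terminates the window.
    """
    c = np.asarray(series.counts)
    n = len(c)
    worn = np.ones(n, dtype=bool)
    intervals: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if c[i] != 0:
            i += 1
            continue
        # scan a candidate window starting at this zero epoch
        k = i
        end = i  # last index (exclusive) of the trailing zero run committed
        episodes = 0
        first_break = None  # where to resume scanning if the window fails
        while k < n:
            if c[k] == 0:
                k += 1
                end = k
                continue
            if first_break is None:
                first_break = k
            # interruption run
            m = k
            while m < n and c[m] != 0 and (m - k) < allowance_max_run \
                    and c[m] < allowance_cpm:
                m += 1
            run_ok = (m > k and (m - k) <= allowance_max_run
                      and (m == n or c[m] == 0))
            if not run_ok or episodes >= max_allowances:
                break
            episodes += 1
            k = m
        if end - i >= window_min:
            worn[i:end] = False
            intervals.append((i, end))
            i = end
        else:
            # window too short: any start inside its leading zero run yields a
            # subset window, so resume at the first interruption (or stop if
            # the zeros ran to the end of the series)
            i = first_break if first_break is not None else n
    return WearMask(worn=worn, intervals=intervals)


def classify_intensity(cpm: int) -> str:
    """Classify one CPM value as 'SB', 'LPA' or 'MVPA'."""
    if cpm < 0:
        raise ValueError("counts per minute must be non-negative")
    if cpm < SB_CUTOFF_CPM:
        return "SB"
    if cpm < MVPA_CUTOFF_CPM:
        return "LPA"
    return "MVPA"


def classify_counts(counts: np.ndarray) -> np.ndarray:
    """Vectorized intensity classes: 0 = SB, 1 = LPA, 2 = MVPA."""
    c = np.asarray(counts)
    if np.any(c < 0):
        raise ValueError("counts per minute must be non-negative")
    return np.where(c < SB_CUTOFF_CPM, 0, np.where(c < MVPA_CUTOFF_CPM, 1, 2))


def _minute_of_day(ts: pd.Timestamp) -> int:
    return ts.hour * 60 + ts.minute


def estimate_sleep(series: EpochSeries, mask: WearMask
                   ) -> tuple[dict[dt.date, int], np.ndarray]:
    """Identify the overnight removal gap per night.

    For each night, among non-wear intervals starting between 18:00 and 03:00
    and ending (device refit) between 03:00 and 12:00 the following morning,
    the longest is credited as that night's sleep (ties: earliest start).
    Returns ``(sleep_minutes_by_start_date, sleep_epoch_mask)``; the sleep
    epochs are excluded from daytime non-wear by the caller.
    """
    ts = series.timestamps
    candidates: dict[dt.date, list[tuple[int, int, int]]] = {}
    for (a, b) in mask.intervals:
        start = ts[a]
        # refit = first epoch after the gap; if the series ends inside the
        # gap there is no refit and the gap cannot be scored as sleep
        if b >= len(ts):
            continue
        refit = ts[b]
        smin = _minute_of_day(start)
        if smin >= EVENING_START_MIN:
            night = start.date()
        elif smin < MORNING_START_MIN:
            night = (start - pd.Timedelta(days=1)).date()
        else:
            continue
        rmin = _minute_of_day(refit)
        if refit.date() != night + dt.timedelta(days=1):
            continue
        if not (MORNING_START_MIN <= rmin <= MORNING_END_MIN):
            continue
        candidates.setdefault(night, []).append((b - a, a, b))
    sleep_by_night: dict[dt.date, int] = {}
    sleep_mask = np.zeros(len(series), dtype=bool)
    for night, cands in candidates.items():
        # longest gap wins; ties broken by earliest start
        cands.sort(key=lambda t: (-t[0], t[1]))
        length, a, b = cands[0]
        sleep_by_night[night] = length
        sleep_mask[a:b] = True
    return sleep_by_night, sleep_mask


def summarize_days(series: EpochSeries, mask: WearMask,
                   sleep_by_night: dict[dt.date, int],
                   sleep_mask: np.ndarray) -> list[DaySummary]:
    """Per-calendar-day wear and intensity tallies.

    Sleep minutes are credited to the night's *starting* day; sleep epochs are
    excluded from both wear and daytime non-wear.
    """
    dates = series.timestamps.normalize()
    counts = np.asarray(series.counts)
    worn = mask.worn & ~sleep_mask
    out: list[DaySummary] = []
    for day in pd.unique(dates):
        sel = np.asarray(dates == day)
        day_counts = counts[sel & worn]
        classes = classify_counts(day_counts)
        wear = int((sel & worn).sum())
        d = pd.Timestamp(day).date()
        out.append(DaySummary(
            date=d,
            wear_minutes=wear,
            sleep_minutes=sleep_by_night.get(d),
            sb_minutes=int((classes == 0).sum()),
            lpa_minutes=int((classes == 1).sum()),
            mvpa_minutes=int((classes == 2).sum()),
            is_weekend=pd.Timestamp(day).weekday() >= 5,
            is_valid=wear >= MIN_WEAR_MINUTES,
        ))
    return out


def impute_missing_sleep(days: list[DaySummary]) -> list[DaySummary]:
    """Fill missing per-day sleep with the subject's mean over other days.

    Days with no overnight gap and no other day to borrow from are dropped.
    """
    known = [d.sleep_minutes for d in days if d.sleep_minutes is not None]
    if not known:
        return [d for d in days if d.sleep_minutes is not None]
    mean_sleep = float(np.mean(known))
    out = []
    for d in days:
        if d.sleep_minutes is None:
            d = DaySummary(**{**d.__dict__, "sleep_minutes": mean_sleep})
        out.append(d)
    return out


def subject_valid(days: list[DaySummary]) -> bool:
    """>= 4 valid days including at least one valid weekend day."""
    valid = [d for d in days if d.is_valid]
    return (len(valid) >= MIN_VALID_DAYS
            and any(d.is_weekend for d in valid))


def weekly_weighted_means(days: list[DaySummary]) -> dict[str, float]:
    """(5 * weekday mean + 2 * weekend mean) / 7 over valid days."""
    valid = [d for d in days if d.is_valid]
    weekday = [d for d in valid if not d.is_weekend]
    weekend = [d for d in valid if d.is_weekend]
    if not weekend:
        raise ValueError("no valid weekend day; subject should be excluded")
    if not weekday:
        raise ValueError("no valid weekday; subject should be excluded")

    def wmean(attr: str) -> float:
        wd = float(np.mean([getattr(d, attr) for d in weekday]))
        we = float(np.mean([getattr(d, attr) for d in weekend]))
        return (5.0 * wd + 2.0 * we) / 7.0

    return {
        "sleep": wmean("sleep_minutes"),
        "SB": wmean("sb_minutes"),
        "LPA": wmean("lpa_minutes"),
        "MVPA": wmean("mvpa_minutes"),
    }


def to_composition(subject_id: str, weighted: dict[str, float],
                   floor: float = 1.0) -> BehaviourDurations:
    """Zero-replace then close weekly behaviour minutes to a 1440-min day."""
    raw = np.array([weighted[p] for p in DEFAULT_PARTS], dtype=float)
    comp = closure(zero_replace(raw, floor=floor), total=1440.0,
                   parts=DEFAULT_PARTS)
    return BehaviourDurations(subject_id=subject_id, weighted_minutes=weighted,
                              composition=comp)


def process_subject(series: EpochSeries) -> dict:
    """Run the full chain for one subject.

    Returns a flat record with the weekly-weighted minutes, closed composition
    (or NaNs when the subject fails the validity rules), the number of valid
    days and the validity flag.
    """
    mask = detect_nonwear(series)
    sleep_by_night, sleep_mask = estimate_sleep(series, mask)
    days = summarize_days(series, mask, sleep_by_night, sleep_mask)
    days = impute_missing_sleep(days)
    valid = subject_valid(days)
    rec: dict = {
        "subject_id": series.subject_id,
        "n_valid_days": sum(d.is_valid for d in days),
        "valid": valid,
    }
    if valid:
        weighted = weekly_weighted_means(days)
        durations = to_composition(series.subject_id, weighted)
        for part, v in zip(DEFAULT_PARTS, durations.composition.values):
            rec[f"{part.lower()}_min"] = v
    else:
        for part in DEFAULT_PARTS:
            rec[f"{part.lower()}_min"] = np.nan
    return rec


def process_epoch_table(epochs: pd.DataFrame) -> pd.DataFrame:
    """Process a long epoch table (subject_id, timestamp, cpm) into the
    per-subject behaviour table."""
    records = []
    for sid, grp in epochs.groupby("subject_id", sort=True):
        series = EpochSeries(subject_id=str(sid),
                             timestamps=pd.DatetimeIndex(grp["timestamp"]),
                             counts=grp["cpm"].to_numpy())
        records.append(process_subject(series))
    return pd.DataFrame.from_records(records)
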