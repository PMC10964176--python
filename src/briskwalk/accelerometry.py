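"""Event-level accelerometer processing for the brisk-walking outcome.

A thigh-worn activity monitor yields an ordered sequence of bouts — sedentary
(sitting/lying), standing, or stepping with a step count.  This module turns
one participant-week of such events into the trial's activity outcomes:

1. sleep/wake delineation: long sedentary blocks seed "sleep" (time in bed);
   candidate waking periods between sleep blocks are kept awake only if they
   contain at least 200 steps, so bathroom trips stay within the sleep block.
   An optional participant log sheet corrects gross (> 1 h) mis-labellings.
2. valid-day filtering: a day counts only when the device was worn the full
   24 h, and a participant is included only with >= 3 valid days.
3. cadence epoching: steps are laid onto 60-s epochs aligned to midnight
   (bouts spanning an epoch boundary are apportioned pro rata at the bout's
   constant within-bout cadence); a waking epoch with more than 100 steps is
   a minute of brisk walking.
4. daily and weekly summaries: brisk and any-pace walking minutes, posture
   hours, and the person-level minutes/week outcome (mean valid day x 7).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ActivityEventSeries",
    "AccelConfig",
    "DailySummary",
    "WeeklyOutcome",
    "delineate_sleep_wake",
    "validate_days",
    "minute_cadence",
    "daily_summary",
    "weekly_outcome",
    "group_summary",
    "read_events_csv",
    "write_events_csv",
]

ACTIVITY_CLASSES = ("sedentary", "standing", "stepping")
SECONDS_PER_DAY = 86_400


@dataclass
class ActivityEventSeries:
    """Ordered, non-overlapping activity bouts for one participant.

    ``events`` columns: ``start`` (naive local Timestamp), ``duration_s``
    (seconds, > 0), ``activity_class`` in {sedentary, standing, stepping},
    ``steps`` (0 unless stepping).  After :func:`delineate_sleep_wake` an
    ``awake`` boolean column is present.
    """

    participant_id: str
    events: pd.DataFrame

    def __post_init__(self) -> None:
        ev = self.events
        required = {"start", "duration_s", "activity_class", "steps"}
        missing = required - set(ev.columns)
        if missing:
            raise ValueError(f"events missing columns {sorted(missing)}")
        if len(ev) == 0:
            return
        if not ev["activity_class"].isin(ACTIVITY_CLASSES).all():
            raise ValueError("unknown activity class present")
        if (ev["duration_s"] <= 0).any():
            raise ValueError("event durations must be positive")
        if ((ev["steps"] != 0) & (ev["activity_class"] != "stepping")).any():
            raise ValueError("non-stepping events must have zero steps")
        if (ev["steps"] < 0).any():
            raise ValueError("steps must be non-negative")
        starts = ev["start"].to_numpy()
        ends = starts + pd.to_timedelta(ev["duration_s"], unit="s").to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise ValueError("events must be time-sorted and non-overlapping")

    @property
    def start_s(self) -> np.ndarray:
        """Event starts in seconds from the series' base midnight."""
        base = self.events["start"].iloc[0].normalize()
        return (
            (self.events["start"] - base).dt.total_seconds().to_numpy()
        )

    @property
    def base_midnight(self) -> pd.Timestamp:
        return self.events["start"].iloc[0].normalize()


@dataclass(frozen=True)
class AccelConfig:
    """Processing thresholds.

    brisk_cadence_threshold: steps/min above which a minute is brisk (strict).
    min_waking_steps: steps a candidate waking period needs to stay "awake".
    min_valid_days: valid days needed for a participant to be included.
    valid_day_coverage: seconds of wear defining a valid day (full 24 h).
    epoch_length: cadence epoch in seconds.
    sleep_block_min_s: minimum sedentary run that seeds a sleep block.
    log_correction_s: algorithm/log discrepancy beyond which the log wins.
    """

    brisk_cadence_threshold: float = 100.0
    min_waking_steps: int = 200
    min_valid_days: int = 3
    valid_day_coverage: float = float(SECONDS_PER_DAY)
    epoch_length: float = 60.0
    sleep_block_min_s: float = 3 * 3600.0
    log_correction_s: float = 3600.0

    def __post_init__(self) -> None:
        for name in (
            "brisk_cadence_threshold",
            "min_waking_steps",
            "min_valid_days",
            "valid_day_coverage",
            "epoch_length",
            "sleep_block_min_s",
            "log_correction_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


# ---------------------------------------------------------------------------
# sleep/wake delineation


def _contiguous_runs(starts: np.ndarray, ends: np.ndarray, mask: np.ndarray):
    """Maximal runs of consecutive masked events with no time gap between."""
    runs = []
    i, n = 0, len(mask)
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and mask[j + 1] and math.isclose(ends[j], starts[j + 1], abs_tol=1e-6):
            j += 1
        runs.append((i, j))
        i = j + 1
    return runs


def delineate_sleep_wake(
    series: ActivityEventSeries,
    log_sheet: pd.DataFrame | None = None,
    config: AccelConfig = AccelConfig(),
) -> ActivityEventSeries:
    """Label every event sleep or wake; returns a new series with ``awake``.

    Sleep cores are maximal contiguous sedentary runs of at least
    ``sleep_block_min_s``.  Each core is then grown outward over adjacent
    non-standing events for as long as the steps accumulated since leaving
    the core stay below ``min_waking_steps``: a candidate waking period needs
    at least that many steps to count as wake, so brief night-time bed exits
    (bathroom trips) are absorbed into the surrounding sleep block, while a
    genuine morning of activity ends the block.  Standing always ends a
    block (standing means out of bed).

    If a log sheet (columns ``date``, ``wake_time``, ``bed_time`` as HH:MM)
    is supplied, each day's algorithmic wake/bed transition is compared with
    the logged one and corrected to the logged clock time whenever they
    disagree by more than ``log_correction_s`` (events are split at the
    logged boundary as needed); when the algorithm finds no transition on a
    logged day the logged time is applied directly.
    """
    ev = series.events.reset_index(drop=True)
    starts = series.start_s
    ends = starts + ev["duration_s"].to_numpy()
    sed = (ev["activity_class"] == "sedentary").to_numpy()
    standing = (ev["activity_class"] == "standing").to_numpy()
    steps = ev["steps"].to_numpy()
    n = len(ev)

    awake = np.ones(n, dtype=bool)
    cores = [
        (i, j)
        for i, j in _contiguous_runs(starts, ends, sed)
        if ends[j] - starts[i] >= config.sleep_block_min_s
    ]
    for i, j in cores:
        awake[i : j + 1] = False

    for i, j in cores:
        # grow left then right; each direction has its own step budget
        for step_dir, edge in ((-1, i), (+1, j)):
            k, acc = edge + step_dir, 0.0
            while 0 <= k < n and not standing[k] and awake[k]:
                adjacent = (
                    math.isclose(ends[k], starts[k + 1], abs_tol=1e-6)
                    if step_dir < 0
                    else math.isclose(ends[k - 1], starts[k], abs_tol=1e-6)
                )
                if not adjacent:
                    break
                acc += steps[k]
                if acc >= config.min_waking_steps:
                    break
                awake[k] = False
                k += step_dir

    out = ev.copy()
    out["awake"] = awake
    labelled = ActivityEventSeries(series.participant_id, out)
    if log_sheet is not None:
        labelled = _apply_log_corrections(labelled, log_sheet, config)
    return labelled


def _split_events_at(ev: pd.DataFrame, t: pd.Timestamp) -> pd.DataFrame:
    """Split any event straddling clock time ``t`` into two pieces."""
    start = ev["start"]
    end = start + pd.to_timedelta(ev["duration_s"], unit="s")
    hit = (start < t) & (end > t)
    if not hit.any():
        return ev
    pieces = []
    for idx, row in ev.iterrows():
        if not hit.loc[idx]:
            pieces.append(row)
            continue
        left = row.copy()
        right = row.copy()
        left_dur = (t - row["start"]).total_seconds()
        frac = left_dur / row["duration_s"]
        left["duration_s"] = left_dur
        left["steps"] = row["steps"] * frac
        right["start"] = t
        right["duration_s"] = row["duration_s"] - left_dur
        right["steps"] = row["steps"] * (1 - frac)
        pieces.extend([left, right])
    return pd.DataFrame(pieces).reset_index(drop=True)


def _apply_log_corrections(
    series: ActivityEventSeries, log_sheet: pd.DataFrame, config: AccelConfig
) -> ActivityEventSeries:
    ev = series.events
    for _, log in log_sheet.iterrows():
        day = pd.Timestamp(log["date"])
        for kind in ("wake_time", "bed_time"):
            if pd.isna(log.get(kind)):
                continue
            t_log = day + _parse_clock(log[kind])
            t_algo = _transition_time(ev, day, kind)
            if t_algo is None:
                # no transition found that day: the log wins outright
                ev = _split_events_at(ev, t_log)
                start = ev["start"]
                if kind == "wake_time":
                    inside = (start >= day) & (start < t_log)
                else:
                    inside = (start >= t_log) & (start < day + pd.Timedelta(days=1))
                ev.loc[inside, "awake"] = False
                continue
            if abs((t_algo - t_log).total_seconds()) <= config.log_correction_s:
                continue
            ev = _split_events_at(ev, t_log)
            start = ev["start"]
            lo, hi = min(t_log, t_algo), max(t_log, t_algo)
            inside = (start >= lo) & (start < hi)
            if kind == "wake_time":
                # log earlier than algo -> those events are wake; later -> sleep
                ev.loc[inside, "awake"] = t_log < t_algo
            else:
                ev.loc[inside, "awake"] = t_log > t_algo
    return ActivityEventSeries(series.participant_id, ev.reset_index(drop=True))


def _parse_clock(hhmm: str) -> pd.Timedelta:
    h, m = str(hhmm).split(":")
    return pd.Timedelta(hours=int(h), minutes=int(m))


def _transition_time(ev: pd.DataFrame, day: pd.Timestamp, kind: str):
    """Algorithmic sleep->wake (wake_time) or wake->sleep (bed_time) boundary
    nearest to the given day."""
    start = ev["start"]
    end = start + pd.to_timedelta(ev["duration_s"], unit="s")
    awake = ev["awake"].to_numpy()
    flips = np.flatnonzero(awake[1:] != awake[:-1])
    times = []
    for f in flips:
        t = end.iloc[f]
        rising = not awake[f] and awake[f + 1]
        if kind == "wake_time" and rising and t.normalize() == day:
            times.append(t)
        if kind == "bed_time" and not rising and t.normalize() == day:
            times.append(t)
    if not times:
        return None
    target = day + (pd.Timedelta(hours=7) if kind == "wake_time" else pd.Timedelta(hours=22))
    return min(times, key=lambda t: abs((t - target).total_seconds()))


# ---------------------------------------------------------------------------
# valid days


def day_coverage(series: ActivityEventSeries) -> pd.Series:
    """Seconds of wear per calendar date (events split across midnight)."""
    ev = series.events
    cover: dict[pd.Timestamp, float] = {}
    for start, dur in zip(ev["start"], ev["duration_s"]):
        t, remaining = start, float(dur)
        while remaining > 1e-9:
            day = t.normalize()
            until_midnight = (day + pd.Timedelta(days=1) - t).total_seconds()
            chunk = min(remaining, until_midnight)
            cover[day] = cover.get(day, 0.0) + chunk
            t = t + pd.Timedelta(seconds=chunk)
            remaining -= chunk
    return pd.Series(cover).sort_index()


def validate_days(
    series: ActivityEventSeries, config: AccelConfig = AccelConfig()
) -> tuple[pd.Series, bool]:
    """Per-day validity flags and the participant-level inclusion decision.

    A day is valid only with full coverage (``valid_day_coverage`` seconds of
    wear); the participant is included only with at least ``min_valid_days``
    valid days.
    """
    cover = day_coverage(series)
    valid = (cover - config.valid_day_coverage).abs() < 1e-6
    return valid, bool(valid.sum() >= config.min_valid_days)


# ---------------------------------------------------------------------------
# cadence epochs


def minute_cadence(
    series: ActivityEventSeries, config: AccelConfig = AccelConfig()
) -> pd.DataFrame:
    """Per-epoch step counts aligned to midnight.

    Steps of a bout spanning an epoch boundary are apportioned pro rata by
    time, i.e. at the bout's constant within-bout cadence.  Returns one row
    per epoch overlapping any event: ``epoch_start``, ``steps``, ``awake``
    (true when more than half the epoch's worn time is wake), ``date``.
    """
    ev = series.events
    if "awake" not in ev.columns:
        raise ValueError("series must be labelled by delineate_sleep_wake first")
    base = series.base_midnight
    starts = series.start_s
    durs = ev["duration_s"].to_numpy(dtype=float)
    ends = starts + durs
    L = config.epoch_length

    first = int(np.floor(starts.min() / L))
    last = int(np.ceil(ends.max() / L))
    n = last - first
    steps = np.zeros(n)
    wake_s = np.zeros(n)
    worn_s = np.zeros(n)

    stepping = ev["steps"].to_numpy(dtype=float)
    awake = ev["awake"].to_numpy(dtype=bool)
    for s, e, st, aw in zip(starts, ends, stepping, awake):
        i0 = int(np.floor(s / L)) - first
        i1 = int(np.ceil(e / L)) - first
        idx = np.arange(i0, i1)
        lo = np.maximum(s, (idx + first) * L)
        hi = np.minimum(e, (idx + first + 1) * L)
        overlap = np.maximum(hi - lo, 0.0)
        worn_s[idx] += overlap
        if aw:
            wake_s[idx] += overlap
        if st:
            steps[idx] += st * overlap / (e - s)

    epoch_start = base + pd.to_timedelta((np.arange(n) + first) * L, unit="s")
    covered = worn_s > 0
    return pd.DataFrame(
        {
            "epoch_start": epoch_start[covered],
            "steps": steps[covered],
            "awake": wake_s[covered] > 0.5 * worn_s[covered],
            "date": epoch_start[covered].normalize(),
        }
    )


# ---------------------------------------------------------------------------
# daily and weekly summaries


@dataclass(frozen=True)
class DailySummary:
    date: pd.Timestamp
    brisk_minutes: float
    total_walking_minutes: float
    sitting_hours: float
    standing_hours: float
    stepping_hours: float
    sleep_hours: float
    valid: bool


def daily_summary(
    series: ActivityEventSeries, config: AccelConfig = AccelConfig()
) -> pd.DataFrame:
    """Per-day activity summary from a labelled series.

    brisk_minutes counts waking epochs whose cadence exceeds the brisk
    threshold; total_walking_minutes counts waking epochs with at least one
    step.  Posture hours come from event durations (sitting/standing split
    over waking time; sleep is all time labelled asleep).
    """
    epochs = minute_cadence(series, config)
    per_epoch_threshold = config.brisk_cadence_threshold * config.epoch_length / 60.0
    valid, _ = validate_days(series, config)

    ev = series.events.copy()
    ev["end"] = ev["start"] + pd.to_timedelta(ev["duration_s"], unit="s")

    rows = []
    for date, grp in epochs.groupby("date"):
        wk = grp[grp["awake"]]
        brisk = float((wk["steps"] > per_epoch_threshold).sum()) * config.epoch_length / 60.0
        walk = float((wk["steps"] >= 1.0).sum()) * config.epoch_length / 60.0
        day_hours = _posture_hours(ev, date)
        rows.append(
            {
                "date": date,
                "brisk_minutes": brisk,
                "total_walking_minutes": walk,
                "sitting_hours": day_hours["sitting"],
                "standing_hours": day_hours["standing"],
                "stepping_hours": day_hours["stepping"],
                "sleep_hours": day_hours["sleep"],
                "valid": bool(valid.get(date, False)),
            }
        )
    return pd.DataFrame(rows)


def _posture_hours(ev: pd.DataFrame, date: pd.Timestamp) -> dict[str, float]:
    day_start = date
    day_end = date + pd.Timedelta(days=1)
    lo = ev["start"].clip(lower=day_start)
    hi = ev["end"].clip(upper=day_end)
    overlap = (hi - lo).dt.total_seconds().clip(lower=0.0)
    out = {"sitting": 0.0, "standing": 0.0, "stepping": 0.0, "sleep": 0.0}
    sleep_mask = ~ev["awake"]
    out["sleep"] = float(overlap[sleep_mask].sum()) / 3600.0
    for cls, key in (("sedentary", "sitting"), ("standing", "standing"), ("stepping", "stepping")):
        mask = ev["awake"] & (ev["activity_class"] == cls)
        out[key] = float(overlap[mask].sum()) / 3600.0
    return out


@dataclass(frozen=True)
class WeeklyOutcome:
    """Person-level weekly walking outcome (mean valid day x 7)."""

    participant_id: str
    brisk_min_per_week: float | None
    walking_min_per_week: float | None
    n_valid_days: int
    included: bool


def weekly_outcome(
    summaries: pd.DataFrame,
    participant_id: str = "",
    config: AccelConfig = AccelConfig(),
) -> WeeklyOutcome:
    """Weekly brisk and any-pace walking minutes from daily summaries.

    Only valid days contribute; the weekly figure is the mean valid-day
    value scaled to 7 days, which is robust to unequal valid-day counts.
    Participants below the valid-day minimum are flagged excluded.
    """
    valid = summaries[summaries["valid"]]
    n = len(valid)
    if n < config.min_valid_days:
        return WeeklyOutcome(participant_id, None, None, n, False)
    return WeeklyOutcome(
        participant_id,
        float(valid["brisk_minutes"].mean() * 7),
        float(valid["total_walking_minutes"].mean() * 7),
        n,
        True,
    )


def group_summary(outcomes: pd.DataFrame, value_col: str = "brisk_min_per_week") -> pd.DataFrame:
    """Median (IQR) of a person-level outcome per arm.

    ``outcomes`` needs an ``arm`` column and the value column; rows with a
    missing value (excluded participants) are dropped first.
    """
    df = outcomes.dropna(subset=[value_col])
    if df.empty or df.groupby("arm").size().min() < 1:
        raise ValueError("each arm needs at least one included participant")
    rows = []
    for arm, grp in df.groupby("arm"):
        v = grp[value_col].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append({"arm": arm, "n": len(v), "median": med, "q1": q1, "q3": q3})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# events CSV dialect


def write_events_csv(series_list: list[ActivityEventSeries], path) -> None:
    """Write events as ``participant_id,start_iso8601,duration_s,activity_class,steps``."""
    frames = []
    for s in series_list:
        df = s.events[["start", "duration_s", "activity_class", "steps"]].copy()
        df.insert(0, "participant_id", s.participant_id)
        df["start"] = df["start"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        frames.append(df.rename(columns={"start": "start_iso8601"}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_events_csv(path) -> list[ActivityEventSeries]:
    df = pd.read_csv(path)
    df["start"] = pd.to_datetime(df["start_iso8601"])
    out = []
    for pid, grp in df.groupby("participant_id", sort=False):
        ev = grp[["start", "duration_s", "activity_class", "steps"]].reset_index(drop=True)
        out.append(ActivityEventSeries(str(pid), ev))
    return out
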