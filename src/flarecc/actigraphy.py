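"""Epoch-level accelerometer streams -> daily objective exposures.

Activity counts arrive in 30-second epochs with sleep/wake labels already
scored upstream.  Counts per minute (cpm) are formed by summing the two
epochs of each clock minute; minutes are classified sedentary (<= 178.50
cpm), moderate-to-vigorous (>= 562.50 cpm) or low (in between).  Per day the
module reports time in bed (hours), sleep efficiency (% of in-bed time
asleep) and sedentary time (% of waking minutes), the three exposures merged
into the daily diary.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: published MotionWatch-style cut points, in counts per minute
SEDENTARY_CPM = 178.50
MVPA_CPM = 562.50

EPOCH_SECONDS = 30


@dataclass(frozen=True)
class ActigraphyDaySummary:
    participant_id: object
    date: dt.date
    time_in_bed_h: float  # NaN when no in-bed interval found
    sleep_efficiency_pct: float
    sedentary_pct: float
    low_minutes: float
    mvpa_minutes: float


def classify_activity(counts_per_minute: float) -> str:
    """Classify one waking minute: 'sedentary' | 'low' | 'mvpa'.

    Boundary values belong to the outer categories (<= 178.50 is sedentary,
    >= 562.50 is moderate-to-vigorous).
    """
    if counts_per_minute < 0:
        raise ValueError("counts per minute cannot be negative")
    if counts_per_minute <= SEDENTARY_CPM:
        return "sedentary"
    if counts_per_minute >= MVPA_CPM:
        return "mvpa"
    return "low"


def _per_minute(stream: pd.DataFrame) -> pd.DataFrame:
    """Aggregate 30-s epochs to clock minutes (cpm = sum of the pair)."""
    df = stream.copy()
    df["minute"] = pd.to_datetime(df["timestamp"]).dt.floor("min")
    return df.groupby("minute", as_index=False).agg(
        cpm=("counts", "sum"), n_epochs=("counts", "size")
    )


def summarize_day(stream: pd.DataFrame, date: dt.date) -> ActigraphyDaySummary:
    """Daily objective exposures from one participant-day's epoch stream.

    The in-bed interval runs from the first to the last sleep-labelled epoch
    of the day's stream (sleep scoring happens upstream); sleep efficiency is
    the sleep-labelled share of that interval.  Waking minutes are clock
    minutes wholly outside the in-bed interval; sedentary time is their
    sedentary-classified share.  Fields that cannot be computed (no sleep
    labels, no waking minutes) come back NaN and are logged.
    """
    df = stream.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if df.empty:
        raise ValueError("empty epoch stream")
    if (df["counts"] < 0).any():
        raise ValueError("negative activity counts")
    pid = df["participant_id"].iloc[0]

    sleep = df.loc[df["state"] == "sleep", "timestamp"]
    if sleep.empty:
        logger.warning("%s %s: no sleep-labelled epochs; sleep metrics absent", pid, date)
        tib_h = eff = np.nan
        bed_start = bed_end = None
    else:
        bed_start = sleep.min()
        bed_end = sleep.max() + pd.Timedelta(seconds=EPOCH_SECONDS)
        tib_s = (bed_end - bed_start).total_seconds()
        in_bed = df[(df["timestamp"] >= bed_start) & (df["timestamp"] < bed_end)]
        sleep_s = float((in_bed["state"] == "sleep").sum()) * EPOCH_SECONDS
        tib_h = tib_s / 3600.0
        eff = 100.0 * sleep_s / tib_s

    if bed_start is None:
        waking = df
    else:
        waking = df[(df["timestamp"] < bed_start) | (df["timestamp"] >= bed_end)]
    waking = waking[waking["state"] == "wake"]
    if waking.empty:
        logger.warning("%s %s: no waking epochs; sedentary metric absent", pid, date)
        return ActigraphyDaySummary(pid, date, tib_h, eff, np.nan, np.nan, np.nan)

    minutes = _per_minute(waking)
    cats = minutes["cpm"].map(classify_activity)
    n = len(minutes)
    sed = float((cats == "sedentary").sum())
    low = float((cats == "low").sum())
    mvpa = float((cats == "mvpa").sum())
    return ActigraphyDaySummary(
        pid, date, tib_h, eff, 100.0 * sed / n, low, mvpa
    )


def read_epoch_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"participant_id", "timestamp", "counts", "state"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"epoch CSV missing columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def summarize_epochs(epochs: pd.DataFrame) -> pd.DataFrame:
    """Per participant-day summaries for a multi-day, multi-participant
    epoch table, ready to merge into the daily wide diary."""
    epochs = epochs.copy()
    epochs["timestamp"] = pd.to_datetime(epochs["timestamp"])
    epochs["date"] = epochs["timestamp"].dt.date
    rows = []
    for (pid, date), grp in epochs.groupby(["participant_id", "date"], sort=True):
        s = summarize_day(grp, date)
        rows.append(
            {
                "participant_id": pid,
                "date": date,
                "sleep_efficiency_pct": s.sleep_efficiency_pct,
                "sedentary_pct": s.sedentary_pct,
                "time_in_bed_h": s.time_in_bed_h,
            }
        )
    return pd.DataFrame(rows)


def merge_into_daily(daily: pd.DataFrame, day_summaries: pd.DataFrame) -> pd.DataFrame:
    """Overwrite the three objective exposures in the daily diary with
    actigraphy-derived values where available."""
    out = daily.merge(
        day_summaries, on=["participant_id", "date"], how="left", suffixes=("", "_acti")
    )
    for col in ["sleep_efficiency_pct", "sedentary_pct", "time_in_bed_h"]:
        acti = f"{col}_acti"
        if acti in out.columns:
            out[col] = out[acti].where(out[acti].notna(), out[col])
            out = out.drop(columns=[acti])
    return out
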