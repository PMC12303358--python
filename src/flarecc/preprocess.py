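"""Raw diary entries -> harmonized daily records -> included participant series.

The diary app records each item several times a day; the analysis keeps one
value per participant-day: the last record submitted strictly after 12:00
(noon) local time.  Ordinal items are harmonized so that higher always means
worse, and participants enter the analysis only if they logged pain on at
least 7 consecutive calendar days and on at least 70% of the study window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: the nine self-reported ordinal exposures (1-5, higher is worse after
#: harmonization)
ORDINAL_EXPOSURES = [
    "fatigue",
    "mood",
    "wellbeing",
    "anxiety",
    "disease_control",
    "challenge",
    "sleepiness",
    "concentration",
    "sleep_quality",
]

#: the three accelerometer-derived continuous exposures
CONTINUOUS_EXPOSURES = ["sleep_efficiency_pct", "sedentary_pct", "time_in_bed_h"]

#: all twelve exposures entering the case-crossover models
EXPOSURES = ORDINAL_EXPOSURES + CONTINUOUS_EXPOSURES

#: every item a raw entry may carry
KNOWN_ITEMS = ["pain", "impact"] + EXPOSURES

#: column order of the daily wide CSV
DAILY_COLUMNS = ["participant_id", "date", "pain", "impact"] + EXPOSURES


@dataclass
class ParticipantSeries:
    """One participant's date-ordered daily records with personal medians.

    ``records`` is a DataFrame with one row per observed day, a ``date``
    column of ``datetime.date`` values in strictly increasing order, and the
    pain / impact / exposure columns (NaN where absent).
    """

    participant_id: object
    records: pd.DataFrame
    pain_median: float = field(init=False)
    impact_median: float = field(init=False)
    observed_day_count: int = field(init=False)

    def __post_init__(self) -> None:
        dates = list(self.records["date"])
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("dates must be strictly increasing")
        self.observed_day_count = len(self.records)
        pain = self.records["pain"].dropna()
        self.pain_median = float(pain.median()) if len(pain) else float("nan")
        impact = self.records["impact"].dropna()
        self.impact_median = float(impact.median()) if len(impact) else float("nan")

    @property
    def observed_pain_days(self) -> int:
        return int(self.records["pain"].notna().sum())

    def value_on(self, column: str, date) -> float:
        """Value of ``column`` on ``date`` (NaN if the day is unobserved)."""
        row = self.records.loc[self.records["date"] == date, column]
        return float(row.iloc[0]) if len(row) else float("nan")


def select_daily_records(entries: pd.DataFrame) -> pd.DataFrame:
    """Collapse timestamped entries to one harmonized record per day.

    Only entries submitted strictly after 12:00 (the record's own local
    clock) are eligible; among those, the latest per (participant, date,
    item) wins, with ties broken by input order (last kept, warned).

    Parameters
    ----------
    entries : DataFrame with columns participant_id, timestamp, item, value.

    Returns
    -------
    Wide daily DataFrame with ``DAILY_COLUMNS``; items with no post-noon
    entry on a date are left NaN.
    """
    df = entries.copy()
    unknown = set(df["item"]) - set(KNOWN_ITEMS)
    if unknown:
        raise ValueError(f"unknown items in entries: {sorted(unknown)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["date"] = df["timestamp"].dt.date
    noon = df["timestamp"].dt.normalize() + pd.Timedelta(hours=12)
    df = df[df["timestamp"] > noon]
    if df.empty:
        return pd.DataFrame(columns=DAILY_COLUMNS)

    dup = df.duplicated(subset=["participant_id", "date", "item", "timestamp"], keep=False)
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} entries share identical timestamps for the same "
            "item; keeping the last in input order",
            stacklevel=2,
        )
    df = df.sort_values("timestamp", kind="stable")
    df = df.drop_duplicates(subset=["participant_id", "date", "item"], keep="last")
    wide = df.pivot(index=["participant_id", "date"], columns="item", values="value")
    wide = wide.reset_index()
    for col in DAILY_COLUMNS:
        if col not in wide.columns:
            wide[col] = np.nan
    return wide[DAILY_COLUMNS].sort_values(["participant_id", "date"]).reset_index(drop=True)


def harmonize_directions(records: pd.DataFrame, orientation_map: dict[str, str]) -> pd.DataFrame:
    """Flip ordinal items so higher scores are worse.

    ``orientation_map`` maps each ordinal item to ``"identity"`` (already
    worse-high) or ``"reverse"`` (flip via v -> 6 - v).  Applying a reversal
    map twice restores the input (involution).
    """
    out = records.copy()
    for item, orient in orientation_map.items():
        if item not in KNOWN_ITEMS:
            raise ValueError(f"unknown item in orientation map: {item!r}")
        if orient not in ("identity", "reverse"):
            raise ValueError(f"orientation for {item!r} must be 'identity' or 'reverse'")
        if orient == "reverse" and item in out.columns:
            out[item] = 6 - out[item]
    return out


def build_series(daily: pd.DataFrame) -> list[ParticipantSeries]:
    """Split a wide daily table into per-participant series."""
    daily = daily.copy()
    daily["date"] = pd.to_datetime(daily["date"]).dt.date
    out = []
    for pid, grp in daily.groupby("participant_id", sort=True):
        grp = grp.sort_values("date").reset_index(drop=True)
        if grp["date"].duplicated().any():
            raise ValueError(f"participant {pid!r} has duplicate dates")
        out.append(ParticipantSeries(pid, grp))
    return out


def _longest_consecutive_run(dates) -> int:
    """Longest run of consecutive calendar dates in a sorted date sequence."""
    best = run = 0
    prev = None
    for d in dates:
        run = run + 1 if prev is not None and (d - prev).days == 1 else 1
        best = max(best, run)
        prev = d
    return best


def apply_inclusion(
    series: list[ParticipantSeries],
    window_days: int = 30,
    min_consecutive: int = 7,
    min_completion: float = 0.70,
) -> tuple[list[ParticipantSeries], pd.DataFrame]:
    """Apply the study inclusion criteria.

    A participant is included iff (a) any symptom data is present, (b) pain
    is recorded on at least ``min_consecutive`` consecutive calendar days,
    and (c) pain is recorded on at least ``min_completion`` of the
    ``window_days``-day study window.  The exclusion log records the first
    failing criterion per excluded participant.
    """
    included: list[ParticipantSeries] = []
    log_rows = []
    for s in series:
        symptom_cols = ["pain", "impact"] + [c for c in EXPOSURES if c in s.records.columns]
        has_any = bool(s.records[symptom_cols].notna().any().any())
        if not has_any:
            log_rows.append({"participant_id": s.participant_id, "reason": "no_symptom_data"})
            continue
        pain_dates = list(s.records.loc[s.records["pain"].notna(), "date"])
        if _longest_consecutive_run(pain_dates) < min_consecutive:
            log_rows.append(
                {"participant_id": s.participant_id, "reason": "pain_lt_7_consecutive_days"}
            )
            continue
        if len(pain_dates) / window_days < min_completion - 1e-12:
            log_rows.append(
                {"participant_id": s.participant_id, "reason": "pain_completion_lt_70pct"}
            )
            continue
        included.append(s)
    log = pd.DataFrame(log_rows, columns=["participant_id", "reason"])
    logger.info("inclusion: %d of %d participants included", len(included), len(series))
    return included, log


def read_daily_csv(path) -> pd.DataFrame:
    """Read a daily wide CSV as written by the simulator / pipeline."""
    df = pd.read_csv(path)
    missing = set(DAILY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"daily CSV missing columns: {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df[DAILY_COLUMNS]


def write_daily_csv(daily: pd.DataFrame, path) -> None:
    daily.to_csv(path, index=False)
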