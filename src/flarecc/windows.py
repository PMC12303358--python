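"""Hazard and control window construction for the case-crossover design.

A hazard window is the 3 days immediately preceding a flare onset; control
windows are 3-day intervals that neither immediately precede a flare nor
overlap any flare or hazard window.  Each window must carry complete data on
all 12 exposures, and every exposure is summarized by its 3-day mean and its
intraindividual standard deviation (iSD, the sample SD over the 3 days).
Controls are selected with the full-stratum bidirectional approach (mutual
overlap among controls allowed) or, for sensitivity analysis, as discrete
non-overlapping intervals tiled greedily from the earliest eligible day.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flares import ONE_DAY, FlareDefinition, FlareEpisode
from .preprocess import EXPOSURES, ParticipantSeries

logger = logging.getLogger(__name__)

WINDOW_DAYS = 3


@dataclass(frozen=True)
class Window:
    participant_id: object
    definition: FlareDefinition
    label: str  # "hazard" | "control"
    start_date: dt.date
    onset_date: dt.date | None  # the flare onset a hazard window precedes
    means: dict[str, float] = field(compare=False)
    isds: dict[str, float] = field(compare=False)

    def days(self) -> list[dt.date]:
        return [self.start_date + ONE_DAY * i for i in range(WINDOW_DAYS)]


@dataclass
class RiskSet:
    participant_id: object
    definition: FlareDefinition
    hazards: list[Window]
    controls: list[Window]

    @property
    def windows(self) -> list[Window]:
        return self.hazards + self.controls


def summarize_window(values) -> tuple[float, float]:
    """(mean, iSD) of one exposure's 3 daily values; iSD uses n-1 = 2."""
    arr = np.asarray(values, dtype=float)
    if arr.shape != (WINDOW_DAYS,) or np.isnan(arr).any():
        raise ValueError("window must have exactly 3 non-missing values")
    return float(arr.mean()), float(arr.std(ddof=1))


def _complete_days(series: ParticipantSeries) -> dict[dt.date, dict[str, float]]:
    """Days on which all 12 exposures are present, mapped to their values."""
    rec = series.records
    mask = rec[EXPOSURES].notna().all(axis=1)
    sub = rec.loc[mask]
    vals = sub[EXPOSURES].to_numpy(dtype=float)
    return dict(zip(sub["date"], vals))


def _make_window(
    series: ParticipantSeries,
    definition: FlareDefinition,
    label: str,
    start: dt.date,
    complete: dict,
    onset: dt.date | None = None,
) -> Window:
    days = [start + ONE_DAY * i for i in range(WINDOW_DAYS)]
    block = np.array([complete[d] for d in days])  # (3, 12)
    mean = block.sum(axis=0) / WINDOW_DAYS
    isd = np.sqrt(((block - mean) ** 2).sum(axis=0) / (WINDOW_DAYS - 1))
    return Window(
        series.participant_id,
        definition,
        label,
        start,
        onset,
        dict(zip(EXPOSURES, mean)),
        dict(zip(EXPOSURES, isd)),
    )


def enumerate_hazard_windows(
    episodes: list[FlareEpisode],
    series: ParticipantSeries,
) -> list[Window]:
    """The 3-day pre-onset window of each flare, where admissible.

    A flare contributes a hazard window only if the window fits inside the
    observation span (onset at least 3 days after the first observed day),
    shares no day with any flare's day range (same definition), and has
    complete 12-exposure data on all 3 days.
    """
    if not episodes:
        return []
    definition = episodes[0].definition
    complete = _complete_days(series)
    flare_days = set()
    for ep in episodes:
        flare_days.update(ep.day_range())
    first_obs = series.records["date"].iloc[0]
    out = []
    for ep in episodes:
        start = ep.onset_date - ONE_DAY * WINDOW_DAYS
        if start < first_obs:
            logger.debug("flare %s: window precedes observation", ep.onset_date)
            continue
        days = [start + ONE_DAY * i for i in range(WINDOW_DAYS)]
        if any(d in flare_days for d in days):
            continue  # pre-flare days overlap another flare
        if any(d not in complete for d in days):
            continue  # incomplete exposure data
        out.append(_make_window(series, definition, "hazard", start, complete, ep.onset_date))
    return out


def enumerate_control_windows(
    series: ParticipantSeries,
    episodes: list[FlareEpisode],
    hazards: list[Window],
    definition: FlareDefinition,
    mode: str = "full_stratum",
    require_followup_day: bool = True,
) -> list[Window]:
    """All eligible 3-day control windows for one participant.

    ``full_stratum``: every 3-consecutive-day window that (a) is not the
    pre-onset window of any flare, (b) shares no day with any flare, (c)
    shares no day with any hazard window, (d) is exposure-complete, and (e),
    when ``require_followup_day``, is followed by an observed pain day that
    is not a flare onset (so the window could itself have preceded a flare).
    ``nonoverlap``: the greedy earliest-first pairwise-disjoint subset of the
    full-stratum candidates.
    """
    if mode not in ("full_stratum", "nonoverlap"):
        raise ValueError(f"unknown control mode {mode!r}")
    definition = FlareDefinition(definition)
    complete = _complete_days(series)
    flare_days = set()
    onsets = set()
    pre_window_starts = set()
    for ep in episodes:
        flare_days.update(ep.day_range())
        onsets.add(ep.onset_date)
        pre_window_starts.add(ep.onset_date - ONE_DAY * WINDOW_DAYS)
    hazard_days = set()
    for h in hazards:
        hazard_days.update(h.days())
    pain_dates = set(series.records.loc[series.records["pain"].notna(), "date"])

    rec_dates = series.records["date"]
    first_obs, last_obs = rec_dates.iloc[0], rec_dates.iloc[-1]
    out = []
    start = first_obs
    while start + ONE_DAY * (WINDOW_DAYS - 1) <= last_obs:
        days = [start + ONE_DAY * i for i in range(WINDOW_DAYS)]
        ok = (
            start not in pre_window_starts
            and not any(d in flare_days for d in days)
            and not any(d in hazard_days for d in days)
            and all(d in complete for d in days)
        )
        if ok and require_followup_day:
            follow = start + ONE_DAY * WINDOW_DAYS
            ok = follow in pain_dates and follow not in onsets
        if ok:
            out.append(_make_window(series, definition, "control", start, complete))
        start += ONE_DAY

    if mode == "nonoverlap":
        selected: list[Window] = []
        next_free: dt.date | None = None
        for w in out:  # already in ascending start order
            if next_free is None or w.start_date >= next_free:
                selected.append(w)
                next_free = w.start_date + ONE_DAY * WINDOW_DAYS
        out = selected
    return out


def build_risk_sets(
    hazards_by_pid: dict[object, list[Window]],
    controls_by_pid: dict[object, list[Window]],
    definition: FlareDefinition,
) -> tuple[list[RiskSet], pd.DataFrame]:
    """One risk set per participant with >=1 hazard and >=1 control window.

    Returns the risk sets and a disposition log accounting for every
    participant that had any window.
    """
    risk_sets = []
    rows = []
    for pid in sorted(set(hazards_by_pid) | set(controls_by_pid), key=str):
        h = hazards_by_pid.get(pid, [])
        c = controls_by_pid.get(pid, [])
        if h and c:
            risk_sets.append(RiskSet(pid, FlareDefinition(definition), h, c))
            status = "risk_set"
        elif h:
            status = "no_controls"
        elif c:
            status = "no_hazards"
        else:
            status = "no_windows"
        rows.append(
            {
                "participant_id": pid,
                "definition": FlareDefinition(definition).value,
                "n_hazards": len(h),
                "n_controls": len(c),
                "status": status,
            }
        )
    disposition = pd.DataFrame(
        rows, columns=["participant_id", "definition", "n_hazards", "n_controls", "status"]
    )
    return risk_sets, disposition


def windows_table(windows: list[Window]) -> pd.DataFrame:
    """Flatten windows to a tidy table (mean_/isd_ columns per exposure)."""
    rows = []
    for w in windows:
        row = {
            "participant_id": w.participant_id,
            "definition": w.definition.value,
            "label": w.label,
            "start_date": w.start_date,
            "onset_date": w.onset_date,
        }
        for e in EXPOSURES:
            row[f"mean_{e}"] = w.means[e]
            row[f"isd_{e}"] = w.isds[e]
        rows.append(row)
    cols = ["participant_id", "definition", "label", "start_date", "onset_date"]
    cols += [f"mean_{e}" for e in EXPOSURES] + [f"isd_{e}" for e in EXPOSURES]
    return pd.DataFrame(rows, columns=cols)
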