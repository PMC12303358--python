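"""Pain-flare detection under three progressively stringent definitions.

A flare is a period of elevated pain that starts on an onset day and ends on
the first later day where pain returns to the participant's personal median
or lower (the return day is part of the flare, so the minimum duration is 2
days).  Onset rules:

* **AA** (above average): pain strictly greater than the personal median.
* **AT** (above threshold): pain greater than 3 on the 1-5 scale.
* **MAT** (move above threshold): pain in {1,2,3} on the previous observed
  calendar day moving to {4,5} today.

All onsets must additionally lie strictly above the personal median (else the
onset would already satisfy the end criterion).  Consecutive days satisfying
a definition's numeric condition collapse into one candidate run whose first
day is the onset; if that first day fails the above-median rule, the whole
run is excluded rather than shifted.  Onsets whose episodes share an end day
with an earlier onset are removed (keep the first).  Missing pain days break
runs and censor open episodes: no flare spans an unobserved day.
"""

from __future__ import annotations

import datetime as dt
import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ParticipantSeries

ONE_DAY = dt.timedelta(days=1)


class FlareDefinition(str, enum.Enum):
    """The three onset definitions, from least to most stringent."""

    AA = "aa"
    AT = "at"
    MAT = "mat"


@dataclass(frozen=True)
class FlareEpisode:
    participant_id: object
    definition: FlareDefinition
    onset_date: dt.date
    end_date: dt.date | None  # None while censored
    censored: bool

    @property
    def duration_days(self) -> int | None:
        if self.censored:
            return None
        return (self.end_date - self.onset_date).days + 1

    def day_range(self) -> list[dt.date]:
        """Calendar days from onset to end inclusive (onset-only if censored,
        in which case the range is not used for window exclusion)."""
        last = self.end_date if self.end_date is not None else self.onset_date
        n = (last - self.onset_date).days + 1
        return [self.onset_date + ONE_DAY * i for i in range(n)]


@dataclass(frozen=True)
class ImpactAssessment:
    """Carry-on effect of a flare: does illness impact stay elevated past the
    flare's end, and for how many days?"""

    episode: FlareEpisode
    affected: bool
    impact_duration_days: int | None  # None when indeterminate
    indeterminate: bool


def personal_median(values) -> float:
    """Sample median over non-missing values (even counts: mean of the two
    middle order statistics, so medians may be non-integers)."""
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot take a personal median of all-missing values")
    return float(np.median(arr))


def _pain_map(series: ParticipantSeries) -> dict[dt.date, float]:
    rec = series.records
    obs = rec.loc[rec["pain"].notna()]
    return dict(zip(obs["date"], obs["pain"].astype(float)))


def detect_flares(
    series: ParticipantSeries,
    definition: FlareDefinition,
    include_censored: bool = False,
) -> list[FlareEpisode]:
    """Detect flare episodes for one participant under one definition.

    Returns episodes in onset order.  Censored episodes (no observed return
    to the median before a gap or the series end) are omitted unless
    ``include_censored`` is set, in which case they appear flagged with
    ``end_date=None``.
    """
    definition = FlareDefinition(definition)
    median = series.pain_median
    if math.isnan(median):
        raise ValueError("pain median undefined: no observed pain days")
    pain = _pain_map(series)
    if not pain:
        return []
    dates = sorted(pain)

    # --- candidate onsets ---------------------------------------------------
    onsets: list[dt.date] = []
    if definition is FlareDefinition.MAT:
        for d in dates:
            prev = d - ONE_DAY
            if prev not in pain:
                continue  # "yesterday" must be an observed calendar day
            if pain[prev] in (1, 2, 3) and pain[d] in (4, 5) and pain[d] > median:
                onsets.append(d)
    else:
        # runs of consecutive observed days meeting the definition's condition
        cond = {
            d: (pain[d] > median if definition is FlareDefinition.AA else pain[d] > 3)
            for d in dates
        }
        for d in dates:
            if not cond[d]:
                continue
            prev = d - ONE_DAY
            if prev in pain and cond[prev]:
                continue  # not the first day of its run
            if pain[d] > median:
                onsets.append(d)
            # else: run-first fails the above-median rule -> run excluded

    # --- episode ends, censoring, same-end dedup ----------------------------
    episodes: list[FlareEpisode] = []
    used_ends: set[dt.date] = set()
    last = dates[-1]
    for onset in onsets:
        end: dt.date | None = None
        censored = False
        d = onset + ONE_DAY
        while True:
            if d > last or d not in pain:
                censored = True  # gap or series end before any return
                break
            if pain[d] <= median:
                end = d
                break
            d += ONE_DAY
        if censored:
            if include_censored:
                episodes.append(
                    FlareEpisode(series.participant_id, definition, onset, None, True)
                )
            continue
        if end in used_ends:
            continue  # later onset sharing an end with an earlier one: removed
        used_ends.add(end)
        episodes.append(FlareEpisode(series.participant_id, definition, onset, end, False))
    return episodes


def flare_duration(episode: FlareEpisode) -> int:
    """Days from onset to end inclusive (minimum 2)."""
    if episode.censored:
        raise ValueError("censored episode has no defined duration")
    return episode.duration_days


def assess_carry_on(
    episode: FlareEpisode, series: ParticipantSeries
) -> ImpactAssessment:
    """Assess whether illness impact stays elevated after the flare ends.

    A flare is *affected* by a carry-on effect iff impact on the flare's end
    day exceeds the personal impact median.  The impact duration counts days
    from the end day (inclusive) until impact first returns to the median or
    lower (exclusive).  The assessment is indeterminate when impact is
    missing on the end day, or when impact never returns within observation
    (including a gap before it does).
    """
    if episode.censored:
        raise ValueError("cannot assess carry-on for a censored episode")
    impact_median = series.impact_median
    if math.isnan(impact_median):
        raise ValueError("impact median undefined")
    rec = series.records
    obs = rec.loc[rec["impact"].notna()]
    impact = dict(zip(obs["date"], obs["impact"].astype(float)))
    end = episode.end_date
    if end not in impact:
        return ImpactAssessment(episode, False, None, True)
    if impact[end] <= impact_median:
        return ImpactAssessment(episode, False, None, False)
    last = max(impact) if impact else end
    d = end
    while True:
        d += ONE_DAY
        if d > last or d not in impact:
            # elevated impact runs into a gap / the series end: duration unknown
            return ImpactAssessment(episode, True, None, True)
        if impact[d] <= impact_median:
            return ImpactAssessment(episode, True, (d - end).days, False)


def monthly_rate(episodes: list[FlareEpisode], observed_pain_days: int) -> float:
    """Flare count scaled to a 30-day month of observed pain days."""
    if observed_pain_days <= 0:
        raise ValueError("observed_pain_days must be positive")
    if observed_pain_days < 7:
        raise ValueError("monthly rate requires at least 7 observed pain days")
    return len(episodes) * 30.0 / observed_pain_days


def _iqr_stats(values: list[float]) -> dict:
    if not values:
        return {"median": np.nan, "q1": np.nan, "q3": np.nan, "min": np.nan, "max": np.nan}
    arr = np.asarray(values, dtype=float)
    return {
        "median": float(np.median(arr)),
        "q1": float(np.percentile(arr, 25)),
        "q3": float(np.percentile(arr, 75)),
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


def summarize_flares(
    all_series: list[ParticipantSeries],
    definition: FlareDefinition,
    include_censored: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort-level flare and carry-on summary for one definition.

    Returns ``(episodes_df, summary_df)``: one row per episode with its
    carry-on assessment, and a one-row table with participants with >=1
    flare, total counts, duration and 30-day monthly-rate distributions, and
    carry-on (impact) statistics.
    """
    definition = FlareDefinition(definition)
    rows = []
    rates = []
    n_with_flare = 0
    for s in all_series:
        eps = detect_flares(s, definition, include_censored=include_censored)
        kept = [e for e in eps if not e.censored]
        if kept:
            n_with_flare += 1
            rates.append(monthly_rate(kept, s.observed_pain_days))
        for e in eps:
            if e.censored:
                rows.append(
                    {
                        "participant_id": s.participant_id,
                        "definition": definition.value,
                        "onset_date": e.onset_date,
                        "end_date": None,
                        "duration_days": np.nan,
                        "censored": True,
                        "carry_on_affected": None,
                        "impact_duration_days": np.nan,
                    }
                )
                continue
            assess = assess_carry_on(e, s)
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "definition": definition.value,
                    "onset_date": e.onset_date,
                    "end_date": e.end_date,
                    "duration_days": e.duration_days,
                    "censored": False,
                    "carry_on_affected": bool(assess.affected),
                    "impact_duration_days": (
                        assess.impact_duration_days
                        if assess.impact_duration_days is not None
                        else np.nan
                    ),
                }
            )
    episodes_df = pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "definition",
            "onset_date",
            "end_date",
            "duration_days",
            "censored",
            "carry_on_affected",
            "impact_duration_days",
        ],
    )
    kept_df = episodes_df.loc[~episodes_df["censored"]]
    durations = kept_df["duration_days"].tolist()
    dur = _iqr_stats(durations)
    rate = _iqr_stats(rates)
    affected = kept_df.loc[kept_df["carry_on_affected"] == True]  # noqa: E712
    analyzed = affected.loc[affected["impact_duration_days"].notna()]
    imp = _iqr_stats(analyzed["impact_duration_days"].tolist())
    summary = pd.DataFrame(
        [
            {
                "definition": definition.value,
                "n_participants": len(all_series),
                "participants_with_flare": n_with_flare,
                "flare_count": len(kept_df),
                "duration_median": dur["median"],
                "duration_q1": dur["q1"],
                "duration_q3": dur["q3"],
                "duration_min": dur["min"],
                "duration_max": dur["max"],
                "monthly_rate_median": rate["median"],
                "monthly_rate_q1": rate["q1"],
                "monthly_rate_q3": rate["q3"],
                "monthly_rate_min": rate["min"],
                "monthly_rate_max": rate["max"],
                "flares_affected": len(affected),
                "flares_impact_analyzed": len(analyzed),
                "impact_duration_median": imp["median"],
                "impact_duration_q1": imp["q1"],
                "impact_duration_q3": imp["q3"],
                "impact_duration_min": imp["min"],
                "impact_duration_max": imp["max"],
            }
        ]
    )
    return episodes_df, summary
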