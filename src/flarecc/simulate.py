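"""Synthetic daily-diary cohorts with known planted exposure -> flare effects.

Each participant contributes a 30-day series of nine 1-5 ordinal symptoms and
three accelerometer-style continuous exposures.  Every exposure rides on a
Gaussian AR(1) latent process (unit stationary variance) plus a
between-person intercept; ordinal items are discretized at fixed thresholds
(equiprobable quintiles of the marginal by default).  Daily pain follows a
proportional-odds model whose linear predictor can include planted log-odds
effects of the 3-day mean and/or intraindividual SD of named exposures over
the preceding days t-3..t-1 — exactly the summaries the case-crossover
models estimate — so downstream estimates can be checked against known truth.
Illness impact tracks pain and decays one day behind elevated pain, which
exercises carry-on detection.  Whole days go missing completely at random.

Defaults emulate a 30-day rheumatoid-arthritis diary study: a low baseline
probability of elevated pain combined with substantial between-person
heterogeneity (intercept SD 1.4) reproduces published RA flare epidemiology —
roughly half the cohort experiences any above-threshold flare in 30 days,
with a median monthly rate near 2 and flare durations of mostly 2 days —
while day-to-day symptom persistence uses a modest AR coefficient of 0.3.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .preprocess import (
    CONTINUOUS_EXPOSURES,
    DAILY_COLUMNS,
    EXPOSURES,
    ORDINAL_EXPOSURES,
)

START_DATE = dt.date(2021, 3, 1)

#: baseline cumulative probabilities P(score >= j), j = 2..5, for pain and
#: impact at a zero linear predictor.  Together with the default
#: between-person intercept SD these are calibrated so a simulated cohort
#: reproduces published RA flare epidemiology: roughly half the cohort with
#: at least one above-threshold flare over 30 days, a median monthly rate
#: near 2 with maxima near 8, and median flare durations of 2 days.
BASELINE_CUM_P = (0.60, 0.28, 0.03, 0.01)

#: location/scale mapping latent z -> continuous exposures, and clip bounds
CONTINUOUS_SCALE = {
    "sleep_efficiency_pct": (85.0, 7.0, 30.0, 100.0),
    "sedentary_pct": (60.0, 12.0, 0.0, 100.0),
    "time_in_bed_h": (8.0, 0.9, 3.0, 14.0),
}

#: centering constants for planted linear predictors (approximate expected
#: values of the summaries; centering only anchors the baseline flare rate)
MEAN_CENTERS = {e: 3.0 for e in ORDINAL_EXPOSURES}
MEAN_CENTERS.update({e: CONTINUOUS_SCALE[e][0] for e in CONTINUOUS_EXPOSURES})
ISD_CENTERS = {e: 1.0 for e in ORDINAL_EXPOSURES}
ISD_CENTERS.update(
    {e: 0.8 * CONTINUOUS_SCALE[e][1] for e in CONTINUOUS_EXPOSURES}
)


@dataclass(frozen=True)
class PlantedEffect:
    """A known exposure effect: `log_odds` per unit of the exposure's 3-day
    `metric` ('mean' or 'isd') on next-day pain elevation."""

    exposure: str
    metric: str
    log_odds: float

    def __post_init__(self):
        if self.exposure not in EXPOSURES:
            raise ValueError(f"unknown exposure {self.exposure!r}")
        if self.metric not in ("mean", "isd"):
            raise ValueError("metric must be 'mean' or 'isd'")


@dataclass
class SimConfig:
    n_participants: int
    n_days: int = 30
    ar_coefficient: float = 0.3
    ordinal_thresholds: tuple[float, ...] | None = None
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    participant_sd: float = 1.4
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.n_days < 7:
            raise ValueError("n_days must be >= 7 (inclusion needs 7 consecutive days)")
        if not 0 <= self.missing_rate < 0.3:
            raise ValueError(
                "missing_rate must be in [0, 0.3): higher rates empty the cohort "
                "under the 70% completion filter"
            )
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must be in [0, 1)")
        if self.participant_sd < 0:
            raise ValueError("participant_sd must be >= 0")
        self.planted_effects = [
            e if isinstance(e, PlantedEffect) else PlantedEffect(*e)
            for e in self.planted_effects
        ]
        if self.ordinal_thresholds is None:
            # equiprobable quintiles of the marginal latent N(0, 1 + sd_b^2)
            scale = np.sqrt(1.0 + self.participant_sd**2)
            self.ordinal_thresholds = tuple(
                float(scale * norm.ppf(k / 5)) for k in range(1, 5)
            )
        thr = self.ordinal_thresholds
        if len(thr) != 4 or any(b <= a for a, b in zip(thr, thr[1:])):
            raise ValueError(
                "ordinal_thresholds must be 4 strictly increasing cutpoints "
                "(yielding exactly 5 categories)"
            )


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort (fully reproducible from the seed)."""

    config: SimConfig
    planted_effects: list[PlantedEffect]
    pain_intercepts: dict
    exposure_intercepts: dict
    latent_series: dict  # pid -> (n_days, 12) latent array
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "planted_effects": [asdict(e) for e in self.planted_effects],
            "pain_intercepts": {str(k): v for k, v in self.pain_intercepts.items()},
            "exposure_intercepts": {
                str(k): list(v) for k, v in self.exposure_intercepts.items()
            },
            "config": {
                "n_participants": self.config.n_participants,
                "n_days": self.config.n_days,
                "ar_coefficient": self.config.ar_coefficient,
                "ordinal_thresholds": list(self.config.ordinal_thresholds),
                "participant_sd": self.config.participant_sd,
                "missing_rate": self.config.missing_rate,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _ar1(rng: np.random.Generator, n: int, rho: float, k: int = 1) -> np.ndarray:
    """k independent AR(1) paths of length n with unit stationary variance."""
    eps = rng.standard_normal((n, k))
    z = np.empty((n, k))
    z[0] = eps[0]
    innov_sd = np.sqrt(1.0 - rho**2)
    for t in range(1, n):
        z[t] = rho * z[t - 1] + innov_sd * eps[t]
    return z

def _ordinal_from_cumulative(rng, cum_logits: np.ndarray) -> np.ndarray:
    """Sample 1-5 scores given per-day cumulative logits for P(score>=j).

    Cumulative probabilities are clipped to be nonincreasing across splits,
    which matters only when a split-specific effect pushes an upper split
    past a lower one in the extreme tail.
    """
    cum_p = expit(cum_logits)
    cum_p = np.minimum.accumulate(cum_p, axis=1)
    u = rng.uniform(size=cum_p.shape[0])
    return 1 + (u[:, None] < cum_p).sum(axis=1)


def _window_summaries(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """3-day mean and sample SD of values over t-3..t-1 for each day t
    (NaN for t < 3, where no full window precedes)."""
    n = len(values)
    means = np.full(n, np.nan)
    isds = np.full(n, np.nan)
    for t in range(3, n):
        w = values[t - 3 : t]
        means[t] = w.mean()
        isds[t] = w.std(ddof=1)
    return means, isds


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, CohortTruth]:
    """Generate one cohort of daily diaries with known ground truth.

    Returns a daily wide DataFrame (one row per participant-day, missing days
    removed) plus the :class:`CohortTruth` realizing the planted effects.
    """
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_participants)
    # cumulative logits theta_j = logit P(score >= j) at a zero predictor
    cum_p = np.asarray(BASELINE_CUM_P)
    theta = np.log(cum_p / (1 - cum_p))

    rows = []
    pain_b: dict = {}
    expo_b: dict = {}
    latents: dict = {}
    thr = np.asarray(config.ordinal_thresholds)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pid = f"P{i + 1:04d}"
        b_pain = rng.normal(0, config.participant_sd)
        b_expo = rng.normal(0, config.participant_sd, size=len(EXPOSURES))
        z = b_expo[None, :] + _ar1(
            rng, config.n_days, config.ar_coefficient, k=len(EXPOSURES)
        )
        values: dict[str, np.ndarray] = {}
        for j, e in enumerate(EXPOSURES):
            if e in ORDINAL_EXPOSURES:
                values[e] = (1 + np.searchsorted(thr, z[:, j], side="right")).astype(float)
            else:
                loc, scale, lo, hi = CONTINUOUS_SCALE[e]
                values[e] = np.clip(loc + scale * z[:, j], lo, hi)

        # planted linear predictor from lagged 3-day summaries; it enters the
        # pain-elevation splits (>=4, >=5) only, so the log-OR for next-day
        # pain elevation per unit summary is exactly the planted value, while
        # sub-threshold pain dynamics stay exposure-free
        eta = np.zeros(config.n_days)
        for eff in config.planted_effects:
            means, isds = _window_summaries(values[eff.exposure])
            summ = means if eff.metric == "mean" else isds
            center = (MEAN_CENTERS if eff.metric == "mean" else ISD_CENTERS)[eff.exposure]
            contrib = eff.log_odds * (summ - center)
            eta = eta + np.where(np.isnan(contrib), 0.0, contrib)

        top_split = np.array([0.0, 0.0, 1.0, 1.0])  # splits >=2,>=3,>=4,>=5
        cum_logits = theta[None, :] + b_pain + eta[:, None] * top_split[None, :]
        pain = _ordinal_from_cumulative(rng, cum_logits).astype(float)

        # impact: tied to same-day pain, plus a decaying trace of yesterday's
        # elevated pain so impact can stay high after a flare's pain subsides
        lag_elev = np.zeros(config.n_days)
        lag_elev[1:] = (pain[:-1] >= 4).astype(float)
        eta_imp = 0.8 * b_pain + 0.8 * (pain - 3.0) + 0.5 * lag_elev
        impact = _ordinal_from_cumulative(rng, theta[None, :] + eta_imp[:, None]).astype(float)

        keep = rng.uniform(size=config.n_days) >= config.missing_rate
        frame = {
            "participant_id": pid,
            "date": [START_DATE + dt.timedelta(days=t) for t in range(config.n_days)],
            "pain": pain,
            "impact": impact,
        }
        frame.update({e: values[e] for e in EXPOSURES})
        rows.append(pd.DataFrame(frame).loc[keep])
        pain_b[pid] = float(b_pain)
        expo_b[pid] = [float(v) for v in b_expo]
        latents[pid] = z

    diary = pd.concat(rows, ignore_index=True)[DAILY_COLUMNS]
    truth = CohortTruth(
        config=config,
        planted_effects=list(config.planted_effects),
        pain_intercepts=pain_b,
        exposure_intercepts=expo_b,
        latent_series=latents,
        seed=config.seed,
    )
    return diary, truth


# ---------------------------------------------------------------------------
# epoch-level actigraphy simulation
# ---------------------------------------------------------------------------

EPOCH_SECONDS = 30


@dataclass
class DayProfile:
    """Target profile for one simulated actigraphy day.

    The in-bed interval starts at ``in_bed_start`` (a clock time on ``date``)
    and lasts ``in_bed_hours``; ``sleep_efficiency_target_pct`` of in-bed
    epochs are scored asleep.  Waking minutes outside the in-bed interval hit
    ``sedentary_target_pct`` sedentary classification, with
    ``mvpa_share_of_active`` of the remaining active minutes at
    moderate-to-vigorous intensity.
    """

    date: dt.date
    in_bed_start: dt.time = dt.time(0, 30)
    in_bed_hours: float = 7.5
    sleep_efficiency_target_pct: float = 90.0
    sedentary_target_pct: float = 60.0
    mvpa_share_of_active: float = 0.25

    def __post_init__(self):
        if self.in_bed_hours > 24:
            raise ValueError("in-bed interval cannot exceed 24 hours")
        if self.in_bed_hours <= 0:
            raise ValueError("in-bed interval must be positive")
        if not 0 <= self.sedentary_target_pct <= 100:
            raise ValueError("sedentary target must be a percentage")
        if not 0 < self.sleep_efficiency_target_pct <= 100:
            raise ValueError("sleep efficiency target must be in (0, 100]")


def generate_epoch_counts(
    profile: DayProfile, seed: int, participant_id: object = "P0001"
) -> pd.DataFrame:
    """One day of 30-second epochs (columns: participant_id, timestamp,
    counts, state) realizing the profile's targets.

    Minutes are assigned whole activity categories, so the realized sedentary
    percentage after cut-point classification lands within rounding (far
    inside +/-2 points) of the target.
    """
    from .actigraphy import MVPA_CPM, SEDENTARY_CPM  # avoid import cycle

    rng = np.random.default_rng(seed)
    day_start = dt.datetime.combine(profile.date, dt.time(0, 0))
    n_epochs = 24 * 3600 // EPOCH_SECONDS
    stamps = [day_start + dt.timedelta(seconds=EPOCH_SECONDS * i) for i in range(n_epochs)]

    bed_start = dt.datetime.combine(profile.date, profile.in_bed_start)
    bed_end = bed_start + dt.timedelta(hours=profile.in_bed_hours)
    in_bed = np.array([bed_start <= s < bed_end for s in stamps])
    idx_bed = np.where(in_bed)[0]
    if idx_bed.size == 0:
        raise ValueError("in-bed interval contains no epochs within the day")

    state = np.full(n_epochs, "wake", dtype=object)
    n_sleep = max(2, round(profile.sleep_efficiency_target_pct / 100 * idx_bed.size))
    n_sleep = min(n_sleep, idx_bed.size)
    sleep_idx = rng.choice(idx_bed, size=n_sleep, replace=False)
    state[sleep_idx] = "sleep"
    # anchor the interval so it is recoverable from the labels alone
    state[idx_bed[0]] = "sleep"
    state[idx_bed[-1]] = "sleep"

    counts = np.empty(n_epochs)
    counts[in_bed] = rng.uniform(0, 8, size=in_bed.sum())
    counts[np.where(in_bed)[0][state[in_bed] == "wake"]] = rng.uniform(
        20, 120, size=int((state[in_bed] == "wake").sum())
    )

    # waking minutes: whole-minute category assignment to hit the target
    wake_idx = np.where(~in_bed)[0]
    minutes = {}
    for i in wake_idx:
        key = stamps[i].replace(second=0)
        minutes.setdefault(key, []).append(i)
    full_minutes = sorted(k for k, v in minutes.items() if len(v) == 2)
    n_min = len(full_minutes)
    n_sed = round(profile.sedentary_target_pct / 100 * n_min)
    order = rng.permutation(n_min)
    sed_minutes = {full_minutes[j] for j in order[:n_sed]}
    active = [full_minutes[j] for j in order[n_sed:]]
    n_mvpa = round(profile.mvpa_share_of_active * len(active))
    mvpa_minutes = set(active[:n_mvpa])
    for key in full_minutes:
        if key in sed_minutes:
            cpm = rng.uniform(0, SEDENTARY_CPM)
        elif key in mvpa_minutes:
            cpm = rng.uniform(MVPA_CPM, 2.5 * MVPA_CPM)
        else:
            cpm = rng.uniform(SEDENTARY_CPM + 1, MVPA_CPM - 1)
        i, j = minutes[key]
        split = rng.uniform(0.3, 0.7)
        counts[i] = cpm * split
        counts[j] = cpm - counts[i]  # exact sum preserves the cpm class
    # partial waking minutes (at in-bed boundaries): keep them sedentary-level
    for key, idxs in minutes.items():
        if len(idxs) == 1:
            counts[idxs[0]] = rng.uniform(0, SEDENTARY_CPM / 2)

    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "timestamp": stamps,
            "counts": counts,
            "state": state,
        }
    )


def write_diary_csv(diary: pd.DataFrame, path) -> None:
    diary.to_csv(path, index=False)
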