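"""End-to-end orchestration: diary -> flares -> windows -> fitted models.

``run_primary`` executes the whole analysis for each requested flare
definition with full-stratum control selection; ``run_sensitivity`` repeats
the window construction with discrete non-overlapping controls and emits a
side-by-side comparison of the odds ratios.  All intermediate artifacts are
plain CSV/JSON.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import actigraphy as acti
from .clogit import FitResult, or_table, primary_model_specs, fit
from .flares import FlareDefinition, detect_flares, summarize_flares
from .preprocess import ParticipantSeries, apply_inclusion, build_series, read_daily_csv
from .simulate import SimConfig, generate_cohort
from .windows import (
    build_risk_sets,
    enumerate_control_windows,
    enumerate_hazard_windows,
    windows_table,
)

logger = logging.getLogger(__name__)

ALL_DEFINITIONS = (FlareDefinition.AA, FlareDefinition.AT, FlareDefinition.MAT)


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    Exactly one of ``diary`` (a DataFrame), ``diary_csv`` or ``simulation``
    must be supplied.  ``epoch_csv`` optionally overrides the three objective
    exposures with actigraphy-derived values.
    """

    diary: pd.DataFrame | None = None
    diary_csv: str | None = None
    epoch_csv: str | None = None
    simulation: SimConfig | None = None
    definitions: tuple = ALL_DEFINITIONS
    mode: str = "full_stratum"
    out_dir: str | None = None
    include_censored: bool = False
    require_followup_day: bool = True
    stratum_mode: str = "participant"
    window_days: int = 30

    def __post_init__(self):
        sources = sum(x is not None for x in (self.diary, self.diary_csv, self.simulation))
        if sources != 1:
            raise ValueError("supply exactly one of diary, diary_csv or simulation")
        self.definitions = tuple(FlareDefinition(d) for d in self.definitions)


@dataclass
class AnalysisBundle:
    """Everything one run produces, keyed by flare definition value."""

    included: list
    exclusion_log: pd.DataFrame
    flares: pd.DataFrame
    flare_summary: pd.DataFrame
    windows: pd.DataFrame
    disposition: pd.DataFrame
    results: pd.DataFrame
    fits: dict = field(default_factory=dict)
    notices: list = field(default_factory=list)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.exclusion_log.to_csv(out / "exclusions.csv", index=False)
        self.flares.to_csv(out / "flares.csv", index=False)
        self.flare_summary.to_csv(out / "flare_summary.csv", index=False)
        self.windows.to_csv(out / "windows.csv", index=False)
        self.disposition.to_csv(out / "disposition.csv", index=False)
        self.results.to_csv(out / "results.csv", index=False)
        if self.notices:
            (out / "notices.txt").write_text("\n".join(self.notices) + "\n")


def _load_daily(config: RunConfig) -> pd.DataFrame:
    if config.diary is not None:
        daily = config.diary.copy()
        daily["date"] = pd.to_datetime(daily["date"]).dt.date
    elif config.diary_csv is not None:
        daily = read_daily_csv(config.diary_csv)
    else:
        daily, _ = generate_cohort(config.simulation)
    if config.epoch_csv is not None:
        epochs = acti.read_epoch_csv(config.epoch_csv)
        daily = acti.merge_into_daily(daily, acti.summarize_epochs(epochs))
    return daily


def build_windows_for_definition(
    included: list[ParticipantSeries],
    definition: FlareDefinition,
    mode: str,
    include_censored: bool = False,
    require_followup_day: bool = True,
):
    """Detect flares and enumerate windows/risk sets for one definition."""
    hazards_by_pid = {}
    controls_by_pid = {}
    all_windows = []
    for s in included:
        episodes = detect_flares(s, definition, include_censored=include_censored)
        kept = [e for e in episodes if not e.censored]
        hz = enumerate_hazard_windows(kept, s)
        ct = enumerate_control_windows(
            s, kept, hz, definition, mode=mode, require_followup_day=require_followup_day
        )
        if hz:
            hazards_by_pid[s.participant_id] = hz
        if ct:
            controls_by_pid[s.participant_id] = ct
        all_windows.extend(hz + ct)
    risk_sets, disposition = build_risk_sets(hazards_by_pid, controls_by_pid, definition)
    return risk_sets, windows_table(all_windows), disposition


def run_primary(config: RunConfig) -> AnalysisBundle:
    """The primary analysis: 24 univariable + 12 multivariable conditional
    logits per flare definition on full-stratum windows (or the mode set in
    ``config``)."""
    daily = _load_daily(config)
    series = build_series(daily)
    included, exclusion_log = apply_inclusion(series, window_days=config.window_days)
    if not included:
        raise ValueError("no participants pass the inclusion criteria")
    logger.info("included %d participants", len(included))

    flare_frames, summary_frames, window_frames, dispo_frames, result_frames = (
        [],
        [],
        [],
        [],
        [],
    )
    fits: dict = {}
    notices = []
    for definition in config.definitions:
        episodes_df, summary_df = summarize_flares(
            included, definition, include_censored=config.include_censored
        )
        flare_frames.append(episodes_df)
        summary_frames.append(summary_df)
        risk_sets, win_df, dispo = build_windows_for_definition(
            included,
            definition,
            config.mode,
            include_censored=config.include_censored,
            require_followup_day=config.require_followup_day,
        )
        window_frames.append(win_df)
        dispo_frames.append(dispo)
        if not risk_sets:
            notices.append(f"{definition.value}: no risk sets; models skipped")
            fits[definition.value] = []
            continue
        def_fits: list[FitResult] = []
        for spec in primary_model_specs(definition.value, config.mode):
            try:
                def_fits.append(fit(risk_sets, spec, stratum_mode=config.stratum_mode))
            except ValueError as err:
                notices.append(f"{definition.value}/{spec.exposure}/{spec.metrics}: {err}")
        fits[definition.value] = def_fits
        result_frames.append(or_table(def_fits))

    def _concat(frames):
        nonempty = [f for f in frames if len(f)]
        if not nonempty:
            return frames[0] if frames else pd.DataFrame()
        return pd.concat(nonempty, ignore_index=True)

    bundle = AnalysisBundle(
        included=included,
        exclusion_log=exclusion_log,
        flares=_concat(flare_frames),
        flare_summary=_concat(summary_frames),
        windows=_concat(window_frames),
        disposition=_concat(dispo_frames),
        results=_concat(result_frames),
        fits=fits,
        notices=notices,
    )
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle


def run_sensitivity(config: RunConfig) -> tuple[AnalysisBundle, AnalysisBundle, pd.DataFrame]:
    """Primary (full-stratum) and nonoverlap analyses side by side.

    Returns both bundles and a comparison table of OR and CI per model.
    """
    import dataclasses

    primary_cfg = dataclasses.replace(config, mode="full_stratum", out_dir=None)
    nonover_cfg = dataclasses.replace(config, mode="nonoverlap", out_dir=None)
    primary = run_primary(primary_cfg)
    nonover = run_primary(nonover_cfg)
    keys = ["definition", "exposure", "metric", "model_type"]
    cols = keys + ["or", "ci_low", "ci_high", "significant", "converged"]
    comparison = primary.results[cols].merge(
        nonover.results[cols], on=keys, suffixes=("_primary", "_nonoverlap")
    )
    if config.out_dir:
        out = Path(config.out_dir)
        primary.write(out / "primary")
        nonover.write(out / "nonoverlap")
        comparison.to_csv(out / "sensitivity_comparison.csv", index=False)
    return primary, nonover, comparison
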