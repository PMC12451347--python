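"""Pipeline orchestration, Table-2/Table-3-shaped outputs and small-cell
disclosure masking.

Stages run in a fixed order: cohort filters -> windows & follow-up ->
quality metrics -> outcome incidence -> period model -> masked report
tables.  Count cells with 0 < value < 10 are masked (displayed ``<10``);
within a row whose cells sum to a published total, a single masked cell
would be back-calculable, so the next-smallest cell is co-masked
(displayed ``masked``).  Zero counts are not disclosive and stay visible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calendars import DEFAULT_RAMADAN_CALENDAR, load_calendar
from .cohort import apply_filters
from .io import read_tables, write_results
from .outcomes import incidence_table
from .period_model import fit_period_model, summarize_metric
from .quality import QualityConfig, compute_window_quality
from .simulate import PRESETS, SimulationConfig, generate_cohort
from .windows import build_windows, compute_follow_up, subjects_at_risk

MASK_THRESHOLD = 10
MASK_STRING = "<10"
COMASK_STRING = "masked"

#: Continuous metrics modelled across windows by default.
DEFAULT_MODEL_METRICS = ("ttr", "tbr", "tar", "vgr", "prop_in", "prop_below", "prop_above")
FLAG_METRICS = ("dose_increase_flag", "dose_reduction_flag", "switched_vka_type", "switched_doac")
SUMMARY_METRICS = DEFAULT_MODEL_METRICS + (
    "median_inr", "mean_inr", "median_interval_days", "n_inr",
    "prop_ge5", "prop_ge8", "median_dose", "mean_dose",
)


def mask_small_cells(
    counts: pd.DataFrame,
    threshold: int = MASK_THRESHOLD,
    row_totals_published: bool = True,
) -> pd.DataFrame:
    """Disclosure-mask a table of integer count cells.

    Cells in (0, threshold) display ``<10``; when a row's total is
    published and exactly one cell of that row is masked, the
    next-smallest cell is additionally masked to block back-calculation.
    Returns a table of display strings.
    """
    out = counts.astype(object).copy()
    for ridx in counts.index:
        values = counts.loc[ridx]
        masked = [c for c in counts.columns if 0 < values[c] < threshold]
        for c in masked:
            out.loc[ridx, c] = MASK_STRING
        if row_totals_published and len(masked) == 1:
            rest = [
                (values[c], c)
                for c in counts.columns
                if c not in masked and values[c] > 0
            ]
            if rest:
                _, comask_col = min(rest)
                out.loc[ridx, comask_col] = COMASK_STRING
    for ridx in counts.index:
        for c in counts.columns:
            if not isinstance(out.loc[ridx, c], str):
                out.loc[ridx, c] = str(int(counts.loc[ridx, c]))
    return out


@dataclass
class PipelineConfig:
    """Inputs and switches for one end-to-end run."""

    simulate: bool = False
    preset: str | None = None
    simulation: SimulationConfig | None = None
    subjects_path: str | None = None
    inr_path: str | None = None
    events_path: str | None = None
    calendar: dict = field(default_factory=lambda: dict(DEFAULT_RAMADAN_CALENDAR))
    quality: QualityConfig = field(default_factory=QualityConfig)
    model_metrics: tuple = DEFAULT_MODEL_METRICS
    mask: bool = True
    seed: int = 0


def load_pipeline_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file.

    Recognised top-level keys: ``simulate`` (bool), ``preset``,
    ``simulation`` (SimulationConfig fields), ``paths``
    (subjects/inr/events), ``calendar_file``, ``quality`` (QualityConfig
    fields), ``model_metrics``, ``mask``, ``seed``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    cfg.simulate = bool(raw.get("simulate", False))
    cfg.preset = raw.get("preset")
    cfg.seed = int(raw.get("seed", 0))
    if "simulation" in raw:
        cfg.simulation = SimulationConfig(**raw["simulation"])
    paths = raw.get("paths", {})
    cfg.subjects_path = paths.get("subjects")
    cfg.inr_path = paths.get("inr")
    cfg.events_path = paths.get("events")
    if "calendar_file" in raw:
        cfg.calendar = load_calendar(raw["calendar_file"])
    if "quality" in raw:
        cfg.quality = QualityConfig(**raw["quality"])
    if "model_metrics" in raw:
        cfg.model_metrics = tuple(raw["model_metrics"])
    cfg.mask = bool(raw.get("mask", True))
    return cfg


def _resolve_simulation(config: PipelineConfig) -> SimulationConfig:
    if config.simulation is not None:
        sim = config.simulation
    elif config.preset is not None:
        sim = PRESETS[config.preset](seed=config.seed, calendar=dict(config.calendar))
    else:
        sim = SimulationConfig(seed=config.seed, calendar=dict(config.calendar))
    return sim


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(
        {
            "simulate": config.simulate,
            "preset": config.preset,
            "simulation": repr(config.simulation),
            "paths": [config.subjects_path, config.inr_path, config.events_path],
            "calendar": {y: [str(s), str(e)] for y, (s, e) in sorted(config.calendar.items())},
            "quality": repr(config.quality),
            "model_metrics": list(config.model_metrics),
            "mask": config.mask,
            "seed": config.seed,
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Run the full analysis; returns the result tables (and writes them).

    Raises with the failing stage's name on any stage error.  Output is
    fully determined by the config and seed.
    """
    log: list[str] = [f"config_hash={_config_hash(config)}", f"seed={config.seed}"]
    results: dict[str, pd.DataFrame] = {}

    stage = "load"
    try:
        if config.simulate:
            sim = _resolve_simulation(config)
            subjects, inr, events = generate_cohort(sim)
            log.append(f"simulated n_subjects={len(subjects)} preset={config.preset}")
        else:
            for name, p in (
                ("subjects", config.subjects_path),
                ("inr", config.inr_path),
                ("events", config.events_path),
            ):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"missing input file for {name!r}: {p}")
            subjects, inr, events, _ = read_tables(
                config.subjects_path, config.inr_path, config.events_path
            )
        log.append(f"rows: subjects={len(subjects)} inr={len(inr)} events={len(events)}")

        stage = "cohort"
        included, flow, reasons = apply_filters(subjects)
        results["cohort_flow"] = flow
        log.append(f"included={len(included)}")

        stage = "windows"
        windows_by_subject = {}
        follow_ups = []
        events_by_subject = {
            sid: list(zip(g["date"], g["event_class"])) for sid, g in events.groupby("subject_id")
        }
        for s in included:
            year = s.covariates.get("year")
            if year is None:
                raise ValueError(f"subject {s.subject_id}: no calendar year")
            wins = build_windows(*config.calendar[int(year)])
            windows_by_subject[s.subject_id] = wins
            follow_ups.append(
                compute_follow_up(s, events_by_subject.get(s.subject_id, []), wins)
            )
        results["follow_up"] = pd.DataFrame(
            {
                "subject_id": [f.subject_id for f in follow_ups],
                "entry": [f.entry for f in follow_ups],
                "exit": [f.exit for f in follow_ups],
                "exit_reason": [f.exit_reason for f in follow_ups],
            }
        )

        stage = "quality"
        quality = compute_window_quality(
            included, inr, follow_ups, windows_by_subject, config=config.quality
        )
        results["window_quality"] = quality
        log.append(f"quality rows={len(quality)} eligible={int(quality['eligible'].sum())}")

        stage = "summary"
        summaries = []
        for metric in SUMMARY_METRICS:
            s = summarize_metric(quality[quality["eligible"]], value_col=metric)
            s.insert(0, "metric", metric)
            summaries.append(s)
        results["quality_summary"] = pd.concat(summaries, ignore_index=True)
        results["flag_summary"] = _flag_summary(quality, mask=config.mask)

        stage = "outcomes"
        # windows per included subject can differ by calendar year; pool by
        # window index using each subject's own window dates
        results["incidence"] = _pooled_incidence(
            included, follow_ups, events, windows_by_subject, mask=config.mask
        )

        stage = "period_model"
        effect_frames = []
        eligible = quality[quality["eligible"]]
        for metric in config.model_metrics:
            res = fit_period_model(eligible, value_col=metric, metric=metric)
            eff = res.effects.copy()
            eff.insert(0, "metric", metric)
            eff["var_subject"] = res.var_subject
            eff["var_residual"] = res.var_residual
            eff["converged"] = res.converged
            effect_frames.append(eff)
        results["period_effects"] = pd.concat(effect_frames, ignore_index=True)

        stage = "write"
        if out_dir is not None:
            write_results(results, out_dir)
            log_path = Path(out_dir) / "run.log"
            log_path.write_text("\n".join(log) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    results["log"] = log
    return results


def _flag_summary(quality: pd.DataFrame, mask: bool) -> pd.DataFrame:
    rows = []
    eligible = quality[quality["eligible"]]
    for metric in FLAG_METRICS:
        for window, g in eligible.groupby("window"):
            gcol = g[metric]
            n_assessed = int(gcol.notna().sum())
            n_flagged = int((gcol == True).sum())  # noqa: E712 - boolean dtype w/ NA
            rows.append(
                {
                    "metric": metric,
                    "window": window,
                    "n_assessed": n_assessed,
                    "n_flagged": n_flagged,
                    "pct": 100.0 * n_flagged / n_assessed if n_assessed else np.nan,
                }
            )
    df = pd.DataFrame(rows)
    if mask and len(df):
        wide = df.pivot(index="metric", columns="window", values="n_flagged").fillna(0).astype(int)
        display = mask_small_cells(wide)
        df["n_flagged_display"] = [
            display.loc[m, w] for m, w in zip(df["metric"], df["window"])
        ]
        hide = df["n_flagged_display"] != df["n_flagged"].astype(str)
        df["n_flagged"] = df["n_flagged"].astype(object)
        df.loc[hide, "pct"] = np.nan
        df.loc[hide, "n_flagged"] = None
    else:
        df["n_flagged_display"] = df["n_flagged"].astype(str)
    return df


def _pooled_incidence(included, follow_ups, events, windows_by_subject, mask: bool) -> pd.DataFrame:
    # Shift every subject onto its own window clock by building per-index
    # pseudo-windows; incidence_table needs concrete dates, so group
    # subjects by calendar year and concatenate the risk sets.
    from .outcomes import OUTCOME_CLASSES, cuminc_30d, incidence_rate, km_mortality, person_time, window_risk_set

    fu_by_id = {f.subject_id: f for f in follow_ups}
    rows = []
    for w_i in (-2, -1, 0, 1, 2):
        risk_parts = []
        by_year: dict[int, list] = {}
        for s in included:
            by_year.setdefault(s.covariates["year"], []).append(s)
        for year, subs in sorted(by_year.items()):
            window = windows_by_subject[subs[0].subject_id][w_i + 2]
            fus = [fu_by_id[s.subject_id] for s in subs]
            ids = {s.subject_id for s in subs}
            ev = events[events["subject_id"].isin(ids)]
            risk_parts.append(window_risk_set(fus, ev, window))
        risk = pd.concat(risk_parts, ignore_index=True) if risk_parts else pd.DataFrame(
            columns=["subject_id", "duration", "event_class"]
        )
        n_at_risk = len(risk)
        durations = risk["duration"].to_numpy(dtype=float)
        pt = person_time(durations)
        for outcome, classes in OUTCOME_CLASSES.items():
            if n_at_risk == 0:
                rows.append(
                    dict(window=w_i, outcome=outcome, n_at_risk=0, n_events=0,
                         person_years=0.0, ir=np.nan, ir_low=np.nan, ir_high=np.nan,
                         cuminc_per1000=np.nan, cuminc_low=np.nan, cuminc_high=np.nan)
                )
                continue
            is_target = risk["event_class"].isin(classes).to_numpy()
            if outcome == "mortality":
                ci = km_mortality(durations, is_target.astype(int))
            else:
                status = np.zeros(n_at_risk, dtype=int)
                status[risk["event_class"].notna().to_numpy()] = 2
                status[is_target] = 1
                ci = cuminc_30d(durations, status)
            x = int(is_target.sum())
            ir, ir_low, ir_high = incidence_rate(x, pt)
            rows.append(
                dict(window=w_i, outcome=outcome, n_at_risk=n_at_risk, n_events=x,
                     person_years=pt, ir=ir, ir_low=ir_low, ir_high=ir_high,
                     cuminc_per1000=1000.0 * ci.point, cuminc_low=1000.0 * ci.ci_low,
                     cuminc_high=1000.0 * ci.ci_high)
            )
    df = pd.DataFrame(rows)
    if mask and len(df):
        wide = df.pivot(index="outcome", columns="window", values="n_events").astype(int)
        display = mask_small_cells(wide)
        df["n_events_display"] = [
            display.loc[o, w] for o, w in zip(df["outcome"], df["window"])
        ]
        hide = df["n_events_display"] != df["n_events"].astype(str)
        df["n_events"] = df["n_events"].astype(object)
        for col in ("ir", "ir_low", "ir_high", "cuminc_per1000", "cuminc_low", "cuminc_high"):
            df.loc[hide, col] = np.nan
        df.loc[hide, "n_events"] = None
    else:
        df["n_events_display"] = df["n_events"].astype(str)
    return df
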