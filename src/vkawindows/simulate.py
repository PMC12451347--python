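"""Synthetic VKA cohort generator.

Emulates the statistical structure the windowed analysis assumes, so every
stage runs without any registry access: feedback-dosed longitudinal INR
trajectories on a realistic visit schedule (lognormal intervals, median
~16 days), therapeutic target ranges 2.0-3.0 / 2.5-3.5 / 3.0-4.0, rare
competing clinical events (composite ~5 per 1000 per 30 days), death, DOAC
switching and VKA discontinuation, and an optional additive INR shift
``ramadan_inr_shift`` applied to measurements dated inside the Ramadan
window (window 0) for end-to-end effect recovery.

Generative model per subject i, visit k:

    INR_ik = mid_i + b_i + delta * 1[date in window 0] + d_ik,
    d_ik   = d_i,k-1 * exp(-ln2 * dt / halflife) + N(0, s^2 (1 - rho^2)),

an AR(1)/OU deviation with stationary SD ``inr_within_sd``; b_i ~
N(0, inr_between_sd^2); observations are floored at 0.8 (physiological
minimum).  The marginal measurement distribution is therefore
N(mid + delta*1[w0], sqrt(between^2 + within^2)) - the closed form used by
the recovery tests.  The injected shift enters the measurement mean
directly, so it is fully expressed from the first window-0 visit.

Dosing: the recommended average daily dose (tablets/day) starts lognormal
and, at each visit whose observed INR lies outside the target range, is
multiplied by (1 -/+ step) with probability ``dose_adjust_prob``, step ~
U(dose_step_min, dose_step_max) >= 10% so adjustments are clinically
relevant by construction.

Randomness: one root seed; each subject draws from a counter-based
substream ``default_rng([seed, i])`` so changing ``n_subjects`` never
reshuffles existing subjects and a fixed seed reproduces files byte for
byte.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._types import EventRecord, Subject, VkaEpisode
from .calendars import DEFAULT_RAMADAN_CALENDAR, validate_calendar
from .io import write_cohort

HORIZON_DAYS = 150  # d0 .. d5
HISTORY_DAYS = 90  # pre-d0 visit history


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Event hazards are expressed as 30-day risks (probability of the event
    within 30 days under the constant hazard); ``doac_switch_30d`` and
    ``discontinuation_30d`` likewise.
    """

    n_subjects: int = 3835
    seed: int = 0
    cohort_label: str = "synthetic"
    calendar: dict = field(default_factory=lambda: dict(DEFAULT_RAMADAN_CALENDAR))

    # visit schedule
    visit_interval_median_days: float = 16.0
    visit_interval_log_sd: float = 0.55

    # INR process
    target_range_probs: tuple = (
        ((2.0, 3.0), 0.43),
        ((2.5, 3.5), 0.465),
        ((3.0, 4.0), 0.105),
    )
    inr_between_sd: float = 0.30
    inr_within_sd: float = 0.55
    inr_halflife_days: float = 5.0
    inr_floor: float = 0.8
    ramadan_inr_shift: float = 0.0

    # dosing feedback
    dose_median_tablets: float = 2.0
    dose_log_sd: float = 0.5
    dose_adjust_prob: float = 0.12
    dose_step_min: float = 0.10
    dose_step_max: float = 0.20

    # events / censoring (30-day risks)
    hazard_bleeding_30d: float = 0.0020
    hazard_arterial_30d: float = 0.0020
    hazard_venous_30d: float = 0.0008
    hazard_death_30d: float = 0.0050
    doac_switch_30d: float = 0.003
    discontinuation_30d: float = 0.004

    # fractions of subjects constructed to fail the cohort filters
    p_recent_start: float = 0.02
    p_missing_target: float = 0.01
    p_doac_prior: float = 0.01

    acenocoumarol_prob: float = 0.82

    def __post_init__(self):
        probs = [p for _, p in self.target_range_probs]
        if abs(sum(probs)) == 0 or any(p < 0 for p in probs):
            raise ValueError("target range probabilities must be non-negative")
        for name in (
            "hazard_bleeding_30d", "hazard_arterial_30d", "hazard_venous_30d",
            "hazard_death_30d", "doac_switch_30d", "discontinuation_30d",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        validate_calendar(self.calendar)


def null_preset(**overrides) -> SimulationConfig:
    """Stationary no-shift conditions (the negative-control cohort)."""
    return SimulationConfig(ramadan_inr_shift=0.0, cohort_label="null", **overrides)


def ramadan_shift_preset(shift: float = 0.3, **overrides) -> SimulationConfig:
    """Additive INR shift during the Ramadan window."""
    return SimulationConfig(
        ramadan_inr_shift=shift, cohort_label="ramadan-shift", **overrides
    )


PRESETS = {"null": null_preset, "ramadan-shift": ramadan_shift_preset}


def rate_per_day(risk_30d: float) -> float:
    """Constant daily hazard matching a 30-day risk."""
    if risk_30d <= 0:
        return 0.0
    return -math.log1p(-risk_30d) / 30.0


def _draw_exponential_day(rng: np.random.Generator, risk_30d: float) -> float:
    rate = rate_per_day(risk_30d)
    if rate == 0.0:
        return math.inf
    return float(rng.exponential(1.0 / rate))


def simulate_schedule(rng: np.random.Generator, config: SimulationConfig, stop_day: float):
    """Visit days relative to d0, from -HISTORY_DAYS until ``stop_day``."""
    mu = math.log(config.visit_interval_median_days)
    sigma = config.visit_interval_log_sd
    days = []
    t = -HISTORY_DAYS + float(rng.uniform(0, config.visit_interval_median_days))
    while t < stop_day:
        days.append(round(t))
        gap = max(1.0, round(float(rng.lognormal(mu, sigma))))
        t += gap
    # deduplicate after rounding (same-day repeats are forbidden at ingest)
    out = []
    for d in days:
        if not out or d > out[-1]:
            out.append(d)
    return np.array(out, dtype=float)


def simulate_inr_trajectory(
    schedule,
    target_low: float,
    target_high: float,
    rng: np.random.Generator,
    config: SimulationConfig,
    subject_offset: float = 0.0,
    ramadan_interval: tuple[float, float] = (60.0, 90.0),
    dose0: float | None = None,
):
    """Simulate observed INRs and recommended doses along a visit schedule.

    ``schedule`` holds visit days relative to d0; the Ramadan window covers
    ``ramadan_interval`` on the same axis.  Returns ``(inr, dose)`` arrays.
    With all noise parameters zero every observed INR equals the target
    midpoint (plus the shift inside the Ramadan window).
    """
    schedule = np.asarray(schedule, dtype=float)
    n = schedule.size
    mid = 0.5 * (target_low + target_high)
    theta = math.log(2.0) / config.inr_halflife_days
    s = config.inr_within_sd

    inr = np.empty(n)
    dose = np.empty(n)
    if dose0 is None:
        dose0 = float(
            np.exp(rng.normal(math.log(config.dose_median_tablets), config.dose_log_sd))
        )
    current_dose = dose0
    dev = float(rng.normal(0.0, s)) if s > 0 else 0.0
    for k in range(n):
        if k > 0:
            rho = math.exp(-theta * (schedule[k] - schedule[k - 1]))
            innov_sd = s * math.sqrt(max(0.0, 1.0 - rho * rho))
            dev = dev * rho + (float(rng.normal(0.0, innov_sd)) if innov_sd > 0 else 0.0)
        shift = (
            config.ramadan_inr_shift
            if ramadan_interval[0] <= schedule[k] < ramadan_interval[1]
            else 0.0
        )
        obs = mid + subject_offset + shift + dev
        inr[k] = max(config.inr_floor, obs)
        # dose recommendation issued at this visit, in response to its INR
        if inr[k] > target_high and rng.uniform() < config.dose_adjust_prob:
            current_dose *= 1.0 - rng.uniform(config.dose_step_min, config.dose_step_max)
        elif inr[k] < target_low and rng.uniform() < config.dose_adjust_prob:
            current_dose *= 1.0 + rng.uniform(config.dose_step_min, config.dose_step_max)
        dose[k] = current_dose
    return inr, dose


def simulate_events(rng: np.random.Generator, config: SimulationConfig):
    """Draw competing event days (relative to d0) over the follow-up horizon.

    Exponential first-event times per class; death competes (events after
    the death day do not exist).  Returns a list of ``(day, event_class)``.
    """
    class_risks = {
        "major_bleeding": config.hazard_bleeding_30d,
        "ischemic_stroke": config.hazard_arterial_30d,
        "venous_te": config.hazard_venous_30d,
    }
    death_day = _draw_exponential_day(rng, config.hazard_death_30d)
    out = []
    for event_class, risk in class_risks.items():
        t = _draw_exponential_day(rng, risk)
        if t < min(HORIZON_DAYS, death_day):
            out.append((int(math.floor(t)), event_class))
    if death_day < HORIZON_DAYS:
        out.append((int(math.floor(death_day)), "death"))
    out.sort()
    return out


def _choose(rng, pairs):
    values = [v for v, _ in pairs]
    probs = np.array([p for _, p in pairs], dtype=float)
    probs = probs / probs.sum()
    return values[int(rng.choice(len(values), p=probs))]


def generate_cohort(config: SimulationConfig):
    """Generate ``(subjects, inr, events)`` for one synthetic cohort.

    Output passes core_io validation; the configured fractions of subjects
    fail the cohort inclusion/exclusion rules (recent treatment start,
    missing target range, prior DOAC dispensing).  Fixed seed => identical
    output.
    """
    years = sorted(config.calendar)
    subjects: list[Subject] = []
    inr_frames = []
    event_rows = []
    for i in range(config.n_subjects):
        rng = np.random.default_rng([int(config.seed), i])
        sid = f"S{i:06d}"
        year = years[int(rng.integers(len(years)))]
        ramadan_start, _ = config.calendar[year]
        d0 = ramadan_start - dt.timedelta(days=60)

        age = float(np.clip(rng.normal(66.0, 12.0), 18.0, 95.0))
        vka_type = (
            "acenocoumarol" if rng.uniform() < config.acenocoumarol_prob else "phenprocoumon"
        )
        if rng.uniform() < config.p_recent_start:
            episode_start = d0 - dt.timedelta(days=int(rng.integers(5, 56)))
        else:
            episode_start = d0 - dt.timedelta(days=int(rng.integers(61, 1200)))

        target = _choose(rng, list(config.target_range_probs))
        if rng.uniform() < config.p_missing_target:
            target = None

        disc_day = _draw_exponential_day(rng, config.discontinuation_30d)
        doac_day = _draw_exponential_day(rng, config.doac_switch_30d)
        episode_end = (
            d0 + dt.timedelta(days=int(math.floor(disc_day)))
            if disc_day < HORIZON_DAYS
            else None
        )

        doac_dispensings = []
        if doac_day < HORIZON_DAYS:
            doac_dispensings.append(d0 + dt.timedelta(days=int(math.floor(doac_day))))
        if rng.uniform() < config.p_doac_prior:
            doac_dispensings.insert(0, d0 - dt.timedelta(days=int(rng.integers(1, 180))))

        vka_dispensings = []
        disp = episode_start
        disp_stop = d0 + dt.timedelta(days=HORIZON_DAYS)
        while disp < disp_stop:
            vka_dispensings.append(disp)
            disp = disp + dt.timedelta(days=int(90 + rng.integers(-10, 11)))

        stop_day = min(HORIZON_DAYS, disc_day, doac_day)
        schedule = simulate_schedule(rng, config, stop_day)
        schedule = schedule[schedule >= -(d0 - episode_start).days]
        lo, hi = target if target is not None else (2.0, 3.0)
        b_i = float(rng.normal(0.0, config.inr_between_sd)) if config.inr_between_sd > 0 else 0.0
        inr_vals, dose_vals = simulate_inr_trajectory(
            schedule, lo, hi, rng, config, subject_offset=b_i
        )
        if schedule.size:
            dates = [d0 + dt.timedelta(days=int(d)) for d in schedule]
            inr_frames.append(
                pd.DataFrame(
                    {
                        "subject_id": sid,
                        "date": dates,
                        "inr": np.round(inr_vals, 6),
                        "target_low": lo if target is not None else np.nan,
                        "target_high": hi if target is not None else np.nan,
                        "dose": np.round(dose_vals, 4),
                    }
                )
            )

        for day, event_class in simulate_events(rng, config):
            event_rows.append(
                {
                    "subject_id": sid,
                    "date": d0 + dt.timedelta(days=day),
                    "event_class": event_class,
                }
            )

        subjects.append(
            Subject(
                subject_id=sid,
                cohort_label=config.cohort_label,
                anchor_d0=d0,
                age_at_d0=round(age, 1),
                vka_episodes=[VkaEpisode(episode_start, episode_end, vka_type)],
                target_range_at_d0=target,
                doac_dispensings=doac_dispensings,
                vka_dispensings=vka_dispensings,
                covariates={"year": year},
            )
        )

    inr = (
        pd.concat(inr_frames, ignore_index=True)
        if inr_frames
        else pd.DataFrame(columns=["subject_id", "date", "inr", "target_low", "target_high", "dose"])
    )
    events = pd.DataFrame(event_rows, columns=["subject_id", "date", "event_class"])
    return subjects, inr, events


def generate_cohort_files(config: SimulationConfig, out_dir):
    """Generate a cohort and write the three canonical CSVs."""
    subjects, inr, events = generate_cohort(config)
    return write_cohort(subjects, inr, events, out_dir)
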