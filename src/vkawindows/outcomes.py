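"""Per-window clinical-event risk estimation.

Each 30-day observation window restarts the clock at its start with the
subjects still in follow-up as the risk set.  For a given outcome, the
30-day cumulative incidence is the Aalen-Johansen estimator treating the
other event classes and death as competing risks; with zero censoring and
zero competing events before day 30 it reduces exactly to events/at-risk.
All-cause mortality uses the Kaplan-Meier complement with a
Greenwood-variance interval.  Incidence rates are first events divided by
person-time, with exact Poisson (chi-squared quantile) 95% CIs.

The Aalen-Johansen and Kaplan-Meier fits delegate to lifelines;
point-estimate CIs for the cumulative incidence are on the
complementary-log-log scale, which respects the [0, 1] boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import AalenJohansenFitter, KaplanMeierFitter
from scipy import stats

from ._types import (
    ARTERIAL_TE_CLASSES,
    BLEEDING_CLASSES,
    COMPOSITE_CLASSES,
    WINDOW_DAYS,
    ObservationWindow,
)
from .windows import at_risk_at

DAYS_PER_YEAR = 365.25
Z95 = stats.norm.ppf(0.975)

#: Outcome definitions as sets of event classes ("mortality" is the
#: Kaplan-Meier outcome, everything else Aalen-Johansen with competing
#: events and death).
OUTCOME_CLASSES = {
    "composite": frozenset(COMPOSITE_CLASSES),
    "bleeding": frozenset(BLEEDING_CLASSES),
    "arterial_te": frozenset(ARTERIAL_TE_CLASSES),
    "mortality": frozenset({"death"}),
}


@dataclass(frozen=True)
class CumulativeIncidence:
    point: float  # probability scale
    ci_low: float
    ci_high: float


def _cll_interval(point: float, variance: float) -> tuple[float, float]:
    """95% CI for a probability via the complementary-log-log transform."""
    if point <= 0.0:
        return 0.0, np.nan
    if point >= 1.0:
        return np.nan, 1.0
    se = np.sqrt(max(variance, 0.0)) / (point * abs(np.log(point)))
    return float(point ** np.exp(Z95 * se)), float(point ** np.exp(-Z95 * se))


def cuminc_30d(
    durations, statuses, horizon: float = WINDOW_DAYS, jitter_seed: int = 12345
) -> CumulativeIncidence | None:
    """Aalen-Johansen cumulative incidence of the target class at the horizon.

    ``statuses``: 0 = censored, 1 = target event, 2 = competing event (any
    other clinical event or death).  Returns ``None`` for an empty risk
    set.  Tied event times are broken by lifelines' deterministic jitter
    (fixed seed), which leaves the estimate unchanged at the horizon.
    """
    durations = np.asarray(durations, dtype=float)
    statuses = np.asarray(statuses, dtype=int)
    if durations.size == 0:
        return None
    if not np.any(statuses == 1):
        return CumulativeIncidence(0.0, 0.0, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fitter = AalenJohansenFitter(calculate_variance=True, seed=jitter_seed)
        fitter.fit(durations, statuses, event_of_interest=1)
    cif = fitter.cumulative_density_.iloc[:, 0]
    var = fitter.variance_
    mask = np.asarray(cif.index, dtype=float) <= horizon + 1e-9
    if not mask.any():
        return CumulativeIncidence(0.0, 0.0, np.nan)
    point = float(cif.to_numpy()[mask][-1])
    variance = float(var.to_numpy()[mask][-1])
    low, high = _cll_interval(point, variance)
    return CumulativeIncidence(point, low, high)


def km_mortality(durations, death_observed, horizon: float = WINDOW_DAYS) -> CumulativeIncidence | None:
    """30-day cumulative all-cause mortality, 1 - Kaplan-Meier survival."""
    durations = np.asarray(durations, dtype=float)
    death_observed = np.asarray(death_observed, dtype=int)
    if durations.size == 0:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        km = KaplanMeierFitter().fit(durations, death_observed)
    times = np.asarray(km.survival_function_.index, dtype=float)
    mask = times <= horizon + 1e-9
    point = 1.0 - float(km.survival_function_.iloc[:, 0].to_numpy()[mask][-1])
    ci = km.confidence_interval_
    low = 1.0 - float(ci.iloc[:, 1].to_numpy()[mask][-1])
    high = 1.0 - float(ci.iloc[:, 0].to_numpy()[mask][-1])
    return CumulativeIncidence(point, low, high)


def incidence_rate(x: int, person_years: float) -> tuple[float, float, float]:
    """Incidence rate per 100 person-years with exact chi-squared 95% CI.

    IR = 100 x / T; CI bounds are chi-squared quantiles
    (chi2(0.025, 2x)/2T, chi2(0.975, 2x+2)/2T) x 100, lower bound 0 when
    x = 0.
    """
    if person_years <= 0:
        raise ValueError("person-time must be positive")
    if x < 0 or int(x) != x:
        raise ValueError("event count must be a non-negative integer")
    ir = 100.0 * x / person_years
    low = 0.0 if x == 0 else 100.0 * stats.chi2.ppf(0.025, 2 * x) / 2.0 / person_years
    high = 100.0 * stats.chi2.ppf(0.975, 2 * x + 2) / 2.0 / person_years
    return ir, float(low), float(high)


def person_time(durations_days) -> float:
    """Total at-risk time in years (365.25 days/year)."""
    return float(np.sum(np.asarray(durations_days, dtype=float))) / DAYS_PER_YEAR


def window_risk_set(
    follow_ups, events: pd.DataFrame, window: ObservationWindow
) -> pd.DataFrame:
    """Duration and terminal event class for each subject at risk.

    Durations restart at the window start and are truncated at the window
    end; a clinical event or death on the window's first day contributes
    half a day.  ``event_class`` is the class of the event terminating
    follow-up inside the window, else None (censored or administratively
    truncated).
    """
    ev_at_exit: dict[str, str] = {}
    if len(events):
        for row in events.itertuples(index=False):
            key = (row.subject_id, row.date)
            ev_at_exit.setdefault(key, row.event_class)
    rows = []
    for fu in follow_ups:
        if not at_risk_at(fu, window.start):
            continue
        duration = min((fu.exit - window.start).days, WINDOW_DAYS)
        event_class = None
        if fu.exit_reason in ("clinical_event", "death") and window.start <= fu.exit < window.end:
            event_class = ev_at_exit.get((fu.subject_id, fu.exit))
            if event_class is None and fu.exit_reason == "death":
                event_class = "death"
            duration = max(duration, 0.5)
        else:
            duration = max(duration, 0.0)
        rows.append(
            {
                "subject_id": fu.subject_id,
                "duration": float(duration),
                "event_class": event_class,
            }
        )
    return pd.DataFrame(rows, columns=["subject_id", "duration", "event_class"])


def incidence_table(follow_ups, events: pd.DataFrame, windows) -> pd.DataFrame:
    """Per-window, per-outcome incidence estimates (Table-3 shape).

    Columns: window, outcome, n_at_risk, n_events, person_years, ir per
    100 PY with CI, and 30-day cumulative incidence per 1000 with CI.
    """
    rows = []
    for window in windows:
        risk = window_risk_set(follow_ups, events, window)
        n_at_risk = len(risk)
        durations = risk["duration"].to_numpy(dtype=float)
        pt = person_time(durations)
        for outcome, classes in OUTCOME_CLASSES.items():
            if n_at_risk == 0:
                rows.append(
                    dict(
                        window=window.index, outcome=outcome, n_at_risk=0, n_events=0,
                        person_years=0.0, ir=np.nan, ir_low=np.nan, ir_high=np.nan,
                        cuminc_per1000=np.nan, cuminc_low=np.nan, cuminc_high=np.nan,
                    )
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
                dict(
                    window=window.index, outcome=outcome, n_at_risk=n_at_risk,
                    n_events=x, person_years=pt, ir=ir, ir_low=ir_low, ir_high=ir_high,
                    cuminc_per1000=1000.0 * ci.point,
                    cuminc_low=1000.0 * ci.ci_low,
                    cuminc_high=1000.0 * ci.ci_high,
                )
            )
    return pd.DataFrame(rows)
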