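"""Competing-risks incidence, Kaplan-Meier mortality and Poisson rates.

The product-limit oracles here are independent step-by-step computations
over the ordered event times, not calls into the estimation path.
"""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from vkawindows import (
    build_windows,
    compute_follow_up,
    cuminc_30d,
    incidence_rate,
    km_mortality,
    person_time,
    window_risk_set,
)
from vkawindows.outcomes import incidence_table

from conftest import D0_2016, RAMADAN_2016, make_subject


def hand_aalen_johansen(durations, statuses, horizon):
    """Step-by-step product-sum: CIF(t) = sum S(t_i-) d1_i / n_i."""
    order = np.argsort(durations, kind="stable")
    durations = np.asarray(durations, float)[order]
    statuses = np.asarray(statuses, int)[order]
    n = len(durations)
    surv = 1.0
    cif = 0.0
    for t in np.unique(durations[statuses > 0]):
        if t > horizon:
            break
        at_risk = np.sum(durations >= t)
        d_target = np.sum((durations == t) & (statuses == 1))
        d_all = np.sum((durations == t) & (statuses > 0))
        cif += surv * d_target / at_risk
        surv *= 1.0 - d_all / at_risk
    return cif


def hand_km(durations, observed, horizon):
    order = np.argsort(durations, kind="stable")
    durations = np.asarray(durations, float)[order]
    observed = np.asarray(observed, int)[order]
    surv = 1.0
    for t in np.unique(durations[observed == 1]):
        if t > horizon:
            break
        at_risk = np.sum(durations >= t)
        d = np.sum((durations == t) & (observed == 1))
        surv *= 1.0 - d / at_risk
    return 1.0 - surv


class TestCumulativeIncidence:
    def test_no_censoring_no_competing_equals_events_over_at_risk(self):
        n, x = 3800, 20
        dur = np.full(n, 30.0)
        status = np.zeros(n, int)
        dur[:x] = np.linspace(1, 29, x)
        status[:x] = 1
        ci = cuminc_30d(dur, status)
        assert ci.point * 1000 == pytest.approx(1000 * x / n, abs=1e-9)
        assert ci.ci_low < ci.point < ci.ci_high

    def test_zero_events(self):
        ci = cuminc_30d([30.0] * 50, [0] * 50)
        assert ci.point == 0.0 and ci.ci_low == 0.0

    def test_empty_risk_set_is_missing(self):
        assert cuminc_30d([], []) is None

    def test_matches_hand_product_sum_with_censoring_and_competing_death(self):
        durations = [2, 5, 5, 8, 11, 14, 20, 25, 28, 30]
        statuses = [1, 0, 2, 1, 0, 2, 1, 0, 1, 0]
        ci = cuminc_30d(durations, statuses)
        expected = hand_aalen_johansen(durations, statuses, 30)
        assert ci.point == pytest.approx(expected, rel=1e-9)

    def test_class_cifs_and_survival_close_to_one(self):
        """Aalen-Johansen closure: CIF_1 + CIF_2 + overall survival = 1."""
        rng = np.random.default_rng(5)
        durations = rng.integers(1, 30, 40).astype(float)
        statuses = rng.integers(0, 3, 40)
        cif1 = hand_aalen_johansen(durations, statuses, 30)
        cif2 = hand_aalen_johansen(durations, 3 - np.where(statuses == 0, 3, statuses), 30)
        surv = 1.0
        for t in np.unique(durations[statuses > 0]):
            at_risk = np.sum(durations >= t)
            d = np.sum((durations == t) & (statuses > 0))
            surv *= 1 - d / at_risk
        assert cif1 + cif2 + surv == pytest.approx(1.0, abs=1e-12)
        assert cuminc_30d(durations, statuses).point == pytest.approx(cif1, rel=1e-9)


class TestKmMortality:
    def test_no_deaths(self):
        ci = km_mortality([30.0] * 20, [0] * 20)
        assert ci.point == 0.0

    def test_all_die_day_one(self):
        ci = km_mortality([1.0] * 5, [1] * 5)
        assert ci.point * 1000 == pytest.approx(1000.0)

    def test_matches_hand_product_limit_with_censoring(self):
        # 3 deaths among 10 with 2 earlier censorings
        durations = [3, 4, 6, 10, 12, 18, 22, 30, 30, 30]
        observed = [0, 1, 0, 1, 0, 1, 0, 0, 0, 0]
        ci = km_mortality(durations, observed)
        expected = hand_km(durations, observed, 30)
        # hand value: 1 - (8/9)(6/7)(4/5)
        assert expected == pytest.approx(1 - (8 / 9) * (6 / 7) * (4 / 5), rel=1e-12)
        assert ci.point == pytest.approx(expected, rel=1e-9)
        assert ci.ci_low < ci.point < ci.ci_high


class TestIncidenceRate:
    def test_zero_events(self):
        ir, lo, hi = incidence_rate(0, 50.0)
        assert (ir, lo) == (0.0, 0.0) and hi > 0

    def test_chi_squared_quantile_interval(self):
        ir, lo, hi = incidence_rate(10, 100.0)
        assert ir == pytest.approx(10.0)
        assert lo == pytest.approx(4.795, abs=5e-4)
        assert hi == pytest.approx(18.390, abs=5e-4)

    def test_doubling_events_and_time_narrows_relative_width(self):
        ir1, lo1, hi1 = incidence_rate(10, 100.0)
        ir2, lo2, hi2 = incidence_rate(20, 200.0)
        assert ir1 == ir2
        assert (hi2 - lo2) < (hi1 - lo1)

    def test_interval_contains_point(self):
        for x in (1, 3, 17):
            ir, lo, hi = incidence_rate(x, 7.3)
            assert lo <= ir <= hi

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            incidence_rate(1, 0.0)
        with pytest.raises(ValueError):
            incidence_rate(-1, 1.0)


class TestPersonTime:
    windows = build_windows(*RAMADAN_2016)

    def test_full_window_cohort(self):
        assert person_time([30.0] * 100) == pytest.approx(100 * 30 / 365.25)

    def test_partial_exit(self):
        assert person_time([15.0]) == pytest.approx(15 / 365.25)

    def test_window_person_time_sums_to_total_follow_up(self):
        subjects = [make_subject(f"S{i}") for i in range(20)]
        doac_day = D0_2016 + dt.timedelta(days=77)
        subjects.append(make_subject("X", doac_dispensings=[doac_day]))
        events = pd.DataFrame(
            {
                "subject_id": ["S0"],
                "date": [D0_2016 + dt.timedelta(days=100)],
                "event_class": ["major_bleeding"],
            }
        )
        fus = [
            compute_follow_up(
                s,
                [(d, c) for d, c in zip(events["date"], events["event_class"])
                 if s.subject_id == "S0"],
                self.windows,
            )
            for s in subjects
        ]
        total_days = sum((fu.exit - fu.entry).days for fu in fus)
        window_days = 0.0
        for w in self.windows:
            risk = window_risk_set(fus, events, w)
            window_days += risk["duration"].sum()
        assert window_days == pytest.approx(total_days)


def test_incidence_table_masks_nothing_and_reports_all_outcomes():
    windows = build_windows(*RAMADAN_2016)
    subjects = [make_subject(f"S{i}") for i in range(40)]
    events = pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(12)],
            "date": [D0_2016 + dt.timedelta(days=10 + i) for i in range(12)],
            "event_class": ["major_bleeding"] * 12,
        }
    )
    ev_lookup = {
        sid: list(zip(g["date"], g["event_class"])) for sid, g in events.groupby("subject_id")
    }
    fus = [compute_follow_up(s, ev_lookup.get(s.subject_id, []), windows) for s in subjects]
    table = incidence_table(fus, events, windows)
    assert set(table["outcome"]) == {"composite", "bleeding", "arterial_te", "mortality"}
    first = table[(table["window"] == -2) & (table["outcome"] == "bleeding")].iloc[0]
    assert first["n_at_risk"] == 40 and first["n_events"] == 12
    assert first["cuminc_per1000"] == pytest.approx(1000 * 12 / 40, abs=1e-6)
    later = table[(table["window"] == 0) & (table["outcome"] == "bleeding")].iloc[0]
    assert later["n_at_risk"] == 28 and later["n_events"] == 0
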