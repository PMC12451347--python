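"""Treatment-quality metrics: Rosendaal interpolation, VGR, proportions,
dose-change classification, eligibility and switch flags."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vkawindows import (
    QualityConfig,
    build_windows,
    classify_dose_change,
    compute_follow_up,
    compute_window_quality,
    inr_proportions,
    rosendaal,
    vgr,
)
from vkawindows.quality import monitoring_stats, switch_flags, window_eligibility

from conftest import D0_2016, RAMADAN_2016, make_subject


def grid_ttr(days, inrs, lo, hi, wstart, wend, exit_day=None, step_minutes=1.0):
    """Independent numerical oracle: classify a fine time grid."""
    days = np.asarray(days, float)
    inrs = np.asarray(inrs, float)
    cov_start = max(wstart, days[0])
    cov_end = min(wend, days[-1])
    if exit_day is not None:
        cov_end = min(cov_end, exit_day)
    if cov_end <= cov_start:
        return None
    step = step_minutes / (24 * 60)
    t = np.arange(cov_start + step / 2, cov_end, step)
    y = np.interp(t, days, inrs)
    below = np.mean(y < lo) * 100
    above = np.mean(y > hi) * 100
    return 100 - below - above, below, above


class TestRosendaal:
    def test_constant_in_range_inr_gives_full_ttr(self):
        assert rosendaal([0, 30], [2.5, 2.5], 2.0, 3.0, 0, 30) == (100.0, 0.0, 0.0)

    def test_rising_through_range_splits_at_crossing(self):
        ttr, tbr, tar = rosendaal([0, 10], [2.0, 4.0], 2.0, 3.0, 0, 10)
        assert (ttr, tbr, tar) == pytest.approx((50.0, 0.0, 50.0))

    def test_rising_from_below_splits_at_crossing(self):
        ttr, tbr, tar = rosendaal([0, 10], [1.0, 3.0], 2.0, 3.0, 0, 10)
        assert (ttr, tbr, tar) == pytest.approx((50.0, 50.0, 0.0))

    def test_boundary_inr_counts_in_range(self):
        assert rosendaal([0, 30], [3.0, 3.0], 2.0, 3.0, 0, 30)[0] == 100.0

    def test_no_extrapolation_beyond_last_measurement(self):
        # covered time ends at day 10; denominator is covered time
        ttr, tbr, tar = rosendaal([0, 10], [2.5, 2.5], 2.0, 3.0, 0, 30)
        assert (ttr, tbr, tar) == (100.0, 0.0, 0.0)

    def test_full_window_denominator_config(self):
        cfg = QualityConfig(denominator="full_window")
        ttr, tbr, tar = rosendaal([0, 15], [2.5, 2.5], 2.0, 3.0, 0, 30, config=cfg)
        assert ttr == pytest.approx(50.0)

    def test_zero_covered_duration_is_missing(self):
        assert rosendaal([40, 50], [2.5, 2.5], 2.0, 3.0, 0, 30) is None
        assert rosendaal([0], [2.5], 2.0, 3.0, 0, 30) is None

    def test_matches_fine_grid_oracle_on_random_trajectories(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(2, 8))
            days = np.sort(rng.uniform(-10, 40, n))
            days += np.arange(n) * 1e-3  # enforce strict increase
            inrs = rng.uniform(0.8, 6.0, n)
            got = rosendaal(days, inrs, 2.0, 3.0, 0.0, 30.0)
            expected = grid_ttr(days, inrs, 2.0, 3.0, 0.0, 30.0)
            if expected is None:
                assert got is None
                continue
            assert got == pytest.approx(expected, abs=0.05)
            assert sum(got) == pytest.approx(100.0, abs=1e-6)

    @given(
        shift=st.floats(-1000, 1000),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=50, deadline=None)
    def test_translation_invariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        days = np.sort(rng.uniform(-5, 35, 4)) + np.arange(4) * 1e-3
        inrs = rng.uniform(1.0, 5.0, 4)
        base = rosendaal(days, inrs, 2.0, 3.0, 0.0, 30.0)
        moved = rosendaal(days + shift, inrs, 2.0, 3.0, shift, 30.0 + shift)
        if base is None:
            assert moved is None
        else:
            assert moved == pytest.approx(base, abs=1e-6)

    @given(
        seed=st.integers(0, 10_000),
        hi1=st.floats(2.5, 4.0),
        hi2=st.floats(2.5, 4.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_raising_upper_limit_monotone(self, seed, hi1, hi2):
        lo_hi, hi_hi = sorted((hi1, hi2))
        rng = np.random.default_rng(seed)
        days = np.sort(rng.uniform(0, 30, 5)) + np.arange(5) * 1e-3
        inrs = rng.uniform(1.0, 6.0, 5)
        narrow = rosendaal(days, inrs, 2.0, lo_hi, 0.0, 30.0)
        wide = rosendaal(days, inrs, 2.0, hi_hi, 0.0, 30.0)
        assert wide[0] >= narrow[0] - 1e-9  # TTR never decreases
        assert wide[2] <= narrow[2] + 1e-9  # TAR never increases


class TestVgr:
    def test_constant_inr_gives_zero(self):
        assert vgr([0, 7, 21], [2.5, 2.5, 2.5]) == 0.0

    def test_single_pair_over_one_week(self):
        assert vgr([0, 7], [2.0, 3.0]) == pytest.approx(1.0)

    def test_two_pairs_average(self):
        assert vgr([0, 7, 21], [2.0, 3.0, 3.0]) == pytest.approx(0.5)

    def test_day_denominator_config(self):
        cfg = QualityConfig(vgr_denominator="days")
        assert vgr([0, 7], [2.0, 3.0], config=cfg) == pytest.approx(1.0 / 7.0)

    @given(c=st.floats(0.1, 10.0), seed=st.integers(0, 1000))
    @settings(max_examples=50, deadline=None)
    def test_time_scaling_inverts_vgr(self, c, seed):
        rng = np.random.default_rng(seed)
        days = np.cumsum(rng.uniform(1, 20, 5))
        inrs = rng.uniform(1, 5, 5)
        base = vgr(days, inrs)
        scaled = vgr(days * c, inrs)
        assert scaled == pytest.approx(base / c, rel=1e-9)


class TestProportions:
    def test_counting_example(self):
        props = inr_proportions([2.5, 3.5, 5.0], 2.0, 3.0)
        assert props == pytest.approx((100 / 3, 0.0, 200 / 3, 100 / 3, 0.0))

    def test_boundary_counts_within(self):
        assert inr_proportions([3.0], 2.0, 3.0)[0] == 100.0
        assert inr_proportions([2.0], 2.0, 3.0)[0] == 100.0

    def test_empty_window_is_missing(self):
        assert inr_proportions([], 2.0, 3.0) is None

    def test_thresholds_inclusive(self):
        _, _, _, ge5, ge8 = inr_proportions([5.0, 8.0], 2.0, 3.0)
        assert (ge5, ge8) == (100.0, 50.0)

    @given(st.lists(st.floats(0.8, 10.0), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_partition_sums_to_100(self, inrs):
        prop_in, below, above, _, _ = inr_proportions(inrs, 2.0, 3.0)
        assert prop_in + below + above == pytest.approx(100.0, abs=1e-6)


class TestDoseChange:
    @pytest.mark.parametrize(
        "prev,nxt,expected",
        [
            (2.00, 1.80, "reduction"),  # exactly -10%: inclusive
            (2.00, 2.19, "none"),  # +9.5%
            (2.00, 2.20, "increase"),  # exactly +10%: inclusive
            (2.00, 1.81, "none"),  # -9.5%
            (0.0, 1.0, "increase"),
            (0.0, 0.0, "none"),
            (1.5, 1.5, "none"),
        ],
    )
    def test_threshold_classification(self, prev, nxt, expected):
        assert classify_dose_change(prev, nxt) == expected


class TestMonitoringAndEligibility:
    def test_two_measurements_sixteen_days_apart(self):
        n, med = monitoring_stats(2, [2.0, 18.0])
        assert (n, med) == (2, 16.0)

    def test_no_measurements(self):
        n, med = monitoring_stats(0, [])
        assert n == 0 and np.isnan(med)

    @pytest.mark.parametrize(
        "n_in,borrowed,expected",
        [(2, False, True), (1, True, True), (1, False, False), (0, True, False)],
    )
    def test_eligibility_rule(self, n_in, borrowed, expected):
        assert window_eligibility(n_in, borrowed, True, True) is expected

    def test_not_on_vka_is_ineligible(self):
        assert window_eligibility(3, True, False, True) is False


class TestWindowQualityTable:
    windows = build_windows(*RAMADAN_2016)

    def _table(self, inr_days, inr_vals, doses=None, subject=None):
        import pandas as pd

        subject = subject or make_subject()
        df = pd.DataFrame(
            {
                "subject_id": subject.subject_id,
                "date": [D0_2016 + dt.timedelta(days=int(d)) for d in inr_days],
                "inr": inr_vals,
                "target_low": 2.0,
                "target_high": 3.0,
                "dose": doses if doses is not None else np.nan,
            }
        )
        fu = compute_follow_up(subject, [], self.windows)
        return compute_window_quality(
            [subject], df, [fu], {subject.subject_id: self.windows}
        )

    def test_borrowed_anchor_makes_window_eligible(self):
        # one INR in window -1 plus the last INR of window -2
        q = self._table([25, 40], [2.5, 2.5])
        row = q[q["window"] == -1].iloc[0]
        assert row["eligible"] and row["n_inr"] == 1
        assert row["ttr"] == pytest.approx(100.0)

    def test_single_unanchored_inr_is_ineligible_and_missing(self):
        q = self._table([40], [2.5])
        row = q[q["window"] == -1].iloc[0]
        assert not row["eligible"]
        assert np.isnan(row["ttr"]) and np.isnan(row["prop_in"])

    def test_conservation_for_eligible_windows(self):
        rng = np.random.default_rng(0)
        days = np.sort(rng.choice(np.arange(-20, 150), size=12, replace=False))
        q = self._table(days, rng.uniform(1.5, 4.5, 12))
        el = q[q["eligible"]]
        assert len(el) > 0
        # conservation holds wherever the metrics are defined
        ros = el[el["ttr"].notna()]
        assert len(ros) > 0
        np.testing.assert_allclose(ros[["ttr", "tbr", "tar"]].sum(axis=1), 100.0, atol=1e-6)
        np.testing.assert_allclose(
            el[["prop_in", "prop_below", "prop_above"]].sum(axis=1), 100.0, atol=1e-6
        )

    def test_dose_flags_from_consecutive_visits(self):
        q = self._table([25, 40, 55], [2.5, 2.5, 2.5], doses=[2.0, 1.7, 1.7])
        row = q[q["window"] == -1].iloc[0]
        assert bool(row["dose_reduction_flag"]) and not bool(row["dose_increase_flag"])

    def test_measurements_after_exit_are_ignored(self):
        doac_day = D0_2016 + dt.timedelta(days=45)
        s = make_subject(doac_dispensings=[doac_day])
        q = self._table([25, 40, 50, 70], [2.5, 2.5, 9.0, 9.0], subject=s)
        row = q[q["window"] == -1].iloc[0]
        # the INR at day 50 falls after the DOAC exit at day 45
        assert row["n_inr"] == 1 and row["prop_ge8"] == 0.0


def test_switch_flags_only_in_switch_window():
    import datetime as dt

    from vkawindows import Subject, VkaEpisode

    switch_day = D0_2016 + dt.timedelta(days=70)
    s = Subject(
        subject_id="S1",
        cohort_label="test",
        anchor_d0=D0_2016,
        age_at_d0=60,
        vka_episodes=[
            VkaEpisode(D0_2016 - dt.timedelta(days=300), switch_day, "acenocoumarol"),
            VkaEpisode(switch_day, None, "phenprocoumon"),
        ],
        target_range_at_d0=(2.0, 3.0),
    )
    windows = build_windows(*RAMADAN_2016)
    flags = [switch_flags(s, w.start, w.end) for w in windows]
    assert [f[0] for f in flags] == [False, False, True, False, False]
    assert not any(f[1] for f in flags)
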