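import datetime as dt

import pytest

from vkawindows import Subject, VkaEpisode
from vkawindows.simulate import SimulationConfig, generate_cohort

RAMADAN_2016 = (dt.date(2016, 6, 6), dt.date(2016, 7, 5))
D0_2016 = dt.date(2016, 4, 7)  # Ramadan start - 60 days


def make_subject(
    subject_id="S1",
    anchor_d0=D0_2016,
    age=65.0,
    episode_start_days_before_d0=200,
    episode_end=None,
    vka_type="acenocoumarol",
    target=(2.0, 3.0),
    vka_dispensing_days_before_d0=(30,),
    doac_dispensings=(),
    year=2016,
):
    return Subject(
        subject_id=subject_id,
        cohort_label="test",
        anchor_d0=anchor_d0,
        age_at_d0=age,
        vka_episodes=[
            VkaEpisode(
                anchor_d0 - dt.timedelta(days=episode_start_days_before_d0),
                episode_end,
                vka_type,
            )
        ],
        target_range_at_d0=target,
        doac_dispensings=list(doac_dispensings),
        vka_dispensings=[
            anchor_d0 - dt.timedelta(days=d) for d in vka_dispensing_days_before_d0
        ],
        covariates={"year": year},
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 120-subject synthetic cohort shared across tests."""
    return generate_cohort(SimulationConfig(n_subjects=120, seed=7))
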