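"""Domain types shared by every stage of the windowed VKA-quality analysis.

The study design anchors five contiguous 30-day observation windows on the
start of Ramadan in a given calendar year (window 0 begins at the Ramadan
start date, follow-up runs from 60 days before to 90 days after it).  These
dataclasses carry the minimal clinical state: a VKA (vitamin K antagonist)
user with treatment episodes and dispensing history, dated INR measurements
with their therapeutic target range and recommended average daily dose,
typed clinical events, and the derived per-subject follow-up interval.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

VKA_TYPES = ("acenocoumarol", "phenprocoumon", "other")

EVENT_CLASSES = (
    "major_bleeding",
    "ischemic_stroke",
    "tia",
    "myocardial_infarction",
    "other_arterial_te",
    "venous_te",
    "death",
)

BLEEDING_CLASSES = frozenset({"major_bleeding"})
ARTERIAL_TE_CLASSES = frozenset(
    {"ischemic_stroke", "tia", "myocardial_infarction", "other_arterial_te"}
)
#: Composite of bleeding plus venous and arterial thromboembolism.
COMPOSITE_CLASSES = BLEEDING_CLASSES | ARTERIAL_TE_CLASSES | {"venous_te"}

WINDOW_INDICES = (-2, -1, 0, 1, 2)
WINDOW_DAYS = 30
FOLLOW_UP_DAYS = 5 * WINDOW_DAYS

EXIT_REASONS = (
    "window_end",
    "doac_dispensing",
    "doac_clinic_record",
    "vka_discontinuation",
    "clinical_event",
    "death",
)

#: Same-day tie priority at follow-up exit (highest first): prefer the
#: outcome with analytic consequence.
EXIT_PRIORITY = (
    "death",
    "clinical_event",
    "doac_dispensing",
    "doac_clinic_record",
    "vka_discontinuation",
    "window_end",
)


@dataclass(frozen=True)
class VkaEpisode:
    """One uninterrupted VKA treatment episode, half-open [start, end)."""

    start: dt.date
    end: dt.date | None  # None = ongoing
    vka_type: str

    def active_at(self, day: dt.date) -> bool:
        return self.start <= day and (self.end is None or day < self.end)


@dataclass
class Subject:
    subject_id: str
    cohort_label: str
    anchor_d0: dt.date  # Ramadan start − 60 days
    age_at_d0: float
    vka_episodes: list[VkaEpisode] = field(default_factory=list)
    target_range_at_d0: tuple[float, float] | None = None
    doac_dispensings: list[dt.date] = field(default_factory=list)
    vka_dispensings: list[dt.date] = field(default_factory=list)
    doac_clinic_dates: list[dt.date] = field(default_factory=list)
    covariates: dict = field(default_factory=dict)

    def episode_at(self, day: dt.date) -> VkaEpisode | None:
        for ep in self.vka_episodes:
            if ep.active_at(day):
                return ep
        return None


@dataclass(frozen=True)
class InrMeasurement:
    """One dated INR observation with target range and recommended dose.

    ``dose`` is the recommended average daily dose in tablets/day and may be
    missing (None).
    """

    subject_id: str
    date: dt.date
    inr: float
    target_low: float | None = None
    target_high: float | None = None
    dose: float | None = None


@dataclass(frozen=True)
class EventRecord:
    subject_id: str
    date: dt.date
    event_class: str

    def __post_init__(self):
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")


@dataclass(frozen=True)
class ObservationWindow:
    """One of five 30-day half-open intervals; index 0 starts at Ramadan."""

    index: int
    start: dt.date
    end: dt.date

    def __post_init__(self):
        if (self.end - self.start).days != WINDOW_DAYS:
            raise ValueError(
                f"window {self.index} spans {(self.end - self.start).days} days, "
                f"expected {WINDOW_DAYS}"
            )
        if self.index not in WINDOW_INDICES:
            raise ValueError(f"window index {self.index} not in {WINDOW_INDICES}")

    def contains(self, day: dt.date) -> bool:
        return self.start <= day < self.end


@dataclass(frozen=True)
class FollowUp:
    """Follow-up from d0 to the first censoring/outcome date."""

    subject_id: str
    entry: dt.date
    exit: dt.date
    exit_reason: str

    def __post_init__(self):
        if not self.entry <= self.exit <= self.entry + dt.timedelta(days=FOLLOW_UP_DAYS):
            raise ValueError(
                f"{self.subject_id}: exit {self.exit} outside "
                f"[{self.entry}, {self.entry + dt.timedelta(days=FOLLOW_UP_DAYS)}]"
            )
        if self.exit_reason not in EXIT_REASONS:
            raise ValueError(f"unknown exit reason {self.exit_reason!r}")
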