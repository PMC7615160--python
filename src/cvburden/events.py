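"""Temporal event-history categories for QoL and cost analyses.

New adverse events enter both analyses through *hierarchical temporal
event-history categories*: for each of ten event types, a mutually
exclusive and exhaustive indicator of the time elapsed since the
qualifying occurrence of that event — none, within 1 year, 1-2 years,
2-3 years, or more than 3 years.

The two analyses run the clock differently:

* **QoL** measures time from the *last* occurrence of each event type to
  the participant's end-of-study QoL measurement (recent events dominate
  current QoL).
* **Costs** measure time from the *first* occurrence of each event type
  to each annual follow-up period (costs are tracked forward from
  disease onset).

Repeated events therefore pull the QoL category toward the event year
but never move the cost clock.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

YEAR_DAYS = 365.25

#: The ten adverse-event types tracked by the analysis.
EVENT_TYPES = (
    "mi",
    "stroke",               # nonhemorrhagic stroke
    "crv_urgent",           # urgent coronary revascularization
    "crv_nonurgent",        # nonurgent coronary revascularization
    "hf_admission",         # hospitalization for heart failure
    "noncoronary_revasc",
    "cancer",               # incident cancer
    "diabetes",             # incident diabetes
    "vascular_death",
    "nonvascular_death",
)

#: Events that by definition entail a hospital admission: their event-year
#: periods have probability 1 of incurring hospital cost.
CERTAIN_ADMISSION_TYPES = ("crv_urgent", "crv_nonurgent", "hf_admission")

DEATH_TYPES = ("vascular_death", "nonvascular_death")

# Category labels, ordered from most recent to most distant.
NO_EVENT = "no_event"
Y0 = "y0"          # within 1 year / event year
Y1_2 = "y1_2"
Y2_3 = "y2_3"
GT3 = "gt3"
CATEGORIES = (NO_EVENT, Y0, Y1_2, Y2_3, GT3)
#: Non-reference categories in temporal order (used by category merging).
TIME_CATEGORIES = (Y0, Y1_2, Y2_3, GT3)


def merged_label(categories: tuple[str, ...] | list[str]) -> str:
    """Canonical label for a union of consecutive time categories."""
    cats = sorted(set(categories), key=TIME_CATEGORIES.index)
    idx = [TIME_CATEGORIES.index(c) for c in cats]
    if idx != list(range(idx[0], idx[-1] + 1)):
        raise ValueError(f"merged categories must be consecutive, got {categories}")
    return "+".join(cats)


def label_members(label: str) -> tuple[str, ...]:
    """The original time categories contained in a (possibly merged) label."""
    parts = tuple(label.split("+"))
    for p in parts:
        if p not in TIME_CATEGORIES:
            raise ValueError(f"unknown category {p!r} in label {label!r}")
    return parts


@dataclass(frozen=True)
class AdverseEvent:
    """A typed, dated post-randomization adverse event."""

    participant_id: int
    event_type: str
    day: float

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.day < 0:
            raise ValueError("event day must be >= 0 (days since randomization)")


# -- QoL clock (last occurrence -> QoL measurement) --------------------


def qol_category(event_days, qol_day: float) -> str:
    """Temporal category of one event type at the QoL measurement date.

    ``event_days`` are all occurrences of the event type for one
    participant; the *last* occurrence on or before ``qol_day`` governs.
    Events after ``qol_day`` are ignored (with a logged warning if no
    earlier occurrence exists).  An event on the measurement day itself
    counts as the event year.
    """
    if qol_day < 0:
        raise ValueError("qol_day must be >= 0")
    days = np.asarray(list(event_days), dtype=float)
    if days.size == 0:
        return NO_EVENT
    eligible = days[days <= qol_day]
    if eligible.size == 0:
        logger.warning(
            "all %d occurrences fall after the QoL measurement day %s; "
            "treating as no new event",
            days.size,
            qol_day,
        )
        return NO_EVENT
    gap_years = (qol_day - eligible.max()) / YEAR_DAYS
    return _gap_to_category(gap_years)


def _gap_to_category(gap_years: float) -> str:
    if gap_years <= 1.0:
        return Y0
    if gap_years <= 2.0:
        return Y1_2
    if gap_years <= 3.0:
        return Y2_3
    return GT3


# -- cost clock (first occurrence -> annual period) --------------------


def cost_category(first_event_day: float | None, period_index: int) -> str:
    """Temporal category of one event type in annual period ``k``.

    Period ``k`` covers days ``[365.25*k, 365.25*(k+1))``.  The *first*
    occurrence of the event type since randomization governs: periods
    before it are unexposed (``no_event``), the period containing it is
    the event year, and later periods age through 1-2y, 2-3y, >3y.
    """
    if period_index < 0:
        raise ValueError("period_index must be >= 0")
    if first_event_day is None or (
        isinstance(first_event_day, float) and np.isnan(first_event_day)
    ):
        return NO_EVENT
    if first_event_day < 0:
        raise ValueError("first_event_day must be >= 0")
    event_period = int(first_event_day // YEAR_DAYS)
    lag = period_index - event_period
    if lag < 0:
        return NO_EVENT
    if lag == 0:
        return Y0
    if lag == 1:
        return Y1_2
    if lag == 2:
        return Y2_3
    return GT3


def classify_fatal(event_day: float, death_day: float | None) -> bool:
    """Whether an event is *fatal*: followed by death in the same annual period."""
    if death_day is None or (isinstance(death_day, float) and np.isnan(death_day)):
        return False
    return int(event_day // YEAR_DAYS) == int(death_day // YEAR_DAYS)


# -- vectorised builders ----------------------------------------------


def first_last_event_days(events: pd.DataFrame) -> pd.DataFrame:
    """First and last occurrence day per (participant, event type).

    ``events`` needs columns ``participant_id, event_type, day``.
    Returns a frame indexed by participant with two columns per type:
    ``first_<type>`` and ``last_<type>`` (NaN where the type never occurs).
    """
    _check_events(events)
    out = {}
    if len(events):
        grouped = events.groupby(["participant_id", "event_type"])["day"]
        firsts = grouped.min().unstack("event_type")
        lasts = grouped.max().unstack("event_type")
    else:
        firsts = lasts = pd.DataFrame()
    for etype in EVENT_TYPES:
        out[f"first_{etype}"] = firsts[etype] if etype in firsts.columns else np.nan
        out[f"last_{etype}"] = lasts[etype] if etype in lasts.columns else np.nan
    frame = pd.DataFrame(out)
    frame.index.name = "participant_id"
    return frame


def qol_categories_frame(events: pd.DataFrame, qol_days: pd.Series) -> pd.DataFrame:
    """QoL-clock category per participant and event type.

    ``qol_days`` maps participant id to the day of the final QoL
    measurement; only those participants appear in the output.  Columns
    are ``qcat_<type>`` with values in :data:`CATEGORIES`.
    """
    _check_events(events)
    ids = qol_days.index
    out = pd.DataFrame(index=ids)
    out.index.name = "participant_id"
    qd = qol_days.to_numpy(dtype=float)
    if len(events):
        eligible = events.merge(
            qol_days.rename("qol_day"), left_on="participant_id", right_index=True
        )
        eligible = eligible[eligible["day"] <= eligible["qol_day"]]
        lasts = (
            eligible.groupby(["participant_id", "event_type"])["day"].max().unstack("event_type")
        )
    else:
        lasts = pd.DataFrame()
    for etype in EVENT_TYPES:
        col = lasts[etype].reindex(ids) if etype in lasts.columns else pd.Series(np.nan, index=ids)
        last = col.to_numpy(dtype=float)
        gap = (qd - last) / YEAR_DAYS
        cat = np.select(
            [np.isnan(last), gap <= 1.0, gap <= 2.0, gap <= 3.0],
            [NO_EVENT, Y0, Y1_2, Y2_3],
            default=GT3,
        )
        out[f"qcat_{etype}"] = cat
    return out


def cost_categories_frame(
    events: pd.DataFrame, period_index: pd.DataFrame
) -> pd.DataFrame:
    """Cost-clock category per person-year row and event type.

    ``period_index`` needs columns ``participant_id, period``; one output
    row per input row, columns ``ccat_<type>``, plus ``certain_admission``
    (True where an admission-defining event occurs in the period).
    """
    _check_events(events)
    firsts = first_last_event_days(events) if len(events) else None
    out = period_index[["participant_id", "period"]].copy()
    k = out["period"].to_numpy(dtype=int)
    if (k < 0).any():
        raise ValueError("period indices must be >= 0")
    for etype in EVENT_TYPES:
        if firsts is not None:
            fd = (
                firsts[f"first_{etype}"]
                .reindex(out["participant_id"])
                .to_numpy(dtype=float)
            )
        else:
            fd = np.full(len(out), np.nan)
        lag = k - np.floor_divide(fd, YEAR_DAYS, where=~np.isnan(fd), out=np.full(len(out), np.nan))
        cat = np.select(
            [np.isnan(fd) | (lag < 0), lag == 0, lag == 1, lag == 2],
            [NO_EVENT, Y0, Y1_2, Y2_3],
            default=GT3,
        )
        out[f"ccat_{etype}"] = cat
    certain = np.zeros(len(out), dtype=bool)
    for etype in CERTAIN_ADMISSION_TYPES:
        certain |= out[f"ccat_{etype}"].to_numpy() == Y0
    out["certain_admission"] = certain
    return out


def _check_events(events: pd.DataFrame) -> None:
    required = {"participant_id", "event_type", "day"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events table missing columns {sorted(missing)}")
    if len(events):
        if (events["day"] < 0).any():
            raise ValueError("event days must be >= 0")
        bad = set(events["event_type"]) - set(EVENT_TYPES)
        if bad:
            raise ValueError(f"unknown event types {sorted(bad)}")


def tidy_categories(frame: pd.DataFrame, clock: str) -> pd.DataFrame:
    """Long-format category table: one row per (participant, [period,] type).

    ``frame`` is a wide frame carrying ``<clock>_<type>`` columns (as
    produced by the frame builders above); useful for CSV export.
    """
    id_cols = [c for c in ("participant_id", "period") if c in frame.columns]
    cat_cols = [c for c in frame.columns if c.startswith(f"{clock}_")]
    out = frame[id_cols + cat_cols].melt(
        id_vars=id_cols, var_name="event_type", value_name="category"
    )
    out["event_type"] = out["event_type"].str.removeprefix(f"{clock}_")
    return out
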