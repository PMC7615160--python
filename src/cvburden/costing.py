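"""Hospital-admission costing: episode merging and annual aggregation.

Hospital admissions are first combined into episodes (admissions with
overlapping lengths of stay are merged and their costs summed), then
each episode's cost is assigned to the annual follow-up period that
contains its admission day, inflated to the target price year and — on
the US (Medicare) convention — uplifted for professional fees.  The
result is one row per participant-year with the total cost, an any-cost
indicator and the exposure (fraction of the year at risk).

Unit costs are an input: mapping admissions to HRG (UK) or DRG (US)
casemix groups and reference prices happens upstream of this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import YEAR_DAYS

EPISODE_COLUMNS = ("participant_id", "admission_day", "discharge_day", "unit_cost")


@dataclass(frozen=True)
class HospitalEpisode:
    """One (possibly merged) inpatient episode for a participant."""

    participant_id: int
    admission_day: float
    discharge_day: float
    unit_cost: float

    def __post_init__(self) -> None:
        if self.discharge_day < self.admission_day:
            raise ValueError("discharge_day must be >= admission_day")
        if self.unit_cost < 0:
            raise ValueError("unit_cost must be >= 0")


def merge_overlapping(episodes: pd.DataFrame) -> pd.DataFrame:
    """Combine admissions with overlapping lengths of stay.

    Two admissions overlap when their stay intervals share at least one
    day; a same-day readmission (discharge day equal to the next
    admission day) is merged, while abutting-but-disjoint stays
    (readmission the day after discharge) are kept separate.  Costs of
    combined admissions are summed.  Idempotent.
    """
    _check_episodes(episodes)
    if len(episodes) == 0:
        return episodes.copy()
    out = []
    for pid, grp in episodes.groupby("participant_id", sort=True):
        grp = grp.sort_values(["admission_day", "discharge_day"])
        adm = grp["admission_day"].to_numpy(dtype=float)
        dis = grp["discharge_day"].to_numpy(dtype=float)
        cost = grp["unit_cost"].to_numpy(dtype=float)
        cur_a, cur_d, cur_c = adm[0], dis[0], cost[0]
        for a, d, c in zip(adm[1:], dis[1:], cost[1:]):
            if a <= cur_d:  # shares at least one day
                cur_d = max(cur_d, d)
                cur_c += c
            else:
                out.append((pid, cur_a, cur_d, cur_c))
                cur_a, cur_d, cur_c = a, d, c
        out.append((pid, cur_a, cur_d, cur_c))
    return pd.DataFrame(out, columns=list(EPISODE_COLUMNS))


def annualize(
    episodes: pd.DataFrame,
    followup_end: pd.Series,
    death_day: pd.Series | None = None,
    inflation: float = 1.0,
    fee_uplift: float = 1.0,
) -> pd.DataFrame:
    """Aggregate episode costs into annual person-year periods.

    Parameters
    ----------
    episodes:
        Merged episodes (``participant_id, admission_day, discharge_day,
        unit_cost``).
    followup_end:
        Per-participant end of follow-up in days, indexed by participant
        id; its index defines the cohort (participants without episodes
        still contribute zero-cost person-years).
    death_day:
        Optional per-participant death day; follow-up is truncated at
        death.
    inflation:
        Multiplier taking unit costs to the target price year (> 0).
    fee_uplift:
        Multiplier for professional fees (>= 1); 1.2 on the US Medicare
        convention, 1.0 for UK NHS reference costs.

    Episodes spanning a period boundary are assigned wholly to the
    period containing the admission day.  The final partial year is kept
    as a shorter period with its exposure recorded.
    """
    _check_episodes(episodes)
    if inflation <= 0:
        raise ValueError("inflation factor must be > 0")
    if fee_uplift < 1:
        raise ValueError("fee_uplift must be >= 1")
    end = followup_end.astype(float).copy()
    if death_day is not None:
        dd = death_day.reindex(end.index).astype(float)
        end = pd.Series(np.fmin(end.to_numpy(), dd.to_numpy()), index=end.index)
    if (end <= 0).any():
        raise ValueError("follow-up end must be > 0 for every participant")

    rows = []
    for pid, e in end.items():
        n_periods = int(np.ceil(e / YEAR_DAYS))
        for k in range(n_periods):
            exposure = min(e - k * YEAR_DAYS, YEAR_DAYS) / YEAR_DAYS
            rows.append((pid, k, exposure))
    out = pd.DataFrame(rows, columns=["participant_id", "period", "exposure"])
    out["cost"] = 0.0

    if len(episodes):
        ep = episodes.copy()
        ep_end = end.reindex(ep["participant_id"]).to_numpy()
        if np.isnan(ep_end).any():
            raise ValueError("episode for participant not in followup_end index")
        if (ep["admission_day"].to_numpy() > ep_end).any():
            raise ValueError("episode admission after end of follow-up")
        ep["period"] = (ep["admission_day"] // YEAR_DAYS).astype(int)
        ep["cost"] = ep["unit_cost"] * inflation * fee_uplift
        totals = ep.groupby(["participant_id", "period"])["cost"].sum()
        idx = pd.MultiIndex.from_frame(out[["participant_id", "period"]])
        out["cost"] = totals.reindex(idx, fill_value=0.0).to_numpy()

    out["any_cost"] = out["cost"] > 0
    return out


def _check_episodes(episodes: pd.DataFrame) -> None:
    missing = set(EPISODE_COLUMNS) - set(episodes.columns)
    if missing:
        raise ValueError(f"episodes table missing columns {sorted(missing)}")
    if len(episodes):
        if (episodes["discharge_day"] < episodes["admission_day"]).any():
            raise ValueError("discharge before admission in episodes table")
        if (episodes["unit_cost"] < 0).any():
            raise ValueError("negative unit cost in episodes table")
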