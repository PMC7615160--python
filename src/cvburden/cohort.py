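"""Synthetic secondary-prevention cohort generator.

Generates complete trial-like datasets with the statistical structure
the downstream analysis assumes: a baseline covariate table, a dated
adverse-event table (ten event types, deaths terminating follow-up),
per-person-year hospital costs drawn from a two-part generating model
under both UK and US costing conventions, and EQ-5D-5L profiles at
baseline and final visit consistent with the generated utilities.

Within a participant, event processes are independent across types
except for configured same-day couplings (by default, about half of MIs
are accompanied by an urgent coronary revascularization, which makes
the same-year MI x urgent-CRV interaction estimable).  Event days are
uniform over the participant's at-risk window; nonfatal types may recur
once, so the last-occurrence (QoL) and first-occurrence (cost) clocks
genuinely differ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import design as dsg
from .config import CohortConfig, ConfigError
from .eq5d import DIMENSIONS, Tariff, toy_tariff
from .events import (
    DEATH_TYPES,
    EVENT_TYPES,
    YEAR_DAYS,
    cost_categories_frame,
    qol_categories_frame,
)

#: Nominal minimum conditional mean cost (currency units) for periods
#: where exposure scaling would otherwise push the mean to zero or below.
MIN_ADMISSION_COST = 25.0

PARTICIPANT_COLUMNS = [
    "participant_id",
    "arm",
    "age",
    "female",
    "region",
    "disease_hist",
    "hf_hist",
    "af",
    "diabetes_hist",
    "sbp_cat",
    "dbp_cat",
    "bmi",
    "bmi_cat",
    "alcohol",
    "smoking",
    "antihypertensive",
    "antithrombotic",
    "amiodarone",
    "statin",
    "ldl_cat",
    "hdl_cat",
    "tg_cat",
    "gfr_cat",
    "uacr_cat",
    "death_day",
    "death_cause",
    "followup_days",
    "qol_day",
    "final_qol_missing",
    "baseline_utility",
    "final_utility",
]


@dataclass
class CohortData:
    """The four generated tables plus provenance."""

    participants: pd.DataFrame
    events: pd.DataFrame
    person_years: pd.DataFrame
    profiles: pd.DataFrame
    config: CohortConfig

    def write(self, outdir) -> None:
        """Write the tables as CSV plus a manifest with seed and config hash."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(outdir / "participants.csv", index=False)
        self.events.to_csv(outdir / "events.csv", index=False)
        self.person_years.to_csv(outdir / "person_years.csv", index=False)
        self.profiles.to_csv(outdir / "profiles.csv", index=False)
        self.config.save(outdir / "config.yaml")
        manifest = {
            "seed": self.config.seed,
            "n_participants": self.config.n_participants,
            "config_hash": self.config.config_hash(),
            "tables": ["participants.csv", "events.csv", "person_years.csv", "profiles.csv"],
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def read(cls, indir) -> "CohortData":
        indir = Path(indir)
        return cls(
            participants=pd.read_csv(indir / "participants.csv"),
            events=pd.read_csv(indir / "events.csv"),
            person_years=pd.read_csv(indir / "person_years.csv"),
            profiles=pd.read_csv(indir / "profiles.csv"),
            config=CohortConfig.load(indir / "config.yaml"),
        )


def generate_cohort(config: CohortConfig, tariff: Tariff | None = None) -> CohortData:
    """Generate one synthetic cohort; deterministic given the config seed."""
    config.validate()
    if config.qol_truth is None or config.cost_truth is None or config.baseline_utility is None:
        raise ConfigError("config requires qol_truth, cost_truth and baseline_utility")
    tariff = tariff or toy_tariff()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    participants = _draw_covariates(config, rng)
    _draw_followup_and_death(participants, config, rng)
    _draw_baseline_utility(participants, config, rng)
    events = _draw_events(participants, config, rng)
    person_years = _draw_costs(participants, events, config, rng)
    _draw_final_qol(participants, events, config, rng)
    profiles = _profiles_from_utilities(participants, tariff)

    return CohortData(
        participants=participants[PARTICIPANT_COLUMNS],
        events=events,
        person_years=person_years,
        profiles=profiles,
        config=config,
    )


# -- covariates --------------------------------------------------------


def _categorical(rng, n, table: dict[str, float]) -> np.ndarray:
    levels = list(table)
    probs = np.array([table[k] for k in levels], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(np.array(levels, dtype=object), size=n, p=probs)


def _draw_covariates(config: CohortConfig, rng) -> pd.DataFrame:
    dist = config.covariate_dist
    n = config.n_participants
    df = pd.DataFrame({"participant_id": np.arange(n, dtype=int)})
    df["arm"] = rng.integers(0, 2, n)
    age_spec = dist["age"]
    a = (age_spec["min"] - age_spec["mean"]) / age_spec["sd"]
    df["age"] = np.round(
        truncnorm.rvs(a, np.inf, loc=age_spec["mean"], scale=age_spec["sd"], size=n, random_state=rng),
        1,
    )
    df["female"] = (rng.random(n) < dist["female"]).astype(int)
    for cat in ("region", "disease_hist", "sbp_cat", "dbp_cat", "bmi_cat",
                "alcohol", "smoking", "ldl_cat", "hdl_cat", "tg_cat",
                "gfr_cat", "uacr_cat"):
        df[cat] = _categorical(rng, n, dist[cat])
    for flag in ("hf_hist", "af", "diabetes_hist", "antihypertensive",
                 "antithrombotic", "amiodarone", "statin"):
        df[flag] = (rng.random(n) < dist[flag]).astype(int)

    # numeric BMI consistent with its category; the printed-missing
    # category has no numeric value (imputed downstream).
    bmi = np.empty(n)
    cat = df["bmi_cat"].to_numpy()
    bmi[cat == "lt25"] = np.clip(rng.normal(23.0, 1.5, (cat == "lt25").sum()), 16, 24.9)
    bmi[cat == "25_30"] = rng.uniform(25.0, 29.9, (cat == "25_30").sum())
    bmi[cat == "ge30"] = np.clip(rng.normal(33.0, 3.0, (cat == "ge30").sum()), 30, 55)
    bmi[cat == "missing"] = np.nan
    df["bmi"] = np.round(bmi, 1)
    return df


def _draw_followup_and_death(df: pd.DataFrame, config: CohortConfig, rng) -> None:
    n = len(df)
    nominal = config.followup_years * YEAR_DAYS
    if config.followup_jitter > 0:
        nominal = nominal + rng.uniform(-1, 1, n) * config.followup_jitter * YEAR_DAYS
    else:
        nominal = np.full(n, nominal)
    p_vd = config.event_rates["vascular_death"]
    p_nvd = config.event_rates["nonvascular_death"]
    dies = rng.random(n) < (p_vd + p_nvd)
    vascular = rng.random(n) < (p_vd / (p_vd + p_nvd) if p_vd + p_nvd > 0 else 0.0)
    death_day = np.where(dies, rng.uniform(0, nominal, n), np.nan)
    df["death_day"] = death_day
    df["death_cause"] = np.where(
        dies, np.where(vascular, "vascular", "nonvascular"), None
    )
    df["followup_days"] = np.fmin(nominal, death_day)
    df.loc[df["followup_days"].isna(), "followup_days"] = nominal[df["followup_days"].isna()]


# -- events ------------------------------------------------------------


def _frailty_weights(df: pd.DataFrame, config: CohortConfig) -> np.ndarray:
    """Per-participant event-rate multipliers (mean 1) tied to baseline QoL."""
    kappa = config.event_frailty_kappa
    if kappa == 0:
        return np.ones(len(df))
    base = df["baseline_utility"].to_numpy(dtype=float)
    w = np.exp(kappa * (config.baseline_utility.mean() - base))
    return w / w.mean()


def _draw_events(df: pd.DataFrame, config: CohortConfig, rng) -> pd.DataFrame:
    n = len(df)
    end = df["followup_days"].to_numpy()
    coupling_by_target = {c.target: c for c in config.event_couplings}
    rows: list[pd.DataFrame] = []
    firsts: dict[str, np.ndarray] = {}
    frailty = _frailty_weights(df, config)

    nonfatal = [e for e in EVENT_TYPES if e not in DEATH_TYPES]
    for etype in nonfatal:
        rate = config.event_rates[etype]
        coupling = coupling_by_target.get(etype)
        if coupling is not None:
            rate = max(rate - config.event_rates[coupling.trigger] * coupling.prob, 0.0)
        prob = np.minimum(rate * frailty, 1.0)
        if etype == "diabetes":
            # incident diabetes only arises in participants without
            # baseline diabetes; rescale so the cohort incidence matches.
            eligible = df["diabetes_hist"].to_numpy() == 0
            share = eligible.mean()
            if share > 0:
                f_el = frailty / frailty[eligible].mean()
                prob = np.minimum(np.where(eligible, rate / share * f_el, 0.0), 1.0)
            else:
                prob = np.zeros(n)
        occurs = rng.random(n) < prob
        day = rng.uniform(0, end, n)
        firsts[etype] = np.where(occurs, day, np.nan)
        rows.append(_event_rows(df, occurs, day, etype))

    # same-day couplings (e.g. urgent CRV performed for an MI)
    for coupling in config.event_couplings:
        trig_day = firsts.get(coupling.trigger)
        if trig_day is None:
            continue
        triggered = (~np.isnan(trig_day)) & (rng.random(n) < coupling.prob)
        rows.append(_event_rows(df, triggered, trig_day, coupling.target))
        tgt = firsts[coupling.target]
        firsts[coupling.target] = np.where(
            triggered, np.fmin(np.nan_to_num(tgt, nan=np.inf), trig_day), tgt
        )

    # single recurrence of nonfatal types (moves the last-occurrence
    # clock without touching the first-occurrence clock)
    for etype in nonfatal:
        first = firsts[etype]
        can_recur = (~np.isnan(first)) & (first < end) & (
            rng.random(n) < config.recurrence_prob
        )
        recur_day = rng.uniform(np.nan_to_num(first), end, n)
        rows.append(_event_rows(df, can_recur, recur_day, etype))

    for etype, cause in (("vascular_death", "vascular"), ("nonvascular_death", "nonvascular")):
        mask = df["death_cause"].to_numpy() == cause
        rows.append(_event_rows(df, mask, df["death_day"].to_numpy(), etype))

    nonempty = [r for r in rows if len(r)]
    if not nonempty:
        return pd.DataFrame({"participant_id": pd.Series(dtype=int),
                             "event_type": pd.Series(dtype=object),
                             "day": pd.Series(dtype=float)})
    events = pd.concat(nonempty, ignore_index=True)
    return events.sort_values(["participant_id", "day", "event_type"]).reset_index(drop=True)


def _event_rows(df, mask, day, etype) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": df["participant_id"].to_numpy()[mask],
            "event_type": etype,
            "day": day[mask],
        }
    )


# -- costs -------------------------------------------------------------


def _person_year_index(df: pd.DataFrame) -> pd.DataFrame:
    end = df["followup_days"].to_numpy()
    n_periods = np.ceil(end / YEAR_DAYS).astype(int)
    pid = np.repeat(df["participant_id"].to_numpy(), n_periods)
    period = np.concatenate([np.arange(k) for k in n_periods])
    end_rep = np.repeat(end, n_periods)
    exposure = np.minimum(end_rep - period * YEAR_DAYS, YEAR_DAYS) / YEAR_DAYS
    return pd.DataFrame({"participant_id": pid, "period": period, "exposure": exposure})


def _draw_costs(df, events, config: CohortConfig, rng) -> pd.DataFrame:
    truth = config.cost_truth
    py = _person_year_index(df)
    cats = cost_categories_frame(events, py)
    py = pd.concat([py, cats.drop(columns=["participant_id", "period"])], axis=1)

    participants = dsg.prepare_covariates(df).set_index("participant_id")
    cov_design, _ = dsg.covariate_design(participants, list(dsg.COVARIATE_BLOCKS))
    row_cov = cov_design.loc[py["participant_id"]].reset_index(drop=True)

    # part 1: probability of any hospital cost (certain for CRV/HF years)
    lp1 = (
        truth.part1.intercept
        + dsg.linear_predictor(row_cov, truth.part1.covariate_effects)
        + dsg.event_effect_predictor(py, truth.part1.event_effects, "ccat")
    )
    p_any = 1.0 / (1.0 + np.exp(-lp1))
    incur = rng.random(len(py)) < p_any
    incur |= py["certain_admission"].to_numpy()

    # part 2: conditional mean cost per perspective (identity link);
    # the non-event baseline is scaled by exposure in partial years,
    # event-year contributions are incurred in full.
    exposure = py["exposure"].to_numpy()
    shape = truth.gamma_shape
    # one gamma draw shared across perspectives up to the mean: the same
    # admissions are costed on both conventions, so draw a unit-mean
    # gamma variate once and scale it by each perspective's mean.
    unit = rng.gamma(shape, 1.0 / shape, len(py))
    for persp, part2 in truth.part2.items():
        base = part2.intercept + dsg.linear_predictor(row_cov, part2.covariate_effects)
        event_part = dsg.event_effect_predictor(py, part2.event_effects, "ccat")
        for (a, b), coef in part2.interaction_effects.items():
            both = (py[f"ccat_{a}"] == "y0") & (py[f"ccat_{b}"] == "y0")
            event_part += coef * both.to_numpy()
        if (base + event_part < 0).any():
            raise ConfigError(
                f"cost_truth.part2[{persp!r}] implies negative conditional mean cost"
            )
        # exposure-scaling of the baseline in partial years can push the
        # mean below zero when event effects are negative; floor it at a
        # nominal admission cost so an incurred admission is never free
        # (degenerate all-zero configurations keep a zero mean).
        floor = np.where(base + event_part > 0, MIN_ADMISSION_COST, 0.0)
        mu = np.maximum(base * exposure + event_part, floor)
        # an incurred admission is never free under either costing
        # convention (tiny draws would otherwise round to zero)
        drawn = np.maximum(np.round(mu * unit, 2), np.where(mu > 0, 0.01, 0.0))
        cost = np.where(incur, drawn, 0.0)
        py[f"cost_{persp}"] = cost
    cost_cols = [f"cost_{p}" for p in truth.part2]
    py["any_cost"] = (py[cost_cols] > 0).any(axis=1)
    return py


# -- QoL ---------------------------------------------------------------


def _draw_baseline_utility(df, config: CohortConfig, rng) -> None:
    n = len(df)
    bu = config.baseline_utility
    full = rng.random(n) < bu.full_health_prob
    a = (bu.lower - bu.rest_mean) / bu.rest_sd
    b = (bu.upper - bu.rest_mean) / bu.rest_sd
    rest = truncnorm.rvs(a, b, loc=bu.rest_mean, scale=bu.rest_sd, size=n, random_state=rng)
    df["baseline_utility"] = np.round(np.where(full, 1.0, rest), 4)


def _draw_final_qol(df, events, config: CohortConfig, rng) -> None:
    n = len(df)
    bu = config.baseline_utility
    alive = df["death_day"].isna().to_numpy()
    df["final_qol_missing"] = (
        (rng.random(n) < config.missing_final_qol_rate) & alive
    ).astype(int)
    df["qol_day"] = np.where(alive, df["followup_days"], np.nan)

    qol_days = pd.Series(
        df.loc[alive, "qol_day"].to_numpy(), index=df.loc[alive, "participant_id"].to_numpy()
    )
    qcats = qol_categories_frame(events, qol_days)

    truth = config.qol_truth
    participants = dsg.prepare_covariates(df.loc[alive]).set_index("participant_id")
    cov_design, _ = dsg.covariate_design(participants, list(dsg.COVARIATE_BLOCKS))
    lp = (
        truth.intercept
        + dsg.linear_predictor(cov_design, truth.covariate_effects)
        + dsg.event_effect_predictor(qcats, truth.event_effects, "qcat")
        + truth.baseline_coef
        * (df.loc[alive, "baseline_utility"].to_numpy() - bu.mean())
    )
    noise = rng.normal(0.0, truth.residual_sd, alive.sum())
    final = np.full(n, np.nan)
    final[alive] = np.round(lp + noise, 4)
    final[df["final_qol_missing"].to_numpy() == 1] = np.nan
    df["final_utility"] = final


def _profiles_from_utilities(df: pd.DataFrame, tariff: Tariff) -> pd.DataFrame:
    """Baseline/final EQ-5D-5L profiles nearest to the generated utilities.

    The generated utility is a latent linear-model outcome and may
    exceed the tariff's range; profiles are clipped to the representable
    range, so round-tripping profiles through the tariff reproduces the
    utility only up to grid resolution and the full-health ceiling.
    """
    _, scores = tariff.all_profiles()
    lo, hi = scores.min(), scores.max()
    frames = []
    for visit, col in (("baseline", "baseline_utility"), ("final", "final_utility")):
        sub = df.loc[df[col].notna(), ["participant_id", col]]
        levels = tariff.nearest_profiles(np.clip(sub[col].to_numpy(), lo, hi))
        frame = pd.DataFrame(levels, columns=list(DIMENSIONS))
        frame.insert(0, "participant_id", sub["participant_id"].to_numpy())
        frame.insert(1, "visit", visit)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
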