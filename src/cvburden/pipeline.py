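"""Config-driven end-to-end analysis runs.

``run_pipeline`` wires the stages together: simulate (or load) the
cohort tables, score EQ-5D profiles, build the temporal event-history
covariates on both clocks, fit the QoL and two-part cost models, and
estimate recycled-prediction incremental costs with cluster-bootstrap
uncertainty.  Scenario switches reproduce the sensitivity analyses:
region subsets, dropping the baseline-QoL adjustment, and alternative
tariffs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortData, generate_cohort
from .config import CohortConfig, ConfigError
from .eq5d import load_tariff, summarize_utilities, toy_tariff
from .events import EVENT_TYPES, qol_categories_frame
from .marginal import incremental_costs, qol_decrement_table
from .modeling import (
    ModelSpec,
    QoLFit,
    TwoPartFit,
    add_interactions,
    fit_qol_model,
    fit_two_part,
    impute_covariates,
    merge_temporal_categories,
    select_covariates,
)

logger = logging.getLogger(__name__)

SCENARIOS = ("main", "region_subset", "no_baseline_adjustment", "alternate_tariff")

#: Event types carrying QoL effects in the final model (MI, CRV and
#: incident diabetes showed no detectable QoL impact and are excluded).
QOL_EVENT_TYPES = ("stroke", "hf_admission", "noncoronary_revasc", "cancer")

QOL_COVARIATE_BLOCKS = (
    "age", "female", "disease_hist", "hf_hist", "af", "diabetes_hist",
    "sbp", "bmi", "alcohol", "smoking", "gfr", "uacr",
)
COST_COVARIATE_BLOCKS = (
    "age", "female", "disease_hist", "hf_hist", "af", "diabetes_hist",
    "gfr", "smoking", "bmi",
)


def standard_qol_spec(baseline_adjustment: bool = True) -> ModelSpec:
    """The final QoL model: Gaussian/identity, last-occurrence clock."""
    return ModelSpec(
        outcome="final_utility",
        family="gaussian",
        link="identity",
        covariate_blocks=QOL_COVARIATE_BLOCKS,
        event_types=QOL_EVENT_TYPES,
        clock="qcat",
        baseline_adjustment=baseline_adjustment,
    )


def standard_cost_spec(perspective: str = "uk") -> ModelSpec:
    """The final cost model: two-part identity-link gamma, clustered SEs.

    The same-year MI x urgent-CRV interaction enters the US model only
    (where it was found significant)."""
    interactions = (("mi", "crv_urgent"),) if perspective == "us" else ()
    return ModelSpec(
        outcome=f"cost_{perspective}",
        family="gamma",
        link="identity",
        two_part=True,
        covariate_blocks=COST_COVARIATE_BLOCKS,
        event_types=EVENT_TYPES,
        clock="ccat",
        interactions=interactions,
        cluster_col="participant_id",
    )


# -- analysis frames ---------------------------------------------------


def qol_analysis_frame(
    participants: pd.DataFrame, events: pd.DataFrame
) -> pd.DataFrame:
    """QoL analysis sample: one row per included participant.

    Participants who died before the final QoL measurement or did not
    provide it are excluded (with counts logged); missing continuous
    covariates are imputed; last-occurrence temporal categories are
    attached.
    """
    n0 = len(participants)
    died = participants["death_day"].notna()
    missing = participants["final_utility"].isna() & ~died
    included = participants.loc[~died & ~missing].copy()
    logger.info(
        "QoL analysis: %d of %d participants included (%.1f%%); %d died, %d missing final QoL",
        len(included), n0, 100 * len(included) / n0, int(died.sum()), int(missing.sum()),
    )
    included = impute_covariates(included)
    qol_days = pd.Series(
        included["qol_day"].to_numpy(), index=included["participant_id"].to_numpy()
    )
    qcats = qol_categories_frame(events, qol_days).reset_index()
    return included.merge(qcats, on="participant_id", validate="1:1")


def cost_analysis_frame(
    participants: pd.DataFrame, person_years: pd.DataFrame
) -> pd.DataFrame:
    """Cost analysis sample: person-year rows joined with covariates."""
    participants = impute_covariates(participants)
    keep = [c for c in participants.columns if c not in person_years.columns or c == "participant_id"]
    frame = person_years.merge(participants[keep], on="participant_id", validate="m:1")
    logger.info(
        "cost analysis: %d person-years from %d participants; %.1f%% with any cost",
        len(frame), frame["participant_id"].nunique(), 100 * frame["any_cost"].mean(),
    )
    return frame


# -- run configuration -------------------------------------------------


@dataclass
class RunConfig:
    """One end-to-end run: inputs, scenario switches and outputs."""

    perspective: str = "uk"
    scenario: str = "main"
    tariff_path: str | None = None
    input_dir: str | None = None
    simulation: CohortConfig | None = None
    region_subset: str | None = None  # for scenario="region_subset"
    n_bootstrap: int = 1000
    seed: int = 0
    output_dir: str = "results"

    def validate(self) -> None:
        if self.perspective not in ("uk", "us"):
            raise ConfigError("perspective must be 'uk' or 'us'")
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"scenario must be one of {SCENARIOS}")
        if (self.input_dir is None) == (self.simulation is None):
            raise ConfigError("exactly one of input_dir / simulation must be supplied")
        if self.n_bootstrap < 2 and self.n_bootstrap != 0:
            raise ConfigError("n_bootstrap must be 0 (off) or >= 2")
        if self.scenario == "region_subset" and not self.region_subset:
            raise ConfigError("scenario 'region_subset' requires region_subset")


@dataclass
class RunResult:
    qol_fit: QoLFit
    cost_fit: TwoPartFit
    qol_decrements: pd.DataFrame
    incremental: pd.DataFrame
    summaries: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    qol_data: pd.DataFrame | None = None
    cost_data: pd.DataFrame | None = None


def event_year_scenarios(event_types=EVENT_TYPES, include_combo: bool = True) -> dict:
    """The standard estimands: each event's event-year increment, plus
    the MI-with-urgent-CRV combination."""
    scenarios = {f"{etype}:y0": {etype: "y0"} for etype in event_types}
    if include_combo:
        scenarios["mi+crv_urgent:y0"] = {"mi": "y0", "crv_urgent": "y0"}
    return scenarios


def run_pipeline(
    config: RunConfig,
    do_selection: bool = False,
    do_merging: bool = False,
    do_interaction_search: bool = False,
) -> RunResult:
    """Execute simulate/load -> score -> build histories -> fit -> estimate.

    By default the final-model specifications are fitted directly; the
    covariate-selection, category-merging and interaction-search
    procedures can be switched on for full model-building runs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # -- inputs --------------------------------------------------------
    if config.simulation is not None:
        cohort = generate_cohort(config.simulation)
    else:
        cohort = CohortData.read(config.input_dir)
    participants, events, person_years = (
        cohort.participants, cohort.events, cohort.person_years,
    )
    tariff = load_tariff(config.tariff_path) if config.tariff_path else toy_tariff()

    if config.scenario == "region_subset":
        keep = participants["region"] == config.region_subset
        participants = participants.loc[keep]
        ids = set(participants["participant_id"])
        events = events[events["participant_id"].isin(ids)]
        person_years = person_years[person_years["participant_id"].isin(ids)]
        logger.info("region subset %r: %d participants", config.region_subset, len(participants))

    # -- score ---------------------------------------------------------
    summaries = {}
    for visit in ("baseline", "final"):
        profs = cohort.profiles[cohort.profiles["visit"] == visit]
        profs = profs[profs["participant_id"].isin(set(participants["participant_id"]))]
        if len(profs):
            summaries[f"{visit}_profiles"] = summarize_utilities(profs, tariff)

    # -- fit QoL -------------------------------------------------------
    qol_data = qol_analysis_frame(participants, events)
    qol_spec = standard_qol_spec(
        baseline_adjustment=config.scenario != "no_baseline_adjustment"
    )
    if do_selection:
        qol_spec, trace = select_covariates(qol_data, qol_spec)
        logger.info("QoL selection: %s", "; ".join(trace) or "no changes")
    if do_merging:
        for etype in qol_spec.event_types:
            qol_spec, trace = merge_temporal_categories(qol_data, qol_spec, etype)
            logger.info("QoL merging %s: %s", etype, "; ".join(trace) or "none")
    qol_fit = fit_qol_model(qol_data, qol_spec)
    qol_table = qol_decrement_table(qol_fit)

    # -- fit costs -----------------------------------------------------
    cost_data = cost_analysis_frame(participants, person_years)
    cost_spec = standard_cost_spec(config.perspective)
    if do_selection:
        cost_spec, trace = select_covariates(cost_data, cost_spec)
        logger.info("cost selection: %s", "; ".join(trace) or "no changes")
    if do_merging:
        for etype in cost_spec.event_types:
            cost_spec, trace = merge_temporal_categories(cost_data, cost_spec, etype)
            logger.info("cost merging %s: %s", etype, "; ".join(trace) or "none")
    if do_interaction_search:
        cost_spec, trace = add_interactions(cost_data, cost_spec)
        logger.info("interactions: %s", "; ".join(trace) or "none tested")
    cost_fit = fit_two_part(cost_data, cost_spec)

    # -- estimate ------------------------------------------------------
    estimates = incremental_costs(
        cost_fit,
        cost_data,
        event_year_scenarios(include_combo=config.perspective == "us"),
        n_bootstrap=config.n_bootstrap,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    inc_table = pd.DataFrame([e.as_dict() for e in estimates]).drop(columns="scenario")
    inc_table.insert(1, "perspective", config.perspective)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "scenario": config.scenario,
        "perspective": config.perspective,
        "n_participants": int(participants["participant_id"].nunique()),
        "n_person_years": int(len(person_years)),
        "qol_included": int(len(qol_data)),
        "config": _encode(config),
    }
    return RunResult(
        qol_fit, cost_fit, qol_table, inc_table, summaries, manifest,
        qol_data=qol_data, cost_data=cost_data,
    )


def write_results(result: RunResult, outdir, make_figures: bool = True) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.qol_decrements.to_csv(outdir / "qol_decrements.csv", index=False)
    result.incremental.to_csv(outdir / "incremental_costs.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    (outdir / "summaries.json").write_text(json.dumps(result.summaries, indent=2))
    fits = {
        "qol": _fit_payload(result.qol_fit.part, result.qol_fit.merge_map),
        "cost_part1": _fit_payload(result.cost_fit.part1, result.cost_fit.merge_map),
        "cost_part2": _fit_payload(result.cost_fit.part2, result.cost_fit.merge_map),
        "cost_stats": result.cost_fit.stats,
    }
    (outdir / "fits.json").write_text(json.dumps(fits, indent=2))
    if make_figures:
        plot_decrements(result.qol_decrements, outdir / "qol_decrements.png")
        plot_increments(result.incremental, outdir / "incremental_costs.png")
        if result.qol_data is not None:
            plot_qol_trajectories(result.qol_data, outdir / "qol_by_time_since_event.png")
        if result.cost_data is not None:
            persp = result.manifest.get("perspective", "uk")
            plot_cost_trajectories(
                result.cost_data, persp, outdir / "cost_by_time_since_event.png"
            )


def _fit_payload(part, merge_map):
    return {
        "params": part.params.round(6).to_dict(),
        "bse": part.bse.round(6).to_dict(),
        "cov": part.cov.round(8).to_dict(),
        "nobs": part.nobs,
        "dispersion": part.dispersion,
        "merge_map": merge_map,
    }


def _encode(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _encode(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    return obj


# -- figures -----------------------------------------------------------


def plot_decrements(table: pd.DataFrame, path) -> None:
    """Horizontal interval plot of QoL decrements by event and category."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if table.empty:
        return
    labels = [f"{r.event_type} ({r.category})" for r in table.itertuples()]
    y = np.arange(len(labels))[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(labels) + 1.5))
    ax.errorbar(
        table["decrement"], y,
        xerr=[table["decrement"] - table["ci_lower"], table["ci_upper"] - table["decrement"]],
        fmt="o", capsize=3, color="tab:blue",
    )
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_yticks(y, labels, fontsize=8)
    ax.set_xlabel("utility change vs no new event")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_increments(table: pd.DataFrame, path) -> None:
    """Bar plot of incremental annual costs with bootstrap CIs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if table.empty:
        return
    y = np.arange(len(table))[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(table) + 1.5))
    has_ci = table["ci_lower"].notna().all()
    xerr = (
        [table["point"] - table["ci_lower"], table["ci_upper"] - table["point"]]
        if has_ci
        else None
    )
    ax.errorbar(table["point"], y, xerr=xerr, fmt="o", capsize=3, color="tab:red")
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_yticks(y, table["name"], fontsize=8)
    ax.set_xlabel("additional annual hospital cost")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_qol_trajectories(qol_data: pd.DataFrame, path) -> None:
    """Mean final utility by time since the last occurrence of each event.

    Descriptive companion to the regression estimates: one line per
    event type over the categories no event, <=1y, 1-2y, 2-3y, >3y.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .events import CATEGORIES

    fig, ax = plt.subplots(figsize=(7, 4.5))
    order = list(CATEGORIES)
    ticks = ["no event", "<=1y", "1-2y", "2-3y", ">3y"]
    for etype in QOL_EVENT_TYPES:
        means = qol_data.groupby(f"qcat_{etype}")["final_utility"].mean()
        ax.plot(
            [order.index(c) for c in means.index],
            means.to_numpy(),
            marker="o",
            label=etype,
        )
    ax.set_xticks(range(len(order)), ticks)
    ax.set_xlabel("time since last event occurrence")
    ax.set_ylabel("mean final utility")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_cost_trajectories(cost_data: pd.DataFrame, perspective: str, path) -> None:
    """Mean annual hospital cost by time since the first event occurrence."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .events import CATEGORIES, DEATH_TYPES

    fig, ax = plt.subplots(figsize=(7, 4.5))
    order = list(CATEGORIES)
    ticks = ["before event", "event year", "1-2y", "2-3y", ">3y"]
    for etype in EVENT_TYPES:
        if etype in DEATH_TYPES:
            continue
        means = cost_data.groupby(f"ccat_{etype}")[f"cost_{perspective}"].mean()
        ax.plot(
            [order.index(c) for c in means.index],
            means.to_numpy(),
            marker="o",
            label=etype,
        )
    ax.set_xticks(range(len(order)), ticks)
    ax.set_xlabel("time since first event occurrence")
    ax.set_ylabel(f"mean annual hospital cost ({perspective})")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
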