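"""Incremental event effects via recycled predictions and cluster bootstrap.

The *recycled prediction* (marginal standardization) method evaluates a
fitted cost model twice on the whole analysis sample — once with a
target event's temporal category switched on for every row and once
with it switched to no-event — holding all other covariates at their
observed values.  The average difference in predicted expected cost
E[cost] = p-hat x mu-hat is the additional annual cost attributable to
the event in that time category.  When a scenario implies an
admission-defining event year (CRV or heart-failure admission), the
probability of incurring cost is fixed at 1 for that scenario.

Uncertainty comes from a cluster bootstrap: participants are resampled
with replacement (all their annual periods travel together), the model
is refitted with the fixed final specification, and the recycled
prediction recomputed; the SE is the SD across resamples and the 95% CI
the 2.5/97.5 percentiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import scipy.stats

from . import design as dsg
from .events import CERTAIN_ADMISSION_TYPES, NO_EVENT, TIME_CATEGORIES, label_members
from .modeling import (
    QoLFit,
    TwoPartFit,
    _gamma_identity_irls,
    _logit_newton,
    _sigmoid,
    build_spec_design,
    fit_two_part,
)

logger = logging.getLogger(__name__)


@dataclass
class IncrementalEstimate:
    """Additional annual cost (or utility change) for one scenario."""

    name: str
    scenario: dict[str, str]
    point: float
    se: float | None = None
    ci_lower: float | None = None
    ci_upper: float | None = None
    n_bootstrap: int | None = None

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "scenario": dict(self.scenario),
            "point": self.point,
            "se": self.se,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "n_bootstrap": self.n_bootstrap,
        }


def resolve_category(merge_map: Mapping[str, list[str]], event_type: str, category: str) -> str:
    """The (possibly merged) model label containing ``category``."""
    if event_type not in merge_map:
        raise KeyError(f"event type {event_type!r} not in the fitted model")
    if category == NO_EVENT:
        return NO_EVENT
    if category not in TIME_CATEGORIES:
        raise KeyError(f"unknown temporal category {category!r}")
    for label in merge_map[event_type]:
        if category in label_members(label):
            return label
    raise KeyError(f"category {category!r} not represented for {event_type!r}")


def _scenario_matrices(
    fit: TwoPartFit, data: pd.DataFrame, X: pd.DataFrame, scenario: Mapping[str, str]
) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix and certain-admission mask under a counterfactual.

    ``scenario`` maps event types to an original temporal category (or
    ``no_event``); all other covariates stay at observed values.
    """
    spec = fit.spec
    mm = fit.merge_map
    Xs = X.copy()
    for etype, category in scenario.items():
        label_on = resolve_category(mm, etype, category)
        for label in mm[etype]:
            col = f"{etype}:{label}"
            if col in Xs.columns:
                Xs[col] = 1.0 if label == label_on else 0.0
            elif label == label_on:
                raise KeyError(
                    f"category {category!r} of {etype!r} has no fitted coefficient"
                )
    # same-year interaction indicators under the scenario
    for (a, b) in spec.interactions:
        col = f"{a}:y0&{b}:y0"
        if col not in Xs.columns:
            continue
        ya = (
            np.full(len(data), scenario[a] == "y0", dtype=float)
            if a in scenario
            else (data[f"{spec.clock}_{a}"].astype(str) == "y0").to_numpy(dtype=float)
        )
        yb = (
            np.full(len(data), scenario[b] == "y0", dtype=float)
            if b in scenario
            else (data[f"{spec.clock}_{b}"].astype(str) == "y0").to_numpy(dtype=float)
        )
        Xs[col] = ya * yb
    certain = np.zeros(len(data), dtype=bool)
    for t in CERTAIN_ADMISSION_TYPES:
        if t in scenario:
            certain |= scenario[t] == "y0"
        elif f"{spec.clock}_{t}" in data.columns:
            certain |= (data[f"{spec.clock}_{t}"].astype(str) == "y0").to_numpy()
    return Xs, certain


def _expected_cost(fit: TwoPartFit, X: pd.DataFrame, certain: np.ndarray) -> np.ndarray:
    p = fit.part1.predict(X)
    p = np.where(certain, 1.0, p)
    mu = fit.part2.predict(X)
    return p * mu


def recycled_prediction(
    fit: TwoPartFit, data: pd.DataFrame, scenario: Mapping[str, str]
) -> float:
    """Incremental mean annual cost of ``scenario`` versus no new event.

    The reference scenario sets only the target event types to
    ``no_event``; every other event's categories stay as observed.
    """
    data = dsg.prepare_covariates(data)
    info, _ = build_spec_design(data, fit.spec, drop_empty=False)
    X = info.matrix
    scenario = dict(scenario)
    off = {etype: NO_EVENT for etype in scenario}
    X_on, certain_on = _scenario_matrices(fit, data, X, scenario)
    X_off, certain_off = _scenario_matrices(fit, data, X, off)
    return float(
        np.mean(_expected_cost(fit, X_on, certain_on) - _expected_cost(fit, X_off, certain_off))
    )


# -- cluster bootstrap -------------------------------------------------


@dataclass
class _ClusterIndex:
    starts: np.ndarray
    sizes: np.ndarray
    order: np.ndarray

    @classmethod
    def build(cls, ids: np.ndarray) -> "_ClusterIndex":
        codes = pd.factorize(ids)[0]
        order = np.argsort(codes, kind="stable")
        sorted_codes = codes[order]
        n_clusters = sorted_codes[-1] + 1
        starts = np.searchsorted(sorted_codes, np.arange(n_clusters))
        sizes = np.diff(np.append(starts, len(codes)))
        return cls(starts=starts, sizes=sizes, order=order)

    @property
    def n_clusters(self) -> int:
        return len(self.starts)

    def resample(self, rng) -> tuple[np.ndarray, np.ndarray]:
        """Row positions and new cluster ids for one bootstrap resample."""
        picked = rng.integers(0, self.n_clusters, self.n_clusters)
        idx = np.concatenate(
            [self.order[s : s + z] for s, z in zip(self.starts[picked], self.sizes[picked])]
        )
        new_ids = np.repeat(np.arange(self.n_clusters), self.sizes[picked])
        return idx, new_ids


def cluster_bootstrap(
    data: pd.DataFrame,
    pipeline: Callable[[pd.DataFrame], Mapping[str, float]],
    n_bootstrap: int = 1000,
    seed: int = 0,
    cluster_col: str = "participant_id",
    max_redraws: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percentile cluster bootstrap of arbitrary estimands.

    ``pipeline`` receives a resampled data frame (participants drawn
    with replacement; all their periods travel together; duplicated
    participants get distinct cluster ids) and returns estimand values.
    Resamples on which the pipeline raises ``ValueError`` (e.g. no
    positive costs) are redrawn, up to ``max_redraws`` extra draws.

    Returns (summary, draws): the summary has one row per estimand with
    ``se``, ``ci_lower``, ``ci_upper`` (2.5/97.5 percentiles).
    """
    if n_bootstrap < 2:
        raise ValueError("n_bootstrap must be >= 2")
    rng = np.random.default_rng(seed)
    index = _ClusterIndex.build(data[cluster_col].to_numpy())
    draws: list[Mapping[str, float]] = []
    redraws = 0
    while len(draws) < n_bootstrap:
        idx, new_ids = index.resample(rng)
        sample = data.iloc[idx].copy()
        sample[cluster_col] = new_ids
        try:
            draws.append(dict(pipeline(sample)))
        except ValueError as exc:
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError(
                    f"cluster bootstrap exceeded {max_redraws} redraws: {exc}"
                ) from exc
            logger.warning("bootstrap resample redrawn (%d so far): %s", redraws, exc)
    if redraws:
        logger.info("cluster bootstrap: %d resamples redrawn", redraws)
    draw_table = pd.DataFrame(draws)
    summary = pd.DataFrame(
        {
            "se": draw_table.std(ddof=1),
            "ci_lower": draw_table.quantile(0.025),
            "ci_upper": draw_table.quantile(0.975),
        }
    )
    summary["n_bootstrap"] = n_bootstrap
    return summary, draw_table


def _independent_column_mask(arr: np.ndarray) -> np.ndarray:
    """Columns that are nonzero and linearly independent (pivoted QR)."""
    import scipy.linalg

    nz = arr.any(axis=0)
    sub = arr[:, nz]
    keep = np.zeros(arr.shape[1], dtype=bool)
    if sub.shape[1] == 0:
        return keep
    scale = np.linalg.norm(sub, axis=0)
    r, pivots = scipy.linalg.qr(sub / scale, mode="r", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(sub.shape) * np.finfo(float).eps * (diag[0] if len(diag) else 1.0)
    rank = int((diag > tol).sum())
    keep[np.flatnonzero(nz)[pivots[:rank]]] = True
    return keep


def _bootstrap_increments(
    fit: TwoPartFit,
    data: pd.DataFrame,
    scenarios: Mapping[str, Mapping[str, str]],
    n_bootstrap: int,
    seed: int,
    max_redraws: int = 50,
) -> pd.DataFrame:
    """Cluster-bootstrap draws of recycled increments for one fit."""
    tasks = [(name, fit, scenario) for name, scenario in scenarios.items()]
    return _bootstrap_increments_joint(tasks, data, n_bootstrap, seed, max_redraws)


def _bootstrap_increments_joint(
    tasks,
    data: pd.DataFrame,
    n_bootstrap: int,
    seed: int,
    max_redraws: int = 50,
) -> pd.DataFrame:
    """Cluster-bootstrap draws of recycled increments, shared resamples.

    ``tasks`` is a list of ``(name, fit, scenario)``; the fits must be
    estimated on the same person-year data (e.g. the UK and US cost
    models) so that one resample stream serves every estimand.  Both
    parts are refitted per resample with each fit's fixed final
    specification; part-1 logistic fits are shared between fits whose
    part-1 estimation problem is identical (same any-cost outcome and
    design, as for costing perspectives that differ only in unit
    prices).  The designs and the counterfactual *deltas* (a scenario
    only changes the target event's indicator columns) are built once;
    a resample re-indexes rows, so each refit reduces to bare
    Newton/IRLS solves plus a handful of mat-vecs.
    """
    data = dsg.prepare_covariates(data)
    certain = data["certain_admission"].to_numpy(dtype=bool)
    cluster_col = tasks[0][1].spec.cluster_col or "participant_id"
    index = _ClusterIndex.build(data[cluster_col].to_numpy())

    # one precomputation per distinct fitted model
    fit_pre: dict[int, dict] = {}
    for _, fit, _ in tasks:
        if id(fit) in fit_pre:
            continue
        info, _ = build_spec_design(data, fit.spec, drop_empty=False)
        X = info.matrix
        cols = list(X.columns)
        arr = X.to_numpy(dtype=float)
        y = data[fit.spec.outcome].to_numpy(dtype=float)
        k1 = _independent_column_mask(arr[~certain])
        k2 = _independent_column_mask(arr[y > 0])
        fit_pre[id(fit)] = {
            "fit": fit, "X": X, "cols": cols, "arr": arr, "y": y,
            "k1": k1, "k2": k2,
            "warm1": fit.part1.params.reindex(cols, fill_value=0.0).to_numpy()[k1],
            "warm2": fit.part2.params.reindex(cols, fill_value=0.0).to_numpy()[k2],
        }

    # group fits whose part-1 problem is identical (same outcome sign
    # pattern and the same part-1 design columns)
    groups: list[list[int]] = []
    for key, pre in fit_pre.items():
        for g in groups:
            ref = fit_pre[g[0]]
            same_y = np.array_equal(pre["y"] > 0, ref["y"] > 0)
            same_cols = [c for i, c in enumerate(pre["cols"]) if pre["k1"][i]] == [
                c for i, c in enumerate(ref["cols"]) if ref["k1"][i]
            ]
            if same_y and same_cols and np.array_equal(
                pre["arr"][:, pre["k1"]], ref["arr"][:, ref["k1"]]
            ):
                g.append(key)
                break
        else:
            groups.append([key])
    group_of = {key: gi for gi, g in enumerate(groups) for key in g}

    # per-task scenario deltas against the task's own design
    task_pre = []
    for name, fit, scenario in tasks:
        pre = fit_pre[id(fit)]
        X, arr, cols = pre["X"], pre["arr"], pre["cols"]
        X_on, c_on = _scenario_matrices(fit, data, X, dict(scenario))
        X_off, c_off = _scenario_matrices(fit, data, X, {e: NO_EVENT for e in scenario})
        diff_cols = [
            j for j, c in enumerate(cols)
            if not (
                np.array_equal(X_on[c].to_numpy(), arr[:, j])
                and np.array_equal(X_off[c].to_numpy(), arr[:, j])
            )
        ]
        d_on = X_on.iloc[:, diff_cols].to_numpy(dtype=float) - arr[:, diff_cols]
        d_off = X_off.iloc[:, diff_cols].to_numpy(dtype=float) - arr[:, diff_cols]
        task_pre.append(
            (name, id(fit), np.array(diff_cols, dtype=int), d_on, c_on, d_off, c_off)
        )

    rng = np.random.default_rng(seed)
    draws: list[dict[str, float]] = []
    redraws = 0
    while len(draws) < n_bootstrap:
        idx, _ = index.resample(rng)
        cr = certain[idx]
        betas: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        group_beta1: dict[int, np.ndarray] = {}
        failed = None
        for key, pre in fit_pre.items():
            yr = pre["y"][idx]
            pos = yr > 0
            if not pos.any():
                failed = "no positive costs in resample"
                break
            Xr = pre["arr"][idx]
            gi = group_of[key]
            if gi not in group_beta1:
                # bootstrap draws do not need full ML precision
                group_beta1[gi], _ = _logit_newton(
                    (yr[~cr] > 0).astype(float), Xr[~cr][:, pre["k1"]], pre["warm1"],
                    tol=1e-8,
                )
            beta1_sub = group_beta1[gi]
            Bk = Xr[pos][:, pre["k2"]]
            yb = yr[pos]
            start = pre["warm2"].copy()
            mu0 = Bk @ start
            if mu0.min() <= 0:
                start, *_ = np.linalg.lstsq(Bk, yb, rcond=None)
                mu0 = Bk @ start
                if mu0.min() <= 0:
                    start[0] += 1e-3 + abs(mu0.min())
            try:
                beta2_sub = _gamma_identity_irls(yb, Bk, start, tol=1e-7)
            except (ValueError, np.linalg.LinAlgError) as exc:
                failed = str(exc)
                break
            n_cols = pre["arr"].shape[1]
            beta1 = np.zeros(n_cols)
            beta1[pre["k1"]] = beta1_sub
            beta2 = np.zeros(n_cols)
            beta2[pre["k2"]] = beta2_sub
            betas[key] = (beta1, beta2, Xr @ beta1, Xr @ beta2)
        if failed is not None:
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError(f"bootstrap exceeded redraw budget: {failed}")
            continue
        vals = {}
        for name, key, dcols, d_on, c_on, d_off, c_off in task_pre:
            beta1, beta2, eta1_obs, mu_obs = betas[key]
            b1, b2 = beta1[dcols], beta2[dcols]
            p_on = _sigmoid(eta1_obs + d_on[idx] @ b1)
            p_on = np.where(c_on[idx], 1.0, p_on)
            p_off = _sigmoid(eta1_obs + d_off[idx] @ b1)
            p_off = np.where(c_off[idx], 1.0, p_off)
            mu_on = mu_obs + d_on[idx] @ b2
            mu_off = mu_obs + d_off[idx] @ b2
            vals[name] = float(np.mean(p_on * mu_on - p_off * mu_off))
        draws.append(vals)
    if redraws:
        logger.info("increment bootstrap: %d resamples redrawn", redraws)
    return pd.DataFrame(draws)


def incremental_costs(
    fit: TwoPartFit,
    data: pd.DataFrame,
    scenarios: Mapping[str, Mapping[str, str]],
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> list[IncrementalEstimate]:
    """Point estimates plus bootstrap uncertainty for several scenarios.

    Each resample refits both parts with the *fixed* final specification
    (family, link, merged categories, interactions) before recomputing
    the recycled predictions.
    """
    points = {
        name: recycled_prediction(fit, data, scenario)
        for name, scenario in scenarios.items()
    }
    if n_bootstrap:
        draw_table = _bootstrap_increments(fit, data, scenarios, n_bootstrap, seed)
        summary = pd.DataFrame(
            {
                "se": draw_table.std(ddof=1),
                "ci_lower": draw_table.quantile(0.025),
                "ci_upper": draw_table.quantile(0.975),
            }
        )
    out = []
    for name, scenario in scenarios.items():
        est = IncrementalEstimate(name=name, scenario=dict(scenario), point=points[name])
        if n_bootstrap:
            est.se = float(summary.loc[name, "se"])
            est.ci_lower = float(summary.loc[name, "ci_lower"])
            est.ci_upper = float(summary.loc[name, "ci_upper"])
            est.n_bootstrap = n_bootstrap
        out.append(est)
    return out


def joint_incremental_costs(
    fits: Mapping[str, TwoPartFit],
    data: pd.DataFrame,
    estimands: Mapping[str, tuple[str, Mapping[str, str]]],
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> list[IncrementalEstimate]:
    """Bootstrap several estimands across several fitted cost models.

    ``estimands`` maps an estimand name to ``(fit key, scenario)``.  All
    fits must share the person-year data; the bootstrap resamples once
    per draw and refits every model on the same resample, which both
    saves time and makes estimates comparable across costing
    perspectives.
    """
    points = {
        name: recycled_prediction(fits[key], data, scenario)
        for name, (key, scenario) in estimands.items()
    }
    if n_bootstrap:
        tasks = [(name, fits[key], scenario) for name, (key, scenario) in estimands.items()]
        draw_table = _bootstrap_increments_joint(tasks, data, n_bootstrap, seed)
        summary = pd.DataFrame(
            {
                "se": draw_table.std(ddof=1),
                "ci_lower": draw_table.quantile(0.025),
                "ci_upper": draw_table.quantile(0.975),
            }
        )
    out = []
    for name, (key, scenario) in estimands.items():
        est = IncrementalEstimate(name=name, scenario=dict(scenario), point=points[name])
        if n_bootstrap:
            est.se = float(summary.loc[name, "se"])
            est.ci_lower = float(summary.loc[name, "ci_lower"])
            est.ci_upper = float(summary.loc[name, "ci_upper"])
            est.n_bootstrap = n_bootstrap
        out.append(est)
    return out


# -- QoL decrements ----------------------------------------------------


def qol_decrement_table(fit: QoLFit, alpha: float = 0.05) -> pd.DataFrame:
    """Per event x (possibly merged) category utility decrement with CI.

    Decrements are the fitted category coefficients; CIs come from the
    model covariance (no bootstrap), using the t distribution on the
    residual degrees of freedom.
    """
    rows = []
    tcrit = scipy.stats.t.ppf(1 - alpha / 2, fit.part.df_resid)
    for etype, labels in fit.merge_map.items():
        for label in labels:
            col = f"{etype}:{label}"
            if col not in fit.params.index:
                continue
            coef = float(fit.params[col])
            se = float(fit.part.bse[col])
            rows.append(
                {
                    "event_type": etype,
                    "category": label,
                    "decrement": coef,
                    "se": se,
                    "ci_lower": coef - tcrit * se,
                    "ci_upper": coef + tcrit * se,
                }
            )
    return pd.DataFrame(rows)
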