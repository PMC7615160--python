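"""QoL linear model and two-part annual-cost GLM with selection procedures.

The QoL model regresses final-visit utility on participant
characteristics, hierarchical temporal event-history categories (last
occurrence to measurement) and, in the main analysis, baseline utility,
with ordinary least squares.

Annual hospital costs are modelled in two parts: a logistic model for
incurring any cost and a conditional-mean GLM for its magnitude, with
standard errors clustered by participant.  Event-year periods of
admission-defining events (urgent/nonurgent coronary revascularization,
heart-failure admission) are excluded from part 1 — their probability of
incurring cost is 1 by definition — but contribute to part 2.

Supporting procedures implement the analysis's model-building rules:
mean imputation within sex x smoking x trial-arm cells, specification
search over family/link candidates (modified Park test, Pregibon link
test, fit statistics), block-level backward-then-forward covariate
selection at the 1% level, F-test merging of adjacent temporal
categories from the most distant pair backwards, and testing of
same-year event interactions where co-occurrence exceeds 5% of the
combined event count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from scipy.special import gammaln

from . import design as dsg
from .events import TIME_CATEGORIES, merged_label

logger = logging.getLogger(__name__)

SIGNIFICANCE_LEVEL = 0.01  # the analysis-wide threshold

_FAMILY_POWER = {"gaussian": 0.0, "poisson": 1.0, "gamma": 2.0}


class RankDeficientError(ValueError):
    """The design matrix is rank deficient; names the collinear columns."""


# -- covariate imputation ---------------------------------------------


def impute_covariates(
    participants: pd.DataFrame, columns: tuple[str, ...] = ("bmi",)
) -> pd.DataFrame:
    """Fill missing continuous covariates with cell means.

    Cells are defined by sex x smoking status x trial arm.  An entirely
    missing cell falls back to the overall mean (logged).  Categorical
    variables with printed "missing" levels keep that level.
    """
    for key in ("female", "smoking", "arm"):
        if participants[key].isna().any():
            raise ValueError(f"imputation grouping variable {key!r} has missing values")
    out = participants.copy()
    for col in columns:
        if col not in out.columns or not out[col].isna().any():
            continue
        cell_means = out.groupby(["female", "smoking", "arm"])[col].transform("mean")
        if cell_means.isna().any() & out[col].isna().any():
            empty = int((cell_means.isna() & out[col].isna()).sum())
            if empty:
                logger.warning(
                    "%d missing %r values in empty imputation cells; using overall mean",
                    empty,
                    col,
                )
        filled = out[col].fillna(cell_means)
        out[col] = filled.fillna(out[col].mean())
    return out


# -- model specification ----------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Specification of a QoL or cost regression."""

    outcome: str
    family: str = "gaussian"
    link: str = "identity"
    two_part: bool = False
    covariate_blocks: tuple[str, ...] = ()
    event_types: tuple[str, ...] = ()
    clock: str = "qcat"
    merge_map: dict | None = None
    interactions: tuple[tuple[str, str], ...] = ()
    cluster_col: str | None = None
    baseline_adjustment: bool = False
    forced: tuple[str, ...] = dsg.FORCED_BLOCKS

    def __post_init__(self):
        if self.family not in _FAMILY_POWER:
            raise ValueError(f"unknown family {self.family!r}")
        if self.link not in ("identity", "log", "logit"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.two_part and self.outcome == "final_utility":
            raise ValueError("two-part models apply to cost outcomes only")
        missing_forced = set(self.forced) - set(self.covariate_blocks)
        if missing_forced:
            raise ValueError(f"forced blocks {sorted(missing_forced)} not in covariate_blocks")

    def resolved_merge_map(self) -> dict[str, list[str]]:
        return {
            etype: list((self.merge_map or {}).get(etype, TIME_CATEGORIES))
            for etype in self.event_types
        }


def build_spec_design(
    data: pd.DataFrame, spec: ModelSpec, drop_empty: bool = True,
    baseline_center: float | None = None,
) -> tuple[dsg.DesignInfo, float | None]:
    """Assemble the design for ``spec``; returns the baseline centring used."""
    extra = None
    center = None
    if spec.baseline_adjustment:
        center = (
            float(data["baseline_utility"].mean()) if baseline_center is None else baseline_center
        )
        extra = {"baseline_c": data["baseline_utility"].to_numpy(dtype=float) - center}
    info = _build(data, spec, drop_empty, extra)
    return info, center


def _build(data, spec: ModelSpec, drop_empty, extra):
    parts = [pd.DataFrame({"intercept": np.ones(len(data))}, index=data.index)]
    cov, cov_map = dsg.covariate_design(data, spec.covariate_blocks)
    parts.append(cov)
    ev, ev_map = dsg.event_design(
        data, spec.event_types, spec.clock, spec.resolved_merge_map(), drop_empty=drop_empty
    )
    parts.append(ev)
    inter_map = {}
    if spec.interactions:
        inter, inter_map = dsg.interaction_design(data, spec.interactions, spec.clock)
        parts.append(inter)
    if extra:
        parts.append(pd.DataFrame(extra, index=data.index))
    return dsg.DesignInfo(pd.concat(parts, axis=1), cov_map, ev_map, inter_map)


def _dependent_columns(X: pd.DataFrame) -> list[str]:
    """Columns made redundant by exact collinearity (pivoted QR)."""
    import scipy.linalg

    arr = X.to_numpy(dtype=float)
    scale = np.linalg.norm(arr, axis=0)
    scale[scale == 0] = 1.0
    r, pivots = scipy.linalg.qr(arr / scale, mode="r", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(arr.shape) * np.finfo(float).eps * (diag[0] if len(diag) else 1.0)
    rank = int((diag > tol).sum())
    return [X.columns[j] for j in sorted(pivots[rank:])]


def _check_rank(X: pd.DataFrame) -> None:
    bad = _dependent_columns(X)
    if bad:
        raise RankDeficientError(f"design is rank deficient; collinear columns: {bad}")


# -- fitted-part container --------------------------------------------


@dataclass
class PartFit:
    """One fitted regression part with its (possibly clustered) covariance."""

    params: pd.Series
    cov: pd.DataFrame
    family: str
    link: str
    nobs: int
    df_resid: float
    dispersion: float
    loglik: float
    aic: float
    bic: float
    n_clusters: int | None = None

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        x = X[self.params.index].to_numpy(dtype=float)
        return x @ self.params.to_numpy()

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        eta = self.linear_predictor(X)
        if self.link == "log":
            return np.exp(eta)
        if self.family == "binomial":
            return 1.0 / (1.0 + np.exp(-eta))
        return eta


def _sm_family(family: str, link: str):
    links = {"identity": sm.families.links.Identity(), "log": sm.families.links.Log()}
    if family == "binomial":
        return sm.families.Binomial()
    if family == "gaussian":
        return sm.families.Gaussian(links[link])
    if family == "poisson":
        return sm.families.Poisson(links[link])
    if family == "gamma":
        return sm.families.Gamma(links[link])
    raise ValueError(family)


def _cluster_kwds(groups):
    if groups is None:
        return {}
    codes = pd.factorize(np.asarray(groups))[0]
    return {"cov_type": "cluster", "cov_kwds": {"groups": codes}}


def fit_part(
    y: np.ndarray,
    X: pd.DataFrame,
    family: str,
    link: str,
    groups=None,
    start_params: np.ndarray | None = None,
    check_rank: bool = True,
) -> PartFit:
    """Fit one GLM part, with the identity-link gamma safeguard.

    Identity-link gamma models start from an identity-link Gaussian fit
    and, if the standard IRLS path fails to keep fitted means positive,
    fall back to a step-halved IRLS.
    """
    if check_rank:
        _check_rank(X)
    y = np.asarray(y, dtype=float)
    kwds = _cluster_kwds(groups)
    n_clusters = int(pd.factorize(np.asarray(groups))[0].max() + 1) if groups is not None else None

    if family == "gamma" and link == "identity":
        return _fit_gamma_identity(y, X, groups, kwds, n_clusters, start_params)

    if family == "binomial":
        return _fit_logit(y, X, groups, n_clusters, start_params)
    model = sm.GLM(y, X, family=_sm_family(family, link))
    res = model.fit(start_params=start_params, **kwds)
    return _wrap_sm(res, family, link, n_clusters)


def _fit_logit(y, X, groups, n_clusters, start_params) -> PartFit:
    """Step-halved Newton logistic fit, tolerant of quasi-separation.

    Rare event-year categories can perfectly predict any-cost in small
    (re)samples; a deviance-based stopping rule and a pseudo-inverse
    guard keep the fit finite there, where the standard Newton path
    breaks on a singular Hessian.  Covariance is the model-based inverse
    Hessian, or the cluster sandwich when ``groups`` is given.
    """
    xa = X.to_numpy(dtype=float)
    n, p = xa.shape
    beta, H = _logit_newton(y, xa, start_params)
    eta = xa @ beta
    prob = _sigmoid(eta)
    dev = _binom_deviance(y, eta)
    bread = np.linalg.pinv(H)
    if groups is not None:
        codes = pd.factorize(np.asarray(groups))[0]
        scores = xa * (y - prob)[:, None]
        g = np.zeros((codes.max() + 1, p))
        np.add.at(g, codes, scores)
        cov = bread @ (g.T @ g) @ bread
    else:
        cov = bread
    llf = -0.5 * dev
    return PartFit(
        params=pd.Series(beta, index=X.columns),
        cov=pd.DataFrame(cov, index=X.columns, columns=X.columns),
        family="binomial",
        link="logit",
        nobs=n,
        df_resid=float(n - p),
        dispersion=1.0,
        loglik=llf,
        aic=-2 * llf + 2 * p,
        bic=-2 * llf + np.log(n) * p,
        n_clusters=n_clusters,
    )


def _logit_newton(y, xa, start_params=None, tol=1e-10):
    """Bare step-halved Newton solver for the logit; returns (beta, H)."""
    p = xa.shape[1]
    beta = (
        np.zeros(p)
        if start_params is None
        else np.asarray(start_params, dtype=float).copy()
    )
    eta = xa @ beta
    dev = _binom_deviance(y, eta)
    H = np.eye(p)
    for _ in range(50):
        prob = _sigmoid(eta)
        w = np.clip(prob * (1 - prob), 1e-10, None)
        H = xa.T @ (xa * w[:, None])
        score = xa.T @ (y - prob)
        ridge = 1e-8 * np.trace(H) / H.shape[0]
        try:
            step = np.linalg.solve(H + ridge * np.eye(H.shape[0]), score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, score, rcond=None)[0]
        lam = 1.0
        for _ in range(40):
            cand = beta + lam * step
            dev_c = _binom_deviance(y, xa @ cand)
            if dev_c <= dev + 1e-12:
                break
            lam *= 0.5
        else:
            break
        delta = dev - dev_c
        beta, eta, dev = cand, xa @ cand, dev_c
        if delta < tol * (abs(dev) + 1.0):
            break
    return beta, H


def _sigmoid(x):
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def _binom_deviance(y, eta):
    # -2 loglik of the Bernoulli logit, numerically stable in eta
    return 2.0 * np.sum(np.logaddexp(0.0, eta) - y * eta)


def _wrap_sm(res, family, link, n_clusters) -> PartFit:
    return PartFit(
        params=pd.Series(np.asarray(res.params), index=res.model.exog_names),
        cov=pd.DataFrame(
            np.asarray(res.cov_params()), index=res.model.exog_names, columns=res.model.exog_names
        ),
        family=family,
        link=link,
        nobs=int(res.nobs),
        df_resid=float(res.df_resid),
        dispersion=float(res.scale),
        loglik=float(res.llf),
        aic=float(res.aic),
        bic=float(res.bic_llf),
        n_clusters=n_clusters,
    )


def _fit_gamma_identity(y, X, groups, kwds, n_clusters, start_params) -> PartFit:
    """Identity-link gamma via step-halved IRLS.

    The unguarded IRLS routinely leaves the positive-mean domain on cost
    data, so the safeguarded solver is the primary path; starting values
    come from an identity-link Gaussian (OLS) fit.
    """
    if start_params is None:
        start_params = np.asarray(sm.OLS(y, X).fit().params)
    else:
        start_params = np.asarray(start_params, dtype=float)
    xa = X.to_numpy(dtype=float)
    mu0 = xa @ start_params
    if mu0.min() <= 0:
        # shift the intercept so all starting means are positive
        start_params = start_params.copy()
        start_params[0] += 1e-3 + abs(mu0.min())
    params = _gamma_identity_irls(y, xa, start_params)
    return _gamma_manual_partfit(y, X, params, groups, n_clusters)


def _gamma_identity_irls(y, X, beta, max_iter=100, tol=1e-9):
    """Step-halved IRLS for the identity-link gamma score equations.

    Keeps every iterate inside the positive-mean region; step-halving
    triggers whenever a full Fisher-scoring step would produce a
    non-positive fitted mean or fail to reduce the deviance.
    """
    mu = X @ beta
    if mu.min() <= 0:
        raise ValueError("starting values give non-positive fitted means")
    dev = _gamma_deviance(y, mu)
    for _ in range(max_iter):
        w = 1.0 / mu**2
        WX = X * w[:, None]
        score = X.T @ ((y - mu) * w)
        info = X.T @ WX
        # a tiny scaled ridge pins directions with (near-)zero
        # information at their current value instead of letting them
        # drift when a resample degenerates
        ridge = 1e-8 * np.trace(info) / info.shape[0]
        try:
            step = np.linalg.solve(info + ridge * np.eye(info.shape[0]), score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        lam = 1.0
        for _ in range(60):
            cand = beta + lam * step
            mu_c = X @ cand
            if mu_c.min() > 0:
                dev_c = _gamma_deviance(y, mu_c)
                if dev_c <= dev + 1e-12:
                    break
            lam *= 0.5
        else:
            raise ValueError("gamma identity IRLS could not find an admissible step")
        delta = dev - dev_c
        beta, mu, dev = cand, mu_c, dev_c
        if delta < tol * (abs(dev) + 1.0):
            break
    return beta


def _gamma_deviance(y, mu):
    return 2.0 * np.sum(-np.log(y / mu) + (y - mu) / mu)


def _gamma_manual_partfit(y, X, params, groups, n_clusters) -> PartFit:
    xa = X.to_numpy(dtype=float)
    mu = xa @ params
    n, p = xa.shape
    df_resid = n - p
    pearson = np.sum(((y - mu) / mu) ** 2)
    dispersion = pearson / df_resid
    w = 1.0 / mu**2
    bread = np.linalg.inv(xa.T @ (xa * w[:, None]))
    scores = xa * ((y - mu) * w)[:, None]
    if groups is not None:
        codes = pd.factorize(np.asarray(groups))[0]
        g = np.zeros((codes.max() + 1, p))
        np.add.at(g, codes, scores)
        meat = g.T @ g
    else:
        meat = scores.T @ scores
    cov = bread @ meat @ bread  # sandwich on the quasi-score scale
    # quasi-likelihood at the gamma ML shape implied by the dispersion
    k = 1.0 / dispersion
    llf = float(np.sum(k * np.log(k * y / mu) - k * y / mu - np.log(y) - gammaln(k)))
    aic = -2 * llf + 2 * (p + 1)
    bic = -2 * llf + np.log(n) * (p + 1)
    return PartFit(
        params=pd.Series(params, index=X.columns),
        cov=pd.DataFrame(cov, index=X.columns, columns=X.columns),
        family="gamma",
        link="identity",
        nobs=n,
        df_resid=df_resid,
        dispersion=dispersion,
        loglik=llf,
        aic=aic,
        bic=bic,
        n_clusters=n_clusters,
    )


# -- Wald tests --------------------------------------------------------


def wald_test(fit: PartFit, columns: list[str]) -> tuple[float, float]:
    """Wald F-statistic and p-value that the named coefficients are all 0."""
    cols = [c for c in columns if c in fit.params.index]
    if not cols:
        return np.nan, 1.0
    b = fit.params[cols].to_numpy()
    V = fit.cov.loc[cols, cols].to_numpy()
    q = len(cols)
    stat = float(b @ np.linalg.solve(V, b)) / q
    df2 = (fit.n_clusters - 1) if fit.n_clusters else fit.df_resid
    return stat, float(scipy.stats.f.sf(stat, q, df2))


def wald_equality_test(fit: PartFit, col_a: str, col_b: str) -> tuple[float, float]:
    """Wald F-test of equality of two coefficients."""
    b = fit.params[col_a] - fit.params[col_b]
    v = (
        fit.cov.loc[col_a, col_a]
        + fit.cov.loc[col_b, col_b]
        - 2 * fit.cov.loc[col_a, col_b]
    )
    stat = float(b**2 / v)
    df2 = (fit.n_clusters - 1) if fit.n_clusters else fit.df_resid
    return stat, float(scipy.stats.f.sf(stat, 1, df2))


# -- QoL model ---------------------------------------------------------


@dataclass
class QoLFit:
    """Fitted QoL linear model (classical OLS covariance by default)."""

    part: PartFit
    spec: ModelSpec
    design_info: dsg.DesignInfo
    baseline_center: float | None
    merge_map: dict[str, list[str]]
    selection_trace: list[str] = field(default_factory=list)

    @property
    def params(self) -> pd.Series:
        return self.part.params

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        data = dsg.prepare_covariates(data)
        info, _ = build_spec_design(
            data, self.spec, drop_empty=False, baseline_center=self.baseline_center
        )
        return self.part.predict(info.matrix)


def fit_qol_model(data: pd.DataFrame, spec: ModelSpec, robust: bool = False) -> QoLFit:
    """OLS fit of final-visit utility.

    ``data`` must contain complete outcome (and, for the main analysis,
    baseline-utility) values: participants who died before the final
    measurement or did not provide it are excluded upstream.
    """
    if data[spec.outcome].isna().any():
        raise ValueError("final utility missing for some rows; exclude them upstream")
    if spec.baseline_adjustment and data["baseline_utility"].isna().any():
        raise ValueError("baseline utility missing for some rows")
    data = dsg.prepare_covariates(data)
    info, center = build_spec_design(data, spec)
    X = _drop_empty_columns(info.matrix)
    _check_rank(X)
    y = data[spec.outcome].to_numpy(dtype=float)
    if robust and spec.cluster_col:
        res = sm.OLS(y, X).fit(**_cluster_kwds(data[spec.cluster_col]))
        n_clusters = int(pd.factorize(data[spec.cluster_col])[0].max() + 1)
    else:
        res = sm.OLS(y, X).fit()
        n_clusters = None
    part = PartFit(
        params=pd.Series(np.asarray(res.params), index=X.columns),
        cov=pd.DataFrame(np.asarray(res.cov_params()), index=X.columns, columns=X.columns),
        family="gaussian",
        link="identity",
        nobs=int(res.nobs),
        df_resid=float(res.df_resid),
        dispersion=float(res.scale),
        loglik=float(res.llf),
        aic=float(res.aic),
        bic=float(res.bic),
        n_clusters=n_clusters,
    )
    return QoLFit(part, spec, info, center, spec.resolved_merge_map())


# -- two-part cost model ----------------------------------------------


@dataclass
class TwoPartFit:
    """Fitted two-part cost model with cluster-robust covariances."""

    part1: PartFit
    part2: PartFit
    spec: ModelSpec
    merge_map: dict[str, list[str]]
    stats: dict[str, float] = field(default_factory=dict)
    selection_trace: list[str] = field(default_factory=list)

    def expected_cost(self, data: pd.DataFrame) -> np.ndarray:
        """E[cost] = p-hat x mu-hat, with p-hat = 1 in certain-admission years."""
        data = dsg.prepare_covariates(data)
        info, _ = build_spec_design(data, self.spec, drop_empty=False)
        X = info.matrix
        p = self.part1.predict(X)
        p = np.where(data["certain_admission"].to_numpy(dtype=bool), 1.0, p)
        mu = self.part2.predict(X)
        return p * mu


def _drop_empty_columns(X: pd.DataFrame) -> pd.DataFrame:
    keep = (X != 0).any(axis=0)
    return X.loc[:, keep] if not keep.all() else X


def _prune_collinear(X: pd.DataFrame) -> pd.DataFrame:
    """Drop exactly collinear columns.

    In small (re)samples distinct event-history indicators can coincide
    — e.g. when every urgent-CRV participant also had a same-day MI —
    and the shared effect is then attributed to the retained column.
    """
    bad = _dependent_columns(X)
    if not bad:
        return X
    logger.warning("dropping collinear design columns: %s", bad)
    return X.drop(columns=bad)


def _align_start(start, key: str, X: pd.DataFrame):
    if not start or key not in start:
        return None
    return start[key].reindex(X.columns, fill_value=0.0).to_numpy()


def fit_two_part(
    data: pd.DataFrame,
    spec: ModelSpec,
    compute_stats: bool = True,
    start: dict[str, pd.Series] | None = None,
) -> TwoPartFit:
    """Fit the two-part cost model on person-year rows.

    Part 1 (any cost, logit) excludes certain-admission event-year rows;
    part 2 fits the configured family/link on positive-cost rows.  Both
    covariances are clustered by ``spec.cluster_col``.
    """
    if not spec.two_part:
        raise ValueError("spec.two_part must be True for fit_two_part")
    data = dsg.prepare_covariates(data)
    cost = data[spec.outcome].to_numpy(dtype=float)
    if not (cost > 0).any():
        raise ValueError("no positive-cost rows: part 2 cannot be estimated")
    groups_all = data[spec.cluster_col] if spec.cluster_col else None

    certain = data["certain_admission"].to_numpy(dtype=bool)
    sample1 = data.loc[~certain]
    info1, _ = build_spec_design(sample1, spec)
    # indicators with no observations in the estimation sample are not
    # estimable and are dropped: certain-admission event-year indicators
    # (and interactions built on them) are always all-zero in part 1
    X1 = _prune_collinear(_drop_empty_columns(info1.matrix))
    y1 = (sample1[spec.outcome].to_numpy(dtype=float) > 0).astype(float)
    part1 = fit_part(
        y1,
        X1,
        "binomial",
        "logit",
        groups=sample1[spec.cluster_col] if spec.cluster_col else None,
        start_params=_align_start(start, "part1", X1),
        check_rank=False,
    )

    sample2 = data.loc[cost > 0]
    info2, _ = build_spec_design(sample2, spec)
    X2 = _prune_collinear(_drop_empty_columns(info2.matrix))
    part2 = fit_part(
        sample2[spec.outcome].to_numpy(dtype=float),
        X2,
        spec.family,
        spec.link,
        groups=sample2[spec.cluster_col] if spec.cluster_col else None,
        start_params=_align_start(start, "part2", X2),
        check_rank=False,
    )
    fit = TwoPartFit(part1, part2, spec, spec.resolved_merge_map())
    if compute_stats:
        fit.stats = _fit_stats(fit, data, cost, groups_all)
    return fit


def _fit_stats(fit: TwoPartFit, data, cost, groups_all) -> dict[str, float]:
    pred = fit.expected_cost(data)
    resid = cost - pred
    return {
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "mae": float(np.mean(np.abs(resid))),
        "aic": fit.part1.aic + fit.part2.aic,
        "bic": fit.part1.bic + fit.part2.bic,
        "loglik": fit.part1.loglik + fit.part2.loglik,
    }


# -- specification search ---------------------------------------------


def park_test(y: np.ndarray, mu: np.ndarray) -> float:
    """Modified Park test slope: Poisson-QMLE regression of squared
    residuals on log fitted mean.  Slope near 0/1/2 points to
    Gaussian/Poisson/gamma variance structure."""
    ok = mu > 0
    r2 = (y[ok] - mu[ok]) ** 2
    X = sm.add_constant(np.log(mu[ok]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(r2, X, family=sm.families.Poisson()).fit()
    return float(res.params[1])


def pregibon_link_test(y, X, family, link, groups=None) -> float:
    """p-value of the squared linear predictor when added to the model."""
    X = _prune_collinear(_drop_empty_columns(X))
    base = fit_part(y, X, family, link, groups=groups, check_rank=False)
    eta = base.linear_predictor(X)
    eta = (eta - eta.mean()) / (eta.std() + 1e-12)
    aug = pd.DataFrame({"intercept": np.ones(len(y)), "eta": eta, "eta2": eta**2}, index=X.index)
    try:
        res = fit_part(y, aug, family, link, groups=groups)
    except Exception:
        return 0.0  # cannot even fit the augmented model: treat as failing
    _, p = wald_test(res, ["eta2"])
    return p


@dataclass
class SpecCandidate:
    family: str
    link: str
    two_part: bool

    def label(self) -> str:
        return f"{'two-part' if self.two_part else 'one-part'} {self.family}/{self.link}"


def compare_specifications(
    data: pd.DataFrame, base_spec: ModelSpec, candidates: list[SpecCandidate]
) -> tuple[pd.DataFrame, ModelSpec]:
    """Rank candidate family/link/parts specifications for the cost model.

    Admissibility requires a modified Park slope within 0.5 of the
    family's variance power and a passing Pregibon link test (p >= 0.01
    on the squared linear predictor); admissible candidates are ranked
    by RMSE of predicted vs observed cost.  Returns the ranking table
    and the chosen specification.
    """
    if not candidates:
        raise ValueError("no candidate specifications supplied")
    rows = []
    cost = data[base_spec.outcome].to_numpy(dtype=float)
    for cand in candidates:
        spec = replace(base_spec, family=cand.family, link=cand.link, two_part=cand.two_part)
        try:
            if cand.two_part:
                fit = fit_two_part(data, spec)
                pred = fit.expected_cost(data)
                pos = cost > 0
                prep = dsg.prepare_covariates(data.loc[pos])
                info_pos, _ = build_spec_design(prep, spec, drop_empty=False)
                slope = park_test(cost[pos], fit.part2.predict(info_pos.matrix))
                link_p = pregibon_link_test(
                    cost[pos], info_pos.matrix, cand.family, cand.link,
                    groups=prep[spec.cluster_col] if spec.cluster_col else None)
                stats = fit.stats
            else:
                prep = dsg.prepare_covariates(data)
                info, _ = build_spec_design(prep, spec)
                part = fit_part(
                    cost, info.matrix, cand.family, cand.link,
                    groups=prep[spec.cluster_col] if spec.cluster_col else None)
                pred = part.predict(info.matrix)
                slope = park_test(cost, pred)
                link_p = pregibon_link_test(
                    cost, info.matrix, cand.family, cand.link,
                    groups=prep[spec.cluster_col] if spec.cluster_col else None)
                stats = {
                    "rmse": float(np.sqrt(np.mean((cost - pred) ** 2))),
                    "mae": float(np.mean(np.abs(cost - pred))),
                    "aic": part.aic,
                    "bic": part.bic,
                }
        except Exception as exc:
            rows.append({"spec": cand.label(), "converged": False, "error": str(exc)})
            continue
        admissible = abs(slope - _FAMILY_POWER[cand.family]) < 0.5 and link_p >= SIGNIFICANCE_LEVEL
        rows.append(
            {
                "spec": cand.label(),
                "family": cand.family,
                "link": cand.link,
                "two_part": cand.two_part,
                "converged": True,
                "park_slope": slope,
                "link_test_p": link_p,
                "admissible": admissible,
                **stats,
            }
        )
    table = pd.DataFrame(rows)
    ok = table[table.get("converged", False) == True]  # noqa: E712
    if ok.empty:
        raise RuntimeError("no candidate specification converged")
    ranked = ok.sort_values(["admissible", "rmse"], ascending=[False, True])
    table = table.set_index("spec").loc[ranked["spec"]].reset_index()
    best = ranked.iloc[0]
    chosen = replace(
        base_spec, family=best["family"], link=best["link"], two_part=bool(best["two_part"])
    )
    return table, chosen


# -- covariate selection ----------------------------------------------


def _fit_for_selection(data, spec) -> tuple[PartFit, object]:
    """The fit whose Wald tests drive selection decisions.

    For the QoL model this is the OLS fit; for cost models, selection
    follows the conditional-mean part with cluster-robust tests (part 1
    shares the selected covariate set).
    """
    if spec.two_part:
        fit = fit_two_part(data, spec)
        return fit.part2, fit
    qfit = fit_qol_model(data, spec)
    return qfit.part, qfit


def select_covariates(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[ModelSpec, list[str]]:
    """Backward elimination then a forward re-check pass, on whole blocks.

    Age and sex are always retained; every other covariate block must be
    significant at the 1% level (block Wald test) to stay.  Event-history
    blocks are part of the search space.  Returns the reduced spec and a
    trace of decisions.
    """
    trace: list[str] = []
    current = spec
    data = dsg.prepare_covariates(data)

    def block_pvalues(fit: PartFit, sp: ModelSpec) -> dict[str, float]:
        info, _ = build_spec_design(data, sp)
        out = {}
        for name in sp.covariate_blocks:
            if name in sp.forced:
                continue
            out[name] = wald_test(fit, info.covariate_cols[name])[1]
        for etype in sp.event_types:
            out[f"event:{etype}"] = wald_test(fit, info.event_cols[etype])[1]
        return out

    def drop(sp: ModelSpec, name: str) -> ModelSpec:
        if name.startswith("event:"):
            etype = name.split(":", 1)[1]
            return replace(sp, event_types=tuple(e for e in sp.event_types if e != etype))
        return replace(sp, covariate_blocks=tuple(b for b in sp.covariate_blocks if b != name))

    # backward pass
    while True:
        fit, _ = _fit_for_selection(data, current)
        pvals = block_pvalues(fit, current)
        if not pvals:
            break
        worst, worst_p = max(pvals.items(), key=lambda kv: kv[1])
        if worst_p < SIGNIFICANCE_LEVEL:
            break
        current = drop(current, worst)
        trace.append(f"backward: dropped {worst} (p={worst_p:.4f})")

    # forward re-check of everything dropped
    dropped_blocks = [b for b in spec.covariate_blocks if b not in current.covariate_blocks]
    dropped_events = [e for e in spec.event_types if e not in current.event_types]
    for name in dropped_blocks + [f"event:{e}" for e in dropped_events]:
        if name.startswith("event:"):
            trial = replace(
                current, event_types=tuple(list(current.event_types) + [name.split(":", 1)[1]])
            )
        else:
            trial = replace(current, covariate_blocks=tuple(list(current.covariate_blocks) + [name]))
        fit, _ = _fit_for_selection(data, trial)
        p = block_pvalues(fit, trial)[name]
        if p < SIGNIFICANCE_LEVEL:
            current = trial
            trace.append(f"forward: re-added {name} (p={p:.4f})")
    return current, trace


# -- temporal-category merging ----------------------------------------


def merge_temporal_categories(
    data: pd.DataFrame, spec: ModelSpec, event_type: str
) -> tuple[ModelSpec, list[str]]:
    """F-test merging of adjacent temporal categories for one event type.

    Starting from the most distant pair (>3y vs 2-3y) and moving toward
    the event year: when the two adjacent categories' effects do not
    differ at the 1% level they are combined into one indicator and the
    model refitted before the next step; the sweep stops at the first
    significant difference.  The event-year category never merges into
    the no-event reference.
    """
    data = dsg.prepare_covariates(data)
    trace: list[str] = []
    current = spec
    while True:
        labels = current.resolved_merge_map()[event_type]
        fit, _ = _fit_for_selection(data, current)
        present = [lab for lab in labels if f"{event_type}:{lab}" in fit.params.index]
        if len(present) < 2:
            break
        # most distant adjacent *present* pair
        a, b = present[-2], present[-1]
        stat, p = wald_equality_test(fit, f"{event_type}:{a}", f"{event_type}:{b}")
        if p < SIGNIFICANCE_LEVEL:
            trace.append(f"{event_type}: kept {a} | {b} distinct (p={p:.4f})")
            break
        merged = merged_label(tuple(dsg.label_members(a) + dsg.label_members(b)))
        new_labels = [lab for lab in labels if lab not in (a, b)]
        insert_at = labels.index(a)
        new_labels.insert(min(insert_at, len(new_labels)), merged)
        mm = dict(current.resolved_merge_map())
        mm[event_type] = new_labels
        current = replace(current, merge_map=mm)
        trace.append(f"{event_type}: merged {a}+{b} (p={p:.4f})")
        if len(new_labels) == 1:
            break
    return current, trace


# -- event interactions ------------------------------------------------


def cooccurrence_share(data: pd.DataFrame, pair: tuple[str, str], clock: str) -> float:
    """Same-period co-occurrences as a share of the pair's combined events."""
    a, b = pair
    ya = data[f"{clock}_{a}"].astype(str) == "y0"
    yb = data[f"{clock}_{b}"].astype(str) == "y0"
    denom = int(ya.sum() + yb.sum())
    return float((ya & yb).sum() / denom) if denom else 0.0


def add_interactions(
    data: pd.DataFrame,
    spec: ModelSpec,
    pairs: list[tuple[str, str]] | None = None,
    threshold: float = 0.05,
) -> tuple[ModelSpec, list[str]]:
    """Test same-year interactions for event pairs that co-occur often.

    A pair is tested only when same-period co-occurrences exceed
    ``threshold`` (5%) of the combined number of contributing events;
    the interaction is retained when significant at the 1% level.
    """
    data = dsg.prepare_covariates(data)
    trace: list[str] = []
    current = spec
    if pairs is None:
        ets = list(spec.event_types)
        pairs = [(a, b) for i, a in enumerate(ets) for b in ets[i + 1 :]]
    for pair in pairs:
        share = cooccurrence_share(data, pair, spec.clock)
        if share <= threshold:
            continue
        trial = replace(current, interactions=tuple(list(current.interactions) + [pair]))
        fit, _ = _fit_for_selection(data, trial)
        col = f"{pair[0]}:y0&{pair[1]}:y0"
        _, p = wald_test(fit, [col])
        if p < SIGNIFICANCE_LEVEL:
            current = trial
            trace.append(f"interaction {pair[0]}xy0 {pair[1]}xy0 retained (p={p:.4f}, share={share:.2f})")
        else:
            trace.append(f"interaction {pair[0]}xy0 {pair[1]}xy0 rejected (p={p:.4f}, share={share:.2f})")
    return current, trace
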