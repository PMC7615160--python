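"""Design-matrix construction shared by the generator and the models.

Covariates are organised in *blocks* (a categorical variable expands to
one block of dummy columns); covariate selection and Wald tests operate
on whole blocks.  Event-history covariates expand to one indicator per
(event type, temporal-category label), where a label may be a merged
union of consecutive categories such as ``"y1_2+y2_3+gt3"``.

The synthetic-data generator evaluates its generating coefficients
through the same builders, so truth dictionaries and fitted coefficient
vectors share one column-naming scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import TIME_CATEGORIES, label_members


@dataclass(frozen=True)
class Block:
    """One covariate block: a numeric column, a flag, or a categorical
    variable expanded to non-reference dummy columns."""

    name: str
    kind: str  # "numeric" | "flag" | "categorical"
    column: str
    levels: tuple[str, ...] = ()  # non-reference levels, in order
    reference: str | None = None

    def design_columns(self) -> tuple[str, ...]:
        if self.kind in ("numeric", "flag"):
            return (self.column,)
        return tuple(f"{self.column}_{lev}" for lev in self.levels)


#: The standard covariate blocks of the analysis (age and sex are the
#: always-retained blocks).
COVARIATE_BLOCKS: dict[str, Block] = {
    b.name: b
    for b in [
        Block("age", "numeric", "age_c"),
        Block("female", "flag", "female"),
        Block("region", "categorical", "region", ("other_europe", "north_america"), "uk"),
        Block(
            "disease_hist",
            "categorical",
            "disease_hist",
            ("cev_only", "pad_only", "mi_cev", "mi_pad", "cev_pad", "mi_cev_pad", "none"),
            "mi_only",
        ),
        Block("hf_hist", "flag", "hf_hist"),
        Block("af", "flag", "af"),
        Block("diabetes_hist", "flag", "diabetes_hist"),
        Block("sbp", "categorical", "sbp_cat", ("125_140", "ge140"), "lt125"),
        Block("dbp", "categorical", "dbp_cat", ("75_85", "ge85"), "lt75"),
        Block("bmi", "categorical", "bmi_cat", ("25_30", "ge30", "missing"), "lt25"),
        Block("alcohol", "categorical", "alcohol", ("former", "current"), "never"),
        Block("smoking", "categorical", "smoking", ("former", "current"), "never"),
        Block("antihypertensive", "flag", "antihypertensive"),
        Block("antithrombotic", "flag", "antithrombotic"),
        Block("amiodarone", "flag", "amiodarone"),
        Block("statin", "flag", "statin"),
        Block("ldl", "categorical", "ldl_cat", ("1_4_1_7", "ge1_7", "missing"), "lt1_4"),
        Block("hdl", "categorical", "hdl_cat", ("0_9_1_1", "ge1_1", "missing"), "lt0_9"),
        Block("tg", "categorical", "tg_cat", ("1_2_1_7", "ge1_7", "missing"), "lt1_2"),
        Block("gfr", "categorical", "gfr_cat", ("45_60", "lt45", "missing"), "ge60"),
        Block("uacr", "categorical", "uacr_cat", ("3_30", "ge30", "missing"), "lt3"),
    ]
}

FORCED_BLOCKS = ("age", "female")

REFERENCE_AGE = 67.0


def prepare_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Add derived covariate columns (centred age) in place of raw ones."""
    out = df.copy()
    if "age_c" not in out.columns:
        out["age_c"] = out["age"] - REFERENCE_AGE
    return out


def covariate_design(
    df: pd.DataFrame, block_names: list[str] | tuple[str, ...]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Dummy-expanded covariate design for the requested blocks.

    Returns the design frame (no intercept) and a mapping from block
    name to the design columns it produced.
    """
    cols: dict[str, np.ndarray] = {}
    mapping: dict[str, list[str]] = {}
    for name in block_names:
        block = COVARIATE_BLOCKS[name]
        produced = []
        if block.kind in ("numeric", "flag"):
            cols[block.column] = df[block.column].to_numpy(dtype=float)
            produced.append(block.column)
        else:
            raw = df[block.column].astype(str).to_numpy()
            for lev in block.levels:
                cname = f"{block.column}_{lev}"
                cols[cname] = (raw == lev).astype(float)
                produced.append(cname)
        mapping[name] = produced
    return pd.DataFrame(cols, index=df.index), mapping


def default_merge_map(event_types) -> dict[str, list[str]]:
    """Unmerged category labels for each event type."""
    return {etype: list(TIME_CATEGORIES) for etype in event_types}


def event_design(
    df: pd.DataFrame,
    event_types,
    clock: str,
    merge_map: dict[str, list[str]] | None = None,
    drop_empty: bool = True,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Indicator columns for (event type, temporal-category label).

    ``clock`` is ``"qcat"`` (last occurrence to QoL measurement) or
    ``"ccat"`` (first occurrence to annual period); the data frame must
    carry the corresponding ``<clock>_<type>`` label columns.  A merged
    label like ``"y1_2+y2_3+gt3"`` produces one indicator for membership
    of any constituent category.  All-zero indicators (categories that
    never occur, e.g. post-death years) are dropped when ``drop_empty``.
    """
    if clock not in ("qcat", "ccat"):
        raise ValueError(f"clock must be 'qcat' or 'ccat', got {clock!r}")
    merge_map = merge_map or default_merge_map(event_types)
    cols: dict[str, np.ndarray] = {}
    mapping: dict[str, list[str]] = {}
    for etype in event_types:
        raw = df[f"{clock}_{etype}"].astype(str).to_numpy()
        produced = []
        for label in merge_map[etype]:
            members = label_members(label)
            ind = np.isin(raw, members).astype(float)
            if drop_empty and not ind.any():
                continue
            cname = f"{etype}:{label}"
            cols[cname] = ind
            produced.append(cname)
        mapping[etype] = produced
    return pd.DataFrame(cols, index=df.index), mapping


def interaction_design(
    df: pd.DataFrame, pairs, clock: str
) -> tuple[pd.DataFrame, dict[tuple[str, str], str]]:
    """Same-year (both in their event-year category) interaction indicators."""
    cols: dict[str, np.ndarray] = {}
    mapping: dict[tuple[str, str], str] = {}
    for a, b in pairs:
        ind = (
            (df[f"{clock}_{a}"].astype(str) == "y0")
            & (df[f"{clock}_{b}"].astype(str) == "y0")
        ).to_numpy(dtype=float)
        cname = f"{a}:y0&{b}:y0"
        cols[cname] = ind
        mapping[(a, b)] = cname
    return pd.DataFrame(cols, index=df.index), mapping


def linear_predictor(
    design: pd.DataFrame, effects: dict[str, float], *, strict: bool = True
) -> np.ndarray:
    """Evaluate ``sum_j effects[j] * design[:, j]``.

    With ``strict`` (default), an effect whose column is absent from the
    design raises ``KeyError`` — this catches naming drift between truth
    dictionaries and the design builders.
    """
    out = np.zeros(len(design))
    for col, coef in effects.items():
        if col not in design.columns:
            if strict:
                raise KeyError(f"effect column {col!r} not in design")
            continue
        out += coef * design[col].to_numpy(dtype=float)
    return out


def event_effect_predictor(
    df: pd.DataFrame, event_effects: dict[str, dict[str, float]], clock: str
) -> np.ndarray:
    """Evaluate generating event-category effects on raw category columns."""
    out = np.zeros(len(df))
    for etype, cats in event_effects.items():
        raw = df[f"{clock}_{etype}"].astype(str).to_numpy()
        for cat, coef in cats.items():
            if coef != 0.0:
                out += coef * (raw == cat)
    return out


@dataclass
class DesignInfo:
    """A fully assembled design: intercept + covariates + events (+
    interactions), with block bookkeeping for tests and selection."""

    matrix: pd.DataFrame
    covariate_cols: dict[str, list[str]] = field(default_factory=dict)
    event_cols: dict[str, list[str]] = field(default_factory=dict)
    interaction_cols: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def columns(self) -> list[str]:
        return list(self.matrix.columns)

    def block_columns(self, block: str) -> list[str]:
        if block in self.covariate_cols:
            return self.covariate_cols[block]
        if block in self.event_cols:
            return self.event_cols[block]
        raise KeyError(block)


def build_design(
    df: pd.DataFrame,
    covariate_blocks,
    event_types,
    clock: str,
    merge_map: dict[str, list[str]] | None = None,
    interactions=(),
    extra_numeric: dict[str, np.ndarray] | None = None,
) -> DesignInfo:
    parts = [pd.DataFrame({"intercept": np.ones(len(df))}, index=df.index)]
    cov, cov_map = covariate_design(df, covariate_blocks)
    parts.append(cov)
    ev, ev_map = event_design(df, event_types, clock, merge_map)
    parts.append(ev)
    inter_map: dict[tuple[str, str], str] = {}
    if interactions:
        inter, inter_map = interaction_design(df, interactions, clock)
        parts.append(inter)
    if extra_numeric:
        parts.append(pd.DataFrame(extra_numeric, index=df.index))
    matrix = pd.concat(parts, axis=1)
    return DesignInfo(matrix, cov_map, ev_map, inter_map)
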