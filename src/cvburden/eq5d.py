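"""EQ-5D-5L profile validation and utility scoring under pluggable value sets.

The EQ-5D-5L descriptive system records five dimensions of health
(mobility, self-care, usual activities, pain/discomfort,
anxiety/depression), each at one of five levels: 1 (no problems) through
5 (extreme problems).  A country-specific *value set* ("tariff") maps
each of the 3125 possible profiles to a utility on a scale where 1 is
full health, 0 is a state equivalent to death and negative values are
states worse than death.

This module implements the additive-decrement family of value sets:

    utility(profile) = 1 - sum_d decrement(d, level_d) + adjustments

which covers the published UK (EEPRU-based), US and Chinese EQ-5D-5L
value sets.  The coefficients of those licensed value sets are not
redistributed here; tariffs are loaded from user-supplied CSV tables
(columns ``dimension, level, decrement``).  A clearly labelled synthetic
"toy" tariff with the same structure is bundled for tests and examples.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)
LEVELS = (1, 2, 3, 4, 5)
FULL_HEALTH = (1, 1, 1, 1, 1)


class TariffError(ValueError):
    """A tariff table is incomplete or violates its anchoring invariants."""


class ProfileError(ValueError):
    """An EQ-5D-5L profile has a level outside 1..5."""


@dataclass(frozen=True)
class EQ5DProfile:
    """One EQ-5D-5L health-state descriptor (five levels, each 1-5)."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self) -> None:
        for dim, level in zip(DIMENSIONS, self.levels):
            if level not in LEVELS:
                raise ProfileError(
                    f"{dim} level must be an integer in 1..5, got {level!r}"
                )

    @property
    def levels(self) -> tuple[int, int, int, int, int]:
        return (
            self.mobility,
            self.self_care,
            self.usual_activities,
            self.pain_discomfort,
            self.anxiety_depression,
        )

    @property
    def is_full_health(self) -> bool:
        return self.levels == FULL_HEALTH


@dataclass
class Tariff:
    """Additive EQ-5D-5L value set.

    Parameters
    ----------
    name:
        Identifier of the value set (e.g. ``"toy"``).
    decrements:
        Mapping ``(dimension, level) -> utility decrement``, covering all
        25 cells.  Level-1 decrements must be 0 so that the full-health
        profile (1,1,1,1,1) anchors at exactly 1.0.
    constant:
        Optional additive adjustment applied to every profile *worse than
        full health* (some value sets subtract a fixed term once any
        problem is reported).  Full health always scores 1.0.
    """

    name: str
    decrements: Mapping[tuple[str, int], float]
    constant: float = 0.0
    _score_grid: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            for level in LEVELS:
                if (dim, level) not in self.decrements:
                    raise TariffError(f"tariff {self.name!r} missing cell ({dim}, {level})")
            if abs(self.decrements[(dim, 1)]) > 1e-12:
                raise TariffError(
                    f"tariff {self.name!r}: level-1 decrement for {dim} must be 0"
                )

    def decrement_matrix(self) -> np.ndarray:
        """5x5 array of decrements, rows = dimensions, columns = levels 1..5."""
        return np.array(
            [[self.decrements[(dim, lev)] for lev in LEVELS] for dim in DIMENSIONS]
        )

    # -- scoring -------------------------------------------------------

    def score(self, profile: EQ5DProfile | Sequence[int]) -> float:
        levels = _as_levels(profile)
        total = sum(self.decrements[(dim, lev)] for dim, lev in zip(DIMENSIONS, levels))
        if levels == FULL_HEALTH:
            return 1.0
        return 1.0 - total + self.constant

    def score_levels(self, levels: np.ndarray) -> np.ndarray:
        """Vectorised scoring of an (n, 5) integer level array."""
        levels = np.asarray(levels)
        if levels.ndim != 2 or levels.shape[1] != 5:
            raise ProfileError("expected an (n, 5) array of levels")
        if ((levels < 1) | (levels > 5)).any():
            raise ProfileError("levels outside 1..5")
        mat = self.decrement_matrix()
        dec = mat[np.arange(5)[None, :], levels - 1].sum(axis=1)
        out = 1.0 - dec + self.constant
        out[(levels == 1).all(axis=1)] = 1.0
        return out

    def all_profiles(self) -> tuple[np.ndarray, np.ndarray]:
        """All 3125 profiles and their utilities (cached)."""
        if self._score_grid is None:
            grid = np.stack(
                np.meshgrid(*[np.array(LEVELS)] * 5, indexing="ij"), axis=-1
            ).reshape(-1, 5)
            scores = self.score_levels(grid)
            object.__setattr__(self, "_score_grid", (grid, scores))
        return self._score_grid  # type: ignore[return-value]

    def nearest_profiles(self, utilities: np.ndarray) -> np.ndarray:
        """Profiles whose tariff score is nearest each utility.

        Ties are broken in favour of the lexicographically smallest
        profile (the grid is enumerated in lexicographic order).
        """
        grid, scores = self.all_profiles()
        order = np.lexsort((np.arange(len(scores)), scores))  # stable by profile order
        s_sorted = scores[order]
        u = np.asarray(utilities, dtype=float)
        idx = np.searchsorted(s_sorted, u)
        idx = np.clip(idx, 1, len(s_sorted) - 1)
        lo, hi = idx - 1, idx
        d_lo = np.abs(u - s_sorted[lo])
        d_hi = np.abs(s_sorted[hi] - u)
        # prefer the candidate with smaller distance; on an exact tie the
        # lexicographically smaller profile among equal-score candidates
        # was kept first by the stable sort, but lo/hi may still tie.
        pick_hi = d_hi < d_lo
        chosen = np.where(pick_hi, hi, lo)
        tie = np.isclose(d_lo, d_hi)
        if tie.any():
            cand_lo, cand_hi = order[lo[tie]], order[hi[tie]]
            g = grid
            lo_smaller = np.array(
                [tuple(g[a]) <= tuple(g[b]) for a, b in zip(cand_lo, cand_hi)]
            )
            chosen[tie] = np.where(lo_smaller, lo[tie], hi[tie])
        return grid[order[chosen]]


def _as_levels(profile: EQ5DProfile | Sequence[int]) -> tuple[int, ...]:
    if isinstance(profile, EQ5DProfile):
        return profile.levels
    levels = tuple(int(v) for v in profile)
    if len(levels) != 5 or any(v not in LEVELS for v in levels):
        raise ProfileError(f"invalid profile {profile!r}")
    return levels


def score_profile(profile: EQ5DProfile | Sequence[int], tariff: Tariff) -> float:
    """Utility of a single profile under ``tariff`` (1.0 for full health)."""
    return tariff.score(profile)


def score_profiles(profiles: pd.DataFrame | np.ndarray, tariff: Tariff) -> np.ndarray:
    """Utilities for a table of profiles (columns = the five dimensions)."""
    if isinstance(profiles, pd.DataFrame):
        arr = profiles[list(DIMENSIONS)].to_numpy(dtype=int)
    else:
        arr = np.asarray(profiles, dtype=int)
    return tariff.score_levels(arr)


def summarize_utilities(
    profiles: pd.DataFrame | np.ndarray | Iterable[Sequence[int]],
    tariff: Tariff,
) -> dict[str, float]:
    """Mean and SD of utilities plus the fraction of full-health profiles.

    Raises ``ValueError`` on an empty input.
    """
    if isinstance(profiles, pd.DataFrame):
        arr = profiles[list(DIMENSIONS)].to_numpy(dtype=int)
    else:
        arr = np.asarray([_as_levels(p) for p in profiles] if not isinstance(profiles, np.ndarray) else profiles, dtype=int)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty set of profiles")
    utilities = tariff.score_levels(arr)
    return {
        "n": int(len(utilities)),
        "mean": float(np.mean(utilities)),
        "sd": float(np.std(utilities, ddof=1)) if len(utilities) > 1 else 0.0,
        "full_health_fraction": float((arr == 1).all(axis=1).mean()),
    }


# -- tariff I/O --------------------------------------------------------


def load_tariff(path_or_buffer, name: str | None = None, constant: float = 0.0) -> Tariff:
    """Load a tariff from a CSV with columns ``dimension, level, decrement``."""
    table = pd.read_csv(path_or_buffer)
    required = {"dimension", "level", "decrement"}
    if not required.issubset(table.columns):
        raise TariffError(f"tariff CSV must have columns {sorted(required)}")
    dec = {
        (str(row.dimension), int(row.level)): float(row.decrement)
        for row in table.itertuples()
    }
    return Tariff(name=name or "user", decrements=dec, constant=constant)


def save_tariff(tariff: Tariff, path) -> None:
    rows = [
        {"dimension": dim, "level": lev, "decrement": tariff.decrements[(dim, lev)]}
        for dim in DIMENSIONS
        for lev in LEVELS
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def toy_tariff() -> Tariff:
    """The bundled synthetic value set.

    This is *not* a licensed national value set: its decrements are
    invented, chosen only to be monotone in level, to weight
    pain/discomfort and mobility more heavily (as published value sets
    do) and to span utilities from 1.0 down to about -0.3.  Licensed UK
    (EEPRU), US or Chinese EQ-5D-5L coefficients should be supplied as a
    CSV via :func:`load_tariff` for real analyses.
    """
    ref = importlib.resources.files("cvburden").joinpath("data/toy_tariff.csv")
    with ref.open("rb") as fh:
        return load_tariff(fh, name="toy")
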