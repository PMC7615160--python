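"""Configuration objects for the synthetic cohort generator and pipeline runs.

All generating parameters of the synthetic cohort are explicit and
serializable: event incidences, the coefficients of the QoL generating
model, the coefficients of the two-part cost generating model, and the
marginal distributions of the baseline covariates.  Packaged defaults
(:mod:`cvburden.defaults`) are calibrated to the published estimates
from a large secondary-prevention trial cohort; every field can be
overridden.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from .events import CERTAIN_ADMISSION_TYPES, DEATH_TYPES, EVENT_TYPES, TIME_CATEGORIES


class ConfigError(ValueError):
    """A configuration field is invalid; the message names the field."""


@dataclass
class QolTruth:
    """Generating coefficients of the linear model for final-visit utility.

    ``intercept`` is the expected utility of the reference patient (male,
    aged 67, prior MI only, lowest risk-factor categories, no new events)
    at the cohort-average baseline utility.  ``baseline_coef`` multiplies
    the participant's centred baseline utility.  ``covariate_effects``
    and ``event_effects`` are keyed by design-matrix column names and by
    (event type, temporal category) respectively; omitted keys mean a
    zero effect.
    """

    intercept: float
    baseline_coef: float
    residual_sd: float
    covariate_effects: dict[str, float] = field(default_factory=dict)
    event_effects: dict[str, dict[str, float]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.residual_sd <= 0:
            raise ConfigError("qol_truth.residual_sd must be > 0")
        for etype, cats in self.event_effects.items():
            if etype not in EVENT_TYPES:
                raise ConfigError(f"qol_truth.event_effects has unknown event type {etype!r}")
            for cat in cats:
                if cat not in TIME_CATEGORIES:
                    raise ConfigError(
                        f"qol_truth.event_effects[{etype!r}] has unknown category {cat!r}"
                    )


@dataclass
class CostPartTruth:
    """Coefficients for one part of the two-part cost generating model.

    For part 1 these are logit coefficients for the probability of any
    hospital cost; for part 2 they are identity-link GBP- or USD-scale
    effects on the conditional mean annual cost.  Event-year categories
    of admission-defining events (urgent/nonurgent coronary
    revascularization, heart-failure admission) carry no part-1
    coefficient: their any-cost probability is 1 by construction.
    """

    intercept: float
    covariate_effects: dict[str, float] = field(default_factory=dict)
    event_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    #: same-year interaction effects, keyed by (event a, event b) pairs
    interaction_effects: dict[tuple[str, str], float] = field(default_factory=dict)

    def validate(self, name: str) -> None:
        for etype, cats in self.event_effects.items():
            if etype not in EVENT_TYPES:
                raise ConfigError(f"{name}.event_effects has unknown event type {etype!r}")
            for cat in cats:
                if cat not in TIME_CATEGORIES:
                    raise ConfigError(
                        f"{name}.event_effects[{etype!r}] has unknown category {cat!r}"
                    )
        for pair in self.interaction_effects:
            if len(pair) != 2 or any(e not in EVENT_TYPES for e in pair):
                raise ConfigError(f"{name}.interaction_effects has invalid pair {pair!r}")


@dataclass
class CostTruth:
    """Two-part generating model for annual hospital costs.

    Part 1 (any-cost logit) is shared across costing perspectives: the
    same admissions are costed under each convention.  Part 2 holds one
    conditional-mean model per perspective (``"uk"``, ``"us"``).
    Conditional costs are drawn from a gamma distribution with shape
    ``gamma_shape`` (default 0.5: heavily right-skewed, SD exceeding the
    mean, as observed for annual hospital costs).
    """

    part1: CostPartTruth
    part2: dict[str, CostPartTruth]
    gamma_shape: float = 0.5

    def validate(self) -> None:
        if self.gamma_shape <= 0:
            raise ConfigError("cost_truth.gamma_shape must be > 0")
        self.part1.validate("cost_truth.part1")
        for etype in CERTAIN_ADMISSION_TYPES:
            if "y0" in self.part1.event_effects.get(etype, {}):
                raise ConfigError(
                    f"cost_truth.part1: {etype} event-year periods are certain "
                    "admissions and carry no part-1 coefficient"
                )
        if not self.part2:
            raise ConfigError("cost_truth.part2 must define at least one perspective")
        for persp, truth in self.part2.items():
            truth.validate(f"cost_truth.part2[{persp!r}]")


@dataclass
class EventCoupling:
    """Same-day triggering of one event type by another.

    With probability ``prob``, an occurrence of ``trigger`` is
    accompanied by a same-day occurrence of ``target`` (e.g. an MI
    treated with an urgent coronary revascularization).  The target's
    configured cumulative incidence is interpreted as the *total*
    incidence; the background (untriggered) incidence is reduced
    accordingly.
    """

    trigger: str
    target: str
    prob: float

    def validate(self) -> None:
        for fld in ("trigger", "target"):
            if getattr(self, fld) not in EVENT_TYPES:
                raise ConfigError(f"event_couplings.{fld} has unknown type {getattr(self, fld)!r}")
        if not 0.0 <= self.prob <= 1.0:
            raise ConfigError("event_couplings.prob must be in [0, 1]")
        if self.trigger in DEATH_TYPES or self.target in DEATH_TYPES:
            raise ConfigError("event_couplings cannot involve death types")


@dataclass
class BaselineUtilityDist:
    """Mixture distribution for baseline utility: a point mass at full
    health plus a truncated normal below the full-health ceiling."""

    full_health_prob: float
    rest_mean: float
    rest_sd: float
    lower: float = -0.3
    upper: float = 0.975

    def validate(self) -> None:
        if not 0.0 <= self.full_health_prob <= 1.0:
            raise ConfigError("baseline_utility.full_health_prob must be in [0, 1]")
        if self.rest_sd <= 0:
            raise ConfigError("baseline_utility.rest_sd must be > 0")
        if self.lower >= self.upper:
            raise ConfigError("baseline_utility.lower must be < upper")

    def mean(self) -> float:
        """Exact population mean (used as the centring constant)."""
        from scipy.stats import truncnorm

        a = (self.lower - self.rest_mean) / self.rest_sd
        b = (self.upper - self.rest_mean) / self.rest_sd
        rest = truncnorm.mean(a, b, loc=self.rest_mean, scale=self.rest_sd)
        return self.full_health_prob * 1.0 + (1 - self.full_health_prob) * float(rest)


@dataclass
class CohortConfig:
    """Full generating configuration for one synthetic cohort."""

    n_participants: int
    seed: int
    followup_years: float = 4.0
    #: half-width (years) of the uniform jitter on individual follow-up
    #: duration; 0 gives every survivor exactly ``followup_years``.
    followup_jitter: float = 0.0
    event_rates: dict[str, float] = field(default_factory=dict)
    event_couplings: list[EventCoupling] = field(default_factory=list)
    #: probability that a nonfatal event type recurs once after its first
    #: occurrence (exercises the last- vs first-occurrence clocks).
    recurrence_prob: float = 0.15
    #: frailty tilt: nonfatal event probabilities scale with
    #: exp(kappa * (mean baseline utility - baseline utility)), so
    #: participants in worse baseline health have more events.  This is
    #: what makes the baseline-QoL adjustment consequential (omitting it
    #: inflates event decrements, as observed in sensitivity analyses).
    event_frailty_kappa: float = 1.0
    qol_truth: QolTruth | None = None
    cost_truth: CostTruth | None = None
    covariate_dist: dict[str, Any] = field(default_factory=dict)
    baseline_utility: BaselineUtilityDist | None = None
    #: probability that a surviving participant misses the final QoL visit
    missing_final_qol_rate: float = 0.0

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ConfigError("n_participants must be > 0")
        if self.followup_years <= 0:
            raise ConfigError("followup_years must be > 0")
        if self.followup_jitter < 0 or self.followup_jitter >= self.followup_years:
            raise ConfigError("followup_jitter must be in [0, followup_years)")
        if set(self.event_rates) != set(EVENT_TYPES):
            raise ConfigError(
                "event_rates keys must be exactly the 10 event types; got "
                f"{sorted(self.event_rates)}"
            )
        for etype, rate in self.event_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"event_rates[{etype!r}] must be in [0, 1]")
        if not 0.0 <= self.missing_final_qol_rate <= 1.0:
            raise ConfigError("missing_final_qol_rate must be in [0, 1]")
        if not 0.0 <= self.recurrence_prob <= 1.0:
            raise ConfigError("recurrence_prob must be in [0, 1]")
        if self.event_frailty_kappa < 0:
            raise ConfigError("event_frailty_kappa must be >= 0")
        for coupling in self.event_couplings:
            coupling.validate()
        if self.qol_truth is not None:
            self.qol_truth.validate()
        if self.cost_truth is not None:
            self.cost_truth.validate()
        if self.baseline_utility is not None:
            self.baseline_utility.validate()

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {_key_str(k): encode(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [encode(v) for v in obj]
            return obj

        return encode(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def save(self, path) -> None:
        path = str(path)
        with open(path, "w") as fh:
            if path.endswith((".yaml", ".yml")):
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
            else:
                json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "CohortConfig":
        raw = dict(raw)
        if raw.get("qol_truth"):
            raw["qol_truth"] = QolTruth(**raw["qol_truth"])
        if raw.get("cost_truth"):
            ct = dict(raw["cost_truth"])
            ct["part1"] = _cost_part_from_dict(ct["part1"])
            ct["part2"] = {k: _cost_part_from_dict(v) for k, v in ct["part2"].items()}
            raw["cost_truth"] = CostTruth(**ct)
        if raw.get("baseline_utility"):
            raw["baseline_utility"] = BaselineUtilityDist(**raw["baseline_utility"])
        if raw.get("event_couplings"):
            raw["event_couplings"] = [
                c if isinstance(c, EventCoupling) else EventCoupling(**c)
                for c in raw["event_couplings"]
            ]
        return cls(**raw)

    @classmethod
    def load(cls, path) -> "CohortConfig":
        with open(str(path)) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)


def _cost_part_from_dict(raw: Mapping[str, Any]) -> CostPartTruth:
    raw = dict(raw)
    if "interaction_effects" in raw:
        raw["interaction_effects"] = {
            tuple(k.split("|")) if isinstance(k, str) else tuple(k): v
            for k, v in raw["interaction_effects"].items()
        }
    return CostPartTruth(**raw)


def _key_str(key):
    if isinstance(key, tuple):
        return "|".join(map(str, key))
    return key
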