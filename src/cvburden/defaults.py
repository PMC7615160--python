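"""Packaged default generating parameters for the synthetic cohort.

The defaults emulate a large secondary-prevention trial population
recruited in Europe and North America: 21 820 participants aged 50+
followed for about four years, with ten tracked adverse-event types,
EQ-5D-5L utilities at baseline and final visit, and annual hospital
costs under UK (NHS) and US (Medicare) costing conventions.

Calibration surfaces
--------------------
* covariate marginals and event cumulative incidences: the published
  baseline table and event counts of the reference cohort;
* the QoL generating coefficients: the published final QoL regression
  (reference-patient utility 0.929 UK / 0.967 US; event-year decrements
  such as heart-failure admission -0.072 and nonhemorrhagic stroke
  -0.067 under the UK tariff);
* the cost generating coefficients: chosen so that the *model-implied
  recycled-prediction increments* equal the published additional annual
  hospital costs (e.g. noncoronary revascularization event year £5830
  UK; MI with urgent CRV $24 722 US) and the overall mean annual cost
  equals £607 / $2114, with hospital costs in about 20% of person-years.
  The part-2 coefficients that achieve this were solved numerically with
  :func:`cvburden.calibration.calibrate_cost_truth` and are frozen here.

Note: the published baseline table reports 85.7% of participants with
eGFR < 45 mL/min/1.73m^2 and 9.7% with eGFR >= 60, which is implausible
for this population and almost certainly a mislabelled row; the defaults
nevertheless follow the printed categories (see docs/methods.md).
"""

from __future__ import annotations

from .config import (
    BaselineUtilityDist,
    CohortConfig,
    CostPartTruth,
    CostTruth,
    EventCoupling,
    QolTruth,
)

#: Participant and event counts printed for the reference cohort; all
#: default rates derive from these.
REFERENCE_COUNTS = {
    "participants": 21_820,
    "person_years": 96_962,
    "qol_analysis_included": 19_321,
    "full_health_final": 6_312,
    "died_during_followup": 1_668,
    "missing_final_qol": 831,
    "events": {
        "mi": 989,
        "crv_urgent": 735,
        "crv_nonurgent": 1_047,
        "stroke": 549,
        "hf_admission": 647,
        "noncoronary_revasc": 901,
        "cancer": 1_618,
        "diabetes": 840,
        "vascular_death": 708,
        "nonvascular_death": 960,
    },
    "mi_with_crv_urgent": 482,
}

_N = REFERENCE_COUNTS["participants"]

DEFAULT_EVENT_RATES = {
    etype: count / _N for etype, count in REFERENCE_COUNTS["events"].items()
}

#: Share of MIs accompanied by a same-day urgent coronary
#: revascularization (482 of 989 in the reference cohort); this drives
#: the same-year co-occurrence that makes the MI x urgent-CRV
#: interaction testable.
DEFAULT_EVENT_COUPLINGS = [
    EventCoupling(
        trigger="mi",
        target="crv_urgent",
        prob=REFERENCE_COUNTS["mi_with_crv_urgent"] / REFERENCE_COUNTS["events"]["mi"],
    )
]

#: Baseline covariate marginals (counts from the published baseline
#: table; probabilities are count/21820).  Categorical variables carry
#: their printed "missing" levels.
DEFAULT_COVARIATE_DIST: dict = {
    "female": 3_110 / _N,
    "age": {"mean": 67.09, "sd": 8.3, "min": 50.0},
    "region": {"uk": 8_381 / _N, "other_europe": 7_357 / _N, "north_america": 6_082 / _N},
    "disease_hist": {
        "mi_only": 13_652 / _N,
        "cev_only": 2_426 / _N,
        "pad_only": 1_245 / _N,
        "mi_cev": 1_536 / _N,
        "mi_pad": 597 / _N,
        "cev_pad": 335 / _N,
        "mi_cev_pad": 182 / _N,
        "none": 1_847 / _N,
    },
    "hf_hist": 1_128 / _N,
    "af": 1_457 / _N,
    "diabetes_hist": 7_360 / _N,
    "sbp_cat": {"lt125": 8_482 / _N, "125_140": 6_954 / _N, "ge140": 6_384 / _N},
    "dbp_cat": {"lt75": 8_399 / _N, "75_85": 7_746 / _N, "ge85": 5_675 / _N},
    "bmi_cat": {"lt25": 3_542 / _N, "25_30": 9_453 / _N, "ge30": 8_785 / _N, "missing": 40 / _N},
    "alcohol": {"never": 10_311 / _N, "former": 2_421 / _N, "current": 9_088 / _N},
    "smoking": {"never": 9_033 / _N, "former": 10_013 / _N, "current": 2_774 / _N},
    "antihypertensive": 20_378 / _N,
    "antithrombotic": 21_075 / _N,
    "amiodarone": 344 / _N,
    "statin": 21_215 / _N,
    "ldl_cat": {"lt1_4": 6_804 / _N, "1_4_1_7": 6_471 / _N, "ge1_7": 8_322 / _N, "missing": 223 / _N},
    "hdl_cat": {"lt0_9": 5_791 / _N, "0_9_1_1": 7_209 / _N, "ge1_1": 8_597 / _N, "missing": 223 / _N},
    "tg_cat": {"lt1_2": 8_589 / _N, "1_2_1_7": 5_957 / _N, "ge1_7": 7_051 / _N, "missing": 223 / _N},
    "gfr_cat": {"lt45": 18_709 / _N, "45_60": 766 / _N, "ge60": 2_122 / _N, "missing": 223 / _N},
    "uacr_cat": {"lt3": 17_251 / _N, "3_30": 2_817 / _N, "ge30": 537 / _N, "missing": 1_215 / _N},
}

#: Baseline-utility mixtures per tariff perspective: a full-health point
#: mass plus a truncated normal, matched to the published baseline means
#: (0.84 UK, 0.88 US).
DEFAULT_BASELINE_UTILITY = {
    "uk": BaselineUtilityDist(full_health_prob=0.30, rest_mean=0.82, rest_sd=0.17),
    "us": BaselineUtilityDist(full_health_prob=0.36, rest_mean=0.86, rest_sd=0.17),
}

# -- QoL generating models --------------------------------------------

# Covariate effects shared by both perspectives: modest utility
# decrements for older age, female sex, current smoking, obesity, atrial
# fibrillation and reduced kidney function, per the published model's
# qualitative findings.  Omitted columns (region, DBP, lipids,
# medications) have zero generating effect and exist to exercise
# covariate selection.
_QOL_COVARIATE_EFFECTS = {
    "age_c": -0.0015,
    "female": -0.03,
    "disease_hist_cev_only": -0.02,
    "disease_hist_pad_only": -0.03,
    "disease_hist_mi_cev": -0.03,
    "disease_hist_mi_pad": -0.035,
    "disease_hist_cev_pad": -0.04,
    "disease_hist_mi_cev_pad": -0.05,
    "disease_hist_none": 0.01,
    "hf_hist": -0.05,
    "af": -0.03,
    "diabetes_hist": -0.02,
    "sbp_cat_125_140": -0.003,
    "sbp_cat_ge140": -0.008,
    "bmi_cat_25_30": -0.01,
    "bmi_cat_ge30": -0.04,
    "alcohol_current": 0.005,
    "alcohol_former": -0.01,
    "smoking_current": -0.03,
    "smoking_former": -0.005,
    "gfr_cat_45_60": -0.015,
    "gfr_cat_lt45": -0.03,
    "uacr_cat_3_30": -0.015,
    "uacr_cat_ge30": -0.05,
}

#: Event-category utility decrements on the *last-occurrence* clock.
#: MI, coronary revascularization and incident diabetes have zero
#: generating effect (the reference analysis detected none and excluded
#: them from its final model).
_QOL_EVENT_EFFECTS = {
    "uk": {
        "stroke": {"y0": -0.067, "y1_2": -0.067, "y2_3": -0.067, "gt3": -0.067},
        "hf_admission": {"y0": -0.072, "y1_2": -0.094, "y2_3": -0.013, "gt3": -0.013},
        "noncoronary_revasc": {"y0": -0.071, "y1_2": -0.041, "y2_3": 0.0, "gt3": 0.0},
        "cancer": {"y0": -0.064, "y1_2": -0.032, "y2_3": -0.032, "gt3": -0.032},
    },
    "us": {
        "stroke": {"y0": -0.069, "y1_2": -0.069, "y2_3": -0.069, "gt3": -0.069},
        "hf_admission": {"y0": -0.103, "y1_2": -0.086, "y2_3": -0.032, "gt3": -0.032},
        "noncoronary_revasc": {"y0": -0.061, "y1_2": -0.048, "y2_3": -0.018, "gt3": -0.018},
        "cancer": {"y0": -0.068, "y1_2": -0.036, "y2_3": -0.036, "gt3": -0.036},
    },
}

DEFAULT_QOL_TRUTH = {
    "uk": QolTruth(
        intercept=0.929,
        baseline_coef=0.6,
        residual_sd=0.17,
        covariate_effects=dict(_QOL_COVARIATE_EFFECTS),
        event_effects=_QOL_EVENT_EFFECTS["uk"],
    ),
    "us": QolTruth(
        intercept=0.967,
        baseline_coef=0.6,
        residual_sd=0.17,
        covariate_effects=dict(_QOL_COVARIATE_EFFECTS),
        event_effects=_QOL_EVENT_EFFECTS["us"],
    ),
}

# -- cost generating model --------------------------------------------

#: Part 1 (logit of any hospital cost in a person-year), shared across
#: costing perspectives.  Event-year periods of admission-defining
#: events (CRV, HF admission) are certain and carry no coefficient.
_COST_PART1_COVARIATES = {
    "age_c": 0.015,
    "female": 0.05,
    "diabetes_hist": 0.25,
    "hf_hist": 0.5,
    "af": 0.3,
    "disease_hist_cev_only": 0.15,
    "disease_hist_pad_only": 0.25,
    "disease_hist_mi_cev": 0.25,
    "disease_hist_mi_pad": 0.3,
    "disease_hist_cev_pad": 0.3,
    "disease_hist_mi_cev_pad": 0.35,
    "disease_hist_none": -0.1,
    "gfr_cat_lt45": 0.2,
    "gfr_cat_45_60": 0.1,
    "smoking_current": 0.15,
    "bmi_cat_ge30": 0.1,
}

_POST = {"y1_2": 0.5, "y2_3": 0.35, "gt3": 0.25}
_COST_PART1_EVENTS = {
    "mi": {"y0": 2.5, **_POST},
    "stroke": {"y0": 2.5, **_POST},
    "noncoronary_revasc": {"y0": 3.0, **_POST},
    "cancer": {"y0": 2.0, **_POST},
    "diabetes": {"y0": 0.3, "y1_2": 0.3, "y2_3": 0.3, "gt3": 0.3},
    "crv_urgent": dict(_POST),
    "crv_nonurgent": dict(_POST),
    # chronic heart failure keeps admission odds persistently elevated
    "hf_admission": {"y1_2": 1.0, "y2_3": 0.9, "gt3": 0.8},
    "vascular_death": {"y0": 1.5},
    "nonvascular_death": {"y0": 1.5},
}

#: Part-1 intercept calibrated (cvburden.calibration) so that 20% of
#: person-years incur any hospital cost.
_COST_PART1_INTERCEPT = -2.2597

_COST_PART2_COVARIATES = {
    "uk": {"age_c": 10.0, "hf_hist": 300.0, "diabetes_hist": 100.0, "af": 150.0, "gfr_cat_lt45": 150.0},
    "us": {"age_c": 30.0, "hf_hist": 900.0, "diabetes_hist": 300.0, "af": 450.0, "gfr_cat_lt45": 450.0},
}

# Part-2 conditional-mean effects (identity link), solved so that the
# model-implied recycled-prediction increments equal the published
# additional annual hospital costs, and the intercept so that the
# overall mean annual cost equals the published mean.  Frozen output of
# cvburden.calibration.calibrate_cost_truth (internal design seed
# 713901, n=40000).
_CALIBRATED_PART2 = {
    "uk": {
        "intercept": 1704.8,
        "events": {
            "mi": {"y0": 2249.3, "y1_2": 729.5, "y2_3": 1018.1, "gt3": 1230.5},
            "stroke": {"y0": 2885.2, "y1_2": 469.0, "y2_3": 732.5, "gt3": 926.6},
            "crv_urgent": {"y0": 3001.3, "y1_2": -259.6, "y2_3": -61.3, "gt3": 85.9},
            "crv_nonurgent": {"y0": 2980.3, "y1_2": 471.6, "y2_3": 746.8, "gt3": 951.0},
            "hf_admission": {"y0": 1520.2, "y1_2": 1373.3, "y2_3": 1581.8, "gt3": 1809.0},
            "noncoronary_revasc": {"y0": 5882.5, "y1_2": 1489.7, "y2_3": 1853.8, "gt3": 2121.6},
            "cancer": {"y0": 2635.7, "y1_2": 1856.6, "y2_3": 1556.5, "gt3": 1801.4},
            "diabetes": {"y0": -81.6, "y1_2": -81.6, "y2_3": -81.6, "gt3": -81.6},
            "vascular_death": {"y0": 443.8},
            "nonvascular_death": {"y0": 1775.5},
        },
        "interactions": {},
    },
    "us": {
        "intercept": 6994.4,
        "events": {
            "mi": {"y0": 5692.1, "y1_2": 791.4, "y2_3": 1689.8, "gt3": 2349.7},
            "stroke": {"y0": 2800.7, "y1_2": 135.8, "y2_3": 973.0, "gt3": 1588.5},
            "crv_urgent": {"y0": 8794.7, "y1_2": -102.9, "y2_3": 725.8, "gt3": 1337.7},
            "crv_nonurgent": {"y0": 11076.2, "y1_2": 1852.7, "y2_3": 2894.4, "gt3": 3664.6},
            "hf_admission": {"y0": 3451.4, "y1_2": 3043.4, "y2_3": 3710.1, "gt3": 4435.5},
            "noncoronary_revasc": {"y0": 12002.7, "y1_2": 3796.4, "y2_3": 4996.0, "gt3": 5877.1},
            "cancer": {"y0": 9261.2, "y1_2": 6375.3, "y2_3": 5279.5, "gt3": 6161.2},
            "diabetes": {"y0": -284.7, "y1_2": -284.7, "y2_3": -284.7, "gt3": -284.7},
            "vascular_death": {"y0": -917.7},
            "nonvascular_death": {"y0": 500.3},
        },
        "interactions": {("mi", "crv_urgent"): 3760.3},
    },
}

#: Published targets of the cost calibration (the implied increments the
#: defaults reproduce); kept here so the calibration can be re-run.
COST_INCREMENT_TARGETS = {
    "uk": {
        "mean_annual_cost": 607.0,
        "any_cost_share": 0.20,
        "events": {
            "mi": {"y0": 2603.0, "y1_2": 360.0, "y2_3": 360.0, "gt3": 360.0},
            "stroke": {"y0": 3049.0, "y1_2": 291.0, "y2_3": 291.0, "gt3": 291.0},
            "crv_urgent": {"y0": 4674.0, "y1_2": 100.0, "y2_3": 100.0, "gt3": 100.0},
            "crv_nonurgent": {"y0": 4651.0, "y1_2": 292.0, "y2_3": 292.0, "gt3": 292.0},
            "hf_admission": {"y0": 3182.0, "y1_2": 861.0, "y2_3": 861.0, "gt3": 861.0},
            "noncoronary_revasc": {"y0": 5830.0, "y1_2": 557.0, "y2_3": 557.0, "gt3": 557.0},
            "cancer": {"y0": 2329.0, "y1_2": 645.0, "y2_3": 478.0, "gt3": 478.0},
            "diabetes": {"y0": 76.0, "y1_2": 76.0, "y2_3": 76.0, "gt3": 76.0},
            "vascular_death": {"y0": 807.0},
            "nonvascular_death": {"y0": 1429.0},
        },
        "combo_mi_crv_urgent_y0": None,  # no same-year interaction (UK)
    },
    "us": {
        "mean_annual_cost": 2114.0,
        "any_cost_share": 0.20,
        "events": {
            "mi": {"y0": 7972.0, "y1_2": 829.0, "y2_3": 829.0, "gt3": 829.0},
            "stroke": {"y0": 5982.0, "y1_2": 657.0, "y2_3": 657.0, "gt3": 657.0},
            "crv_urgent": {"y0": 15251.0, "y1_2": 604.0, "y2_3": 604.0, "gt3": 604.0},
            "crv_nonurgent": {"y0": 17539.0, "y1_2": 1114.0, "y2_3": 1114.0, "gt3": 1114.0},
            "hf_admission": {"y0": 9898.0, "y1_2": 2484.0, "y2_3": 2484.0, "gt3": 2484.0},
            "noncoronary_revasc": {"y0": 14133.0, "y1_2": 1619.0, "y2_3": 1619.0, "gt3": 1619.0},
            "cancer": {"y0": 8438.0, "y1_2": 2263.0, "y2_3": 1657.0, "gt3": 1657.0},
            "diabetes": {"y0": 287.0, "y1_2": 287.0, "y2_3": 287.0, "gt3": 287.0},
            "vascular_death": {"y0": 1840.0},
            "nonvascular_death": {"y0": 2505.0},
        },
        "combo_mi_crv_urgent_y0": 24722.0,  # same-year interaction (US only)
    },
}


def default_cost_truth() -> CostTruth:
    part2 = {}
    for persp, cal in _CALIBRATED_PART2.items():
        part2[persp] = CostPartTruth(
            intercept=cal["intercept"],
            covariate_effects=dict(_COST_PART2_COVARIATES[persp]),
            event_effects={e: dict(c) for e, c in cal["events"].items()},
            interaction_effects=dict(cal["interactions"]),
        )
    return CostTruth(
        part1=CostPartTruth(
            intercept=_COST_PART1_INTERCEPT,
            covariate_effects=dict(_COST_PART1_COVARIATES),
            event_effects={e: dict(c) for e, c in _COST_PART1_EVENTS.items()},
        ),
        part2=part2,
        gamma_shape=0.5,
    )


def default_config(
    n_participants: int = _N,
    seed: int = 0,
    perspective: str = "uk",
) -> CohortConfig:
    """The packaged default cohort configuration.

    ``perspective`` selects the tariff scale of the QoL generating model
    and of the baseline-utility distribution (``"uk"`` or ``"us"``);
    annual costs are always generated under both costing conventions.
    """
    import copy

    survivors = _N - REFERENCE_COUNTS["died_during_followup"]
    config = CohortConfig(
        n_participants=n_participants,
        seed=seed,
        followup_years=4.0,
        followup_jitter=0.0,
        event_rates=dict(DEFAULT_EVENT_RATES),
        event_couplings=copy.deepcopy(DEFAULT_EVENT_COUPLINGS),
        recurrence_prob=0.15,
        qol_truth=copy.deepcopy(DEFAULT_QOL_TRUTH[perspective]),
        cost_truth=default_cost_truth(),
        covariate_dist=copy.deepcopy(DEFAULT_COVARIATE_DIST),
        baseline_utility=copy.deepcopy(DEFAULT_BASELINE_UTILITY[perspective]),
        missing_final_qol_rate=REFERENCE_COUNTS["missing_final_qol"] / survivors,
    )
    config.validate()
    return config
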