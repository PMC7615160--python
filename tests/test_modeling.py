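"""QoL and two-part cost models, specification tests and selection rules."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cvburden import default_config, generate_cohort
from cvburden.modeling import (
    ModelSpec,
    RankDeficientError,
    SpecCandidate,
    add_interactions,
    build_spec_design,
    compare_specifications,
    fit_part,
    fit_qol_model,
    fit_two_part,
    impute_covariates,
    merge_temporal_categories,
    park_test,
    select_covariates,
)
from cvburden.pipeline import (
    cost_analysis_frame,
    qol_analysis_frame,
    standard_cost_spec,
    standard_qol_spec,
)


class TestImputation:
    def _frame(self):
        return pd.DataFrame(
            {
                "female": [0, 0, 0, 1, 1, 1],
                "smoking": ["never"] * 6,
                "arm": [0, 0, 0, 0, 0, 0],
                "bmi": [24.0, 26.0, np.nan, 30.0, 32.0, np.nan],
            }
        )

    def test_no_missing_unchanged(self):
        df = self._frame().dropna()
        out = impute_covariates(df)
        pd.testing.assert_frame_equal(out, df)

    def test_cell_mean_used(self):
        out = impute_covariates(self._frame())
        assert out.loc[2, "bmi"] == pytest.approx(25.0)   # male never-smoker cell
        assert out.loc[4 + 1, "bmi"] == pytest.approx(31.0)

    def test_empty_cell_falls_back_to_overall_mean(self, caplog):
        df = self._frame()
        df.loc[df.female == 1, "bmi"] = np.nan  # whole female cell missing
        out = impute_covariates(df)
        assert out.loc[3, "bmi"] == pytest.approx(25.0)  # overall mean of observed

    def test_missing_grouping_variable_rejected(self):
        df = self._frame()
        df.loc[0, "smoking"] = np.nan
        with pytest.raises(ValueError):
            impute_covariates(df)


class TestQolModel:
    def test_zero_noise_recovers_generating_coefficients(self):
        """With (near) zero residual noise OLS interpolates the truth."""
        cfg = default_config(n_participants=2500, seed=77)
        cfg.qol_truth.residual_sd = 1e-9
        cohort = generate_cohort(cfg)
        data = qol_analysis_frame(cohort.participants, cohort.events)
        fit = fit_qol_model(data, standard_qol_spec())
        truth = cfg.qol_truth
        # the fitted intercept is evaluated at the sample-mean baseline
        expected_intercept = truth.intercept + truth.baseline_coef * (
            data["baseline_utility"].mean() - cfg.baseline_utility.mean()
        )
        # stored utilities are quantized to 1e-4, which bounds the
        # attainable agreement
        assert fit.params["intercept"] == pytest.approx(expected_intercept, abs=5e-4)
        assert fit.params["hf_admission:y0"] == pytest.approx(-0.072, abs=5e-4)
        assert fit.params["stroke:y1_2"] == pytest.approx(-0.067, abs=5e-4)
        assert fit.params["female"] == pytest.approx(-0.03, abs=5e-4)
        assert fit.params["baseline_c"] == pytest.approx(0.6, abs=5e-4)

    def test_missing_outcome_rejected(self, small_cohort):
        data = small_cohort.participants  # includes decedents (NaN outcome)
        with pytest.raises(ValueError, match="exclude"):
            fit_qol_model(data, standard_qol_spec())

    def test_rank_deficiency_names_columns(self, small_qol_frame):
        data = small_qol_frame.copy()
        data["af"] = data["hf_hist"]  # exact collinearity
        with pytest.raises(RankDeficientError, match="af|hf_hist"):
            fit_qol_model(data, standard_qol_spec())


def _plain_two_part_frame(rng, n=400, all_positive=False):
    """Minimal person-year-like frame with no event covariates."""
    age = rng.normal(67, 8, n)
    female = rng.integers(0, 2, n).astype(float)
    p = 1.0 if all_positive else 0.6
    incur = rng.random(n) < p
    mu = 2000 + 30 * (age - 67) + 500 * female
    cost = np.where(incur, rng.gamma(0.5, mu / 0.5), 0.0)
    return pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "age": age,
            "female": female,
            "cost": cost,
            "certain_admission": False,
        }
    )


def _plain_spec():
    return ModelSpec(
        outcome="cost",
        family="gamma",
        link="identity",
        two_part=True,
        covariate_blocks=("age", "female"),
        event_types=(),
        clock="ccat",
        cluster_col="participant_id",
    )


class TestTwoPartModel:
    def test_all_positive_costs_degenerate_part1(self, rng):
        data = _plain_two_part_frame(rng, all_positive=True)
        fit = fit_two_part(data, _plain_spec())
        from cvburden import design as dsg
        X = build_spec_design(dsg.prepare_covariates(data), _plain_spec(), drop_empty=False)[0].matrix
        assert fit.part1.predict(X).min() > 0.99
        expected = fit.expected_cost(data)
        assert np.allclose(expected, fit.part2.predict(X), rtol=0.02)

    def test_expected_cost_decomposition_oracle(self, small_cost_frame):
        """E[Y] = p x mu: the mean fitted expected cost reproduces the
        sample mean cost."""
        fit = fit_two_part(small_cost_frame, standard_cost_spec("uk"))
        pred = fit.expected_cost(small_cost_frame).mean()
        assert pred == pytest.approx(small_cost_frame["cost_uk"].mean(), rel=0.05)

    def test_certain_rows_excluded_from_part1_only(self, small_cost_frame):
        fit = fit_two_part(small_cost_frame, standard_cost_spec("uk"))
        certain = small_cost_frame["certain_admission"]
        assert fit.part1.nobs == int((~certain).sum())
        assert fit.part2.nobs == int((small_cost_frame["cost_uk"] > 0).sum())
        # certain rows with positive cost are in the part-2 sample
        assert (small_cost_frame.loc[certain, "cost_uk"] > 0).all()

    def test_part1_exclusion_never_changes_part2(self, small_cost_frame):
        """Flipping the certain-admission flags changes part 1's sample
        but leaves part 2 untouched."""
        fit_a = fit_two_part(small_cost_frame, standard_cost_spec("uk"))
        relaxed = small_cost_frame.copy()
        relaxed["certain_admission"] = False
        fit_b = fit_two_part(relaxed, standard_cost_spec("uk"))
        pd.testing.assert_series_equal(fit_a.part2.params, fit_b.part2.params)
        assert fit_a.part1.nobs < fit_b.part1.nobs

    def test_no_positive_costs_rejected(self, rng):
        data = _plain_two_part_frame(rng)
        data["cost"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            fit_two_part(data, _plain_spec())

    def test_logit_matches_statsmodels_reference(self, rng):
        n = 3000
        X = pd.DataFrame(
            {"intercept": 1.0, "x": rng.normal(size=n), "f": rng.integers(0, 2, n) * 1.0}
        )
        y = (rng.random(n) < 1 / (1 + np.exp(-(-1 + 0.7 * X.x)))).astype(float)
        mine = fit_part(y, X, "binomial", "logit")
        ref = sm.Logit(y, X).fit(disp=False)
        assert np.allclose(mine.params, ref.params, atol=1e-6)
        assert np.allclose(mine.bse, ref.bse, rtol=1e-4)

    def test_gamma_identity_matches_statsmodels_reference(self, rng):
        n = 4000
        X = pd.DataFrame({"intercept": 1.0, "x": rng.integers(0, 2, n) * 1.0})
        mu = 1000 + 600 * X.x.to_numpy()
        y = rng.gamma(2.0, mu / 2.0)
        mine = fit_part(y, X, "gamma", "identity")
        ref = sm.GLM(y, X, family=sm.families.Gamma(sm.families.links.Identity())).fit(
            start_params=[1000.0, 600.0]
        )
        assert np.allclose(mine.params, ref.params, rtol=1e-5)

    def test_singleton_clusters_reduce_to_classical_sandwich(self, rng):
        """With one period per participant the cluster-robust covariance
        equals the heteroskedasticity-robust (HC0) sandwich."""
        n = 2000
        X = pd.DataFrame({"intercept": 1.0, "x": rng.normal(size=n)})
        y = (rng.random(n) < 0.4).astype(float)
        clustered = fit_part(y, X, "binomial", "logit", groups=np.arange(n))
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit(cov_type="HC0")
        assert np.allclose(clustered.cov, ref.cov_params(), rtol=1e-4)


class TestSpecificationSearch:
    def test_park_slope_identifies_variance_power(self, rng):
        n = 4000
        mu = rng.uniform(500, 5000, n)
        gamma_y = rng.gamma(0.7, mu / 0.7)
        assert abs(park_test(gamma_y, mu) - 2.0) < 0.5
        gauss_y = mu + rng.normal(0, 300, n)
        assert abs(park_test(gauss_y, mu)) < 0.5

    def test_single_candidate_chosen_trivially(self, small_cost_frame):
        table, chosen = compare_specifications(
            small_cost_frame,
            standard_cost_spec("uk"),
            [SpecCandidate("gamma", "identity", True)],
        )
        assert len(table) == 1
        assert (chosen.family, chosen.link, chosen.two_part) == ("gamma", "identity", True)

    def test_identity_gamma_two_part_preferred_on_its_own_data(self, small_cost_frame):
        """Data generated by a two-part identity-link gamma model rank
        that specification first among the candidate battery."""
        candidates = [
            SpecCandidate("gaussian", "identity", False),
            SpecCandidate("gaussian", "log", False),
            SpecCandidate("poisson", "log", False),
            SpecCandidate("gaussian", "identity", True),
            SpecCandidate("poisson", "log", True),
            SpecCandidate("gamma", "log", True),
            SpecCandidate("gamma", "identity", True),
        ]
        table, chosen = compare_specifications(
            small_cost_frame, standard_cost_spec("uk"), candidates
        )
        assert chosen.two_part and chosen.family == "gamma" and chosen.link == "identity"


@pytest.fixture(scope="module")
def selection_cohort():
    """QoL cohort whose truth zeroes out age, sex and lipids but
    keeps a strong heart-failure-history effect."""
    cfg = default_config(n_participants=6000, seed=314)
    cfg.qol_truth.covariate_effects["age_c"] = 0.0
    cfg.qol_truth.covariate_effects["female"] = 0.0
    cohort = generate_cohort(cfg)
    return qol_analysis_frame(cohort.participants, cohort.events)


class TestCovariateSelection:
    def test_selection_rules(self, selection_cohort):
        spec = ModelSpec(
            outcome="final_utility",
            covariate_blocks=("age", "female", "hf_hist", "ldl", "uacr", "dbp"),
            event_types=("stroke", "hf_admission"),
            clock="qcat",
            baseline_adjustment=True,
        )
        reduced, trace = select_covariates(selection_cohort, spec)
        # forced blocks survive even with zero generating effects
        assert "age" in reduced.covariate_blocks and "female" in reduced.covariate_blocks
        # zero-effect blocks are eliminated
        assert "ldl" not in reduced.covariate_blocks
        assert "dbp" not in reduced.covariate_blocks
        # strongly predictive blocks and event histories survive
        assert "hf_hist" in reduced.covariate_blocks
        assert "stroke" in reduced.event_types
        assert any("dropped" in t for t in trace)


class TestCategoryMerging:
    def test_equal_tail_categories_collapse(self):
        """Equal generating effects beyond the event year collapse into
        one band while the distinct event-year effect survives."""
        cfg = default_config(n_participants=9000, seed=2718)
        cfg.qol_truth.event_effects["stroke"] = {
            "y0": -0.15, "y1_2": -0.04, "y2_3": -0.04, "gt3": -0.04
        }
        cohort = generate_cohort(cfg)
        data = qol_analysis_frame(cohort.participants, cohort.events)
        spec, trace = merge_temporal_categories(data, standard_qol_spec(), "stroke")
        labels = spec.resolved_merge_map()["stroke"]
        assert labels == ["y0", "y1_2+y2_3+gt3"]

    def test_distinct_categories_not_merged(self):
        # a common event with widely separated category effects gives
        # the pairwise F-tests the power to keep all four bands
        cfg = default_config(n_participants=9000, seed=2719)
        cfg.event_rates["stroke"] = 0.15
        cfg.qol_truth.event_effects["stroke"] = {
            "y0": -0.30, "y1_2": -0.20, "y2_3": -0.10, "gt3": -0.01
        }
        cohort = generate_cohort(cfg)
        data = qol_analysis_frame(cohort.participants, cohort.events)
        spec, trace = merge_temporal_categories(data, standard_qol_spec(), "stroke")
        assert spec.resolved_merge_map()["stroke"] == ["y0", "y1_2", "y2_3", "gt3"]

    def test_single_category_event_is_noop(self, small_qol_frame):
        data = small_qol_frame.copy()
        rows = np.arange(len(data))
        data["qcat_stroke"] = np.where(rows % 20 == 0, "y0", "no_event")
        spec, trace = merge_temporal_categories(data, standard_qol_spec(), "stroke")
        assert spec.resolved_merge_map()["stroke"] == ["y0", "y1_2", "y2_3", "gt3"]
        assert trace == []


class TestInteractions:
    def test_pair_without_cooccurrence_not_tested(self, small_cost_frame):
        spec = standard_cost_spec("uk")
        out, trace = add_interactions(small_cost_frame, spec, pairs=[("stroke", "cancer")])
        assert out.interactions == ()
        assert trace == []

    def test_true_interaction_retained(self):
        """A strong same-year MI x urgent-CRV cost interaction is found
        and kept when co-occurrence clears the 5% bar."""
        cfg = default_config(n_participants=4000, seed=99)
        cfg.cost_truth.part2["uk"].interaction_effects[("mi", "crv_urgent")] = 15000.0
        cohort = generate_cohort(cfg)
        data = cost_analysis_frame(cohort.participants, cohort.person_years)
        spec = standard_cost_spec("uk")
        out, trace = add_interactions(data, spec, pairs=[("mi", "crv_urgent")])
        assert ("mi", "crv_urgent") in out.interactions

    def test_null_interaction_rarely_retained(self):
        """With zero generating interaction the 1%-level test keeps the
        term only at its nominal false-positive rate."""
        kept = 0
        for seed in range(12):
            cfg = default_config(n_participants=1500, seed=500 + seed)
            cohort = generate_cohort(cfg)  # UK truth has no interaction
            data = cost_analysis_frame(cohort.participants, cohort.person_years)
            out, _ = add_interactions(
                data, standard_cost_spec("uk"), pairs=[("mi", "crv_urgent")]
            )
            kept += ("mi", "crv_urgent") in out.interactions
        assert kept <= 2
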