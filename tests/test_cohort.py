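"""Synthetic cohort generator: determinism, calibration and consistency."""

import numpy as np
import pandas as pd
import pytest

from cvburden import CohortData, ConfigError, default_config, generate_cohort
from cvburden.config import CostPartTruth, CostTruth
from cvburden.defaults import DEFAULT_COVARIATE_DIST, DEFAULT_EVENT_RATES
from cvburden.events import DEATH_TYPES, EVENT_TYPES, NO_EVENT


def binomial_sd(p, n):
    return np.sqrt(p * (1 - p) / n)


class TestDeterminism:
    def test_same_seed_reproduces_tables(self):
        cfg = default_config(n_participants=600, seed=42)
        a = generate_cohort(cfg)
        b = generate_cohort(default_config(n_participants=600, seed=42))
        for x, y in [
            (a.participants, b.participants),
            (a.events, b.events),
            (a.person_years, b.person_years),
            (a.profiles, b.profiles),
        ]:
            pd.testing.assert_frame_equal(x, y)

    def test_written_tables_byte_identical(self, tmp_path):
        cfg = default_config(n_participants=300, seed=5)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_cohort(cfg).write(d1)
        generate_cohort(default_config(n_participants=300, seed=5)).write(d2)
        for name in ("participants.csv", "events.csv", "person_years.csv", "profiles.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
        again = CohortData.read(d1)
        assert again.config.config_hash() == cfg.config_hash()

    def test_different_seed_differs(self):
        a = generate_cohort(default_config(n_participants=300, seed=1))
        b = generate_cohort(default_config(n_participants=300, seed=2))
        assert not a.participants["baseline_utility"].equals(b.participants["baseline_utility"])


class TestDegenerateConfig:
    def test_no_events_zero_costs(self):
        cfg = default_config(n_participants=200, seed=0)
        cfg.event_rates = {e: 0.0 for e in EVENT_TYPES}
        cfg.cost_truth = CostTruth(
            part1=CostPartTruth(intercept=0.0),
            part2={"uk": CostPartTruth(intercept=0.0), "us": CostPartTruth(intercept=0.0)},
        )
        cohort = generate_cohort(cfg)
        assert len(cohort.events) == 0
        py = cohort.person_years
        assert (py["cost_uk"] == 0).all() and (py["cost_us"] == 0).all()
        assert not py["any_cost"].any()
        for etype in EVENT_TYPES:
            assert (py[f"ccat_{etype}"] == NO_EVENT).all()


class TestCalibration:
    def test_event_incidences_match_configured_rates(self, small_cohort):
        """Cumulative incidences within 3 binomial SDs of the defaults
        (e.g. MI 4.5%)."""
        n = len(small_cohort.participants)
        ev = small_cohort.events
        for etype in ("mi", "stroke", "noncoronary_revasc", "cancer", "diabetes"):
            rate = DEFAULT_EVENT_RATES[etype]
            got = ev.loc[ev.event_type == etype, "participant_id"].nunique() / n
            assert abs(got - rate) < 3 * binomial_sd(rate, n), etype

    def test_covariate_marginals_match_table(self, small_cohort):
        """Generated frequencies within 4 binomial SDs of the configured
        marginals (e.g. female 14.3%)."""
        p = small_cohort.participants
        n = len(p)
        checks = {
            ("female", None): DEFAULT_COVARIATE_DIST["female"],
            ("smoking", "current"): DEFAULT_COVARIATE_DIST["smoking"]["current"],
            ("gfr_cat", "lt45"): DEFAULT_COVARIATE_DIST["gfr_cat"]["lt45"],
            ("disease_hist", "mi_only"): DEFAULT_COVARIATE_DIST["disease_hist"]["mi_only"],
        }
        for (col, level), target in checks.items():
            got = (p[col] == 1).mean() if level is None else (p[col] == level).mean()
            assert abs(got - target) < 4 * binomial_sd(target, n), (col, level)

    def test_age_eligibility_floor(self, small_cohort):
        assert (small_cohort.participants["age"] >= 50).all()

    def test_mi_crv_coupling_produces_cooccurrence(self, small_cohort):
        """About half of MIs carry a same-day urgent CRV, so same-year
        co-occurrence is far above the 5% interaction-testing bar."""
        from cvburden.modeling import cooccurrence_share

        share = cooccurrence_share(small_cohort.person_years, ("mi", "crv_urgent"), "ccat")
        assert share > 0.15

    def test_mean_cost_matches_analytic_oracle(self, small_cohort):
        """Empirical mean annual cost agrees with the analytic
        part1-probability x part2-mean computed from the generating
        coefficients on the realized design."""
        from cvburden.calibration import _Design, _Part1, _mu_observed
        from cvburden import design as dsg

        cohort = small_cohort
        py = cohort.person_years.reset_index(drop=True)
        parts = dsg.prepare_covariates(cohort.participants).set_index("participant_id")
        cov, _ = dsg.covariate_design(parts, list(dsg.COVARIATE_BLOCKS))
        des = _Design(
            py=py,
            row_cov=cov.loc[py["participant_id"]].reset_index(drop=True),
            certain_obs=py["certain_admission"].to_numpy(dtype=bool),
        )
        p = _Part1(cohort.config.cost_truth, des).p_observed()
        for persp in ("uk", "us"):
            mu = _mu_observed(cohort.config.cost_truth, persp, des, scaled=True)
            analytic = float(np.mean(p * mu))
            empirical = float(py[f"cost_{persp}"].mean())
            mc_se = py[f"cost_{persp}"].std() / np.sqrt(len(py))
            assert abs(empirical - analytic) < 4 * mc_se, persp


class TestConsistency:
    def test_events_within_at_risk_window(self, small_cohort):
        p = small_cohort.participants.set_index("participant_id")
        ev = small_cohort.events
        end = p["followup_days"].reindex(ev["participant_id"]).to_numpy()
        assert (ev["day"].to_numpy() >= 0).all()
        assert (ev["day"].to_numpy() <= end + 1e-9).all()

    def test_death_types_unique_and_terminal(self, small_cohort):
        ev = small_cohort.events
        deaths = ev[ev.event_type.isin(DEATH_TYPES)]
        assert deaths.participant_id.is_unique
        p = small_cohort.participants.set_index("participant_id")
        dd = p["death_day"].dropna()
        assert set(deaths.participant_id) == set(dd.index)

    def test_person_year_invariants(self, small_cohort):
        py = small_cohort.person_years
        assert ((py["exposure"] > 0) & (py["exposure"] <= 1)).all()
        assert (py.loc[py["certain_admission"], "any_cost"]).all()
        assert (py["any_cost"] == ((py["cost_uk"] > 0) | (py["cost_us"] > 0))).all()

    def test_decedents_lack_final_utility(self, small_cohort):
        p = small_cohort.participants
        died = p["death_day"].notna()
        assert p.loc[died, "final_utility"].isna().all()
        assert p.loc[died, "qol_day"].isna().all()

    def test_profiles_near_generated_utilities(self, small_cohort, tariff):
        """Profile tariff scores track the generated utilities up to
        grid resolution and the full-health ceiling."""
        from cvburden.eq5d import score_profiles

        prof = small_cohort.profiles.query("visit == 'baseline'")
        p = small_cohort.participants.set_index("participant_id")
        scored = score_profiles(prof, tariff)
        target = p.loc[prof["participant_id"], "baseline_utility"].to_numpy()
        assert np.abs(scored - np.clip(target, None, 1.0)).max() < 0.05


class TestConfigValidation:
    def test_missing_event_rate_key_named(self):
        cfg = default_config(n_participants=10, seed=0)
        del cfg.event_rates["mi"]
        with pytest.raises(ConfigError, match="event_rates"):
            cfg.validate()

    @pytest.mark.parametrize(
        "mutate, field",
        [
            (lambda c: setattr(c, "n_participants", 0), "n_participants"),
            (lambda c: setattr(c, "followup_years", -1.0), "followup_years"),
            (lambda c: c.event_rates.update(mi=1.5), "event_rates"),
            (lambda c: setattr(c.qol_truth, "residual_sd", 0.0), "residual_sd"),
            (lambda c: setattr(c.cost_truth, "gamma_shape", -1.0), "gamma_shape"),
            (lambda c: setattr(c, "missing_final_qol_rate", 2.0), "missing_final_qol_rate"),
        ],
    )
    def test_invalid_fields_named(self, mutate, field):
        cfg = default_config(n_participants=10, seed=0)
        mutate(cfg)
        with pytest.raises(ConfigError, match=field):
            cfg.validate()

    def test_certain_admission_part1_coefficient_rejected(self):
        cfg = default_config(n_participants=10, seed=0)
        cfg.cost_truth.part1.event_effects["crv_urgent"]["y0"] = 2.0
        with pytest.raises(ConfigError, match="certain"):
            cfg.validate()

    def test_config_yaml_round_trip(self, tmp_path):
        from cvburden.config import CohortConfig

        cfg = default_config(n_participants=50, seed=3)
        path = tmp_path / "config.yaml"
        cfg.save(path)
        again = CohortConfig.load(path)
        assert again.config_hash() == cfg.config_hash()
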