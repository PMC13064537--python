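"""Tests of the synthetic claims generator: determinism, marginals, renewal process."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from rvikit import (
    ConfigurationError,
    GeneratorConfig,
    ObservationWindow,
    assign_outcomes,
    compute_rvi,
    generate_cohort,
    generate_visit_history,
    inject_exclusion_cases,
)
from rvikit.regularity import DEFAULT_WINDOW
from rvikit.synthetic import EFFECT_TERMS, _generate_patients, _stream


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value,match",
        [
            ("n_patients", 0, "n_patients"),
            ("p_male", 1.2, "p_male"),
            ("income_quintile_probs", (0.5, 0.2, 0.1, 0.1, 0.05), "income_quintile_probs"),
            ("subgroup_probs", (0.5, 0.5), "subgroup_probs"),
            ("interval_cv_target", 0.0, "interval_cv_target"),
            ("nb_dispersion", -1.0, "nb_dispersion"),
            ("clustering_near_death", 0.5, "clustering_near_death"),
        ],
    )
    def test_invalid_config_names_offending_field(self, field, value, match):
        cfg = dataclasses.replace(GeneratorConfig(), **{field: value})
        with pytest.raises(ConfigurationError, match=match):
            cfg.validate()

    def test_missing_effect_coefficient_lists_expected_names(self):
        effects = GeneratorConfig().true_effects
        del effects["ed_visits"]["homecare"]
        cfg = GeneratorConfig(true_effects=effects)
        with pytest.raises(ConfigurationError, match="homecare"):
            cfg.validate()


class TestDeterminism:
    def test_same_seed_gives_byte_identical_tables(self, tmp_path):
        from rvikit import write_cohort

        a = generate_cohort(GeneratorConfig(n_patients=150, seed=1))
        b = generate_cohort(GeneratorConfig(n_patients=150, seed=1))
        pa = write_cohort(a, tmp_path / "a", seed=1)
        pb = write_cohort(b, tmp_path / "b", seed=1)
        for k in pa:
            assert pa[k].read_bytes() == pb[k].read_bytes()

    def test_different_seed_differs(self):
        a = generate_cohort(GeneratorConfig(n_patients=100, seed=1))
        b = generate_cohort(GeneratorConfig(n_patients=100, seed=2))
        assert not a.patients.equals(b.patients)


@pytest.fixture(scope="module")
def patients():
    cfg = GeneratorConfig(n_patients=50_000, seed=11)
    return _generate_patients(cfg, _stream(cfg.seed, 0))


class TestPatientMarginals:
    def test_male_share_within_three_binomial_sd(self, patients):
        p = 0.553
        sd = np.sqrt(p * (1 - p) / len(patients))
        assert abs((patients["sex"] == "M").mean() - p) < 3 * sd

    @pytest.mark.parametrize(
        "col,p",
        [("rural", 0.127), ("homecare", 0.764), ("cancer", 0.351)],
    )
    def test_flag_shares(self, patients, col, p):
        sd = np.sqrt(p * (1 - p) / len(patients))
        assert abs(patients[col].mean() - p) < 3 * sd

    def test_income_quintile_shares(self, patients):
        probs = (0.251, 0.227, 0.194, 0.169, 0.159)
        obs = patients["income_quintile"].value_counts(normalize=True).sort_index()
        for k, p in enumerate(probs, start=1):
            assert obs[k] == pytest.approx(p, abs=3 * np.sqrt(p * (1 - p) / len(patients)))

    def test_age_and_adg_quartiles_near_targets(self, patients):
        assert patients["age_2y_before_death"].median() == pytest.approx(80, abs=1)
        q = patients["age_2y_before_death"].quantile([0.25, 0.75])
        assert q[0.25] == pytest.approx(71, abs=1.5)
        assert q[0.75] == pytest.approx(87, abs=1.5)
        assert patients["adg_count"].median() == pytest.approx(13, abs=1)

    def test_subgroup_shares(self, patients):
        obs = patients["subgroup"].value_counts(normalize=True)
        assert obs["ACOPD_HF"] == pytest.approx(0.182, abs=0.01)
        assert obs["ACOPD"] == pytest.approx(0.130, abs=0.01)
        assert obs["HF"] == pytest.approx(0.688, abs=0.01)

    def test_death_dates_inside_accrual_window(self, patients):
        assert patients["death_date"].min() >= pd.Timestamp("2017-01-01")
        assert patients["death_date"].max() <= pd.Timestamp("2019-12-31")


class TestVisitHistories:
    def test_near_zero_dispersion_gives_perfect_regularity(self):
        rng = np.random.default_rng(0)
        w = ObservationWindow(730, 30)
        h = generate_visit_history(10, 1e-6, w, rng=rng)
        gaps = np.diff(h)
        assert compute_rvi(gaps).rvi > 0.99
        assert len(h) == pytest.approx(10, abs=2)

    def test_exponential_regime_sample_cv_near_one(self):
        rng = np.random.default_rng(1)
        w = ObservationWindow(4000, 0)
        h = generate_visit_history(400, 1.0, w, rng=rng)
        gaps = np.diff(h).astype(float)
        assert gaps.std(ddof=1) / gaps.mean() == pytest.approx(1.0, abs=0.12)

    def test_histories_strictly_increasing_and_in_window(self):
        rng = np.random.default_rng(2)
        w = ObservationWindow(730, 30)
        for _ in range(50):
            h = generate_visit_history(9, 0.9, w, rng=rng)
            assert (np.diff(h) > 0).all()
            assert h.size == 0 or (h.min() > 30 and h.max() <= 730)

    def test_clustering_compresses_near_death_gaps(self):
        # mean gap in the final 90 days ~ one third of the earlier mean
        rng = np.random.default_rng(3)
        w = ObservationWindow(730, 0)
        late, early = [], []
        for _ in range(2000):
            h = generate_visit_history(73, 0.9, w, clustering=3.0, rng=rng)[::-1]
            # h now decreasing offsets = forward in time
            gaps = -np.diff(h)
            ends = h[1:]
            late.extend(gaps[ends < 90])
            early.extend(gaps[ends >= 90])
        ratio = np.mean(late) / np.mean(early)
        assert 0.25 < ratio < 0.45

    @pytest.mark.parametrize("rate,cv", [(0, 1.0), (5, 0)])
    def test_invalid_parameters_rejected(self, rate, cv):
        with pytest.raises(ConfigurationError):
            generate_visit_history(rate, cv, DEFAULT_WINDOW)


class TestCohortInvariants:
    def test_no_visit_on_or_after_death(self, small_cohort):
        m = small_cohort.visits.merge(
            small_cohort.patients[["patient_id", "death_date"]], on="patient_id"
        )
        assert (m["visit_date"] < m["death_date"]).all()

    def test_every_patient_meets_fp_eligibility_floor(self, small_cohort):
        v = small_cohort.visits
        fp = v[v["physician_role"] == "FP"].merge(
            small_cohort.patients[["patient_id", "death_date"]], on="patient_id"
        )
        off = (fp["death_date"] - fp["visit_date"]).dt.days
        fp = fp[(off > 30) & (off <= 730)]
        days = fp.groupby("patient_id")["visit_date"].nunique()
        assert len(days) == len(small_cohort.patients)
        assert (days >= 2).all()

    def test_outcomes_join_one_to_one(self, small_cohort):
        assert sorted(small_cohort.outcomes["patient_id"]) == sorted(
            small_cohort.patients["patient_id"]
        )
        assert (small_cohort.outcomes["n_hospitalizations_30d"] >= 0).all()
        assert (small_cohort.outcomes["n_ed_visits_30d"] >= 0).all()


class TestAssignOutcomes:
    def _null_effects(self):
        return {o: {t: 0.0 for t in EFFECT_TERMS} for o in
                ("hospitalizations", "ed_visits", "acute_care_death")}

    def test_intercept_only_counts_hit_baseline_mean(self, small_cohort):
        rng = np.random.default_rng(0)
        means = {"hospitalizations": 0.7, "ed_visits": 0.7, "acute_care_death": 0.5}
        big = pd.concat([small_cohort.patients] * 10, ignore_index=True)
        big["patient_id"] = np.arange(len(big))
        expo = pd.DataFrame(
            {
                "patient_id": big["patient_id"],
                "quintile": "Q1",
                "sp_quintile": "Q1",
                "fp_visits": 9,
                "sp_visits": 12,
            }
        )
        out = assign_outcomes(big, expo, self._null_effects(), 0.3, means, rng)
        n = len(out)
        se = np.sqrt(0.7 * (1 + 0.3 * 0.7) / n)
        assert out["n_hospitalizations_30d"].mean() == pytest.approx(0.7, abs=4 * se)

    def test_intercept_only_death_probability_hits_baseline(self, small_cohort):
        rng = np.random.default_rng(1)
        means = {"hospitalizations": 0.7, "ed_visits": 0.7, "acute_care_death": 0.617}
        big = pd.concat([small_cohort.patients] * 10, ignore_index=True)
        big["patient_id"] = np.arange(len(big))
        expo = pd.DataFrame(
            {
                "patient_id": big["patient_id"],
                "quintile": "Q1",
                "sp_quintile": "Q1",
                "fp_visits": 9,
                "sp_visits": 12,
            }
        )
        out = assign_outcomes(big, expo, self._null_effects(), 0.3, means, rng)
        se = np.sqrt(0.617 * 0.383 / len(out))
        assert out["acute_care_death"].mean() == pytest.approx(0.617, abs=4 * se)

    def test_missing_coefficient_is_configuration_error(self, small_cohort):
        effects = self._null_effects()
        del effects["hospitalizations"]["rvi_q5"]
        expo = pd.DataFrame(
            {
                "patient_id": small_cohort.patients["patient_id"],
                "quintile": "Q1",
                "sp_quintile": "Q1",
                "fp_visits": 9,
                "sp_visits": 12,
            }
        )
        with pytest.raises(ConfigurationError, match="rvi_q5"):
            assign_outcomes(
                small_cohort.patients, expo, effects, 0.3,
                {"hospitalizations": 0.7, "ed_visits": 0.7, "acute_care_death": 0.5},
                np.random.default_rng(0),
            )


class TestInjection:
    def test_requested_counts_tagged(self, injected_cohort, small_cohort):
        tags = injected_cohort.patients["injected_violation"]
        assert (tags != "").sum() == 10
        assert tags.value_counts()["underage"] == 2
        assert len(injected_cohort.patients) == len(small_cohort.patients) + 10

    def test_unknown_kind_rejected(self, small_cohort):
        with pytest.raises(ConfigurationError, match="unknown violation"):
            inject_exclusion_cases(small_cohort, {"bogus": 1})

    def test_injected_visits_precede_death(self, injected_cohort):
        m = injected_cohort.visits.merge(
            injected_cohort.patients[["patient_id", "death_date"]], on="patient_id"
        )
        assert (m["visit_date"] < m["death_date"]).all()
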