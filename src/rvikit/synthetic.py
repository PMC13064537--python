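"""Synthetic decedent-cohort generator.

Emulates the statistical structure of an administrative-claims cohort of
adults who died with cardiorespiratory conditions (advanced COPD and/or
heart failure): demographics and comorbidity marginals, outpatient visit
histories with controllable inter-visit dispersion, and last-month
acute-care outcomes drawn from configurable negative-binomial / logistic
generative models.  Every default encodes the study conditions the
analysis targets — a median of ~9 family-physician and ~12 specialist
visits over the two-years-minus-30-days exposure window, inter-visit
coefficient of variation around 0.9 (hence median RVI near 0.011), and
the published adjusted effect sizes as generative truths.

Visit histories follow a gamma renewal process: gaps are i.i.d.
gamma(shape=1/cv^2, scale chosen to hit the target visit count in
expectation), which nests exponential visiting at cv=1 and near-regular
visiting as cv -> 0.  An optional clustering multiplier compresses gaps in
the final 90 days before death, emulating the intensification of
outpatient care near death.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import ConfigurationError
from .regularity import (
    ATTRIBUTION_WINDOW,
    DEFAULT_WINDOW,
    ObservationWindow,
    ROLE_FP,
    ROLE_SPECIALIST,
    quintile_categorize,
    score_cohort,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "default_true_effects",
    "generate_cohort",
    "generate_visit_history",
    "assign_outcomes",
    "inject_exclusion_cases",
    "write_cohort",
    "read_cohort",
]

#: Inverse-normal quartile constant: P(|Z| < 0.6745) = 0.5.
_Z_QUARTILE = 0.674489750196082

OUTCOME_NAMES = ("hospitalizations", "ed_visits", "acute_care_death")

#: Regression terms of each generative outcome model (intercept handled
#: separately).  Continuous covariates enter centred at their empirical
#: means so the configured baseline stays interpretable as a cohort-level
#: rate/probability.
EFFECT_TERMS = (
    "rvi_q2", "rvi_q3", "rvi_q4", "rvi_q5",
    "sp_rvi_q2", "sp_rvi_q3", "sp_rvi_q4", "sp_rvi_q5",
    "age", "male", "rural",
    "income_q2", "income_q3", "income_q4", "income_q5",
    "adg_count", "fp_visits", "sp_visits",
    "homecare", "cancer",
)

DIRECT_CARE_SPECIALTIES = (
    "cardiology", "respirology", "internal medicine", "oncology",
    "geriatrics", "nephrology", "gastroenterology", "neurology",
    "endocrinology", "palliative medicine",
)

_ROLE_CATEGORIES = [ROLE_FP, ROLE_SPECIALIST]
_SPECIALTY_CATEGORIES = ["family medicine", *DIRECT_CARE_SPECIALTIES]

VIOLATION_KINDS = (
    "underage", "over-age-limit", "insurance-gap", "long-term-care", "too-few-visits",
)


def default_true_effects() -> dict:
    """Generative log-scale coefficients for the three outcome models.

    The top-quintile and homecare coefficients are the published adjusted
    estimates (hospitalizations IRR 1.07, ED visits IRR 1.06, acute-care
    death OR 1.30; homecare 0.96 / 0.50 / 0.83); intermediate quintiles
    ramp linearly to the top-quintile value, specialist-regularity terms
    are zero, and the remaining covariate effects are modest values with
    the reported directions (comorbidity burden increases acute-care use,
    cancer decreases it).
    """

    def quintile_ramp(top):
        t = math.log(top)
        return {"rvi_q2": 0.25 * t, "rvi_q3": 0.5 * t, "rvi_q4": 0.75 * t, "rvi_q5": t}

    zeros = {t: 0.0 for t in EFFECT_TERMS}
    hosp = {**zeros, **quintile_ramp(1.07),
            "homecare": math.log(0.96), "cancer": math.log(0.85),
            "adg_count": math.log(1.03), "age": 0.002, "male": 0.02,
            "sp_visits": 0.004}
    ed = {**zeros, **quintile_ramp(1.06),
          "homecare": math.log(0.50), "cancer": math.log(0.85),
          "adg_count": math.log(1.03), "age": 0.001, "male": 0.01,
          "sp_visits": 0.003}
    death = {**zeros, **quintile_ramp(1.30),
             "homecare": math.log(0.83), "cancer": math.log(0.80),
             "adg_count": math.log(1.05), "age": 0.01, "male": 0.05,
             "rural": 0.02}
    return {"hospitalizations": hosp, "ed_visits": ed, "acute_care_death": death}


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults encode the target cohort's marginals: 55.3% male, median age
    80 (71, 87) two years before death, 12.7% rural, income-quintile
    shares (25.1, 22.7, 19.4, 16.9, 15.9)%, 76.4% homecare, 35.1% cancer,
    median 13 (11, 16) aggregated diagnosis groups, subgroup shares
    18.2 / 13.0 / 68.8% for ACOPD&HF / ACOPD-only / HF-only, ~9 FP and
    ~12 specialist visits over the default exposure window, and an
    inter-visit coefficient of variation of 0.9.
    """

    n_patients: int = 20_000
    seed: int = 0
    death_window: tuple = (date(2017, 1, 1), date(2019, 12, 31))
    p_male: float = 0.553
    age_median_iqr: tuple = (80.0, 71.0, 87.0)
    p_rural: float = 0.127
    income_quintile_probs: tuple = (0.251, 0.227, 0.194, 0.169, 0.159)
    p_homecare: float = 0.764
    p_cancer: float = 0.351
    adg_median_iqr: tuple = (13.0, 11.0, 16.0)
    subgroup_probs: tuple = (0.182, 0.130, 0.688)  # ACOPD&HF, ACOPD only, HF only
    fp_visit_rate: float = 9.0
    sp_visit_rate: float = 12.0
    interval_cv_target: float = 0.9
    clustering_near_death: float = 1.0
    true_effects: dict = field(default_factory=default_true_effects)
    nb_dispersion: float = 0.3
    outcome_means: dict = field(
        default_factory=lambda: {
            "hospitalizations": 0.8,
            "ed_visits": 0.9,
            "acute_care_death": 0.617,
        }
    )

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be a positive integer")
        for name in ("p_male", "p_rural", "p_homecare", "p_cancer"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        for name, probs, k in (
            ("income_quintile_probs", self.income_quintile_probs, 5),
            ("subgroup_probs", self.subgroup_probs, 3),
        ):
            if len(probs) != k or any(p < 0 for p in probs):
                raise ConfigurationError(f"{name} must be {k} non-negative proportions")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1 (got {sum(probs)})")
        for name in ("fp_visit_rate", "sp_visit_rate", "interval_cv_target", "nb_dispersion"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.clustering_near_death < 1.0:
            raise ConfigurationError("clustering_near_death must be >= 1")
        med, lo, hi = self.age_median_iqr
        if not (0 < lo <= med <= hi):
            raise ConfigurationError("age_median_iqr must satisfy 0 < P25 <= median <= P75")
        med, lo, hi = self.adg_median_iqr
        if not (0 < lo <= med <= hi):
            raise ConfigurationError("adg_median_iqr must satisfy 0 < P25 <= median <= P75")
        missing = set(OUTCOME_NAMES) - set(self.outcome_means)
        if missing:
            raise ConfigurationError(f"outcome_means missing entries: {sorted(missing)}")
        for name, coefs in self.true_effects.items():
            if name not in OUTCOME_NAMES:
                raise ConfigurationError(
                    f"true_effects has unknown outcome '{name}'; expected {OUTCOME_NAMES}"
                )
            absent = set(EFFECT_TERMS) - set(coefs)
            if absent:
                raise ConfigurationError(
                    f"true_effects['{name}'] missing coefficients {sorted(absent)}; "
                    f"expected names: {EFFECT_TERMS}"
                )
        if set(self.true_effects) != set(OUTCOME_NAMES):
            raise ConfigurationError(
                f"true_effects must define all outcomes {OUTCOME_NAMES}"
            )


@dataclass
class SyntheticCohort:
    """Generated claims bundle: patients, visit claims, and outcomes."""

    patients: pd.DataFrame
    visits: pd.DataFrame
    outcomes: pd.DataFrame
    exposure_truth: pd.DataFrame | None = None  # generative quintiles, for audits


def _stream(seed: int, stage: int) -> np.random.Generator:
    """Independent substream for one generation stage."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stage)]))


def _lognormal_from_median_iqr(median, p25, p75, size, rng):
    """Split lognormal hitting the median and both quartiles exactly.

    A single-sigma lognormal cannot match an asymmetric quartile pair, so
    the two half-distributions get their own log-scale spreads.
    """
    mu = math.log(median)
    s_lo = (mu - math.log(p25)) / _Z_QUARTILE if p25 < median else 0.0
    s_hi = (math.log(p75) - mu) / _Z_QUARTILE if p75 > median else 0.0
    z = rng.standard_normal(size)
    return np.exp(mu + np.where(z < 0, s_lo, s_hi) * z)


def _renewal_histories(
    n: int,
    rate: float,
    cv: float,
    window: ObservationWindow,
    clustering: float,
    rng: np.random.Generator,
) -> list:
    """Vectorized gamma-renewal visit histories.

    *rate* is the expected visit count over *window*.  Clustering > 1 is
    implemented by time-rescaling: the final 90 days of the window are
    traversed at 1/clustering speed in operational time, which divides
    gap lengths falling there by the multiplier.  Returns a list of
    increasing integer day-offset arrays (offsets before death).
    """
    span = float(window.span)
    g = span / rate  # mean gap, days
    shape = 1.0 / (cv * cv)
    boundary = max(span - 90.0, 0.0)
    op_len = boundary + (span - boundary) * clustering
    exp_gaps = op_len / g
    m = int(exp_gaps + 10.0 * math.sqrt(exp_gaps) + 20)
    gaps = rng.gamma(shape, g / shape, size=(n, m))
    tau = np.cumsum(gaps, axis=1)
    # map operational time back to real window time
    t = np.where(tau <= boundary, tau, boundary + (tau - boundary) / clustering)
    # round to nearest whole day: stable for near-regular arrivals that
    # would otherwise straddle integer-day boundaries
    days = np.floor(t + 0.5).astype(np.int64)
    valid = (t < span) & (days < span)
    # arrival days are non-decreasing within a row; drop same-day repeats
    changed = np.ones_like(valid)
    changed[:, 1:] = days[:, 1:] != days[:, :-1]
    keep = valid & changed
    counts = keep.sum(axis=1)
    flat = days[keep]
    parts = np.split(flat, np.cumsum(counts)[:-1])
    start = window.start_offset
    return [start - p[::-1] for p in parts]  # increasing offsets


def generate_visit_history(
    rate: float,
    cv: float,
    window: ObservationWindow,
    clustering: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One visit history from the gamma renewal process.

    Inter-visit gaps are gamma(shape=1/cv^2) with scale set so the
    expected number of visits over *window* equals *rate*; when
    ``clustering > 1`` gaps in the final 90 days before the window end are
    divided by the multiplier.  Dates are rounded to whole days with
    duplicates collapsed; returns strictly increasing integer day-offsets
    before death.
    """
    if rate <= 0:
        raise ConfigurationError("rate must be positive")
    if cv <= 0:
        raise ConfigurationError("cv must be positive")
    if clustering < 1.0:
        raise ConfigurationError("clustering must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    return _renewal_histories(1, rate, cv, window, clustering, rng)[0]


def _generate_patients(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_patients
    d0, d1 = config.death_window
    span_days = (d1 - d0).days
    death_offsets = rng.integers(0, span_days + 1, n)
    death_dates = pd.to_datetime(d0) + pd.to_timedelta(death_offsets, unit="D")

    med, p25, p75 = config.age_median_iqr
    age = _lognormal_from_median_iqr(med, p25, p75, n, rng)
    # ages at death span [19, 104]: the generator respects the eligibility
    # floor so attrition comes only from injected violations
    age = np.clip(np.round(age), 19, 102).astype(int)

    med, p25, p75 = config.adg_median_iqr
    adg = _lognormal_from_median_iqr(med, p25, p75, n, rng)
    adg = np.clip(np.round(adg), 1, 32).astype(int)

    subgroups = rng.choice(
        np.array(["ACOPD_HF", "ACOPD", "HF"]), size=n, p=np.asarray(config.subgroup_probs)
    )
    return pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "death_date": death_dates,
            "age_2y_before_death": age,
            "sex": np.where(rng.random(n) < config.p_male, "M", "F"),
            "rural": rng.random(n) < config.p_rural,
            "income_quintile": rng.choice(
                np.arange(1, 6), size=n, p=np.asarray(config.income_quintile_probs)
            ),
            "homecare": rng.random(n) < config.p_homecare,
            "cancer": rng.random(n) < config.p_cancer,
            "adg_count": adg,
            "subgroup": subgroups,
            "insurance_gap": np.zeros(n, dtype=bool),
            "ltc_residence": np.zeros(n, dtype=bool),
            "injected_violation": np.array([""] * n, dtype=object),
        }
    )


def _visits_frame(patients, histories, physician_ids, role, specialties, rng):
    """Assemble a long claims table from per-patient offset arrays."""
    counts = np.array([len(h) for h in histories])
    pid = np.repeat(patients["patient_id"].to_numpy(), counts)
    death = np.repeat(patients["death_date"].to_numpy(), counts)
    offsets = np.concatenate(histories) if len(histories) else np.array([], dtype=int)
    dates = pd.to_datetime(death) - pd.to_timedelta(offsets, unit="D")
    loc_codes = rng.choice(3, size=len(pid), p=[0.92, 0.04, 0.04]).astype(np.int8)
    loc = pd.Categorical.from_codes(loc_codes, categories=["Office", "Home", "Phone"])
    role_code = _ROLE_CATEGORIES.index(role)
    if isinstance(specialties, str):
        specialties = pd.Categorical.from_codes(
            np.full(len(pid), _SPECIALTY_CATEGORIES.index(specialties), dtype=np.int8),
            categories=_SPECIALTY_CATEGORIES,
        )
    return pd.DataFrame(
        {
            "patient_id": pid,
            "physician_id": physician_ids,
            "physician_role": pd.Categorical.from_codes(
                np.full(len(pid), role_code, dtype=np.int8), categories=_ROLE_CATEGORIES
            ),
            "specialty": specialties,
            "visit_date": dates,
            "location": loc,
        }
    )


# exposure-window floor: forced fallback offsets for pathological draws
_FALLBACK_OFFSETS = (500, 260)


def _fp_histories(config: GeneratorConfig, rng: np.random.Generator) -> list:
    """FP visit histories spanning attribution + exposure + final month.

    Generated over the full (1460, 0] span at the daily intensity implied
    by ``fp_visit_rate`` visits per default exposure window, so that both
    virtual attachment (which looks at days 1460-730) and near-death
    clustering are represented.  Patients are regenerated until they meet
    the two-visit eligibility floor in the default exposure window, so
    attrition testing is driven by deliberately injected violations.
    """
    full = ObservationWindow(ATTRIBUTION_WINDOW.start_offset, 0)
    scale = full.span / DEFAULT_WINDOW.span
    histories = _renewal_histories(
        config.n_patients, config.fp_visit_rate * scale, config.interval_cv_target,
        full, config.clustering_near_death, rng,
    )
    for _ in range(8):
        bad = [
            i for i, h in enumerate(histories)
            if np.count_nonzero(DEFAULT_WINDOW.contains(h)) < 2
        ]
        if not bad:
            break
        redraw = _renewal_histories(
            len(bad), config.fp_visit_rate * scale, config.interval_cv_target,
            full, config.clustering_near_death, rng,
        )
        for i, h in zip(bad, redraw):
            histories[i] = h
    for i, h in enumerate(histories):  # deterministic last resort
        if np.count_nonzero(DEFAULT_WINDOW.contains(h)) < 2:
            histories[i] = np.unique(np.r_[h, _FALLBACK_OFFSETS])
    return histories


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort under *config*.

    Deterministic given ``(config, config.seed)``.  Visit histories feed
    the same public scoring path used by the analysis (default-window FP
    RVI, empirical quintiles), and outcomes are then drawn from the
    configured generative models — so refitting the analysis models on the
    generated tables recovers ``true_effects`` up to Monte-Carlo error.
    """
    config.validate()
    seed = config.seed
    patients = _generate_patients(config, _stream(seed, 0))

    rng_fp = _stream(seed, 1)
    fp_hist = _fp_histories(config, rng_fp)
    n = config.n_patients
    fp_pool = max(1, n // 100)
    fp_of_patient = _stream(seed, 2).integers(10_000, 10_000 + fp_pool, n)
    fp_counts = np.array([len(h) for h in fp_hist])
    fp_visits = _visits_frame(
        patients, fp_hist, np.repeat(fp_of_patient, fp_counts), ROLE_FP,
        "family medicine", _stream(seed, 3),
    )

    rng_sp = _stream(seed, 4)
    sp_window = ObservationWindow(DEFAULT_WINDOW.start_offset, 0)
    sp_scale = sp_window.span / DEFAULT_WINDOW.span
    sp_hist = _renewal_histories(
        n, config.sp_visit_rate * sp_scale, config.interval_cv_target,
        sp_window, config.clustering_near_death, rng_sp,
    )
    rng_spid = _stream(seed, 5)
    n_spec = 1 + rng_spid.poisson(4.3, n)  # specialist pool size per patient, median ~5
    sp_counts = np.array([len(h) for h in sp_hist])
    pool_start = np.concatenate([[0], np.cumsum(n_spec)[:-1]])
    slot = rng_spid.integers(0, np.repeat(n_spec, sp_counts))
    sp_phys = 50_000 + np.repeat(pool_start, sp_counts) + slot
    sp_spec = pd.Categorical.from_codes(
        (1 + sp_phys % len(DIRECT_CARE_SPECIALTIES)).astype(np.int8),
        categories=_SPECIALTY_CATEGORIES,
    )
    sp_visits = _visits_frame(patients, sp_hist, sp_phys, ROLE_SPECIALIST, sp_spec, _stream(seed, 6))

    visits = pd.concat([fp_visits, sp_visits], ignore_index=True)
    visits = visits.sort_values(
        ["patient_id", "visit_date", "physician_role", "physician_id"], kind="mergesort"
    ).reset_index(drop=True)

    exposures = _exposure_table(patients, visits)
    outcomes = assign_outcomes(
        patients, exposures, config.true_effects, config.nb_dispersion,
        config.outcome_means, _stream(seed, 7),
    )
    return SyntheticCohort(patients, visits, outcomes, exposure_truth=exposures)


def _exposure_table(patients: pd.DataFrame, visits: pd.DataFrame) -> pd.DataFrame:
    """Default-window FP and specialist RVI quintiles plus visit counts."""
    fp = score_cohort(visits, patients, DEFAULT_WINDOW, role=ROLE_FP)
    sp = score_cohort(visits, patients, DEFAULT_WINDOW, role=ROLE_SPECIALIST)
    fp_q = quintile_categorize(fp[fp["eligible"]][["patient_id", "rvi"]])
    out = fp[["patient_id", "n_visits"]].rename(columns={"n_visits": "fp_visits"})
    out = out.merge(
        sp[["patient_id", "n_visits", "rvi"]].rename(
            columns={"n_visits": "sp_visits", "rvi": "sp_rvi"}
        ),
        on="patient_id",
    )
    out = out.merge(
        fp[["patient_id", "rvi"]].rename(columns={"rvi": "fp_rvi"}), on="patient_id"
    )
    out = out.merge(
        fp_q.rename(columns={"quintile": "quintile"})[["patient_id", "quintile"]],
        on="patient_id", how="left",
    )
    sp_elig = sp[sp["eligible"]]
    if len(sp_elig) >= 5:
        sp_q = quintile_categorize(sp_elig[["patient_id", "rvi"]])
        out = out.merge(
            sp_q.rename(columns={"quintile": "sp_quintile"})[["patient_id", "sp_quintile"]],
            on="patient_id", how="left",
        )
    else:
        out["sp_quintile"] = np.nan
    return out


def _design_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Columns named after EFFECT_TERMS, continuous terms centred."""
    X = pd.DataFrame(index=df.index)
    for q in (2, 3, 4, 5):
        X[f"rvi_q{q}"] = (df["quintile"] == f"Q{q}").astype(float)
        X[f"sp_rvi_q{q}"] = (df.get("sp_quintile", pd.Series(index=df.index)) == f"Q{q}").astype(float)
        X[f"income_q{q}"] = (df["income_quintile"] == q).astype(float)
    for raw, name in (
        ("age_2y_before_death", "age"), ("adg_count", "adg_count"),
        ("fp_visits", "fp_visits"), ("sp_visits", "sp_visits"),
    ):
        col = df[raw].astype(float)
        X[name] = col - col.mean()
    X["male"] = (df["sex"] == "M").astype(float)
    X["rural"] = df["rural"].astype(float)
    X["homecare"] = df["homecare"].astype(float)
    X["cancer"] = df["cancer"].astype(float)
    return X[list(EFFECT_TERMS)]


def assign_outcomes(
    patients: pd.DataFrame,
    exposures: pd.DataFrame,
    true_effects: Mapping,
    nb_dispersion: float,
    outcome_means: Mapping,
    rng: np.random.Generator,
    count_cap: int = 10,
) -> pd.DataFrame:
    """Draw last-30-day outcomes from the generative regression models.

    Hospitalization and ED counts are negative binomial (log link,
    variance mu + alpha*mu^2 with alpha = *nb_dispersion*), acute-care
    death is Bernoulli (logit link).  Intercepts are set so the baseline
    in *outcome_means* is the linear predictor at the cohort-mean
    covariate profile; categorical effects therefore shift individuals
    around that baseline.  Counts are capped at *count_cap* to guard
    against pathological draws.
    """
    for name in OUTCOME_NAMES:
        coefs = true_effects.get(name)
        if coefs is None:
            raise ConfigurationError(f"true_effects missing outcome '{name}'")
        absent = set(EFFECT_TERMS) - set(coefs)
        if absent:
            raise ConfigurationError(
                f"true_effects['{name}'] missing coefficients {sorted(absent)}; "
                f"expected names: {EFFECT_TERMS}"
            )
    df = patients.merge(exposures, on="patient_id", how="inner")
    X = _design_matrix(df)
    # centre the remaining (dummy) terms so the configured baselines are
    # cohort-level means rather than reference-cell values
    Xc = X - X.mean(axis=0)
    out = pd.DataFrame({"patient_id": df["patient_id"].to_numpy()})
    for name in ("hospitalizations", "ed_visits"):
        beta = pd.Series(true_effects[name]).reindex(list(EFFECT_TERMS))
        lp = math.log(outcome_means[name]) + Xc.to_numpy() @ beta.to_numpy()
        mu = np.exp(lp)
        alpha = float(nb_dispersion)
        y = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))
        col = {"hospitalizations": "n_hospitalizations_30d", "ed_visits": "n_ed_visits_30d"}[name]
        out[col] = np.minimum(y, count_cap).astype(int)
    beta = pd.Series(true_effects["acute_care_death"]).reindex(list(EFFECT_TERMS))
    base = outcome_means["acute_care_death"]
    lp = math.log(base / (1 - base)) + Xc.to_numpy() @ beta.to_numpy()
    out["acute_care_death"] = rng.random(len(df)) < expit(lp)
    return out


def inject_exclusion_cases(
    cohort: SyntheticCohort,
    spec: Mapping[str, int],
    rng: np.random.Generator | None = None,
) -> SyntheticCohort:
    """Append patients that violate specific eligibility rules.

    *spec* maps violation kinds (``underage``, ``over-age-limit``,
    ``insurance-gap``, ``long-term-care``, ``too-few-visits``) to the
    number of cases to add.  Each injected patient violates exactly its
    own rule, and carries the ground-truth label in the
    ``injected_violation`` column for attrition-test assertions.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    unknown = set(spec) - set(VIOLATION_KINDS)
    if unknown:
        raise ConfigurationError(
            f"unknown violation kinds {sorted(unknown)}; expected {VIOLATION_KINDS}"
        )
    patients = cohort.patients.copy()
    visits = cohort.visits.copy()
    outcomes = cohort.outcomes.copy()
    next_id = int(patients["patient_id"].max()) + 1
    d0, d1 = date(2018, 1, 1), date(2018, 12, 31)
    new_p, new_v, new_o = [], [], []
    for kind in VIOLATION_KINDS:  # fixed order for determinism
        for _ in range(int(spec.get(kind, 0))):
            pid = next_id
            next_id += 1
            death = pd.Timestamp(d0) + pd.Timedelta(int(rng.integers(0, (d1 - d0).days + 1)), "D")
            row = {
                "patient_id": pid, "death_date": death,
                "age_2y_before_death": 70, "sex": "F", "rural": False,
                "income_quintile": 3, "homecare": False, "cancer": False,
                "adg_count": 10, "subgroup": "HF",
                "insurance_gap": kind == "insurance-gap",
                "ltc_residence": kind == "long-term-care",
                "injected_violation": kind,
            }
            if kind == "underage":
                row["age_2y_before_death"] = 15  # aged 17 at death
            elif kind == "over-age-limit":
                row["age_2y_before_death"] = 104  # aged 106 at death
            offsets = (400,) if kind == "too-few-visits" else (500, 300, 100)
            new_p.append(row)
            for off in offsets:
                new_v.append(
                    {
                        "patient_id": pid, "physician_id": 9_999,
                        "physician_role": ROLE_FP, "specialty": "family medicine",
                        "visit_date": death - pd.Timedelta(off, "D"),
                        "location": "Office",
                    }
                )
            new_o.append(
                {
                    "patient_id": pid, "n_hospitalizations_30d": 0,
                    "n_ed_visits_30d": 0, "acute_care_death": False,
                }
            )
    if new_p:
        patients = pd.concat([patients, pd.DataFrame(new_p)], ignore_index=True)
        visits = pd.concat([visits, pd.DataFrame(new_v)], ignore_index=True)
        outcomes = pd.concat([outcomes, pd.DataFrame(new_o)], ignore_index=True)
    return SyntheticCohort(patients, visits, outcomes, exposure_truth=cohort.exposure_truth)


def write_cohort(cohort: SyntheticCohort, outdir, seed: int | None = None) -> dict:
    """Write patients.csv / visits.csv / outcomes.csv (ISO dates).

    When *seed* is given each file starts with a ``# seed=<seed>`` comment
    line; read the files back with ``read_cohort`` or ``comment='#'``.
    Returns the mapping of table name to path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("patients", cohort.patients),
        ("visits", cohort.visits),
        ("outcomes", cohort.outcomes),
    ):
        path = outdir / f"{name}.csv"
        df = df.copy()
        for col in df.columns:
            if pd.api.types.is_datetime64_any_dtype(df[col]):
                df[col] = df[col].dt.strftime("%Y-%m-%d")
        with open(path, "w") as fh:
            if seed is not None:
                fh.write(f"# rvikit synthetic cohort; seed={seed}\n")
            df.to_csv(fh, index=False)
        paths[name] = path
    return paths


def read_cohort(outdir) -> SyntheticCohort:
    """Read a cohort written by :func:`write_cohort`."""
    outdir = Path(outdir)
    patients = pd.read_csv(outdir / "patients.csv", comment="#", parse_dates=["death_date"])
    patients["injected_violation"] = (
        patients.get("injected_violation", pd.Series(dtype=object)).fillna("").astype(str)
    )
    visits = pd.read_csv(outdir / "visits.csv", comment="#", parse_dates=["visit_date"])
    outcomes = pd.read_csv(outdir / "outcomes.csv", comment="#")
    outcomes["acute_care_death"] = outcomes["acute_care_death"].astype(bool)
    return SyntheticCohort(patients, visits, outcomes)
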