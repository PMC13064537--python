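import numpy as np
import pandas as pd
import pytest

from rvikit import GeneratorConfig, generate_cohort, inject_exclusion_cases

DEATH = pd.Timestamp("2018-06-15")


def make_visits(rows, death=DEATH):
    """Build a visits table from (patient_id, offsets, role, phys_id, specialty) tuples.

    Offsets are integer days before the patient's death date.
    """
    records = []
    for pid, offsets, role, phys, spec in rows:
        for off in offsets:
            records.append(
                {
                    "patient_id": pid,
                    "physician_id": phys,
                    "physician_role": role,
                    "specialty": spec,
                    "visit_date": death - pd.Timedelta(int(off), "D"),
                    "location": "Office",
                }
            )
    return pd.DataFrame(records)


def make_patients(pids, death=DEATH, **overrides):
    n = len(pids)
    base = {
        "patient_id": list(pids),
        "death_date": [death] * n,
        "age_2y_before_death": [75] * n,
        "sex": ["F"] * n,
        "rural": [False] * n,
        "income_quintile": [3] * n,
        "homecare": [False] * n,
        "cancer": [False] * n,
        "adg_count": [12] * n,
        "subgroup": ["HF"] * n,
        "insurance_gap": [False] * n,
        "ltc_residence": [False] * n,
        "injected_violation": [""] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort small enough for fast unit tests."""
    return generate_cohort(GeneratorConfig(n_patients=800, seed=7))


@pytest.fixture(scope="session")
def injected_cohort(small_cohort):
    spec = {k: 2 for k in (
        "underage", "over-age-limit", "insurance-gap", "long-term-care", "too-few-visits"
    )}
    return inject_exclusion_cases(small_cohort, spec, np.random.default_rng(3))
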