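"""Assembly of the patient-level analysis table.

Joins the retained patients to their death-anchored exposures (FP and
pooled-specialist RVI quintiles), utilization covariates, and last-month
outcomes, producing the table the adjusted regressions are fitted on.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import InputError
from .regularity import (
    DEFAULT_WINDOW,
    ObservationWindow,
    ROLE_FP,
    ROLE_SPECIALIST,
    quintile_categorize,
    score_cohort,
)

__all__ = ["build_analysis_table", "utilization_measures"]


def build_analysis_table(
    patients: pd.DataFrame,
    visits: pd.DataFrame,
    outcomes: pd.DataFrame | None = None,
    window: ObservationWindow = DEFAULT_WINDOW,
    attachment: Mapping | None = None,
) -> pd.DataFrame:
    """One row per RVI-eligible patient, ready for model fitting.

    Scores both provider roles over *window*, cuts FP scores into
    empirical quintiles (the exposure) and specialist scores likewise
    (for the sensitivity model), and merges demographics, comorbidity,
    visit counts and — when given — outcomes.  Patients without a
    computable FP score (fewer than two in-window visits) are dropped
    here; they should normally have been excluded upstream.  Patients
    without a computable specialist score keep ``sp_quintile = "Q1"``
    (reference level), so the sensitivity model contrasts scoreable
    regularity levels against everyone else.
    """
    visits = visits[visits["patient_id"].isin(patients["patient_id"])]
    fp = score_cohort(visits, patients, window, role=ROLE_FP, attachment=attachment)
    sp = score_cohort(visits, patients, window, role=ROLE_SPECIALIST)
    fp_elig = fp[fp["eligible"]]
    if len(fp_elig) < 5:
        raise InputError("fewer than 5 patients with computable FP regularity scores")
    fp_q = quintile_categorize(fp_elig[["patient_id", "rvi"]])

    tab = patients.merge(
        fp_q.rename(columns={"score": "fp_rvi"}), on="patient_id", how="inner"
    )
    tab = tab.merge(
        fp[["patient_id", "n_visits", "degenerate"]].rename(
            columns={"n_visits": "fp_visits", "degenerate": "fp_rvi_degenerate"}
        ),
        on="patient_id",
    )
    tab = tab.merge(
        sp[["patient_id", "n_visits", "rvi"]].rename(
            columns={"n_visits": "sp_visits", "rvi": "sp_rvi"}
        ),
        on="patient_id",
    )
    sp_elig = sp[sp["eligible"]]
    if len(sp_elig) >= 5:
        sp_q = quintile_categorize(sp_elig[["patient_id", "rvi"]])
        tab = tab.merge(
            sp_q[["patient_id", "quintile"]].rename(columns={"quintile": "sp_quintile"}),
            on="patient_id", how="left",
        )
        tab["sp_quintile"] = tab["sp_quintile"].fillna("Q1")
    else:
        tab["sp_quintile"] = "Q1"

    tab["age"] = tab["age_2y_before_death"].astype(float)
    tab["male"] = (tab["sex"] == "M").astype(int)
    tab["rural"] = tab["rural"].astype(int)
    tab["homecare"] = tab["homecare"].astype(int)
    tab["cancer"] = tab["cancer"].astype(int)

    if outcomes is not None:
        tab = tab.merge(outcomes, on="patient_id", how="inner")
    return tab.reset_index(drop=True)


def utilization_measures(
    patients: pd.DataFrame,
    visits: pd.DataFrame,
    window: ObservationWindow = DEFAULT_WINDOW,
    attachment: Mapping | None = None,
) -> pd.DataFrame:
    """Per-patient measures entering the Pearson correlation analysis.

    Columns: fp_rvi, sp_rvi, fp_visits, sp_visits, n_unique_specialists;
    rows limited to patients with both regularity scores computable.
    """
    visits = visits[visits["patient_id"].isin(patients["patient_id"])]
    fp = score_cohort(visits, patients, window, role=ROLE_FP, attachment=attachment)
    sp = score_cohort(visits, patients, window, role=ROLE_SPECIALIST)

    v = visits[visits["physician_role"] == ROLE_SPECIALIST].merge(
        patients[["patient_id", "death_date"]], on="patient_id"
    )
    off = (v["death_date"] - v["visit_date"]).dt.days
    v = v[window.contains(off.to_numpy())]
    n_unique = v.groupby("patient_id")["physician_id"].nunique()

    m = fp[fp["eligible"]][["patient_id", "rvi", "n_visits"]].rename(
        columns={"rvi": "fp_rvi", "n_visits": "fp_visits"}
    )
    m = m.merge(
        sp[sp["eligible"]][["patient_id", "rvi", "n_visits"]].rename(
            columns={"rvi": "sp_rvi", "n_visits": "sp_visits"}
        ),
        on="patient_id", how="inner",
    )
    m["n_unique_specialists"] = m["patient_id"].map(n_unique).fillna(0).astype(int)
    return m.reset_index(drop=True)
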