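"""Cohort eligibility filters, physician attachment, and specialty filtering.

Reproduces the flowchart logic of a death-anchored claims cohort: adults
(19+) at death, below 105 at death (older ages flag administrative
date-of-birth errors), continuously insured over the last two years of
life, community-dwelling (no long-term-care residence), and with at least
two outpatient family-physician visits in the exposure window so the
regularity exposure is computable.  Rules are applied in that fixed order
and each removed patient is tallied under the first rule it fails, which
makes the attrition report well defined.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError
from .regularity import (
    ATTRIBUTION_WINDOW,
    DEFAULT_WINDOW,
    OUTPATIENT_LOCATIONS,
    ObservationWindow,
    ROLE_FP,
    ROLE_SPECIALIST,
)

__all__ = [
    "ExclusionReport",
    "EXCLUSION_RULES",
    "DEFAULT_EXCLUDED_SPECIALTIES",
    "apply_exclusions",
    "attach_physician",
    "filter_specialist_claims",
]

EXCLUSION_RULES = (
    "age<19",
    "age>=105",
    "insurance-ineligible",
    "long-term-care",
    "<2 FP visits",
)

REQUIRED_FLAG_COLUMNS = ("insurance_gap", "ltc_residence")

#: Specialties through which patients do not receive direct outpatient
#: specialist care; the real list is open-ended, so it stays configurable.
DEFAULT_EXCLUDED_SPECIALTIES = (
    "emergency medicine",
    "pathology",
    "laboratory medicine",
    "diagnostic radiology",
    "anesthesiology",
)

_KNOWN_SPECIALTIES = set(DEFAULT_EXCLUDED_SPECIALTIES) | {
    "family medicine", "cardiology", "respirology", "internal medicine",
    "oncology", "geriatrics", "nephrology", "gastroenterology",
    "neurology", "endocrinology", "palliative medicine",
}


@dataclass
class ExclusionReport:
    """Ordered attrition tally; one line per rule, first-failing rule wins."""

    initial_n: int
    steps: list = field(default_factory=list)  # (rule, n_removed, n_remaining)

    @property
    def final_n(self) -> int:
        return self.steps[-1][2] if self.steps else self.initial_n

    @property
    def total_removed(self) -> int:
        return sum(s[1] for s in self.steps)

    def add(self, rule: str, n_removed: int) -> None:
        remaining = (self.steps[-1][2] if self.steps else self.initial_n) - n_removed
        self.steps.append((rule, int(n_removed), int(remaining)))

    def to_dict(self) -> dict:
        return {
            "initial_n": self.initial_n,
            "steps": [
                {"rule": r, "n_removed": nr, "n_remaining": nrem}
                for r, nr, nrem in self.steps
            ],
            "final_n": self.final_n,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def pretty(self) -> str:
        lines = [f"Initial cohort: n = {self.initial_n}"]
        for rule, nr, nrem in self.steps:
            lines.append(f"  - removed {nr:>6} ({rule}); remaining {nrem}")
        lines.append(f"Final analysis cohort: n = {self.final_n}")
        return "\n".join(lines)


def _fp_visit_days_in_window(
    visits: pd.DataFrame, patients: pd.DataFrame, window: ObservationWindow
) -> pd.Series:
    """Distinct outpatient FP visit days per patient inside *window*."""
    v = visits[
        (visits["physician_role"] == ROLE_FP)
        & (visits["location"].isin(OUTPATIENT_LOCATIONS) if "location" in visits else True)
    ]
    merged = v.merge(patients[["patient_id", "death_date"]], on="patient_id", how="inner")
    off = (merged["death_date"] - merged["visit_date"]).dt.days
    merged = merged.assign(day_offset=off)
    merged = merged[window.contains(merged["day_offset"].to_numpy())]
    days = merged[["patient_id", "day_offset"]].drop_duplicates()
    counts = days.groupby("patient_id").size()
    return patients["patient_id"].map(counts).fillna(0).astype(int)


def apply_exclusions(
    patients: pd.DataFrame,
    visits: pd.DataFrame,
    exposure_window: ObservationWindow = DEFAULT_WINDOW,
    flags: pd.DataFrame | None = None,
):
    """Apply the eligibility rules in fixed order.

    ``flags`` may carry the ``insurance_gap`` / ``ltc_residence`` booleans
    keyed by ``patient_id``; by default they are read off the patients
    table.  Ages in the rules are ages *at death* (the table stores age
    two years before death).  Returns ``(retained_patients, report)``;
    the report tallies each removed patient under the first rule it fails,
    so the tallies sum to the total attrition exactly.
    """
    p = patients
    if flags is not None:
        p = p.drop(columns=[c for c in REQUIRED_FLAG_COLUMNS if c in p], errors="ignore")
        p = p.merge(flags, on="patient_id", how="left")
    missing = [c for c in REQUIRED_FLAG_COLUMNS if c not in p.columns]
    if missing:
        raise InputError(
            f"missing flag columns {missing}; required: {list(REQUIRED_FLAG_COLUMNS)}"
        )
    age_at_death = p["age_2y_before_death"].to_numpy() + 2
    fp_days = _fp_visit_days_in_window(visits, p, exposure_window).to_numpy()
    fails = {
        "age<19": age_at_death < 19,
        "age>=105": age_at_death >= 105,
        "insurance-ineligible": p["insurance_gap"].fillna(False).to_numpy(dtype=bool),
        "long-term-care": p["ltc_residence"].fillna(False).to_numpy(dtype=bool),
        "<2 FP visits": fp_days < 2,
    }
    report = ExclusionReport(initial_n=len(p))
    remaining = np.ones(len(p), dtype=bool)
    for rule in EXCLUSION_RULES:
        hit = remaining & fails[rule]
        report.add(rule, int(hit.sum()))
        remaining &= ~hit
    retained = patients[remaining].reset_index(drop=True)
    return retained, report


@dataclass(frozen=True)
class AttachmentRecord:
    patient_id: object
    attachment_type: str  # formal | virtual | unattached
    physician_id: object
    basis_count: int
    tie: bool


def attach_physician(
    patients: pd.DataFrame,
    visits: pd.DataFrame,
    roster: pd.DataFrame | None = None,
    attribution_window: ObservationWindow = ATTRIBUTION_WINDOW,
) -> pd.DataFrame:
    """Attach every patient to a family physician.

    A formal roster entry (``roster``: patient_id, physician_id) takes
    precedence.  Otherwise the patient is virtually attached to the FP
    with the most outpatient claims in the attribution window (default:
    the two years before the last two years of life); ties break to the
    smallest physician id and are flagged.  Patients with neither roster
    entry nor any in-window FP claim come back ``unattached`` and should
    be excluded downstream with their own attrition line.

    Output is invariant to the row order of *visits*.
    """
    v = visits[
        (visits["physician_role"] == ROLE_FP)
        & (visits["location"].isin(OUTPATIENT_LOCATIONS) if "location" in visits else True)
    ]
    merged = v.merge(patients[["patient_id", "death_date"]], on="patient_id", how="inner")
    off = (merged["death_date"] - merged["visit_date"]).dt.days
    merged = merged[attribution_window.contains(off.to_numpy())]
    counts = (
        merged.groupby(["patient_id", "physician_id"]).size().rename("n").reset_index()
    )
    counts = counts.sort_values(
        ["patient_id", "n", "physician_id"], ascending=[True, False, True], kind="mergesort"
    )
    top = counts.groupby("patient_id").first().reset_index()
    n_top = counts.merge(top[["patient_id", "n"]], on=["patient_id", "n"])
    ties = n_top.groupby("patient_id").size() > 1
    top["tie"] = top["patient_id"].map(ties).fillna(False)

    rostered = {}
    if roster is not None:
        rostered = dict(zip(roster["patient_id"], roster["physician_id"]))
    virtual = top.set_index("patient_id")

    records = []
    for pid in patients["patient_id"]:
        if pid in rostered:
            records.append((pid, "formal", rostered[pid], 0, False))
        elif pid in virtual.index:
            row = virtual.loc[pid]
            records.append((pid, "virtual", row["physician_id"], int(row["n"]), bool(row["tie"])))
        else:
            records.append((pid, "unattached", np.nan, 0, False))
    return pd.DataFrame(
        records, columns=["patient_id", "attachment_type", "physician_id", "basis_count", "tie"]
    )


def filter_specialist_claims(
    visits: pd.DataFrame,
    excluded_specialties: Sequence[str] = DEFAULT_EXCLUDED_SPECIALTIES,
) -> pd.DataFrame:
    """Drop specialist claims from non-direct-care specialties.

    Keeps specialist-role rows whose specialty is not on the exclusion
    list.  Unknown specialty codes pass through with a warning tally so a
    misconfigured dictionary surfaces without destroying data.
    """
    if "specialty" not in visits.columns:
        raise InputError("visits table must carry a specialty column")
    sp = visits[visits["physician_role"] == ROLE_SPECIALIST]
    excluded = set(excluded_specialties)
    unknown = set(sp["specialty"].unique()) - _KNOWN_SPECIALTIES - excluded
    if unknown:
        n_unknown = int(sp["specialty"].isin(unknown).sum())
        warnings.warn(
            f"{n_unknown} specialist claims with unknown specialty codes "
            f"{sorted(unknown)} passed through"
        )
    return sp[~sp["specialty"].isin(excluded)].reset_index(drop=True)
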