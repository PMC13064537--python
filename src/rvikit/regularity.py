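"""Relative variance index (RVI) of outpatient visit timing.

The RVI summarises how evenly spaced a patient's outpatient visits are over
a death-anchored observation window.  For the inter-visit gap durations
``g_1..g_n`` (in days) it is

    cv  = sd(g) / mean(g)          (sample standard deviation, n-1 denominator)
    rvi = 1 / (1 + 100 * cv)

so perfectly even spacing gives 1.0 and highly irregular spacing drives the
score towards 0.  The factor 100 makes the index extremely sensitive to
small deviations: five 30-day gaps score 1.0, while four 30-day gaps and a
single 31-day gap already score 0.40.  The formula here is a calibrated
reconstruction pinned to those two worked values and to the ~0.011 cohort
median observed under near-exponential visiting; see ``docs/methods.md``.

Scores are compared within a cohort by cutting them into empirical
quintiles (Q1 = least regular), which is how the index is used as a
regression exposure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError, UndefinedExposureError

__all__ = [
    "ObservationWindow",
    "VisitTimeline",
    "RviResult",
    "DEFAULT_WINDOW",
    "SENSITIVITY_WINDOWS",
    "OUTPATIENT_LOCATIONS",
    "extract_intervals",
    "compute_rvi",
    "score_cohort",
    "quintile_categorize",
    "window_sensitivity",
]

#: Location codes that count as outpatient physician visits.
OUTPATIENT_LOCATIONS = ("Office", "Home", "Phone")

ROLE_FP = "FP"
ROLE_SPECIALIST = "specialist"


@dataclass(frozen=True)
class ObservationWindow:
    """Half-open, death-anchored observation window.

    The window covers calendar days ``[death - start_offset, death - end_offset)``.
    Equivalently a visit with day-offset ``d`` before death (``d >= 1``) is
    inside the window iff ``end_offset < d <= start_offset``.  With the
    default (730, 30) window a visit exactly 30 days before death is
    excluded ("truncating the final 30 days") while a visit exactly 730
    days before death is included.
    """

    start_offset: int
    end_offset: int

    def __post_init__(self):
        if not (self.start_offset > self.end_offset >= 0):
            raise InputError(
                "ObservationWindow requires start_offset > end_offset >= 0, "
                f"got ({self.start_offset}, {self.end_offset})"
            )

    @property
    def span(self) -> int:
        """Window length in days."""
        return self.start_offset - self.end_offset

    def contains(self, offsets) -> np.ndarray:
        """Vectorized membership test for day-offsets before death."""
        offsets = np.asarray(offsets)
        return (offsets > self.end_offset) & (offsets <= self.start_offset)

    @property
    def label(self) -> str:
        return f"{self.start_offset}-{self.end_offset}"


#: Two years before death, truncating the final 30 days.
DEFAULT_WINDOW = ObservationWindow(730, 30)

#: Alternative look-back periods for the sensitivity analysis:
#: two years to three months, two years to one year, one year to three months.
SENSITIVITY_WINDOWS = (
    ObservationWindow(730, 90),
    ObservationWindow(730, 365),
    ObservationWindow(365, 90),
)

#: Attribution window for virtual physician attachment (the two years
#: before the last two years of life).
ATTRIBUTION_WINDOW = ObservationWindow(1460, 730)


@dataclass(frozen=True)
class VisitTimeline:
    """Ordered visit days for one patient and one provider role.

    ``visit_days`` are integer day-offsets before death (larger = earlier),
    sorted in increasing order; all strictly positive because visits
    precede death.
    """

    patient_id: object
    role: str
    visit_days: tuple

    def __post_init__(self):
        days = np.asarray(self.visit_days)
        if days.size and days.min() <= 0:
            raise InputError("visit day-offsets must be strictly positive (visits precede death)")


@dataclass(frozen=True)
class RviResult:
    """Regularity score with its audit trail.

    ``degenerate`` is True when only a single interval exists, in which
    case interval variance is undefined and the score is reported as 1.0
    with ``cv`` set to 0 by convention; downstream consumers can filter on
    the flag.
    """

    n_visits_in_window: int
    n_intervals: int
    mean_interval: float
    cv: float
    rvi: float
    degenerate: bool


def extract_intervals(timeline, window: ObservationWindow) -> np.ndarray:
    """Return consecutive gap durations (days) for visits inside *window*.

    *timeline* may be a :class:`VisitTimeline` or any sequence of integer
    day-offsets before death.  The input must already be sorted in
    non-decreasing order; an unsorted input raises :class:`InputError`
    rather than being silently re-sorted, so that upstream data faults
    surface.  Same-day duplicates are collapsed to a single visit day.
    Returns an empty array when fewer than two distinct in-window days
    remain.
    """
    days = np.asarray(timeline.visit_days if isinstance(timeline, VisitTimeline) else timeline)
    if days.size and np.any(np.diff(days) < 0):
        raise InputError("visit days must be sorted in non-decreasing order")
    inw = days[window.contains(days)]
    inw = np.unique(inw)
    if inw.size < 2:
        return np.array([], dtype=float)
    return np.diff(inw).astype(float)


def compute_rvi(gaps) -> RviResult:
    """Score a list of inter-visit gap durations.

    Raises :class:`UndefinedExposureError` on an empty gap list (the
    patient has fewer than two in-window visits and must be excluded
    upstream) and :class:`InputError` on non-positive gaps.  With a single
    gap the variance is undefined; the result is 1.0 with the
    ``degenerate`` flag set.

    Gaps are sorted internally before computing moments so the score is
    bit-identical under permutation of the input.
    """
    g = np.sort(np.asarray(gaps, dtype=float))
    if g.size == 0:
        raise UndefinedExposureError(
            "no inter-visit intervals: regularity is undefined for this patient"
        )
    if np.any(g <= 0):
        raise InputError("gap durations must be strictly positive")
    if g.size == 1:
        return RviResult(2, 1, float(g[0]), 0.0, 1.0, True)
    mean = float(g.mean())
    sd = float(g.std(ddof=1))
    cv = sd / mean
    rvi = 1.0 / (1.0 + 100.0 * cv)
    return RviResult(int(g.size) + 1, int(g.size), mean, cv, rvi, False)


def _window_day_offsets(
    visits: pd.DataFrame,
    patients: pd.DataFrame,
    window: ObservationWindow,
    role: str,
    attachment: Mapping | None,
) -> pd.DataFrame:
    """Distinct in-window (patient_id, day_offset) pairs for one role."""
    if "death_date" not in patients.columns:
        raise InputError("patients table must carry a death_date column")
    if patients["death_date"].isna().any():
        raise InputError("missing death date for one or more patients")

    v = visits[visits["physician_role"] == role]
    if "location" in v.columns:
        v = v[v["location"].isin(OUTPATIENT_LOCATIONS)]
    if attachment is not None and role == ROLE_FP:
        att = pd.Series(attachment, name="attached_fp")
        v = v.merge(att.rename_axis("patient_id").reset_index(), on="patient_id", how="inner")
        v = v[v["physician_id"] == v["attached_fp"]]

    merged = v.merge(patients[["patient_id", "death_date"]], on="patient_id", how="left")
    orphans = merged["death_date"].isna()
    if orphans.any():
        warnings.warn(
            f"dropping {int(orphans.sum())} claim rows that do not join to a patient",
            stacklevel=3,
        )
        merged = merged[~orphans]
    offsets = (merged["death_date"] - merged["visit_date"]).dt.days
    merged = merged.assign(day_offset=offsets)
    merged = merged[window.contains(merged["day_offset"].to_numpy())]
    pairs = merged[["patient_id", "day_offset"]].drop_duplicates()
    return pairs.sort_values(["patient_id", "day_offset"], kind="mergesort")


def _score_from_pairs(pairs: pd.DataFrame, all_patients: pd.Series) -> pd.DataFrame:
    """Vectorized per-patient RVI from sorted distinct (patient, offset) pairs."""
    pid = pairs["patient_id"].to_numpy()
    off = pairs["day_offset"].to_numpy(dtype=float)
    if len(pid):
        boundaries = np.flatnonzero(np.r_[True, pid[1:] != pid[:-1]])
        counts = np.diff(np.r_[boundaries, len(pid)])
        gaps = np.diff(off)
        gap_valid = np.ones(len(gaps), dtype=bool)
        gap_valid[boundaries[1:] - 1] = False  # gaps across patient boundaries
        grp = np.repeat(np.arange(len(boundaries)), counts - 1)
        g = gaps[gap_valid]
        n_int = counts - 1
        sums = np.zeros(len(boundaries))
        sumsq = np.zeros(len(boundaries))
        np.add.at(sums, grp, g)
        np.add.at(sumsq, grp, g * g)
        with np.errstate(divide="ignore", invalid="ignore"):
            mean = sums / n_int
            var = np.where(n_int > 1, (sumsq - n_int * mean**2) / np.maximum(n_int - 1, 1), 0.0)
            var = np.maximum(var, 0.0)  # guard tiny negative rounding
            cv = np.sqrt(var) / mean
            rvi = 1.0 / (1.0 + 100.0 * cv)
        res = pd.DataFrame(
            {
                "patient_id": pid[boundaries],
                "n_visits": counts,
                "n_intervals": n_int,
                "mean_interval": mean,
                "cv": np.where(n_int >= 1, cv, np.nan),
                "rvi": np.where(n_int >= 1, rvi, np.nan),
                "degenerate": n_int == 1,
                "eligible": n_int >= 1,
            }
        )
    else:
        res = pd.DataFrame(
            columns=[
                "patient_id", "n_visits", "n_intervals", "mean_interval",
                "cv", "rvi", "degenerate", "eligible",
            ]
        )
    # patients with zero or one in-window visit still get a row
    missing = all_patients[~all_patients.isin(res["patient_id"])]
    if len(missing):
        res = pd.concat(
            [
                res,
                pd.DataFrame(
                    {
                        "patient_id": missing.to_numpy(),
                        "n_visits": 0,
                        "n_intervals": 0,
                        "mean_interval": np.nan,
                        "cv": np.nan,
                        "rvi": np.nan,
                        "degenerate": False,
                        "eligible": False,
                    }
                ),
            ],
            ignore_index=True,
        )
    # single-visit patients: n_intervals == 0 -> ineligible (handled above via n_int >= 1)
    res.loc[res["n_intervals"] == 0, "eligible"] = False
    return res.sort_values("patient_id", kind="mergesort").reset_index(drop=True)


def score_cohort(
    visits: pd.DataFrame,
    patients: pd.DataFrame,
    window: ObservationWindow = DEFAULT_WINDOW,
    role: str = ROLE_FP,
    attachment: Mapping | None = None,
) -> pd.DataFrame:
    """Per-patient RVI over *window* for one provider role.

    Family-physician scores use the attached physician's visits when an
    ``attachment`` mapping (patient_id -> physician_id) is supplied;
    specialist scores pool all specialists into a single timeline.  Claims
    outside Office/Home/Phone locations are not outpatient visits and are
    ignored.  Patients with fewer than two distinct in-window visit days
    are flagged ``eligible=False`` rather than scored.

    Returns a DataFrame with one row per patient:
    patient_id, role, window, n_visits, n_intervals, mean_interval, cv,
    rvi, degenerate, eligible.  Degenerate (single-interval) scores are
    1.0 by convention and carry the flag.
    """
    pairs = _window_day_offsets(visits, patients, window, role, attachment)
    res = _score_from_pairs(pairs, patients["patient_id"])
    res.insert(1, "role", role)
    res.insert(2, "window", window.label)
    # degenerate single-interval case scores 1.0 by convention
    res.loc[res["degenerate"], "rvi"] = 1.0
    res.loc[res["degenerate"], "cv"] = 0.0
    return res


def quintile_categorize(scores) -> pd.DataFrame:
    """Cut per-patient scores into empirical quintiles Q1..Q5 (Q1 lowest).

    Cut points are the 20/40/60/80th percentiles under the
    linear-interpolation percentile definition; scores tied with a cut
    point fall in the lower quintile.  *scores* is a Series indexed by
    patient id or a DataFrame with ``patient_id`` and ``rvi`` columns.
    """
    if isinstance(scores, pd.DataFrame):
        s = scores.set_index("patient_id")["rvi"]
    else:
        s = pd.Series(scores)
    if s.isna().any():
        raise InputError("scores contain missing values; exclude ineligible patients first")
    if s.size < 5:
        raise InputError(f"quintile categorization needs at least 5 patients, got {s.size}")
    cuts = np.percentile(s.to_numpy(), [20, 40, 60, 80])
    if np.all(cuts == cuts[0]) and np.all(s.to_numpy() == cuts[0]):
        warnings.warn("degenerate quantiles: all scores identical; every patient assigned Q1")
    idx = (s.to_numpy()[:, None] > cuts[None, :]).sum(axis=1)
    return pd.DataFrame(
        {
            "patient_id": s.index.to_numpy(),
            "score": s.to_numpy(),
            "quintile": np.array([f"Q{i + 1}" for i in range(5)])[idx],
        }
    )


def window_sensitivity(
    visits: pd.DataFrame,
    patients: pd.DataFrame,
    windows: Sequence[ObservationWindow],
    role: str = ROLE_FP,
    attachment: Mapping | None = None,
):
    """Recompute RVI scores under alternative look-back windows.

    Returns ``(summary, scores_wide)``: *summary* has one row per window
    with the eligible n, median and quartiles of the score; *scores_wide*
    is a patient x window table of scores (NaN where ineligible) whose
    ``delta_*`` columns hold per-patient differences from the first
    window, supporting paired comparisons.
    """
    windows = list(windows)
    if len(windows) < 2:
        raise InputError("window_sensitivity needs at least 2 windows")
    rows = []
    wide = pd.DataFrame({"patient_id": patients["patient_id"].to_numpy()})
    for w in windows:
        sc = score_cohort(visits, patients, w, role=role, attachment=attachment)
        elig = sc[sc["eligible"]]
        rows.append(
            {
                "window": w.label,
                "n_eligible": int(len(elig)),
                "median_rvi": float(elig["rvi"].median()) if len(elig) else np.nan,
                "p25_rvi": float(elig["rvi"].quantile(0.25)) if len(elig) else np.nan,
                "p75_rvi": float(elig["rvi"].quantile(0.75)) if len(elig) else np.nan,
            }
        )
        col = sc.set_index("patient_id")["rvi"].where(sc.set_index("patient_id")["eligible"])
        wide[w.label] = wide["patient_id"].map(col)
    ref = windows[0].label
    for w in windows[1:]:
        wide[f"delta_{w.label}"] = wide[w.label] - wide[ref]
    return pd.DataFrame(rows), wide
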