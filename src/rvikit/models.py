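"""Adjusted outcome models for last-month acute-care utilization.

Count outcomes (hospitalizations, ED visits in the last 30 days of life)
are modelled with negative binomial regression (log link, NB2
mean-dispersion parameterization, dispersion estimated by maximum
likelihood); the binary acute-care-death outcome with logistic
regression.  The exposure is the family-physician visit-regularity (RVI)
quintile with Q1 (least regular) as reference; a sensitivity variant adds
the pooled-specialist RVI quintiles.  Exponentiated coefficients are
reported as incidence rate ratios (IRR) or odds ratios (OR) with Wald 95%
confidence intervals, plus the model AIC for goodness-of-fit comparison.

The API follows the statsmodels idiom: build an :class:`OutcomeModel`
from an analysis table, call :meth:`~OutcomeModel.fit`, and read
estimates off the returned :class:`OutcomeResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import ConvergenceError, InputError

__all__ = [
    "ModelSpec",
    "OutcomeModel",
    "OutcomeResults",
    "ModelComparison",
    "fit_outcome_model",
    "compare_models",
    "correlation_matrix",
]

#: Covariates of the adjusted models, measured at two years before death
#: (age, demographics, comorbidity burden) or over the exposure window
#: (visit counts); homecare receipt and cancer prevalence are included so
#: their adjusted effects are estimable alongside the exposure.
DEFAULT_COVARIATES = (
    "age", "male", "rural", "income_quintile", "adg_count",
    "fp_visits", "sp_visits", "homecare", "cancer",
)

QUINTILE_LEVELS = ("Q1", "Q2", "Q3", "Q4", "Q5")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one adjusted outcome model."""

    outcome: str
    family: str  # "negbin" | "logistic"
    exposure: str = "quintile"
    exposure_ref: str = "Q1"
    include_specialist_rvi: bool = False
    covariates: tuple = DEFAULT_COVARIATES
    label: str = ""

    def __post_init__(self):
        if self.family not in ("negbin", "logistic"):
            raise InputError(f"unknown family '{self.family}'; use 'negbin' or 'logistic'")
        if self.exposure_ref not in QUINTILE_LEVELS:
            raise InputError(f"exposure_ref must be one of {QUINTILE_LEVELS}")


def _dummies(series: pd.Series, levels: Sequence, ref, prefix: str) -> pd.DataFrame:
    out = pd.DataFrame(index=series.index)
    for lev in levels:
        if lev == ref:
            continue
        out[f"{prefix}{lev}"] = (series == lev).astype(float)
    return out


class OutcomeModel:
    """A single adjusted outcome regression, statsmodels style.

    Construct with :meth:`from_dataframe`, which builds the design matrix
    (quintile and income dummies, linear age/comorbidity/visit-count
    terms) and validates completeness — missing values in modelled
    columns are rejected, never imputed.
    """

    def __init__(self, endog: np.ndarray, exog: pd.DataFrame, spec: ModelSpec):
        self.endog = np.asarray(endog)
        self.exog = exog
        self.spec = spec
        self.nobs = len(exog)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, spec: ModelSpec) -> "OutcomeModel":
        needed = [spec.outcome, spec.exposure, *spec.covariates]
        if spec.include_specialist_rvi:
            needed.append("sp_quintile")
        missing_cols = [c for c in needed if c not in data.columns]
        if missing_cols:
            raise InputError(f"analysis table missing columns: {missing_cols}")
        block = data[needed]
        if block.isna().any().any():
            bad = block.columns[block.isna().any()].tolist()
            raise InputError(
                f"missing values in modelled columns {bad}; "
                "reject or exclude incomplete rows upstream (no imputation)"
            )
        y = data[spec.outcome].to_numpy()
        if spec.family == "negbin":
            if np.any(y < 0) or not np.allclose(y, np.round(y)):
                raise InputError(f"outcome '{spec.outcome}' must be non-negative integer counts")
            y = y.astype(int)
        else:
            y = np.asarray(y, dtype=float)
            if not np.isin(y, (0.0, 1.0)).all():
                raise InputError(f"outcome '{spec.outcome}' must be binary")

        X = pd.DataFrame(index=data.index)
        X["const"] = 1.0
        X = pd.concat(
            [X, _dummies(data[spec.exposure], QUINTILE_LEVELS, spec.exposure_ref, "rvi_")],
            axis=1,
        )
        if spec.include_specialist_rvi:
            X = pd.concat(
                [X, _dummies(data["sp_quintile"], QUINTILE_LEVELS, "Q1", "sp_rvi_")], axis=1
            )
        for cov in spec.covariates:
            if cov == "income_quintile":
                X = pd.concat(
                    [X, _dummies(data[cov], (1, 2, 3, 4, 5), 1, "income_q")], axis=1
                )
            else:
                X[cov] = data[cov].astype(float)
        return cls(y, X, spec)

    def fit(self, maxiter: int = 200) -> "OutcomeResults":
        """Maximum-likelihood fit; raises :class:`ConvergenceError` on failure."""
        X = self.exog.to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if self.spec.family == "negbin":
                start = sm.Poisson(self.endog, X).fit(disp=0, maxiter=maxiter)
                model = sm.NegativeBinomial(self.endog, X, loglike_method="nb2")
                res = model.fit(
                    start_params=np.append(start.params, 0.1),
                    method="bfgs", maxiter=maxiter, disp=0, gtol=1e-8,
                )
                # near the alpha=0 boundary BFGS can stop without setting the
                # flag although the score is numerically zero; accept that
                if not res.mle_retvals.get("converged", True):
                    if np.abs(model.score(res.params)).max() < 1e-2:
                        res.mle_retvals["converged"] = True
            else:
                try:
                    res = sm.Logit(self.endog, X).fit(disp=0, maxiter=maxiter)
                except Exception as exc:  # statsmodels PerfectSeparation*
                    if "separat" in str(exc).lower() or "Singular" in str(exc):
                        raise ConvergenceError(
                            "separation detected in logistic model; a larger sample or "
                            "fewer categories is needed", trace=str(exc),
                        ) from exc
                    raise
        if not res.mle_retvals.get("converged", True):
            raise ConvergenceError(
                f"{self.spec.family} fit for '{self.spec.outcome}' did not converge",
                trace=res.mle_retvals,
            )
        return OutcomeResults(self, res)


class OutcomeResults:
    """Fitted-model container: estimates, Wald CIs, AIC, diagnostics."""

    def __init__(self, model: OutcomeModel, smresults):
        self.model = model
        self.spec = model.spec
        self._res = smresults
        names = list(model.exog.columns)
        k = len(names)
        self.params = pd.Series(smresults.params[:k], index=names)
        self.bse = pd.Series(smresults.bse[:k], index=names)
        #: NB2 dispersion estimate (variance = mu + alpha mu^2); None for logistic
        self.alpha = (
            float(smresults.params[k]) if self.spec.family == "negbin" else None
        )
        self.aic = float(smresults.aic)
        self.nobs = int(model.nobs)
        self.converged = bool(smresults.mle_retvals.get("converged", True))

    def effects(self, include_intercept: bool = False) -> pd.DataFrame:
        """Exponentiated coefficient table: term, estimate (IRR/OR), Wald 95% CI."""
        terms = self.params.index.tolist()
        if not include_intercept:
            terms = [t for t in terms if t != "const"]
        est = np.exp(self.params[terms])
        lo = np.exp(self.params[terms] - 1.96 * self.bse[terms])
        hi = np.exp(self.params[terms] + 1.96 * self.bse[terms])
        scale = "IRR" if self.spec.family == "negbin" else "OR"
        return pd.DataFrame(
            {
                "term": terms,
                "estimate": est.to_numpy(),
                "lower95": lo.to_numpy(),
                "upper95": hi.to_numpy(),
                "scale": scale,
                "outcome": self.spec.outcome,
                "model": self.spec.label or ("sensitivity" if self.spec.include_specialist_rvi else "base"),
            }
        )

    def summary(self) -> str:
        """Readable fit summary with ratio-scale estimates."""
        eff = self.effects()
        lines = [
            f"Outcome: {self.spec.outcome}  family: {self.spec.family}  "
            f"n = {self.nobs}  AIC = {self.aic:.1f}"
            + (f"  alpha = {self.alpha:.3f}" if self.alpha is not None else ""),
            f"{'term':<14}{eff['scale'].iloc[0]:>8}{'lower95':>10}{'upper95':>10}",
        ]
        for _, r in eff.iterrows():
            lines.append(
                f"{r['term']:<14}{r['estimate']:>8.3f}{r['lower95']:>10.3f}{r['upper95']:>10.3f}"
            )
        return "\n".join(lines)

    def plot_forest(self, ax=None, terms: Sequence[str] | None = None):
        """Forest plot of ratio-scale estimates with 95% CIs."""
        import matplotlib.pyplot as plt

        eff = self.effects()
        if terms is not None:
            eff = eff[eff["term"].isin(terms)]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.4 * len(eff) + 1))
        y = np.arange(len(eff))[::-1]
        ax.errorbar(
            eff["estimate"], y,
            xerr=[eff["estimate"] - eff["lower95"], eff["upper95"] - eff["estimate"]],
            fmt="o", color="black", ecolor="gray", capsize=2,
        )
        ax.axvline(1.0, color="red", lw=0.8, ls="--")
        ax.set_yticks(y)
        ax.set_yticklabels(eff["term"])
        ax.set_xlabel(eff["scale"].iloc[0] + " (95% CI)")
        ax.set_title(self.spec.outcome)
        return ax


def fit_outcome_model(data: pd.DataFrame, spec: ModelSpec) -> OutcomeResults:
    """Convenience one-shot: build and fit in one call."""
    return OutcomeModel.from_dataframe(data, spec).fit()


@dataclass(frozen=True)
class ModelComparison:
    aic_base: float
    aic_sensitivity: float

    @property
    def delta(self) -> float:
        """AIC(base) - AIC(sensitivity); positive favours the sensitivity model."""
        return self.aic_base - self.aic_sensitivity

    def to_dict(self) -> dict:
        return {
            "aic_base": self.aic_base,
            "aic_sensitivity": self.aic_sensitivity,
            "delta": self.delta,
        }


def compare_models(
    base: ModelSpec, sensitivity: ModelSpec, data: pd.DataFrame
) -> ModelComparison:
    """AIC comparison of the base model and its specialist-RVI variant.

    The two specs must differ only in the specialist-RVI terms and are
    fitted on the same rows; a row-set mismatch (e.g. from differential
    missingness) raises :class:`InputError`.
    """
    if replace(base, include_specialist_rvi=True, label="") != replace(
        sensitivity, include_specialist_rvi=True, label=""
    ):
        raise InputError("specs must differ only by the specialist-RVI terms")
    m_base = OutcomeModel.from_dataframe(data, base)
    m_sens = OutcomeModel.from_dataframe(data, sensitivity)
    if not m_base.exog.index.equals(m_sens.exog.index):
        raise InputError("base and sensitivity fits must use the same rows")
    return ModelComparison(m_base.fit().aic, m_sens.fit().aic)


def correlation_matrix(measures: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations among per-patient utilization/regularity measures.

    Expects columns such as fp_rvi, sp_rvi, fp_visits, sp_visits,
    n_unique_specialists.  Zero-variance columns yield NaN entries (not a
    silent 0) and a warning naming them.
    """
    num = measures.select_dtypes(include=[np.number])
    if len(num) < 3:
        raise InputError("correlation matrix needs at least 3 complete rows")
    if num.isna().any().any():
        raise InputError("measures contain missing values; drop incomplete rows first")
    zero_var = num.columns[num.std(ddof=1) == 0].tolist()
    if zero_var:
        warnings.warn(f"zero-variance columns {zero_var}: correlations undefined (NaN)")
    return num.corr(method="pearson")
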