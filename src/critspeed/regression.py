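"""VO2max prediction model: stepwise OLS on critical speed and sex.

Model 1 regresses relative VO2max (mL/kg/min) on CS alone (the
hypothesis variable, forced in first); Model 2 adds sex (F=0, M=1) when
its partial t-test clears the 0.05 entry criterion. With only two
candidate predictors, removal testing is a no-op. The standard error of
the estimate uses the n - k - 1 denominator.

The published coefficient set (CS 8.449, sex 4.387, intercept 14.683,
SEE 3.34 mL/kg/min) ships as the default for prediction without a
locally fitted model.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import reliability
from .config import EQ2_COEF_CS, EQ2_COEF_SEX, EQ2_INTERCEPT, EQ2_SEE

SEX_ENTRY_ALPHA = 0.05


@dataclass
class ModelFit:
    coef_cs: float
    coef_sex: float  # 0.0 when sex did not enter
    intercept: float
    se_cs: float
    se_sex: float
    beta_cs: float
    beta_sex: float
    see: float  # mL/kg/min, sqrt(RSS / (n - k - 1))
    r2_model1: float
    r2_model2: float
    n: int
    included_terms: tuple = ("cs",)
    notes: tuple = ()

    def __post_init__(self) -> None:
        if self.see < 0:
            raise ValueError("SEE must be >= 0")
        if self.r2_model2 < self.r2_model1 - 1e-12:
            raise ValueError("adding a term cannot reduce R^2")
        if self.n <= len(self.included_terms) + 1:
            raise ValueError("too few observations for the fitted terms")

    def to_dict(self) -> dict:
        return {
            "coef_cs": self.coef_cs,
            "coef_sex": self.coef_sex,
            "intercept": self.intercept,
            "se_cs": self.se_cs,
            "se_sex": self.se_sex,
            "beta_cs": self.beta_cs,
            "beta_sex": self.beta_sex,
            "see": self.see,
            "r2_model1": self.r2_model1,
            "r2_model2": self.r2_model2,
            "n": self.n,
            "included_terms": list(self.included_terms),
            "notes": list(self.notes),
        }


PUBLISHED_FIT = ModelFit(
    coef_cs=EQ2_COEF_CS,
    coef_sex=EQ2_COEF_SEX,
    intercept=EQ2_INTERCEPT,
    se_cs=1.323,
    se_sex=1.525,
    beta_cs=0.709,
    beta_sex=0.320,
    see=EQ2_SEE,
    r2_model1=0.67,
    r2_model2=0.76,
    n=25,
    included_terms=("cs", "sex"),
    notes=("published coefficient set",),
)


def _standardized_beta(coef: float, x: np.ndarray, y: np.ndarray) -> float:
    sy = y.std(ddof=1)
    if sy == 0:
        return float("nan")
    return coef * x.std(ddof=1) / sy


def fit_stepwise(cohort: pd.DataFrame) -> ModelFit:
    """Fit the stepwise prediction model on a valid cohort.

    ``cohort`` needs columns ``cs``, ``sex`` (0/1) and ``vo2max``
    (the observed criterion value).
    """
    for col in ("cs", "sex", "vo2max"):
        if col not in cohort.columns:
            raise ValueError(f"cohort table missing column {col!r}")
    cs = cohort["cs"].to_numpy(float)
    sex = cohort["sex"].to_numpy(float)
    y = cohort["vo2max"].to_numpy(float)
    n = y.size
    if n < 5:
        raise ValueError("need at least 5 athletes to fit the model")
    if np.ptp(cs) == 0:
        raise ValueError("rank-deficient design: CS has no variance")

    m1 = sm.OLS(y, sm.add_constant(cs)).fit()
    r2_model1 = float(m1.rsquared)

    notes: list[str] = []
    both_sexes = np.unique(sex).size == 2
    sex_enters = False
    if not both_sexes:
        notes.append("single-sex cohort: sex step skipped")
        final, r2_model2 = m1, r2_model1
    else:
        X2 = sm.add_constant(np.column_stack([cs, sex]))
        m2 = sm.OLS(y, X2).fit()
        if float(m2.pvalues[2]) < SEX_ENTRY_ALPHA:
            sex_enters = True
            final, r2_model2 = m2, float(m2.rsquared)
        else:
            notes.append(
                f"sex did not meet the p<{SEX_ENTRY_ALPHA} entry criterion "
                f"(p={float(m2.pvalues[2]):.3f})"
            )
            final, r2_model2 = m1, r2_model1

    see = float(np.sqrt(final.ssr / final.df_resid)) if final.df_resid > 0 else 0.0
    if sex_enters:
        return ModelFit(
            coef_cs=float(final.params[1]),
            coef_sex=float(final.params[2]),
            intercept=float(final.params[0]),
            se_cs=float(final.bse[1]),
            se_sex=float(final.bse[2]),
            beta_cs=_standardized_beta(float(final.params[1]), cs, y),
            beta_sex=_standardized_beta(float(final.params[2]), sex, y),
            see=see,
            r2_model1=r2_model1,
            r2_model2=r2_model2,
            n=n,
            included_terms=("cs", "sex"),
            notes=tuple(notes),
        )
    return ModelFit(
        coef_cs=float(final.params[1]),
        coef_sex=0.0,
        intercept=float(final.params[0]),
        se_cs=float(final.bse[1]),
        se_sex=float("nan"),
        beta_cs=_standardized_beta(float(final.params[1]), cs, y),
        beta_sex=float("nan"),
        see=see,
        r2_model1=r2_model1,
        r2_model2=r2_model2,
        n=n,
        included_terms=("cs",),
        notes=tuple(notes),
    )


def predict_vo2max(cs, sex, fit: ModelFit | None = None):
    """Predicted relative VO2max (mL/kg/min) from CS and sex.

    Defaults to the published coefficient set when no fitted model is
    given. ``sex`` is coded F=0 / M=1.
    """
    if fit is None:
        fit = PUBLISHED_FIT
    cs_arr = np.asarray(cs, dtype=float)
    sex_arr = np.asarray(sex)
    if not np.isin(sex_arr, (0, 1)).all():
        raise ValueError("sex must be coded 0 (female) or 1 (male)")
    out = fit.coef_cs * cs_arr + fit.coef_sex * sex_arr.astype(float) + fit.intercept
    return float(out) if out.ndim == 0 else out


def fitted_values(cohort: pd.DataFrame, fit: ModelFit) -> np.ndarray:
    if "sex" in fit.included_terms:
        return predict_vo2max(cohort["cs"].to_numpy(float), cohort["sex"].to_numpy(), fit)
    return fit.coef_cs * cohort["cs"].to_numpy(float) + fit.intercept


def compare_observed_predicted(cohort: pd.DataFrame, fit: ModelFit) -> dict:
    """Paired comparison of observed VO2max against model predictions.

    When the fit was produced from this same cohort (OLS with an
    intercept), the residuals sum to zero, so the paired t statistic is
    0 and p = 1 up to floating point.
    """
    observed = cohort["vo2max"].to_numpy(float)
    predicted = fitted_values(cohort, fit)
    if observed.size != predicted.size:
        raise ValueError("cohort and fit sizes do not match")
    t, p = reliability.paired_t(observed, predicted)
    return {
        "n": int(observed.size),
        "mean_observed": float(observed.mean()),
        "sd_observed": float(observed.std(ddof=1)),
        "mean_predicted": float(predicted.mean()),
        "sd_predicted": float(predicted.std(ddof=1)),
        "t": t,
        "p": p,
    }
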