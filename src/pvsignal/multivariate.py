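"""Confirmatory multivariable logistic regression.

The target-event indicator is regressed on sex (male reference, so the
reported odds ratio is for female), age, BMI and one 0/1 exposure indicator
per drug pre-selected by the disproportionality screen.  The fit is plain
maximum likelihood (no interactions, no regularisation) on complete-case
rows, with Wald confidence intervals and p-values.

For continuous covariates two summaries are reported: the unit odds ratio
exp(beta) (per one year of age, per one BMI unit) and the range odds ratio
exp(beta * (max - min)) over the observed range of the analysed rows, which
expresses the covariate's leverage across the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = ["LogisticSpec", "LogisticFit", "build_design", "fit_logistic",
           "unit_and_range_or"]

Z_95 = 1.959963984540054


@dataclass(frozen=True)
class LogisticSpec:
    """Model specification for the confirmatory regression."""

    drug_indicators: Tuple[str, ...]
    continuous_covariates: Tuple[str, ...] = ("age_years", "bmi")
    sex_covariate: bool = True            # female indicator, male reference
    outcome: str = "is_target_event"
    complete_case: bool = True

    def __post_init__(self):
        if not self.drug_indicators:
            raise ValueError("drug_indicators must be nonempty")
        cols = list(self.continuous_covariates) + list(self.drug_indicators)
        if len(set(cols)) != len(cols):
            raise ValueError("duplicate covariates in specification")


@dataclass
class LogisticFit:
    """Per-term estimates from the maximum-likelihood fit."""

    params: pd.DataFrame        # index: term; columns: coef, odds_ratio, ci_low, ci_high, p_value
    n_used: int
    converged: bool
    llf: float
    unit_or: Dict[str, float] = field(default_factory=dict)
    range_or: Dict[str, float] = field(default_factory=dict)

    def odds_ratio(self, term: str) -> float:
        return float(self.params.loc[term, "odds_ratio"])

    def ci95(self, term: str) -> Tuple[float, float]:
        row = self.params.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])


def build_design(rows: pd.DataFrame, spec: LogisticSpec
                 ) -> Tuple[pd.DataFrame, pd.Series]:
    """Design matrix and outcome vector for the specified model.

    Complete-case: rows missing any covariate are dropped.  All-zero drug
    indicator columns (drug absent from the analysed rows) are dropped with a
    warning because they cannot be estimated.
    """
    needed = list(spec.continuous_covariates)
    if spec.sex_covariate:
        needed.append("sex")
    mask = rows[spec.outcome].notna()
    if spec.complete_case:
        for col in needed:
            mask &= rows[col].notna()
    sub = rows[mask]
    design = pd.DataFrame(index=sub.index)
    if spec.sex_covariate:
        design["female"] = (sub["sex"] == "female").astype(float)
    for col in spec.continuous_covariates:
        design[col] = sub[col].astype(float)
    for drug in spec.drug_indicators:
        col = f"drug:{drug}"
        design[col] = (sub["drug_name"] == drug).astype(float)
        if design[col].sum() == 0:
            logger.warning("dropping all-zero drug indicator %r", drug)
            design = design.drop(columns=[col])
    outcome = sub[spec.outcome].astype(float)
    return design, outcome


def fit_logistic(design: pd.DataFrame, outcome: pd.Series,
                 groups: pd.Series | None = None) -> LogisticFit:
    """Maximum-likelihood logistic fit with Wald intervals.

    Newton-Raphson first; BFGS fallback if it fails to converge.  A fit that
    still has not converged is returned with ``converged=False`` and NaN
    inference columns rather than misleading partial results.

    ``groups`` (typically the case id) switches the covariance to the
    cluster-robust sandwich estimator: one report contributes several
    analysis rows (one per suspected drug and event), and treating those
    duplicated rows as independent understates the standard errors.  Point
    estimates are unaffected.
    """
    uniq = set(np.unique(outcome))
    if not uniq >= {0.0, 1.0}:
        raise ValueError("outcome must contain both classes (0 and 1)")
    X = sm.add_constant(design, has_constant="add")
    model = sm.Logit(outcome, X)
    fit_kwds = {}
    if groups is not None:
        codes = pd.Series(groups).loc[design.index]
        fit_kwds = {"cov_type": "cluster",
                    "cov_kwds": {"groups": pd.factorize(codes)[0]}}
    try:
        res = model.fit(disp=0, maxiter=100, **fit_kwds)
        converged = bool(res.mle_retvals.get("converged", False))
    except Exception:
        res, converged = None, False
    if not converged:
        try:
            res = model.fit(method="bfgs", disp=0, maxiter=500, **fit_kwds)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            res = None
    if res is None:
        raise RuntimeError("logistic fit failed")
    coefs = res.params
    if converged:
        se = res.bse
        p = res.pvalues
        params = pd.DataFrame({
            "coef": coefs,
            "odds_ratio": np.exp(coefs),
            "ci_low": np.exp(coefs - Z_95 * se),
            "ci_high": np.exp(coefs + Z_95 * se),
            "p_value": p,
        })
    else:
        logger.warning("logistic fit did not converge; inference withheld")
        params = pd.DataFrame({
            "coef": coefs,
            "odds_ratio": np.exp(coefs),
            "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan,
        })
    fit = LogisticFit(params=params, n_used=int(len(outcome)),
                      converged=converged, llf=float(res.llf))
    return fit


def unit_and_range_or(fit_or_coefs, design: pd.DataFrame,
                      continuous: Sequence[str] = ("age_years", "bmi"),
                      ) -> Tuple[Dict[str, float], Dict[str, float]]:
    """Unit and range odds ratios for continuous covariates.

    ``unit_or = exp(beta)``; ``range_or = exp(beta * (max - min))`` over the
    observed range in the analysed rows (a constant covariate has range 0 and
    so range OR 1).  Accepts a :class:`LogisticFit` or a plain mapping of
    coefficients.  The maps are also stored on the fit when one is given.
    """
    if isinstance(fit_or_coefs, LogisticFit):
        coefs: Mapping[str, float] = fit_or_coefs.params["coef"]
    else:
        coefs = fit_or_coefs
    unit: Dict[str, float] = {}
    rng: Dict[str, float] = {}
    for col in continuous:
        if col not in coefs or col not in design.columns:
            continue
        beta = float(coefs[col])
        span = float(design[col].max() - design[col].min())
        unit[col] = float(np.exp(beta))
        rng[col] = float(np.exp(beta * span))
    if isinstance(fit_or_coefs, LogisticFit):
        fit_or_coefs.unit_or = unit
        fit_or_coefs.range_or = rng
    return unit, rng
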