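"""Association of PRS quintile with prevalent disease, incident disease and biomarkers.

Prevalence ratios come from a log-link Poisson working model on the binary
prevalent status with HC0 sandwich standard errors ("robust Poisson");
hazard ratios from a Cox proportional-hazards fit (Efron tie handling, as in
lifelines) on the prevalent-free subset; cumulative incidence is one minus
the Kaplan–Meier estimate per risk category; biomarker effects are OLS betas.
All intervals are Wald, estimate ± 1.96 SE on the log (PR, HR) or identity
(beta) scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex", "bmi")
BIOMARKERS = ("fpg", "g2h", "tc", "tg", "hdl", "ldl")
Z95 = 1.959963984540054


@dataclass(frozen=True)
class EffectEstimate:
    contrast: str  # e.g. "Q5_vs_Q1"
    measure: str  # "PR" | "HR" | "beta"
    estimate: float
    ci_low: float
    ci_high: float
    pvalue: float


def _quintile_design(cohort: pd.DataFrame, covariates) -> pd.DataFrame:
    if "quintile" not in cohort:
        raise ValueError("cohort needs a 'quintile' column")
    if 1 not in set(cohort.quintile):
        raise ValueError("reference quintile 1 absent")
    X = pd.DataFrame(index=cohort.index)
    for q in (2, 3, 4, 5):
        X[f"Q{q}"] = (cohort.quintile == q).astype(float)
    for c in covariates:
        X[c] = cohort[c].astype(float)
    return X


def _wald(measure: str, contrast: str, coef: float, se: float, log_scale: bool) -> EffectEstimate:
    from scipy import stats

    z = coef / se
    p = 2 * stats.norm.sf(abs(z))
    lo, hi = coef - Z95 * se, coef + Z95 * se
    if log_scale:
        coef, lo, hi = np.exp(coef), np.exp(lo), np.exp(hi)
    return EffectEstimate(contrast, measure, float(coef), float(lo), float(hi), float(p))


def prevalence_ratios(
    cohort: pd.DataFrame, covariates=DEFAULT_COVARIATES
) -> list[EffectEstimate]:
    """Robust-Poisson prevalence ratios for quintiles 2–5 vs quintile 1."""
    y = cohort["prevalent_t2d"].astype(float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("prevalent status must be binary")
    X = sm.add_constant(_quintile_design(cohort, covariates))
    model = sm.GLM(y, X, family=sm.families.Poisson())
    try:
        fit = model.fit(cov_type="HC0")
    except Exception as exc:  # pragma: no cover - surfaced with context
        raise RuntimeError(f"robust Poisson fit failed: {exc}") from exc
    if not np.all(np.isfinite(fit.params)):
        raise RuntimeError("robust Poisson fit did not converge (non-finite coefficients)")
    return [
        _wald("PR", f"Q{q}_vs_Q1", fit.params[f"Q{q}"], fit.bse[f"Q{q}"], log_scale=True)
        for q in (2, 3, 4, 5)
    ]


def hazard_ratios(
    cohort: pd.DataFrame, covariates=DEFAULT_COVARIATES, full_model: bool = False
) -> list[EffectEstimate]:
    """Cox hazard ratios for quintiles 2–5 vs 1 on the prevalent-free subset.

    ``full_model=True`` additionally adjusts for the six baseline biomarkers.
    Quintiles without any event yield a non-identifiable (NaN) estimate.
    """
    df = cohort[cohort["prevalent_t2d"] == 0].copy()
    df = df[df["time_years"] > 0]
    if df.empty or df["event"].sum() < 1:
        raise ValueError("no incident events available for Cox regression")
    covs = tuple(covariates) + (BIOMARKERS if full_model else ())
    X = _quintile_design(df, covs)
    X["time_years"] = df["time_years"].astype(float)
    X["event"] = df["event"].astype(int)

    events_per_q = df.groupby("quintile").event.sum()
    dead = {q for q in (2, 3, 4, 5) if events_per_q.get(q, 0) == 0}
    for q in dead:
        logger.warning("quintile %d has zero events: HR non-identifiable", q)
        X = X.drop(columns=[f"Q{q}"])

    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(X, duration_col="time_years", event_col="event")

    out = []
    for q in (2, 3, 4, 5):
        if q in dead:
            out.append(EffectEstimate(f"Q{q}_vs_Q1", "HR", np.nan, np.nan, np.nan, np.nan))
        else:
            coef = float(cph.params_[f"Q{q}"])
            se = float(cph.standard_errors_[f"Q{q}"])
            out.append(_wald("HR", f"Q{q}_vs_Q1", coef, se, log_scale=True))
    return out


def cumulative_incidence(cohort: pd.DataFrame, group_col: str = "risk_category"):
    """1 - Kaplan–Meier per group on the prevalent-free subset.

    Returns {group: DataFrame(time, cumulative_incidence)}; empty groups are
    omitted with a warning.
    """
    df = cohort[cohort["prevalent_t2d"] == 0]
    curves: dict[str, pd.DataFrame] = {}
    for label, grp in df.groupby(group_col):
        if grp.empty:
            logger.warning("group %s empty; omitted from cumulative incidence", label)
            continue
        km = KaplanMeierFitter()
        km.fit(grp["time_years"], grp["event"])
        surv = km.survival_function_
        curves[str(label)] = pd.DataFrame(
            {
                "time": surv.index.to_numpy(dtype=float),
                "cumulative_incidence": 1.0 - surv.iloc[:, 0].to_numpy(),
            }
        )
    return curves


def biomarker_associations(
    cohort: pd.DataFrame, biomarker: str, covariates=DEFAULT_COVARIATES
) -> list[EffectEstimate]:
    """OLS betas of one biomarker on quintiles 2–5 in non-prevalent individuals.

    Adjusts for the default covariates plus the other five biomarkers.
    """
    if biomarker not in BIOMARKERS:
        raise ValueError(f"unknown biomarker {biomarker!r}; choose from {BIOMARKERS}")
    df = cohort[cohort["prevalent_t2d"] == 0]
    y = df[biomarker].astype(float)
    if y.nunique() < 2:
        raise ValueError(f"biomarker {biomarker} is degenerate")
    others = tuple(b for b in BIOMARKERS if b != biomarker)
    X = sm.add_constant(_quintile_design(df, tuple(covariates) + others))
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise RuntimeError("collinear design matrix in biomarker regression")
    fit = sm.OLS(y, X).fit()
    return [
        _wald("beta", f"Q{q}_vs_Q1", fit.params[f"Q{q}"], fit.bse[f"Q{q}"], log_scale=False)
        for q in (2, 3, 4, 5)
    ]


def estimates_frame(estimates) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contrast": [e.contrast for e in estimates],
            "measure": [e.measure for e in estimates],
            "estimate": [e.estimate for e in estimates],
            "ci_low": [e.ci_low for e in estimates],
            "ci_high": [e.ci_high for e in estimates],
            "pvalue": [e.pvalue for e in estimates],
        }
    )
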