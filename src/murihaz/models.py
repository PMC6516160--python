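"""Association models: Cox sex-by-site interaction and age-stratified
bodyweight-lifespan regressions.

Cox proportional-hazards fitting goes through :mod:`lifelines`
(Efron tie correction); dummy coding uses reference levels F (sex) and TJL
(site), so the interaction hazard ratios read as the male contrast at a
site relative to the male contrast at TJL. The interaction block is tested
with a likelihood-ratio test against the model without the product terms
(the LRT is invariant to the choice of coding).

Bodyweight regressions are ordinary least squares of lifespan (days) on
weight (grams) within sex-by-measurement-age strata, via statsmodels; the
standardized coefficient is ``beta * sd(weight) / sd(lifespan)``, whose
square equals R^2 in a univariate fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import CoxPHFitter
import statsmodels.api as sm

from .datasets import CohortTable

__all__ = [
    "CoxResult",
    "CoxTerm",
    "RegressionResult",
    "InteractionResult",
    "cox_fit",
    "weight_regression",
    "interaction_regression",
]


@dataclass(frozen=True)
class CoxTerm:
    name: str
    coef: float  # log-hazard scale
    se: float
    hazard_ratio: float
    p: float


@dataclass
class CoxResult:
    terms: list[CoxTerm]
    loglik_full: float
    loglik_reduced: float
    lrt_statistic: float
    lrt_df: int
    lrt_p: float

    def term(self, name: str) -> CoxTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass(frozen=True)
class RegressionResult:
    """Slope of lifespan on bodyweight within one stratum."""

    stratum: str  # "pooled", "F", or "M"
    age_months: int
    coefficient: float  # days per gram
    se: float
    p: float
    r_squared: float
    standardized_coefficient: float
    n: int


@dataclass
class InteractionResult:
    """OLS of lifespan on weight, a moderator, and their product terms."""

    moderator: str
    age_months: int
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    interaction_f: float
    interaction_df: tuple[int, int]
    interaction_p: float
    n: int


def _cox_design(cohort: CohortTable, include_interaction: bool) -> pd.DataFrame:
    tab = cohort.table
    df = pd.DataFrame({
        "duration": tab["age_days"].to_numpy(dtype=float),
        "event": (tab["status"] == "died").to_numpy().astype(int),
        "male": (tab["sex"] == "M").to_numpy().astype(float),
    })
    sites = [s for s in tab["site"].cat.categories if s in set(tab["site"])]
    ref = "TJL" if "TJL" in sites else sites[0]
    for s in sites:
        if s == ref:
            continue
        df[f"site_{s}"] = (tab["site"] == s).to_numpy().astype(float)
        if include_interaction:
            df[f"male:site_{s}"] = df["male"] * df[f"site_{s}"]
    return df


def cox_fit(cohort: CohortTable, include_interaction: bool = True) -> CoxResult:
    """Cox PH model of lifespan on sex, site, and (optionally) sex-by-site.

    Censored animals enter as censored observations; ties are handled by the
    Efron correction. The likelihood-ratio test compares the full model
    against the model without the interaction block (df = number of product
    terms); with ``include_interaction=False`` the LRT compares against the
    null (no-covariate) model instead.
    """
    full_df = _cox_design(cohort, include_interaction)
    covars = [c for c in full_df.columns if c not in ("duration", "event")]
    for c in covars:
        if full_df[c].nunique() < 2:
            raise ValueError(f"degenerate covariate {c!r}: single level in the data")
    if full_df["event"].sum() == 0:
        raise ValueError("no events in the cohort")

    full = CoxPHFitter()
    full.fit(full_df, duration_col="duration", event_col="event")

    if include_interaction:
        reduced_df = _cox_design(cohort, include_interaction=False)
        reduced = CoxPHFitter()
        reduced.fit(reduced_df, duration_col="duration", event_col="event")
        ll_reduced = float(reduced.log_likelihood_)
        df_lrt = len(covars) - (len(reduced_df.columns) - 2)
    else:
        null_lrt = full.log_likelihood_ratio_test()  # full model vs no covariates
        ll_reduced = float(full.log_likelihood_ - null_lrt.test_statistic / 2.0)
        df_lrt = len(covars)

    ll_full = float(full.log_likelihood_)
    lrt = max(2.0 * (ll_full - ll_reduced), 0.0)
    terms = [
        CoxTerm(
            name=name,
            coef=float(full.params_[name]),
            se=float(full.standard_errors_[name]),
            hazard_ratio=float(np.exp(full.params_[name])),
            p=float(full.summary.loc[name, "p"]),
        )
        for name in full.params_.index
    ]
    return CoxResult(
        terms=terms,
        loglik_full=ll_full,
        loglik_reduced=ll_reduced,
        lrt_statistic=lrt,
        lrt_df=df_lrt,
        lrt_p=float(stats.chi2.sf(lrt, df=df_lrt)),
    )


def _stratum_ols(weights: np.ndarray, lifespan: np.ndarray, stratum: str,
                 age_months: int) -> RegressionResult:
    if len(weights) < 3:
        raise ValueError(f"stratum {stratum!r} at {age_months} months has < 3 animals")
    if np.std(weights) == 0:
        raise ValueError(f"zero weight variance in stratum {stratum!r}")
    X = sm.add_constant(weights)
    fit = sm.OLS(lifespan, X).fit()
    beta = float(fit.params[1])
    std_beta = beta * float(np.std(weights, ddof=1) / np.std(lifespan, ddof=1))
    return RegressionResult(
        stratum=stratum,
        age_months=int(age_months),
        coefficient=beta,
        se=float(fit.bse[1]),
        p=float(fit.pvalues[1]),
        r_squared=float(fit.rsquared),
        standardized_coefficient=std_beta,
        n=len(weights),
    )


def weight_regression(joined: pd.DataFrame, age_months: int,
                      stratify_by_sex: bool = True) -> list[RegressionResult]:
    """OLS of lifespan (days) on bodyweight (g) at one measurement age.

    ``joined`` is the output of :func:`murihaz.datasets.join_weights`
    (censored animals and post-mortem weights already excluded). Returns one
    :class:`RegressionResult` per stratum: both sexes separately when
    ``stratify_by_sex``, otherwise a single pooled fit.
    """
    sub = joined[joined["age_months"] == age_months]
    if len(sub) == 0:
        raise ValueError(f"no weights at measurement age {age_months} months")
    results = []
    if stratify_by_sex:
        for sex in ("F", "M"):
            s = sub[sub["sex"] == sex]
            results.append(_stratum_ols(s["weight_g"].to_numpy(dtype=float),
                                        s["lifespan_days"].to_numpy(dtype=float),
                                        sex, age_months))
    else:
        results.append(_stratum_ols(sub["weight_g"].to_numpy(dtype=float),
                                    sub["lifespan_days"].to_numpy(dtype=float),
                                    "pooled", age_months))
    return results


def interaction_regression(joined: pd.DataFrame, age_months: int,
                           moderator: str = "sex") -> InteractionResult:
    """OLS of lifespan on weight, a moderator (sex or site), and the
    weight-by-moderator product terms, with an F-test of the interaction
    block against the additive model."""
    if moderator not in ("sex", "site"):
        raise ValueError(f"moderator must be 'sex' or 'site', got {moderator!r}")
    sub = joined[joined["age_months"] == age_months].copy()
    if len(sub) == 0:
        raise ValueError(f"no weights at measurement age {age_months} months")
    levels = [l for l in pd.unique(sub[moderator].astype(str))]
    if len(levels) < 2:
        raise ValueError(f"moderator {moderator!r} has fewer than 2 levels")
    ref = {"sex": "F", "site": "TJL"}[moderator]
    levels = sorted(levels, key=lambda l: (l != ref, l))

    y = sub["lifespan_days"].to_numpy(dtype=float)
    w = sub["weight_g"].to_numpy(dtype=float)
    X = pd.DataFrame({"weight": w})
    inter_cols = []
    for l in levels[1:]:
        dummy = (sub[moderator].astype(str) == l).to_numpy().astype(float)
        X[f"{moderator}_{l}"] = dummy
        X[f"weight:{moderator}_{l}"] = w * dummy
        inter_cols.append(f"weight:{moderator}_{l}")
    X = sm.add_constant(X)
    fit = sm.OLS(y, X).fit()
    reduced = sm.OLS(y, X.drop(columns=inter_cols)).fit()
    f_stat, f_p, f_df = fit.compare_f_test(reduced)
    return InteractionResult(
        moderator=moderator,
        age_months=int(age_months),
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        interaction_f=float(f_stat),
        interaction_df=(int(f_df), int(fit.df_resid)),
        interaction_p=float(f_p),
        n=len(y),
    )
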