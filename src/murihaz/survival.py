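"""Classical survival comparisons: Kaplan-Meier, log-rank, median CI, and
the maximum-lifespan proportion test.

The product-limit estimator, its variance (Greenwood by default, the
Aalen/Tsiatis form optionally) and the log-transformed confidence band are
implemented directly so the median-CI inversion and the maximum-lifespan
threshold share one set of conventions. The maximum-lifespan comparison
follows the quantile approach used in aging studies: approximate maximum
lifespan as the age at which the pooled population reaches 90% mortality,
then compare the per-sex proportions still alive at that age with a
two-sided Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datasets import CohortTable

__all__ = [
    "KMCurve",
    "MedianEstimate",
    "MaxLifespanResult",
    "km_curve",
    "median_with_ci",
    "logrank",
    "max_lifespan_test",
]


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit estimate at the observed event ages."""

    event_ages: np.ndarray  # increasing, ages with >= 1 death
    survival: np.ndarray  # S(t) at each event age
    variance_of_log_s: np.ndarray  # cumulative variance of log S
    n_at_risk: np.ndarray
    n_events: np.ndarray
    variance_method: str = "greenwood"

    def survival_at(self, age: float) -> float:
        """Step-function value of S at ``age`` (right-continuous)."""
        i = np.searchsorted(self.event_ages, age, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])

    def confidence_band(self, conf_level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise log-transformed CI: ``exp(log S +/- z * se(log S))``."""
        z = stats.norm.ppf(0.5 + conf_level / 2.0)
        se = np.sqrt(self.variance_of_log_s)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_s = np.log(self.survival)
            lower = np.where(self.survival > 0, np.exp(log_s - z * se), 0.0)
            upper = np.where(self.survival > 0, np.minimum(np.exp(log_s + z * se), 1.0), 0.0)
        return lower, upper


@dataclass(frozen=True)
class MedianEstimate:
    median_days: float | None
    ci_lower_days: float | None
    ci_upper_days: float | None
    method: str = "km-log-greenwood"


@dataclass
class MaxLifespanResult:
    """Fisher-exact comparison of the proportions alive at the pooled
    90%-mortality age."""

    threshold_age_days: float
    counts: dict[str, tuple[int, int]]  # sex -> (alive, dead) at threshold
    proportions: dict[str, float]
    proportion_ci: dict[str, tuple[float, float]]
    fisher_p: float
    odds_ratio: float


def _as_arrays(ages, statuses) -> tuple[np.ndarray, np.ndarray]:
    ages = np.asarray(ages, dtype=float)
    statuses = np.asarray(statuses)
    if statuses.dtype.kind in "UOS":
        died = statuses == "died"
    else:
        died = statuses.astype(bool)
    if len(ages) == 0:
        raise ValueError("need at least one record")
    return ages, died


def km_curve(ages, statuses, variance: str = "greenwood") -> KMCurve:
    """Product-limit survival estimate under right censoring.

    ``statuses`` may be "died"/"censored" strings or booleans (True=death).
    Ties at one age are handled by simultaneous multiplication; censored
    animals leave the risk set after their censoring age (a censoring tied
    with a death is counted at risk for that death, the usual convention).
    ``variance`` selects the cumulative variance of log S: ``"greenwood"``
    (``sum d/(n(n-d))``) or ``"aalen"`` (``sum d/n^2``).
    """
    if variance not in ("greenwood", "aalen"):
        raise ValueError(f"unknown variance method {variance!r}")
    ages, died = _as_arrays(ages, statuses)
    order = np.argsort(ages, kind="stable")
    ages, died = ages[order], died[order]
    n = len(ages)

    event_ages = np.unique(ages[died])
    # risk set: alive and uncensored just before t, i.e. age >= t
    n_at_risk = n - np.searchsorted(ages, event_ages, side="left")
    d = np.array([np.sum(died & (ages == t)) for t in event_ages], dtype=float)

    frac = 1.0 - d / n_at_risk
    survival = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        if variance == "greenwood":
            terms = np.where(n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), np.inf)
        else:
            terms = d / n_at_risk.astype(float) ** 2
    var_log_s = np.cumsum(terms)
    return KMCurve(event_ages=event_ages, survival=survival,
                   variance_of_log_s=var_log_s, n_at_risk=n_at_risk.astype(int),
                   n_events=d.astype(int), variance_method=variance)


def _first_crossing(event_ages: np.ndarray, values: np.ndarray, level: float) -> float | None:
    below = values <= level + 1e-12  # cumprod rounding must not shift the crossing
    if not below.any():
        return None
    return float(event_ages[int(np.argmax(below))])


def median_with_ci(curve: KMCurve, conf_level: float = 0.95) -> MedianEstimate:
    """Median lifespan with a CI by inversion of the pointwise S band.

    The median is the smallest age with ``S <= 0.5``; the CI endpoints are
    the smallest ages where the lower/upper confidence bounds of S cross
    0.5. Either endpoint may be undefined (``None``) if its bound never
    reaches 0.5 within the observed ages.
    """
    median = _first_crossing(curve.event_ages, curve.survival, 0.5)
    if median is None:
        return MedianEstimate(None, None, None,
                              method=f"km-log-{curve.variance_method}")
    lower_band, upper_band = curve.confidence_band(conf_level)
    ci_lo = _first_crossing(curve.event_ages, lower_band, 0.5)
    ci_hi = _first_crossing(curve.event_ages, upper_band, 0.5)
    return MedianEstimate(median, ci_lo, ci_hi,
                          method=f"km-log-{curve.variance_method}")


def logrank(ages_a, statuses_a, ages_b, statuses_b) -> tuple[float, float]:
    """One-degree-of-freedom log-rank test between two groups.

    At each shared event time the observed deaths in group A are compared
    with the hypergeometric expectation given the margins; the statistic is
    ``(sum O - E)^2 / sum V`` with a chi-square(1) tail p-value.
    """
    ages_a, died_a = _as_arrays(ages_a, statuses_a)
    ages_b, died_b = _as_arrays(ages_b, statuses_b)
    ages = np.concatenate([ages_a, ages_b])
    died = np.concatenate([died_a, died_b])
    group_a = np.zeros(len(ages), dtype=bool)
    group_a[: len(ages_a)] = True
    if not died.any():
        raise ValueError("log-rank requires at least one event")

    event_times = np.unique(ages[died])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = ages >= t
        n_tot = int(at_risk.sum())
        n_a = int((at_risk & group_a).sum())
        dying = died & (ages == t)
        d_tot = int(dying.sum())
        d_a = int((dying & group_a).sum())
        if n_tot <= 1:
            continue
        e_a = d_tot * n_a / n_tot
        o_minus_e += d_a - e_a
        var += d_tot * (n_tot - d_tot) * n_a * (n_tot - n_a) / (n_tot**2 * (n_tot - 1))
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def max_lifespan_test(cohort: CohortTable, mortality_quantile: float = 0.90,
                      proportion_from: str = "counts",
                      censored_rule: str = "exclude") -> MaxLifespanResult:
    """Sex comparison of the proportion reaching 'maximum lifespan'.

    The threshold is the smallest age at which the pooled (both-sex) KM
    survival falls to ``1 - mortality_quantile`` — KM-based, hence
    censoring-consistent. Within each sex, animals censored before the
    threshold have unknown status there and are excluded
    (``censored_rule="exclude"``; ``"dead"`` counts them as not reaching
    it). The 2x2 alive/dead-by-sex table is tested with a two-sided Fisher
    exact test (summing tables with probability <= the observed one);
    per-sex proportion CIs are Clopper-Pearson. ``proportion_from="km"``
    reports the per-sex KM survival at the threshold instead of raw counts
    (the table and p-value always use counts).
    """
    cohort.require_both_sexes()
    if proportion_from not in ("counts", "km"):
        raise ValueError(f"unknown proportion_from {proportion_from!r}")
    if censored_rule not in ("exclude", "dead"):
        raise ValueError(f"unknown censored_rule {censored_rule!r}")
    tab = cohort.table
    pooled = km_curve(tab["age_days"], tab["status"])
    threshold = _first_crossing(pooled.event_ages, pooled.survival,
                                1.0 - mortality_quantile)
    if threshold is None:
        raise ValueError(
            f"pooled survival never reaches {1 - mortality_quantile:.0%}; threshold undefined"
        )

    counts: dict[str, tuple[int, int]] = {}
    proportions: dict[str, float] = {}
    prop_ci: dict[str, tuple[float, float]] = {}
    for sex in ("F", "M"):
        sub = tab[tab["sex"] == sex]
        ages = sub["age_days"].to_numpy(dtype=float)
        censored = (sub["status"] == "censored").to_numpy()
        if censored_rule == "exclude":
            keep = ~(censored & (ages <= threshold))
        else:
            keep = np.ones(len(ages), dtype=bool)
        ages_k = ages[keep]
        alive = int(np.sum(ages_k > threshold))
        dead = int(len(ages_k) - alive)
        if alive + dead == 0:
            raise ValueError(f"sex {sex!r} has no classifiable animals at the threshold")
        counts[sex] = (alive, dead)
        if proportion_from == "km":
            km_sex = km_curve(ages, ~censored)
            proportions[sex] = km_sex.survival_at(threshold)
        else:
            proportions[sex] = alive / (alive + dead)
        lo, hi = _clopper_pearson(alive, alive + dead)
        prop_ci[sex] = (lo, hi)

    table = np.array([counts["F"], counts["M"]])
    odds_ratio, p = stats.fisher_exact(table, alternative="two-sided")
    return MaxLifespanResult(
        threshold_age_days=float(threshold), counts=counts,
        proportions=proportions, proportion_ci=prop_ci,
        fisher_p=float(p), odds_ratio=float(odds_ratio),
    )


def _clopper_pearson(k: int, n: int, conf_level: float = 0.95) -> tuple[float, float]:
    alpha = 1.0 - conf_level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi
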