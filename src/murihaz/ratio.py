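"""Age-specific male:female hazard-ratio curves with bootstrap bands.

The point estimate is the ratio of the two sexes' smoothed hazards fitted
with identical smoother settings on a common age grid (restricted to ages
where both sexes contribute person-time). Uncertainty comes from a
nonparametric bootstrap that resamples animals with replacement within each
sex, refits both hazards per replicate (re-selecting the smoothing
parameter unless told otherwise), and takes pointwise 2.5th/97.5th
percentiles across replicate ratio curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import CohortTable, ValidationError
from .hazard import SmootherSettings, bin_exposure, fit_smoothed_hazard

__all__ = ["HazardRatioCurve", "HRSummary", "hazard_ratio_curve", "bootstrap_hr", "hr_summary"]

#: Grid step of the ratio curve, in days (below the visual resolution of a
#: lifespan-scale hazard plot, above numerical noise).
GRID_STEP_DAYS = 5.0

#: A curve whose total range is below this is reported as having no
#: distinct peak.
FLAT_TOLERANCE = 0.05


@dataclass
class HazardRatioCurve:
    """Male:female hazard ratio on an age grid, with bootstrap bands."""

    age_grid: np.ndarray
    hr: np.ndarray
    band_lower: np.ndarray | None = None
    band_upper: np.ndarray | None = None
    n_bootstrap: int = 0
    replicate_curves: np.ndarray | None = None  # (B, len(grid))
    n_redraws: int = 0

    def __post_init__(self) -> None:
        if np.any(self.hr <= 0):
            raise ValueError("hazard ratio must be positive")
        if self.band_lower is not None and np.any(self.band_lower > self.band_upper):
            raise ValueError("band_lower must not exceed band_upper")


@dataclass(frozen=True)
class HRSummary:
    """Peak and convergence summary of a hazard-ratio curve."""

    peak_age_days: float
    peak_hr: float
    convergence_age_days: float | None
    no_distinct_peak: bool = False


def _sex_exposures(cohort: CohortTable, settings: SmootherSettings):
    cohort.require_both_sexes()
    tab = cohort.table
    entry = cohort.weaning_age_days
    top = float(tab["age_days"].max())
    edges = np.arange(entry, top, settings.bin_width_days)
    edges = np.append(edges, edges[-1] + settings.bin_width_days)
    out = {}
    for sex in ("F", "M"):
        sub = cohort.subset((tab["sex"] == sex).to_numpy())
        if (sub.table["status"] == "died").sum() == 0:
            raise ValidationError(f"sex stratum {sex!r} has no events")
        out[sex] = bin_exposure(sub, bin_edges=edges, entry_age=entry)
    return out, edges


#: The ratio grid ends once either sex's at-risk count drops below
#: ``max(MIN_AT_RISK, TAIL_FRACTION * n_sex)``. Smoothed-ratio inference on
#: the last handful of animals is boundary extrapolation, and the bootstrap
#: band undercovers there (too few distinct animals to resample); hazard
#: displays of cohorts at this scale conventionally stop near the age where
#: about 2% remain at risk.
MIN_AT_RISK = 10
TAIL_FRACTION = 0.02


def _common_grid(exp_f, exp_m, edges: np.ndarray, cohort: CohortTable) -> np.ndarray:
    """Ages with positive person-time in both sexes and an adequate risk
    set, on the 5-day grid."""
    both = (exp_f.persontime > 0) & (exp_m.persontime > 0)
    j = np.flatnonzero(both)
    lo, hi = edges[j[0]], edges[j[-1] + 1]
    tab = cohort.table
    for sex in ("F", "M"):
        ages = np.sort(tab.loc[tab["sex"] == sex, "age_days"].to_numpy(dtype=float))
        k = max(MIN_AT_RISK, int(np.ceil(TAIL_FRACTION * len(ages))))
        if len(ages) >= k:
            hi = min(hi, ages[-k])
    return np.arange(lo, hi + 0.5 * GRID_STEP_DAYS, GRID_STEP_DAYS)


def _hr_on_grid(exp_f, exp_m, grid: np.ndarray, settings: SmootherSettings) -> np.ndarray:
    curves = {}
    for sex, exp in (("F", exp_f), ("M", exp_m)):
        curves[sex] = fit_smoothed_hazard(
            exp, lam=settings.lam, n_knots=settings.n_knots,
            degree=settings.degree, penalty_order=settings.penalty_order,
        )
    return curves["M"](grid) / curves["F"](grid)


def hazard_ratio_curve(cohort: CohortTable,
                       settings: SmootherSettings = SmootherSettings()) -> HazardRatioCurve:
    """Point-estimate male:female hazard-ratio curve.

    Both sexes are smoothed with identical settings on shared bin edges; the
    output grid covers only ages where both sexes have positive person-time.
    """
    exposures, edges = _sex_exposures(cohort, settings)
    grid = _common_grid(exposures["F"], exposures["M"], edges, cohort)
    hr = _hr_on_grid(exposures["F"], exposures["M"], grid, settings)
    return HazardRatioCurve(age_grid=grid, hr=hr)


def bootstrap_hr(cohort: CohortTable, B: int = 1000, seed: int = 0,
                 settings: SmootherSettings = SmootherSettings(),
                 stratify: str = "sex", keep_replicates: bool = True,
                 max_redraw: int = 100) -> HazardRatioCurve:
    """Bootstrap the hazard-ratio curve; bands are pointwise 95% percentiles.

    The resampling unit is the animal, drawn with replacement within each
    stratum (``stratify="sex"`` by default, or ``"sex_site_cohort"``). Each
    replicate refits both hazards on the original common grid, re-selecting
    the smoothing parameter when ``settings.lam == "auto"``. A replicate in
    which either sex has no events is redrawn (the number of redraws is
    reported on the result).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if stratify not in ("sex", "sex_site_cohort"):
        raise ValueError(f"unknown stratification {stratify!r}")

    exposures, edges = _sex_exposures(cohort, settings)
    grid = _common_grid(exposures["F"], exposures["M"], edges, cohort)
    hr = _hr_on_grid(exposures["F"], exposures["M"], grid, settings)

    tab = cohort.table
    if stratify == "sex":
        keys = tab["sex"].astype(str)
    else:
        keys = (tab["sex"].astype(str) + "|" + tab["site"].astype(str)
                + "|" + tab["cohort"].astype(str))
    strata = {k: np.flatnonzero((keys == k).to_numpy()) for k in keys.unique()}
    sex_codes = tab["sex"].to_numpy()
    ages = tab["age_days"].to_numpy(dtype=float)
    died = (tab["status"] == "died").to_numpy()
    entry = cohort.weaning_age_days

    rng = np.random.default_rng(seed)
    reps = np.empty((B, len(grid)))
    n_redraws = 0
    b = 0
    while b < B:
        idx = np.concatenate([rng.choice(members, size=len(members), replace=True)
                              for members in strata.values()])
        ok = True
        rep_exp = {}
        for sex in ("F", "M"):
            sel = idx[sex_codes[idx] == sex]
            if not died[sel].any():
                ok = False
                break
            rep_exp[sex] = _bin_ages(ages[sel], died[sel], edges, entry)
        if not ok:
            n_redraws += 1
            if n_redraws > max_redraw:
                raise RuntimeError("too many zero-event bootstrap replicates")
            continue
        reps[b] = _hr_on_grid(rep_exp["F"], rep_exp["M"], grid, settings)
        b += 1

    # order-statistic percentiles: symmetric under curve inversion and, at
    # B = 2, degenerate to the pointwise min/max of the two replicates
    lower = np.quantile(reps, 0.025, axis=0, method="lower")
    upper = np.quantile(reps, 0.975, axis=0, method="higher")
    return HazardRatioCurve(
        age_grid=grid, hr=hr, band_lower=lower, band_upper=upper,
        n_bootstrap=B, replicate_curves=reps if keep_replicates else None,
        n_redraws=n_redraws,
    )


def _bin_ages(ages: np.ndarray, died: np.ndarray, edges: np.ndarray,
              entry: float):
    """Fast path of :func:`murihaz.hazard.bin_exposure` for resampled arrays."""
    from .hazard import ExposureTable

    lo = np.maximum(entry, edges[:-1][None, :])
    hi = np.minimum(ages[:, None], edges[1:][None, :])
    persontime = np.clip(hi - lo, 0.0, None).sum(axis=0)
    idx = np.searchsorted(edges, ages[died], side="right") - 1
    idx = np.minimum(idx, len(edges) - 2)
    events = np.bincount(idx, minlength=len(edges) - 1).astype(float)
    return ExposureTable(bin_edges=edges, events=events, persontime=persontime,
                         n_animals=len(ages), entry_age=entry)


def hr_summary(curve: HazardRatioCurve) -> HRSummary:
    """Summarize the peak and the convergence age of a hazard-ratio curve.

    The peak is the argmax of the point estimate (first age on ties); a
    curve whose range is below 0.05 is flagged as having no distinct peak.
    The convergence age is the smallest grid age after the peak from which
    the band contains 1 *at every later grid age* — convergence is a
    sustained state, a single touch of the band is noise. ``None`` if the
    band never settles around 1, or if the curve has no bands.
    """
    hr = curve.hr
    i_peak = int(np.argmax(hr))
    flat = float(hr.max() - hr.min()) < FLAT_TOLERANCE
    if flat:
        i_peak = 0
    peak_age = float(curve.age_grid[i_peak])
    conv: float | None = None
    if curve.band_lower is not None:
        contains = (curve.band_lower <= 1.0) & (curve.band_upper >= 1.0)
        after = np.flatnonzero(~contains[i_peak + 1:])
        if contains[i_peak + 1:].size:
            if after.size == 0:
                conv = float(curve.age_grid[i_peak + 1])
            else:
                j = i_peak + 1 + int(after[-1]) + 1
                if j < len(contains):
                    conv = float(curve.age_grid[j])
    return HRSummary(peak_age_days=peak_age, peak_hr=float(hr[i_peak]),
                     convergence_age_days=conv, no_distinct_peak=flat)
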