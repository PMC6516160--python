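"""Estimate the smoothed age-specific mortality hazard for each sex.

Deaths and person-time are binned into 30-day age intervals and the log
hazard is fitted with a penalized B-spline Poisson model; the smoothing
parameter is selected by the variance-component iteration.
"""

import numpy as np

from murihaz import SimConfig, bin_exposure, fit_smoothed_hazard, simulate_cohort

sim = simulate_cohort(SimConfig.study_like(n_per_sex_per_site=100, seed=42))
tab = sim.cohort.table

for sex in ("F", "M"):
    sub = sim.cohort.subset((tab["sex"] == sex).to_numpy())
    exposure = bin_exposure(sub, bin_width_days=30.0)
    curve = fit_smoothed_hazard(exposure, lam="auto")
    print(f"\n{sex}: {curve.n_events} deaths, lambda={curve.lam:.3g}, "
          f"effective df={curve.effective_df:.1f}")
    for age in (200, 350, 500, 800, 1000):
        h = curve(np.array([float(age)]))[0]
        print(f"   h({age} d) = {h:.2e} per day")

# The female hazard is close to log-linear (Gompertz-like, ~2 effective df);
# the male hazard needs more df to track the mid-life excess and is roughly
# double the female hazard near 350 days.
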