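"""Bootstrap the age-specific male:female hazard-ratio curve.

Animals are resampled with replacement within each sex; both hazards are
refit per replicate (smoothing re-selected) and the 95% band is the
pointwise percentile envelope. The summary reports the peak of the excess
male mortality and the age from which the band settles around 1
(mortality convergence). B is kept small here for speed; analyses use
B = 1,000.
"""

import numpy as np

from murihaz import SimConfig, bootstrap_hr, hr_summary, simulate_cohort

sim = simulate_cohort(SimConfig.study_like(n_per_sex_per_site=100, seed=42))
curve = bootstrap_hr(sim.cohort, B=100, seed=7)
s = hr_summary(curve)

print(f"peak male:female hazard ratio {s.peak_hr:.2f} at {s.peak_age_days:.0f} d")
if s.convergence_age_days is not None:
    print(f"band contains 1 from {s.convergence_age_days:.0f} d onward "
          "(mortality convergence)")
for age in (200, 350, 500, 800):
    i = int(np.argmin(np.abs(curve.age_grid - age)))
    print(f"  HR({age} d) = {curve.hr[i]:.2f} "
          f"[{curve.band_lower[i]:.2f}, {curve.band_upper[i]:.2f}]")

# The ratio rises through early adulthood, peaks in mid-life near the
# generator's true peak (2.2 x at 350 d before site mixing), and returns
# to 1 around 800 d.
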