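"""Generate a synthetic multi-site mouse cohort and look at its survival.

The study-like preset is calibrated so the female median lifespan lands
near 887 days and the male median near 803 days, with the male deficit
concentrated in mid-life.
"""

from murihaz import SimConfig, km_curve, median_with_ci, simulate_cohort

cfg = SimConfig.study_like(n_per_sex_per_site=100, seed=42)
sim = simulate_cohort(cfg)
tab = sim.cohort.table

print(f"animals: {len(tab)}  (sites: {sorted(cfg.sites)}, "
      f"cohorts: {len(cfg.cohorts)})")
print(f"censored males (cage censoring): "
      f"{int((tab['status'] == 'censored').sum())}")

for sex in ("F", "M"):
    sub = tab[tab["sex"] == sex]
    est = median_with_ci(km_curve(sub["age_days"], sub["status"]))
    print(f"{sex}: median lifespan {est.median_days:.0f} d "
          f"(95% CI {est.ci_lower_days:.0f}-{est.ci_upper_days:.0f})")

# The median gap (~80 d) comes entirely from the mid-life male
# excess-mortality window; late-life hazards are identical by construction.
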