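import numpy as np
import pandas as pd
import pytest

from murihaz import (
    SimConfig,
    km_curve,
    logrank,
    median_with_ci,
    simulate_cohort,
    true_hazard,
    true_hazard_ratio,
)
from murihaz.simulate import (
    GompertzParams,
    HRBump,
    WeightModel,
    _frailty_weight,
    frailty_taper,
)
from dataclasses import replace


class TestTrueHazard:
    def test_unit_peak_ratio_gives_unit_ratio(self):
        cfg = replace(SimConfig.study_like(), hr_bump=HRBump(peak_ratio=1.0),
                      sites={"TJL": 1.0, "UM": 1.0, "UT": 1.0})
        t = np.linspace(25, 1200, 50)
        assert np.allclose(true_hazard_ratio(cfg, t, "UM"), 1.0)
        assert np.allclose(true_hazard(cfg, "M", "TJL", t),
                           true_hazard(cfg, "F", "TJL", t))

    def test_ratio_at_peak_is_site_scaled_peak_ratio(self):
        cfg = SimConfig.study_like()
        peak = cfg.hr_bump.peak_age_days
        for site, m in cfg.sites.items():
            assert true_hazard_ratio(cfg, peak, site) == pytest.approx(
                cfg.hr_bump.peak_ratio * m)

    def test_ratio_is_one_from_convergence_onward(self):
        cfg = SimConfig.study_like()
        t = np.array([800.0, 900.0, 1500.0])
        for site in cfg.sites:
            assert np.all(true_hazard_ratio(cfg, t, site) == 1.0)

    def test_true_ratio_unimodal_with_max_at_peak(self):
        cfg = SimConfig.study_like()
        t = np.arange(21.0, 1200.0)
        r = true_hazard_ratio(cfg, t, "TJL")
        i = int(np.argmax(r))
        assert t[i] == cfg.hr_bump.peak_age_days
        assert np.all(np.diff(r[: i + 1]) >= -1e-12)
        assert np.all(np.diff(r[i:][r[i:] > 1.0]) <= 1e-12)

    def test_age_below_weaning_rejected(self):
        with pytest.raises(ValueError, match="weaning"):
            true_hazard(SimConfig.study_like(), "F", "TJL", 5.0)

    def test_frailty_taper_profile(self):
        cfg = SimConfig.study_like()
        t0, t1 = frailty_taper(cfg)
        assert _frailty_weight(cfg, np.array([t0 - 1.0]))[0] == 1.0
        assert _frailty_weight(cfg, np.array([t1 + 1.0]))[0] == 0.0
        mid = _frailty_weight(cfg, np.array([(t0 + t1) / 2]))[0]
        assert 0.0 < mid < 1.0


class TestSimulateCohort:
    def test_no_censoring_mechanisms_all_die(self):
        cfg = replace(SimConfig.study_like(n_per_sex_per_site=20, seed=2),
                      cage_censor_prob_m=0.0, admin_censor_age_days=None)
        sim = simulate_cohort(cfg)
        assert (sim.cohort.table["status"] == "died").all()

    def test_seed_determinism_bit_identical(self):
        cfg = SimConfig.study_like(n_per_sex_per_site=15, seed=7)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.cohort.table, b.cohort.table)
        pd.testing.assert_frame_equal(a.weights, b.weights)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_all_ages_at_or_after_weaning(self, study_like_sim):
        cfg = study_like_sim.config
        assert (study_like_sim.cohort.table["age_days"] >= cfg.weaning_age_days).all()

    def test_monotone_empirical_survival_per_stratum(self, small_sim):
        tab = small_sim.cohort.table
        for (_, _), grp in tab.groupby(["sex", "site"], observed=True):
            ages = np.sort(grp["age_days"].to_numpy())
            surv = 1.0 - np.arange(1, len(ages) + 1) / len(ages)
            assert np.all(np.diff(surv) <= 0)

    def test_admin_censoring_caps_ages(self):
        cfg = replace(SimConfig.study_like(n_per_sex_per_site=30, seed=3),
                      admin_censor_age_days=900.0)
        sim = simulate_cohort(cfg)
        tab = sim.cohort.table
        assert tab["age_days"].max() <= 900.0
        capped = tab["age_days"] == 900.0
        assert (tab.loc[capped, "status"] == "censored").all()

    def test_cage_censoring_censors_whole_cages_before_first_death(self):
        cfg = replace(SimConfig.study_like(n_per_sex_per_site=200, seed=4),
                      cage_censor_prob_m=0.5)
        sim = simulate_cohort(cfg)
        tab = sim.cohort.table.merge(sim.truth, on="mouse_id")
        males = tab[tab["sex"] == "M"]
        cen = males[males["status"] == "censored"]
        assert len(cen) > 0
        for cage, grp in cen.groupby("cage_id"):
            full_cage = males[males["cage_id"] == cage]
            # everyone in a censored cage is censored, at one shared age
            assert (full_cage["status"] == "censored").all()
            assert grp["age_days"].nunique() == 1
            assert grp["age_days"].iloc[0] <= full_cage["true_death_age_days"].min()

    def test_female_median_matches_quadrature_oracle(self):
        """Sampled female median agrees with an independent numeric inversion
        of the frailty-integrated survival curve (n = 5,000)."""
        cfg = replace(SimConfig.study_like(n_per_sex_per_site=5000 // 3, seed=9),
                      cohorts=(2004,), cage_censor_prob_m=0.0)
        sim = simulate_cohort(cfg)
        ages = sim.cohort.table.loc[sim.cohort.table["sex"] == "F", "age_days"]

        # oracle: Gauss-Hermite over frailty, trapezoid over age
        g = cfg.female_gompertz
        grid = np.arange(cfg.weaning_age_days, 2500.0)
        h = g.a * np.exp(g.b * grid)
        gt = _frailty_weight(cfg, grid)
        x, w = np.polynomial.hermite_e.hermegauss(40)
        w = w / w.sum()
        S = np.zeros_like(grid)
        c = cfg.weight_model.frailty_hazard_coupling_f
        for z, wt in zip(x, w):
            hz = h * np.exp(c * z * gt)
            Hz = np.concatenate([[0.0], np.cumsum(0.5 * (hz[1:] + hz[:-1]))])
            S += wt * np.exp(-Hz)
        oracle_median = float(np.interp(-0.5, -S, grid))
        assert abs(float(np.median(ages)) - oracle_median) < 15.0

    def test_study_like_medians_and_ordering(self, study_like_sim):
        """Calibration: female median in [850, 925] and male median lower."""
        tab = study_like_sim.cohort.table
        med = {}
        for sex in "FM":
            sub = tab[tab["sex"] == sex]
            med[sex] = median_with_ci(km_curve(sub["age_days"], sub["status"])).median_days
        assert 850.0 <= med["F"] <= 925.0
        assert med["M"] < med["F"]

    def test_null_preset_sexes_indistinguishable(self):
        cfg = SimConfig.null_preset(n_per_sex_per_site=112, seed=11)  # ~2,000/sex
        sim = simulate_cohort(cfg)
        tab = sim.cohort.table
        f = tab[tab["sex"] == "F"]
        m = tab[tab["sex"] == "M"]
        _, p = logrank(f["age_days"], f["status"], m["age_days"], m["status"])
        assert p > 0.01


class TestSimulateWeights:
    def test_degenerate_config_shares_one_weight_curve(self):
        wm = WeightModel(frailty_weight_coupling_f=0.0, frailty_weight_coupling_m=0.0,
                         terminal_loss_fraction=0.0, measurement_noise_sd_g=0.0)
        cfg = replace(SimConfig.study_like(n_per_sex_per_site=10, seed=5),
                      weight_model=wm, cage_censor_prob_m=0.0)
        sim = simulate_cohort(cfg)
        w = sim.weights.merge(sim.cohort.table[["mouse_id", "sex"]], on="mouse_id")
        for (_, _), grp in w.groupby(["sex", "age_months"], observed=True):
            assert grp["weight_g"].nunique() == 1

    def test_weights_only_emitted_while_under_observation(self, small_sim):
        w = small_sim.weights.merge(small_sim.cohort.table[["mouse_id", "age_days"]],
                                    on="mouse_id")
        assert (w["measured_age_days"] < w["age_days"]).all()

    def test_males_heavier_than_females(self, small_sim):
        w = small_sim.weights.merge(small_sim.cohort.table[["mouse_id", "sex"]],
                                    on="mouse_id")
        w6 = w[w["age_months"] == 6]
        assert (w6[w6["sex"] == "M"]["weight_g"].mean()
                > w6[w6["sex"] == "F"]["weight_g"].mean() + 4.0)


class TestConfigRoundTrip:
    def test_yaml_round_trip(self, tmp_path):
        cfg = SimConfig.study_like(n_per_sex_per_site=17, seed=3)
        p = tmp_path / "simconfig.yaml"
        cfg.to_yaml(p)
        assert SimConfig.from_yaml(p) == cfg

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            HRBump(peak_ratio=0.5)
        with pytest.raises(ValueError):
            HRBump(peak_age_days=900.0, convergence_age_days=800.0)
        with pytest.raises(ValueError):
            GompertzParams(a=-1e-4)
        with pytest.raises(ValueError):
            replace(SimConfig.study_like(), cage_censor_prob_m=1.5)
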