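import numpy as np
import pandas as pd
import pytest

from murihaz import (
    cox_fit,
    interaction_regression,
    join_weights,
    weight_regression,
)
from tests.conftest import make_cohort


def joined_frame(weights, lifespans, sexes=None, sites=None, age_months=6):
    n = len(weights)
    return pd.DataFrame({
        "mouse_id": [f"m{i}" for i in range(n)],
        "age_months": age_months,
        "weight_g": np.asarray(weights, float),
        "measured_age_days": age_months * 30.44,
        "sex": sexes if sexes is not None else ["M"] * n,
        "site": sites if sites is not None else ["TJL"] * n,
        "cohort": 2004,
        "lifespan_days": np.asarray(lifespans, float),
        "status": "died",
    })


class TestCoxFit:
    def test_null_relabeling_gives_near_zero_coefficients(self):
        # one stratum duplicated under both labels: by symmetry beta = 0
        rng = np.random.default_rng(0)
        ages = np.clip(rng.exponential(700.0, 500), 1.0, None)
        c = make_cohort(np.concatenate([ages, ages]),
                        sexes=["F"] * 500 + ["M"] * 500)
        res = cox_fit(c, include_interaction=False)
        assert abs(res.term("male").coef) < 0.05

    def test_known_log_hazard_ratio_recovered(self):
        rng = np.random.default_rng(1)
        ages = np.concatenate([rng.exponential(500.0, 1000),
                               rng.exponential(1000.0, 1000)])  # M hazard = 0.5x
        c = make_cohort(np.clip(ages, 1.0, None),
                        sexes=["F"] * 1000 + ["M"] * 1000)
        res = cox_fit(c, include_interaction=False)
        assert res.term("male").coef == pytest.approx(np.log(0.5), abs=0.1)
        assert res.term("male").hazard_ratio == pytest.approx(
            np.exp(res.term("male").coef))

    def test_toy_coefficient_matches_partial_likelihood_grid_search(self):
        c = make_cohort([1.0, 2.0, 3.0, 4.0], sexes=["F", "M", "F", "M"])
        res = cox_fit(c, include_interaction=False)
        x = np.array([0.0, 1.0, 0.0, 1.0])

        def neg_log_pl(beta):
            # event order 1,2,3,4; risk sets shrink from the front
            ll = 0.0
            for i in range(4):
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[i:])))
            return -ll

        grid = np.arange(-5.0, 5.0, 1e-4)
        beta_star = grid[np.argmin([neg_log_pl(b) for b in grid])]
        assert res.term("male").coef == pytest.approx(beta_star, abs=1e-4)

    def test_interaction_lrt_detects_male_only_site_effect(self, study_like_sim):
        res = cox_fit(study_like_sim.cohort, include_interaction=True)
        assert res.lrt_statistic >= 0.0
        assert res.lrt_df == 2
        assert res.lrt_p < 0.01  # UM males really are different in the preset
        # UM males longer-lived than the TJL male contrast -> HR < 1
        assert res.term("male:site_UM").hazard_ratio < 1.0

    def test_interaction_coefficient_recovers_male_only_site_multiplier(self):
        """A constant male-only hazard multiplier m at one site is estimated
        by the interaction coefficient: log m inside its 95% Wald CI in most
        seeds (exponential lifespans, 600/site/sex)."""
        m_true = 0.6
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(900 + seed)
            ages, sexes, sites = [], [], []
            for site in ("TJL", "UM"):
                for sex in ("F", "M"):
                    rate = 1.0 / 800.0
                    if sex == "M" and site == "UM":
                        rate *= m_true
                    ages.append(rng.exponential(1.0 / rate, 600))
                    sexes += [sex] * 600
                    sites += [site] * 600
            c = make_cohort(np.clip(np.concatenate(ages), 1.0, None),
                            sexes=sexes, sites=sites)
            res = cox_fit(c, include_interaction=True)
            t = res.term("male:site_UM")
            hits += (t.coef - 1.96 * t.se) <= np.log(m_true) <= (t.coef + 1.96 * t.se)
        assert hits >= 8

    def test_degenerate_covariate_named(self):
        c = make_cohort([100.0, 200.0, 300.0], sexes=["F", "F", "F"])
        with pytest.raises(ValueError, match="male"):
            cox_fit(c, include_interaction=False)


class TestWeightRegression:
    def test_exact_line_recovered(self):
        w = np.array([20.0, 25.0, 30.0, 35.0, 40.0])
        res, = weight_regression(joined_frame(w, 1000.0 - 2.0 * w),
                                 6, stratify_by_sex=False)
        assert res.coefficient == pytest.approx(-2.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.standardized_coefficient == pytest.approx(-1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        w = rng.uniform(20, 45, 20)
        y = 900.0 - 5.0 * w + rng.normal(0, 40, 20)
        res, = weight_regression(joined_frame(w, y), 6, stratify_by_sex=False)
        X = np.column_stack([np.ones(20), w])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / 18
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        r2 = 1 - (resid @ resid) / np.sum((y - y.mean()) ** 2)
        assert res.coefficient == pytest.approx(beta[1], abs=1e-10)
        assert res.se == pytest.approx(se, abs=1e-10)
        assert res.r_squared == pytest.approx(r2, abs=1e-10)

    def test_standardized_coefficient_squared_is_r2(self):
        rng = np.random.default_rng(3)
        w = rng.uniform(20, 45, 50)
        y = 800.0 - 3.0 * w + rng.normal(0, 60, 50)
        res, = weight_regression(joined_frame(w, y), 6, stratify_by_sex=False)
        assert res.standardized_coefficient**2 == pytest.approx(res.r_squared,
                                                                abs=1e-10)
        assert np.sign(res.standardized_coefficient) == np.sign(res.coefficient)

    def test_unit_change_rescales_slope_only(self):
        rng = np.random.default_rng(4)
        w = rng.uniform(20, 45, 30)
        y = 800.0 - 3.0 * w + rng.normal(0, 50, 30)
        res_g, = weight_regression(joined_frame(w, y), 6, stratify_by_sex=False)
        res_kg, = weight_regression(joined_frame(w / 1000.0, y), 6,
                                    stratify_by_sex=False)
        assert res_kg.coefficient == pytest.approx(1000.0 * res_g.coefficient)
        assert res_kg.r_squared == pytest.approx(res_g.r_squared)
        assert res_kg.standardized_coefficient == pytest.approx(
            res_g.standardized_coefficient)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(5)
        w = rng.uniform(20, 45, 25)
        y = 800.0 - 3.0 * w + rng.normal(0, 50, 25)
        frame = joined_frame(w, y)
        shuffled = frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a, = weight_regression(frame, 6, stratify_by_sex=False)
        b, = weight_regression(shuffled, 6, stratify_by_sex=False)
        assert a.coefficient == pytest.approx(b.coefficient, abs=1e-12)

    def test_zero_weight_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            weight_regression(joined_frame([30.0] * 5, [1, 2, 3, 4, 5]),
                              6, stratify_by_sex=False)

    def test_sex_stratification(self, study_like_sim):
        joined, _ = join_weights(study_like_sim.cohort, study_like_sim.weights)
        res = weight_regression(joined, 6, stratify_by_sex=True)
        assert {r.stratum for r in res} == {"F", "M"}
        m = next(r for r in res if r.stratum == "M")
        f = next(r for r in res if r.stratum == "F")
        assert m.coefficient < 0
        assert abs(m.coefficient) > abs(f.coefficient)


class TestInteractionRegression:
    def test_duplicated_strata_zero_interaction(self):
        rng = np.random.default_rng(6)
        w = rng.uniform(20, 45, 30)
        y = 800.0 - 3.0 * w + rng.normal(0, 50, 30)
        frame = pd.concat([joined_frame(w, y, sexes=["F"] * 30),
                           joined_frame(w, y, sexes=["M"] * 30)],
                          ignore_index=True)
        res = interaction_regression(frame, 6, moderator="sex")
        assert res.params["weight:sex_M"] == pytest.approx(0.0, abs=1e-9)
        assert res.params["sex_M"] == pytest.approx(0.0, abs=1e-9)

    def test_detects_true_slope_difference(self):
        rng = np.random.default_rng(7)
        w = rng.uniform(20, 45, 400)
        yf = 900.0 - 1.0 * w[:200] + rng.normal(0, 30, 200)
        ym = 900.0 - 8.0 * w[200:] + rng.normal(0, 30, 200)
        frame = pd.concat([joined_frame(w[:200], yf, sexes=["F"] * 200),
                           joined_frame(w[200:], ym, sexes=["M"] * 200)],
                          ignore_index=True)
        res = interaction_regression(frame, 6, moderator="sex")
        assert res.interaction_p < 1e-6
        assert res.params["weight:sex_M"] == pytest.approx(-7.0, abs=1.0)

    def test_single_level_moderator_rejected(self):
        frame = joined_frame([20.0, 30.0, 40.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="2 levels"):
            interaction_regression(frame, 6, moderator="sex")

    def test_site_moderator_supported(self, study_like_sim):
        joined, _ = join_weights(study_like_sim.cohort, study_like_sim.weights)
        res = interaction_regression(joined, 6, moderator="site")
        assert res.interaction_df[0] == 2
        assert 0.0 <= res.interaction_p <= 1.0
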