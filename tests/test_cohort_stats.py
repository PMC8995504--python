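import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from femstrength.cohort_stats import (collinearity_screen, fit_ladder, fit_ols,
                                      group_comparison, mann_whitney,
                                      predict_strength, published_best_model,
                                      quartile_summary, spearman)
from femstrength.synthetic_data import default_cohort_spec, generate_cohort


def brute_force_u_pvalue(a, b):
    """Enumerate every assignment of pooled ranks to group A (tie-free data)."""
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    u_obs = stats.rankdata(pooled)[:n].sum() - n * (n + 1) / 2
    centre = n * m / 2
    count = 0
    total = 0
    ranks = stats.rankdata(pooled)
    for combo in itertools.combinations(range(n + m), n):
        u = ranks[list(combo)].sum() - n * (n + 1) / 2
        if abs(u - centre) >= abs(u_obs - centre) - 1e-12:
            count += 1
        total += 1
    assert total == comb(n + m, n)
    return count / total


class TestMannWhitney:
    def test_textbook_separated_groups(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.method == "exact"

    @pytest.mark.parametrize("seed,n,m", [(0, 3, 3), (1, 4, 3), (2, 5, 5),
                                          (3, 6, 4), (4, 5, 4)])
    def test_exact_p_equals_brute_force_enumeration(self, seed, n, m):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=n), rng.normal(size=m) + 0.5
        res = mann_whitney(a, b)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(brute_force_u_pvalue(a, b), abs=1e-12)

    def test_identical_samples_give_central_u(self):
        x = [3.0, 1.0, 2.0, 4.0]
        res = mann_whitney(x, list(reversed(x)))
        assert res.statistic == pytest.approx(len(x) ** 2 / 2)
        assert res.p_value == pytest.approx(1.0)

    def test_ties_fall_back_to_corrected_normal(self):
        res = mann_whitney([1, 2, 2, 3], [2, 3, 4, 4])
        assert res.method.startswith("normal")

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self):
        x = np.array([0.3, 1.2, 2.0, 3.5, 7.7])
        assert spearman(x, np.exp(x)).statistic == pytest.approx(1.0)
        assert spearman(x, -x).statistic == pytest.approx(-1.0)

    def test_exact_p_matches_full_permutation_enumeration(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        res = spearman(x, y)
        assert res.method == "exact-permutation"
        # Independent oracle: all 120 permutations, Pearson on ranks.
        xr = stats.rankdata(x)
        rhos = [stats.pearsonr(xr, stats.rankdata(y)[list(p)])[0]
                for p in itertools.permutations(range(5))]
        expected = np.mean(np.abs(rhos) >= abs(res.statistic) - 1e-12)
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = spearman(x, y)
        assert res.statistic == pytest.approx(
            stats.pearsonr(stats.rankdata(x), stats.rankdata(y))[0], abs=1e-12)

    def test_constant_input_reported_undefined(self):
        res = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isnan(res.statistic)
        assert res.method == "undefined-constant-input"


class TestRegressionLadder:
    def test_noiseless_cohort_recovers_generating_coefficients(self):
        spec = default_cohort_spec(noise_sd=0.0, seed=4)
        table = generate_cohort(spec)
        for g in spec.groups:
            sub = table[table["group"] == g.name]
            preds = tuple(sorted(g.slopes))
            m = fit_ols(sub, "femoral_strength", preds)
            assert m.adjusted_r_squared == pytest.approx(1.0, abs=1e-10)
            assert m.coefficients["const"] == pytest.approx(g.intercept, rel=1e-8)
            for p in preds:
                assert m.coefficients[p] == pytest.approx(g.slopes[p], rel=1e-8)

    def test_ladder_is_row_order_invariant(self):
        table = generate_cohort(default_cohort_spec(seed=5))
        sub = table[table["group"] == "t2dm"]
        shuffled = sub.sample(frac=1.0, random_state=0)
        m1 = fit_ladder(sub, "fn_t_score", ["pentosidine", "age"])
        m2 = fit_ladder(shuffled, "fn_t_score", ["pentosidine", "age"])
        for a, b in zip(m1, m2):
            assert a.coefficients == pytest.approx(b.coefficients)
            assert a.adjusted_r_squared == pytest.approx(b.adjusted_r_squared)

    def test_saturated_rung_reported_unfittable(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.normal(size=(5, 5)),
                             columns=["femoral_strength", "a", "b", "c", "d"])
        models = fit_ladder(table, "a", ["b", "c", "d"])
        assert not models[-1].fittable
        with pytest.raises(ValueError):
            predict_strength(models[-1], {})

    def test_rank_deficient_design_flagged(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame({"femoral_strength": rng.normal(size=12),
                              "a": rng.normal(size=12)})
        table["b"] = 2 * table["a"]      # exact collinearity
        m = fit_ols(table, "femoral_strength", ("a", "b"))
        assert not m.fittable
        assert "rank-deficient" in m.note

    def test_pure_noise_predictor_does_not_improve_adjusted_r2_in_expectation(self):
        spec = default_cohort_spec(n_t2dm=20, n_control=3, noise_sd=800.0, seed=0)
        table = generate_cohort(spec)
        sub = table[table["group"] == "t2dm"].reset_index(drop=True)
        rng = np.random.default_rng(123)
        deltas = []
        base = fit_ols(sub, "femoral_strength", ("fn_t_score",))
        for _ in range(500):
            noisy = sub.copy()
            noisy["junk"] = rng.normal(size=len(sub))
            m = fit_ols(noisy, "femoral_strength", ("fn_t_score", "junk"))
            deltas.append(m.adjusted_r_squared - base.adjusted_r_squared)
        assert np.mean(deltas) < 0.01

    def test_collinearity_screen_prefers_stronger_strength_correlate(self):
        table = generate_cohort(default_cohort_spec(seed=6))
        sub = table[table["group"] == "t2dm"]
        kept = collinearity_screen(sub, "femoral_strength",
                                   ["femoral_bmd", "fn_t_score"], threshold=0.8)
        assert len(kept) == 1
        # the survivor is the better strength correlate of the pair
        survivor = kept[0]
        other = ({"femoral_bmd", "fn_t_score"} - {survivor}).pop()
        assert abs(sub[survivor].corr(sub["femoral_strength"])) >= \
            abs(sub[other].corr(sub["femoral_strength"]))


class TestPredictStrength:
    def test_published_constants_at_zero_covariates(self):
        t2dm = published_best_model("t2dm")
        control = published_best_model("control")
        zeros_t = {p: 0.0 for p in t2dm.predictors}
        zeros_c = {p: 0.0 for p in control.predictors}
        assert predict_strength(t2dm, zeros_t) == pytest.approx(29240.848)
        assert predict_strength(control, zeros_c) == pytest.approx(9584.833)

    def test_missing_covariate_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            predict_strength(published_best_model("control"), {"bmi": 24.0})

    def test_refit_model_passes_through_the_mean(self):
        table = generate_cohort(default_cohort_spec(seed=7))
        sub = table[table["group"] == "control"]
        m = fit_ols(sub, "femoral_strength", ("fn_t_score", "bmi", "p1np"))
        at_mean = predict_strength(m, {p: sub[p].mean() for p in m.predictors})
        assert at_mean == pytest.approx(sub["femoral_strength"].mean(), rel=1e-8)


def test_group_comparison_table_shape():
    table = generate_cohort(default_cohort_spec(seed=8))
    out = group_comparison(table, ["age", "hba1c", "femoral_strength"])
    assert len(out) == 3
    assert {"U", "p_value", "method"} <= set(out.columns)


def test_quartile_summary_linear_interpolation():
    med, q1, q3 = quartile_summary([1, 2, 3, 4])
    assert (med, q1, q3) == (2.5, 1.75, 3.25)
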