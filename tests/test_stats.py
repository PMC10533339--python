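"""Group tests, correlations, standardized regression, mediation."""

import numpy as np
import pandas as pd
import pytest

from fadesame import (chi_square_independence, correlate, group_compare,
                      mediation_fit, proportion_mediated, residualize,
                      simulate_mediation_cohort, standardized_regression)
from fadesame.stats import build_table1, build_table2, build_table3, \
    build_table4


class TestGroupCompare:
    def test_identical_groups_null(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = group_compare(x, x)
        assert res.t == 0 and res.cohens_d == 0

    def test_hand_computed_cohens_d(self):
        res = group_compare([1, 2, 3], [3, 4, 5])
        assert res.cohens_d == pytest.approx(-2.0)

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=10), rng.normal(1, 1, size=12)
        ab, ba = group_compare(x, y), group_compare(y, x)
        assert ab.t == pytest.approx(-ba.t)
        assert ab.cohens_d == pytest.approx(-ba.cohens_d)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            group_compare([1, 1], [1, 1])


class TestChiSquare:
    def test_independence_gives_zero(self):
        chi2, p = chi_square_independence([[10, 10], [10, 10]])
        assert chi2 == 0 and p == pytest.approx(1.0)

    def test_perfect_association_closed_form(self):
        # N (ad - bc)^2 / (r1 r2 c1 c2) = 40 * 400^2 / 20^4
        chi2, _ = chi_square_independence([[20, 0], [0, 20]])
        assert chi2 == pytest.approx(40.0)

    def test_transpose_invariance(self):
        t = [[12, 5], [7, 20]]
        assert chi_square_independence(t)[0] == pytest.approx(
            chi_square_independence(np.transpose(t))[0])

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_independence([[0, 0], [5, 7]])


class TestCorrelate:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r, p = correlate(x, 2 * x)
        assert r == pytest.approx(1.0)

    def test_point_biserial_equals_t_formula(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 2, 40).astype(float)
        y = rng.normal(size=40) + g
        r, _ = correlate(g, y, kind="point_biserial")
        res = group_compare(y[g == 1], y[g == 0])
        t, df = res.t, res.df
        assert abs(r) == pytest.approx(abs(t) / np.sqrt(t ** 2 + df))

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(2)
        r, _ = correlate(rng.normal(size=10000), rng.normal(size=10000))
        assert abs(r) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate(np.ones(5), np.arange(5.0))


class TestStandardizedRegression:
    def test_single_predictor_beta_equals_pearson_r(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        y = 0.6 * x + rng.normal(size=50)
        res = standardized_regression(y, {"x": x})
        r, _ = correlate(x, y)
        assert res.beta["x"] == pytest.approx(r)

    def test_orthogonal_predictors_keep_marginal_betas(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        rng = np.random.default_rng(4)
        y = 0.5 * x1 - 0.3 * x2 + rng.normal(size=n)
        res = standardized_regression(y, {"x1": x1, "x2": x2})
        for name, x in (("x1", x1), ("x2", x2)):
            r, _ = correlate(x, y)
            assert res.beta[name] == pytest.approx(r, abs=1e-10)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            standardized_regression(np.arange(10.0),
                                    {"x": np.arange(10.0),
                                     "z": np.zeros(10)})

    def test_collinear_design_rejected(self):
        x = np.random.default_rng(5).normal(size=30)
        with pytest.raises(ValueError, match="collinear"):
            standardized_regression(x, {"a": x, "b": 2 * x + 1e-12})


class TestResidualize:
    def test_interceptonly_is_mean_centring(self):
        y = np.array([1.0, 2.0, 6.0])
        assert np.allclose(residualize(y), y - 3.0)

    def test_orthogonal_to_covariates(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=40)
        Z = {"a": rng.normal(size=40), "b": rng.normal(size=40)}
        res = residualize(y, Z)
        assert abs(res.mean()) < 1e-10
        for v in Z.values():
            assert abs(res @ (v - v.mean())) < 1e-8

    def test_partial_correlation_identity(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=200)
        x = z + rng.normal(size=200)
        y = z + rng.normal(size=200)
        rx, ry = residualize(x, {"z": z}), residualize(y, {"z": z})
        r_res, _ = correlate(rx, ry)
        rxy, _ = correlate(x, y)
        rxz, _ = correlate(x, z)
        ryz, _ = correlate(y, z)
        partial = (rxy - rxz * ryz) / np.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))
        assert r_res == pytest.approx(partial, abs=1e-10)


class TestMediation:
    def test_additivity_exact_on_arbitrary_data(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            x, m, y = rng.normal(size=(3, 37))
            fit = mediation_fit(x, m, y)
            assert fit.c == pytest.approx(fit.c_prime + fit.indirect,
                                          abs=1e-12)

    def test_null_model_calibration(self):
        rng = np.random.default_rng(9)
        x, m, y = rng.normal(size=(3, 10000))
        fit = mediation_fit(x, m, y)
        assert abs(fit.indirect) < 0.05
        assert fit.p["indirect"] > 0.05

    def test_planted_paths_recovered(self):
        x, m, y = simulate_mediation_cohort(0.5, 0.4, 0.2, 100000, seed=10)
        fit = mediation_fit(x, m, y)
        assert fit.a == pytest.approx(0.5, abs=0.02)
        assert fit.b == pytest.approx(0.4, abs=0.02)
        assert fit.c_prime == pytest.approx(0.2, abs=0.02)
        assert fit.indirect == pytest.approx(0.2, abs=0.02)
        assert proportion_mediated(fit) == pytest.approx(50.0, abs=2.0)

    def test_recovery_unbiased_across_seeds(self):
        """Mean recovered paths over many simulated cohorts stay within
        +-0.05 of the planted values (bias check)."""
        ests = []
        for seed in range(100):
            x, m, y = simulate_mediation_cohort(0.5, 0.4, 0.2, 10000,
                                                seed=seed)
            fit = mediation_fit(x, m, y)
            ests.append((fit.a, fit.b, fit.c_prime))
        mean = np.mean(ests, axis=0)
        assert np.allclose(mean, [0.5, 0.4, 0.2], atol=0.05)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(11)
        x, m, y = rng.normal(size=(3, 200))
        f0 = mediation_fit(x, m, y)
        f1 = mediation_fit(3 * x - 7, 0.1 * m + 2, -1 * y)
        assert f1.a == pytest.approx(f0.a)
        assert abs(f1.indirect) == pytest.approx(abs(f0.indirect))

    def test_bootstrap_deterministic_given_seed(self):
        rng = np.random.default_rng(12)
        x, m, y = rng.normal(size=(3, 60))
        f1 = mediation_fit(x, m, y, method="bootstrap", n_boot=300, seed=4)
        f2 = mediation_fit(x, m, y, method="bootstrap", n_boot=300, seed=4)
        assert f1.se["indirect"] == f2.se["indirect"]
        assert f1.boot_ci == f2.boot_ci

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            mediation_fit(np.ones(20), np.arange(20.0), np.arange(20.0))

    def test_proportion_arithmetic(self):
        class Dummy:
            indirect, c = 0.2, 0.4
        assert proportion_mediated(Dummy()) == pytest.approx(50.0)
        Dummy.c = 0.0
        with pytest.raises(ValueError, match="undefined"):
            proportion_mediated(Dummy())


@pytest.fixture(scope="module")
def scored(small_cohort):
    from fadesame import score_cohort
    scores = score_cohort(small_cohort.maps, ratings=small_cohort.ratings)
    return small_cohort.subjects.merge(
        scores.drop(columns=["group"]), on="subject_id")


class TestReportTables:
    def test_table1_rows_and_tests(self, scored):
        t1 = build_table1(scored)
        assert {"a_prime", "openness", "gender"} <= set(t1["variable"])
        assert (t1.loc[t1["variable"] == "gender", "test"] == "chi2").all()
        assert t1["p"].between(0, 1).all()

    def test_table2_has_all_group_trait_pairs(self, scored):
        t2 = build_table2(scored)
        assert set(t2["group"]) == {"young", "older"}
        sub = t2[(t2["group"] == "older") & (t2["measure"] == "same_memory")]
        assert "openness" in set(sub["trait"])
        assert t2["r"].between(-1, 1).all()

    def test_table3_covariate_structure(self, scored):
        t3 = build_table3(scored)
        per_outcome = t3.groupby("outcome")["predictor"].apply(set)
        expected = {"openness", "age", "gender", "education", "mwtb"}
        assert all(s == expected for s in per_outcome)

    def test_table4_mediation_rows(self, scored):
        t4 = build_table4(scored, seed=0)
        assert set(t4["mediator"]) == {"fade_memory", "same_memory"}
        ind = t4[t4["path"] == "indirect"]
        assert ind["proportion_mediated"].notna().all()
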