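import numpy as np
import pandas as pd
import pytest

from ufib.stats import (
    bartlett_test,
    bh_fdr,
    clinical_correlation_table,
    compare_densities,
    design_matrix,
    pearson_r,
    permutation_alpha,
    residualize,
    welch_t,
)


def hand_welch(a, b):
    """Textbook Welch formulas, coded independently of the module."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va = ((a - a.mean()) ** 2).sum() / (na - 1)
    vb = ((b - b.mean()) ** 2).sum() / (nb - 1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df


def hand_bartlett(a, b):
    """Two-sample Bartlett statistic from the classical formula."""
    samples = [np.asarray(a, float), np.asarray(b, float)]
    k = 2
    ni = np.array([len(s) for s in samples])
    vi = np.array([((s - s.mean()) ** 2).sum() / (len(s) - 1) for s in samples])
    N = ni.sum()
    sp2 = ((ni - 1) * vi).sum() / (N - k)
    num = (N - k) * np.log(sp2) - ((ni - 1) * np.log(vi)).sum()
    den = 1 + (1.0 / (3 * (k - 1))) * ((1.0 / (ni - 1)).sum() - 1.0 / (N - k))
    return num / den


class TestResidualize:
    def test_exact_linear_in_age_gives_zero_residuals(self):
        cohort = pd.DataFrame(
            {"subject_id": [str(i) for i in range(10)],
             "group": ["control"] * 5 + ["patient"] * 5,
             "age": np.linspace(20, 40, 10),
             "sex": ["M", "F"] * 5}
        )
        X = design_matrix(cohort)
        y = 3.0 + 0.5 * cohort["age"].to_numpy()
        assert np.allclose(residualize(y, X), 0.0, atol=1e-10)

    def test_intercept_only_demeans(self, rng):
        y = rng.normal(size=12)
        X = pd.DataFrame({"intercept": np.ones(12)})
        assert np.allclose(residualize(y, X), y - y.mean(), atol=1e-12)

    def test_matches_pseudoinverse_oracle(self, rng):
        X = pd.DataFrame(
            {"intercept": np.ones(30), "age": rng.uniform(18, 60, 30),
             "sex": rng.integers(0, 2, 30).astype(float)}
        )
        y = rng.normal(size=30)
        M = X.to_numpy()
        expected = y - M @ (np.linalg.pinv(M) @ y)
        assert np.allclose(residualize(y, X), expected, atol=1e-9)

    def test_rank_deficiency_names_column(self):
        X = pd.DataFrame({"intercept": np.ones(10), "age": np.arange(10.0),
                          "age2": 2 * np.arange(10.0)})
        with pytest.raises(ValueError, match="age"):
            residualize(np.arange(10.0), X)

    def test_residuals_orthogonal_to_design(self, rng):
        X = pd.DataFrame({"intercept": np.ones(25), "age": rng.uniform(18, 60, 25),
                          "sex": rng.integers(0, 2, 25).astype(float)})
        r = residualize(rng.normal(size=25), X)
        assert np.allclose(X.to_numpy().T @ r, 0.0, atol=1e-8)


class TestWelch:
    def test_worked_example(self):
        res = welch_t([1, 2, 3], [2, 4, 6])
        assert res.statistic == pytest.approx(-1.549, abs=1e-3)
        assert res.df == pytest.approx(2.941, abs=1e-3)

    def test_identical_samples(self):
        res = welch_t([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_formula_on_random_inputs(self, rng):
        for _ in range(100):
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(3, 40))
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(3, 40))
            t, df = hand_welch(a, b)
            res = welch_t(a, b)
            assert res.statistic == pytest.approx(t, abs=1e-9)
            assert res.df == pytest.approx(df, abs=1e-9)

    def test_equal_variance_large_n_converges_to_pooled_t(self, rng):
        a = rng.normal(0.0, 1.0, 500)
        b = rng.normal(0.2, 1.0, 500)
        na, nb = len(a), len(b)
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
        pooled_t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert welch_t(a, b).statistic == pytest.approx(pooled_t, abs=1e-3)

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [2.0, 3.0])


class TestBartlett:
    def test_identical_samples_statistic_zero(self):
        res = bartlett_test([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_formula(self, rng):
        for _ in range(50):
            a = rng.normal(0, rng.uniform(0.5, 2), rng.integers(5, 40))
            b = rng.normal(0, rng.uniform(0.5, 2), rng.integers(5, 40))
            assert bartlett_test(a, b).statistic == pytest.approx(hand_bartlett(a, b), abs=1e-9)

    def test_null_rejection_rate_near_nominal(self):
        # equal-variance normals: rejection rate at alpha=0.05 should be ~5%
        rng = np.random.default_rng(7)
        reps = 4000
        rejections = 0
        for _ in range(reps):
            a = rng.normal(0, 1, 50)
            b = rng.normal(0, 1, 50)
            rejections += bartlett_test(a, b).p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.01)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            bartlett_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBH:
    def test_step_up_worked_example(self):
        # thresholds (rank/4)*0.05 = 0.0125/0.025/0.0375/0.05 -> all rejected
        p_adj, reject = bh_fdr([0.005, 0.01, 0.03, 0.04], q=0.05)
        assert reject.all()

    def test_single_p_unchanged(self):
        p_adj, _ = bh_fdr([0.123])
        assert p_adj[0] == pytest.approx(0.123)

    def test_all_ones_nothing_rejected(self):
        p_adj, reject = bh_fdr([1.0] * 6)
        assert not reject.any() and np.allclose(p_adj, 1.0)

    def test_adjusted_at_least_raw_and_monotone(self, rng):
        p = rng.uniform(size=40)
        p_adj, _ = bh_fdr(p)
        assert np.all(p_adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(p_adj[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestPearson:
    def test_perfect_correlations(self):
        assert pearson_r([1, 2, 3], [2, 4, 6]).statistic == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [6, 4, 2]).statistic == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        # cov = 0.5, sd_x = 1, sd_y = 1 -> r = 0.5
        assert pearson_r([1, 2, 3], [1, 3, 2]).statistic == pytest.approx(0.5, abs=1e-12)

    def test_p_via_t_transform_oracle(self, rng):
        from scipy.stats import t as tdist

        x = rng.normal(size=25)
        y = 0.4 * x + rng.normal(size=25)
        res = pearson_r(x, y)
        r = res.statistic
        t = r * np.sqrt(23 / (1 - r**2))
        assert res.p == pytest.approx(2 * tdist.sf(abs(t), 23), abs=1e-9)

    def test_pairwise_complete(self):
        x = [1.0, 2, 3, np.nan, 5]
        y = [2.0, 4, 6, 8, np.nan]
        assert pearson_r(x, y).statistic == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson_r([1, 2], [3, 4])


class TestPermutationAlpha:
    def test_single_test_threshold_near_alpha(self, rng):
        y = rng.normal(size=(40, 1))
        groups = np.array(["control"] * 20 + ["patient"] * 20)
        res = permutation_alpha(y, groups, n_perm=2000, alpha=0.05, seed=1)
        assert res.alpha_adjusted == pytest.approx(0.05, abs=0.02)

    def test_duplicated_tests_do_not_overcorrect(self, rng):
        # m perfectly correlated tests: threshold stays near the single-test
        # alpha, well above the Bonferroni bound alpha/m
        col = rng.normal(size=(40, 1))
        y = np.tile(col, (1, 10))
        groups = np.array(["control"] * 20 + ["patient"] * 20)
        res = permutation_alpha(y, groups, n_perm=2000, alpha=0.05, seed=2)
        assert res.alpha_adjusted > 0.05 / 10
        assert res.alpha_adjusted == pytest.approx(0.05, abs=0.02)

    def test_threshold_between_bonferroni_and_alpha(self, rng):
        y = rng.normal(size=(30, 25))
        groups = np.array(["control"] * 15 + ["patient"] * 15)
        res = permutation_alpha(y, groups, n_perm=1000, alpha=0.05, seed=3)
        assert 0.05 / 25 <= res.alpha_adjusted <= 0.05

    def test_seed_reproducibility(self, rng):
        y = rng.normal(size=(24, 8))
        groups = np.array(["control"] * 12 + ["patient"] * 12)
        a = permutation_alpha(y, groups, n_perm=500, seed=9)
        b = permutation_alpha(y, groups, n_perm=500, seed=9)
        assert np.array_equal(a.null_min_p, b.null_min_p)
        assert a.alpha_adjusted == b.alpha_adjusted

    def test_tiny_groups_enumerated_exactly(self, rng):
        y = rng.normal(size=(8, 3))
        groups = np.array(["control"] * 4 + ["patient"] * 4)
        res = permutation_alpha(y, groups, n_perm=1000, seed=0)
        assert res.exhaustive and res.n_perm == 70  # C(8,4)


class TestDensityComparison:
    def _cohort(self, n_per_group):
        n = 2 * n_per_group
        return pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(n)],
             "group": ["control"] * n_per_group + ["patient"] * n_per_group,
             "age": np.tile(np.linspace(20, 40, n_per_group), 2),
             "sex": ["M", "F"] * n_per_group}
        )

    def test_identical_groups_give_p_one(self):
        cohort = self._cohort(6)
        vals = [4.0, 9, 6, 11, 7, 5]
        dens = pd.DataFrame({1: vals + vals}, index=cohort["subject_id"])
        table, total = compare_densities(dens, cohort)
        assert table.loc[0, "p"] == pytest.approx(1.0, abs=1e-9)
        assert not table["reject"].any()
        assert total.p == pytest.approx(1.0, abs=1e-9)

    def test_large_shift_detected_after_bh(self, rng):
        cohort = self._cohort(30)
        base = rng.normal(50, 3, size=(60, 4))
        dens = pd.DataFrame(base, index=cohort["subject_id"], columns=[1, 2, 3, 4])
        dens.loc[cohort["group"].to_numpy() == "patient", 1] += 9  # 3 SD shift
        table, _ = compare_densities(dens, cohort)
        assert bool(table.set_index("tract_id").loc[1, "reject"])
        assert table.set_index("tract_id").loc[1, "t"] < 0  # control - patient < 0

    def test_total_is_sum_of_tracts(self, rng):
        cohort = self._cohort(5)
        dens = pd.DataFrame(rng.integers(5, 30, size=(10, 3)).astype(float),
                            index=cohort["subject_id"], columns=[1, 2, 3])
        assert np.array_equal(dens.sum(axis=1).to_numpy(),
                              dens[[1, 2, 3]].to_numpy().sum(axis=1))


class TestClinicalCorrelations:
    def _inputs(self, rng, n_pat=20):
        cohort = pd.DataFrame(
            {"subject_id": [f"p{i}" for i in range(n_pat)],
             "group": ["patient"] * n_pat,
             "age": rng.uniform(18, 35, n_pat),
             "sex": rng.choice(["M", "F"], n_pat),
             "panss8_total": rng.normal(20, 5, n_pat),
             "sofas": rng.normal(55, 10, n_pat)}
        )
        seg = pd.DataFrame(
            {"subject": cohort["subject_id"], "tract_id": 1, "metric": "FA",
             "value": rng.normal(0.4, 0.02, n_pat)}
        )
        return cohort, seg

    def test_exact_linear_variable_gives_r_one(self, rng):
        cohort, seg = self._inputs(rng)
        cohort["panss8_total"] = 2.0 * seg["value"].to_numpy() + 1.0
        table = clinical_correlation_table(seg, cohort, variables=("panss8_total",))
        assert table.loc[0, "r"] == pytest.approx(1.0)

    def test_table_shape_is_cells_times_variables(self, rng):
        cohort, seg = self._inputs(rng)
        seg2 = seg.copy()
        seg2["metric"] = "RD"
        both = pd.concat([seg, seg2], ignore_index=True)
        table = clinical_correlation_table(both, cohort, variables=("panss8_total", "sofas"))
        assert len(table) == 2 * 2  # (tract, metric) cells x variables

    def test_independent_variable_rarely_rejected(self, rng):
        # null calibration: independent score, BH at q=0.05 over 40 replicates
        n_rej = 0
        for rep in range(40):
            cohort, seg = self._inputs(np.random.default_rng(100 + rep))
            table = clinical_correlation_table(seg, cohort, variables=("panss8_total", "sofas"))
            n_rej += (table["p_adjusted"] < 0.05).any()
        assert n_rej <= 6  # ~5% expected; generous binomial slack
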