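import numpy as np
import pandas as pd
import pytest
from scipy import stats

from specdcm.peb import DesignMatrix, build_design
from specdcm.validate import cohort_stats, cva, loo_crossval


def _loo_cohort(rng, n_per_group=20, effect=0.35, k=5, between=0.1, post=0.03):
    n = 2 * n_per_group
    x = np.array([0] * n_per_group + [1] * n_per_group)
    beta_v = effect * np.array([1, -1, 1, 1, -1])[:k]
    mus = between * rng.standard_normal((n, k)) + x[:, None] * beta_v
    covs = [post**2 * np.eye(k)] * n
    df = pd.DataFrame({"id": range(n), "group": x,
                       "age": rng.normal(65, 8, n),
                       "sex": rng.integers(0, 2, n)})
    return list(zip(mus, covs)), build_design(df)


class TestLooCrossval:
    def test_null_effect_gives_near_zero_correlation(self):
        """Without a group effect the predictions carry no signal.

        Leave-one-out predictions share training folds, so the null
        distribution of r is overdispersed relative to 1/sqrt(n) and
        slightly negative (the usual cross-validated-correlation
        artifact); the frozen bounds come from this null simulation.
        """
        rs = []
        for seed in range(10):
            rng = np.random.default_rng(400 + seed)
            posts, design = _loo_cohort(rng, n_per_group=45, effect=0.0)
            rs.append(loo_crossval(posts, design, np.arange(5)).r_pb)
        rs = np.asarray(rs)
        assert np.all(np.abs(rs) < 0.55)
        assert np.sum(np.abs(rs) < 0.25) >= 6
        assert -0.25 < rs.mean() < 0.1

    def test_group_effect_is_predictive(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(500 + seed)
            posts, design = _loo_cohort(rng, effect=0.35)
            res = loo_crossval(posts, design, np.arange(5))
            hits += (res.r_pb > 0) and (res.p_value < 0.05)
        assert hits >= 8

    def test_credible_interval_bookkeeping(self):
        rng = np.random.default_rng(0)
        posts, design = _loo_cohort(rng)
        res = loo_crossval(posts, design, np.arange(5))
        assert 0 <= res.n_within_interval <= design.n_subjects
        assert np.all(res.ci_low <= res.ci_high)
        assert abs(res.r_pb) <= 1.0

    @pytest.mark.parametrize("k", [1, 3])
    def test_connection_count_variants_share_contract(self, k):
        rng = np.random.default_rng(1)
        posts, design = _loo_cohort(rng, k=5)
        res = loo_crossval(posts, design, np.arange(k))
        assert res.predicted.shape == (design.n_subjects,)
        assert np.isfinite(res.p_value)

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(2)
        posts, design = _loo_cohort(rng, n_per_group=8)
        res1 = loo_crossval(posts, design, np.arange(5))
        perm = rng.permutation(design.n_subjects)
        d2 = DesignMatrix(design.X[perm], list(design.names), design.centred)
        res2 = loo_crossval([posts[i] for i in perm], d2, np.arange(5))
        assert res1.r_pb == pytest.approx(res2.r_pb, abs=1e-10)
        assert res1.n_within_interval == res2.n_within_interval

    def test_unknown_connection_rejected(self):
        rng = np.random.default_rng(3)
        posts, design = _loo_cohort(rng, n_per_group=4)
        with pytest.raises(IndexError):
            loo_crossval(posts, design, np.array([99]))

    def test_empty_subset_rejected(self):
        rng = np.random.default_rng(4)
        posts, design = _loo_cohort(rng, n_per_group=4)
        with pytest.raises(ValueError):
            loo_crossval(posts, design, np.array([], dtype=int))


class TestCva:
    def test_exact_linear_association(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((15, 5))
        w = np.array([0.5, -1.0, 0.2, 0.8, -0.3])
        severity = X @ w  # noiseless linear readout
        res = cva(X, severity)
        assert res.correlations[0] == pytest.approx(1.0, abs=1e-8)
        assert res.r == pytest.approx(1.0, abs=1e-8)

    def test_single_connection_equals_partial_correlation(self):
        rng = np.random.default_rng(1)
        n = 30
        age = rng.normal(65, 8, n)
        sex = rng.integers(0, 2, n).astype(float)
        x = 0.4 * age / 10 + rng.standard_normal(n)
        y = -0.8 * x + 0.3 * sex + rng.standard_normal(n)
        conf = np.column_stack([age, sex])
        res = cva(x[:, None], y, conf)
        Z = np.column_stack([np.ones(n), conf])
        rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        partial = np.corrcoef(rx, ry)[0, 1]
        assert res.correlations[0] == pytest.approx(abs(partial), abs=1e-10)

    def test_matches_sklearn_cca_scores(self):
        from sklearn.cross_decomposition import CCA

        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 4))
        Y = X @ rng.standard_normal((4, 2)) + 0.5 * rng.standard_normal((40, 2))
        res = cva(X, Y)
        cc = CCA(n_components=1).fit(X - X.mean(0), Y - Y.mean(0))
        u, v = cc.transform(X - X.mean(0), Y - Y.mean(0))
        r_sklearn = abs(np.corrcoef(u[:, 0], v[:, 0])[0, 1])
        assert res.correlations[0] == pytest.approx(r_sklearn, abs=1e-4)

    def test_permuted_severity_p_values_are_uniform(self):
        rng = np.random.default_rng(3)
        n = 15
        X = rng.standard_normal((n, 5))
        severity = rng.standard_normal(n)
        conf = np.column_stack([rng.normal(65, 8, n), rng.integers(0, 2, n)])
        ps = []
        for _ in range(100):
            ps.append(cva(X, rng.permutation(severity), conf).p_value)
        ps = np.asarray(ps)
        # binomial tolerance at 100 permutations (3 sigma ~ 0.15)
        assert abs(np.mean(ps < 0.5) - 0.5) < 0.16
        assert abs(np.mean(ps < 0.2) - 0.2) < 0.13

    def test_confound_reparameterization_invariance(self):
        rng = np.random.default_rng(4)
        n = 25
        X = rng.standard_normal((n, 3))
        y = rng.standard_normal(n)
        conf = rng.standard_normal((n, 2))
        A = np.array([[2.0, 0.3], [-0.5, 1.2]])  # invertible reparameterization
        res1 = cva(X, y, conf)
        res2 = cva(X, y, conf @ A + 7.0)
        assert np.allclose(res1.correlations, res2.correlations, atol=1e-8)

    def test_rank_deficient_block_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            cva(np.zeros((10, 2)), np.arange(10.0))

    def test_more_params_than_subjects_rejected(self):
        with pytest.raises(ValueError):
            cva(np.zeros((4, 5)), np.arange(4.0))


class TestCohortStats:
    def test_pooled_t_from_printed_summaries(self):
        out = cohort_stats([{"variable": "smell", "test": "t",
                             "mean1": 7.92, "sd1": 3.16, "n1": 75,
                             "mean2": 6.40, "sd2": 3.29, "n2": 15}])
        assert round(float(out["statistic"][0]), 2) == 1.69

    def test_chi_square_from_count_table(self):
        out = cohort_stats([{"variable": "motor", "test": "chi2",
                             "table": [[29, 42, 4], [7, 8, 0]]}])
        assert round(float(out["statistic"][0]), 2) == 1.02

    def test_identical_groups_give_zero(self):
        out = cohort_stats([
            {"test": "t", "mean1": 5.0, "sd1": 1.0, "n1": 20,
             "mean2": 5.0, "sd2": 1.0, "n2": 20},
            {"test": "chi2", "table": [[10, 10], [10, 10]]},
        ])
        assert np.allclose(out["statistic"], 0.0)

    def test_pooled_t_matches_raw_data_oracle(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 2.0, 40)
        b = rng.normal(0.4, 2.0, 25)
        out = cohort_stats([{"test": "t",
                             "mean1": a.mean(), "sd1": a.std(ddof=1), "n1": 40,
                             "mean2": b.mean(), "sd2": b.std(ddof=1), "n2": 25}])
        t_raw, p_raw = stats.ttest_ind(a, b, equal_var=True)
        assert float(out["statistic"][0]) == pytest.approx(t_raw, abs=1e-10)
        assert float(out["p_value"][0]) == pytest.approx(p_raw, abs=1e-10)

    def test_fisher_and_mannwhitney(self):
        rng = np.random.default_rng(1)
        out = cohort_stats([
            {"test": "fisher", "table": [[31, 44], [11, 4]]},
            {"test": "mannwhitney", "x": rng.normal(0, 1, 30).tolist(),
             "y": rng.normal(0.5, 1, 20).tolist()},
        ])
        orr = stats.contingency.odds_ratio(np.array([[31, 44], [11, 4]]))
        assert float(out["statistic"][0]) == pytest.approx(orr.statistic)
        assert np.isfinite(out["p_value"]).all()

    def test_malformed_table_rejected(self):
        with pytest.raises(ValueError):
            cohort_stats([{"test": "fisher", "table": [[1, 2, 3], [4, 5, 6]]}])
        with pytest.raises(ValueError):
            cohort_stats([{"test": "nope"}])
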