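import numpy as np
import pandas as pd
import pytest

from specdcm.peb import PEB, DesignMatrix, build_design, fit_peb


def _cov_table(n, n_vh, rng):
    group = np.array([0] * (n - n_vh) + [1] * n_vh)
    return pd.DataFrame({
        "id": [f"s{i}" for i in range(n)],
        "group": group,
        "age": rng.normal(65, 8, n).round(1),
        "sex": rng.integers(0, 2, n),
    })


class TestBuildDesign:
    def test_age_centring(self):
        df = pd.DataFrame({"id": ["a", "b"], "group": [0, 1],
                           "age": [60.0, 70.0], "sex": [0, 1]})
        d = build_design(df)
        assert np.allclose(d.column("age"), [-5.0, 5.0])
        assert np.allclose(d.column("mean"), 1.0)
        assert np.allclose(d.column("VH"), [0.0, 1.0])

    def test_single_group_drops_vh_with_warning(self):
        df = pd.DataFrame({"id": list("abc"), "group": [0, 0, 0],
                           "age": [60, 61, 62], "sex": [0, 1, 0]})
        with pytest.warns(UserWarning):
            d = build_design(df)
        assert "VH" not in d.names

    def test_cohort_sized_design(self):
        rng = np.random.default_rng(0)
        d = build_design(_cov_table(90, 15, rng))
        assert d.X.shape == (90, 4)
        assert d.column("VH").sum() == 15
        assert d.column("sex").sum() == pytest.approx(0.0, abs=1e-10)

    def test_missing_values_rejected(self):
        df = pd.DataFrame({"id": ["a", "b"], "group": [0, 1],
                           "age": [60.0, np.nan], "sex": [0, 1]})
        with pytest.raises(ValueError):
            build_design(df)


class TestFitPeb:
    def test_matches_conjugate_oracle_with_fixed_precision(self):
        """With equal known subject covariances and a fixed between-subject
        precision the second level is exactly Bayesian linear regression."""
        rng = np.random.default_rng(0)
        n, p, gamma, vb = 12, 3, 4.0, 1.0 / 16.0
        df = _cov_table(n, 5, rng)
        design = build_design(df)
        X = design.X
        Sigma = 0.02 * np.eye(p)
        mus = rng.standard_normal((n, p))
        model = fit_peb(list(zip(mus, [Sigma] * n)), design,
                        between_precision=gamma, prior_var_beta=vb)

        V = Sigma + np.eye(p) / gamma
        Xk = np.kron(X, np.eye(p))
        W = np.kron(np.eye(n), np.linalg.inv(V))
        y = mus.ravel()
        prec = Xk.T @ W @ Xk + np.eye(Xk.shape[1]) / vb
        mean = np.linalg.solve(prec, Xk.T @ W @ y)
        assert np.allclose(model.beta_vector(), mean, atol=1e-6)
        assert np.allclose(model.beta_cov, np.linalg.inv(prec), atol=1e-6)

    def test_shrinkage_toward_subject_mean_with_n(self):
        rng = np.random.default_rng(1)
        p = 2
        target = np.array([0.3, -0.2])
        Sigma = 0.05 * np.eye(p)
        means = {}
        for n in (4, 40):
            mus = [target.copy() for _ in range(n)]
            design = DesignMatrix(np.ones((n, 1)), ["mean"])
            model = fit_peb(list(zip(mus, [Sigma] * n)), design)
            means[n] = model.beta[0]
            # shrunk between the group prior mean (0) and the subject mean
            assert np.all(np.abs(model.beta[0]) <= np.abs(target) + 1e-9)
            assert np.all(model.beta[0] * target >= 0)
        assert np.all(np.abs(means[40] - target) < np.abs(means[4] - target))

    def test_vh_effect_credible_interval_coverage(self, layout, spec):
        """A +0.35 Hz group effect on lPFC->V1 is detected (90% credible
        interval excluding zero) in at least 80% of 20 seeded replicates
        at n=20 per group."""
        from tests.conftest import make_synthetic_posteriors

        k = layout.connection_param_index(spec.region_index("lPFC"),
                                          spec.region_index("V1"))
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            posts, x, _ = make_synthetic_posteriors(
                layout, spec, rng, n_per_group=20,
                effects={("lPFC", "V1"): 0.35})
            df = pd.DataFrame({"id": range(40), "group": x,
                               "age": rng.normal(65, 8, 40),
                               "sex": rng.integers(0, 2, 40)})
            design = build_design(df)
            model = fit_peb(posts, design)
            i = design.names.index("VH") * 64 + k
            sd = np.sqrt(model.beta_cov[i, i])
            lo = model.beta_vector()[i] - 1.6449 * sd
            hits += lo > 0
        assert hits >= 16

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        n, p = 10, 3
        df = _cov_table(n, 4, rng)
        design = build_design(df)
        mus = rng.standard_normal((n, p))
        covs = [0.03 * np.eye(p) + 0.01 * np.ones((p, p)) for _ in range(n)]
        m1 = fit_peb(list(zip(mus, covs)), design)
        perm = rng.permutation(n)
        d2 = DesignMatrix(design.X[perm], list(design.names), design.centred)
        m2 = fit_peb([(mus[i], covs[i]) for i in perm], d2)
        assert np.allclose(m1.beta, m2.beta, atol=1e-8)
        assert m1.between_subject_precision == pytest.approx(
            m2.between_subject_precision, rel=1e-6)

    def test_design_without_vh_has_no_vh_betas(self):
        rng = np.random.default_rng(3)
        n, p = 8, 2
        df = _cov_table(n, 3, rng)
        design = build_design(df).drop("VH")
        mus = rng.standard_normal((n, p))
        model = fit_peb(list(zip(mus, [0.05 * np.eye(p)] * n)), design)
        assert model.beta.shape == (3, p)
        assert "VH" not in model.design.names

    def test_dimension_mismatch_raises(self):
        design = DesignMatrix(np.ones((2, 1)), ["mean"])
        with pytest.raises(ValueError):
            fit_peb([(np.zeros(3), np.eye(3)), (np.zeros(2), np.eye(2))], design)

    def test_singular_design_raises(self):
        X = np.ones((4, 2))
        design = DesignMatrix(X, ["mean", "dup"])
        mus = np.zeros((4, 2))
        with pytest.raises(np.linalg.LinAlgError):
            fit_peb(list(zip(mus, [np.eye(2)] * 4)), design)
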