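import itertools

import numpy as np
import pandas as pd
import pytest

from specdcm.modelspace import (JointPosterior, ModelSpace, _factor3_families,
                                bayesian_model_reduction, bma,
                                build_model_space, family_posterior,
                                greedy_search, joint_bmc)
from specdcm.peb import PEB, build_design
from tests.conftest import make_synthetic_posteriors


@pytest.fixture(scope="module")
def space(spec):
    return build_model_space(spec)


def _fit_synthetic_peb(layout, spec, seed, effects=None, n_per_group=20):
    rng = np.random.default_rng(seed)
    posts, x, _ = make_synthetic_posteriors(layout, spec, rng,
                                            n_per_group=n_per_group,
                                            effects=effects)
    df = pd.DataFrame({"id": range(len(x)), "group": x,
                       "age": rng.normal(65, 8, len(x)),
                       "sex": rng.integers(0, 2, len(x))})
    return PEB().fit(posts, build_design(df)).model_


class TestBayesianModelReduction:
    def test_identity_reduction(self):
        rng = np.random.default_rng(0)
        d = 4
        A = rng.standard_normal((d, d))
        C = A @ A.T + d * np.eye(d)
        m = rng.standard_normal(d)
        C0 = np.eye(d)
        mr, Cr, dF = bayesian_model_reduction(m, C, np.zeros(d), C0,
                                              np.zeros(d), C0.copy())
        assert dF == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(mr, m)
        assert np.allclose(Cr, C)

    def test_matches_direct_conjugate_inversion(self):
        """On a linear-Gaussian model, reducing the prior analytically must
        agree with re-inverting the data under the reduced prior."""
        rng = np.random.default_rng(1)
        d, n = 3, 40
        X = rng.standard_normal((n, d))
        theta_true = np.array([0.8, 0.0, -0.5])
        sigma2 = 0.5
        y = X @ theta_true + np.sqrt(sigma2) * rng.standard_normal(n)

        def invert(prior_cov):
            prec = X.T @ X / sigma2 + np.linalg.inv(prior_cov)
            cov = np.linalg.inv(prec)
            mean = cov @ (X.T @ y / sigma2)
            # exact log evidence of the Gaussian model
            M = X @ prior_cov @ X.T + sigma2 * np.eye(n)
            sign, ld = np.linalg.slogdet(M)
            ev = -0.5 * (n * np.log(2 * np.pi) + ld + y @ np.linalg.solve(M, y))
            return mean, cov, ev

        C0 = np.eye(d)
        m_full, C_full, ev_full = invert(C0)
        C0r = C0.copy()
        C0r[1, 1] = 1e-8  # switch the second parameter off
        m_dir, C_dir, ev_dir = invert(C0r)

        mr, Cr, dF = bayesian_model_reduction(m_full, C_full, np.zeros(d), C0,
                                              np.zeros(d), C0r)
        assert np.allclose(mr, m_dir, atol=1e-8)
        assert np.allclose(Cr, C_dir, atol=1e-8)
        assert dF == pytest.approx(ev_dir - ev_full, abs=1e-8)

    def test_pruning_redundant_parameter_raises_evidence(self):
        # posterior informed (variance reduced) but centred at the prior
        # mean: clamping trades no accuracy for less complexity
        C0 = np.eye(2)
        C = np.diag([0.3, 0.9])
        m = np.array([0.0, 0.0])
        C0r = np.diag([1e-8, 1.0])
        _, _, dF = bayesian_model_reduction(m, C, np.zeros(2), C0,
                                            np.zeros(2), C0r)
        assert dF > 0

    def test_non_psd_input_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            bayesian_model_reduction(np.zeros(2), -np.eye(2), np.zeros(2),
                                     np.eye(2), np.zeros(2), np.eye(2))


class TestBuildModelSpace:
    def test_factor3_has_29_families(self, spec):
        assert len(_factor3_families(spec)) == 29

    def test_midline_complement_subsets_collapse(self, spec):
        """The full set and the two subsets lacking only a midline group
        map to the same edge set: 31 nonempty subsets yield 29 families."""
        ext = spec.extrinsic_indices

        def edges(groups):
            out = set()
            for idx in ext:
                s, d = spec.pair_of(int(idx))
                if {spec.regions[s].group, spec.regions[d].group} & groups:
                    out.add(int(idx))
            return frozenset(out)

        all5 = {"LGN", "medThal", "V1", "HC", "PFC"}
        assert edges(all5) == edges(all5 - {"V1"}) == edges(all5 - {"medThal"})
        distinct = {edges(set(c)) for r in range(1, 6)
                    for c in itertools.combinations(sorted(all5), r)}
        assert len(distinct) == 29

    def test_space_size_and_uniqueness(self, space):
        assert space.n_models == 179
        assert len({m.tobytes() for m in space.masks}) == 179

    def test_null_model(self, space):
        null = space.masks[space.null_index]
        assert not null.any()
        assert space.labels[space.null_index] is None

    def test_intrinsic_on_outside_null(self, space, spec):
        intr = spec.intrinsic_indices
        for i, mask in enumerate(space.masks):
            if i == space.null_index:
                continue
            assert mask[intr].all()

    def test_deterministic_construction(self, spec):
        s1 = build_model_space(spec)
        s2 = build_model_space(spec)
        assert np.array_equal(s1.masks, s2.masks)
        assert s1.labels == s2.labels

    def test_serialization(self, space):
        text = space.to_json()
        assert text.count("1") > 0 and "factor1" in text


class TestJointBmc:
    def test_two_model_softmax(self, layout, spec):
        peb = _fit_synthetic_peb(layout, spec, 0, n_per_group=6)
        full = np.ones(64, dtype=bool)
        reduced = full.copy()
        reduced[spec.extrinsic_indices[:20]] = False
        toy = ModelSpace(np.array([full, reduced, np.zeros(64, dtype=bool)]),
                         [{"factor1": "both", "factor2": "both", "factor3": "all"},
                          {"factor1": "both", "factor2": "both", "factor3": "some"},
                          None], spec)
        joint = joint_bmc(peb, toy)
        logp = joint.log_evidence - joint.log_evidence.max()
        expected = np.exp(logp) / np.exp(logp).sum()
        assert np.allclose(joint.prob, expected, atol=1e-12)

    def test_normalization_and_positivity(self, layout, spec, space):
        peb = _fit_synthetic_peb(layout, spec, 1, n_per_group=6)
        joint = joint_bmc(peb, space)
        assert joint.prob.sum() == pytest.approx(1.0, abs=1e-10)
        assert joint.prob.min() >= 0.0
        assert joint.prob.shape == (179, 179)

    def test_recovers_generating_family(self, layout, spec, space):
        """The generating effects sit on intrahemispheric edges to and
        from LGN and PFC (the only two-group family covering all of
        them); the differences posterior should concentrate on the intra
        and LGN+PFC families in a majority of seeds."""
        wins_f2 = 0
        wins_f3 = 0
        seeds = range(10)
        for seed in seeds:
            peb = _fit_synthetic_peb(layout, spec, 200 + seed)  # default map
            joint = joint_bmc(peb, space)
            f2 = family_posterior(joint, space, 2)
            f3 = family_posterior(joint, space, 3)
            wins_f2 += f2.sum(axis=0).idxmax() == "intra"
            wins_f3 += f3.sum(axis=0).idxmax() == "LGN+PFC"
        assert wins_f2 > len(seeds) / 2
        assert wins_f3 > len(seeds) / 2


class TestFamilyPosterior:
    def test_uniform_joint_gives_uniform_families(self, space):
        M = space.n_models
        joint = JointPosterior(np.full((M, M), 1.0 / M**2), np.zeros((M, M)))
        for factor in (1, 2, 3):
            table = family_posterior(joint, space, factor)
            assert float(table.values.sum()) == pytest.approx(1.0)
            assert np.allclose(table.values, table.values.flat[0], atol=1e-12)

    def test_toy_pooling_matches_enumeration(self, spec):
        masks = np.zeros((4, 64), dtype=bool)
        masks[0, spec.extrinsic_indices] = True
        masks[1, spec.extrinsic_indices[:30]] = True
        masks[2, spec.extrinsic_indices[30:]] = True
        for m in masks[:3]:
            m[spec.intrinsic_indices] = True
        labels = [{"factor1": "a", "factor2": "x", "factor3": "r"},
                  {"factor1": "a", "factor2": "x", "factor3": "r"},
                  {"factor1": "b", "factor2": "x", "factor3": "r"},
                  None]
        toy = ModelSpace(masks, labels, spec)
        F = np.log(np.array([[8, 4, 2, 1], [4, 2, 1, 1],
                             [2, 1, 1, 1], [1, 1, 1, 1]], dtype=float))
        p = np.exp(F) / np.exp(F).sum()
        joint = JointPosterior(p, F)
        table = family_posterior(joint, toy, 1)
        # brute-force pooling with equal family priors (a: 2 models, b: 1, null: 1)
        sizes = np.array([2.0, 2.0, 1.0, 1.0])
        w = p / np.outer(sizes, sizes)
        w /= w.sum()
        fam = np.array([0, 0, 1, 2])
        expected = np.zeros((3, 3))
        for i in range(4):
            for j in range(4):
                expected[fam[i], fam[j]] += w[i, j]
        assert np.allclose(table.values, expected, atol=1e-12)

    def test_invalid_factor_rejected(self, space):
        M = space.n_models
        joint = JointPosterior(np.full((M, M), 1.0 / M**2), np.zeros((M, M)))
        with pytest.raises(ValueError):
            family_posterior(joint, space, 4)


class TestBma:
    def test_single_model_space_returns_peb_betas(self, layout, spec):
        peb = _fit_synthetic_peb(layout, spec, 2, n_per_group=6)
        full = np.ones(64, dtype=bool)
        solo = ModelSpace(full[None, :],
                          [{"factor1": "both", "factor2": "both", "factor3": "all"}],
                          spec)
        joint = JointPosterior(np.array([[1.0]]), np.zeros((1, 1)))
        avg = bma(joint, solo, peb, threshold=0.51)
        assert np.allclose(avg.means, peb.beta, atol=1e-12)
        assert np.all(avg.presence[peb.design.names.index("mean")] == 1.0)

    def test_weighted_two_model_average(self, layout, spec):
        peb = _fit_synthetic_peb(layout, spec, 3, n_per_group=6)
        # make one VH beta visibly nonzero and nearly decoupled
        peb.beta[peb.design.names.index("VH")][0] = 1.0
        peb.beta_cov = np.eye(peb.beta.size) * 1e-4
        full = np.ones(64, dtype=bool)
        reduced = full.copy()
        reduced[spec.extrinsic_indices[0]] = False
        toy = ModelSpace(np.array([full, reduced]),
                         [{"factor1": "both", "factor2": "both", "factor3": "all"},
                          {"factor1": "both", "factor2": "both", "factor3": "some"}],
                         spec)
        prob = np.array([[0.8, 0.0], [0.0, 0.2]])
        joint = JointPosterior(prob, np.log(prob + 1e-300))
        avg = bma(joint, toy, peb, threshold=0.95)
        vh = peb.design.names.index("VH")
        assert avg.means[vh][0] == pytest.approx(0.8, abs=1e-3)
        assert avg.presence[vh][0] == pytest.approx(0.8)
        assert avg.thresholded[vh][0] == 0.0  # suppressed below 95%

    def test_default_threshold_is_95_percent(self, layout, spec):
        peb = _fit_synthetic_peb(layout, spec, 4, n_per_group=6)
        full = np.ones(64, dtype=bool)
        solo = ModelSpace(full[None, :],
                          [{"factor1": "both", "factor2": "both", "factor3": "all"}],
                          spec)
        joint = JointPosterior(np.array([[1.0]]), np.zeros((1, 1)))
        assert bma(joint, solo, peb).threshold == 0.95

    def test_invalid_threshold_rejected(self, layout, spec, space):
        peb = _fit_synthetic_peb(layout, spec, 5, n_per_group=6)
        joint = JointPosterior(np.full((179, 179), 1.0 / 179**2),
                               np.zeros((179, 179)))
        with pytest.raises(ValueError):
            bma(joint, space, peb, threshold=0.4)


class TestGreedySearch:
    def test_final_iteration_has_256_models(self, layout, spec):
        peb = _fit_synthetic_peb(layout, spec, 6, n_per_group=10)
        res = greedy_search(peb)
        assert res.n_models == 256

    def test_uninformative_posterior_prunes_everything(self, layout, spec):
        peb = _fit_synthetic_peb(layout, spec, 7, n_per_group=6)
        k = peb.beta.size
        peb.beta = np.zeros_like(peb.beta)
        peb.beta_cov = np.eye(k) * peb.prior_var_beta  # posterior == prior
        res = greedy_search(peb)
        assert np.all(res.thresholded == 0.0)
        assert res.presence.max() < 0.95

    def test_true_effects_survive_pruning(self, layout, spec):
        """Five 0.35 Hz group differences survive the automatic search
        (presence > 95%) for at least 4 of 5 connections in >= 80% of
        10 seeded replicates at n = 20 per group."""
        key = [("lLGN", "V1"), ("lPFC", "V1"), ("rPFC", "V1"),
               ("lLGN", "lPFC"), ("lPFC", "medThal")]
        effects = {pair: 0.35 for pair in key}
        idx = [layout.connection_param_index(spec.region_index(s),
                                             spec.region_index(d))
               for s, d in key]
        good_seeds = 0
        for seed in range(10):
            peb = _fit_synthetic_peb(layout, spec, 300 + seed, effects=effects)
            res = greedy_search(peb)
            vh = res.covariates.index("VH")
            survived = int(np.sum(res.presence[vh][idx] > 0.95))
            good_seeds += survived >= 4
        assert good_seeds >= 8
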