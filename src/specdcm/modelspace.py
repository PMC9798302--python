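"""Bayesian model reduction over a factorial space of reduced group models.

Hypotheses about which connections carry the group mean and the
hallucination (VH) effect are expressed as reduced priors: a connection
that is "switched off" has its group-level prior variance shrunk to
(near) zero, so its effect is clamped at the prior expectation of zero.
Because the second level is linear-Gaussian, the evidence and posterior
of every reduced model follow analytically from the full model's
posterior and priors (Bayesian model reduction) — no re-fitting.

The factorial space crosses three factors: hierarchy direction (top-down
off / bottom-up off / both on), laterality (inter off / intra off / both
on) and regional involvement (the 29 distinct "to and from a subset of
the five bilateral groups" families).  3 x 3 x 29 = 261 combinations
collapse to 178 unique masks, plus a null model with every connection
(including intrinsic ones) switched off: 179 models each for the
commonalities and the differences, hence 179^2 = 32 041 joint hypotheses.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .network import BILATERAL_GROUPS, NetworkSpec, classify_connection
from .peb import PEBModel

__all__ = [
    "bayesian_model_reduction",
    "ModelSpace",
    "build_model_space",
    "JointPosterior",
    "joint_bmc",
    "family_posterior",
    "bma",
    "BMAResult",
    "greedy_search",
]

#: reduced prior variance implementing "switched off" (kept > 0 for
#: numerical stability of the Gaussian algebra)
CLAMP_VARIANCE = 1e-8

FACTOR1_FAMILIES = ("top_down", "bottom_up", "both")
FACTOR2_FAMILIES = ("inter", "intra", "both")


# ---------------------------------------------------------------------------
# Bayesian model reduction
# ---------------------------------------------------------------------------

def bayesian_model_reduction(post_mean, post_cov, prior_mean, prior_cov,
                             red_prior_mean, red_prior_cov):
    """Analytic posterior and log-evidence change under a reduced prior.

    Given the full model's Gaussian posterior and prior and a reduced
    prior (typically with selected variances shrunk to near zero), returns
    ``(reduced_mean, reduced_cov, delta_F)`` where ``delta_F`` is the
    reduced-minus-full log evidence in nats.  Pure Gaussian algebra; no
    re-inversion of data.
    """
    m = np.asarray(post_mean, dtype=float)
    C = np.asarray(post_cov, dtype=float)
    m0 = np.asarray(prior_mean, dtype=float)
    C0 = np.asarray(prior_cov, dtype=float)
    m0r = np.asarray(red_prior_mean, dtype=float)
    C0r = np.asarray(red_prior_cov, dtype=float)
    for M in (C, C0, C0r):
        if np.any(np.linalg.eigvalsh(0.5 * (M + M.T)) < -1e-8):
            raise np.linalg.LinAlgError("covariance inputs must be PSD")

    P = np.linalg.inv(C)
    P0 = np.linalg.inv(C0)
    P0r = np.linalg.inv(C0r)
    Pr = P + P0r - P0
    Cr = np.linalg.inv(Pr)
    h = P @ m + P0r @ m0r - P0 @ m0
    mr = Cr @ h

    def _logdet(M):
        sign, ld = np.linalg.slogdet(M)
        if sign <= 0:
            raise np.linalg.LinAlgError("non-PD matrix in model reduction")
        return ld

    delta_f = 0.5 * (_logdet(P) + _logdet(P0r) - _logdet(P0) - _logdet(Pr)) \
        - 0.5 * (m @ P @ m + m0r @ P0r @ m0r - m0 @ P0 @ m0 - mr @ Pr @ mr)
    return mr, Cr, float(delta_f)


class _ClampReducer:
    """Fast BMR for diagonal zero-mean priors when clamping subsets.

    Precomputes what is shared across the thousands of reduced models:
    the posterior mean/covariance and the prior variance vector.  For a
    clamp set S the evidence change and reduced posterior only involve
    the |S| x |S| block of the posterior covariance.
    """

    def __init__(self, post_mean, post_cov, prior_var, eps: float = CLAMP_VARIANCE):
        self.m = np.asarray(post_mean, dtype=float)
        self.C = np.asarray(post_cov, dtype=float)
        self.v = np.asarray(prior_var, dtype=float)
        self.eps = eps

    def delta_f(self, S: np.ndarray) -> float:
        if S.size == 0:
            return 0.0
        v = self.v[S]
        d = 1.0 / self.eps - 1.0 / v
        Css = self.C[np.ix_(S, S)]
        M = Css + np.diag(1.0 / d)
        sign, ld_m = np.linalg.slogdet(M)
        if sign <= 0:
            raise np.linalg.LinAlgError("non-PD reduction block")
        # logdet(I + D Css) = sum(log d) + logdet(Css + D^-1)
        ld = np.sum(np.log(d)) + ld_m
        mS = self.m[S]
        quad = mS @ np.linalg.solve(M, mS)
        return float(0.5 * (np.sum(np.log(v / self.eps)) - ld) - 0.5 * quad)

    def reduced_mean(self, S: np.ndarray) -> np.ndarray:
        if S.size == 0:
            return self.m.copy()
        v = self.v[S]
        d = 1.0 / self.eps - 1.0 / v
        M = self.C[np.ix_(S, S)] + np.diag(1.0 / d)
        w = np.linalg.solve(M, self.m[S])
        return self.m - self.C[:, S] @ w


# ---------------------------------------------------------------------------
# Factorial model space
# ---------------------------------------------------------------------------

@dataclass
class ModelSpace:
    """Unique connection masks with per-factor family labels.

    ``masks`` is (n_models, 64) boolean over the canonical connection
    index (True = free).  The null model (all off) carries ``None``
    labels.
    """

    masks: np.ndarray
    labels: list
    spec: NetworkSpec = field(repr=False)

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        seen = {m.tobytes() for m in self.masks}
        if len(seen) != len(self.masks):
            raise ValueError("model space masks are not unique")

    @property
    def n_models(self) -> int:
        return len(self.masks)

    @property
    def null_index(self) -> int:
        return int(np.flatnonzero(~self.masks.any(axis=1))[0])

    def neural_free(self) -> np.ndarray:
        """(n_models, 64) over the neural parameter order (56 extrinsic + 8 intrinsic)."""
        ext = self.spec.extrinsic_indices
        intr = self.spec.intrinsic_indices
        return np.concatenate([self.masks[:, ext], self.masks[:, intr]], axis=1)

    def family_sizes(self, factor: int) -> dict:
        key = f"factor{factor}"
        sizes: dict = {}
        for lab in self.labels:
            if lab is None:
                continue
            sizes[lab[key]] = sizes.get(lab[key], 0) + 1
        return sizes

    def to_json(self) -> str:
        return json.dumps({
            "masks": ["".join("1" if b else "0" for b in m) for m in self.masks],
            "labels": self.labels,
        })


def _factor3_families(spec: NetworkSpec) -> list:
    """The 29 distinct regional-involvement families.

    Subsets of the five bilateral groups map to the set of extrinsic
    connections touching the subset; the empty subset is dropped and
    duplicate edge-sets (the full set and the two midline-only-complement
    sets coincide) are removed, keeping the first in enumeration order.
    """
    ext = spec.extrinsic_indices
    groups = BILATERAL_GROUPS
    fams = []
    seen = {}
    for r in range(1, len(groups) + 1):
        for subset in itertools.combinations(range(len(groups)), r):
            chosen = {groups[i] for i in subset}
            free = np.zeros(64, dtype=bool)
            for idx in ext:
                src, dst = spec.pair_of(idx)
                touched = {spec.regions[src].group, spec.regions[dst].group}
                if touched & chosen:
                    free[idx] = True
            key = free.tobytes()
            if key not in seen:
                name = "+".join(g for g in groups if g in chosen)
                seen[key] = name
                fams.append((name, free))
    return fams


def build_model_space(spec: NetworkSpec) -> ModelSpace:
    """Construct the deduplicated factorial model space (exactly 179 models)."""
    ext = spec.extrinsic_indices
    labels_by_index = {int(i): classify_connection(*spec.pair_of(int(i)), spec)
                       for i in ext}

    def _f1(off_direction):
        free = np.zeros(64, dtype=bool)
        for idx in ext:
            free[idx] = labels_by_index[int(idx)].direction != off_direction
        return free

    factor1 = [("top_down", _f1("bottom_up")), ("bottom_up", _f1("top_down")),
               ("both", _f1(None))]

    def _f2(off_hemi):
        free = np.zeros(64, dtype=bool)
        for idx in ext:
            free[idx] = labels_by_index[int(idx)].hemispheric != off_hemi
        return free

    factor2 = [("inter", _f2("intra")), ("intra", _f2("inter")),
               ("both", _f2(None))]
    factor3 = _factor3_families(spec)

    intr = spec.intrinsic_indices
    masks = []
    labels = []
    seen = {}
    n_combos = 0
    for (n1, m1), (n2, m2), (n3, m3) in itertools.product(factor1, factor2, factor3):
        n_combos += 1
        free = m1 & m2 & m3
        free[intr] = True  # intrinsic connections stay on outside the null
        key = free[ext].tobytes()  # dedup on the extrinsic edge-set only
        if key in seen:
            continue
        seen[key] = len(masks)
        masks.append(free)
        labels.append({"factor1": n1, "factor2": n2, "factor3": n3})
    assert n_combos == 3 * 3 * len(factor3)

    null = np.zeros(64, dtype=bool)
    masks.append(null)
    labels.append(None)
    return ModelSpace(np.asarray(masks), labels, spec)


# ---------------------------------------------------------------------------
# Joint Bayesian model comparison over commonalities x differences
# ---------------------------------------------------------------------------

@dataclass
class JointPosterior:
    """Posterior probabilities over (commonalities model, differences model)."""

    prob: np.ndarray
    log_evidence: np.ndarray  # delta-F of each reduced model vs the full PEB

    def __post_init__(self) -> None:
        self.prob = np.asarray(self.prob, dtype=float)
        if self.prob.ndim != 2 or self.prob.shape[0] != self.prob.shape[1]:
            raise ValueError("joint posterior must be square")
        if abs(self.prob.sum() - 1.0) > 1e-10 or np.any(self.prob < 0):
            raise ValueError("joint posterior must be a probability table")

    @property
    def commonalities_marginal(self) -> np.ndarray:
        return self.prob.sum(axis=1)

    @property
    def differences_marginal(self) -> np.ndarray:
        return self.prob.sum(axis=0)

    def to_tsv(self, path) -> None:
        """Write the dense probability matrix (rows = commonalities models)."""
        np.savetxt(path, self.prob, delimiter="\t")

    @classmethod
    def from_tsv(cls, path) -> "JointPosterior":
        prob = np.loadtxt(path, delimiter="\t")
        return cls(prob, np.log(np.maximum(prob, 1e-300)))


def _clamp_sets(peb: PEBModel, space: ModelSpace):
    """Flat clamp-index sets per model for the mean and VH blocks."""
    free = space.neural_free()
    mean_block = peb.block("mean")
    vh_block = peb.block("VH")
    clamp_mean = [mean_block[~free[i]] for i in range(space.n_models)]
    clamp_vh = [vh_block[~free[i]] for i in range(space.n_models)]
    return clamp_mean, clamp_vh


def _reducer(peb: PEBModel) -> _ClampReducer:
    prior_var = np.full(peb.beta.size, peb.prior_var_beta)
    return _ClampReducer(peb.beta_vector(), peb.beta_cov, prior_var)


def joint_bmc(peb: PEBModel, space: ModelSpace) -> JointPosterior:
    """Score all (commonalities, differences) reduced-model pairs.

    Model (i, j) clamps the group-mean effects of the connections switched
    off in mask i and the VH effects of those switched off in mask j.
    Posterior probabilities are the softmax of the reduced free energies
    under flat model priors.
    """
    for need in ("mean", "VH"):
        if need not in peb.design.names:
            raise ValueError(f"PEB design lacks the {need!r} covariate")
    if peb.n_params != 64:
        raise ValueError("joint BMC expects the 64 neural parameters")
    red = _reducer(peb)
    clamp_mean, clamp_vh = _clamp_sets(peb, space)
    M = space.n_models
    F = np.empty((M, M))
    for i in range(M):
        ci = clamp_mean[i]
        for j in range(M):
            S = np.concatenate([ci, clamp_vh[j]])
            F[i, j] = red.delta_f(S)
    logp = F - logsumexp(F)
    return JointPosterior(np.exp(logp), F)


def family_posterior(joint: JointPosterior, space: ModelSpace, factor: int) -> pd.DataFrame:
    """Pool the joint posterior into family x family cells for one factor.

    Model probabilities are reweighted so that every family carries equal
    prior mass (the standard correction for unequal family sizes); the
    null model is reported as its own cell.
    """
    if factor not in (1, 2, 3):
        raise ValueError("factor must be 1, 2 or 3")
    key = f"factor{factor}"
    fam_names = []
    for lab in space.labels:
        if lab is not None and lab[key] not in fam_names:
            fam_names.append(lab[key])
    names = fam_names + ["null"]
    fam_of = np.array([names.index(lab[key]) if lab is not None else len(fam_names)
                       for lab in space.labels])
    sizes = np.bincount(fam_of, minlength=len(names)).astype(float)
    w = 1.0 / sizes[fam_of]
    weighted = joint.prob * np.outer(w, w)
    weighted /= weighted.sum()
    pooled_rows = np.zeros((len(names), weighted.shape[1]))
    np.add.at(pooled_rows, fam_of, weighted)
    table = np.zeros((len(names), len(names)))
    np.add.at(table.T, fam_of, pooled_rows.T)
    return pd.DataFrame(table, index=names, columns=names)


# ---------------------------------------------------------------------------
# Bayesian model averaging
# ---------------------------------------------------------------------------

@dataclass
class BMAResult:
    """Model-averaged group effects with per-parameter presence probabilities.

    ``means`` / ``presence`` are (n_covariates, 64) over the neural
    parameter order; ``thresholded`` zeroes entries whose presence
    probability does not exceed the reporting threshold (their probability
    is retained in ``presence``).
    """

    means: np.ndarray
    presence: np.ndarray
    threshold: float
    covariates: list
    n_models: int = 0  # models averaged over (179^2 factorial; 256 greedy)

    @property
    def thresholded(self) -> np.ndarray:
        out = self.means.copy()
        out[self.presence < self.threshold] = 0.0
        return out

    def connection_table(self, spec: NetworkSpec) -> pd.DataFrame:
        """Labelled per-connection table (value in Hz, or log-scale for self)."""
        rows = []
        ext = list(spec.extrinsic_indices) + list(spec.intrinsic_indices)
        for k, idx in enumerate(ext):
            src, dst = spec.pair_of(int(idx))
            for c, name in enumerate(self.covariates):
                rows.append({
                    "src": spec.regions[src].name,
                    "dst": spec.regions[dst].name,
                    "kind": "intrinsic" if src == dst else "extrinsic",
                    "covariate": name,
                    "value": self.thresholded[c, k],
                    "presence_probability": self.presence[c, k],
                })
        return pd.DataFrame(rows)


def bma(joint: JointPosterior, space: ModelSpace, peb: PEBModel,
        threshold: float = 0.95) -> BMAResult:
    """Average the reduced posteriors over all models, weighted by probability.

    The presence probability of a parameter is the summed posterior
    probability of the models in which it is free; parameters at or below
    the reporting threshold are zeroed in ``thresholded`` (probability
    retained).  The default threshold is 0.95 ("present vs absent with
    >95% posterior probability").
    """
    if not 0.5 < threshold < 1.0:
        raise ValueError("threshold must lie in (0.5, 1)")
    red = _reducer(peb)
    clamp_mean, clamp_vh = _clamp_sets(peb, space)
    M = space.n_models
    k = peb.beta.size
    avg = np.zeros(k)
    for i in range(M):
        pj = joint.prob[i]
        ci = clamp_mean[i]
        for j in range(M):
            if pj[j] < 1e-12:
                continue
            S = np.concatenate([ci, clamp_vh[j]])
            avg += pj[j] * red.reduced_mean(S)

    free = space.neural_free()  # (M, 64)
    p_mean = joint.commonalities_marginal @ free
    p_vh = joint.differences_marginal @ free
    c, p = peb.beta.shape
    presence = np.ones((c, p))
    presence[peb.design.names.index("mean")] = p_mean
    presence[peb.design.names.index("VH")] = p_vh
    return BMAResult(avg.reshape(c, p), presence, threshold,
                     list(peb.design.names), n_models=M * M)


# ---------------------------------------------------------------------------
# Automatic (greedy) search
# ---------------------------------------------------------------------------

def greedy_search(peb: PEBModel, threshold: float = 0.95,
                  n_final: int = 8, max_sweeps: int = 64,
                  tol: float = 1e-4) -> BMAResult:
    """Greedy pruning of group-level parameters by model evidence.

    Starting from the full model, each sweep scores every remaining
    parameter by the evidence change of switching it off alone, takes the
    ``n_final`` most dispensable ones and scores all 2**n_final on/off
    combinations on top of the current reduced prior; the best combination
    (ties resolved toward the more reduced model) is applied.  The search
    stops when no further reduction increases the free energy; the models
    of the final iteration (256 for ``n_final=8``) are Bayesian-model
    averaged.
    """
    red = _reducer(peb)
    k = peb.beta.size
    clamped = np.zeros(k, dtype=bool)
    final_sets: list = [np.array([], dtype=int)]
    final_f = np.array([0.0])

    for _ in range(max_sweeps):
        base = np.flatnonzero(clamped)
        f_base = red.delta_f(base)
        candidates = np.flatnonzero(~clamped)
        if candidates.size == 0:
            break
        scores = np.array([red.delta_f(np.append(base, c)) for c in candidates])
        top = candidates[np.argsort(-scores)[:n_final]]
        combos = []
        f_combo = []
        for bits in itertools.product((0, 1), repeat=len(top)):
            extra = top[np.asarray(bits, dtype=bool)]
            S = np.concatenate([base, extra])
            combos.append(S)
            f_combo.append(red.delta_f(S))
        f_combo = np.asarray(f_combo)
        final_sets, final_f = combos, f_combo
        # best combination; near-ties resolved toward the sparser model
        near = f_combo >= f_combo.max() - tol
        best = max(np.flatnonzero(near), key=lambda ix: len(combos[ix]))
        if len(combos[best]) == len(base):
            break
        clamped[:] = False
        clamped[combos[best]] = True

    w = np.exp(final_f - logsumexp(final_f))
    avg = np.zeros(k)
    pres_flat = np.zeros(k)
    for wt, S in zip(w, final_sets):
        if wt < 1e-12:
            continue
        avg += wt * red.reduced_mean(S)
        freep = np.ones(k, dtype=bool)
        freep[S] = False
        pres_flat += wt * freep
    c, p = peb.beta.shape
    return BMAResult(avg.reshape(c, p), pres_flat.reshape(c, p), threshold,
                     list(peb.design.names), n_models=len(final_sets))
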