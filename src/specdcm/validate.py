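"""Out-of-sample prediction of hallucination status, severity association
and cohort summary statistics.

Leave-one-out cross-validation refits the group model (PEB) without each
subject and predicts that subject's group-covariate score from their own
connection parameters; prediction quality is summarized by the
point-biserial correlation between predicted and actual (demeaned) group
membership.  Canonical variate analysis relates the key connection
strengths to hallucination severity within the hallucinating group after
adjusting both blocks for age and sex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .peb import PEB, DesignMatrix

__all__ = ["LooResult", "loo_crossval", "CvaResult", "cva", "cohort_stats"]


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class LooResult:
    """Per-subject posterior predictions of the group covariate."""

    predicted: np.ndarray  # posterior expectation, demeaned
    ci_low: np.ndarray  # 90% credible interval (raw covariate scale)
    ci_high: np.ndarray
    actual: np.ndarray  # demeaned labels
    r_pb: float  # point-biserial correlation
    p_value: float
    n_within_interval: int

    def __post_init__(self) -> None:
        if abs(self.r_pb) > 1.0 + 1e-12:
            raise ValueError("|r_pb| cannot exceed 1")


def loo_crossval(posteriors, design: DesignMatrix, connections,
                 target: str = "VH", **peb_kwargs) -> LooResult:
    """Leave-one-out prediction of the group covariate from connectivity.

    ``posteriors``: per-subject (mean, covariance) neural posteriors;
    ``connections``: indices (into the neural parameter vector) of the
    connections used for prediction — typically the top group differences
    ranked from the current Bayesian model average, passed in explicitly.

    For each held-out subject a PEB model is fitted to the rest; the
    held-out subject's covariate score is then inferred by Bayesian linear
    regression: their parameter means, minus the contribution of the known
    covariates, are regressed on the group-difference effect under a
    Gaussian prior matched to the training covariate moments.  The
    observation covariance combines the subject's posterior covariance,
    the estimated between-subject covariance and the propagated
    uncertainty of the known-covariate effects.
    """
    connections = np.asarray(connections, dtype=int)
    if connections.size == 0:
        raise ValueError("connection subset must be nonempty")
    n = design.n_subjects
    p_full = np.asarray(posteriors[0][0]).size
    if np.any(connections < 0) or np.any(connections >= p_full):
        raise IndexError("connection subset references unknown connections")
    if target not in design.names:
        raise ValueError(f"design lacks target covariate {target!r}")

    sub = [(np.asarray(m)[connections],
            np.asarray(C)[np.ix_(connections, connections)])
           for m, C in posteriors]
    k = connections.size
    t_col = design.names.index(target)
    labels = design.X[:, t_col]
    # fold-independent prior over the unknown covariate: the full-sample
    # moments.  A training-fold mean would differ systematically between
    # groups (the classic leave-one-out mean artifact) and anti-correlate
    # predictions with labels whenever the likelihood is weak.
    x_bar = labels.mean()
    x_var = labels.var()
    if x_var <= 0:
        raise ValueError("target covariate is constant")

    pred = np.empty(n)
    lo = np.empty(n)
    hi = np.empty(n)
    for i in range(n):
        train = [sub[j] for j in range(n) if j != i]
        rows = np.delete(np.arange(n), i)
        d_train = DesignMatrix(design.X[rows], list(design.names), design.centred)
        model = PEB(**peb_kwargs).fit(train, d_train).model_

        beta = model.beta  # (c, k)
        bv = beta[t_col]
        x_known = design.X[i].copy()
        x_known[t_col] = 0.0
        r = sub[i][0] - x_known @ beta
        # observation covariance: subject posterior + between-subject +
        # uncertainty of the known-covariate betas
        V = sub[i][1] + np.eye(k) / model.between_subject_precision
        for a, ca in enumerate(design.names):
            if a == t_col:
                continue
            for b in range(len(design.names)):
                if b == t_col:
                    continue
                blk = model.beta_cov[np.ix_(model.block(ca), model.block(design.names[b]))]
                V += x_known[a] * x_known[b] * blk
        Vi_bv = np.linalg.solve(V, bv)
        prec = 1.0 / x_var + bv @ Vi_bv
        mean = (x_bar / x_var + bv @ np.linalg.solve(V, r)) / prec
        sd = 1.0 / np.sqrt(prec)
        pred[i] = mean
        lo[i] = mean - 1.6449 * sd
        hi[i] = mean + 1.6449 * sd

    within = int(np.sum((labels >= lo) & (labels <= hi)))
    pred_dm = pred - pred.mean()
    act_dm = labels - labels.mean()
    r_pb, p = stats.pearsonr(pred_dm, act_dm)
    return LooResult(pred_dm, lo, hi, act_dm, float(r_pb), float(p), within)


# ---------------------------------------------------------------------------
# Canonical variate analysis
# ---------------------------------------------------------------------------

@dataclass
class CvaResult:
    """Canonical correlations and first-pair subject scores."""

    correlations: np.ndarray  # in [0, 1], non-increasing
    x_scores: np.ndarray  # first canonical variate of connectivity
    y_scores: np.ndarray  # first canonical variate of severity
    r: float  # Pearson correlation of the first pair
    p_value: float  # Wilks/Bartlett chi-square approximation

    def __post_init__(self) -> None:
        c = np.asarray(self.correlations)
        if np.any(c < -1e-10) or np.any(c > 1 + 1e-10) or np.any(np.diff(c) > 1e-10):
            raise ValueError("canonical correlations must be non-increasing in [0, 1]")


def _residualize(block: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(confounds, block, rcond=None)
    return block - confounds @ beta


def cva(params: np.ndarray, severity: np.ndarray,
        confounds: np.ndarray | None = None) -> CvaResult:
    """Canonical correlation between connectivity and severity, adjusted
    for confounds.

    ``params``: subjects x k connection values; ``severity``: the severity
    scores (one or more columns); ``confounds``: subjects x c (age, sex);
    an intercept is always included.  Both blocks are residualized on the
    confounds before the canonical decomposition.  Scores of the first
    pair are sign-aligned so their correlation is nonnegative.
    Significance uses Bartlett's chi-square approximation of Wilks'
    lambda.
    """
    X = np.atleast_2d(np.asarray(params, dtype=float))
    Y = np.asarray(severity, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("blocks must have the same number of subjects")
    if n <= X.shape[1]:
        raise ValueError("need more subjects than connection parameters")
    Z = np.ones((n, 1))
    if confounds is not None:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] != n:
            confounds = confounds.T
        Z = np.column_stack([Z, confounds])
    Xr = _residualize(X, Z)
    Yr = _residualize(Y, Z)

    def _orth(M):
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        rank = int(np.sum(s > max(M.shape) * np.finfo(float).eps * s.max()))
        if rank == 0:
            raise np.linalg.LinAlgError("rank-deficient block in CVA")
        return U[:, :rank]

    Ux = _orth(Xr)
    Uy = _orth(Yr)
    A, rho, Bt = np.linalg.svd(Ux.T @ Uy)
    rho = np.clip(rho, 0.0, 1.0)
    x_scores = Ux @ A[:, 0]
    y_scores = Uy @ Bt.T[:, 0]
    if x_scores @ y_scores < 0:
        y_scores = -y_scores
    r = float(np.corrcoef(x_scores, y_scores)[0, 1])

    p_, q_ = Ux.shape[1], Uy.shape[1]
    wilks = float(np.prod(1.0 - rho**2))
    dof_adjust = Z.shape[1] - 1  # confound columns absorb degrees of freedom
    factor = n - dof_adjust - 1 - 0.5 * (p_ + q_ + 1)
    chi2 = -factor * np.log(max(wilks, np.finfo(float).tiny))
    p_value = float(stats.chi2.sf(chi2, p_ * q_))
    return CvaResult(rho, x_scores, y_scores, r, p_value)


# ---------------------------------------------------------------------------
# Cohort summary statistics
# ---------------------------------------------------------------------------

def _stat_row(row: dict) -> dict:
    test = row["test"]
    out = {"variable": row.get("variable", ""), "test": test}
    if test == "t":
        t, p = stats.ttest_ind_from_stats(
            row["mean1"], row["sd1"], row["n1"],
            row["mean2"], row["sd2"], row["n2"], equal_var=True)
        out.update(statistic=float(t), p_value=float(p))
    elif test == "chi2":
        table = np.asarray(row["table"], dtype=float)
        res = stats.chi2_contingency(table, correction=False)
        out.update(statistic=float(res.statistic), p_value=float(res.pvalue))
    elif test == "fisher":
        table = np.asarray(row["table"], dtype=int)
        if table.shape != (2, 2):
            raise ValueError("Fisher test needs a 2x2 table")
        orr = stats.contingency.odds_ratio(table)  # conditional MLE
        _, p = stats.fisher_exact(table)
        out.update(statistic=float(orr.statistic), p_value=float(p))
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(np.asarray(row["x"], dtype=float),
                                 np.asarray(row["y"], dtype=float),
                                 alternative="two-sided")
        out.update(statistic=float(res.statistic), p_value=float(res.pvalue))
    else:
        raise ValueError(f"unknown test {test!r}")
    return out


def cohort_stats(rows) -> pd.DataFrame:
    """Per-variable group-comparison statistics from printed summaries or raw columns.

    Each row is a dict with ``test`` one of:

    * ``"t"`` — pooled-variance two-sample t from summary statistics
      (``mean1, sd1, n1, mean2, sd2, n2``);
    * ``"chi2"`` — Pearson chi-square, no continuity correction, from a
      count ``table``;
    * ``"fisher"`` — Fisher exact test on a 2x2 ``table`` (statistic is
      the conditional-MLE odds ratio);
    * ``"mannwhitney"`` — Mann-Whitney U from raw columns ``x`` and ``y``.
    """
    return pd.DataFrame([_stat_row(dict(r)) for r in rows])
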