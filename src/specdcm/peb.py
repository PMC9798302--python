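"""Parametric empirical Bayes: a hierarchical Bayesian GLM over subjects.

Each subject contributes a Gaussian posterior (mean and covariance) over
the 64 neural parameters.  The second level models those posteriors as

    mu_i = (x_i kron I_p) beta + eps_i + nu_i,
    eps_i ~ N(0, Sigma_i)   (first-level posterior uncertainty)
    nu_i  ~ N(0, I_p / gamma)  (between-subject variability)

with design row x_i = (mean, VH, age, sex), a Gaussian shrinkage prior on
the group effects beta and a log-normal-style hyperprior on the single
between-subject precision gamma.  gamma is set by maximizing the (exact,
conjugate) log evidence plus hyperprior — the free-energy ascent of
empirical Bayes.  Because the model is linear-Gaussian given gamma, the
posterior over beta is available in closed form; full subject covariances,
not point estimates, inform the fit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

__all__ = ["DesignMatrix", "PEBModel", "build_design", "PEB", "fit_peb"]


@dataclass
class DesignMatrix:
    """Second-level design: rows = subjects, columns = covariates."""

    X: np.ndarray
    names: list
    centred: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.names):
            raise ValueError("design shape does not match covariate names")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.names.index(name)]

    def drop(self, name: str) -> "DesignMatrix":
        keep = [i for i, n in enumerate(self.names) if n != name]
        return DesignMatrix(self.X[:, keep], [self.names[i] for i in keep],
                            {k: v for k, v in self.centred.items() if k != name})


def build_design(covariates: pd.DataFrame) -> DesignMatrix:
    """Design matrix (mean, VH, age, sex) from a subject covariate table.

    ``group`` may be 0/1 or the labels {"VH", "nonVH"}; ``sex`` may be 0/1
    or {"F", "M"} (female = 1).  Age and sex are mean-centred so the mean
    column captures the group average; VH stays 0/1.  A constant VH column
    (single-group input) is dropped with a warning.
    """
    required = {"group", "age", "sex"}
    missing = required - set(covariates.columns)
    if missing:
        raise ValueError(f"covariate table lacks columns: {sorted(missing)}")
    if covariates[list(required)].isna().any().any():
        raise ValueError("covariate table contains missing values")

    n = len(covariates)
    group = covariates["group"]
    if group.dtype == object:
        vh = (group == "VH").astype(float).to_numpy()
    else:
        vh = group.astype(float).to_numpy()
    if not set(np.unique(vh)) <= {0.0, 1.0}:
        raise ValueError("VH group must be coded 0/1 (or labels VH/nonVH)")
    sex = covariates["sex"]
    if sex.dtype == object:
        sex = (sex == "F").astype(float)
    sex = sex.astype(float).to_numpy()
    age = covariates["age"].astype(float).to_numpy()

    cols = [np.ones(n)]
    names = ["mean"]
    if np.ptp(vh) == 0:
        warnings.warn("VH column is constant (single group); dropping it",
                      UserWarning)
    else:
        cols.append(vh)
        names.append("VH")
    cols.append(age - age.mean())
    names.append("age")
    cols.append(sex - sex.mean())
    names.append("sex")
    return DesignMatrix(np.column_stack(cols), names,
                        centred={"age": True, "sex": True, "VH": False})


@dataclass
class PEBModel:
    """Fitted second-level model.

    ``beta`` is (n_covariates, p): group-level expectations per covariate
    and neural parameter.  ``beta_cov`` is the joint posterior covariance
    of the flattened (covariate-major) beta vector.
    """

    beta: np.ndarray
    beta_cov: np.ndarray
    between_subject_precision: float
    free_energy: float
    design: DesignMatrix
    prior_var_beta: float
    subject_means: np.ndarray  # (n, p)
    subject_covs: np.ndarray  # (n, p, p)

    @property
    def n_params(self) -> int:
        return self.beta.shape[1]

    def beta_vector(self) -> np.ndarray:
        return self.beta.ravel()

    def prior(self) -> tuple[np.ndarray, np.ndarray]:
        k = self.beta.size
        return np.zeros(k), np.eye(k) * self.prior_var_beta

    def block(self, name: str) -> np.ndarray:
        """Flat indices of one covariate's betas."""
        i = self.design.names.index(name)
        p = self.n_params
        return np.arange(i * p, (i + 1) * p)

    def to_json(self) -> str:
        return json.dumps({
            "beta": self.beta.tolist(),
            "beta_cov": self.beta_cov.tolist(),
            "between_subject_precision": self.between_subject_precision,
            "free_energy": self.free_energy,
            "covariates": self.design.names,
            "prior_var_beta": self.prior_var_beta,
        })


def _evidence(mus, covs, X, gamma, prior_var_beta):
    """Exact log evidence of the linear-Gaussian second level, given gamma.

    Returns (log evidence, posterior mean, posterior covariance) over the
    flattened beta.
    """
    n, p = mus.shape
    c = X.shape[1]
    k = c * p
    V = covs + np.eye(p) / gamma  # (n, p, p), batched
    cho = np.linalg.cholesky(V)
    logdet_v = 2.0 * np.sum(np.log(np.diagonal(cho, axis1=-2, axis2=-1)))
    P = np.linalg.inv(V)
    Pm = np.einsum("nij,nj->ni", P, mus)
    H = np.einsum("na,nij,nb->aibj", X, P, X).reshape(k, k) \
        + np.eye(k) / prior_var_beta
    rhs = np.einsum("na,ni->ai", X, Pm).ravel()
    quad = float(np.einsum("ni,ni->", mus, Pm))
    cho_h = np.linalg.cholesky(H)
    logdet_h = 2.0 * np.sum(np.log(np.diag(cho_h)))
    b = np.linalg.solve(H, rhs)
    log_ev = -0.5 * (n * p * np.log(2 * np.pi) + logdet_v
                     + k * np.log(prior_var_beta) + logdet_h
                     + quad - b @ rhs)
    return log_ev, b, np.linalg.inv(H)


class PEB(BaseEstimator):
    """Group-level parametric empirical Bayes estimator.

    Parameters
    ----------
    prior_var_beta : prior variance of each group-level effect (default 1/16).
    log_precision_prior_var : variance of the Gaussian hyperprior on
        log(between-subject precision), centred at 0 (default 1/16).
    between_precision : if given, the between-subject precision is fixed at
        this value instead of being estimated (used by conjugate oracles).
    """

    def __init__(self, prior_var_beta: float = 1.0 / 16.0,
                 log_precision_prior_var: float = 1.0 / 16.0,
                 between_precision: float | None = None,
                 log_gamma_bounds: tuple = (-8.0, 8.0)):
        self.prior_var_beta = prior_var_beta
        self.log_precision_prior_var = log_precision_prior_var
        self.between_precision = between_precision
        self.log_gamma_bounds = log_gamma_bounds

    def fit(self, posteriors, design: DesignMatrix):
        """Fit from per-subject (mean, covariance) posteriors.

        ``posteriors``: sequence of (mu_i, Sigma_i) pairs (neural
        sub-vectors), all of one dimension p.
        """
        mus = np.asarray([np.asarray(m, dtype=float) for m, _ in posteriors])
        covs = np.asarray([np.asarray(c, dtype=float) for _, c in posteriors])
        if mus.ndim != 2 or len(mus) < 2:
            raise ValueError("need at least two subjects")
        if covs.shape != (len(mus), mus.shape[1], mus.shape[1]):
            raise ValueError("subject posterior dimensions disagree")
        X = design.X
        if len(X) != len(mus):
            raise ValueError("design and posterior subject counts differ")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError("singular second-level design")

        tau = 1.0 / self.log_precision_prior_var

        def neg_f(log_gamma):
            ev, *_ = _evidence(mus, covs, X, np.exp(log_gamma), self.prior_var_beta)
            return -(ev - 0.5 * tau * log_gamma**2)

        if self.between_precision is not None:
            log_gamma = float(np.log(self.between_precision))
        else:
            res = minimize_scalar(neg_f, bounds=self.log_gamma_bounds,
                                  method="bounded",
                                  options={"xatol": 1e-4})
            log_gamma = float(res.x)
        gamma = float(np.exp(log_gamma))
        ev, b, Sb = _evidence(mus, covs, X, gamma, self.prior_var_beta)
        f = ev - 0.5 * tau * log_gamma**2

        c, p = X.shape[1], mus.shape[1]
        self.model_ = PEBModel(
            beta=b.reshape(c, p), beta_cov=Sb,
            between_subject_precision=gamma, free_energy=float(f),
            design=design, prior_var_beta=self.prior_var_beta,
            subject_means=mus, subject_covs=covs)
        self.beta_ = self.model_.beta
        self.beta_cov_ = Sb
        self.gamma_ = gamma
        self.free_energy_ = float(f)
        return self


def fit_peb(posteriors, design: DesignMatrix, **kwargs) -> PEBModel:
    """Functional wrapper over :class:`PEB`."""
    return PEB(**kwargs).fit(posteriors, design).model_
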