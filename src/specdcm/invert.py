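"""Variational-Laplace inversion of the spectral DCM.

The scheme maximizes the variational free energy

    F = accuracy - complexity
      = E_q[log p(y | theta)] - KL[q(theta) || p(theta)]

under a Gaussian (Laplace) posterior q.  Updates are Gauss-Newton steps
with Levenberg-Marquardt damping and explicit step rejection, so the free
energy is non-decreasing across accepted iterations.  The data vector is
the non-redundant real/imaginary stacking of the observed cross-spectra;
its precision is a single hyperparameter (log precision, Gaussian
hyperprior) updated by guarded Newton steps.

Observed spectra are rescaled to the diagonal magnitude of the prior-mean
prediction before inversion (unit scale under the default constants), so
the log-amplitude noise parameters start in the bulk of their priors; the
scale is absorbed by those parameters and leaves coupling estimates (Hz)
untouched.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .forward import StabilityError, max_real_eigenvalue, predicted_csd_matrix
from .params import ParamLayout, PriorDensity, default_priors
from .spectra import CrossSpectra, csd_to_vector, variance_explained

__all__ = ["SubjectPosterior", "SpectralDCM", "invert_subject", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    """Inversion failed to converge; carries the free-energy trace."""

    def __init__(self, message: str, f_trace: list[float], posterior: "SubjectPosterior"):
        super().__init__(message)
        self.f_trace = f_trace
        self.posterior = posterior


@dataclass
class SubjectPosterior:
    """Gaussian posterior over the full DCM parameter vector."""

    mean: np.ndarray
    cov: np.ndarray
    free_energy: float
    variance_explained: float
    f_trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.variance_explained > 100.0 + 1e-9:
            raise ValueError("variance_explained cannot exceed 100%")

    def neural_posterior(self, layout: ParamLayout) -> tuple[np.ndarray, np.ndarray]:
        """Marginal over the neural sub-vector (extrinsic then intrinsic)."""
        sl = layout.sl_neural
        return self.mean[sl].copy(), self.cov[sl, sl.start:sl.stop].copy()

    def to_json(self) -> str:
        return json.dumps({
            "mean": self.mean.tolist(),
            "cov": self.cov.tolist(),
            "free_energy": self.free_energy,
            "variance_explained": self.variance_explained,
        })

    @classmethod
    def from_json(cls, text: str) -> "SubjectPosterior":
        d = json.loads(text)
        return cls(np.asarray(d["mean"]), np.asarray(d["cov"]),
                   d["free_energy"], d["variance_explained"])


def _stabilize(theta: np.ndarray, m0: np.ndarray, layout: ParamLayout,
               max_bisect: int = 32) -> np.ndarray:
    """Shrink a proposal toward the prior mean until the Jacobian is stable."""
    if max_real_eigenvalue(layout.a_matrix(theta)) < -1e-6:
        return theta
    lo, hi = 0.0, 1.0  # fraction of the step away from m0
    for _ in range(max_bisect):
        mid = 0.5 * (lo + hi)
        cand = m0 + mid * (theta - m0)
        if max_real_eigenvalue(layout.a_matrix(cand)) < -1e-6:
            lo = mid
        else:
            hi = mid
    return m0 + lo * (theta - m0)


class _Objective:
    """Prediction, Jacobian and free energy for a fixed data vector."""

    def __init__(self, y: np.ndarray, layout: ParamLayout, freqs: np.ndarray,
                 prior_mean: np.ndarray, prior_prec: np.ndarray, free: np.ndarray,
                 fd_step: float = 1e-3):
        self.y = y
        self.layout = layout
        self.freqs = freqs
        self.m0 = prior_mean
        self.free = free
        self.pi0 = prior_prec  # precision over the free sub-vector
        self.fd_step = fd_step
        sign, logdet = np.linalg.slogdet(prior_prec)
        self.logdet_pi0 = logdet

    def predict(self, theta_full: np.ndarray) -> np.ndarray:
        S = predicted_csd_matrix(theta_full, self.layout, self.freqs,
                                 check_stability=False)
        return csd_to_vector(S).ravel()

    def predict_and_jacobian(self, theta_full: np.ndarray):
        """Prediction and Jacobian over the free parameters.

        Coupling derivatives are exact: with T(f) the end-to-end transfer
        and Tn(f) the neural resolvent, d Tn / dA[dst,src] =
        Tn e_dst e_src' Tn, so the CSD derivative is the rank-2 Hermitian
        update  u a^H + a u^H  with u = T[:,dst] and
        a = T (G_u * conj(Tn[src,:])).  Noise-spectrum derivatives are
        exact as well; the 2n+1 hemodynamic log-scalings use central
        differences of the closed-form regional response only.
        """
        from .forward import (HemodynamicConstants as C, _hemo_transfer,
                              noise_spectra)

        lay = self.layout
        n = lay.n
        freqs = self.freqs
        h = self.fd_step
        cols = np.flatnonzero(self.free)
        n_neural = lay.n_extrinsic + n
        n_dyn = n_neural + 2 * n + 1  # + hemodynamic block + epsilon
        neural_cols = cols[cols < n_neural]
        hemo_cols = cols[(cols >= n_neural) & (cols < n_dyn)]
        noise_cols = cols[cols >= n_dyn]

        # --- base quantities --------------------------------------------
        eye = np.eye(n)
        w = 2j * np.pi * freqs[:, None, None]
        A = lay.a_matrix(theta_full)
        Tn = np.linalg.inv(w * eye - A)  # (nf, n, n)
        kappa = C.kappa0 * np.exp(theta_full[lay.sl_decay])
        tau = C.tau0 * np.exp(theta_full[lay.sl_transit])
        hv = _hemo_transfer(kappa, tau, np.asarray(theta_full[lay.idx_epsilon]),
                            freqs, C)  # (nf, n)
        T = hv[..., None] * Tn
        gu, ge = noise_spectra(theta_full, lay, freqs)
        gu, ge = gu[0], ge[0]  # (nf, n)

        def _csd(Tb, gub=None, geb=None):
            gub = gu if gub is None else gub
            geb = ge if geb is None else geb
            S = np.einsum("...ik,...k,...jk->...ij", Tb, gub, np.conj(Tb))
            idx = np.arange(n)
            S[..., idx, idx] += geb
            return S

        g = csd_to_vector(_csd(T)).ravel()
        blocks = []

        # --- couplings: exact rank-2 derivatives -------------------------
        if neural_cols.size:
            # W[f, j, s] = sum_m T[f,j,m] gu[f,m] conj(Tn[f,s,m])
            W = np.einsum("fjm,fm,fsm->fjs", T, gu, np.conj(Tn))
            # dS[(dst,src)][f,i,j] = T[f,i,dst] conj(W[f,j,src]) +
            #                        W[f,i,src] conj(T[f,j,dst])
            Z = np.einsum("fid,fjs->dsfij", T, np.conj(W))
            dS_pair = Z + np.conj(np.swapaxes(Z, -1, -2))
            cols_ds = []
            pairs = lay.extrinsic_pairs()
            for c in neural_cols:
                if c < lay.n_extrinsic:
                    src, dst = pairs[c]
                    cols_ds.append(dS_pair[dst, src])
                else:
                    i = c - lay.n_extrinsic
                    scale = -0.5 * np.exp(theta_full[lay.sl_a_self][i])
                    cols_ds.append(scale * dS_pair[i, i])
            blocks.append(csd_to_vector(np.asarray(cols_ds)).reshape(
                len(cols_ds), -1).T)

        # --- hemodynamics: FD on the closed-form response, exact in T ----
        if hemo_cols.size:
            m = hemo_cols.size
            batch = np.repeat(theta_full[None, :], 2 * m, axis=0)
            batch[np.arange(m), hemo_cols] += h
            batch[m + np.arange(m), hemo_cols] -= h
            kb = C.kappa0 * np.exp(batch[:, lay.sl_decay])
            tb = C.tau0 * np.exp(batch[:, lay.sl_transit])
            hb = _hemo_transfer(kb, tb, batch[:, lay.idx_epsilon], freqs, C)
            dh = (hb[:m] - hb[m:]) / (2 * h)  # (m, nf, n)
            dT = dh[..., None] * Tn[None]
            Z = np.einsum("bfik,fk,fjk->bfij", dT, gu, np.conj(T))
            dS = Z + np.conj(np.swapaxes(Z, -1, -2))
            blocks.append(csd_to_vector(dS).reshape(m, -1).T)

        # --- noise spectra: exact derivatives ----------------------------
        if noise_cols.size:
            logf = np.log(freqs)
            outer = np.einsum("fik,fjk->kfij", T, np.conj(T))  # (n, nf, n, n)
            dcols = []
            d_uamp = gu.T[:, :, None, None] * outer
            d_uexp = d_uamp * (-logf[None, :, None, None]) \
                * np.exp(theta_full[lay.sl_u_exp])[:, None, None, None]
            d_eamp = np.zeros((n, freqs.size, n, n), dtype=complex)
            idx = np.arange(n)
            d_eamp[idx, :, idx, idx] = ge.T
            d_eexp = d_eamp * (-logf[None, :, None, None]) \
                * np.exp(theta_full[lay.sl_e_exp])[:, None, None, None]
            per_block = {0: d_uamp, 1: d_uexp, 2: d_eamp, 3: d_eexp}
            for c in noise_cols:
                off = c - n_dyn
                dcols.append(csd_to_vector(per_block[off // n][off % n]).ravel())
            blocks.append(np.array(dcols).T)

        J = np.concatenate(blocks, axis=1) if blocks else np.zeros((g.size, 0))
        return g, J

    def free_energy(self, theta_full, lam, g, jj, hyper_mean, hyper_prec):
        """Variational free energy at (mu, Sigma(lam), lam).

        ``jj`` is the Gauss-Newton curvature J'J of the Jacobian the
        variational covariance is built from (cached by the caller).
        """
        r = self.y - g
        e = theta_full[self.free] - self.m0[self.free]
        H = np.exp(lam) * jj + self.pi0
        cho = np.linalg.cholesky(H)
        logdet_H = 2.0 * np.sum(np.log(np.diag(cho)))
        Sigma = np.linalg.inv(H)
        ny = self.y.size
        acc = -0.5 * np.exp(lam) * (r @ r + np.sum(jj * Sigma)) \
            + 0.5 * ny * lam - 0.5 * ny * np.log(2 * np.pi)
        comp = 0.5 * (e @ self.pi0 @ e + np.sum(self.pi0 * Sigma)
                      - self.logdet_pi0 + logdet_H - self.free.sum())
        hyp = -0.5 * hyper_prec * (lam - hyper_mean) ** 2
        return acc - comp + hyp, Sigma, r


def invert_subject(observed: CrossSpectra, prior: PriorDensity,
                   layout: ParamLayout | None = None, *,
                   hyper_mean: float = 6.0, hyper_var: float = 1.0 / 128.0,
                   max_iter: int = 128, tol: float = 1e-2, patience: int = 4,
                   fd_step: float = 1e-3, on_nonconvergence: str = "raise",
                   ) -> SubjectPosterior:
    """Invert one subject's observed cross-spectra under the given priors.

    Parameters with (near) zero prior variance are clamped at their prior
    mean and excluded from the optimization.  Raises
    :class:`ConvergenceError` (carrying the free-energy trace and the last
    iterate) if the stopping rule is not met within ``max_iter``
    iterations and ``on_nonconvergence == "raise"``; with ``"warn"`` the
    last iterate is returned.
    """
    if layout is None:
        layout = ParamLayout(observed.n_regions)
    if prior.size != layout.size:
        raise ValueError("prior dimension does not match parameter layout")

    # rescale data to the scale of the prior-mean prediction, so that the
    # log-amplitude noise parameters start in the bulk of their priors
    obs_scale = float(np.mean(np.abs(np.diagonal(observed.csd, axis1=-2, axis2=-1))))
    if obs_scale <= 0:
        raise ValueError("observed spectra are identically zero")
    ref = predicted_csd_matrix(prior.mean, layout, observed.freqs,
                               check_stability=False)
    ref_scale = float(np.mean(np.abs(np.diagonal(ref, axis1=-2, axis2=-1))))
    scale = obs_scale / ref_scale
    csd_n = observed.csd / scale
    y = csd_to_vector(csd_n).ravel()

    var0 = np.diag(prior.cov)
    free = var0 > 1e-10
    m0 = prior.mean.copy()
    pi0 = np.linalg.inv(prior.cov[np.ix_(free, free)])
    hyper_prec = 1.0 / hyper_var

    obj = _Objective(y, layout, observed.freqs, m0, pi0, free, fd_step)
    mu = m0.copy()
    lam = hyper_mean
    g, J = obj.predict_and_jacobian(mu)
    jj = J.T @ J
    F, Sigma, r = obj.free_energy(mu, lam, g, jj, hyper_mean, hyper_prec)
    f_trace = [F]
    rho = 0.25
    still = 0

    for _ in range(max_iter):
        # --- parameter step (Gauss-Newton with LM damping) ---------------
        # candidates are screened with a surrogate free energy that reuses
        # the current Jacobian for the curvature terms (a cheap forward
        # evaluation); the exact free energy, with the Jacobian recomputed
        # at the candidate, decides acceptance, so the accepted trace is
        # monotone by construction.
        grad = np.exp(lam) * (J.T @ r) - pi0 @ (mu[free] - m0[free])
        H = np.exp(lam) * jj + pi0
        accepted = False
        for _trial in range(8):
            d = np.linalg.solve(H + rho * np.diag(np.diag(H)), grad)
            cand = mu.copy()
            cand[free] = mu[free] + d
            cand = _stabilize(cand, m0, layout)
            g_s = obj.predict(cand)
            F_s, _, _ = obj.free_energy(cand, lam, g_s, jj,
                                        hyper_mean, hyper_prec)
            if not (np.isfinite(F_s) and F_s > F):
                rho *= 8.0
                continue
            g_c, J_c = obj.predict_and_jacobian(cand)
            jj_c = J_c.T @ J_c
            F_c, Sigma_c, r_c = obj.free_energy(cand, lam, g_c, jj_c,
                                                hyper_mean, hyper_prec)
            if np.isfinite(F_c) and F_c > F:
                mu, g, J, Sigma, jj, r = cand, g_c, J_c, Sigma_c, jj_c, r_c
                dF = F_c - F
                F = F_c
                rho = max(rho / 2.0, 1e-4)
                accepted = True
                break
            rho *= 8.0
        if not accepted:
            dF = 0.0  # local maximum w.r.t. parameters at this damping

        # --- hyperparameter (log data precision) Newton step -------------
        c = r @ r + np.sum(jj * Sigma)
        for _trial in range(3):
            g1 = -0.5 * np.exp(lam) * c + 0.5 * y.size - hyper_prec * (lam - hyper_mean)
            g2 = -0.5 * np.exp(lam) * c - hyper_prec
            step = np.clip(-g1 / g2, -2.0, 2.0)
            if abs(step) < 1e-8:
                break
            F_l, Sigma_l, _ = obj.free_energy(mu, lam + step, g, jj,
                                              hyper_mean, hyper_prec)
            if np.isfinite(F_l) and F_l > F:
                lam += step
                dF += F_l - F
                F, Sigma = F_l, Sigma_l
            else:
                break
        f_trace.append(F)

        still = still + 1 if abs(dF) < tol else 0
        if still >= patience:
            break
    converged = still >= patience

    # assemble the full-size posterior (clamped parameters: zero variance)
    cov = np.zeros((layout.size, layout.size))
    cov[np.ix_(free, free)] = Sigma
    pred = predicted_csd_matrix(mu, layout, observed.freqs, check_stability=False)
    ve = variance_explained(CrossSpectra(observed.freqs, csd_n),
                            CrossSpectra(observed.freqs, pred))
    post = SubjectPosterior(mu, cov, float(F), ve, f_trace)
    if not converged:
        msg = f"variational Laplace did not converge in {max_iter} iterations"
        if on_nonconvergence == "raise":
            raise ConvergenceError(msg, f_trace, post)
        warnings.warn(msg, RuntimeWarning)
    return post


class SpectralDCM(BaseEstimator):
    """Subject-level spectral DCM, sklearn-style.

    ``fit`` takes either a :class:`CrossSpectra` or a regions x volumes
    time-series array (in which case ``dt`` must be given and the
    empirical spectra are estimated by the MAR route first).

    Attributes after fitting: ``mean_``, ``covariance_``,
    ``free_energy_``, ``variance_explained_``, ``posterior_``.
    """

    def __init__(self, n_regions: int = 8, prior_variances: dict | None = None,
                 n_freqs: int = 32, mar_order: int = 8,
                 hyper_mean: float = 6.0, hyper_var: float = 1.0 / 128.0,
                 max_iter: int = 128, tol: float = 1e-2,
                 on_nonconvergence: str = "raise"):
        self.n_regions = n_regions
        self.prior_variances = prior_variances
        self.n_freqs = n_freqs
        self.mar_order = mar_order
        self.hyper_mean = hyper_mean
        self.hyper_var = hyper_var
        self.max_iter = max_iter
        self.tol = tol
        self.on_nonconvergence = on_nonconvergence

    def fit(self, X, y=None, dt: float | None = None,
            prior: PriorDensity | None = None):
        from .spectra import default_frequency_grid, estimate_csd

        layout = ParamLayout(self.n_regions)
        if isinstance(X, CrossSpectra):
            observed = X
        else:
            if dt is None:
                raise ValueError("dt is required when fitting from time series")
            observed = estimate_csd(np.asarray(X), dt, order=self.mar_order,
                                    freqs=default_frequency_grid(self.n_freqs))
        if prior is None:
            prior = default_priors(layout, self.prior_variances)
        self.layout_ = layout
        self.prior_ = prior
        self.posterior_ = invert_subject(
            observed, prior, layout,
            hyper_mean=self.hyper_mean, hyper_var=self.hyper_var,
            max_iter=self.max_iter, tol=self.tol,
            on_nonconvergence=self.on_nonconvergence)
        self.mean_ = self.posterior_.mean
        self.covariance_ = self.posterior_.cov
        self.free_energy_ = self.posterior_.free_energy
        self.variance_explained_ = self.posterior_.variance_explained
        return self

    def predict(self, freqs: np.ndarray) -> np.ndarray:
        """Predicted cross-spectral matrices at the posterior mean."""
        return predicted_csd_matrix(self.mean_, self.layout_, np.asarray(freqs))
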