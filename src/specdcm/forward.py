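"""Generative mapping from DCM parameters to BOLD cross-spectral densities.

Neural dynamics are linear and stochastic, ``dx/dt = A x + u`` with
power-law endogenous fluctuations ``u``.  Each region's activity drives a
linearized balloon (hemodynamic) model whose output is the BOLD signal.
Because everything is linear, the model's second-order statistics are
available in closed form: at frequency f the predicted cross-spectral
density is

    S(f) = T(f) G_u(f) T(f)* + G_e(f)

where ``T(f) = diag(h(f)) (2*pi*i*f*I - A)^{-1}`` composes the neural and
hemodynamic transfer functions, ``G_u(f) = diag(amp_u * f**-exp_u)`` is
the neuronal fluctuation spectrum and ``G_e`` the observation-noise
spectrum.  All functions broadcast over a leading batch axis of parameter
vectors, which is what makes finite-difference Jacobians cheap.
"""

from __future__ import annotations

import numpy as np

from .params import ParamLayout

__all__ = [
    "HemodynamicConstants",
    "effective_jacobian",
    "transfer_function",
    "predicted_csd_matrix",
    "StabilityError",
]


class StabilityError(ValueError):
    """Raised when the neural Jacobian has a non-negative real eigenvalue."""


class HemodynamicConstants:
    """Canonical balloon-model constants (fixed, not estimated).

    kappa0: signal decay rate (1/s); gamma: flow autoregulation (1/s);
    tau0: venous transit time (s); alpha: Grubb vessel stiffness exponent;
    E0: resting oxygen extraction fraction; V0: resting venous volume
    (percent signal scale); TE: echo time (s); r0, nu0: susceptibility
    constants of the BOLD signal equation.
    """

    kappa0 = 0.64
    gamma = 0.32
    tau0 = 2.0
    alpha = 0.32
    E0 = 0.4
    V0 = 4.0
    TE = 0.03
    r0 = 25.0
    nu0 = 40.3

    #: baseline amplitude of the power-law noise spectra (both endogenous
    #: fluctuations and observation noise); log-amplitude parameters scale
    #: it.  Chosen so the prior-mean prediction has unit mean diagonal
    #: magnitude over the analysis band, which calibrates both the
    #: log-amplitude priors and the data-precision hyperprior for spectra
    #: normalized to unit scale.
    noise_floor = 5.6e-5


def effective_jacobian(theta: np.ndarray, layout: ParamLayout) -> np.ndarray:
    """Neural Jacobian A: couplings in Hz, diagonal ``-0.5*exp(a_self)``."""
    return layout.a_matrix(theta)


def max_real_eigenvalue(A: np.ndarray) -> np.ndarray:
    """Largest real part of the eigenvalues of A (batched)."""
    return np.linalg.eigvals(A).real.max(axis=-1)


def _hemo_transfer(kappa: np.ndarray, tau: np.ndarray, epsilon: np.ndarray,
                   freqs: np.ndarray, const: type[HemodynamicConstants]) -> np.ndarray:
    """Per-region scalar transfer from neural activity to BOLD.

    The balloon model linearized about its fixed point (s=0, f=v=q=1) is
    lower block-triangular in the state pairs (s,f) and (v,q), so the
    frequency response solves by substitution without any matrix algebra.

    kappa, tau: (..., n); epsilon: (...,); freqs: (nf,).
    Returns (..., nf, n) complex.
    """
    c = const
    a = 1.0 - c.E0
    w = 2j * np.pi * freqs  # (nf,)
    w = w[:, None]  # (nf, 1) to broadcast against regions
    kappa = kappa[..., None, :]  # (..., 1, n)
    tau = tau[..., None, :]
    eps = np.exp(epsilon)[..., None, None]

    # flow response: s'' = x - kappa s' - gamma (f - 1)
    z2 = 1.0 / (w**2 + kappa * w + c.gamma)  # d(flow)/d(x) in frequency domain
    # volume and deoxyhemoglobin responses
    m32 = 1.0 / tau
    m33 = -1.0 / (c.alpha * tau)
    m42 = (c.E0 + a * np.log(a)) / (c.E0 * tau)
    m43 = -(1.0 / c.alpha - 1.0) / tau
    m44 = -1.0 / tau
    z3 = m32 * z2 / (w - m33)
    z4 = (m42 * z2 + m43 * z3) / (w - m44)

    k1 = 4.3 * c.nu0 * c.E0 * c.TE
    k2 = eps * c.r0 * c.E0 * c.TE
    k3 = 1.0 - eps
    return c.V0 * ((k2 - k3) * z3 - (k1 + k2) * z4)


def transfer_function(theta: np.ndarray, layout: ParamLayout, freqs: np.ndarray,
                      hemodynamics: bool = True,
                      const: type[HemodynamicConstants] = HemodynamicConstants,
                      check_stability: bool = True) -> np.ndarray:
    """End-to-end transfer T(f) from fluctuations to observed signal.

    theta: (..., size); returns (..., nf, n, n) complex.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    freqs = np.asarray(freqs, dtype=float)
    A = layout.a_matrix(theta)
    if check_stability:
        if np.any(max_real_eigenvalue(A) > -1e-6):
            raise StabilityError("neural Jacobian is not stable (Re(eig) >= 0)")
    n = layout.n
    eye = np.eye(n)
    w = 2j * np.pi * freqs[:, None, None]  # (nf, 1, 1)
    M = w * eye - A[..., None, :, :]  # (..., nf, n, n)
    T = np.linalg.inv(M)
    if hemodynamics:
        kappa = const.kappa0 * np.exp(theta[..., layout.sl_decay])
        tau = const.tau0 * np.exp(theta[..., layout.sl_transit])
        h = _hemo_transfer(kappa, tau, theta[..., layout.idx_epsilon], freqs, const)
        T = h[..., :, :, None] * T  # diag(h) @ T
    return T


def noise_spectra(theta: np.ndarray, layout: ParamLayout, freqs: np.ndarray,
                  const: type[HemodynamicConstants] = HemodynamicConstants
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Power-law spectra (G_u, G_e), each (..., nf, n) real positive."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    f = np.asarray(freqs, dtype=float)[:, None]
    gu = const.noise_floor * np.exp(theta[..., layout.sl_u_amp])[..., None, :] \
        * f ** (-np.exp(theta[..., layout.sl_u_exp]))[..., None, :]
    ge = const.noise_floor * np.exp(theta[..., layout.sl_e_amp])[..., None, :] \
        * f ** (-np.exp(theta[..., layout.sl_e_exp]))[..., None, :]
    return gu, ge


def predicted_csd_matrix(theta: np.ndarray, layout: ParamLayout, freqs: np.ndarray,
                         hemodynamics: bool = True, observation_noise: bool = True,
                         const: type[HemodynamicConstants] = HemodynamicConstants,
                         check_stability: bool = True) -> np.ndarray:
    """Predicted cross-spectral density matrices.

    theta: (..., size) parameter vectors; returns (..., nf, n, n) complex,
    Hermitian with nonnegative diagonal at every frequency.
    """
    squeeze = np.asarray(theta).ndim == 1
    T = transfer_function(theta, layout, freqs, hemodynamics=hemodynamics,
                          const=const, check_stability=check_stability)
    gu, ge = noise_spectra(theta, layout, freqs, const=const)
    # T @ diag(gu) @ T^H
    S = np.einsum("...ik,...k,...jk->...ij", T, gu, np.conj(T))
    if observation_noise:
        n = layout.n
        idx = np.arange(n)
        S[..., idx, idx] += ge
    # enforce exact Hermitian symmetry against floating-point drift
    S = 0.5 * (S + np.conj(np.swapaxes(S, -1, -2)))
    return S[0] if squeeze else S
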