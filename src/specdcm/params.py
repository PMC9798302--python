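"""Parameter vectors and prior densities for the spectral DCM.

A subject-level model over ``n`` regions has, in this fixed order:

* ``n*(n-1)`` extrinsic couplings (Hz) — off-diagonal entries of the
  neural Jacobian, ordered by connection index (row-major over
  (destination, source), self pairs skipped);
* ``n`` intrinsic log-scalings — the self coupling of region i is
  ``-0.5 * exp(a_self_i)`` Hz, inherently inhibitory;
* ``n`` transit log-scalings and ``n`` decay log-scalings of the
  hemodynamic (balloon) model, one global log-scaling ``epsilon`` of the
  intra/extravascular signal ratio;
* per-region log amplitude and log exponent of the endogenous neuronal
  fluctuation spectrum ``G_u(f) = amp * f**(-exp)`` (2n parameters) and
  of the additive observation-noise spectrum ``G_e`` (2n parameters).

For the 8-region visual network this gives 56 + 8 + 17 + 32 = 113 free
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ParamLayout", "PriorDensity", "default_priors"]


@dataclass(frozen=True)
class ParamLayout:
    """Slice map of the flat parameter vector for an ``n``-region model."""

    n: int

    @property
    def n_extrinsic(self) -> int:
        return self.n * (self.n - 1)

    @property
    def size(self) -> int:
        return self.n_extrinsic + self.n + (2 * self.n + 1) + 4 * self.n

    def _block(self, offset: int, length: int) -> slice:
        return slice(offset, offset + length)

    @property
    def sl_a_off(self) -> slice:
        return self._block(0, self.n_extrinsic)

    @property
    def sl_a_self(self) -> slice:
        return self._block(self.n_extrinsic, self.n)

    @property
    def sl_transit(self) -> slice:
        return self._block(self.n_extrinsic + self.n, self.n)

    @property
    def sl_decay(self) -> slice:
        return self._block(self.n_extrinsic + 2 * self.n, self.n)

    @property
    def idx_epsilon(self) -> int:
        return self.n_extrinsic + 3 * self.n

    @property
    def sl_u_amp(self) -> slice:
        o = self.n_extrinsic + 3 * self.n + 1
        return self._block(o, self.n)

    @property
    def sl_u_exp(self) -> slice:
        o = self.n_extrinsic + 4 * self.n + 1
        return self._block(o, self.n)

    @property
    def sl_e_amp(self) -> slice:
        o = self.n_extrinsic + 5 * self.n + 1
        return self._block(o, self.n)

    @property
    def sl_e_exp(self) -> slice:
        o = self.n_extrinsic + 6 * self.n + 1
        return self._block(o, self.n)

    @property
    def sl_neural(self) -> slice:
        """The neural sub-vector (extrinsic + intrinsic) taken to the group level."""
        return self._block(0, self.n_extrinsic + self.n)

    # -- packing -----------------------------------------------------------
    def extrinsic_pairs(self) -> list[tuple[int, int]]:
        """(src, dst) pairs in connection-index order (8*dst + src, src != dst)."""
        return [(i % self.n, i // self.n) for i in range(self.n * self.n) if i % self.n != i // self.n]

    def a_matrix(self, theta: np.ndarray) -> np.ndarray:
        """Neural Jacobian for a batch of parameter vectors.

        ``theta``: (..., size).  Returns (..., n, n) with off-diagonal
        couplings in Hz and diagonal ``-0.5 * exp(a_self)``.
        """
        theta = np.asarray(theta, dtype=float)
        batch = theta.shape[:-1]
        A = np.zeros(batch + (self.n, self.n))
        a_off = theta[..., self.sl_a_off]
        for k, (src, dst) in enumerate(self.extrinsic_pairs()):
            A[..., dst, src] = a_off[..., k]
        diag = -0.5 * np.exp(theta[..., self.sl_a_self])
        idx = np.arange(self.n)
        A[..., idx, idx] = diag
        return A

    def connection_param_index(self, src: int, dst: int) -> int:
        """Position in the parameter vector of connection src -> dst."""
        if src == dst:
            return self.n_extrinsic + src  # intrinsic block follows extrinsic
        return self.extrinsic_pairs().index((src, dst))


@dataclass
class PriorDensity:
    """Gaussian prior/posterior over a flat parameter vector."""

    mean: np.ndarray
    cov: np.ndarray  # full matrix; diagonal priors simply carry a diagonal matrix

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValueError("covariance shape does not match mean")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")

    @property
    def size(self) -> int:
        return self.mean.size


#: default prior variances (one table; overridable through PipelineConfig)
DEFAULT_PRIOR_VARIANCES = {
    "a_off": 1.0 / 64.0,
    "a_self": 1.0 / 256.0,
    "transit": 1.0 / 256.0,
    "decay": 1.0 / 256.0,
    "epsilon": 1.0 / 256.0,
    "u_amp": 1.0 / 64.0,
    "u_exp": 1.0 / 64.0,
    "e_amp": 1.0 / 64.0,
    "e_exp": 1.0 / 64.0,
}


def default_priors(layout: ParamLayout, variances: dict | None = None) -> PriorDensity:
    """Shrinkage priors over the full parameter vector (zero means).

    Variances per block follow ``DEFAULT_PRIOR_VARIANCES`` unless
    overridden: extrinsic couplings N(0, 1/64) Hz^2; intrinsic, hemodynamic
    and epsilon log-scalings N(0, 1/256); noise log-amplitudes and
    log-exponents N(0, 1/64).
    """
    v = dict(DEFAULT_PRIOR_VARIANCES)
    if variances:
        unknown = set(variances) - set(v)
        if unknown:
            raise KeyError(f"unknown prior variance keys: {sorted(unknown)}")
        v.update(variances)
    var = np.empty(layout.size)
    var[layout.sl_a_off] = v["a_off"]
    var[layout.sl_a_self] = v["a_self"]
    var[layout.sl_transit] = v["transit"]
    var[layout.sl_decay] = v["decay"]
    var[layout.idx_epsilon] = v["epsilon"]
    var[layout.sl_u_amp] = v["u_amp"]
    var[layout.sl_u_exp] = v["u_exp"]
    var[layout.sl_e_amp] = v["e_amp"]
    var[layout.sl_e_exp] = v["e_exp"]
    return PriorDensity(np.zeros(layout.size), np.diag(var))
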