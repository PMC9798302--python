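"""Cross-spectral densities: container, empirical estimation, comparison.

The empirical route fits a multivariate autoregressive (MAR) model to the
detrended ROI time series by least squares and evaluates its parametric
cross-spectral density on the analysis frequency grid — the same
second-order summary the generative model predicts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CrossSpectra",
    "default_frequency_grid",
    "estimate_csd",
    "csd_to_vector",
    "variance_explained",
]

F_MIN = 0.0078  # Hz, lower edge of the resting-state analysis band
F_MAX = 0.1  # Hz, upper edge


def default_frequency_grid(n_points: int = 32, f_min: float = F_MIN,
                           f_max: float = F_MAX) -> np.ndarray:
    """Linearly spaced analysis frequencies in [0.0078, 0.1] Hz."""
    return np.linspace(f_min, f_max, n_points)


@dataclass
class CrossSpectra:
    """Complex n x n spectral-density matrices over a frequency grid."""

    freqs: np.ndarray  # (nf,) Hz, strictly increasing
    csd: np.ndarray  # (nf, n, n) complex, Hermitian per frequency

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.csd = np.asarray(self.csd, dtype=complex)
        if self.freqs.ndim != 1 or np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        nf = self.freqs.size
        if self.csd.shape[0] != nf or self.csd.shape[-1] != self.csd.shape[-2]:
            raise ValueError("csd must be (nf, n, n)")
        if not np.allclose(self.csd, np.conj(np.swapaxes(self.csd, -1, -2)),
                           atol=1e-8 * max(1.0, np.abs(self.csd).max())):
            raise ValueError("csd matrices must be Hermitian")

    @property
    def n_regions(self) -> int:
        return self.csd.shape[-1]

    # -- serialization (columnar: frequency, i, j, real, imag) -------------
    def to_frame(self) -> pd.DataFrame:
        nf, n, _ = self.csd.shape
        f, i, j = np.meshgrid(np.arange(nf), np.arange(n), np.arange(n), indexing="ij")
        return pd.DataFrame({
            "frequency": self.freqs[f.ravel()],
            "i": i.ravel(),
            "j": j.ravel(),
            "real": self.csd.real.ravel(),
            "imag": self.csd.imag.ravel(),
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CrossSpectra":
        df = pd.read_csv(path, sep="\t")
        freqs = np.unique(df["frequency"].to_numpy())
        n = int(df["i"].max()) + 1
        csd = np.zeros((freqs.size, n, n), dtype=complex)
        fidx = np.searchsorted(freqs, df["frequency"].to_numpy())
        csd[fidx, df["i"].to_numpy(), df["j"].to_numpy()] = (
            df["real"].to_numpy() + 1j * df["imag"].to_numpy())
        return cls(freqs, csd)


def estimate_csd(ts: np.ndarray, dt: float, order: int = 8,
                 freqs: np.ndarray | None = None) -> CrossSpectra:
    """Parametric (MAR) cross-spectral density of a multichannel series.

    ``ts`` is regions x volumes (already detrended).  A vector
    autoregression of the given order is fitted by ordinary least squares
    (statsmodels, no deterministic terms) and its spectrum

        S(f) = dt * H(f) Sigma H(f)^H,   H(f) = (I - sum_k A_k e^{-2 pi i f k dt})^{-1}

    is evaluated on ``freqs``.  Parametric MAR spectra are Hermitian and
    positive semidefinite by construction.
    """
    from statsmodels.tsa.api import VAR

    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("ts must be regions x volumes")
    n, t = ts.shape
    if t <= 8 * order:
        raise ValueError(f"need more than {8 * order} volumes for MAR order {order}")
    if freqs is None:
        freqs = default_frequency_grid()
    freqs = np.asarray(freqs, dtype=float)

    if n == 1:
        # statsmodels VAR requires >= 2 channels; univariate AR by OLS
        y = ts[0]
        X = np.column_stack([y[order - k - 1:t - k - 1] for k in range(order)])
        yy = y[order:]
        coefs, *_ = np.linalg.lstsq(X, yy, rcond=None)
        resid = yy - X @ coefs
        sigma = np.atleast_2d(resid @ resid / resid.size)
        A = coefs.reshape(order, 1, 1)
    else:
        res = VAR(ts.T).fit(maxlags=order, trend="n")
        if res.coefs.shape[0] < order or not np.all(np.isfinite(res.coefs)):
            raise np.linalg.LinAlgError("singular MAR fit")
        A = res.coefs  # (order, n, n)
        sigma = res.sigma_u_mle

    if not np.all(np.isfinite(sigma)):
        raise np.linalg.LinAlgError("singular MAR fit")

    eye = np.eye(n)
    k = np.arange(1, order + 1)
    # (nf, order) phase factors
    phase = np.exp(-2j * np.pi * freqs[:, None] * k[None, :] * dt)
    Af = np.tensordot(phase, A, axes=(1, 0))  # (nf, n, n)
    H = np.linalg.inv(eye - Af)
    S = dt * np.einsum("fik,kl,fjl->fij", H, sigma, np.conj(H))
    S = 0.5 * (S + np.conj(np.swapaxes(S, -1, -2)))
    return CrossSpectra(freqs, S)


_TRIU_CACHE: dict = {}


def _triu(n: int):
    if n not in _TRIU_CACHE:
        _TRIU_CACHE[n] = (np.triu_indices(n), np.triu_indices(n, k=1))
    return _TRIU_CACHE[n]


def csd_to_vector(csd: np.ndarray) -> np.ndarray:
    """Stack a (nf, n, n) Hermitian CSD into a real data vector.

    Uses the non-redundant half: real parts of the upper triangle including
    the diagonal, then imaginary parts of the strict upper triangle,
    concatenated across frequencies.
    """
    csd = np.asarray(csd)
    n = csd.shape[-1]
    (iu_r, ju_r), (iu_i, ju_i) = _triu(n)
    re = csd[..., iu_r, ju_r].real
    im = csd[..., iu_i, ju_i].imag
    return np.concatenate([re.reshape(*csd.shape[:-3], -1),
                           im.reshape(*csd.shape[:-3], -1)], axis=-1)


def variance_explained(observed: CrossSpectra, predicted: CrossSpectra) -> float:
    """Percent variance of the observed spectra explained by the prediction.

    100 * (1 - ||obs - pred||^2 / ||obs - mean(obs)||^2) over the stacked
    real/imaginary data vector.
    """
    if observed.freqs.size != predicted.freqs.size or \
            not np.allclose(observed.freqs, predicted.freqs):
        raise ValueError("observed and predicted spectra must share a grid")
    y = csd_to_vector(observed.csd)
    g = csd_to_vector(predicted.csd)
    denom = np.sum((y - y.mean()) ** 2)
    if denom <= 0:
        raise ZeroDivisionError("observed spectra have zero variance")
    return float(100.0 * (1.0 - np.sum((y - g) ** 2) / denom))
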