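"""Synthetic resting-state cohorts with a known hallucination effect.

The generator draws each subject's DCM parameters around group means
(non-hallucinators at the population pattern; hallucinators offset on the
named connections), pushes them through the generative model and emits
either sampled cross-spectra (a complex-Wishart perturbation of the true
spectral density — the default, matching what the analysis consumes) or
BOLD time series synthesized from the stationary spectrum.  Covariates
loosely match the cohort's demographics; hallucination severity is a
noisy linear readout of the subject's key connection strengths, so the
severity association the canonical variate analysis looks for exists by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .forward import max_real_eigenvalue, predicted_csd_matrix
from .network import NetworkSpec, build_visual_network
from .params import ParamLayout, default_priors
from .spectra import CrossSpectra, default_frequency_grid

__all__ = ["SimulationConfig", "SyntheticCohort", "default_effect_map",
           "default_commonalities", "simulate_cohort"]

#: intrinsic (self-connection) log-scale offset magnitude in the
#: hallucinating group; signs follow the reported group differences
INTRINSIC_OFFSET = 0.2


def default_effect_map() -> dict:
    """Group-difference offsets for hallucinators on named connections.

    Extrinsic offsets (Hz) reproduce the magnitude and direction of the
    six reported differences; intrinsic log-scale offsets carry the
    reported signs (right PFC and right hippocampus more self-inhibited,
    left PFC / left hippocampus / left LGN disinhibited).
    """
    m = {
        ("lLGN", "V1"): -0.39,
        ("lLGN", "medThal"): -0.32,
        ("lLGN", "lPFC"): +0.35,
        ("lPFC", "medThal"): +0.33,
        ("lPFC", "V1"): +0.38,
        ("rPFC", "V1"): -0.36,
    }
    for region, sign in (("rPFC", +1), ("rHC", +1),
                         ("lPFC", -1), ("lHC", -1), ("lLGN", -1)):
        m[(region, region)] = sign * INTRINSIC_OFFSET
    return m


def default_commonalities() -> dict:
    """Population-mean extrinsic couplings shared by both groups (Hz).

    Strongly positive interhemispheric coupling between homologous
    regions, positive geniculate and prefrontal input to V1, and mildly
    negative thalamic afferents to PFC.
    """
    m = {}
    for l, r in (("lLGN", "rLGN"), ("lHC", "rHC"), ("lPFC", "rPFC")):
        m[(l, r)] = 0.25
        m[(r, l)] = 0.25
    m[("lLGN", "V1")] = 0.20
    m[("rLGN", "V1")] = 0.20
    m[("lPFC", "V1")] = 0.15
    m[("rPFC", "V1")] = 0.15
    m[("medThal", "lPFC")] = -0.10
    m[("medThal", "rPFC")] = -0.10
    return m


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic cohort.

    Defaults mirror the acquisition (TR 3.36 s, 110 volumes of which the
    first five are discarded) and the analysis-scale recovery setting of
    20 subjects per group with between-subject variability of 0.1 Hz.
    """

    seed: int
    n_per_group: int = 20
    tr: float = 3.36
    volumes: int = 110
    discard: int = 5
    n_freqs: int = 32
    effect_map: dict | None = None  # None -> default_effect_map()
    commonalities: dict | None = None  # None -> default_commonalities()
    between_subject_sd: float = 0.1  # Hz, neural parameters
    parameter_jitter_scale: float = 1.0  # scales hemodynamic/noise prior draws
    wishart_dof: int | None = 40  # spectral sampling noise; None = noiseless
    observation_mode: str = "spectral"  # or "timeseries"
    severity_snr: float = 2.0  # amplitude SNR of the severity readout
    severity_scale: float = 30.0  # score units per Hz of weighted deviation
    severity_offset: float = 6.0
    max_resample: int = 50

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        if self.n_per_group < 1 or self.volumes <= self.discard:
            raise ValueError("invalid cohort dimensions")
        if self.observation_mode not in ("spectral", "timeseries"):
            raise ValueError("observation_mode must be 'spectral' or 'timeseries'")


@dataclass
class SyntheticCohort:
    """A generated cohort: truth, observations, covariates, motion traces."""

    config: SimulationConfig
    spec: NetworkSpec
    thetas: np.ndarray  # (n_subjects, n_params) true parameters
    spectra: list  # per-subject CrossSpectra
    timeseries: np.ndarray | None  # (n_subjects, 8, volumes) or None
    covariates: pd.DataFrame  # id, group, age, sex, severity
    fd: np.ndarray  # (n_subjects, volumes)
    n_resampled: int = 0
    key_connections: list = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.thetas)

    def truth_json(self) -> str:
        return json.dumps({
            "thetas": self.thetas.tolist(),
            "effect_map": {f"{s}->{d}": v for (s, d), v in
                           (self.config.effect_map or default_effect_map()).items()},
            "key_connections": self.key_connections,
            "n_resampled": self.n_resampled,
        })


def _apply_offsets(theta: np.ndarray, offsets: dict, spec: NetworkSpec,
                   layout: ParamLayout) -> None:
    for (src, dst), value in offsets.items():
        i, j = spec.region_index(src), spec.region_index(dst)
        theta[layout.connection_param_index(i, j)] += value


def _wishart_perturb(S: np.ndarray, dof: int, rng: np.random.Generator) -> np.ndarray:
    """Complex-Wishart sample with expectation S (per frequency)."""
    nf, n, _ = S.shape
    out = np.empty_like(S)
    for f in range(nf):
        # guard the Cholesky against tiny negative rounding
        L = np.linalg.cholesky(S[f] + 1e-12 * np.eye(n))
        Z = (rng.standard_normal((n, dof)) + 1j * rng.standard_normal((n, dof))) / np.sqrt(2)
        X = L @ Z
        out[f] = X @ X.conj().T / dof
    return out


def _synthesize_timeseries(theta: np.ndarray, layout: ParamLayout, tr: float,
                           volumes: int, rng: np.random.Generator) -> np.ndarray:
    """Stationary BOLD series with the model's spectral density.

    Frequency-domain synthesis: complex-normal Fourier coefficients shaped
    by a matrix square root of the predicted spectrum, inverse-FFT'd to a
    real series.  Exact for the stationary linear model (no integration
    bias).
    """
    n = layout.n
    freqs = np.fft.rfftfreq(volumes, d=tr)
    pos = freqs > 0
    S = np.zeros((freqs.size, n, n), dtype=complex)
    S[pos] = predicted_csd_matrix(theta, layout, freqs[pos], check_stability=False)
    coeff = np.zeros((freqs.size, n), dtype=complex)
    df = 1.0 / (volumes * tr)
    for f in np.flatnonzero(pos):
        vals, vecs = np.linalg.eigh(S[f])
        root = vecs * np.sqrt(np.clip(vals, 0, None) * df)
        z = (rng.standard_normal(n) + 1j * rng.standard_normal(n)) / np.sqrt(2)
        coeff[f] = root @ z
    ts = np.fft.irfft(coeff.T * volumes, n=volumes, axis=1)
    return ts


def simulate_cohort(config: SimulationConfig,
                    spec: NetworkSpec | None = None) -> SyntheticCohort:
    """Generate a cohort under the configured study conditions.

    Subjects are listed non-hallucinators first.  Unstable parameter
    draws (neural Jacobian with a non-negative eigenvalue) are resampled
    up to ``max_resample`` times and counted in ``n_resampled``.
    """
    if spec is None:
        spec = build_visual_network()
    layout = ParamLayout(spec.n_regions)
    rng = np.random.default_rng(config.seed)
    effects = config.effect_map if config.effect_map is not None else default_effect_map()
    common = (config.commonalities if config.commonalities is not None
              else default_commonalities())
    prior = default_priors(layout)
    prior_sd = np.sqrt(np.diag(prior.cov))

    base = np.zeros(layout.size)
    _apply_offsets(base, common, spec, layout)
    vh_mean = base.copy()
    _apply_offsets(vh_mean, effects, spec, layout)

    n = config.n_per_group
    groups = np.array([0] * n + [1] * n)
    n_sub = 2 * n
    sl_neural = layout.sl_neural
    jitter_idx = np.arange(sl_neural.stop, layout.size)

    thetas = np.empty((n_sub, layout.size))
    n_resampled = 0
    for i in range(n_sub):
        mean = vh_mean if groups[i] else base
        for attempt in range(config.max_resample + 1):
            theta = mean.copy()
            theta[sl_neural] += config.between_subject_sd * rng.standard_normal(
                sl_neural.stop - sl_neural.start)
            theta[jitter_idx] += (config.parameter_jitter_scale
                                  * prior_sd[jitter_idx]
                                  * rng.standard_normal(jitter_idx.size))
            if max_real_eigenvalue(layout.a_matrix(theta)) < -1e-6:
                break
            n_resampled += 1
        else:
            raise RuntimeError("could not draw a stable subject in "
                               f"{config.max_resample} attempts")
        thetas[i] = theta

    freqs = default_frequency_grid(config.n_freqs)
    spectra = []
    timeseries = None
    if config.observation_mode == "timeseries":
        timeseries = np.empty((n_sub, spec.n_regions, config.volumes))
    for i in range(n_sub):
        S = predicted_csd_matrix(thetas[i], layout, freqs, check_stability=False)
        if config.observation_mode == "spectral":
            if config.wishart_dof is not None:
                S = _wishart_perturb(S, config.wishart_dof, rng)
            S = 0.5 * (S + np.conj(np.swapaxes(S, -1, -2)))
            spectra.append(CrossSpectra(freqs, S))
        else:
            timeseries[i] = _synthesize_timeseries(
                thetas[i], layout, config.tr, config.volumes, rng)
            spectra.append(CrossSpectra(freqs, S))  # true spectra kept as truth

    # covariates loosely matching the cohort demographics
    age = np.where(groups == 0,
                   rng.normal(64.1, 7.8, n_sub), rng.normal(65.3, 8.8, n_sub))
    p_female = np.where(groups == 0, 31 / 75, 11 / 15)
    sex = (rng.random(n_sub) < p_female).astype(int)  # 1 = female

    key = [("lLGN", "V1"), ("lPFC", "V1"), ("rPFC", "V1"),
           ("lLGN", "lPFC"), ("lPFC", "medThal")]
    key_idx = [layout.connection_param_index(spec.region_index(s), spec.region_index(d))
               for s, d in key]
    w = np.array([effects.get(k, 0.0) for k in key])
    norm = np.linalg.norm(w)
    w = w / norm if norm > 0 else w
    deviation = (thetas[:, key_idx] - base[key_idx]) @ w
    signal_sd = max(config.between_subject_sd, 1e-12)
    noise_sd = signal_sd / config.severity_snr if config.severity_snr > 0 else 0.0
    severity = (config.severity_offset
                + config.severity_scale * (deviation + noise_sd * rng.standard_normal(n_sub)))
    severity[groups == 0] = 0.0

    fd = rng.gamma(shape=4.0, scale=0.03, size=(n_sub, config.volumes))

    covariates = pd.DataFrame({
        "id": [f"sub-{i:03d}" for i in range(n_sub)],
        "group": groups,
        "age": np.round(age, 1),
        "sex": sex,
        "severity": np.round(severity, 2),
    })
    return SyntheticCohort(config, spec, thetas, spectra, timeseries,
                           covariates, fd, n_resampled,
                           key_connections=[f"{s}->{d}" for s, d in key])
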