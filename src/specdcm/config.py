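"""Pipeline configuration: one validated, serializable mapping.

Unknown keys are rejected so that typos in a YAML file fail loudly rather
than silently fall back to defaults.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Everything the pipeline driver needs, with the analysis defaults."""

    seed: int = 1
    # cohort (ignored when cohort_dir points at pre-generated data)
    n_per_group: int = 20
    observation_mode: str = "spectral"
    between_subject_sd: float = 0.1
    wishart_dof: int | None = 40
    cohort_dir: str | None = None
    # acquisition / spectra
    tr: float = 3.36
    volumes: int = 110
    discard: int = 5
    n_freqs: int = 32
    mar_order: int = 8
    # QC thresholds (mm / proportion)
    qc_mean_fd: float = 0.3
    qc_spike_fd: float = 5.0
    qc_outlier_fd: float = 0.5
    qc_outlier_fraction: float = 0.30
    # inversion
    prior_variances: dict | None = None
    hyper_mean: float = 6.0
    hyper_var: float = 1.0 / 128.0
    max_iter: int = 128
    tol: float = 1e-2
    # second level
    prior_var_beta: float = 1.0 / 16.0
    log_precision_prior_var: float = 1.0 / 16.0
    # model space / reporting
    reporting_threshold: float = 0.95
    run_greedy: bool = True
    loo_k: int = 5
    verbosity: int = 1

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") \
            else json.loads(text)
        return cls.from_dict(data or {})

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]
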