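"""Plain-text file I/O for time series, covariates, cohorts and results.

Time series travel as TSV with a header of region names and the sampling
interval in a ``# dt = <seconds>`` comment line; covariates as CSV;
posteriors, model spaces and result bundles as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import NetworkSpec
from .spectra import CrossSpectra
from .synthesize import SimulationConfig, SyntheticCohort

__all__ = ["read_timeseries", "write_timeseries", "write_cohort", "read_cohort",
           "write_results"]


def write_timeseries(path, ts: np.ndarray, names, dt: float) -> None:
    """Write a regions x volumes matrix as TSV (regions are columns)."""
    path = Path(path)
    df = pd.DataFrame(np.asarray(ts).T, columns=list(names))
    with open(path, "w") as fh:
        fh.write(f"# dt = {dt!r}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_timeseries(path, spec: NetworkSpec | None = None):
    """Read a TSV time-series file; returns (regions x volumes, names, dt).

    Columns are reordered to the canonical network order when ``spec`` is
    given; a missing ``dt`` header or unknown region names raise.
    """
    path = Path(path)
    dt = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "dt" in first:
            dt = float(first.split("=")[1])
            df = pd.read_csv(fh, sep="\t")
        else:
            raise ValueError(f"{path}: missing '# dt = <seconds>' metadata line")
    if df.isna().any().any():
        raise ValueError(f"{path}: non-numeric or missing cells")
    names = list(df.columns)
    if spec is not None:
        canonical = [r.name for r in spec.regions]
        if set(names) != set(canonical):
            raise ValueError(f"{path}: region names {names} do not match the network")
        df = df[canonical]
        names = canonical
    return df.to_numpy().T.astype(float), names, dt


def write_cohort(cohort: SyntheticCohort, directory) -> Path:
    """Write a cohort as a directory of plain-text files."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    names = [r.name for r in cohort.spec.regions]
    cohort.covariates.to_csv(d / "covariates.csv", index=False)
    (d / "truth.json").write_text(cohort.truth_json())
    (d / "network.json").write_text(cohort.spec.to_json())
    cfg = {k: (v if not isinstance(v, dict) else
               {f"{a}->{b}": float(x) for (a, b), x in v.items()})
           for k, v in cohort.config.__dict__.items()}
    (d / "config.json").write_text(json.dumps(cfg, indent=2))
    pd.DataFrame(cohort.fd.T,
                 columns=cohort.covariates["id"]).to_csv(d / "fd.tsv", sep="\t",
                                                         index=False)
    for i, sid in enumerate(cohort.covariates["id"]):
        if cohort.timeseries is not None:
            write_timeseries(d / f"{sid}_timeseries.tsv",
                             cohort.timeseries[i], names, cohort.config.tr)
        else:
            cohort.spectra[i].to_tsv(d / f"{sid}_csd.tsv")
    return d


def read_cohort(directory) -> SyntheticCohort:
    """Read back a cohort directory written by :func:`write_cohort`."""
    d = Path(directory)
    spec = NetworkSpec.from_json((d / "network.json").read_text())
    cfg_raw = json.loads((d / "config.json").read_text())
    for key in ("effect_map", "commonalities"):
        if isinstance(cfg_raw.get(key), dict):
            cfg_raw[key] = {tuple(k.split("->")): v for k, v in cfg_raw[key].items()}
    config = SimulationConfig(**cfg_raw)
    covariates = pd.read_csv(d / "covariates.csv")
    truth = json.loads((d / "truth.json").read_text())
    thetas = np.asarray(truth["thetas"])
    fd = pd.read_csv(d / "fd.tsv", sep="\t").to_numpy().T
    spectra = []
    timeseries = None
    if (d / f"{covariates['id'][0]}_timeseries.tsv").exists():
        ts_list = []
        for sid in covariates["id"]:
            ts, _, _ = read_timeseries(d / f"{sid}_timeseries.tsv", spec)
            ts_list.append(ts)
        timeseries = np.asarray(ts_list)
    else:
        for sid in covariates["id"]:
            spectra.append(CrossSpectra.from_tsv(d / f"{sid}_csd.tsv"))
    return SyntheticCohort(config, spec, thetas, spectra, timeseries,
                           covariates, fd, truth.get("n_resampled", 0),
                           truth.get("key_connections", []))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    return obj


def write_results(bundle: dict, path) -> Path:
    """Serialize a results bundle to JSON (numpy/pandas made plain)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(bundle), indent=2))
    return path
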