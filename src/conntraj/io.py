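"""Readers and writers for the pipeline's on-disk dialects.

Connectivity travels either as long-format CSV (subject_id, region_i,
region_j, value) or as a wide HDF5 matrix with an /edge_index dataset;
covariates as CSV with mandatory columns subject_id, age, sex, site;
region time series as per-run TSV plus a one-column FD file, or a single
HDF5 container with groups /<subject>/<run>/{values,fd}.  Every fitted
run can write a JSON manifest recording seeds and thresholds.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .connectivity import ConnectivityDataset, RegionRun
from .model import PosteriorSamples

REQUIRED_COVARIATE_COLUMNS = ("subject_id", "age", "sex", "site")


def read_covariates(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_COVARIATE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"covariates file missing column(s): {missing}")
    return frame


def write_covariates(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_timeseries_run(values_path, fd_path, run_id: str = "") -> RegionRun:
    values = pd.read_csv(values_path, sep=None, engine="python", header=None).to_numpy(float)
    fd = pd.read_csv(fd_path, header=None).to_numpy(float).ravel()
    return RegionRun(values=values, frame_fd=fd, run_id=run_id or str(values_path))


def read_timeseries_h5(path) -> dict:
    """Load ``/<subject>/<run>/{values,fd}`` groups into nested dicts of runs."""
    out: dict = {}
    with h5py.File(path, "r") as h5:
        for subject in h5:
            runs = []
            for run in h5[subject]:
                grp = h5[subject][run]
                runs.append(
                    RegionRun(values=grp["values"][()], frame_fd=grp["fd"][()], run_id=run)
                )
            out[subject] = runs
    return out


def connectivity_to_long(dataset: ConnectivityDataset) -> pd.DataFrame:
    edges = dataset.edge_index
    n_sub, n_edge = dataset.F.shape
    return pd.DataFrame(
        {
            "subject_id": np.repeat(dataset.subject_ids, n_edge),
            "region_i": np.tile(edges[:, 0], n_sub),
            "region_j": np.tile(edges[:, 1], n_sub),
            "value": dataset.F.ravel(),
        }
    )


def write_connectivity_csv(dataset: ConnectivityDataset, path) -> None:
    connectivity_to_long(dataset).to_csv(path, index=False)


def read_connectivity_csv(path, covariates: pd.DataFrame) -> ConnectivityDataset:
    long = pd.read_csv(path)
    wide = long.pivot_table(
        index="subject_id", columns=["region_i", "region_j"], values="value", sort=True
    )
    cov = covariates.set_index("subject_id").loc[wide.index]
    edges = np.array([list(c) for c in wide.columns])
    return ConnectivityDataset(
        F=wide.to_numpy(),
        site=cov["site"].to_numpy(),
        edge_index=edges,
        subject_ids=wide.index.to_numpy(),
    )


def write_connectivity_h5(dataset: ConnectivityDataset, path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("F", data=dataset.F)
        h5.create_dataset("edge_index", data=dataset.edge_index)
        h5.create_dataset("site", data=dataset.site)
        h5.create_dataset("subject_ids", data=np.asarray(dataset.subject_ids))


def read_connectivity_h5(path) -> ConnectivityDataset:
    with h5py.File(path, "r") as h5:
        return ConnectivityDataset(
            F=h5["F"][()],
            site=h5["site"][()],
            edge_index=h5["edge_index"][()],
            subject_ids=h5["subject_ids"][()],
        )


def write_samples_h5(samples: PosteriorSamples, path) -> None:
    with h5py.File(path, "w") as h5:
        grp = h5.create_group("samples")
        for name in ("B", "labels", "p", "sigma2", "delta2", "iterations"):
            grp.create_dataset(name, data=getattr(samples, name))


def read_samples_h5(path) -> PosteriorSamples:
    with h5py.File(path, "r") as h5:
        grp = h5["samples"]
        return PosteriorSamples(**{k: grp[k][()] for k in grp})


def write_manifest(path, **entries) -> None:
    """JSON run manifest (seed, thresholds, iteration counts, versions)."""
    from . import __version__

    payload = {"conntraj_version": __version__, **entries}
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
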