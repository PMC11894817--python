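"""Edge-level functional connectivity: Pearson correlations from region
time series, Fisher z transformation, and per-edge standardization.

A subject's connectivity is computed per fMRI run on motion-retained
frames (framewise displacement below a threshold), correlations are
averaged across runs on the r scale, and Fisher z is applied afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class RegionRun:
    """One fMRI run for one subject: T x R region signals plus per-frame FD (mm)."""

    values: np.ndarray
    frame_fd: np.ndarray
    run_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_fd = np.asarray(self.frame_fd, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x R matrix")
        if self.frame_fd.shape != (self.values.shape[0],):
            raise ValueError("frame_fd length must match the number of frames")
        if np.any(self.frame_fd < 0):
            raise ValueError("framewise displacement must be nonnegative")


def edge_pairs(n_regions: int) -> np.ndarray:
    """Canonical edge ordering: pairs (i, j) with i > j, 0-based, E x 2."""
    i, j = np.tril_indices(n_regions, k=-1)
    return np.column_stack([i, j])


def _corr_matrix(frames: np.ndarray, run_id: str) -> np.ndarray:
    sd = frames.std(axis=0)
    scale = np.maximum(1.0, np.abs(frames).max(axis=0))
    bad = np.flatnonzero(sd <= 1e-12 * scale)
    if bad.size:
        raise ValueError(
            f"zero-variance signal for region(s) {bad.tolist()} in run '{run_id}'; "
            "correlation undefined"
        )
    return np.corrcoef(frames, rowvar=False)


def compute_region_fc(
    runs: list[RegionRun], fd_threshold: float = 0.2
) -> tuple[np.ndarray, np.ndarray]:
    """Run-averaged Pearson correlations for every region pair of one subject.

    Frames with FD >= ``fd_threshold`` are censored; a run needs at least two
    retained frames to contribute, otherwise it is excluded with a warning.
    Per-run correlation matrices are arithmetically averaged on the r scale.

    Returns
    -------
    rho : length-E vector of run-averaged correlations in canonical edge order.
    pairs : E x 2 array of (i, j) region indices with i > j.
    """
    if not runs:
        raise ValueError("no runs supplied")
    n_regions = runs[0].values.shape[1]
    if n_regions < 2:
        raise ValueError("need at least two regions")
    if any(r.values.shape[1] != n_regions for r in runs):
        raise ValueError("all runs must share the same number of regions")

    mats = []
    for run in runs:
        keep = run.frame_fd < fd_threshold
        if keep.sum() < 2:
            warnings.warn(
                f"run '{run.run_id}' has {int(keep.sum())} frames below "
                f"FD {fd_threshold} mm; excluded",
                stacklevel=2,
            )
            continue
        mats.append(_corr_matrix(run.values[keep], run.run_id))
    if not mats:
        raise ValueError("all runs excluded by the FD threshold")

    avg = np.mean(mats, axis=0)
    pairs = edge_pairs(n_regions)
    return avg[pairs[:, 0], pairs[:, 1]], pairs


def fisher_z(rho: np.ndarray, clip_eps: float = 1e-7) -> np.ndarray:
    """Fisher z transform ``0.5 [ln(1+rho) - ln(1-rho)]``.

    Correlations are clamped to ``[-1 + clip_eps, 1 - clip_eps]`` so that
    perfect correlations map to large finite values.
    """
    rho = np.asarray(rho, dtype=float)
    if not np.all(np.isfinite(rho)):
        raise ValueError("non-finite correlation input")
    if np.any(np.abs(rho) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    clipped = np.clip(rho, -1.0 + clip_eps, 1.0 - clip_eps)
    return np.arctanh(clipped)


@dataclass
class EdgeCorrelations:
    """Subjects x E correlations and their Fisher-z values."""

    rho: np.ndarray
    edge_index: np.ndarray
    phi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rho = np.atleast_2d(np.asarray(self.rho, dtype=float))
        if self.phi is None:
            self.phi = fisher_z(self.rho)


def standardize_edges(phi: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and scale every edge column to mean 0 / unit sample variance.

    Returns the standardized matrix together with the per-edge (mean, sd)
    used, which are retained for reporting only.
    """
    phi = np.asarray(phi, dtype=float)
    mean = phi.mean(axis=0)
    sd = phi.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd <= 1e-12 * np.maximum(1.0, np.abs(phi).max(axis=0)))
    if bad.size:
        raise ValueError(f"constant edge column(s): {bad.tolist()}")
    return (phi - mean) / sd, mean, sd


@dataclass
class ConnectivityDataset:
    """Harmonized, standardized Fisher-z connectivity with site labels.

    ``F`` is subjects x E with each column standardized to mean 0 and unit
    sample variance; ``site`` holds integer site labels with 0 the
    reference site.
    """

    F: np.ndarray
    site: np.ndarray
    edge_index: np.ndarray
    subject_ids: np.ndarray | None = None
    edge_mean: np.ndarray | None = None
    edge_scale: np.ndarray | None = None
    region_ids: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.site = np.asarray(self.site)
        if self.F.shape[0] != self.site.shape[0]:
            raise ValueError("site labels must match the number of subjects")
        if self.subject_ids is None:
            self.subject_ids = np.arange(self.F.shape[0])

    @property
    def n_subjects(self) -> int:
        return self.F.shape[0]

    @property
    def n_edges(self) -> int:
        return self.F.shape[1]

    @property
    def n_regions(self) -> int:
        return int(self.edge_index.max()) + 1

    @property
    def n_sites(self) -> int:
        return int(np.unique(self.site).size)
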