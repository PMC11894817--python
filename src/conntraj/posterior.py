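"""Posterior summaries: cluster assignment, trajectory bands, network
subdivision and reporting filters."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignMatrix
from .model import PosteriorSamples

UNASSIGNED = -1


@dataclass
class ClusterAssignment:
    """Posterior mean labels and the hard >0.5-rule assignment."""

    mbar: np.ndarray  # R x K posterior label means
    hard_labels: np.ndarray  # cluster id, or UNASSIGNED
    region_ids: np.ndarray

    @property
    def n_unassigned(self) -> int:
        return int((self.hard_labels == UNASSIGNED).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.region_ids,
                "cluster": self.hard_labels,
                "mbar_max": self.mbar.max(axis=1),
            }
        )


def assign_clusters(samples: PosteriorSamples, region_ids=None) -> ClusterAssignment:
    """Average the one-hot labels over retained draws; a region is assigned
    to cluster k* only when its mean label there strictly exceeds 0.5."""
    n, R = samples.labels.shape
    K = samples.n_clusters
    mbar = np.zeros((R, K))
    for k in range(K):
        mbar[:, k] = (samples.labels == k).mean(axis=0)
    best = mbar.argmax(axis=1)
    hard = np.where(mbar[np.arange(R), best] > 0.5, best, UNASSIGNED)
    if region_ids is None:
        region_ids = np.arange(R)
    return ClusterAssignment(mbar=mbar, hard_labels=hard, region_ids=np.asarray(region_ids))


@dataclass
class TrajectoryWithBands:
    """Per cluster pair and sex: posterior-mean FC curve with pointwise
    2.5/97.5-percentile bands over the retained draws."""

    ages: np.ndarray
    pairs: list  # list of (k1, k2)
    mean: dict = field(default_factory=dict)  # (k1,k2,sex) -> (q,)
    lower: dict = field(default_factory=dict)
    upper: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (k1, k2) in self.pairs:
            for sex, name in ((0, "female"), (1, "male")):
                key = (k1, k2, sex)
                rows.append(
                    pd.DataFrame(
                        {
                            "cluster_i": k1,
                            "cluster_j": k2,
                            "sex": name,
                            "age": self.ages,
                            "mean": self.mean[key],
                            "lo": self.lower[key],
                            "hi": self.upper[key],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def estimate_trajectories(
    samples: PosteriorSamples,
    ages: np.ndarray,
    design: DesignMatrix,
    pairs: list | None = None,
) -> TrajectoryWithBands:
    """Posterior-mean curves (from the across-draw average coefficients)
    and pointwise percentile bands (from the per-draw curves)."""
    ages = np.asarray(ages, dtype=float)
    K = samples.n_clusters
    if pairs is None:
        pairs = [(k1, k2) for k1 in range(K) for k2 in range(k1, K)]
    x_rows = {0: design.rows_for_ages(ages, sex=0), 1: design.rows_for_ages(ages, sex=1)}
    bands = TrajectoryWithBands(ages=ages, pairs=list(pairs))
    b_bar = samples.B.mean(axis=0)  # (5, K, K)
    for (k1, k2) in pairs:
        beta_draws = samples.B[:, :, k1, k2]  # (n, 5)
        for sex in (0, 1):
            curves = beta_draws @ x_rows[sex].T  # (n, q)
            key = (k1, k2, sex)
            bands.mean[key] = x_rows[sex] @ b_bar[:, k1, k2]
            bands.lower[key] = np.percentile(curves, 2.5, axis=0)
            bands.upper[key] = np.percentile(curves, 97.5, axis=0)
    return bands


def reportable_pairs(
    assignment: ClusterAssignment,
    edge_index: np.ndarray,
    selected: np.ndarray | None = None,
    min_connections: int = 4,
) -> list:
    """Cluster pairs linked by at least ``min_connections`` selected edges
    between assigned regions (the practical-significance reporting rule)."""
    labels = assignment.hard_labels
    edges = edge_index if selected is None else edge_index[selected]
    counts: dict = {}
    for i, j in edges:
        ki, kj = labels[i], labels[j]
        if ki == UNASSIGNED or kj == UNASSIGNED:
            continue
        key = (min(ki, kj), max(ki, kj))
        counts[key] = counts.get(key, 0) + 1
    return sorted(k for k, c in counts.items() if c >= min_connections)


def subdivide_by_network(
    assignment: ClusterAssignment, network_map: dict | pd.Series
) -> pd.DataFrame:
    """Split clusters spanning several functional networks into
    single-network subclusters.

    Every assigned region must have a network label.  Final cluster names
    are ``{network}-{letter}`` with letters assigned per network in
    descending region-count order (ties broken by original cluster id).
    Returns a frame with columns region, network, cluster, subcluster.
    """
    network_map = dict(network_map)
    rows = []
    for region, cluster in zip(assignment.region_ids, assignment.hard_labels):
        if cluster == UNASSIGNED:
            continue
        if region not in network_map:
            raise ValueError(f"region {region!r} has no network label")
        rows.append((region, network_map[region], int(cluster)))
    frame = pd.DataFrame(rows, columns=["region", "network", "cluster"])

    groups = (
        frame.groupby(["network", "cluster"])
        .size()
        .rename("n_regions")
        .reset_index()
    )
    labels = {}
    for network, block in groups.groupby("network"):
        ordered = block.sort_values(
            ["n_regions", "cluster"], ascending=[False, True]
        ).reset_index(drop=True)
        for rank, row in ordered.iterrows():
            suffix = chr(ord("a") + rank)
            labels[(network, row["cluster"])] = f"{network}-{suffix}"
    frame["subcluster"] = [
        labels[(net, clu)] for net, clu in zip(frame["network"], frame["cluster"])
    ]
    return frame


def report_filter(
    clusters: pd.DataFrame,
    min_regions: int = 4,
    min_size: int = 500,
    sizes: dict | pd.Series | None = None,
    by: str = "subcluster",
) -> pd.DataFrame:
    """Keep clusters with at least ``min_regions`` regions OR whose total
    region size (e.g. grayordinate count) reaches ``min_size``."""
    frame = clusters.copy()
    if sizes is not None:
        sizes = dict(sizes)
        frame["size"] = frame["region"].map(sizes)
        if frame["size"].isna().any() and min_size is not None:
            warnings.warn("missing region sizes treated as 0", stacklevel=2)
            frame["size"] = frame["size"].fillna(0)
    kept = []
    for name, block in frame.groupby(by):
        ok = len(block) >= min_regions
        if not ok and sizes is not None:
            ok = block["size"].sum() >= min_size
        if ok:
            kept.append(block)
    if not kept:
        return frame.iloc[0:0]
    return pd.concat(kept).sort_index()
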