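"""Spectral initialization of the region clustering.

Each region pair's fitted trajectory (female curve followed by male
curve) is a vector of length 2q.  Two regions i and j are similar when,
for third regions k, the trajectories of (i,k) and (j,k) are correlated;
the similarity phi_ij is the arithmetic mean of those correlations over
all k not in {i, j}.  The resulting R x R symmetric matrix is clustered
spectrally, with the number of clusters picked by the largest eigengap
of the symmetric-normalized Laplacian unless fixed by the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .edgewise import EdgewiseResults


@dataclass
class InitialClustering:
    n_clusters: int
    labels: np.ndarray
    eigenvalues: np.ndarray | None = None
    eigengaps: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = np.bincount(self.labels, minlength=self.n_clusters)
        if np.any(counts == 0):
            warnings.warn("empty cluster in the initial labeling", stacklevel=2)


def trajectory_tensor(
    results: EdgewiseResults, ages: np.ndarray, n_regions: int | None = None
) -> np.ndarray:
    """R x R x 2q tensor of per-pair trajectory vectors (symmetric in i,j)."""
    edges = results.model.edge_index
    if n_regions is None:
        n_regions = int(edges.max()) + 1
    vecs = results.trajectory_vectors(ages)  # E x 2q
    V = np.zeros((n_regions, n_regions, vecs.shape[1]))
    V[edges[:, 0], edges[:, 1]] = vecs
    V[edges[:, 1], edges[:, 0]] = vecs
    return V


def _row_correlations(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation of corresponding rows of A and B; constant rows -> nan."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    na = np.sqrt((Ac**2).sum(axis=1))
    nb = np.sqrt((Bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Ac * Bc).sum(axis=1) / (na * nb)


def similarity_matrix(V: np.ndarray) -> np.ndarray:
    """R x R trajectory-similarity matrix Psi.

    ``Psi[i, j]`` is the mean over k not in {i, j} of the correlation
    between the (i,k) and (j,k) trajectory vectors.  Terms where either
    vector is constant are skipped (with a warning) and the divisor
    reduced.  The diagonal is set to 1 and is not meaningful.
    """
    R = V.shape[0]
    if R < 3:
        raise ValueError("need at least 3 regions")
    psi = np.eye(R)
    skipped = 0
    for i in range(R):
        for j in range(i + 1, R):
            ks = [k for k in range(R) if k != i and k != j]
            corrs = _row_correlations(V[i, ks], V[j, ks])
            valid = np.isfinite(corrs)
            skipped += int((~valid).sum())
            if not valid.any():
                raise ValueError(f"no valid similarity terms for regions ({i}, {j})")
            psi[i, j] = psi[j, i] = corrs[valid].mean()
    if skipped:
        warnings.warn(
            f"{skipped} constant trajectory vector term(s) skipped", stacklevel=2
        )
    return psi


def spectral_cluster(
    psi: np.ndarray,
    n_clusters: int | None = None,
    k_range: tuple[int, int] | None = None,
    seed: int = 0,
    n_init: int = 50,
    affinity: str = "exp",
    bandwidth: float = 0.5,
) -> InitialClustering:
    """Spectral clustering of the similarity matrix.

    The correlation-valued matrix is mapped to a nonnegative affinity:
    ``exp(-(1 - psi)/bandwidth)`` by default, which sends perfectly
    similar regions to 1 while uncorrelated or anticorrelated trajectory
    families decay toward 0 (``affinity="shift"`` uses the order-preserving
    linear map ``(psi + 1)/2`` instead, which keeps uncorrelated pairs at
    affinity 0.5 and blurs the spectrum when between-cluster trajectory
    correlations are moderate).  The diagonal is zeroed.  Eigenvalues of
    the symmetric-normalized Laplacian are computed; if ``n_clusters`` is
    not given it is chosen as the largest eigengap within ``k_range``
    (default ``2..min(60, R-1)``).  Regions are embedded in the bottom-K
    eigenvectors, row-normalized, and clustered by k-means with
    ``n_init`` restarts at a fixed seed.
    """
    psi = np.asarray(psi, dtype=float)
    R = psi.shape[0]
    if not np.allclose(psi, psi.T, atol=1e-12):
        raise ValueError("similarity matrix must be symmetric")
    if n_clusters is not None and n_clusters > R:
        raise ValueError(f"n_clusters={n_clusters} exceeds the number of regions {R}")

    if affinity == "exp":
        W = np.exp(-(1.0 - psi) / bandwidth)
    elif affinity == "shift":
        W = (psi + 1.0) / 2.0
    else:
        raise ValueError("affinity must be 'exp' or 'shift'")
    np.fill_diagonal(W, 0.0)
    deg = W.sum(axis=1)
    # isolated nodes get unit degree so the Laplacian stays defined
    deg = np.where(deg > 0, deg, 1.0)
    d_isqrt = 1.0 / np.sqrt(deg)
    L = np.eye(R) - d_isqrt[:, None] * W * d_isqrt[None, :]
    evals, evecs = np.linalg.eigh(L)

    if k_range is None:
        k_range = (2, min(60, R - 1))
    kmin, kmax = k_range
    gaps = {k: float(evals[k] - evals[k - 1]) for k in range(kmin, kmax + 1)}
    if n_clusters is None:
        best = max(gaps, key=gaps.get)
        if gaps[best] < 1e-8:
            warnings.warn(
                "no meaningful eigengap; falling back to the minimum cluster count",
                stacklevel=2,
            )
            best = kmin
        n_clusters = best

    U = evecs[:, :n_clusters]
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    U = U / np.where(norms > 0, norms, 1.0)
    km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed).fit(U)
    return InitialClustering(
        n_clusters=n_clusters,
        labels=km.labels_,
        eigenvalues=evals,
        eigengaps=gaps,
    )
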