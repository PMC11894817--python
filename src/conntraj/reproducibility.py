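"""Split-half reproducibility of trajectory estimates and edge selection.

The cohort is divided into pairs of disjoint, roughly equal halves; the
independent edge regression is refitted in each half and per-edge
concatenated (female, male) trajectory vectors are compared by Pearson
correlation.  Edge-selection agreement between halves is summarized by
the Szymkiewicz-Simpson overlap coefficient.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .design import build_design
from .edgewise import EdgewiseRegression


def split_half(
    n_subjects: int, n_splits: int = 50, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random ~50/50 partitions of subject indices; disjoint, exhaustive,
    sizes differing by at most one."""
    if n_subjects < 20:
        raise ValueError("need at least 20 subjects to split")
    rng = np.random.default_rng(seed)
    half = n_subjects // 2
    out = []
    for _ in range(n_splits):
        perm = rng.permutation(n_subjects)
        out.append((np.sort(perm[:half]), np.sort(perm[half:])))
    return out


def trajectory_correlation(vecs1: np.ndarray, vecs2: np.ndarray) -> np.ndarray:
    """Per-edge Pearson correlation between two sets of trajectory vectors
    (E x 2q each); constant vectors yield NaN with a warning."""
    vecs1 = np.atleast_2d(vecs1)
    vecs2 = np.atleast_2d(vecs2)
    if vecs1.shape != vecs2.shape:
        raise ValueError("trajectory sets must share shape (same age grid)")
    a = vecs1 - vecs1.mean(axis=1, keepdims=True)
    b = vecs2 - vecs2.mean(axis=1, keepdims=True)
    na = np.sqrt((a**2).sum(axis=1))
    nb = np.sqrt((b**2).sum(axis=1))
    bad = (na == 0) | (nb == 0)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} constant trajectory vector(s): correlation undefined",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=1) / (na * nb)
    r[bad] = np.nan
    return r


def overlap_coefficient(set_a, set_b) -> float:
    """|A n B| / min(|A|, |B|) (Szymkiewicz-Simpson)."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("overlap coefficient undefined for empty sets")
    return len(a & b) / min(len(a), len(b))


def split_half_study(
    F: np.ndarray,
    covariates: pd.DataFrame,
    ages: np.ndarray,
    n_splits: int = 50,
    r2_threshold: float = 0.10,
    seed: int = 0,
) -> dict:
    """Independent-regression reproducibility over random half splits.

    For each division, both halves get their own standardized design and
    edge fits; per-edge trajectory correlations are recorded, as are the
    R^2-selected edge sets of the two halves and their overlap
    coefficient.

    Returns a dict with ``correlations`` (n_splits x E), ``overlap``
    (length n_splits), and the full-data selection for reference.
    """
    F = np.asarray(F, dtype=float)
    splits = split_half(F.shape[0], n_splits=n_splits, seed=seed)
    corrs = np.empty((n_splits, F.shape[1]))
    overlaps = np.empty(n_splits)

    full_design = build_design(covariates["age"].to_numpy(), covariates["sex"].to_numpy())
    full_sel = EdgewiseRegression(F, full_design).fit().select_by_r2(r2_threshold)

    for r, (idx1, idx2) in enumerate(splits):
        halves = []
        for idx in (idx1, idx2):
            design = build_design(
                covariates["age"].to_numpy()[idx], covariates["sex"].to_numpy()[idx]
            )
            res = EdgewiseRegression(F[idx], design).fit()
            halves.append(res)
        v1 = halves[0].trajectory_vectors(ages)
        v2 = halves[1].trajectory_vectors(ages)
        corrs[r] = trajectory_correlation(v1, v2)
        sel1 = np.flatnonzero(halves[0].select_by_r2(r2_threshold))
        sel2 = np.flatnonzero(halves[1].select_by_r2(r2_threshold))
        overlaps[r] = (
            overlap_coefficient(sel1, sel2) if sel1.size and sel2.size else np.nan
        )
    return {
        "correlations": corrs,
        "overlap": overlaps,
        "full_selection": np.flatnonzero(full_sel),
    }
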