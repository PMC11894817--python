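"""Parametric empirical-Bayes batch harmonization (ComBat).

Removes additive (location) and multiplicative (scale) site effects from
feature columns, shrinking per-site estimates toward pooled priors:
normal for locations, inverse-gamma for scales, with prior
hyperparameters fitted by the method of moments and the conditional
posterior means found by fixed-point iteration (Johnson, Li & Rabinovic,
2007).  Sites are batches; rows are subjects; columns are features
(edges).
"""

from __future__ import annotations

import warnings

import numpy as np


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(
    sdat: np.ndarray,
    g_hat: np.ndarray,
    d_hat: np.ndarray,
    g_bar: float,
    t2: float,
    a: float,
    b: float,
    conv: float = 1e-4,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-point iteration for the EB posterior means (gamma*, delta*)."""
    n = sdat.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((sdat - g_new) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2 + a - 1)
        change = max(
            np.abs(g_new - g_old).max() / np.abs(g_old).max() if np.abs(g_old).max() else 0.0,
            np.abs(d_new - d_old).max() / d_old.max(),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_harmonize(
    phi: np.ndarray,
    site: np.ndarray,
    covariates: np.ndarray | None = None,
) -> np.ndarray:
    """Harmonize subjects x E feature matrix across sites.

    Parameters
    ----------
    phi : subjects x E matrix (e.g. Fisher-z connectivity).
    site : length-S site labels (any hashable values).
    covariates : optional S x p matrix of biological covariates whose
        effects are estimated alongside the site means and restored after
        adjustment (e.g. the age/sex design columns).

    Returns
    -------
    Harmonized matrix of the same shape.  With a single site the input is
    returned unchanged (there is no batch effect to remove).
    """
    phi = np.asarray(phi, dtype=float)
    site = np.asarray(site)
    if phi.ndim != 2:
        raise ValueError("phi must be a subjects x features matrix")
    if site.shape != (phi.shape[0],):
        raise ValueError("site must have one label per subject")

    levels, batch = np.unique(site, return_inverse=True)
    n_batch = levels.size
    if n_batch == 1:
        warnings.warn("single site: nothing to harmonize", stacklevel=2)
        return phi.copy()
    counts = np.bincount(batch)
    singletons = levels[counts < 2]
    if singletons.size:
        raise ValueError(f"site(s) with fewer than 2 subjects: {singletons.tolist()}")

    n, n_feat = phi.shape
    onehot = np.zeros((n, n_batch))
    onehot[np.arange(n), batch] = 1.0
    design = onehot if covariates is None else np.hstack([onehot, np.asarray(covariates, float)])

    # Feature-wise OLS of data on [batch one-hot | covariates].
    b_hat, *_ = np.linalg.lstsq(design, phi, rcond=None)
    grand_mean = (counts / n) @ b_hat[:n_batch]
    resid = phi - design @ b_hat
    var_pooled = (resid**2).mean(axis=0)
    if np.any(var_pooled == 0):
        raise ValueError("feature(s) with zero pooled variance")

    stand_mean = np.tile(grand_mean, (n, 1))
    if covariates is not None:
        stand_mean = stand_mean + np.asarray(covariates, float) @ b_hat[n_batch:]
    s_data = (phi - stand_mean) / np.sqrt(var_pooled)

    # Per-site location/scale estimates on the standardized data.
    gamma_hat = np.stack([s_data[batch == i].mean(axis=0) for i in range(n_batch)])
    delta_hat = np.stack([s_data[batch == i].var(axis=0, ddof=1) for i in range(n_batch)])
    if np.any(delta_hat <= 1e-20):
        i, j = np.argwhere(delta_hat <= 1e-20)[0]
        raise ValueError(f"edge {j} is constant within site {levels[i]!r}")

    adjusted = np.empty_like(s_data)
    for i in range(n_batch):
        g_bar = gamma_hat[i].mean()
        t2 = gamma_hat[i].var(ddof=1)
        a, b = _aprior(delta_hat[i]), _bprior(delta_hat[i])
        g_star, d_star = _it_sol(
            s_data[batch == i], gamma_hat[i], delta_hat[i], g_bar, t2, a, b
        )
        adjusted[batch == i] = (s_data[batch == i] - g_star) / np.sqrt(d_star)

    return adjusted * np.sqrt(var_pooled) + stand_mean
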