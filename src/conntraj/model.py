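"""The clustering-enabled regression model and its Gibbs sampler.

Each of R regions carries a latent cluster label; an edge (i, j) inherits
its five regression coefficients from the K x K symmetric coefficient
matrices B_1..B_5 indexed by the endpoint clusters.  Edge noise is
normal with a per-edge variance sigma2_ij inflated by a per-site
multiplier delta2_{d,ij}, with the reference site's multiplier fixed at
1 for identifiability.  Priors: labels are multinomial with Dirichlet
mixture weights; coefficients are normal with inverse-gamma variances;
all variances are inverse-gamma.

All full conditionals are conjugate and are sampled in the fixed sweep
order xi2, sigma2, delta2, B, p, m.  The conditional derivations are
validated by a Geweke getting-it-right suite and by enumeration/GLS
oracles in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .design import DesignMatrix

_VAR_FLOOR = 1e-300


@dataclass
class GibbsConfig:
    """Sampler settings; ``rho0``/``varrho0`` are the inverse-gamma prior
    shapes-and-rates for coefficient variances and noise variances."""

    n_iter: int = 2000
    n_burn: int = 1000
    seed: int = 0
    rho0: float = 0.01
    varrho0: float = 1e-6
    rho0_rate: float | None = None  # None -> rho0 (the IG(rho0, rho0) prior)
    varrho0_rate: float | None = None  # None -> varrho0
    alpha: float | None = None  # Dirichlet concentration; None -> 1/K
    update_order: str = "ascending"  # or "random"

    @property
    def xi2_rate(self) -> float:
        return self.rho0 if self.rho0_rate is None else self.rho0_rate

    @property
    def var_rate(self) -> float:
        return self.varrho0 if self.varrho0_rate is None else self.varrho0_rate

    def __post_init__(self) -> None:
        if self.n_burn >= self.n_iter:
            raise ValueError("n_burn must be smaller than n_iter")
        if self.rho0 <= 0 or self.varrho0 <= 0:
            raise ValueError("hyperparameters must be positive")


@dataclass
class ClusterModelState:
    """One configuration of all model parameters."""

    labels: np.ndarray  # (R,) ints in 0..K-1
    B: np.ndarray  # (5, K, K), each slice symmetric
    sigma2: np.ndarray  # (E,)
    delta2: np.ndarray  # (D, E); row 0 identically 1
    p: np.ndarray  # (K,)
    xi2: np.ndarray  # (5, K, K), each slice symmetric

    def copy(self) -> "ClusterModelState":
        return ClusterModelState(
            labels=self.labels.copy(),
            B=self.B.copy(),
            sigma2=self.sigma2.copy(),
            delta2=self.delta2.copy(),
            p=self.p.copy(),
            xi2=self.xi2.copy(),
        )

    def validate(self) -> None:
        if not np.allclose(self.B, np.transpose(self.B, (0, 2, 1))):
            raise ValueError("B slices must be symmetric")
        if np.any(self.sigma2 <= 0) or np.any(self.delta2 <= 0) or np.any(self.xi2 <= 0):
            raise ValueError("variances must be positive")
        if not np.allclose(self.delta2[0], 1.0):
            raise ValueError("reference-site variance multiplier must equal 1")


@dataclass
class PosteriorSamples:
    """Retained post-burn-in Gibbs draws of every parameter block."""

    B: np.ndarray  # (n, 5, K, K)
    labels: np.ndarray  # (n, R)
    p: np.ndarray  # (n, K)
    sigma2: np.ndarray  # (n, E)
    delta2: np.ndarray  # (n, D, E)
    iterations: np.ndarray  # (n,) original sweep indices

    @property
    def n_draws(self) -> int:
        return self.B.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.B.shape[2]


def _tril_pairs(K: int) -> list[tuple[int, int]]:
    return [(k1, k2) for k1 in range(K) for k2 in range(k1 + 1)]


def _symmetrize_draw(draw_fn, K: int, shape_extra: tuple, rng) -> np.ndarray:
    out = np.empty(shape_extra + (K, K))
    for k1, k2 in _tril_pairs(K):
        v = draw_fn(k1, k2)
        out[..., k1, k2] = v
        out[..., k2, k1] = v
    return out


def _inv_gamma(rng: np.random.Generator, shape, rate):
    """Inverse-gamma draw in shape/rate parameterization with underflow guard."""
    g = rng.gamma(shape, 1.0 / np.asarray(rate, dtype=float))
    return 1.0 / np.maximum(g, _VAR_FLOOR)


class ClusterTrajectoryModel:
    """Bayesian node-clustered edge regression.

    Parameters
    ----------
    endog : subjects x E matrix of (screened) standardized connectivity.
    design : standardized five-predictor :class:`DesignMatrix`.
    site : length-S integer site labels, 0 = reference site.
    edge_index : E x 2 region indices (0-based, within the modeled regions).
    n_clusters : K.
    config : :class:`GibbsConfig`.
    """

    def __init__(
        self,
        endog: np.ndarray,
        design: DesignMatrix,
        site: np.ndarray,
        edge_index: np.ndarray,
        n_clusters: int,
        config: GibbsConfig | None = None,
        n_regions: int | None = None,
    ):
        self.design = design
        self.X = np.asarray(design.X, dtype=float)
        self.site = np.asarray(site, dtype=int)
        self.edge_index = np.asarray(edge_index, dtype=int)
        self.K = int(n_clusters)
        self.config = config or GibbsConfig()

        self.n_sites = int(self.site.max()) + 1
        self.n_regions = (
            int(self.edge_index.max()) + 1 if n_regions is None else int(n_regions)
        )
        self._site_masks = [self.site == d for d in range(self.n_sites)]
        self._site_counts = np.array([m.sum() for m in self._site_masks])
        if np.any(self._site_counts == 0):
            warnings.warn("site(s) with no subjects; their multipliers follow the prior",
                          stacklevel=2)
        self._XtX_site = np.stack(
            [self.X[m].T @ self.X[m] for m in self._site_masks]
        )  # (D, 5, 5)
        # incident selected edges per region
        self._incident: list[tuple[np.ndarray, np.ndarray]] = []
        for i in range(self.n_regions):
            hit = np.flatnonzero((self.edge_index == i).any(axis=1))
            partners = np.where(
                self.edge_index[hit, 0] == i,
                self.edge_index[hit, 1],
                self.edge_index[hit, 0],
            )
            if hit.size == 0:
                warnings.warn(
                    f"region {i} has no incident selected edges; its label is "
                    "drawn from the mixture weights alone",
                    stacklevel=2,
                )
            self._incident.append((hit, partners))
        self.set_endog(endog)

    # -- data ---------------------------------------------------------------

    def set_endog(self, endog: np.ndarray) -> None:
        endog = np.asarray(endog, dtype=float)
        if endog.shape != (self.X.shape[0], self.edge_index.shape[0]):
            raise ValueError("endog shape must be subjects x edges")
        self.endog = endog
        self._XtF_site = np.stack(
            [self.X[m].T @ endog[m] for m in self._site_masks]
        )  # (D, 5, E)

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[0]

    @property
    def alpha(self) -> float:
        return self.config.alpha if self.config.alpha is not None else 1.0 / self.K

    # -- model algebra ------------------------------------------------------

    def mean_matrix(self, state: ClusterModelState) -> np.ndarray:
        """Fitted means, subjects x E, from the cluster-pair coefficients."""
        li = state.labels[self.edge_index[:, 0]]
        lj = state.labels[self.edge_index[:, 1]]
        return self.X @ state.B[:, li, lj]

    def _weights(self, state: ClusterModelState) -> np.ndarray:
        """Inverse noise variances 1/(sigma2_e * delta2_{d_s,e}), subjects x E."""
        return 1.0 / (state.sigma2[None, :] * state.delta2[self.site, :])

    def log_likelihood(self, state: ClusterModelState) -> float:
        var = state.sigma2[None, :] * state.delta2[self.site, :]
        if np.any(var <= 0):
            raise ValueError("non-positive noise variance")
        r = self.endog - self.mean_matrix(state)
        return float(-0.5 * (np.log(2 * np.pi * var) + r**2 / var).sum())

    def simulate_endog(self, state: ClusterModelState, rng: np.random.Generator) -> np.ndarray:
        """Draw a response matrix from the model at the given parameters."""
        sd = np.sqrt(state.sigma2[None, :] * state.delta2[self.site, :])
        return self.mean_matrix(state) + rng.normal(size=(self.n_subjects, self.n_edges)) * sd

    # -- prior --------------------------------------------------------------

    def prior_draw(self, rng: np.random.Generator) -> ClusterModelState:
        cfg = self.config
        K, E, D = self.K, self.n_edges, self.n_sites
        p = rng.dirichlet(np.full(K, self.alpha))
        labels = rng.choice(K, size=self.n_regions, p=p)
        xi2 = _symmetrize_draw(
            lambda a, b: _inv_gamma(rng, cfg.rho0, np.full(5, cfg.xi2_rate)), K, (5,), rng
        )
        B = np.zeros((5, K, K))
        for k1, k2 in _tril_pairs(K):
            v = rng.normal(size=5) * np.sqrt(xi2[:, k1, k2])
            B[:, k1, k2] = v
            B[:, k2, k1] = v
        sigma2 = _inv_gamma(rng, cfg.varrho0, np.full(E, cfg.var_rate))
        delta2 = np.ones((D, E))
        for d in range(1, D):
            delta2[d] = _inv_gamma(rng, cfg.varrho0, np.full(E, cfg.var_rate))
        return ClusterModelState(labels=labels, B=B, sigma2=sigma2,
                                 delta2=delta2, p=p, xi2=xi2)

    # -- full conditionals ---------------------------------------------------

    def sample_xi2(self, state: ClusterModelState, rng: np.random.Generator) -> None:
        cfg = self.config
        shape = cfg.rho0 + 0.5
        for k1, k2 in _tril_pairs(self.K):
            rate = cfg.xi2_rate + 0.5 * state.B[:, k1, k2] ** 2
            v = _inv_gamma(rng, shape, rate)
            state.xi2[:, k1, k2] = v
            state.xi2[:, k2, k1] = v

    def sample_sigma2(self, state: ClusterModelState, rng: np.random.Generator) -> None:
        cfg = self.config
        r2 = (self.endog - self.mean_matrix(state)) ** 2
        scaled = (r2 / state.delta2[self.site, :]).sum(axis=0)
        state.sigma2 = _inv_gamma(
            rng, cfg.varrho0 + 0.5 * self.n_subjects, cfg.var_rate + 0.5 * scaled
        )

    def sample_delta2(self, state: ClusterModelState, rng: np.random.Generator) -> None:
        cfg = self.config
        r2 = (self.endog - self.mean_matrix(state)) ** 2
        for d in range(1, self.n_sites):
            mask = self._site_masks[d]
            n_d = self._site_counts[d]
            rate = cfg.var_rate + 0.5 * (r2[mask] / state.sigma2[None, :]).sum(axis=0)
            state.delta2[d] = _inv_gamma(rng, cfg.varrho0 + 0.5 * n_d, rate)
        state.delta2[0] = 1.0  # reference site never sampled

    def beta_conditional(
        self, state: ClusterModelState, k1: int, k2: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Conditional mean and covariance of the 5-vector beta_{k1 k2}.

        The conditional is the generalized-least-squares posterior formed
        from all selected edges whose endpoint clusters are {k1, k2},
        with the normal prior N(0, diag(xi2)).
        """
        li = state.labels[self.edge_index[:, 0]]
        lj = state.labels[self.edge_index[:, 1]]
        if k1 == k2:
            in_pair = (li == k1) & (lj == k1)
        else:
            in_pair = ((li == k1) & (lj == k2)) | ((li == k2) & (lj == k1))
        prec = np.diag(1.0 / state.xi2[:, k1, k2])
        rhs = np.zeros(5)
        if in_pair.any():
            e_idx = np.flatnonzero(in_pair)
            inv_var = 1.0 / (state.sigma2[e_idx][None, :] * state.delta2[:, e_idx])  # (D, Ep)
            prec = prec + np.einsum("d,dab->ab", inv_var.sum(axis=1), self._XtX_site)
            rhs = np.einsum("dae,de->a", self._XtF_site[:, :, e_idx], inv_var)
        cov = np.linalg.inv(prec)
        return cov @ rhs, cov

    def sample_beta(self, state: ClusterModelState, rng: np.random.Generator) -> None:
        for k1, k2 in _tril_pairs(self.K):
            mean, cov = self.beta_conditional(state, k1, k2)
            try:
                L = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    f"singular conditional precision for cluster pair ({k1},{k2})"
                ) from err
            draw = mean + L @ rng.normal(size=5)
            state.B[:, k1, k2] = draw
            state.B[:, k2, k1] = draw

    def sample_p(self, state: ClusterModelState, rng: np.random.Generator) -> None:
        counts = np.bincount(state.labels, minlength=self.K)
        state.p = rng.dirichlet(self.alpha + counts)

    def label_logits(self, state: ClusterModelState, i: int) -> np.ndarray:
        """Unnormalized log conditional probabilities of region i's label.

        Sums, for each candidate cluster k, log p_k and the quadratic part
        of the log-likelihood of every selected edge incident to i (the
        variance terms do not depend on k and cancel).
        """
        e_idx, partners = self._incident[i]
        logits = np.log(np.maximum(state.p, _VAR_FLOOR)).copy()
        if e_idx.size == 0:
            return logits
        lj = state.labels[partners]
        W = self._weights(state)[:, e_idx]  # (S, Ei)
        F_i = self.endog[:, e_idx]
        for k in range(self.K):
            mu = self.X @ state.B[:, k, lj]  # (S, Ei)
            logits[k] += -0.5 * ((F_i - mu) ** 2 * W).sum()
        return logits

    def label_conditional_probs(self, state: ClusterModelState, i: int) -> np.ndarray:
        logits = self.label_logits(state, i)
        logits = logits - logits.max()
        probs = np.exp(logits)
        return probs / probs.sum()

    def sample_m(self, state: ClusterModelState, rng: np.random.Generator) -> None:
        order = np.arange(self.n_regions)
        if self.config.update_order == "random":
            order = rng.permutation(order)
        for i in order:
            probs = self.label_conditional_probs(state, i)
            state.labels[i] = rng.choice(self.K, p=probs)

    # -- sweep and fit -------------------------------------------------------

    def sweep(self, state: ClusterModelState, rng: np.random.Generator) -> None:
        """One Gibbs sweep in the order xi2, sigma2, delta2, B, p, m."""
        self.sample_xi2(state, rng)
        self.sample_sigma2(state, rng)
        self.sample_delta2(state, rng)
        self.sample_beta(state, rng)
        self.sample_p(state, rng)
        self.sample_m(state, rng)

    def initial_state(
        self,
        init_labels: np.ndarray,
        edge_params: np.ndarray | None = None,
        edge_resid_var: np.ndarray | None = None,
    ) -> ClusterModelState:
        """Initial parameter values from edge-fit MLEs and spectral labels.

        B starts at the average of the per-edge OLS coefficients over the
        edges in each cluster pair (0 where a pair has no edges), sigma2
        at the per-edge residual variances, delta2 and xi2 at 1.
        """
        labels = np.array(init_labels, dtype=int)  # copy: the sampler mutates labels in place
        if labels.shape != (self.n_regions,) or labels.max() >= self.K:
            raise ValueError("init labels inconsistent with the model dimensions")
        K, E, D = self.K, self.n_edges, self.n_sites
        B = np.zeros((5, K, K))
        if edge_params is not None:
            li, lj = labels[self.edge_index[:, 0]], labels[self.edge_index[:, 1]]
            for k1, k2 in _tril_pairs(K):
                if k1 == k2:
                    sel = (li == k1) & (lj == k1)
                else:
                    sel = ((li == k1) & (lj == k2)) | ((li == k2) & (lj == k1))
                if sel.any():
                    avg = edge_params[:, sel].mean(axis=1)
                    B[:, k1, k2] = avg
                    B[:, k2, k1] = avg
        sigma2 = (
            np.ones(E) if edge_resid_var is None else np.maximum(edge_resid_var, 1e-8)
        )
        counts = np.bincount(labels, minlength=K)
        p = (counts + self.alpha) / (counts.sum() + K * self.alpha)
        return ClusterModelState(
            labels=labels,
            B=B,
            sigma2=sigma2,
            delta2=np.ones((D, E)),
            p=p,
            xi2=np.ones((5, K, K)),
        )

    def fit(
        self,
        init_labels: np.ndarray,
        edge_params: np.ndarray | None = None,
        edge_resid_var: np.ndarray | None = None,
    ):
        """Run the Gibbs sampler and return a results object."""
        from .results import ClusterTrajectoryResults

        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        state = self.initial_state(init_labels, edge_params, edge_resid_var)
        n_keep = cfg.n_iter - cfg.n_burn
        K, E, D, R = self.K, self.n_edges, self.n_sites, self.n_regions
        out = PosteriorSamples(
            B=np.empty((n_keep, 5, K, K)),
            labels=np.empty((n_keep, R), dtype=int),
            p=np.empty((n_keep, K)),
            sigma2=np.empty((n_keep, E)),
            delta2=np.empty((n_keep, D, E)),
            iterations=np.arange(cfg.n_burn, cfg.n_iter),
        )
        for it in range(cfg.n_iter):
            self.sweep(state, rng)
            if not np.isfinite(state.B).all() or not np.isfinite(state.sigma2).all():
                raise FloatingPointError(f"sampler diverged at iteration {it}")
            if it >= cfg.n_burn:
                j = it - cfg.n_burn
                out.B[j] = state.B
                out.labels[j] = state.labels
                out.p[j] = state.p
                out.sigma2[j] = state.sigma2
                out.delta2[j] = state.delta2
        return ClusterTrajectoryResults(model=self, samples=out)
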