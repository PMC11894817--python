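"""Simulation studies validating the sampler and pipeline.

These are the package's own correctness experiments: a Geweke
getting-it-right comparison for the Gibbs sampler, planted-truth
parameter recovery for the full pipeline, frequentist calibration of the
mass-univariate screen, credible-band coverage, and split-half
reproducibility.  The test suite and the acceptance script both run
them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .design import build_design
from .edgewise import EdgewiseRegression
from .model import ClusterTrajectoryModel, GibbsConfig, _tril_pairs
from .pipeline import DEFAULT_AGES, run_pipeline
from .reproducibility import split_half_study
from .synthetic import (
    GroundTruth,
    generate_covariates,
    generate_fc,
    make_scenario,
)

# ---------------------------------------------------------------------------
# Geweke getting-it-right
# ---------------------------------------------------------------------------


def _ess(x: np.ndarray) -> float:
    """Effective sample size via Geyer's initial positive sequence."""
    x = np.asarray(x, dtype=float)
    n = x.size
    x = x - x.mean()
    if np.allclose(x, 0):
        return float(n)
    acov = np.correlate(x, x, mode="full")[n - 1 :] / n
    rho = acov / acov[0]
    tau = 1.0
    for k in range(1, n // 2):
        gamma = rho[2 * k - 1] + rho[2 * k]
        if gamma <= 0:
            break
        tau += 2.0 * gamma
    return n / tau


def _geweke_model(
    rho0: float = 3.0,
    varrho0: float = 3.0,
    rho0_rate: float = 0.03,
    varrho0_rate: float = 3.0,
    seed: int = 0,
):
    """Tiny fully-connected instance: R=6 regions, K=2, S=20 subjects, D=2."""
    S, R = 20, 6
    rng = np.random.default_rng(seed)
    ages = np.linspace(10, 95, S) + rng.uniform(-1, 1, S)
    sex = np.tile([0, 1], S // 2)
    site = np.tile([0, 1], S // 2)
    design = build_design(ages, sex)
    from .connectivity import edge_pairs

    edges = edge_pairs(R)
    cfg = GibbsConfig(
        n_iter=2, n_burn=1, seed=seed, rho0=rho0, varrho0=varrho0,
        rho0_rate=rho0_rate, varrho0_rate=varrho0_rate,
    )
    model = ClusterTrajectoryModel(
        endog=np.zeros((S, edges.shape[0])),
        design=design,
        site=site,
        edge_index=edges,
        n_clusters=2,
        config=cfg,
    )
    return model


def _geweke_functionals(model: ClusterTrajectoryModel, state) -> dict:
    K = model.K
    tril = _tril_pairs(K)
    b_vals = np.array([state.B[:, k1, k2] for k1, k2 in tril]).ravel()
    xi_vals = np.array([state.xi2[:, k1, k2] for k1, k2 in tril]).ravel()
    log_sig = np.log(state.sigma2)
    log_del = np.log(state.delta2[1])
    out = {
        "B_mean": b_vals.mean(),
        "B_sq": (b_vals**2).mean(),
        "log_xi2": np.log(xi_vals).mean(),
        "log_xi2_sq": (np.log(xi_vals) ** 2).mean(),
        "log_sigma2": log_sig.mean(),
        "log_sigma2_sq": (log_sig**2).mean(),
        "log_delta2": log_del.mean(),
        "log_delta2_sq": (log_del**2).mean(),
        "p0": state.p[0],
        "p0_sq": state.p[0] ** 2,
        "label0_frac": float((state.labels == 0).mean()),
    }
    return out


def geweke_study(
    n_draws: int = 10000,
    seed: int = 0,
    rho0: float = 3.0,
    varrho0: float = 3.0,
    rho0_rate: float = 0.03,
    varrho0_rate: float = 3.0,
) -> pd.DataFrame:
    """Successive-conditional vs direct prior simulation.

    The Gibbs sweep alternated with data refreshment has the prior as its
    stationary marginal over parameters; moments of scalar functionals of
    every parameter block are compared against iid prior draws, with the
    chain's autocorrelation absorbed into the standard error through an
    effective sample size.  The validation instance uses inverse-gamma
    shapes of 3 (so every compared functional has finite fourth moments,
    which the study-analysis priors' shapes below 1 do not give) and a
    small coefficient-variance rate so that coefficient blocks stay
    comparable across clusters and the label chain actually mixes; the
    sampler code paths are identical at any hyperparameter values.
    """
    model = _geweke_model(
        rho0=rho0, varrho0=varrho0, rho0_rate=rho0_rate,
        varrho0_rate=varrho0_rate, seed=seed,
    )
    rng = np.random.default_rng(seed + 1)

    prior_rows = []
    for _ in range(n_draws):
        prior_rows.append(_geweke_functionals(model, model.prior_draw(rng)))
    prior = pd.DataFrame(prior_rows)

    state = model.prior_draw(rng)
    chain_rows = []
    for _ in range(n_draws):
        model.set_endog(model.simulate_endog(state, rng))
        model.sweep(state, rng)
        chain_rows.append(_geweke_functionals(model, state))
    chain = pd.DataFrame(chain_rows)

    rows = []
    for col in chain.columns:
        c, p = chain[col].to_numpy(), prior[col].to_numpy()
        se = np.sqrt(c.var(ddof=1) / _ess(c) + p.var(ddof=1) / p.size)
        rows.append(
            {
                "functional": col,
                "chain_mean": c.mean(),
                "prior_mean": p.mean(),
                "z": (c.mean() - p.mean()) / se,
            }
        )
    return pd.DataFrame(rows).set_index("functional")


# ---------------------------------------------------------------------------
# Planted-truth recovery
# ---------------------------------------------------------------------------


def _match_clusters(true_labels: np.ndarray, fitted_labels: np.ndarray, K: int) -> np.ndarray:
    """Map true cluster id -> fitted cluster id by maximal overlap."""
    conf = np.zeros((K, K))
    for t, f in zip(true_labels, fitted_labels):
        if f >= 0:
            conf[t, f] += 1
    rows, cols = linear_sum_assignment(-conf)
    mapping = np.arange(K)
    mapping[rows] = cols
    return mapping


def recovery_study(
    seed: int = 0,
    scenario: str = "well_separated_K3",
    n_iter: int = 800,
    n_burn: int = 400,
    r2_threshold: float = 0.10,
    k_range: tuple[int, int] = (2, 8),
) -> dict:
    """Full-pipeline parameter recovery on a planted-cluster scenario.

    Returns the adjusted Rand index of the posterior hard labels against
    the planted labels, the maximum absolute error of the posterior-mean
    coefficients after cluster matching, and the eigengap-selected K.
    """
    truth, cov = make_scenario(scenario)
    dataset = generate_fc(truth, cov, seed=seed)
    cfg = GibbsConfig(n_iter=n_iter, n_burn=n_burn, seed=seed + 1)
    out = run_pipeline(
        dataset,
        cov,
        r2_threshold=r2_threshold,
        config=cfg,
        k_range=k_range,
        spectral_seed=seed,
    )
    K = truth.n_clusters
    assign = out.results.assign_clusters()
    fitted = assign.hard_labels
    true_sub = truth.labels[out.modeled_regions]
    ari = adjusted_rand_score(true_sub, fitted)

    b_err = np.nan
    if out.init.n_clusters == K:
        mapping = _match_clusters(true_sub, fitted, K)
        b_hat = out.results.posterior_mean_B()
        b_mapped = b_hat[:, mapping][:, :, mapping]
        b_err = float(np.abs(b_mapped - truth.B).max())
    return {
        "ari": float(ari),
        "max_beta_error": b_err,
        "selected_K": int(out.init.n_clusters),
        "n_unassigned": int(assign.n_unassigned),
        "pipeline": out,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# Mass-univariate calibration
# ---------------------------------------------------------------------------


def type1_error_study(
    seed: int = 0, n_edges: int = 10000, n_subjects: int = 1000, alpha: float = 0.05
) -> dict:
    """Empirical size of the age-group partial F-test on pure-noise edges."""
    rng = np.random.default_rng(seed)
    cov = generate_covariates(n_subjects, seed=seed + 1)
    design = build_design(cov["age"].to_numpy(), cov["sex"].to_numpy())
    F = rng.normal(size=(n_subjects, n_edges))
    res = EdgewiseRegression(F, design).fit()
    return {
        "type1_rate": float((res.pvalues_age < alpha).mean()),
        "pvalues": res.pvalues_age,
    }


def fdr_study(
    seed: int = 0,
    n_edges: int = 5000,
    n_reps: int = 200,
    n_subjects: int = 500,
    null_frac: float = 0.9,
    q: float = 0.01,
) -> dict:
    """Realized false discovery rate of BH selection on a null/signal mix."""
    rng = np.random.default_rng(seed)
    cov = generate_covariates(n_subjects, seed=seed + 1)
    design = build_design(cov["age"].to_numpy(), cov["sex"].to_numpy())
    n_null = int(round(null_frac * n_edges))
    n_sig = n_edges - n_null
    beta_sig = np.array([0.35, 0.15, 0.0, 0.10, 0.05])
    fdp = np.empty(n_reps)
    power = np.empty(n_reps)
    is_null = np.zeros(n_edges, dtype=bool)
    is_null[:n_null] = True
    signal = np.zeros((n_subjects, n_edges))
    signal[:, n_null:] = np.tile((design.X @ beta_sig)[:, None], (1, n_sig))
    for r in range(n_reps):
        F = signal + rng.normal(size=(n_subjects, n_edges))
        res = EdgewiseRegression(F, design).fit()
        rej = res.fdr_select("age", q=q)
        n_rej = rej.sum()
        fdp[r] = (rej & is_null).sum() / max(n_rej, 1)
        power[r] = (rej & ~is_null).sum() / n_sig
    return {
        "realized_fdr": float(fdp.mean()),
        "mean_power": float(power.mean()),
        "nominal_q": q,
    }


# ---------------------------------------------------------------------------
# Credible-band coverage
# ---------------------------------------------------------------------------


def coverage_study(
    seed: int = 0,
    n_reps: int = 50,
    n_iter: int = 500,
    n_burn: int = 250,
    ages: np.ndarray = DEFAULT_AGES,
) -> dict:
    """Pointwise 95% band coverage of the true population-mean curves.

    Replicated draws from the moderate-signal two-cluster scenario are
    pushed through screening, spectral initialization and the Gibbs
    sampler; coverage is pooled over replicates, cluster pairs, sexes and
    grid ages.
    """
    truth, cov = make_scenario("coverage_moderate")
    K = truth.n_clusters
    covered = 0
    total = 0
    for r in range(n_reps):
        dataset = generate_fc(truth, cov, seed=seed * 10007 + r)
        cfg = GibbsConfig(n_iter=n_iter, n_burn=n_burn, seed=seed * 31 + r)
        out = run_pipeline(
            dataset, cov, r2_threshold=0.10, n_clusters=K, config=cfg,
            spectral_seed=seed + r,
        )
        assign = out.results.assign_clusters()
        mapping = _match_clusters(
            truth.labels[out.modeled_regions], assign.hard_labels, K
        )
        bands = out.results.trajectories(ages)
        for k1 in range(K):
            for k2 in range(k1, K):
                f1, f2 = mapping[k1], mapping[k2]
                key_pair = (min(f1, f2), max(f1, f2))
                for sex in (0, 1):
                    x = out.design.rows_for_ages(ages, sex=sex)
                    true_curve = x @ truth.B[:, k1, k2]
                    lo = bands.lower[key_pair + (sex,)]
                    hi = bands.upper[key_pair + (sex,)]
                    covered += int(((true_curve >= lo) & (true_curve <= hi)).sum())
                    total += true_curve.size
    return {"coverage": covered / total, "n_reps": n_reps}


# ---------------------------------------------------------------------------
# Split-half reproducibility
# ---------------------------------------------------------------------------


def reproducibility_study(
    seed: int = 0,
    n_splits: int = 20,
    ages: np.ndarray = DEFAULT_AGES,
    effect_scales: tuple[float, float] = (1.0, 2.0),
) -> dict:
    """Split-half trajectory correlation at implied R^2 = 10% and
    monotonicity of the selection overlap in effect size."""
    truth, cov = make_scenario("r2_ten_percent")
    medians = {}
    overlaps = {}
    for scale in effect_scales:
        scaled = GroundTruth(
            labels=truth.labels,
            B=truth.B * scale,
            sigma2=truth.sigma2,
            delta2=truth.delta2,
            edge_index=truth.edge_index,
            age_range=truth.age_range,
            sex_balance=truth.sex_balance,
            site_probs=truth.site_probs,
        )
        dataset = generate_fc(scaled, cov, seed=seed + 7)
        study = split_half_study(
            dataset.F, cov, ages, n_splits=n_splits, r2_threshold=0.10, seed=seed
        )
        medians[scale] = float(np.nanmedian(study["correlations"]))
        overlaps[scale] = float(np.nanmedian(study["overlap"]))
    base, boosted = effect_scales
    return {
        "median_trajectory_correlation": medians[base],
        "median_overlap": overlaps[base],
        "median_overlap_boosted": overlaps[boosted],
        "overlap_monotone": overlaps[boosted] >= overlaps[base],
    }
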