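"""Mass-univariate edge regression.

Every connectivity edge is regressed, without intercept, on the five
standardized age/sex predictors.  Because both response and predictors
are centered, R-squared is computed about zero.  Grouped partial F-tests
assess the age-related block {age, age^2, age*sex, age^2*sex} and the
sex-related block {sex, age*sex, age^2*sex} by comparing the full model
to the model with the block removed; the overall F-test compares against
the empty model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import AGE_GROUP, SEX_GROUP, DesignMatrix

RACE_GROUPS = (
    "Black",
    "Asian/Hawaiian/Pacific Islander",
    "American Indian/Alaska Native",
    "Multiracial",
)


def _sse(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS coefficients and residual sum of squares, all columns of Y at once."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return beta, (resid**2).sum(axis=0)


@dataclass
class TrajectorySet:
    """Sex-specific fitted mean-FC curves on an age grid, one per edge/pair."""

    ages: np.ndarray
    female: np.ndarray  # q x E
    male: np.ndarray  # q x E
    provenance: str = "independent"

    def concatenated(self) -> np.ndarray:
        """E x 2q vectors: female curve then male curve."""
        return np.vstack([self.female, self.male]).T


class EdgewiseResults:
    """Estimates, fit statistics and selection helpers for all edges."""

    def __init__(
        self,
        model: "EdgewiseRegression",
        params: np.ndarray,
        sse_full: np.ndarray,
        sst: np.ndarray,
        sse_age_reduced: np.ndarray,
        sse_sex_reduced: np.ndarray,
    ):
        self.model = model
        self.params = params  # 5 x E
        self.sse = sse_full
        self.sst = sst
        S = model.n_subjects
        k = params.shape[0]
        self.df_resid = S - k
        self.rsquared = 1.0 - sse_full / sst

        def partial_p(sse_reduced: np.ndarray, df_num: int) -> np.ndarray:
            f = ((sse_reduced - sse_full) / df_num) / (sse_full / self.df_resid)
            return stats.f.sf(np.maximum(f, 0.0), df_num, self.df_resid)

        self.pvalues_age = partial_p(sse_age_reduced, len(AGE_GROUP))
        self.pvalues_sex = partial_p(sse_sex_reduced, len(SEX_GROUP))
        self.pvalues_model = partial_p(sst, k)

    # -- selection ---------------------------------------------------------

    def fdr_select(self, which: str = "age", q: float = 0.01) -> np.ndarray:
        """Benjamini–Hochberg step-up rejection mask at FDR level ``q``."""
        pvals = {
            "age": self.pvalues_age,
            "sex": self.pvalues_sex,
            "model": self.pvalues_model,
        }[which]
        return fdr_select(pvals, q)

    def select_by_r2(self, threshold: float = 0.10) -> np.ndarray:
        """Mask of edges whose R-squared strictly exceeds ``threshold``."""
        if not 0 <= threshold < 1:
            raise ValueError("threshold must lie in [0, 1)")
        return self.rsquared > threshold

    # -- prediction --------------------------------------------------------

    def predict_trajectory(
        self, ages: np.ndarray, edges: np.ndarray | None = None
    ) -> TrajectorySet:
        """Fitted female/male mean-FC curves over an age grid."""
        beta = self.params if edges is None else self.params[:, edges]
        xf = self.model.design.rows_for_ages(ages, sex=0)
        xm = self.model.design.rows_for_ages(ages, sex=1)
        return TrajectorySet(
            ages=np.asarray(ages, float), female=xf @ beta, male=xm @ beta
        )

    def trajectory_vectors(self, ages: np.ndarray) -> np.ndarray:
        """E x 2q concatenated (female, male) trajectory vectors."""
        return self.predict_trajectory(ages).concatenated()

    # -- reporting ---------------------------------------------------------

    def summary(self, q: float = 0.01, r2_threshold: float = 0.10) -> pd.DataFrame:
        edges = self.model.edge_index
        frame = pd.DataFrame(
            {
                "region_i": edges[:, 0],
                "region_j": edges[:, 1],
                **{
                    f"beta{l + 1}": self.params[l] for l in range(self.params.shape[0])
                },
                "r2": self.rsquared,
                "p_age": self.pvalues_age,
                "p_sex": self.pvalues_sex,
                "p_model": self.pvalues_model,
                "sig_age": self.fdr_select("age", q),
                "sig_sex": self.fdr_select("sex", q),
                "sig_model": self.fdr_select("model", q),
                "selected_r2": self.select_by_r2(r2_threshold),
            }
        )
        return frame


class EdgewiseRegression:
    """Independent no-intercept OLS of each edge on the five predictors.

    Parameters
    ----------
    endog : subjects x E matrix of standardized connectivity responses.
    design : the standardized :class:`~conntraj.design.DesignMatrix`.
    edge_index : optional E x 2 array of region pairs for reporting.
    """

    def __init__(
        self,
        endog: np.ndarray,
        design: DesignMatrix,
        edge_index: np.ndarray | None = None,
    ):
        endog = np.asarray(endog, dtype=float)
        if endog.ndim == 1:
            endog = endog[:, None]
        if endog.shape[0] != design.X.shape[0]:
            raise ValueError("endog and design must have the same number of subjects")
        S, k = design.X.shape
        if S <= k:
            raise ValueError(f"need more than {k} subjects, got {S}")
        if np.linalg.matrix_rank(design.X) < k:
            raise ValueError("design matrix is rank deficient")
        self.endog = endog
        self.design = design
        if edge_index is None:
            edge_index = np.column_stack([np.arange(endog.shape[1]), np.arange(endog.shape[1])])
        self.edge_index = np.asarray(edge_index)

    @property
    def n_subjects(self) -> int:
        return self.endog.shape[0]

    @property
    def n_edges(self) -> int:
        return self.endog.shape[1]

    def fit(self) -> EdgewiseResults:
        X = self.design.X
        Y = self.endog
        params, sse_full = _sse(X, Y)
        sst = (Y**2).sum(axis=0)  # total SS about zero: no intercept, centered Y
        keep_age = [c for c in range(X.shape[1]) if c not in AGE_GROUP]
        keep_sex = [c for c in range(X.shape[1]) if c not in SEX_GROUP]
        _, sse_age = _sse(X[:, keep_age], Y)
        _, sse_sex = _sse(X[:, keep_sex], Y)
        return EdgewiseResults(self, params, sse_full, sst, sse_age, sse_sex)


def fdr_select(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini–Hochberg step-up rejections at FDR level ``q``."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, alpha=q, method="fdr_bh")[0]


# -- covariate extensions ---------------------------------------------------


@dataclass
class RaceExtendedResults:
    """Nine-predictor fit with standardized race dummies appended."""

    params: np.ndarray  # (5 + n_kept) x E
    kept_groups: tuple
    rsquared: np.ndarray
    rsquared_base: np.ndarray
    incremental_rsquared: np.ndarray
    pvalues_race: np.ndarray


def fit_with_race(
    endog: np.ndarray,
    design: DesignMatrix,
    race: np.ndarray,
) -> RaceExtendedResults:
    """OLS with race-group dummies added to the five age/sex predictors.

    ``race`` holds group names; subjects in none of the four coded groups
    (e.g. "White") form the reference.  Dummies are standardized like the
    other predictors; a dummy constant in-sample is dropped with a
    warning.  Reports the partial-F p-value and incremental R-squared of
    the race block over the five-predictor model.
    """
    endog = np.atleast_2d(np.asarray(endog, dtype=float))
    if endog.shape[0] != design.X.shape[0]:
        endog = endog.T
    race = np.asarray(race)

    cols, kept = [], []
    for name in RACE_GROUPS:
        dummy = (race == name).astype(float)
        if dummy.std() == 0:
            warnings.warn(f"race dummy '{name}' is constant; dropped", stacklevel=2)
            continue
        cols.append((dummy - dummy.mean()) / dummy.std(ddof=1))
        kept.append(name)

    X_base = design.X
    _, sse_base = _sse(X_base, endog)
    sst = (endog**2).sum(axis=0)
    r2_base = 1 - sse_base / sst
    if not cols:
        params, _ = _sse(X_base, endog)
        return RaceExtendedResults(
            params=params,
            kept_groups=(),
            rsquared=r2_base,
            rsquared_base=r2_base,
            incremental_rsquared=np.zeros_like(r2_base),
            pvalues_race=np.ones_like(r2_base),
        )

    X_full = np.hstack([X_base, np.column_stack(cols)])
    params, sse_full = _sse(X_full, endog)
    r2_full = 1 - sse_full / sst
    df_num = len(cols)
    df_den = endog.shape[0] - X_full.shape[1]
    f = ((sse_base - sse_full) / df_num) / (sse_full / df_den)
    return RaceExtendedResults(
        params=params,
        kept_groups=tuple(kept),
        rsquared=r2_full,
        rsquared_base=r2_base,
        incremental_rsquared=r2_full - r2_base,
        pvalues_race=stats.f.sf(np.maximum(f, 0.0), df_num, df_den),
    )


def residualize_on_vascular(
    F: np.ndarray, vascular: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Two-step vascular adjustment: regress each edge on BMI and the two
    blood pressures (with intercept) and return the residuals.

    Subjects with missing vascular values are dropped listwise (count
    logged via warning).  Returns ``(residuals, kept_mask)``.
    """
    F = np.asarray(F, dtype=float)
    V = np.asarray(vascular, dtype=float)
    if V.ndim == 1:
        V = V[:, None]
    if np.any(V.std(axis=0) == 0):
        raise ValueError("constant vascular column")
    keep = ~np.isnan(V).any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} subjects with missing vascular values", stacklevel=2)
    X = np.column_stack([np.ones(keep.sum()), V[keep]])
    beta, *_ = np.linalg.lstsq(X, F[keep], rcond=None)
    return F[keep] - X @ beta, keep
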