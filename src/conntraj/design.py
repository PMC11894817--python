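"""Predictor construction for the lifespan connectivity regression.

The regression explains connectivity with five predictors built from a
subject's age ``A`` (years) and sex ``G`` (0 = female, 1 = male):

    z = (A, A^2, G, A*G, A^2*G)

Each raw column is standardized to sample mean 0 and unit sample variance
(n-1 denominator) before fitting; the per-column (mean, sd) pairs are kept
so that prediction rows for an arbitrary age grid can be mapped onto the
same standardized scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PREDICTOR_NAMES = ("age", "age_sq", "sex", "age_sex", "age_sq_sex")

#: Column indices of the age-related predictor group {A, A^2, A*G, A^2*G}.
AGE_GROUP = (0, 1, 3, 4)
#: Column indices of the sex-related predictor group {G, A*G, A^2*G}.
SEX_GROUP = (2, 3, 4)


def raw_predictors(age: np.ndarray, sex: np.ndarray) -> np.ndarray:
    """Stack the raw (unstandardized) predictor columns, S x 5."""
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    return np.column_stack(
        [age, age**2, sex, age * sex, age**2 * sex]
    )


@dataclass(frozen=True)
class ColumnTransform:
    """Invertible per-column standardization ``x = (z - mean) / sd``."""

    mean: np.ndarray
    sd: np.ndarray

    def apply(self, raw: np.ndarray) -> np.ndarray:
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        return (raw - self.mean) / self.sd

    def invert(self, standardized: np.ndarray) -> np.ndarray:
        return np.atleast_2d(standardized) * self.sd + self.mean


@dataclass
class DesignMatrix:
    """S x 5 standardized design with its stored standardization transform."""

    X: np.ndarray
    transform: ColumnTransform
    names: tuple = field(default=PREDICTOR_NAMES)

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    def rows_for_ages(self, ages: np.ndarray, sex: int) -> np.ndarray:
        """Standardized prediction rows for an age grid and a single sex.

        Raw rows are ``(t, t^2, 0, 0, 0)`` for females and
        ``(t, t^2, 1, t, t^2)`` for males, mapped through the stored
        transform so they live on the training predictor scale.
        """
        ages = np.asarray(ages, dtype=float)
        if ages.min() < 0 or ages.max() > 120:
            import warnings

            warnings.warn(
                f"age grid [{ages.min()}, {ages.max()}] extends outside the "
                "sanity window [0, 120]",
                stacklevel=2,
            )
        g = np.full(ages.shape, float(sex))
        return self.transform.apply(raw_predictors(ages, g))


def build_design(age: np.ndarray, sex: np.ndarray) -> DesignMatrix:
    """Build and standardize the five-predictor design.

    Parameters
    ----------
    age : array of ages in years, positive.
    sex : array of 0/1 indicators (0 = female, 1 = male).

    Raises
    ------
    ValueError
        if fewer than 6 subjects, or any raw column is constant (e.g. a
        single-sex cohort).
    """
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    if age.ndim != 1 or age.shape != sex.shape:
        raise ValueError("age and sex must be 1-d arrays of equal length")
    if age.size < 6:
        raise ValueError(f"need at least 6 subjects, got {age.size}")
    if np.any(age <= 0):
        raise ValueError("ages must be positive")
    if not np.isin(sex, (0.0, 1.0)).all():
        raise ValueError("sex must be coded 0 (female) / 1 (male)")

    raw = raw_predictors(age, sex)
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ", ".join(PREDICTOR_NAMES[i] for i in bad)
        raise ValueError(f"constant predictor column(s): {names}")
    transform = ColumnTransform(mean=mean, sd=sd)
    return DesignMatrix(X=transform.apply(raw), transform=transform)


def design_from_covariates(covariates: pd.DataFrame) -> DesignMatrix:
    """Build the design from a covariates table with ``age`` and ``sex``."""
    return build_design(covariates["age"].to_numpy(), covariates["sex"].to_numpy())
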