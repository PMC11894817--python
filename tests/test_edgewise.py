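import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conntraj.design import build_design
from conntraj.edgewise import (
    EdgewiseRegression,
    fdr_select,
    fit_with_race,
    residualize_on_vascular,
)


@pytest.fixture(scope="module")
def fitted(design_600):
    rng = np.random.default_rng(11)
    S = design_600.n_subjects
    beta = np.zeros((5, 3))
    beta[:, 0] = [1, 0, 0, 0, 0]  # noiseless pure-age edge
    beta[:, 1] = [0.3, 0.1, -0.2, 0.1, 0.0]
    F = design_600.X @ beta
    F[:, 1] += rng.normal(size=S)
    F[:, 2] = rng.normal(size=S)  # pure noise edge
    model = EdgewiseRegression(F, design_600)
    return model.fit(), F


class TestFitEdge:
    def test_noiseless_edge_recovered_exactly(self, fitted):
        res, _ = fitted
        assert np.allclose(res.params[:, 0], [1, 0, 0, 0, 0], atol=1e-10)
        assert np.isclose(res.rsquared[0], 1.0)
        assert res.pvalues_model[0] < 1e-200

    def test_params_match_pseudoinverse_oracle(self, fitted, design_600):
        res, F = fitted
        oracle = np.linalg.pinv(design_600.X) @ F
        assert np.allclose(res.params, oracle, atol=1e-8)

    def test_r2_matches_residual_oracle(self, fitted, design_600):
        res, F = fitted
        resid = F - design_600.X @ res.params
        r2 = 1 - (resid**2).sum(axis=0) / (F**2).sum(axis=0)
        assert np.allclose(res.rsquared, r2, atol=1e-10)

    def test_partial_f_matches_closed_form(self, fitted, design_600):
        res, F = fitted
        X = design_600.X
        sse_full = ((F - X @ np.linalg.pinv(X) @ F) ** 2).sum(axis=0)
        Xr = X[:, [2]]  # drop the age group {0,1,3,4}
        sse_red = ((F - Xr @ np.linalg.pinv(Xr) @ F) ** 2).sum(axis=0)
        S = X.shape[0]
        f = ((sse_red - sse_full) / 4) / (sse_full / (S - 5))
        p = stats.f.sf(f, 4, S - 5)
        assert np.allclose(res.pvalues_age, p, atol=1e-10)

    def test_too_few_subjects_rejected(self):
        d = build_design(np.array([10, 20, 30, 40, 50, 60.0]), np.array([0, 1, 0, 1, 0, 1]))
        X5 = d.X[:5]
        d5 = type(d)(X=X5, transform=d.transform)
        with pytest.raises(ValueError):
            EdgewiseRegression(np.zeros((5, 1)), d5)

    def test_null_pvalues_uniform(self, design_600):
        rng = np.random.default_rng(2024)
        F = rng.normal(size=(design_600.n_subjects, 2000))
        res = EdgewiseRegression(F, design_600).fit()
        # Kolmogorov-Smirnov against U(0,1)
        assert stats.kstest(res.pvalues_age, "uniform").pvalue > 1e-3
        rate = (res.pvalues_age < 0.05).mean()
        assert 0.035 < rate < 0.065


class TestSelection:
    def test_bh_stepup_hand_example(self):
        mask = fdr_select(np.array([0.001, 0.02, 0.9]), q=0.05)
        assert mask.tolist() == [True, True, False]

    def test_all_ones_rejects_none(self):
        assert not fdr_select(np.ones(10), q=0.05).any()

    def test_empty_input(self):
        assert fdr_select(np.array([]), q=0.05).size == 0

    def test_monotone_in_pvalues(self, rng):
        p = rng.uniform(size=50)
        base = fdr_select(p, q=0.1)
        p2 = p.copy()
        p2[7] = p2[7] / 10
        improved = fdr_select(p2, q=0.1)
        # every originally rejected hypothesis stays rejected
        assert np.all(improved | ~base)

    def test_never_more_than_unadjusted_alpha_count(self, rng):
        p = rng.uniform(size=500)
        q = 0.05
        assert fdr_select(p, q).sum() <= (p <= q).sum()

    def test_r2_threshold_is_strict(self, design_600):
        rng = np.random.default_rng(41)
        res = EdgewiseRegression(rng.normal(size=(design_600.n_subjects, 3)), design_600).fit()
        res.rsquared = np.array([0.05, 0.10, 0.11])  # fresh instance, safe to pin
        mask = res.select_by_r2(0.10)
        assert mask.tolist() == [False, False, True]
        assert res.select_by_r2(0.0).tolist() == [True, True, True]


class TestTrajectories:
    def test_zero_beta_gives_flat_zero_curves(self, design_600):
        res = EdgewiseRegression(
            np.zeros((design_600.n_subjects, 1)), design_600
        ).fit()
        t = res.predict_trajectory(np.arange(8, 101))
        assert np.allclose(t.female, 0) and np.allclose(t.male, 0)

    def test_sex_difference_is_linear_identity(self, fitted, design_600):
        res, _ = fitted
        ages = np.linspace(8, 100, 12)
        t = res.predict_trajectory(ages)
        xf = design_600.rows_for_ages(ages, 0)
        xm = design_600.rows_for_ages(ages, 1)
        gap = (xm - xf) @ res.params
        assert np.allclose(t.male - t.female, gap, atol=1e-10)

    def test_generator_round_trip_noiseless(self, design_600):
        beta = np.array([-0.4, -0.1, 0.15, 0.05, 0.02])
        F = design_600.X @ beta[:, None]
        res = EdgewiseRegression(F, design_600).fit()
        ages = np.arange(8, 101, dtype=float)
        t = res.predict_trajectory(ages)
        truth_f = design_600.rows_for_ages(ages, 0) @ beta
        truth_m = design_600.rows_for_ages(ages, 1) @ beta
        assert np.allclose(t.female.ravel(), truth_f, atol=1e-8)
        assert np.allclose(t.male.ravel(), truth_m, atol=1e-8)


class TestRaceExtension:
    def _race(self, rng, S, frac=0.3):
        race = np.array(["White"] * S, dtype=object)
        idx = rng.choice(S, int(frac * S), replace=False)
        race[idx] = "Black"
        return race

    def test_independent_race_adds_nothing(self, design_600):
        rng = np.random.default_rng(31)
        S = design_600.n_subjects
        F = rng.normal(size=(S, 200))
        race = self._race(rng, S)
        ext = fit_with_race(F, design_600, race)
        assert np.all(ext.incremental_rsquared < 0.03)
        rate = (ext.pvalues_race < 0.05).mean()
        assert 0.01 < rate < 0.10

    def test_group_shift_increases_incremental_r2_monotonically(self, design_600):
        rng = np.random.default_rng(32)
        S = design_600.n_subjects
        noise = rng.normal(size=S)
        race = self._race(rng, S)
        r2s = []
        for delta in (0.0, 0.5, 1.0, 2.0):
            F = (noise + delta * (race == "Black"))[:, None]
            r2s.append(fit_with_race(F, design_600, race).incremental_rsquared[0])
        assert np.all(np.diff(r2s) > 0)

    def test_all_white_collapses_to_base_model(self, design_600):
        rng = np.random.default_rng(33)
        F = rng.normal(size=(design_600.n_subjects, 2))
        race = np.array(["White"] * design_600.n_subjects)
        with pytest.warns(UserWarning, match="dropped"):
            ext = fit_with_race(F, design_600, race)
        base = EdgewiseRegression(F, design_600).fit()
        assert ext.kept_groups == ()
        assert np.allclose(ext.params, base.params)
        assert np.allclose(ext.rsquared, base.rsquared)


class TestVascularResidualization:
    def test_exact_linear_dependence_gives_zero_residuals(self, rng):
        bmi = rng.uniform(18, 35, 100)
        vas = pd.DataFrame({"bmi": bmi, "dbp": rng.uniform(60, 90, 100), "sbp": rng.uniform(100, 140, 100)})
        F = (2 * bmi)[:, None]
        resid, keep = residualize_on_vascular(F, vas)
        assert keep.all()
        assert np.allclose(resid, 0, atol=1e-8)

    def test_residuals_orthogonal_to_vascular_columns(self, rng):
        vas = pd.DataFrame(rng.normal(size=(120, 3)), columns=["bmi", "dbp", "sbp"])
        F = rng.normal(size=(120, 5))
        resid, _ = residualize_on_vascular(F, vas)
        for c in vas.columns:
            assert np.allclose(vas[c].to_numpy() @ resid, 0, atol=1e-8)
        # intercept included: residuals are centered
        assert np.allclose(resid.mean(axis=0), 0, atol=1e-8)

    def test_missing_values_dropped_listwise(self, rng):
        vas = pd.DataFrame(rng.normal(size=(50, 3)), columns=["bmi", "dbp", "sbp"])
        vas.iloc[3, 0] = np.nan
        F = rng.normal(size=(50, 2))
        with pytest.warns(UserWarning, match="1 subjects"):
            resid, keep = residualize_on_vascular(F, vas)
        assert keep.sum() == 49 and resid.shape[0] == 49
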