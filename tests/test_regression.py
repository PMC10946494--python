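"""Pairwise OLS fitting, metrics and predictor selection.

The OLS path is cross-checked against two independent oracles: a direct
evaluation of the normal-equation formulas in extended precision
(math.fsum), and statsmodels' OLS.
"""

import math

import numpy as np
import pytest
import statsmodels.api as sm_api
from hypothesis import given, settings, strategies as st

from shiftmap import ShiftTable, best_predictor, fit_all_pairs, fit_pair, rrmse_matrix
from shiftmap.regression import (
    DegeneratePredictorError,
    NoStablePredictorError,
    RegressionError,
)
import pandas as pd


def fsum_ols(y, x):
    """Normal-equation oracle with compensated summation."""
    n = len(x)
    xbar = math.fsum(x) / n
    ybar = math.fsum(y) / n
    sxx = math.fsum((xi - xbar) ** 2 for xi in x)
    sxy = math.fsum((xi - xbar) * (yi - ybar) for xi, yi in zip(x, y))
    a = sxy / sxx
    b = ybar - a * xbar
    resid = [yi - (a * xi + b) for xi, yi in zip(x, y)]
    ssres = math.fsum(r * r for r in resid)
    sstot = math.fsum((yi - ybar) ** 2 for yi in y)
    r2 = 1.0 - ssres / sstot if sstot > 0 else float("nan")
    return a, b, r2, math.sqrt(ssres / n), max(abs(r) for r in resid)


class TestFitPair:
    def test_identity_line(self):
        m = fit_pair(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert m.a == pytest.approx(1.0)
        assert m.b == pytest.approx(0.0, abs=1e-14)
        assert m.r2 == pytest.approx(1.0)
        assert m.rmse == pytest.approx(0.0, abs=1e-14)
        assert m.max_abs_resid == pytest.approx(0.0, abs=1e-14)

    def test_exact_line(self):
        m = fit_pair(np.array([3.0, 5.0, 7.0]), np.array([1.0, 2.0, 3.0]))
        assert m.a == pytest.approx(2.0)
        assert m.b == pytest.approx(1.0)
        assert m.r2 == pytest.approx(1.0)

    def test_against_fsum_and_statsmodels(self):
        y = np.array([1.33, 1.36, 1.34, 1.38])
        x = np.array([0.98, 1.00, 0.99, 1.01])
        m = fit_pair(y, x)
        a, b, r2, rmse, mar = fsum_ols(y, x)
        assert m.a == pytest.approx(a, rel=1e-12)
        assert m.b == pytest.approx(b, rel=1e-12)
        assert m.r2 == pytest.approx(r2, rel=1e-12)
        assert m.rmse == pytest.approx(rmse, rel=1e-12)
        assert m.max_abs_resid == pytest.approx(mar, rel=1e-12)
        sm_fit = sm_api.OLS(y, sm_api.add_constant(x)).fit()
        assert m.a == pytest.approx(sm_fit.params[1], rel=1e-10)
        assert m.b == pytest.approx(sm_fit.params[0], rel=1e-10)
        assert m.se_a == pytest.approx(sm_fit.bse[1], rel=1e-10)

    def test_rrmse_definition(self):
        y = np.array([1.0, 1.2, 1.1, 1.3])
        x = np.array([0.5, 0.7, 0.55, 0.75])
        m = fit_pair(y, x)
        assert m.rrmse == pytest.approx(100.0 * m.rmse / np.mean(y))

    def test_rmse_ddof(self):
        y = np.array([1.0, 1.2, 1.1, 1.35])
        x = np.array([0.5, 0.7, 0.55, 0.75])
        m0 = fit_pair(y, x, rmse_ddof=0)
        m2 = fit_pair(y, x, rmse_ddof=2)
        assert m2.rmse == pytest.approx(m0.rmse * math.sqrt(4 / 2))

    def test_constant_predictor_raises(self):
        with pytest.raises(DegeneratePredictorError):
            fit_pair(np.array([1.0, 2.0, 3.0]), np.array([5.0, 5.0, 5.0]))

    def test_constant_response_flagged_unusable(self):
        m = fit_pair(np.array([2.0, 2.0, 2.0]), np.array([1.0, 2.0, 3.0]))
        assert not m.usable
        assert math.isnan(m.r2)

    def test_too_few_samples(self):
        with pytest.raises(RegressionError):
            fit_pair(np.array([1.0]), np.array([2.0]))

    def test_max_abs_resid_at_least_rmse(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(1.0, 0.01, 30)
            y = 1.3 * x + rng.normal(0, 1e-3, 30)
            m = fit_pair(y, x)
            assert m.max_abs_resid >= m.rmse - 1e-15


@settings(max_examples=200, derandomize=True)
@given(
    data=st.lists(
        st.tuples(st.floats(-5, 5), st.floats(-5, 5)),
        min_size=3,
        max_size=12,
    ),
)
def test_ols_reciprocity_and_pearson(data):
    """a(y|x) * a(x|y) = r^2, and r^2 equals the squared Pearson correlation."""
    y = np.array([d[0] for d in data])
    x = np.array([d[1] for d in data])
    if np.ptp(x) < 1e-6 or np.ptp(y) < 1e-6:
        return
    myx = fit_pair(y, x)
    mxy = fit_pair(x, y)
    r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    assert myx.a * mxy.a == pytest.approx(r2, rel=1e-10, abs=1e-10)
    assert myx.r2 == pytest.approx(r2, rel=1e-10, abs=1e-10)
    assert mxy.r2 == pytest.approx(r2, rel=1e-10, abs=1e-10)


def test_shift_invariance():
    """Adding a constant to both x and y changes only the intercept."""
    rng = np.random.default_rng(5)
    x = rng.normal(1.0, 0.01, 50)
    y = 1.2 * x + rng.normal(0, 1e-3, 50)
    m1 = fit_pair(y, x)
    m2 = fit_pair(y + 3.0, x + 3.0)
    assert m2.a == pytest.approx(m1.a, rel=1e-9)
    assert m2.rmse == pytest.approx(m1.rmse, rel=1e-9)
    assert m2.r2 == pytest.approx(m1.r2, rel=1e-9)
    assert m2.b == pytest.approx(m1.b + 3.0 * (1 - m1.a), rel=1e-6)


class TestFitAllPairs:
    def test_sixteen_systems_give_240_models(self, serum_like_models):
        assert len(serum_like_models) == 240

    def test_three_columns_give_six_models(self, toy_table):
        mm = fit_all_pairs(toy_table, min_n=2)
        assert len(mm) == 6

    def test_low_overlap_flagged_unstable(self):
        rng = np.random.default_rng(1)
        n = 60
        base = rng.normal(1.0, 0.01, n)
        df = pd.DataFrame({"a": base, "b": base * 1.1 + rng.normal(0, 1e-4, n)})
        df.loc[df.index[8:], "b"] = np.nan  # only 8 co-detections
        mm = fit_all_pairs(ShiftTable(df.set_axis([f"s{i}" for i in range(n)])),
                           min_n=50)
        m = mm.get("b", "a")
        assert m.n == 8
        assert not m.stable
        assert m.usable

    def test_json_roundtrip(self, serum_like_models, tmp_path):
        p = tmp_path / "models.json"
        serum_like_models.to_json(p)
        from shiftmap.regression import ModelMatrix

        back = ModelMatrix.from_json(p)
        assert len(back) == len(serum_like_models)
        m1 = serum_like_models.get("alanine_CH3", "valine_CH3")
        m2 = back.get("alanine_CH3", "valine_CH3")
        assert m1.a == m2.a and m1.rmse == m2.rmse and m1.n == m2.n


class TestRrmseMatrix:
    def test_shape_and_empty_diagonal(self, serum_like_models):
        df = rrmse_matrix(serum_like_models)
        assert df.shape == (16, 16)
        assert np.isnan(np.diag(df.to_numpy())).all()

    def test_unstable_cells_masked(self, serum_like_models):
        df = rrmse_matrix(serum_like_models, mask_unstable=True)
        m = serum_like_models.get("ethanol_CH3", "hydroxybutyrate_CH3")
        assert not m.stable
        assert np.isnan(df.loc["ethanol_CH3", "hydroxybutyrate_CH3"])
        full = rrmse_matrix(serum_like_models, mask_unstable=False)
        assert np.isfinite(full.loc["ethanol_CH3", "hydroxybutyrate_CH3"])

    def test_noiseless_limit_near_zero(self):
        from shiftmap import serum_panel_spec, simulate_shift_table

        spec = serum_panel_spec(sigma=0.0, precision=None, full_detection=True)
        t = simulate_shift_table(spec, 100, seed=2)
        mm = fit_all_pairs(t, min_n=2)
        df = rrmse_matrix(mm)
        # within-class pairs are exactly collinear without noise
        assert df.loc["alanine_CH3", "valine_CH3"] < 1e-10


class TestBestPredictor:
    def test_single_candidate(self):
        rng = np.random.default_rng(2)
        x = rng.normal(1.0, 0.01, 100)
        df = pd.DataFrame(
            {"a": x, "b": 1.2 * x + rng.normal(0, 1e-4, 100)},
            index=[f"s{i}" for i in range(100)],
        )
        mm = fit_all_pairs(ShiftTable(df), min_n=50)
        assert best_predictor(mm, "b") == "a"

    def test_matches_exhaustive_scan(self, serum_like_models):
        mm = serum_like_models
        for resp in mm.systems:
            eligible = {
                p: m for p, m in mm.incoming(resp).items()
                if m.stable and m.usable and math.isfinite(m.rrmse)
            }
            brute = min(
                eligible.items(),
                key=lambda kv: (abs(kv[1].rrmse), -kv[1].r2, kv[0]),
            )[0]
            assert best_predictor(mm, resp) == brute

    def test_candidate_restriction(self, serum_like_models):
        cands = {"lactate_CH3", "acetate_CH3"}
        got = best_predictor(serum_like_models, "pyruvate_CH3", candidates=cands)
        assert got in cands

    def test_no_stable_candidates_errors(self):
        rng = np.random.default_rng(4)
        x = rng.normal(1.0, 0.01, 10)
        df = pd.DataFrame(
            {"a": x, "b": 1.2 * x + rng.normal(0, 1e-4, 10)},
            index=[f"s{i}" for i in range(10)],
        )
        mm = fit_all_pairs(ShiftTable(df), min_n=50)
        with pytest.raises(NoStablePredictorError, match="unstable"):
            best_predictor(mm, "b")
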