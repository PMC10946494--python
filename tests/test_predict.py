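"""Semi/auto chained prediction and validation reports."""

import numpy as np
import pandas as pd
import pytest

from shiftmap import (
    ShiftTable,
    bind_map,
    fit_all_pairs,
    serum_panel_spec,
    predict_auto,
    predict_semi,
    published_map,
    simulate_shift_table,
    validate_predictions,
)
from shiftmap.mapping import MapEdge, PredictionMap
from shiftmap.predict import (
    SOURCE_ALTERNATE,
    SOURCE_OBSERVED,
    SOURCE_PRIMARY,
    SOURCE_UNAVAILABLE,
    PredictionResult,
)
from shiftmap.regression import PairModel


def _manual_model(resp, pred, a, b):
    return PairModel(
        response_id=resp, predictor_id=pred, a=a, b=b, n=100,
        r2=0.999, rmse=1e-4, rrmse=0.01, max_abs_resid=3e-4, se_a=1e-3,
    )


@pytest.fixture()
def chain_map():
    """r -> m1 -> m2 -> m3: three stacked affine models."""
    pmap = PredictionMap(
        root="r",
        parents={
            "m1": MapEdge("r", "m1", _manual_model("m1", "r", 1.1, 0.2)),
            "m2": MapEdge("m1", "m2", _manual_model("m2", "m1", 0.9, -0.05)),
            "m3": MapEdge("m2", "m3", _manual_model("m3", "m2", 1.05, 0.5)),
        },
    )
    pmap.chain_rmse.update({"r": 0, "m1": 1e-4, "m2": 2e-4, "m3": 3e-4})
    pmap.chain_envelope.update({"r": 0, "m1": 3e-4, "m2": 6e-4, "m3": 9e-4})
    return pmap


class TestPredictSemi:
    def test_affine_evaluation(self):
        pmap = PredictionMap(
            root="r",
            parents={"y": MapEdge("r", "y", _manual_model("y", "r", 1.0, 0.35))},
        )
        pmap.chain_rmse.update({"r": 0.0, "y": 1e-4})
        pmap.chain_envelope.update({"r": 0.0, "y": 3e-4})
        t = ShiftTable(pd.DataFrame({"r": [0.9860]}, index=["s1"]))
        res = predict_semi(pmap, t)
        row = res.frame[(res.frame["system"] == "y")].iloc[0]
        assert row["predicted"] == pytest.approx(1.3360)
        assert row["source"] == SOURCE_PRIMARY

    def test_missing_predictor_unavailable(self, chain_map):
        t = ShiftTable(
            pd.DataFrame(
                {"r": [1.0], "m1": [np.nan], "m2": [np.nan]}, index=["s1"]
            )
        )
        res = predict_semi(chain_map, t)
        by = res.frame.set_index("system")
        assert by.loc["m1", "source"] == SOURCE_PRIMARY   # r observed
        assert by.loc["m2", "source"] == SOURCE_UNAVAILABLE
        assert by.loc["m3", "source"] == SOURCE_UNAVAILABLE

    def test_alternate_edge_fallback(self, serum_like_models):
        bound = bind_map(published_map(), serum_like_models)
        spec = serum_panel_spec()
        t = simulate_shift_table(spec, 300, seed=21)
        res = predict_semi(bound, t)
        sources = res.frame[res.frame["system"] == "acetone_CH3"].set_index(
            "sample"
        )["source"]
        eth = t.column("ethanol_CH3")
        pyr = t.column("pyruvate_CH3")
        for sample, src in sources.items():
            if not np.isnan(eth[sample]):
                assert src == SOURCE_PRIMARY
            elif not np.isnan(pyr[sample]):
                assert src == SOURCE_ALTERNATE
            else:
                assert src == SOURCE_UNAVAILABLE
        assert (sources == SOURCE_ALTERNATE).sum() > 0

    def test_alternates_can_be_disabled(self, serum_like_models):
        bound = bind_map(published_map(), serum_like_models)
        t = simulate_shift_table(serum_panel_spec(), 200, seed=22)
        res = predict_semi(bound, t, use_alternates=False)
        src = res.frame[res.frame["system"] == "acetone_CH3"]["source"]
        assert SOURCE_ALTERNATE not in set(src)


class TestPredictAuto:
    def test_depth3_equals_composed_affine_map(self, chain_map):
        """Chained prediction is the composition a3*(a2*(a1*v+b1)+b2)+b3."""
        anchors = pd.Series([0.9, 1.0, 1.1], index=["s1", "s2", "s3"])
        res = predict_auto(chain_map, anchors)
        wide = res.wide(raw=True)
        for v, sample in zip(anchors, anchors.index):
            m1 = 1.1 * v + 0.2
            m2 = 0.9 * m1 - 0.05
            m3 = 1.05 * m2 + 0.5
            assert abs(wide.at[sample, "m3"] - m3) < 1e-12
            assert abs(wide.at[sample, "m1"] - m1) < 1e-12

    def test_anchor_carried_as_observed(self, chain_map):
        res = predict_auto(chain_map, pd.Series([1.0], index=["s1"]))
        row = res.frame[res.frame["system"] == "r"].iloc[0]
        assert row["source"] == SOURCE_OBSERVED
        assert row["predicted"] == 1.0

    def test_missing_anchor_sample_skipped(self, chain_map):
        res = predict_auto(
            chain_map, pd.Series([1.0, np.nan], index=["s1", "s2"])
        )
        assert set(res.frame["sample"]) == {"s1"}

    def test_est_error_is_chain_envelope(self, chain_map):
        res = predict_auto(chain_map, pd.Series([1.0], index=["s1"]))
        by = res.frame.set_index("system")
        assert by.loc["m3", "est_error"] == pytest.approx(9e-4)


class TestExactLineLimit:
    def test_semi_auto_observed_all_agree_at_sigma_zero(self):
        """Without noise or quantization the maps are exact: semi == auto ==
        observed, to floating-point resolution."""
        spec = serum_panel_spec(sigma=0.0, precision=None, full_detection=True,
                               collinear=True)
        train = simulate_shift_table(spec, 120, seed=31)
        mm = fit_all_pairs(train, min_n=50)
        bound = bind_map(published_map(), mm)
        test = simulate_shift_table(spec, 40, seed=32)
        semi = predict_semi(bound, test)
        auto = predict_auto(bound, test.column("valine_CH3"))
        sw = semi.wide(raw=True)
        aw = auto.wide(raw=True)
        obs = test.data
        assert np.nanmax(np.abs(sw - obs[sw.columns])) < 1e-9
        assert np.nanmax(np.abs(aw - obs[aw.columns])) < 1e-9
        assert (semi.frame["source"] != SOURCE_UNAVAILABLE).all()

    def test_quantized_sigma_zero_agrees_within_one_quantum_per_hop(self):
        spec = serum_panel_spec(sigma=0.0, precision=4, full_detection=True,
                               collinear=True)
        train = simulate_shift_table(spec, 200, seed=33)
        mm = fit_all_pairs(train, min_n=50)
        bound = bind_map(published_map(), mm)
        test = simulate_shift_table(spec, 50, seed=34)
        semi = predict_semi(bound, test)
        err = validate_predictions(semi, test).frame["max_abs_error_ppm"]
        assert (err.dropna() < 3e-4).all()  # rounding-limited, not model error


class TestValidatePredictions:
    def test_perfect_predictions_give_zero_errors(self, chain_map):
        t = ShiftTable(
            pd.DataFrame({"r": [1.0], "m1": [1.3]}, index=["s1"])
        )
        frame = pd.DataFrame(
            [
                ("s1", "r", 1.0, 1.0, SOURCE_OBSERVED, 0.0),
                ("s1", "m1", 1.3, 1.3, SOURCE_PRIMARY, 1e-4),
            ],
            columns=["sample", "system", "predicted", "predicted_raw",
                     "source", "est_error"],
        )
        rep = validate_predictions(PredictionResult("semi", frame), t)
        assert rep.frame.loc["m1", "max_abs_error_ppm"] == 0.0
        assert rep.overall["rmse_ppm"] == 0.0

    def test_linewidth_conversion(self):
        t = ShiftTable(
            pd.DataFrame({"y": [1.0000, 2.0000]}, index=["s1", "s2"])
        )
        frame = pd.DataFrame(
            [
                ("s1", "y", 1.0005, 1.0005, SOURCE_PRIMARY, np.nan),
                ("s2", "y", 1.9990, 1.9990, SOURCE_PRIMARY, np.nan),
            ],
            columns=["sample", "system", "predicted", "predicted_raw",
                     "source", "est_error"],
        )
        rep = validate_predictions(
            PredictionResult("semi", frame), t, linewidth_ppm=0.001
        )
        assert rep.frame.loc["y", "max_abs_error_linewidths"] == pytest.approx(1.0)
        assert rep.frame.loc["y", "n"] == 2

    def test_max_at_least_rmse(self, serum_like_models):
        bound = bind_map(published_map(), serum_like_models)
        t = simulate_shift_table(serum_panel_spec(), 150, seed=41)
        rep = validate_predictions(predict_semi(bound, t), t)
        ok = rep.frame.dropna()
        assert (ok["max_abs_error_ppm"] >= ok["rmse_ppm"] - 1e-15).all()

    def test_no_overlap_reports_n_zero(self, chain_map):
        t = ShiftTable(pd.DataFrame({"m9": [1.0]}, index=["s1"]))
        frame = pd.DataFrame(
            [("s1", "m1", 1.2, 1.2, SOURCE_PRIMARY, np.nan)],
            columns=["sample", "system", "predicted", "predicted_raw",
                     "source", "est_error"],
        )
        rep = validate_predictions(PredictionResult("semi", frame), t)
        assert rep.frame.loc["m1", "n"] == 0
        assert np.isnan(rep.frame.loc["m1", "max_abs_error_ppm"])

    def test_predictions_are_per_sample_local(self, chain_map):
        """Adding samples never changes existing per-sample predictions."""
        a1 = predict_auto(chain_map, pd.Series([1.0], index=["s1"]))
        a2 = predict_auto(
            chain_map, pd.Series([1.0, 2.0], index=["s1", "s2"])
        )
        v1 = a1.frame[a1.frame["sample"] == "s1"].set_index("system")["predicted_raw"]
        v2 = a2.frame[a2.frame["sample"] == "s1"].set_index("system")["predicted_raw"]
        pd.testing.assert_series_equal(v1, v2)

    def test_csv_roundtrip(self, chain_map, tmp_path):
        res = predict_auto(chain_map, pd.Series([1.0, 1.2], index=["s1", "s2"]))
        p = tmp_path / "pred.csv"
        res.to_csv(p)
        back = PredictionResult.from_csv(p, mode="auto")
        pd.testing.assert_frame_equal(
            res.frame.reset_index(drop=True), back.frame, check_dtype=False
        )
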