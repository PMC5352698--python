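"""Segmented QSRR model: routing, blending, prefilter and stepwise refit."""

import numpy as np
import pandas as pd
import pytest

from sphingolib.rt import (
    correlation_prefilter,
    fit_stepwise,
    normalize_descriptor_name,
    paper_2017,
    predict_rt,
    split_by_segment,
)


def row(**kwargs):
    base = {name: 0.0 for name in
            ("XLogP", "SssCH2", "C2SP3", "BIC0", "ATSC2m", "ATSC2v",
             "LipoaffinityIndex", "SpMAD_Dzi")}
    base.update(kwargs)
    return base


class TestPredict:
    def test_intercept_only_early_segment(self):
        assert predict_rt(row()) == pytest.approx(-14.0)

    def test_late_segment(self):
        assert predict_rt(row(XLogP=20.0)) == pytest.approx(12.7)

    def test_blend_is_unweighted_mean(self):
        # mean(-14 + 0.55*16, 9.5 + 0.16*16) = mean(-5.2, 12.06)
        assert predict_rt(row(XLogP=16.0)) == pytest.approx(3.43)

    def test_all_coefficients_of_early_segment(self):
        value = predict_rt(row(XLogP=10.0, SssCH2=2.0, C2SP3=3.0, BIC0=0.5,
                               ATSC2m=100.0, ATSC2v=200.0))
        expected = (-14.0 + 0.55 * 10 + 0.17 * 2 + 0.048 * 3 + 71 * 0.5
                    - 0.0022 * 100 + 0.00081 * 200)
        assert value == pytest.approx(expected)

    def test_all_coefficients_of_late_segment(self):
        value = predict_rt(row(XLogP=25.0, LipoaffinityIndex=12.0,
                               SpMAD_Dzi=4.0, C2SP3=6.0))
        expected = 9.5 + 0.16 * 25 + 0.076 * 12 - 0.14 * 4 + 0.085 * 6
        assert value == pytest.approx(expected)

    @pytest.mark.parametrize("xlogp", [15.95, 16.1, 16.3, 16.55])
    def test_blend_lies_between_segment_predictions(self, xlogp):
        r = row(XLogP=xlogp, SssCH2=1.0, C2SP3=2.0, BIC0=0.1,
                LipoaffinityIndex=3.0, SpMAD_Dzi=1.0)
        early, late = paper_2017().segments
        lo, hi = sorted((early.predict(r), late.predict(r)))
        assert lo <= predict_rt(r) <= hi

    def test_missing_descriptor_named_in_error(self):
        with pytest.raises(ValueError, match="BIC0"):
            predict_rt({"XLogP": 3.0})
        with pytest.raises(ValueError, match="XLogP"):
            predict_rt(row(XLogP=float("nan")))

    def test_descriptor_name_synonyms(self):
        assert normalize_descriptor_name("ATSC2 m") == "ATSC2m"
        assert normalize_descriptor_name(" xlogp ") == "XLogP"
        r = {normalize_descriptor_name(k): v for k, v in row().items()}
        r["ATSC2 m"] = r.pop("ATSC2m")
        assert predict_rt(r) == pytest.approx(-14.0)


class TestPrefilter:
    def test_scaled_and_anticorrelated_columns_retained(self):
        rng = np.random.default_rng(0)
        rt = rng.normal(10, 2, size=30)
        table = pd.DataFrame({
            "twice": 2 * rt,
            "minus": -rt,
            "noise": rng.normal(size=30),
            "const": np.ones(30),
        })
        selected, report = correlation_prefilter(table, rt)
        assert "twice" in selected
        assert "minus" in selected  # |r| convention
        assert "noise" not in selected
        assert report["removed_constant"] == ["const"]

    def test_duplicate_columns_removed(self):
        rt = np.array([1.0, 2.0, 3.0, 4.0])
        table = pd.DataFrame({"a": rt, "b": rt, "c": rt + 1})
        selected, report = correlation_prefilter(table, rt)
        assert report["removed_duplicate"] == ["b"]
        assert selected == ["a", "c"]

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            correlation_prefilter(pd.DataFrame({"a": [1.0, 2.0]}), [1.0, 2.0])


class TestStepwise:
    def test_noiseless_single_predictor_recovery(self):
        rng = np.random.default_rng(1)
        x1 = rng.normal(size=40)
        table = pd.DataFrame({
            "x1": x1,
            **{f"n{i}": rng.normal(size=40) for i in range(4)},
        })
        fit = fit_stepwise(table, 2.0 * x1)
        assert fit.selected[0] == "x1"
        assert fit.coefficients["x1"] == pytest.approx(2.0, abs=1e-8)
        assert fit.coefficients["intercept"] == pytest.approx(0.0, abs=1e-8)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-6)

    def test_two_signal_recovery_with_noise(self):
        rng = np.random.default_rng(7)
        n = 200
        X = rng.normal(size=(n, 20))
        table = pd.DataFrame(X, columns=[f"x{i:02d}" for i in range(20)])
        y = 3.0 * X[:, 0] - 1.0 * X[:, 1] + rng.normal(0, 0.1, size=n)
        fit = fit_stepwise(table, y)
        assert {"x00", "x01"} <= set(fit.selected)
        assert fit.coefficients["x00"] == pytest.approx(3.0, abs=0.05)
        assert fit.coefficients["x01"] == pytest.approx(-1.0, abs=0.05)
        # AIC trace strictly decreasing over accepted steps
        assert all(later < earlier for earlier, later in
                   zip(fit.aic_trace, fit.aic_trace[1:]))

    def test_orthogonal_candidates_give_intercept_only(self):
        y = np.tile([1.0, -1.0], 10)
        x = np.tile([1.0, 1.0, -1.0, -1.0], 5)  # exactly orthogonal to y
        fit = fit_stepwise(pd.DataFrame({"x": x}), y)
        assert fit.selected == []
        assert fit.coefficients["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            fit_stepwise(pd.DataFrame({"a": [1.0, 2.0]}), [1.0, 2.0])

    def test_published_equation_recovery_at_training_noise(self):
        """Refit on synthetic data from the early-segment equation with
         0.14 min Gaussian noise recovers each coefficient within 3 SE."""
        rng = np.random.default_rng(42)
        n = 200
        scales = {"XLogP": 3.0, "SssCH2": 10.0, "C2SP3": 10.0,
                  "BIC0": 0.05, "ATSC2m": 500.0, "ATSC2v": 2000.0}
        true = {"XLogP": 0.55, "SssCH2": 0.17, "C2SP3": 0.048,
                "BIC0": 71.0, "ATSC2m": -0.0022, "ATSC2v": 0.00081}
        table = pd.DataFrame({k: rng.normal(0, s, size=n) for k, s in scales.items()})
        y = -14.0 + sum(true[k] * table[k] for k in true) + rng.normal(0, 0.14, size=n)
        fit = fit_stepwise(table, y)
        assert set(fit.selected) == set(true)
        for name, beta in true.items():
            se = fit.standard_errors[name]
            assert abs(fit.coefficients[name] - beta) < 3 * se
        assert fit.coefficients["intercept"] == pytest.approx(-14.0, abs=0.05)
        assert fit.residual_sd == pytest.approx(0.14, rel=0.15)

    def test_refit_on_own_prediction_is_exact(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({
            "XLogP": rng.uniform(5, 15, size=50),
            "SssCH2": rng.normal(20, 5, size=50),
            "C2SP3": rng.normal(30, 5, size=50),
            "BIC0": rng.normal(0.3, 0.05, size=50),
            "ATSC2m": rng.normal(0, 500, size=50),
            "ATSC2v": rng.normal(0, 2000, size=50),
            "LipoaffinityIndex": np.zeros(50),
            "SpMAD_Dzi": np.zeros(50),
        })
        rt = [predict_rt(r.to_dict()) for _, r in table.iterrows()]
        fit = fit_stepwise(table.drop(columns=["LipoaffinityIndex", "SpMAD_Dzi"]), rt)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-8)


class TestSplit:
    def test_overlapping_windows(self):
        table = pd.DataFrame({"XLogP": [10.0, 16.0, 40.0], "other": [1, 2, 3]})
        rt = [5.0, 8.0, 14.0]
        (ab, rt_ab), (c, rt_c) = split_by_segment(table, rt)
        assert list(ab["XLogP"]) == [10.0, 16.0]
        assert list(c["XLogP"]) == [16.0, 40.0]
        assert list(rt_ab) == [5.0, 8.0]
        assert list(rt_c) == [8.0, 14.0]

    def test_missing_xlogp_column(self):
        with pytest.raises(KeyError):
            split_by_segment(pd.DataFrame({"a": [1.0]}), [1.0])


def test_builtin_model_json_roundtrip(tmp_path):
    model = paper_2017()
    path = tmp_path / "model.json"
    model.to_json(path)
    from sphingolib.rt import RTModel

    loaded = RTModel.from_json(path)
    assert loaded == model
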