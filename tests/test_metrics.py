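"""R^2 / NRMSE definitions, report assembly, and generalization protocol."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canopytraits.exceptions import DomainError
from canopytraits.metrics import (EvalReport, build_report,
                                  generalization_eval, nrmse, r_squared)


class TestRSquared:
    def test_perfect_prediction(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_mean_prediction_is_zero(self):
        a = [1.0, 2.0, 3.0, 4.0]
        assert r_squared(a, [2.5] * 4) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # SSE = 1, SST = 2 -> 0.5
        assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_constant_actual_rejected(self):
        with pytest.raises(DomainError):
            r_squared([2, 2, 2], [1, 2, 3])


class TestNRMSE:
    def test_perfect_prediction_zero(self):
        assert nrmse([5, 6], [5, 6]) == 0.0

    def test_hand_computed_value(self):
        assert nrmse([10, 10], [9, 11]) == pytest.approx(10.0)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(DomainError):
            nrmse([-1, 1], [0, 0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(c=st.floats(min_value=0.01, max_value=1000))
    def test_scale_invariance(self, c):
        a = np.array([10.0, 12.0, 9.0, 20.0])
        p = np.array([11.0, 10.0, 9.5, 18.0])
        assert nrmse(a * c, p * c) == pytest.approx(nrmse(a, p), rel=1e-9)


def _truth(n=12):
    rng = np.random.default_rng(0)
    return pd.DataFrame({
        "lfw": rng.random(n) * 100 + 10,
        "ldw": rng.random(n) * 5 + 0.5,
        "la": rng.random(n) * 1000 + 100,
        "cultivar": (["Flandria", "Tiberius", "Locarno"] * n)[:n],
    }, index=[f"s{i}" for i in range(n)])


class TestBuildReport:
    def test_perfect_model_grid(self):
        truth = _truth()
        pred = truth[["lfw", "ldw", "la"]].copy()
        rep = build_report({"CNN": pred}, truth)
        grid = rep.grid("r2")
        assert np.allclose(grid.loc["CNN"], 1.0)
        assert np.allclose(rep.grid("nrmse_pct").loc["CNN"], 0.0)

    def test_per_cultivar_rows(self):
        truth = _truth()
        pred = truth[["lfw", "ldw", "la"]] * 1.05
        rep = build_report({"CNN": pred}, truth, strata=("all", "cultivar"))
        per_cv = rep.rows[rep.rows["stratum"] != "all"]
        assert len(per_cv) == 3 * 3  # 3 cultivars x 3 traits

    def test_missing_predictions_rejected(self):
        truth = _truth()
        pred = truth[["lfw", "ldw", "la"]].iloc[:-1]
        with pytest.raises(DomainError):
            build_report({"CNN": pred}, truth)

    def test_pooled_sse_equals_sum_of_stratum_sses(self):
        truth = _truth()
        rng = np.random.default_rng(3)
        pred = truth[["lfw", "ldw", "la"]] \
            + rng.normal(0, 5, (len(truth), 3))
        rep = build_report({"M": pred}, truth, strata=("all", "cultivar"))
        pairs = rep.pairs[rep.pairs["trait"] == "lfw"]
        sse_all = ((pairs["actual"] - pairs["predicted"]) ** 2).sum()
        sse_strata = sum(
            ((g["actual"] - g["predicted"]) ** 2).sum()
            for _, g in pairs.groupby("cultivar"))
        assert sse_all == pytest.approx(sse_strata)

    def test_summary_mentions_both_metrics(self):
        truth = _truth()
        rep = build_report({"CNN": truth[["lfw", "ldw", "la"]]}, truth)
        text = rep.summary()
        assert "R^2" in text and "NRMSE" in text


@pytest.fixture(scope="module")
def fitted(cultivars):
    from canopytraits.cnn import CNNTraitModel, TrainConfig
    from canopytraits.dataset import center_crop_resize
    from canopytraits.pipeline import benchmark_cnn_config
    from canopytraits.synthdata import SceneSpec, render_plant

    images, targets = [], []
    for i in range(6):
        s = render_plant(cultivars[1], (i % 7) + 1,
                         SceneSpec(rng_seed=50 + i))
        images.append(center_crop_resize(s.rgb, None, 128))
        targets.append(s.traits.as_array())
    return CNNTraitModel(np.stack(images), np.stack(targets),
                         config=benchmark_cnn_config()).fit(
        TrainConfig(max_epochs=1, batch_size=6, rng_seed=0))


class TestGeneralization:
    def _new_season(self, cultivars, n=4, illumination=1.15):
        import dataclasses

        from canopytraits.dataset import center_crop_resize
        from canopytraits.synthdata import SceneSpec, render_plant
        images, rows = [], []
        for i in range(n):
            sc = SceneSpec(rng_seed=900 + i, illumination_scale=illumination)
            s = render_plant(cultivars[1], (i % 7) + 1, sc)
            images.append(center_crop_resize(s.rgb, None, 128))
            rows.append({"id": f"s2_{i}", "lfw": s.traits.lfw,
                         "ldw": s.traits.ldw, "la": s.traits.la})
        truth = pd.DataFrame(rows).set_index("id")
        return np.stack(images), truth

    def test_no_refitting_and_finite_metrics(self, fitted, cultivars):
        images, truth = self._new_season(cultivars)
        before = fitted.weights_hash()
        rep = generalization_eval(fitted, images, truth,
                                  train_ids=["t0", "t1"])
        assert fitted.weights_hash() == before
        assert rep.label == "cross-season"
        assert np.isfinite(rep.rows["r2"]).all()

    def test_id_overlap_rejected(self, fitted, cultivars):
        images, truth = self._new_season(cultivars)
        with pytest.raises(DomainError):
            generalization_eval(fitted, images, truth,
                                train_ids=[truth.index[0]])

    def test_empty_new_season_rejected(self, fitted):
        with pytest.raises(DomainError):
            generalization_eval(fitted, np.zeros((0, 128, 128, 3)),
                                pd.DataFrame())
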