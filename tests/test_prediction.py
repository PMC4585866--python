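"""Deviance scoring, auto-/cross-prediction, specificity and SDT metrics."""

import numpy as np
import pytest

from aci.estimation import TrialTable
from aci.observer import ObserverSpec, simulate_pixel_trials
from aci.prediction import (PredictionMatrix, auto_prediction,
                            cross_prediction, deviance, prediction_matrix,
                            sdt_metrics, specificity)
from tests.conftest import make_pixel_world, simulate_table

LAM = 300.0  # working penalty for the reduced-grid worlds


class TestDeviance:
    def test_perfect_prediction_is_zero(self):
        r = np.array([0, 1, 1, 0])
        assert deviance(r.astype(float), r) == pytest.approx(0.0, abs=1e-9)

    def test_coin_flip_closed_form(self):
        # 100 trials at p = 0.5: D = -2 * 100 * ln(1/2) = 200 ln 2
        p = np.full(100, 0.5)
        r = np.zeros(100, dtype=int)
        assert deviance(p, r) == pytest.approx(200 * np.log(2), rel=1e-12)

    def test_nonnegative_and_clipped(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        r = rng.integers(2, size=50)
        assert deviance(p, r) >= 0
        assert np.isfinite(deviance(np.zeros(5), np.ones(5, dtype=int)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            deviance(np.full(3, 0.5), np.zeros(4, dtype=int))


class TestAutoPrediction:
    def test_own_model_beats_chance(self, pixel_world):
        t = simulate_table(pixel_world, 9600, seed=12)  # ~4,000 balanced
        dev, acc = auto_prediction(t, LAM, seed=0)
        assert acc >= 0.6
        # and beats the coin-flip per-trial deviance of 2 ln 2
        assert dev / (t.n_trials / 10) < 2 * np.log(2)

    def test_coin_flip_responses_predict_at_chance(self, pixel_world):
        rng = np.random.default_rng(7)
        t = simulate_table(pixel_world, 4000, seed=71, balance=False)
        coin = TrialTable(X=t.X, response=rng.integers(2, size=t.n_trials),
                          correct=np.ones(t.n_trials, dtype=bool),
                          grid_shape=t.grid_shape, balanced=True)
        _, acc = auto_prediction(coin, LAM, seed=1)
        assert acc == pytest.approx(0.5, abs=0.02)

    def test_near_deterministic_observer_predicts_highly(self, pixel_world):
        # scaling signal and noise together = raising the gain: responses
        # become a deterministic function of the stimulus
        world = make_pixel_world(signal=20.0, noise=20.0, seed=9)
        t = simulate_table(world, 6000, seed=91)
        # a crisper observer supports (and CV would select) lighter smoothing
        _, acc = auto_prediction(t, 100.0, seed=2)
        assert acc >= 0.9


class TestCrossPrediction:
    def test_train_equals_test_reproduces_auto(self, balanced_table):
        a = auto_prediction(balanced_table, LAM, seed=3)
        c = cross_prediction(balanced_table, balanced_table, LAM, seed=3)
        assert a == c

    def test_twin_observers_cross_predict_like_auto(self, pixel_world):
        t1 = simulate_table(pixel_world, 3000, seed=101)
        t2 = simulate_table(pixel_world, 3000, seed=102)
        _, auto_acc = auto_prediction(t1, LAM, seed=4)
        _, cross_acc = cross_prediction(t2, t1, LAM, seed=4)
        assert cross_acc == pytest.approx(auto_acc, abs=0.05)

    def test_orthogonal_templates_cross_predict_at_chance(self):
        w1 = make_pixel_world(seed=3)
        grid = w1["grid"]
        # observer 2: template orthogonal to observer 1's, same stimuli
        rng = np.random.default_rng(5)
        raw = rng.standard_normal(grid)
        tpl1 = w1["template"]
        raw -= np.vdot(raw, tpl1) * tpl1
        tpl2 = raw / np.linalg.norm(raw)
        mid = 0.5 * float(np.vdot(w1["da"] + w1["ga"], tpl2))
        obs2 = ObserverSpec(template=tpl2, bias=-w1["gain"] * mid,
                            gain=w1["gain"])
        X, r, cls = simulate_pixel_trials(obs2, [w1["da"], w1["ga"]], 3000,
                                          w1["pixel_sd"], seed=51)
        t2 = TrialTable(X=X, response=r, correct=(r == cls), grid_shape=grid,
                        balanced=True)
        t1 = simulate_table(w1, 3000, seed=52)
        _, acc = cross_prediction(t1, t2, LAM, seed=5)
        assert acc == pytest.approx(0.5, abs=0.04)

    def test_grid_mismatch_rejected(self, balanced_table):
        other = TrialTable(X=np.random.default_rng(0).random((40, 6)),
                           response=np.tile([0, 1], 20),
                           correct=np.ones(40, dtype=bool), grid_shape=(2, 3),
                           balanced=True)
        with pytest.raises(ValueError):
            cross_prediction(balanced_table, other, LAM)


class TestSpecificity:
    def test_identical_observers_near_zero(self, pixel_world):
        tables = [simulate_table(pixel_world, 2000, seed=s)
                  for s in (111, 112, 113)]
        pm = prediction_matrix(tables, LAM, seed=6)
        for i in range(3):
            s = specificity(pm, i)
            # exchangeable population: own-model advantage ~ 0 relative to
            # the per-listener deviance scale
            assert abs(s) < 0.12 * pm.deviance[i, i]

    def test_idiosyncratic_observers_negative(self):
        tables = []
        for k, seed in enumerate((3, 4, 5)):
            w = make_pixel_world(seed=seed)   # different template each
            tables.append(simulate_table(w, 2500, seed=200 + k))
        pm = prediction_matrix(tables, LAM, seed=7)
        for i in range(3):
            assert specificity(pm, i) < 0

    def test_single_listener_rejected(self):
        pm = PredictionMatrix(deviance=np.ones((1, 1)),
                              accuracy=np.ones((1, 1)), listener_ids=["a"],
                              fold_seed=0)
        with pytest.raises(ValueError):
            specificity(pm, 0)


class TestSDT:
    def _table(self, hits, fas, n=100):
        cls = np.concatenate([np.ones(n, int), np.zeros(n, int)])
        resp = np.concatenate([(np.arange(n) < hits * n).astype(int),
                               (np.arange(n) < fas * n).astype(int)])
        return TrialTable(X=np.zeros((2 * n, 4)), response=resp,
                          correct=(resp == cls), grid_shape=(2, 2),
                          target_class=cls, balanced=True)

    def test_symmetric_chance_gives_zero(self):
        m = sdt_metrics(self._table(0.5, 0.5))
        assert m.d_prime == pytest.approx(0.0, abs=1e-9)
        assert m.criterion == pytest.approx(0.0, abs=1e-9)

    def test_textbook_dprime(self):
        # hit 0.84, fa 0.16 -> d' = z(0.84) - z(0.16) ~= 1.99
        m = sdt_metrics(self._table(0.84, 0.16))
        assert m.d_prime == pytest.approx(1.989, abs=0.01)

    def test_extreme_rates_corrected(self):
        m = sdt_metrics(self._table(1.0, 0.16))
        assert m.hit_rate == pytest.approx(1 - 1 / 200)  # 1/(2N), N=100
        assert np.isfinite(m.d_prime)

    def test_missing_class_rejected(self):
        t = self._table(0.8, 0.2)
        sub = t.subset(np.flatnonzero(t.target_class == 1))
        with pytest.raises(ValueError):
            sdt_metrics(sub)


def test_population_auto_beats_cross_on_average():
    """Heterogeneous templates: own model predicts best (deviance gap < 0)."""
    tables = []
    for k, seed in enumerate((13, 14, 15, 16)):
        w = make_pixel_world(seed=seed)
        tables.append(simulate_table(w, 2000, seed=300 + k))
    pm = prediction_matrix(tables, LAM, seed=8)
    n = len(tables)
    auto_acc = np.diag(pm.accuracy).mean()
    cross_acc = pm.accuracy[~np.eye(n, dtype=bool)].mean()
    assert auto_acc >= cross_acc
    assert np.all(pm.accuracy >= 0) and np.all(pm.accuracy <= 1)
    assert np.all(pm.deviance >= 0)
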