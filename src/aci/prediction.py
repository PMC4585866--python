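"""Auto-/cross-prediction deviance analysis and signal-detection metrics.

How well does a listener's fitted template predict responses — their
own held-out responses (auto-prediction, 10-fold cross-validation) and
other listeners' responses (cross-prediction)?  Both use the identical
fold machinery: the training listener's balanced trials are split into
ten response-stratified subsets, a model is fitted on each nine-subset
training set, and each model is scored on the corresponding held-out
partition of the *test* listener's data; the ten held-out deviances
(and prediction accuracies) are averaged.  With train == test this is
ordinary cross-validation, so auto- and cross-prediction deviances are
on the same scale.

Specificity of a listener's strategy is the auto-prediction deviance
minus the mean cross-prediction deviance of their data under the other
listeners' models: negative when the own model predicts best.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .estimation import (TrialTable, deviance_of_probs, fit_aci,
                         stratified_folds)

deviance = deviance_of_probs


def _accuracy(p: np.ndarray, r: np.ndarray) -> float:
    """Fraction of trials whose predicted-probability side matches r.

    A predicted probability of exactly 0.5 takes no side and counts as
    an incorrect prediction.
    """
    p = np.asarray(p)
    r = np.asarray(r)
    hit = ((p > 0.5) & (r == 1)) | ((p < 0.5) & (r == 0))
    return float(hit.mean())


def cross_prediction(train_table: TrialTable, test_table: TrialTable,
                     penalty_weight: float, n_folds: int = 10,
                     seed: int = 0, tol: float = 1e-6):
    """Score models fitted on one listener against another's responses.

    Returns (mean held-out deviance, mean held-out accuracy) over
    ``n_folds`` folds.  With ``train_table is test_table`` (or an equal
    table and the same seed) this reproduces auto-prediction exactly.
    """
    if train_table.X.shape[1] != test_table.X.shape[1] or \
            train_table.grid_shape != test_table.grid_shape:
        raise ValueError("train and test tables use different pixel grids")
    rng_train = np.random.default_rng([seed, 0])
    rng_test = np.random.default_rng([seed, 0])
    train_folds = stratified_folds(train_table.response, n_folds, rng_train)
    test_folds = stratified_folds(test_table.response, n_folds, rng_test)
    devs, accs = [], []
    for tr_idx, te_idx in zip(train_folds, test_folds):
        mask = np.ones(train_table.n_trials, dtype=bool)
        mask[tr_idx] = False
        model = fit_aci(train_table.subset(np.flatnonzero(mask)),
                        penalty_weight, tol=tol)
        p = model.predict_proba(test_table.X[te_idx])
        r = test_table.response[te_idx]
        devs.append(deviance_of_probs(p, r))
        accs.append(_accuracy(p, r))
    return float(np.mean(devs)), float(np.mean(accs))


def auto_prediction(table: TrialTable, penalty_weight: float,
                    n_folds: int = 10, seed: int = 0, tol: float = 1e-6):
    """10-fold cross-validated deviance and accuracy on the listener's own data."""
    return cross_prediction(table, table, penalty_weight, n_folds, seed, tol)


@dataclass
class PredictionMatrix:
    """N x N train-by-test deviance and accuracy matrices.

    Entry [j, i] scores models trained on listener j against listener
    i's responses; the diagonal is auto-prediction (10-fold CV).
    """

    deviance: np.ndarray
    accuracy: np.ndarray
    listener_ids: list
    fold_seed: int

    def to_frame(self, which: str = "deviance") -> pd.DataFrame:
        m = getattr(self, which)
        return pd.DataFrame(m, index=self.listener_ids,
                            columns=self.listener_ids)


def prediction_matrix(tables, penalty_weight: float, n_folds: int = 10,
                      seed: int = 0, tol: float = 1e-6) -> PredictionMatrix:
    tables = list(tables)
    n = len(tables)
    dev = np.empty((n, n))
    acc = np.empty((n, n))
    for j in range(n):          # training listener
        for i in range(n):      # tested listener
            dev[j, i], acc[j, i] = cross_prediction(
                tables[j], tables[i], penalty_weight, n_folds, seed, tol)
    ids = [t.listener_id or str(k) for k, t in enumerate(tables)]
    return PredictionMatrix(deviance=dev, accuracy=acc, listener_ids=ids,
                            fold_seed=seed)


def specificity(matrix: PredictionMatrix, listener_i: int) -> float:
    """Auto-prediction deviance minus mean others-model deviance on own data.

    Lower deviance means a better fit, so a listener whose own model
    predicts their responses best gets a negative specificity.
    """
    d = matrix.deviance
    n = d.shape[0]
    if n < 2:
        raise ValueError("specificity needs at least two listeners")
    others = [d[j, listener_i] for j in range(n) if j != listener_i]
    return float(d[listener_i, listener_i] - np.mean(others))


@dataclass(frozen=True)
class SDTMetrics:
    d_prime: float
    criterion: float
    hit_rate: float
    fa_rate: float


def sdt_metrics(table: TrialTable) -> SDTMetrics:
    """Sensitivity d' and decision criterion for the da/ga categorization.

    'ga' responses to /ga/ targets are hits, to /da/ targets false
    alarms; extreme rates are pulled in by the 1/(2N) rule before the
    normal quantile transform.
    """
    if table.target_class is None:
        raise ValueError("table lacks target-class information")
    cls = np.asarray(table.target_class)
    resp = table.response
    out = {}
    for label, value in (("hit", 1), ("fa", 0)):
        mask = cls == value
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"no trials with target class {value}")
        rate = float(resp[mask].mean())
        rate = min(max(rate, 1 / (2 * n)), 1 - 1 / (2 * n))
        out[label] = rate
    zh, zf = norm.ppf(out["hit"]), norm.ppf(out["fa"])
    return SDTMetrics(d_prime=float(zh - zf),
                      criterion=float(-(zh + zf) / 2),
                      hit_rate=out["hit"], fa_rate=out["fa"])
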