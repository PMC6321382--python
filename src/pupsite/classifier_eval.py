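"""RBF-SVM training and evaluation.

Wraps scikit-learn's SVC behind the package's FeatureMatrix container and
provides the evaluation protocols used throughout: jackknife (leave-one-out),
repeated stratified 10-fold cross-validation, and exhaustive (C, gamma) grid
search.  Performance is summarized by sensitivity, specificity and accuracy
(as percentages), the Matthews correlation coefficient, and a rank-based
(Mann-Whitney) AUC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .peptide_io import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SvmConfig:
    """RBF-kernel SVM hyperparameters."""

    C: float = 0.70711
    gamma: float = 1.4142
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if self.kernel != "rbf":
            raise ValueError("only the RBF kernel is supported")


@dataclass(frozen=True)
class EvalMetrics:
    """Confusion counts plus Sn/Sp/Acc (percent), MCC and optional AUC.

    Fields whose denominator vanished are NaN (MCC: 0) and listed in
    ``undefined``.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float | None = None
    undefined: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float]:
        d = {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "Sn": self.sn, "Sp": self.sp, "Acc": self.acc, "MCC": self.mcc,
        }
        if self.auc is not None:
            d["AUC"] = self.auc
        return d


def compute_metrics(
    tp: int, fp: int, tn: int, fn: int, auc_value: float | None = None
) -> EvalMetrics:
    """Sn, Sp, Acc (percent) and MCC from confusion counts.

    MCC uses the square-rooted denominator; a vanishing denominator yields
    MCC = 0 with an ``undefined`` flag, and Sn/Sp become NaN when their
    class is empty.
    """
    for name, v in [("TP", tp), ("FP", fp), ("TN", tn), ("FN", fn)]:
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer")
    tp, fp, tn, fn = int(tp), int(fp), int(tn), int(fn)
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty confusion table")
    undefined: set[str] = set()
    if tp + fn > 0:
        sn = 100.0 * tp / (tp + fn)
    else:
        sn = math.nan
        undefined.add("Sn")
    if tn + fp > 0:
        sp = 100.0 * tn / (tn + fp)
    else:
        sp = math.nan
        undefined.add("Sp")
    acc = 100.0 * (tp + tn) / total
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    if denom > 0:
        mcc = (tp * tn - fn * fp) / math.sqrt(denom)
    else:
        mcc = 0.0
        undefined.add("MCC")
    return EvalMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn, sn=sn, sp=sp, acc=acc, mcc=mcc,
        auc=auc_value, undefined=frozenset(undefined),
    )


def auc(decision_scores: Sequence[float], y: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores contribute 1/2."""
    s = np.asarray(decision_scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    r_pos = ranks[y == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class TrainedSvm:
    """A fitted SVC bound to the feature names it was trained on."""

    estimator: SVC
    feature_names: list[str]
    config: SvmConfig

    def _check(self, X: FeatureMatrix) -> np.ndarray:
        if X.feature_names != self.feature_names:
            raise ValueError("prediction features do not match training features")
        return X.values

    def predict(self, X: FeatureMatrix) -> np.ndarray:
        return self.estimator.predict(self._check(X)).astype(int)

    def decision_function(self, X: FeatureMatrix) -> np.ndarray:
        return self.estimator.decision_function(self._check(X))


def train_svm(
    X: FeatureMatrix, y: Sequence[int], config: SvmConfig = SvmConfig()
) -> TrainedSvm:
    y = np.asarray(y, dtype=int)
    if y.shape[0] != X.n_samples:
        raise ValueError("label length does not match sample count")
    if len(set(y.tolist())) < 2:
        raise ValueError("training labels contain a single class")
    if not np.isfinite(X.values).all():
        raise ValueError("feature matrix contains non-finite values")
    est = SVC(kernel="rbf", C=config.C, gamma=config.gamma)
    est.fit(X.values, y)
    return TrainedSvm(est, list(X.feature_names), config)


def _fit_predict(
    X: np.ndarray,
    y: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
    config: SvmConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Train on ``train`` rows, return (predictions, scores) on ``test``.

    A training split collapsing to one class predicts that (majority)
    class everywhere, with matching-sign scores, and logs the event.
    """
    classes = set(y[train].tolist())
    if len(classes) < 2:
        only = classes.pop()
        logger.warning("single-class training split: predicting class %d", only)
        pred = np.full(test.size, only)
        score = np.where(pred == 1, 1.0, -1.0)
        return pred, score
    est = SVC(kernel="rbf", C=config.C, gamma=config.gamma)
    est.fit(X[train], y[train])
    return est.predict(X[test]).astype(int), est.decision_function(X[test])


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    return tp, fp, tn, fn


def jackknife_eval(
    X: FeatureMatrix, y: Sequence[int], config: SvmConfig = SvmConfig()
) -> EvalMetrics:
    """Leave-one-out evaluation; confusion counts pooled over all n."""
    y = np.asarray(y, dtype=int)
    n = X.n_samples
    if n < 2 or len(set(y.tolist())) < 2:
        raise ValueError("jackknife needs n >= 2 and both classes")
    preds = np.empty(n, dtype=int)
    scores = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        train = idx[idx != i]
        p, s = _fit_predict(X.values, y, train, np.array([i]), config)
        preds[i], scores[i] = p[0], s[0]
    tp, fp, tn, fn = _confusion(y, preds)
    return compute_metrics(tp, fp, tn, fn, auc_value=auc(scores, y))


@dataclass
class CvReport:
    """Repeated k-fold result: per-repeat metrics and their means."""

    protocol: str
    k: int
    repeats: int
    seed: int
    leakage_mode: str
    repeat_metrics: list[EvalMetrics]
    pooled: EvalMetrics

    @property
    def means(self) -> dict[str, float]:
        keys = ["Sn", "Sp", "Acc", "MCC", "AUC"]
        out = {}
        for key in keys:
            vals = [m.as_dict().get(key) for m in self.repeat_metrics]
            vals = [v for v in vals if v is not None and not math.isnan(v)]
            out[key] = float(np.mean(vals)) if vals else math.nan
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [m.as_dict() for m in self.repeat_metrics]
        df = pd.DataFrame(rows)
        df.insert(0, "repeat", range(1, len(rows) + 1))
        return df

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def _stratified_folds(
    y: np.ndarray, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    n = y.shape[0]
    if k == n:  # leave-one-out; stratification is meaningless at k = n
        idx = np.arange(n)
        return [(idx[idx != i], np.array([i])) for i in range(n)]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2 ** 31))
    return [(tr, te) for tr, te in skf.split(np.zeros(n), y)]


def kfold_eval(
    X: FeatureMatrix,
    y: Sequence[int],
    config: SvmConfig = SvmConfig(),
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> CvReport:
    """Repeated stratified k-fold CV; folds reshuffled each repeat.

    Per-repeat metrics pool the confusion counts of that repeat's folds;
    the report's ``pooled`` entry pools all repeats.
    """
    y = np.asarray(y, dtype=int)
    n = X.n_samples
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes required")
    repeat_metrics: list[EvalMetrics] = []
    all_scores: list[np.ndarray] = []
    all_true: list[np.ndarray] = []
    grand = np.zeros(4, dtype=int)
    for rep in range(repeats):
        preds = np.empty(n, dtype=int)
        scores = np.empty(n)
        for train, test in _stratified_folds(y, k, seed + 9973 * rep):
            p, s = _fit_predict(X.values, y, train, test, config)
            preds[test], scores[test] = p, s
        tp, fp, tn, fn = _confusion(y, preds)
        grand += (tp, fp, tn, fn)
        repeat_metrics.append(
            compute_metrics(tp, fp, tn, fn, auc_value=auc(scores, y))
        )
        all_scores.append(scores)
        all_true.append(y)
    pooled = compute_metrics(
        *grand, auc_value=auc(np.concatenate(all_scores), np.concatenate(all_true))
    )
    return CvReport(
        protocol="kfold", k=k, repeats=repeats, seed=seed,
        leakage_mode="precomputed-features",
        repeat_metrics=repeat_metrics, pooled=pooled,
    )


DEFAULT_GRID: tuple[float, ...] = tuple(
    2.0 ** (e / 2.0) for e in range(-10, 11)
)  # 2^-5 ... 2^5 in half-integer exponent steps


def grid_search(
    X: FeatureMatrix,
    y: Sequence[int],
    C_grid: Sequence[float] = DEFAULT_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GRID,
    folds: int = 10,
    seed: int = 0,
    repeats: int = 1,
) -> tuple[SvmConfig, pd.DataFrame]:
    """Exhaustive (C, gamma) search scored by mean CV accuracy.

    Ties broken by larger MCC, then smaller C, then smaller gamma.
    """
    if not len(C_grid) or not len(gamma_grid):
        raise ValueError("grids must be non-empty")
    rows = []
    for C in C_grid:
        for g in gamma_grid:
            cfg = SvmConfig(C=C, gamma=g)
            rep = kfold_eval(X, y, cfg, k=folds, repeats=repeats, seed=seed)
            m = rep.means
            rows.append((C, g, m["Sn"], m["Sp"], m["Acc"], m["MCC"]))
    table = pd.DataFrame(rows, columns=["C", "gamma", "Sn", "Sp", "Acc", "MCC"])
    best = max(rows, key=lambda r: (r[4], r[5], -r[0], -r[1]))
    return SvmConfig(C=best[0], gamma=best[1]), table
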