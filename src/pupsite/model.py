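"""Model-level interface: a pupylation-site predictor fitted to windows.

``PupylationSVM`` bundles the full pipeline — feature encoding (correlation-
selected dipeptide composition, Top-n-gram, positional bi-profile scores,
pseudo amino acid composition), class rebalancing (KPCA oversampling + fuzzy
undersampling) and an RBF SVM — behind a statsmodels-style ``fit()`` that
returns a ``PupylationResults`` carrying the trained classifier, the fitted
feature model, the resampling report and resubstitution metrics.

Cross-validation supports two leakage modes:

* ``paper-faithful`` — the training set is balanced once, before the folds
  are drawn, so synthetic positives derived from test-fold samples can leak
  into training.  This mirrors the original protocol and inflates scores.
* ``leak-free`` — feature fitting (pair ranking, positional profiles) and
  resampling are redone inside every training fold; held-out windows are
  never touched before prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import encoders, feature_selection, resampling
from .classifier_eval import (
    CvReport,
    EvalMetrics,
    SvmConfig,
    TrainedSvm,
    _confusion,
    _stratified_folds,
    auc,
    compute_metrics,
    grid_search,
    kfold_eval,
    train_svm,
)
from .encoders import ANBPBModel, PropertyTables, combine_features
from .feature_selection import PairRanking, rank_amino_acid_pairs, select_aapc_features
from .peptide_io import (
    FeatureMatrix,
    PeptideWindow,
    SiteDataset,
    read_window_table,
)

logger = logging.getLogger(__name__)

PAPER_FAITHFUL = "paper-faithful"
LEAK_FREE = "leak-free"

KNOWN_ENCODERS = ("aac", "aapc", "top1gram", "top2gram", "anbpb", "pcpseaac")

# coarse sub-grid of the sqrt(2)-spaced search grid, used when a fit tunes
# its own (C, gamma) by internal cross-validation
TUNE_C_GRID: tuple[float, ...] = (2.0 ** -3, 1.0, 2.0 ** 3)
TUNE_GAMMA_GRID: tuple[float, ...] = (2.0 ** -5, 2.0 ** -2.5, 1.0, 2.0 ** 2.5)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs, validated up front.

    Defaults follow the method's reported configuration: 320 of 400 ranked
    dipeptide features combined with Top-1-gram, the positional bi-profile
    block and PC-PseAAC (lambda=5, weight=0.05); balancing to 1:1 with
    k = 3 clusters repeated 4 times; RBF SVM at C = 0.70711,
    gamma = 1.4142.
    """

    encoders: tuple[str, ...] = ("aapc", "top1gram", "anbpb", "pcpseaac")
    select_n: int | None = 320
    pse_lambda: int = 5
    pse_weight: float = 0.05
    balance: bool = True
    target_pos: int | None = None  # None: 2 * n_pos
    target_neg: int | None = None  # None: same as target_pos
    kmeans_k: int = 3
    kmeans_repeats: int = 4
    svm: SvmConfig = field(default_factory=SvmConfig)
    tune: bool = False  # per-fit coarse (C, gamma) grid search
    tune_folds: int = 3
    leakage_mode: str = PAPER_FAITHFUL
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.encoders) - set(KNOWN_ENCODERS)
        if unknown:
            raise ValueError(f"unknown encoders: {sorted(unknown)}")
        if not self.encoders:
            raise ValueError("at least one encoder required")
        if self.select_n is not None and self.select_n not in feature_selection.STEP_GRID:
            raise ValueError("select_n must be a multiple of 20 in [20, 400]")
        if self.select_n is not None and "aapc" not in self.encoders:
            raise ValueError("select_n requires the aapc encoder")
        if self.leakage_mode not in (PAPER_FAITHFUL, LEAK_FREE):
            raise ValueError(f"unknown leakage mode {self.leakage_mode!r}")


@dataclass
class FeatureModel:
    """Per-training-set state needed to encode new windows consistently."""

    config: PipelineConfig
    ranking: PairRanking | None
    anbpb: ANBPBModel | None
    tables: PropertyTables

    def encode(self, windows: Sequence[PeptideWindow]) -> FeatureMatrix:
        blocks: list[tuple[str, FeatureMatrix]] = []
        for name in self.config.encoders:
            if name == "aac":
                blocks.append(("aac", encoders.aac_matrix(windows)))
            elif name == "aapc":
                fm = encoders.aapc_matrix(windows)
                if self.config.select_n is not None:
                    fm = select_aapc_features(fm, self.ranking, self.config.select_n)
                blocks.append(("aapc", fm))
            elif name in ("top1gram", "top2gram"):
                n = 1 if name == "top1gram" else 2
                blocks.append((name, encoders.top_n_gram_matrix(windows, n)))
            elif name == "anbpb":
                blocks.append(("anbpb", encoders.anbpb_matrix(self.anbpb, windows)))
            elif name == "pcpseaac":
                blocks.append((
                    "pcpseaac",
                    encoders.pc_pseaac_matrix(
                        windows,
                        lam=self.config.pse_lambda,
                        weight=self.config.pse_weight,
                        tables=self.tables,
                    ),
                ))
        return combine_features(blocks)


def fit_feature_model(
    windows: Sequence[PeptideWindow], config: PipelineConfig
) -> FeatureModel:
    """Fit the data-dependent encoder state (pair ranking, positional
    profiles) on labeled training windows only."""
    pos = [w for w in windows if w.label == "positive"]
    neg = [w for w in windows if w.label == "negative"]
    ranking = None
    if "aapc" in config.encoders and config.select_n is not None:
        ranking = rank_amino_acid_pairs(encoders.aac_matrix(list(windows)))
    anbpb = None
    if "anbpb" in config.encoders:
        anbpb = encoders.fit_anbpb(pos, neg)
    return FeatureModel(
        config=config,
        ranking=ranking,
        anbpb=anbpb,
        tables=encoders.load_default_property_tables(),
    )


class PupylationSVM:
    """Pupylation-site prediction model over a labeled window dataset."""

    def __init__(self, dataset: SiteDataset, config: PipelineConfig | None = None):
        if not dataset.positives or not dataset.negatives:
            raise ValueError("dataset must contain both labeled classes")
        self.dataset = dataset
        self.config = config or PipelineConfig()

    @classmethod
    def from_window_table(
        cls, path, config: PipelineConfig | None = None
    ) -> "PupylationSVM":
        return cls(read_window_table(path), config=config)

    def _balance(
        self, X: FeatureMatrix, y: np.ndarray, seed: int
    ) -> tuple[FeatureMatrix, np.ndarray, resampling.ResamplingReport | None]:
        cfg = self.config
        if not cfg.balance:
            return X, y, None
        pos_rows = np.flatnonzero(y == 1)
        neg_rows = np.flatnonzero(y == 0)
        pos_fm = X.take(pos_rows)
        neg_fm = X.take(neg_rows)
        # default: grow positives toward 2x, but never past the negative
        # count, so already-balanced data passes through unchanged
        target_pos = cfg.target_pos or max(
            pos_fm.n_samples, min(2 * pos_fm.n_samples, neg_fm.n_samples)
        )
        target_neg = min(cfg.target_neg or target_pos, neg_fm.n_samples)
        return resampling.balance_dataset(
            pos_fm, neg_fm, target_pos, target_neg,
            k=cfg.kmeans_k, repeats=cfg.kmeans_repeats, seed=seed,
        )

    def fit(self) -> "PupylationResults":
        cfg = self.config
        windows = self.dataset.windows
        fmodel = fit_feature_model(windows, cfg)
        X = fmodel.encode(windows)
        y = self.dataset.labels_array()
        Xb, yb, report = self._balance(X, y, cfg.seed)
        svm_cfg = cfg.svm
        if cfg.tune:
            svm_cfg, _ = grid_search(
                Xb, yb, C_grid=TUNE_C_GRID, gamma_grid=TUNE_GAMMA_GRID,
                folds=cfg.tune_folds, seed=cfg.seed,
            )
        svm = train_svm(Xb, yb, svm_cfg)
        preds = svm.predict(X)
        resub = compute_metrics(
            *_confusion(y, preds), auc_value=auc(svm.decision_function(X), y)
        )
        return PupylationResults(
            model=self, feature_model=fmodel, svm=svm,
            resampling_report=report, resubstitution=resub,
        )


@dataclass
class PupylationResults:
    """Fit results: trained classifier plus everything needed to reuse it."""

    model: PupylationSVM
    feature_model: FeatureModel
    svm: TrainedSvm
    resampling_report: resampling.ResamplingReport | None
    resubstitution: EvalMetrics

    @property
    def config(self) -> PipelineConfig:
        return self.model.config

    def predict(self, windows: Sequence[PeptideWindow]) -> np.ndarray:
        """Binary predictions (1 = pupylation site) for new windows."""
        return self.svm.predict(self.feature_model.encode(windows))

    def decision_scores(self, windows: Sequence[PeptideWindow]) -> np.ndarray:
        return self.svm.decision_function(self.feature_model.encode(windows))

    def cross_validate(
        self, k: int = 10, repeats: int = 10, seed: int | None = None
    ) -> CvReport:
        return cross_validate_windows(
            self.model.dataset, self.config, k=k, repeats=repeats,
            seed=self.config.seed if seed is None else seed,
        )

    def summary(self) -> str:
        cfg = self.config
        counts = self.model.dataset.counts
        lines = [
            "Pupylation-site SVM results",
            "=" * 60,
            f"windows:            {len(self.model.dataset)} "
            f"({counts['positive']} positive, {counts['negative']} negative)",
            f"encoders:           {', '.join(cfg.encoders)}",
            f"dipeptide subset:   {cfg.select_n if cfg.select_n else 'all 400'}",
            f"feature dimension:  {len(self.svm.feature_names)}",
            f"SVM:                RBF, C={cfg.svm.C}, gamma={cfg.svm.gamma}",
            f"leakage mode:       {cfg.leakage_mode}",
        ]
        if self.resampling_report is not None:
            r = self.resampling_report
            lines.append(
                f"rebalanced:         {r.n_pos_before}:{r.n_neg_before} -> "
                f"{r.n_pos_after}:{r.n_neg_after} "
                f"(k={r.k}, repeats={r.repeats}, seed={r.seed})"
            )
        m = self.resubstitution
        lines += [
            "-" * 60,
            "resubstitution (training windows):",
            f"  Sn={m.sn:.2f}%  Sp={m.sp:.2f}%  Acc={m.acc:.2f}%  "
            f"MCC={m.mcc:.4f}  AUC={m.auc:.4f}",
        ]
        return "\n".join(lines)


def cross_validate_windows(
    dataset: SiteDataset,
    config: PipelineConfig,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> CvReport:
    """Window-level cross-validation in the configured leakage mode."""
    if config.leakage_mode == PAPER_FAITHFUL:
        model = PupylationSVM(dataset, config)
        fmodel = fit_feature_model(dataset.windows, config)
        X = fmodel.encode(dataset.windows)
        y = dataset.labels_array()
        Xb, yb, _ = model._balance(X, y, seed)
        if config.balance:
            logger.warning(
                "paper-faithful mode balances before CV: synthetic samples "
                "derived from test folds can leak into training"
            )
        report = kfold_eval(Xb, yb, config.svm, k=k, repeats=repeats, seed=seed)
        report.leakage_mode = PAPER_FAITHFUL
        return report
    return _leak_free_cv(dataset, config, k, repeats, seed)


def _leak_free_cv(
    dataset: SiteDataset,
    config: PipelineConfig,
    k: int,
    repeats: int,
    seed: int,
) -> CvReport:
    windows = dataset.windows
    y = dataset.labels_array()
    n = len(windows)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    repeat_metrics: list[EvalMetrics] = []
    all_scores: list[np.ndarray] = []
    grand = np.zeros(4, dtype=int)
    for rep in range(repeats):
        preds = np.empty(n, dtype=int)
        scores = np.empty(n)
        for f, (train, test) in enumerate(
            _stratified_folds(y, k, seed + 9973 * rep)
        ):
            fold_ds = SiteDataset([windows[i] for i in train])
            fold_cfg = replace(config, seed=seed + 7919 * rep + f)
            res = PupylationSVM(fold_ds, fold_cfg).fit()
            test_windows = [windows[i] for i in test]
            preds[test] = res.predict(test_windows)
            scores[test] = res.decision_scores(test_windows)
        tp, fp, tn, fn = _confusion(y, preds)
        grand += (tp, fp, tn, fn)
        repeat_metrics.append(
            compute_metrics(tp, fp, tn, fn, auc_value=auc(scores, y))
        )
        all_scores.append(scores)
    pooled = compute_metrics(
        *grand,
        auc_value=auc(np.concatenate(all_scores), np.tile(y, repeats)),
    )
    return CvReport(
        protocol="kfold", k=k, repeats=repeats, seed=seed,
        leakage_mode=LEAK_FREE,
        repeat_metrics=repeat_metrics, pooled=pooled,
    )
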