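"""Feature-selected random-forest prediction of spontaneous VT termination.

The classifier is a random forest over the first-10-CL variability and
AR(1) stability features.  Features whose impurity importance strictly
exceeds the mean importance (measured on a forest fit to the training
data) are retained; evaluation is stratified k-fold cross-validation
with out-of-fold predicted probabilities pooled across folds and the
diagnostic metrics computed on the pooled predictions at a 0.5
threshold.  The positive class is spontaneous termination.

By default feature selection is re-run inside every training fold so the
cross-validation estimate is leakage-free; ``selection="once"``
reproduces the simpler (leakier) variant with a single selection pass on
the full data before cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

DEFAULT_CANDIDATES = [
    "mean_cl10",
    "sd_cl10",
    "rmssd10",
    "nn50_10",
    "pnn50_10",
    "tinn10",
    "ar_phi",
    "ar_resid_sd",
    "ar_const",
]


@dataclass
class ClassifierConfig:
    n_trees: int = 500
    k_folds: int = 10
    seed: int = 0
    candidate_features: list[str] = field(default_factory=lambda: list(DEFAULT_CANDIDATES))
    positive_class: str = "terminating"
    selection: str = "per-fold"  # or "once"
    group_by_patient: bool = False

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not self.candidate_features:
            raise ValueError("candidate_features must be non-empty")
        if self.selection not in ("per-fold", "once"):
            raise ValueError("selection must be 'per-fold' or 'once'")


@dataclass
class FoldMetrics:
    fold: int
    n_test: int
    accuracy: float
    selected_features: list[str]


@dataclass
class EvalResult:
    accuracy: float
    accuracy_ci95: tuple[float, float]
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    auroc: float
    selected_features: list[str]
    per_fold: list[FoldMetrics]
    pooled_probabilities: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "accuracy_ci95": list(self.accuracy_ci95),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "auroc": self.auroc,
            "selected_features": self.selected_features,
            "per_fold": [
                {
                    "fold": f.fold,
                    "n_test": f.n_test,
                    "accuracy": f.accuracy,
                    "selected_features": f.selected_features,
                }
                for f in self.per_fold
            ],
        }


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict:
    """Accuracy, sensitivity, specificity, PPV, NPV from a 2x2 table.

    Ratios with a zero denominator are reported as ``None`` (missing),
    never as 0.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be non-negative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("at least one count must be positive")

    def ratio(num, den):
        return num / den if den > 0 else None

    return {
        "accuracy": (tp + tn) / total,
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


def _design(features: pd.DataFrame, cfg: ClassifierConfig):
    missing = [c for c in cfg.candidate_features if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks candidate feature(s) {missing}")
    # canonical row order: metrics do not depend on input row order
    if "episode_id" in features.columns:
        features = features.sort_values("episode_id", kind="mergesort").reset_index(drop=True)
    X = features[cfg.candidate_features].to_numpy(dtype=float)
    y = (features["label"].to_numpy() == cfg.positive_class).astype(int)
    # canonical training/stratification labels independent of which class is
    # 'positive': a positive_class swap reuses the same folds and models and
    # only re-projects the metrics
    y_strat = np.asarray(pd.factorize(features["label"], sort=True)[0])
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    return features, X, y, y_strat


def _forest(cfg: ClassifierConfig, seed: int) -> RandomForestClassifier:
    # sqrt-features per split and unlimited depth: common forest defaults
    return RandomForestClassifier(
        n_estimators=cfg.n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )


def _select(X: np.ndarray, y: np.ndarray, cfg: ClassifierConfig, seed: int) -> list[int]:
    forest = _forest(cfg, seed).fit(X, y)
    imp = forest.feature_importances_
    keep = np.flatnonzero(imp > imp.mean())
    if len(keep) == 0:  # exact ties with the mean (e.g. a single candidate)
        keep = np.flatnonzero(imp >= imp.mean())
    return list(keep)


def select_features(
    features: pd.DataFrame, cfg: ClassifierConfig | None = None
) -> list[str]:
    """Features whose forest importance strictly exceeds the mean importance.

    Deterministic for a fixed ``cfg.seed``.
    """
    cfg = cfg or ClassifierConfig()
    _, X, _, y_strat = _design(features, cfg)
    keep = _select(X, y_strat, cfg, cfg.seed)
    return [cfg.candidate_features[i] for i in keep]


def cross_validate(features: pd.DataFrame, cfg: ClassifierConfig | None = None) -> EvalResult:
    """Stratified k-fold cross-validation of the feature-selected forest.

    Within each training fold (default): select features, refit the
    forest on the selected columns, predict out-of-fold probabilities.
    Pooled out-of-fold predictions give the diagnostic metrics (0.5
    threshold) and AUROC; the 95% CI on accuracy is the normal
    approximation ``acc +/- 1.96 sqrt(acc (1-acc)/n)``.  Bit-identical
    for a fixed seed.
    """
    cfg = cfg or ClassifierConfig()
    features, X, y, y_strat = _design(features, cfg)
    n = len(y)
    n_pos, n_neg = int(y.sum()), int(n - y.sum())
    if min(n_pos, n_neg) < cfg.k_folds:
        raise ValueError(
            f"smallest class has {min(n_pos, n_neg)} episodes < k_folds={cfg.k_folds}; "
            "use a smaller k"
        )

    if cfg.group_by_patient:
        if "patient_id" not in features.columns:
            raise ValueError("group_by_patient requires a 'patient_id' column")
        groups = features["patient_id"].to_numpy()
        splitter = StratifiedGroupKFold(n_splits=cfg.k_folds, shuffle=True, random_state=cfg.seed)
        splits = splitter.split(X, y_strat, groups)
    else:
        splitter = StratifiedKFold(n_splits=cfg.k_folds, shuffle=True, random_state=cfg.seed)
        splits = splitter.split(X, y_strat)

    # the canonical code of the positive class, for projecting probabilities
    pos_code = int(y_strat[np.argmax(y == 1)])

    once_keep: list[int] | None = None
    if cfg.selection == "once":
        once_keep = _select(X, y_strat, cfg, cfg.seed)

    proba = np.full(n, np.nan)
    per_fold: list[FoldMetrics] = []
    for fold, (tr, te) in enumerate(splits):
        fold_seed = cfg.seed + 1000 + fold
        keep = once_keep if once_keep is not None else _select(X[tr], y_strat[tr], cfg, fold_seed)
        model = _forest(cfg, fold_seed).fit(X[np.ix_(tr, keep)], y_strat[tr])
        p = model.predict_proba(X[np.ix_(te, keep)])[:, list(model.classes_).index(pos_code)]
        proba[te] = p
        fold_acc = float(np.mean((p >= 0.5).astype(int) == y[te]))
        per_fold.append(
            FoldMetrics(fold, len(te), fold_acc, [cfg.candidate_features[i] for i in keep])
        )

    pred = (proba >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    cm = confusion_metrics(tp, fp, tn, fn)
    acc = cm["accuracy"]
    half = 1.96 * math.sqrt(acc * (1.0 - acc) / n)
    auroc = float(roc_auc_score(y, proba))

    # consensus selected set: features kept in a majority of folds
    counts: dict[str, int] = {}
    for f in per_fold:
        for name in f.selected_features:
            counts[name] = counts.get(name, 0) + 1
    majority = [name for name in cfg.candidate_features if counts.get(name, 0) > len(per_fold) / 2]

    return EvalResult(
        accuracy=acc,
        accuracy_ci95=(acc - half, acc + half),
        sensitivity=cm["sensitivity"],
        specificity=cm["specificity"],
        ppv=cm["ppv"],
        npv=cm["npv"],
        auroc=auroc,
        selected_features=majority,
        per_fold=per_fold,
        pooled_probabilities=proba,
    )
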