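"""Classification protocol: SMOTE, z-scoring, sequential forward selection
by F1, and leave-one-out evaluation of SVM / k-NN models.

All resampling and scaling is fitted inside each training fold (both the
inner 5-fold used for selection scoring and the outer leave-one-out),
so no information from a held-out sample leaks into preprocessing.  A
non-nested "global SMOTE" mode exists behind an explicit flag for
comparison only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.svm import SVC

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    classifier: str = "svm"          # "svm" | "knn"
    svm_kernel: str = "linear"
    svm_c: float = 1.0
    knn_k: int = 5
    smote_neighbors: int = 5
    max_features: int = 7
    inner_folds: int = 5
    seed: int = 0
    positive_class: str = "PR"
    unsafe_smote_global: bool = False

    def __post_init__(self) -> None:
        if self.classifier not in ("svm", "knn"):
            raise ValueError("classifier must be 'svm' or 'knn'")
        if self.max_features < 1:
            raise ValueError("max_features must be >= 1")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def _safe_ratio(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def metrics_from_confusion(c: ConfusionCounts) -> dict:
    """Sensitivity/specificity/accuracy/precision/F1/balanced accuracy.

    Ratios are fractions in [0, 1]; ``*_pct`` fields are rounded to one
    decimal as percentages.  Undefined ratios are reported as 0 with a
    flag listing which ones.
    """
    sn, f_sn = _safe_ratio(c.TP, c.TP + c.FN)
    sp, f_sp = _safe_ratio(c.TN, c.TN + c.FP)
    acc, f_acc = _safe_ratio(c.TP + c.TN, c.total)
    prec, f_prec = _safe_ratio(c.TP, c.TP + c.FP)
    f1, f_f1 = _safe_ratio(2.0 * prec * sn, prec + sn)
    flagged = [name for name, f in
               (("sensitivity", f_sn), ("specificity", f_sp),
                ("accuracy", f_acc), ("precision", f_prec), ("f1", f_f1)) if f]
    return {
        "sensitivity": sn, "specificity": sp, "accuracy": acc,
        "precision": prec, "f1": f1, "balanced_accuracy": 0.5 * (sn + sp),
        "sensitivity_pct": round(100.0 * sn, 1),
        "specificity_pct": round(100.0 * sp, 1),
        "accuracy_pct": round(100.0 * acc, 1),
        "precision_pct": round(100.0 * prec, 1),
        "undefined": flagged,
    }


# ---------------------------------------------------------------------------
# preprocessing


def smote_balance(X: np.ndarray, y: np.ndarray, k_neighbors: int = 5,
                  rng: np.random.Generator | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Equalize class sizes by convex minority interpolation.

    Synthetic samples lie on segments between a minority sample and one
    of its k nearest minority neighbours.  Already-balanced input is
    returned unchanged.
    """
    rng = rng or np.random.default_rng()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote_balance expects exactly two classes")
    if counts[0] == counts[1]:
        return X, y
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    Xm = X[y == minority]
    if len(Xm) < 2:
        raise ValueError("minority class too small for interpolation")
    k = min(k_neighbors, len(Xm) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)  # first neighbour is the sample itself
    base = rng.integers(0, len(Xm), size=n_needed)
    pick = rng.integers(1, k + 1, size=n_needed)
    lam = rng.uniform(0.0, 1.0, size=n_needed)[:, None]
    neigh = Xm[idx[base, pick]]
    synth = Xm[base] + lam * (neigh - Xm[base])
    Xb = np.vstack([X, synth])
    yb = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return Xb, yb


@dataclass
class ZScaler:
    mean: np.ndarray
    sd: np.ndarray
    keep: np.ndarray  # columns with non-zero training variance

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)[..., self.keep]
        return (X - self.mean[self.keep]) / self.sd[self.keep]


def zscore_fit(X: np.ndarray) -> ZScaler:
    """Fit per-feature standardization on training data only."""
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all features have zero training variance")
    if not keep.all():
        log.warning("dropping %d zero-variance features", (~keep).sum())
    sd = np.where(keep, sd, 1.0)
    return ZScaler(mean=mean, sd=sd, keep=keep)


def zscore(train: np.ndarray, *apply: np.ndarray):
    """Convenience wrapper: scale the training set and any apply sets."""
    scaler = zscore_fit(train)
    out = [scaler.transform(train)]
    out.extend(scaler.transform(a) for a in apply)
    return out[0] if not apply else tuple(out)


def _make_classifier(cfg: PipelineConfig):
    if cfg.classifier == "svm":
        return SVC(kernel=cfg.svm_kernel, C=cfg.svm_c)
    return KNeighborsClassifier(n_neighbors=cfg.knn_k)


def _labels_to_binary(y: np.ndarray, positive: str) -> np.ndarray:
    return (np.asarray(y) == positive).astype(int)


def _decision_scores(clf, X: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    """Positive-class score: signed distance (SVM) or vote fraction (k-NN)."""
    if cfg.classifier == "svm":
        scores = clf.decision_function(X)
        # decision_function is oriented toward classes_[1]
        if clf.classes_[1] != cfg.positive_class:
            scores = -scores
        return scores
    proba = clf.predict_proba(X)
    col = list(clf.classes_).index(cfg.positive_class)
    return proba[:, col]


def _fit_fold(X_tr: np.ndarray, y_tr: np.ndarray, X_te: np.ndarray,
              cfg: PipelineConfig, rng: np.random.Generator):
    """SMOTE + z-score + fit on one training fold; returns clf, scaled test."""
    Xb, yb = smote_balance(X_tr, y_tr, cfg.smote_neighbors, rng)
    scaler = zscore_fit(Xb)
    clf = _make_classifier(cfg)
    clf.fit(scaler.transform(Xb), yb)
    return clf, scaler.transform(X_te)


def _f1(y_true01: np.ndarray, y_pred01: np.ndarray) -> float:
    tp = int(np.sum((y_true01 == 1) & (y_pred01 == 1)))
    fp = int(np.sum((y_true01 == 0) & (y_pred01 == 1)))
    fn = int(np.sum((y_true01 == 1) & (y_pred01 == 0)))
    if 2 * tp + fp + fn == 0:
        return 0.0
    return 2.0 * tp / (2.0 * tp + fp + fn)


# ---------------------------------------------------------------------------
# selection and evaluation


def inner_cv_f1(X: np.ndarray, y: np.ndarray, cfg: PipelineConfig) -> float:
    """Mean F1 over stratified inner folds with nested preprocessing."""
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=cfg.inner_folds, shuffle=True,
                          random_state=cfg.seed)
    scores = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        rng = np.random.default_rng((cfg.seed, 7, fold))
        clf, X_te = _fit_fold(X[tr], y[tr], X[te], cfg, rng)
        pred = clf.predict(X_te)
        scores.append(_f1(_labels_to_binary(y[te], cfg.positive_class),
                          _labels_to_binary(pred, cfg.positive_class)))
    return float(np.mean(scores))


def sfs_select(features: pd.DataFrame, labels: pd.Series,
               cfg: PipelineConfig) -> list[str]:
    """Greedy sequential forward selection scored by inner-fold F1.

    Returns the nested feature sequence up to ``cfg.max_features``;
    ties break toward the earlier column.
    """
    if features.shape[1] < 1:
        raise ValueError("dataset has no features")
    y = labels.to_numpy()
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    X_all = features.to_numpy(dtype=float)
    columns = list(features.columns)
    selected: list[int] = []
    remaining = list(range(len(columns)))
    for _step in range(min(cfg.max_features, len(columns))):
        best_idx, best_score = None, -np.inf
        for j in remaining:
            score = inner_cv_f1(X_all[:, selected + [j]], y, cfg)
            if score > best_score:
                best_idx, best_score = j, score
        selected.append(best_idx)
        remaining.remove(best_idx)
        log.debug("SFS step %d: %s (inner F1 %.3f)", len(selected),
                  columns[best_idx], best_score)
    return [columns[j] for j in selected]


@dataclass
class ReportRow:
    """Metrics of one model size from pooled leave-one-out folds."""

    n_features: int
    features: list[str]
    counts: ConfusionCounts
    metrics: dict
    auc: float
    roc: tuple[np.ndarray, np.ndarray]  # (fpr, tpr)
    scores: np.ndarray = field(repr=False, default=None)

    def as_record(self) -> dict:
        rec = {"n_features": self.n_features, "features": list(self.features),
               **{k: v for k, v in self.metrics.items()}, "auc": self.auc,
               **asdict(self.counts)}
        return rec


def evaluate_loocv(features: pd.DataFrame, labels: pd.Series,
                   subset: list[str], cfg: PipelineConfig) -> ReportRow:
    """Leave-one-patient-out evaluation of a fixed feature subset.

    Preprocessing (SMOTE + scaling) is refit on every training fold; the
    pooled held-out predictions form the confusion counts, and pooled
    decision scores form the ROC/AUC.
    """
    if not subset:
        raise ValueError("feature subset is empty")
    X = features[subset].to_numpy(dtype=float)
    y = labels.to_numpy()
    n = len(y)
    y01 = _labels_to_binary(y, cfg.positive_class)

    if cfg.unsafe_smote_global:
        rng = np.random.default_rng((cfg.seed, 13))
        Xg, yg = smote_balance(X, y, cfg.smote_neighbors, rng)
    preds = np.empty(n, dtype=int)
    scores = np.empty(n, dtype=float)
    for i in range(n):
        tr = np.arange(n) != i
        rng = np.random.default_rng((cfg.seed, 11, i))
        if cfg.unsafe_smote_global:
            keep = np.ones(len(yg), dtype=bool)
            keep[i] = False
            scaler = zscore_fit(Xg[keep])
            clf = _make_classifier(cfg)
            clf.fit(scaler.transform(Xg[keep]), yg[keep])
            X_te = scaler.transform(X[i:i + 1])
        else:
            clf, X_te = _fit_fold(X[tr], y[tr], X[i:i + 1], cfg, rng)
        pred = clf.predict(X_te)[0]
        preds[i] = int(pred == cfg.positive_class)
        scores[i] = _decision_scores(clf, X_te, cfg)[0]

    counts = ConfusionCounts(
        TP=int(np.sum((y01 == 1) & (preds == 1))),
        FP=int(np.sum((y01 == 0) & (preds == 1))),
        TN=int(np.sum((y01 == 0) & (preds == 0))),
        FN=int(np.sum((y01 == 1) & (preds == 0))),
    )
    if len(np.unique(y01)) == 2:
        fpr, tpr, _ = roc_curve(y01, scores)
        auc_val = float(sk_auc(fpr, tpr))
    else:  # degenerate single-class input
        fpr, tpr, auc_val = np.array([0.0, 1.0]), np.array([0.0, 1.0]), 0.5
    return ReportRow(n_features=len(subset), features=list(subset),
                     counts=counts, metrics=metrics_from_confusion(counts),
                     auc=auc_val, roc=(fpr, tpr), scores=scores)


@dataclass
class ModelReport:
    """Per-model-size LOOCV results for one classifier and dataset."""

    classifier: str
    dataset_name: str
    selected: list[str]
    rows: list[ReportRow]
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_record() for r in self.rows])


def run_model_sizes(features: pd.DataFrame, labels: pd.Series,
                    cfg: PipelineConfig, dataset_name: str = "stage1"
                    ) -> ModelReport:
    """SFS then LOOCV for every model size 1..max_features."""
    order = sfs_select(features, labels, cfg)
    rows = [evaluate_loocv(features, labels, order[:k], cfg)
            for k in range(1, len(order) + 1)]
    return ModelReport(classifier=cfg.classifier, dataset_name=dataset_name,
                       selected=order, rows=rows, seed=cfg.seed)


def run_full_pipeline(frames, cfg: PipelineConfig | None = None,
                      classifiers: tuple[str, ...] = ("svm", "knn"),
                      ng: int = 16) -> dict[str, ModelReport]:
    """Two-stage protocol on a cohort of frame records.

    Stage 1: texture dataset (7 maps x 68 features), SFS + LOOCV for
    model sizes 1..max_features per classifier.  Stage 2: the stage-1
    five-feature subset generates TOT maps; the enhanced dataset is run
    with identical classifier settings.
    """
    from qustex.texture.dataset import assemble_dataset
    from qustex.tot import assemble_tot_dataset

    cfg = cfg or PipelineConfig()
    stage1 = assemble_dataset(frames, ng=ng)
    reports: dict[str, ModelReport] = {}
    for name in classifiers:
        ccfg = PipelineConfig(**{**asdict(cfg), "classifier": name})
        rep1 = run_model_sizes(stage1.features, stage1.labels, ccfg,
                               dataset_name="stage1")
        reports[f"{name}_stage1"] = rep1
        base5 = rep1.selected[:5]
        stage2 = assemble_tot_dataset(base5, stage1, frames, ng=ng)
        rep2 = run_model_sizes(stage2.features, stage2.labels, ccfg,
                               dataset_name="stage2")
        reports[f"{name}_stage2"] = rep2
    return reports
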