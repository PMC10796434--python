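"""Classifiers, cross-validation loops, and metric machinery.

Four model families with fixed default hyperparameters (any override is
recorded in the report so every run carries a full parameter audit). The
positive class is "synergistic" throughout; the decision threshold on the
predicted positive-class probability is 0.5 with >= mapping to positive.
Undefined rates (zero denominators) are reported as None and excluded from
fold averaging with a recorded count.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .core_io import ANTAGONISTIC, SYNERGISTIC
from .dataset_builder import (FoldAssignment, LabeledInstance, LadderDataset,
                              attach_augmented_to_training)
from .features import EmbeddingProvider, featurize_many

logger = logging.getLogger(__name__)

POSITIVE_LABEL = SYNERGISTIC

MODEL_DEFAULTS: Dict[str, Dict[str, object]] = {
    "LR": dict(penalty="l2", tol=1e-4, C=0.45, max_iter=500),
    "SVM": dict(C=0.42, kernel="linear", tol=1e-3, probability=True),
    "RF": dict(n_estimators=300, min_samples_leaf=85, max_features="sqrt"),
    "GBT": dict(n_estimators=650, min_samples_leaf=120, max_features="sqrt",
                learning_rate=0.28, max_depth=5),
}


@dataclass
class ModelSpec:
    family: str
    overrides: Dict[str, object] = field(default_factory=dict)
    class_weighting: str = "balanced"   # "balanced" | "none"
    seed: int = 0

    def effective_hyperparameters(self) -> Dict[str, object]:
        if self.family not in MODEL_DEFAULTS:
            raise ValueError(f"unknown model family {self.family!r}")
        params = dict(MODEL_DEFAULTS[self.family])
        unknown = set(self.overrides) - set(params)
        if unknown:
            raise ValueError(f"unknown hyperparameter(s) for {self.family}: {sorted(unknown)}")
        params.update(self.overrides)
        return params


def make_model(spec: ModelSpec, seed: Optional[int] = None):
    """Instantiate the configured scikit-learn classifier."""
    params = spec.effective_hyperparameters()
    class_weight = "balanced" if spec.class_weighting == "balanced" else None
    rs = spec.seed if seed is None else seed
    if spec.family == "LR":
        return LogisticRegression(class_weight=class_weight, random_state=rs, **params)
    if spec.family == "SVM":
        # Probability outputs come from SVC's internal (Platt) calibration.
        return SVC(class_weight=class_weight, random_state=rs, **params)
    if spec.family == "RF":
        return RandomForestClassifier(class_weight=class_weight, random_state=rs, **params)
    if spec.family == "GBT":
        # GradientBoostingClassifier has no class_weight; balanced weighting
        # is applied via per-sample weights at fit time (see _fit_model).
        return GradientBoostingClassifier(random_state=rs, **params)
    raise ValueError(f"unknown model family {spec.family!r}")


@dataclass
class MetricsReport:
    acc: Optional[float]
    tpr: Optional[float]
    fpr: Optional[float]
    ppv: Optional[float]
    mcc: Optional[float]
    f1: Optional[float]
    auc: Optional[float] = None
    confusion: Tuple[int, int, int, int] = (0, 0, 0, 0)  # (tp, fp, tn, fn)


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> MetricsReport:
    """Rates from a 2x2 confusion table; zero-denominator rates are None."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("all-zero confusion table")

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    acc = (tp + tn) / total
    tpr = ratio(tp, tp + fn)
    fpr = ratio(fp, fp + tn)
    ppv = ratio(tp, tp + fp)
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(mcc_den) if mcc_den > 0 else None
    f1 = (2 * ppv * tpr / (ppv + tpr)
          if ppv is not None and tpr is not None and (ppv + tpr) > 0 else None)
    return MetricsReport(acc=acc, tpr=tpr, fpr=fpr, ppv=ppv, mcc=mcc, f1=f1,
                         confusion=(tp, fp, tn, fn))


def metrics_from_predictions(y_true: Sequence[int], y_pred: Sequence[int]) -> MetricsReport:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return confusion_metrics(tp, fp, tn, fn)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC via the midrank Mann-Whitney statistic."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(scores)  # midranks for ties
    u = float(np.sum(ranks[labels == 1])) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def roc_curve_points(scores: Sequence[float], labels: Sequence[int]
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """(fpr, tpr) points sweeping the decision threshold over unique scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_labels == 1)
    fps = np.cumsum(sorted_labels == 0)
    # Keep only the last point of each tied-score run.
    keep = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tps, fps = tps[keep], fps[keep]
    n_pos, n_neg = tps[-1], fps[-1]
    tpr = np.r_[0.0, tps / max(n_pos, 1)]
    fpr = np.r_[0.0, fps / max(n_neg, 1)]
    return fpr, tpr


@dataclass
class FoldResult:
    fold: int
    metrics: MetricsReport
    n_train_original: int
    n_train_augmented: int
    n_validation: int
    roc: Tuple[Tuple[float, ...], Tuple[float, ...]]  # (fpr, tpr)


@dataclass
class CrossvalReport:
    protocol: str
    dataset: str          # "original" | "augmented"
    family: str
    effective_hyperparameters: Dict[str, object]
    overrides: Dict[str, object]
    class_weighting: str
    seed: int
    per_fold: List[FoldResult]
    mean_metrics: Dict[str, Optional[float]]
    n_undefined: Dict[str, int]
    mean_roc: Tuple[Tuple[float, ...], Tuple[float, ...]]
    skipped_folds: List[int]
    probability_model: Optional[str] = None

    def to_dict(self) -> dict:
        return asdict(self)


def _labels_to_int(instances: Sequence[LabeledInstance]) -> np.ndarray:
    return np.array([1 if i.label == POSITIVE_LABEL else 0 for i in instances], dtype=int)


def _fit_model(spec: ModelSpec, X: np.ndarray, y: np.ndarray, seed: int):
    model = make_model(spec, seed=seed)
    if spec.family == "GBT" and spec.class_weighting == "balanced":
        # Balanced per-sample weights: n / (2 * n_class).
        weights = np.where(y == 1, len(y) / (2.0 * max(np.sum(y == 1), 1)),
                           len(y) / (2.0 * max(np.sum(y == 0), 1)))
        model.fit(X, y, sample_weight=weights)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, y)
    return model


def _positive_probability(model, X: np.ndarray) -> np.ndarray:
    idx = list(model.classes_).index(1)
    return model.predict_proba(X)[:, idx]


FPR_GRID = np.linspace(0.0, 1.0, 101)

_RATES = ("acc", "tpr", "fpr", "ppv", "mcc", "f1", "auc")


def crossval(instances: Sequence[LabeledInstance],
             augmented: Sequence[LabeledInstance],
             assignment: FoldAssignment,
             spec: ModelSpec,
             drug_provider: EmbeddingProvider,
             cell_provider: EmbeddingProvider,
             use_augmented: bool = False,
             ratio_tolerance: float = 0.005) -> CrossvalReport:
    """K-fold train/validate loop; validation always on original instances.

    Augmented instances (when enabled) enter only the training side, via
    :func:`attach_augmented_to_training`, so no validation fold ever sees an
    augmented record or offspring of its own parents. Per-fold model seeds
    derive from ``spec.seed`` by a fixed counter (seed + fold), making folds
    independently reproducible. Folds whose validation split has a single
    class are skipped with a warning and recorded.
    """
    training_sets = attach_augmented_to_training(
        assignment, instances, list(augmented) if use_augmented else [],
        ratio_tolerance=ratio_tolerance, seed=spec.seed)

    per_fold: List[FoldResult] = []
    skipped: List[int] = []
    interp_tprs: List[np.ndarray] = []
    for fold in range(assignment.n_folds):
        ts = training_sets[fold]
        validation = [inst for inst in instances if inst.fold == fold]
        y_val = _labels_to_int(validation)
        if len(validation) == 0 or len(set(y_val.tolist())) < 2:
            logger.warning("fold %d skipped: single-class or empty validation split", fold)
            skipped.append(fold)
            continue
        train = ts.original + (ts.augmented if use_augmented else [])
        y_train = _labels_to_int(train)
        if len(set(y_train.tolist())) < 2:
            logger.warning("fold %d skipped: single-class training split", fold)
            skipped.append(fold)
            continue
        X_train = featurize_many(train, drug_provider, cell_provider)
        X_val = featurize_many(validation, drug_provider, cell_provider)
        model = _fit_model(spec, X_train, y_train, seed=spec.seed + fold)
        prob = _positive_probability(model, X_val)
        y_pred = (prob >= 0.5).astype(int)
        metrics = metrics_from_predictions(y_val, y_pred)
        metrics.auc = roc_auc(prob, y_val)
        fpr, tpr = roc_curve_points(prob, y_val)
        interp_tprs.append(np.interp(FPR_GRID, fpr, tpr))
        per_fold.append(FoldResult(
            fold=fold, metrics=metrics,
            n_train_original=len(ts.original),
            n_train_augmented=len(ts.augmented) if use_augmented else 0,
            n_validation=len(validation),
            roc=(tuple(map(float, fpr)), tuple(map(float, tpr)))))

    mean_metrics: Dict[str, Optional[float]] = {}
    n_undefined: Dict[str, int] = {}
    for name in _RATES:
        values = [getattr(f.metrics, name) for f in per_fold]
        defined = [v for v in values if v is not None]
        n_undefined[name] = len(values) - len(defined)
        mean_metrics[name] = float(np.mean(defined)) if defined else None

    mean_roc = (tuple(map(float, FPR_GRID)),
                tuple(map(float, np.mean(interp_tprs, axis=0))) if interp_tprs else ())
    return CrossvalReport(
        protocol=assignment.scheme,
        dataset="augmented" if use_augmented else "original",
        family=spec.family,
        effective_hyperparameters=spec.effective_hyperparameters(),
        overrides=dict(spec.overrides),
        class_weighting=spec.class_weighting,
        seed=spec.seed,
        per_fold=per_fold,
        mean_metrics=mean_metrics,
        n_undefined=n_undefined,
        mean_roc=mean_roc,
        skipped_folds=skipped,
        probability_model="platt" if spec.family == "SVM" else "native")


@dataclass
class ProbabilityQuartiles:
    q1: float
    q2: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def whisker_low(self) -> float:
        return self.q1 - 1.5 * self.iqr

    @property
    def whisker_high(self) -> float:
        return self.q3 + 1.5 * self.iqr

    @classmethod
    def from_probabilities(cls, probs: Sequence[float]) -> "ProbabilityQuartiles":
        q1, q2, q3 = np.percentile(np.asarray(probs, dtype=float), [25, 50, 75])
        return cls(q1=float(q1), q2=float(q2), q3=float(q3))


def probability_spectrum(model, ladder: Sequence[LadderDataset],
                         drug_provider: EmbeddingProvider,
                         cell_provider: EmbeddingProvider
                         ) -> Dict[float, Dict[str, Optional[ProbabilityQuartiles]]]:
    """Quartiles of predicted positive-class probability per ladder rung and class."""
    out: Dict[float, Dict[str, Optional[ProbabilityQuartiles]]] = {}
    for rung in ladder:
        per_class: Dict[str, Optional[ProbabilityQuartiles]] = {}
        for label in (SYNERGISTIC, ANTAGONISTIC):
            members = [i for i in rung.instances if i.label == label]
            if not members:
                per_class[label] = None
                continue
            X = featurize_many(members, drug_provider, cell_provider)
            probs = _positive_probability(model, X)
            per_class[label] = ProbabilityQuartiles.from_probabilities(probs)
        out[rung.threshold] = per_class
    return out
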