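"""Sleep-stage classification across jitter levels and its summaries.

Per participant and per jitter level, a multi-class classifier (Gaussian-
kernel SVM combined one-vs-one, or kNN) is evaluated by stratified 10-fold
cross-validation on the per-epoch HRV features.  From the resulting error
curves the module derives:

* kNN-based Bayes-error bounds for an L-class problem,
      (L-1)/L * (1 - sqrt(1 - L/(L-1) * E_kNN)) <= E_bayes <= E_kNN;
* per-feature sensitivity slopes (OLS of error % on HBI MAE in seconds);
* ensemble mean +/- 1.96 SD curves across participants;
* pooled confusion matrices, excluding participants whose matrix has an
  all-zero predicted-class column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .hrv import FEATURE_COLUMNS
from .synthdata import ValidationError

ALL_FEATURES = tuple(FEATURE_COLUMNS)


class ClassTooSmallError(RuntimeError):
    """A class has fewer members than CV folds; the cell must be flagged."""


@dataclass(frozen=True)
class EvalConfig:
    """Classifier evaluation settings."""

    classifier: str = "svm-gaussian-ovo"
    k_folds: int = 10
    knn_k: int = 10
    feature_subset: tuple[str, ...] = ALL_FEATURES
    scheme: str = "micro"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValidationError("k_folds must be >= 2")
        if not self.feature_subset:
            raise ValidationError("feature_subset must be non-empty")
        if self.classifier not in ("svm-gaussian-ovo", "knn"):
            raise ValidationError(f"unknown classifier {self.classifier!r}")
        unknown = set(self.feature_subset) - set(ALL_FEATURES)
        if unknown:
            raise ValidationError(f"unknown features: {sorted(unknown)}")


def _make_estimator(cfg: EvalConfig):
    if cfg.classifier == "svm-gaussian-ovo":
        # SVC is natively one-vs-one for multiclass; backend-default C/gamma.
        clf = SVC(kernel="rbf", random_state=cfg.seed)
    else:
        clf = KNeighborsClassifier(n_neighbors=cfg.knn_k)
    return make_pipeline(StandardScaler(), clf)


def cv_error(X: np.ndarray, y: np.ndarray, cfg: EvalConfig,
             return_confusion: bool = False, class_labels=None):
    """Stratified k-fold cross-validation error (%) for one participant/level.

    Features are z-scored with train-fold statistics inside each fold.
    Raises :class:`ClassTooSmallError` if any class has fewer members than
    folds so callers can flag, never silently drop, the cell.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim == 1:
        X = X[:, None]
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("need at least two classes for classification")
    if counts.min() < cfg.k_folds:
        raise ClassTooSmallError(
            f"class {classes[counts.argmin()]!r} has {counts.min()} members "
            f"< {cfg.k_folds} folds"
        )
    cv = StratifiedKFold(n_splits=cfg.k_folds, shuffle=True, random_state=cfg.seed)
    pred = cross_val_predict(_make_estimator(cfg), X, y, cv=cv)
    err = 100.0 * float(np.mean(pred != y))
    if return_confusion:
        labels = classes if class_labels is None else np.asarray(class_labels)
        return err, confusion_matrix(y, pred, labels=labels), tuple(labels)
    return err


def bayes_bounds(e_knn: float, n_classes: int) -> tuple[float, float]:
    """kNN-derived lower and upper bounds on the Bayes error (fractions)."""
    if n_classes < 2:
        raise ValidationError("n_classes must be >= 2")
    if not 0.0 <= e_knn:
        raise ValidationError("e_knn must be >= 0")
    L = float(n_classes)
    radicand = 1.0 - L / (L - 1.0) * e_knn
    if radicand < -1e-12:
        raise ValidationError(
            f"e_knn={e_knn} exceeds (L-1)/L={(L - 1) / L:.4f}; bound undefined"
        )
    lower = (L - 1.0) / L * (1.0 - np.sqrt(max(radicand, 0.0)))
    return float(lower), float(e_knn)


def sensitivity_slope(mae_s: np.ndarray, error_pct: np.ndarray) -> float:
    """OLS slope of classification error (%) on HBI MAE (s), i.e. %/s."""
    mae_s = np.asarray(mae_s, dtype=float)
    error_pct = np.asarray(error_pct, dtype=float)
    if mae_s.size < 3:
        raise ValidationError("need >= 3 points for a sensitivity slope")
    if np.std(mae_s) == 0:
        raise ValidationError("degenerate MAE spread; slope undefined")
    return float(stats.linregress(mae_s, error_pct).slope)


def mean_sensitivity_slope(curves: pd.DataFrame) -> float:
    """Average per-participant OLS slope; expects columns participant_id,
    mae_ms, error_pct."""
    slopes = [
        sensitivity_slope(g["mae_ms"].to_numpy() / 1000.0, g["error_pct"].to_numpy())
        for _, g in curves.groupby("participant_id")
    ]
    return float(np.mean(slopes))


def ensemble_curve(curves: pd.DataFrame) -> pd.DataFrame:
    """Across-participant mean and +/- 1.96 SD band per jitter level.

    ``curves`` has one row per (participant_id, level) with columns mae_ms
    and error_pct; all participants must share the level grid.
    """
    g = curves.groupby("level")
    out = pd.DataFrame(
        {
            "mae_ms": g["mae_ms"].mean(),
            "mean_error_pct": g["error_pct"].mean(),
            "sd_error_pct": g["error_pct"].std(ddof=1).fillna(0.0),
        }
    ).reset_index()
    out["lo_error_pct"] = out["mean_error_pct"] - 1.96 * out["sd_error_pct"]
    out["hi_error_pct"] = out["mean_error_pct"] + 1.96 * out["sd_error_pct"]
    return out


def aggregate_confusion(
    confusions: list[np.ndarray],
) -> tuple[np.ndarray, int]:
    """Sum per-participant confusion matrices, excluding degenerate ones.

    A participant whose matrix has any all-zero predicted-class column (a
    class the classifier never predicted) is excluded; the number excluded
    is returned alongside the pooled matrix.
    """
    kept, excluded = [], 0
    for cm in confusions:
        cm = np.asarray(cm)
        if np.any(cm.sum(axis=0) == 0):
            excluded += 1
        else:
            kept.append(cm)
    if not kept:
        raise ValidationError("every participant excluded by the zero-column rule")
    return np.sum(kept, axis=0), excluded


@dataclass
class EvaluationResult:
    """Long-form error table plus confusion matrices from evaluate_cohort."""

    errors: pd.DataFrame
    confusions: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)
    class_order: tuple[str, ...] = ()


def evaluate_cohort(
    features: pd.DataFrame,
    ladder_mae_ms: dict[str, dict[int, float]],
    cfg: EvalConfig,
    levels: list[int] | None = None,
) -> EvaluationResult:
    """Per-participant, per-level CV error over a stacked feature table.

    ``features`` carries columns participant_id, level, epoch_index, stage,
    valid and the HRV feature columns; ``ladder_mae_ms`` maps participant ->
    level -> realized MAE (level 0 is the baseline, MAE 0).  Epochs invalid
    at any level are excluded at every level of that participant so sample
    sizes stay equal across levels.
    """
    feats = list(cfg.feature_subset)
    rows = []
    confusions: dict[tuple[str, int], np.ndarray] = {}
    class_order = tuple(sorted(features["stage"].unique()))
    for pid, per_part in features.groupby("participant_id", sort=True):
        use_levels = sorted(per_part["level"].unique()) if levels is None else levels
        ok = (
            per_part[per_part["level"].isin(use_levels)]
            .groupby("epoch_index")["valid"]
            .all()
        )
        good_epochs = set(ok[ok].index)
        part = per_part[per_part["epoch_index"].isin(good_epochs)]
        for lvl in use_levels:
            sl = part[part["level"] == lvl].sort_values("epoch_index")
            X = sl[feats].to_numpy()
            y = sl["stage"].to_numpy()
            mae = 0.0 if lvl == 0 else ladder_mae_ms[str(pid)][lvl]
            try:
                err, cm, _ = cv_error(
                    X, y, cfg, return_confusion=True, class_labels=class_order
                )
                flagged = False
            except ClassTooSmallError:
                err, cm = np.nan, None
                flagged = True
            rows.append(
                {
                    "participant_id": pid,
                    "level": lvl,
                    "mae_ms": mae,
                    "scheme": cfg.scheme,
                    "feature_subset": "+".join(feats),
                    "error_pct": err,
                    "flagged": flagged,
                }
            )
            if cm is not None:
                confusions[(str(pid), int(lvl))] = cm
    return EvaluationResult(
        errors=pd.DataFrame(rows), confusions=confusions, class_order=class_order
    )
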