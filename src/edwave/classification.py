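"""Two-step SVM classification of epochs and balanced-accuracy metrics.

Stage 1 separates normal background from epileptiform discharges (EDs);
stage 2, trained on ED rows only, separates repeated sharps from runs of
sharp-and-slow-waves.  Both stages are Gaussian-RBF support vector machines.
The published configuration states the kernel as a *scaling factor* sigma,
i.e. ``k(u, v) = exp(-||u - v||^2 / (2 sigma^2))``; this maps onto sklearn's
``gamma = 1 / (2 sigma^2)``.  The KKT stopping tolerance ``L`` maps onto
SVC's ``tol``; the KKT violation level ``K`` has no sklearn analogue and its
published value of 0 makes it a no-op.

Because class sizes are severely unbalanced (tens of sharps against tens of
thousands of normal segments), accuracy is the mean over classes of
``(sensitivity + specificity) / 2`` rather than raw fraction correct.  The
*selectivity* is implemented exactly as printed in its source,
``Sel = sum_i TP_i / sum_i (TN_i + FP_i)`` -- note the right-hand side sums
over classes even though the original notation indexes the left by class.

Cross-validation is stratified k-fold; within each training split the normal
class is subsampled to at most ``normal_cap`` rows (test folds are never
capped).  Features are z-scored with training-fold statistics before the SVM
(switchable off).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._exceptions import ConfigurationError, UndefinedMetricError

CLASS_ORDER = ("normal", "sharp", "ssw")


@dataclass
class SvmConfig:
    """RBF-SVM hyperparameters for one classification stage."""

    box_constraint: float
    kernel_sigma: float
    kkt_tolerance: float
    kkt_violation: float = 0.0
    stage: str = ""

    def __post_init__(self) -> None:
        if self.box_constraint <= 0 or self.kernel_sigma <= 0:
            raise ValueError("box_constraint and kernel_sigma must be positive")
        if self.kkt_tolerance <= 0 or self.kkt_violation < 0:
            raise ValueError("kkt_tolerance must be > 0 and kkt_violation >= 0")

    @property
    def gamma(self) -> float:
        """sklearn gamma equivalent of the sigma scaling factor."""
        return 1.0 / (2.0 * self.kernel_sigma**2)


def default_svm_configs() -> tuple[SvmConfig, SvmConfig]:
    """The packaged stage-1 (ED vs normal) and stage-2 (sharp vs SSW) configs."""
    return (
        SvmConfig(box_constraint=1.0, kernel_sigma=3.0, kkt_tolerance=0.01, stage="ed_vs_normal"),
        SvmConfig(box_constraint=0.1, kernel_sigma=3.0, kkt_tolerance=0.05, stage="sharp_vs_ssw"),
    )


@dataclass
class MetricsReport:
    """Per-class sensitivity/specificity (%), selectivity, balanced accuracy."""

    classes: tuple[str, ...]
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    selectivity: float
    accuracy: float
    confusion: np.ndarray

    def as_dict(self) -> dict[str, float]:
        d: dict[str, float] = {}
        for c in self.classes:
            d[f"sens_{c}"] = self.sensitivity[c]
            d[f"spec_{c}"] = self.specificity[c]
        d["sel"] = self.selectivity
        d["acc"] = self.accuracy
        return d


class TwoStepModel:
    """Composed normal-vs-ED and sharp-vs-SSW SVMs with per-stage z-scoring."""

    def __init__(self) -> None:
        self.stage1: SVC | None = None
        self.stage2: SVC | None = None
        self.scaler1: StandardScaler | None = None
        self.scaler2: StandardScaler | None = None
        self.classes_: tuple[str, ...] = ()
        self.ed_fallback: str | None = None
        self.n_features_: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or (X.shape[0] and X.shape[1] != self.n_features_):
            raise ValueError(
                f"expected {self.n_features_} features, got {X.shape[1] if X.ndim == 2 else 'n/a'}"
            )
        n = X.shape[0]
        out = np.empty(n, dtype=object)
        if n == 0:
            return out.astype(str)
        if self.stage1 is not None:
            X1 = self.scaler1.transform(X) if self.scaler1 is not None else X
            is_ed = self.stage1.predict(X1) == "ed"
            out[~is_ed] = "normal"
        else:
            is_ed = np.ones(n, dtype=bool)
        if is_ed.any():
            if self.stage2 is not None:
                X2 = self.scaler2.transform(X[is_ed]) if self.scaler2 is not None else X[is_ed]
                out[is_ed] = self.stage2.predict(X2)
            else:
                out[is_ed] = self.ed_fallback
        return out.astype(str)


def train_two_step(
    X: np.ndarray,
    y: Sequence[str],
    cfg_stage1: SvmConfig | None = None,
    cfg_stage2: SvmConfig | None = None,
    seed: int = 0,
    standardize: bool = True,
) -> TwoStepModel:
    """Train the two-step classifier; deterministic given the seed.

    Stage 1 is trained whenever the normal class and at least one ED class
    are present; stage 2 whenever both ED classes are present.  A dataset
    with fewer than two classes is a training error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    present = [c for c in CLASS_ORDER if c in y]
    if len(present) < 2:
        raise ConfigurationError("training requires at least two classes")
    d1 = cfg_stage1 or default_svm_configs()[0]
    d2 = cfg_stage2 or default_svm_configs()[1]
    model = TwoStepModel()
    model.classes_ = tuple(present)
    model.n_features_ = X.shape[1]

    def _fit(cfg: SvmConfig, Xs: np.ndarray, ys: np.ndarray) -> tuple[SVC, StandardScaler | None]:
        scaler = None
        if standardize:
            scaler = StandardScaler().fit(Xs)
            Xs = scaler.transform(Xs)
        svc = SVC(
            C=cfg.box_constraint,
            kernel="rbf",
            gamma=cfg.gamma,
            tol=cfg.kkt_tolerance,
            random_state=seed,
        )
        svc.fit(Xs, ys)
        return svc, scaler

    if "normal" in present:
        y1 = np.where(y == "normal", "normal", "ed")
        model.stage1, model.scaler1 = _fit(d1, X, y1)
    ed_mask = y != "normal"
    ed_classes = [c for c in ("sharp", "ssw") if c in y]
    if len(ed_classes) == 2:
        model.stage2, model.scaler2 = _fit(d2, X[ed_mask], y[ed_mask])
    elif ed_classes:
        model.ed_fallback = ed_classes[0]
    return model


def predict(model: TwoStepModel, X: np.ndarray) -> np.ndarray:
    """Predict epoch classes with a trained two-step model."""
    return model.predict(X)


def eq5_metrics(
    confusion: np.ndarray, classes: Sequence[str] | None = None
) -> MetricsReport:
    """Balanced-accuracy metrics from a confusion matrix (rows = true class).

    Sens_i = TP/(TP+FN), Spec_i = TN/(TN+FP), Acc = mean_i (Sens_i+Spec_i)/2,
    Sel = sum TP_i / sum (TN_i + FP_i), all in percent.
    """
    confusion = np.asarray(confusion, dtype=float)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (confusion < 0).any():
        raise ValueError("confusion counts must be non-negative")
    n_classes = confusion.shape[0]
    if classes is None:
        classes = tuple(f"class{i}" for i in range(n_classes))
    classes = tuple(classes)
    total = confusion.sum()
    sens: dict[str, float] = {}
    spec: dict[str, float] = {}
    tp_sum = 0.0
    tnfp_sum = 0.0
    for i, c in enumerate(classes):
        tp = confusion[i, i]
        fn = confusion[i].sum() - tp
        fp = confusion[:, i].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:
            raise UndefinedMetricError(f"class {c!r} has no positive examples")
        sens[c] = 100.0 * tp / (tp + fn)
        spec[c] = 100.0 * tn / (tn + fp) if tn + fp > 0 else 100.0
        tp_sum += tp
        tnfp_sum += tn + fp
    acc = float(np.mean([(sens[c] + spec[c]) / 2.0 for c in classes]))
    sel = 100.0 * tp_sum / tnfp_sum if tnfp_sum > 0 else 100.0
    return MetricsReport(
        classes=classes,
        sensitivity=sens,
        specificity=spec,
        selectivity=float(sel),
        accuracy=acc,
        confusion=confusion,
    )


def accuracy_from_rates(
    sensitivities: Sequence[float], specificities: Sequence[float]
) -> float:
    """Balanced accuracy (%) from per-class sensitivity/specificity pairs (%)."""
    s = np.asarray(sensitivities, dtype=float)
    p = np.asarray(specificities, dtype=float)
    if s.shape != p.shape:
        raise ValueError("sensitivities and specificities must pair up")
    return float(np.mean((s + p) / 2.0))


@dataclass
class CrossValidationResult:
    folds: list[MetricsReport]
    classes: tuple[str, ...]

    @property
    def accuracy_mean(self) -> float:
        return float(np.mean([f.accuracy for f in self.folds]))

    @property
    def accuracy_std(self) -> float:
        return float(np.std([f.accuracy for f in self.folds], ddof=1))

    def to_frame(self) -> pd.DataFrame:
        """Per-iteration metrics plus average/stdev rows (benchmark-table layout)."""
        rows = [f.as_dict() for f in self.folds]
        frame = pd.DataFrame(rows)
        frame.insert(0, "iteration", np.arange(1, len(rows) + 1))
        avg = frame.drop(columns="iteration").mean()
        std = frame.drop(columns="iteration").std(ddof=1)
        frame.loc["Avg."] = ["Avg."] + avg.tolist()
        frame.loc["St dev."] = ["St dev."] + std.tolist()
        return frame


def cross_validate(
    X: np.ndarray,
    y: Sequence[str],
    cfg_stage1: SvmConfig | None = None,
    cfg_stage2: SvmConfig | None = None,
    n_folds: int = 10,
    normal_cap: int = 20000,
    seed: int = 0,
    standardize: bool = True,
) -> CrossValidationResult:
    """Stratified k-fold cross-validation of the two-step classifier.

    Folds are stratified so each test group holds (as nearly as divisibility
    allows) the same number of segments per class.  In each training split
    the normal class is randomly subsampled to at most ``normal_cap`` rows;
    when the cap exceeds the available normals it is inert.  Reproducible by
    seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ConfigurationError(
            f"every class needs >= {n_folds} members; smallest has {counts.min()}"
        )
    classes = tuple(c for c in CLASS_ORDER if c in labels)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    folds = []
    for train_idx, test_idx in skf.split(X, y):
        norm_local = np.flatnonzero(y[train_idx] == "normal")
        if norm_local.size > normal_cap:
            drop = rng.choice(norm_local, size=norm_local.size - normal_cap, replace=False)
            keep = np.ones(train_idx.size, dtype=bool)
            keep[drop] = False
            train_idx = train_idx[keep]
        model = train_two_step(
            X[train_idx], y[train_idx], cfg_stage1, cfg_stage2,
            seed=seed, standardize=standardize,
        )
        pred = model.predict(X[test_idx])
        cm = confusion_matrix(y[test_idx], pred, labels=list(classes))
        folds.append(eq5_metrics(cm, classes))
    return CrossValidationResult(folds=folds, classes=classes)


def feature_group_ablation(
    X: np.ndarray,
    y: Sequence[str],
    groups: Mapping[str, Sequence[int]],
    **cv_kwargs,
) -> dict[str, float]:
    """Cross-validated mean accuracy of each feature group taken alone."""
    X = np.asarray(X, dtype=float)
    out = {}
    for name, idx in groups.items():
        idx = list(idx)
        if not idx:
            raise ValueError(f"feature group {name!r} is empty")
        if len(set(idx)) != len(idx):
            raise ValueError(f"feature group {name!r} has duplicate indices")
        if min(idx) < 0 or max(idx) >= X.shape[1]:
            raise ValueError(f"feature group {name!r} indexes outside the matrix")
        out[name] = cross_validate(X[:, idx], y, **cv_kwargs).accuracy_mean
    return out
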