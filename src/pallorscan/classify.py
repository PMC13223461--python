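"""Gold-standard labeling, MLP classification, and evaluation metrics.

Labels come from each subject's hemoglobin concentration (g/dL, complete
blood count), graded into three classes with sex-specific cutoffs:

    male:   anemic  hb < 10.5   moderate  10.5 <= hb <= 13.5   normal hb > 13.5
    female: anemic  hb < 10.5   moderate  10.5 <= hb <= 12.0   normal hb > 12.0

Boundary values fall in the moderate class (closed interval).

The classifier is a single-hidden-layer perceptron (25 ReLU units, softmax
output) on z-scored features.  Evaluation follows a stratified 90/10 split
and reports BOTH resubstitution metrics (on the training data — optimistic,
but a convention in this screening literature) and held-out metrics, clearly
distinguished.  Per-class metrics use the one-vs-rest reduction of the 3x3
confusion matrix; AUC uses the rank (Mann-Whitney) formulation, ties
contributing one half.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import ModelStateError, TrainingError, ValidationError
from .features import FEATURE_NAMES

__all__ = [
    "CLASSES",
    "MLPConfig",
    "MetricsReport",
    "EvaluationResult",
    "label_from_hb",
    "train_classifier",
    "predict_class",
    "confusion_matrix",
    "classification_metrics",
    "roc_auc_ovr",
    "stratified_split",
    "evaluate_split",
    "save_model",
    "load_model",
]

#: Canonical class order (alphabetical; also the severity-to-health order).
CLASSES = ("anemic", "moderate", "normal")

#: Sex-specific upper bound of the moderate band (g/dL); anemic < 10.5 for both.
_ANEMIC_UPPER = 10.5
_MODERATE_UPPER = {"male": 13.5, "female": 12.0}


def label_from_hb(sex: str, hb: float) -> str:
    """Grade a hemoglobin value into anemic / moderate / normal.

    ``sex`` is ``"male"`` or ``"female"``; ``hb`` in g/dL must lie in the
    plausibility window (0, 25).
    """
    if sex not in _MODERATE_UPPER:
        raise ValidationError(f"sex must be 'male' or 'female', got {sex!r}")
    hb = float(hb)
    if not (0.0 < hb < 25.0) or not np.isfinite(hb):
        raise ValidationError(f"hb={hb} g/dL outside plausibility window (0, 25)")
    if hb < _ANEMIC_UPPER:
        return "anemic"
    if hb <= _MODERATE_UPPER[sex]:
        return "moderate"
    return "normal"


@dataclass(frozen=True)
class MLPConfig:
    """Hyper-parameters of the screening MLP."""

    hidden_units: int = 25
    activation: str = "relu"
    max_iterations: int = 1000
    test_fraction: float = 0.10
    seed: int = 0


def _feature_matrix(table: pd.DataFrame) -> np.ndarray:
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise ValidationError(f"feature table missing columns: {missing}")
    X = table[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValidationError("feature table contains non-finite values")
    return X


def train_classifier(table: pd.DataFrame, config: MLPConfig = MLPConfig()) -> Pipeline:
    """Fit scaler + MLP on a labeled feature table.

    ``table`` needs the seven feature columns plus a ``label`` column; every
    class must be present.  The same seed yields an identical model (the
    deterministic L-BFGS solver is used — well suited to this small dense
    problem).
    """
    if "label" not in table.columns:
        raise ValidationError("feature table needs a 'label' column")
    y = table["label"].to_numpy()
    present = set(y)
    absent = [c for c in CLASSES if c not in present]
    if absent:
        raise TrainingError(f"training data lacks class(es): {absent}")
    X = _feature_matrix(table)
    model = Pipeline(
        [
            ("scaler", StandardScaler()),
            (
                "mlp",
                MLPClassifier(
                    hidden_layer_sizes=(config.hidden_units,),
                    activation=config.activation,
                    solver="lbfgs",
                    max_iter=config.max_iterations,
                    random_state=config.seed,
                ),
            ),
        ]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings on tiny fixtures
        model.fit(X, y)
    return model


def predict_class(model: Pipeline, features) -> tuple[str, np.ndarray]:
    """Predict one sample: (label, class probabilities in CLASSES order).

    The label is the probability argmax; exact ties resolve to the
    lexicographically first class.
    """
    if not hasattr(model, "predict_proba") or not hasattr(model[-1], "coefs_"):
        raise ModelStateError("model is not trained")
    x = np.asarray(
        features.as_array() if hasattr(features, "as_array") else features,
        dtype=np.float64,
    ).reshape(1, -1)
    if not np.all(np.isfinite(x)):
        raise ValidationError("feature vector contains non-finite values")
    proba_raw = model.predict_proba(x)[0]
    order = {c: i for i, c in enumerate(model[-1].classes_)}
    proba = np.array([proba_raw[order[c]] for c in CLASSES])
    return CLASSES[int(np.argmax(proba))], proba


def confusion_matrix(truths: Sequence[str], predictions: Sequence[str]) -> np.ndarray:
    """3x3 count matrix; rows are true classes, columns predicted (CLASSES order)."""
    truths = list(truths)
    predictions = list(predictions)
    if len(truths) != len(predictions):
        raise ValidationError(
            f"length mismatch: {len(truths)} truths vs {len(predictions)} predictions"
        )
    if len(truths) == 0:
        raise ValidationError("cannot build a confusion matrix from empty input")
    idx = {c: i for i, c in enumerate(CLASSES)}
    cm = np.zeros((3, 3), dtype=np.int64)
    for t, p in zip(truths, predictions):
        try:
            cm[idx[t], idx[p]] += 1
        except KeyError as exc:
            raise ValidationError(f"unknown class label {exc.args[0]!r}") from None
    return cm


@dataclass
class MetricsReport:
    """Per-class one-vs-rest metrics plus macro averages, all fractions in [0, 1].

    A ratio with a zero denominator (e.g. PPV for a never-predicted class) is
    NaN, never silently 0.
    """

    per_class: dict = field(default_factory=dict)
    macro: dict = field(default_factory=dict)
    overall_accuracy: float = float("nan")
    n_samples: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _safe_div(num: float, den: float, what: str, cls: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined for class {cls!r} (zero denominator)")
        return float("nan")
    return num / den


def classification_metrics(cm: np.ndarray) -> MetricsReport:
    """Accuracy, precision/PPV, sensitivity, specificity, F1, FDR and macro means.

    Each class is reduced one-vs-rest: TP its diagonal entry, FN the rest of
    its row, FP the rest of its column, TN everything else.  The macro value
    is the unweighted mean over classes (NaN-propagating); overall accuracy is
    trace/total.
    """
    cm = np.asarray(cm, dtype=np.int64)
    if cm.shape != (3, 3) or (cm < 0).any():
        raise ValidationError("confusion matrix must be 3x3 with counts >= 0")
    total = int(cm.sum())
    if total < 1:
        raise ValidationError("confusion matrix is empty")

    report = MetricsReport(n_samples=total)
    for i, cls in enumerate(CLASSES):
        tp = float(cm[i, i])
        fn = float(cm[i].sum() - cm[i, i])
        fp = float(cm[:, i].sum() - cm[i, i])
        tn = float(total - tp - fn - fp)
        precision = _safe_div(tp, tp + fp, "precision/PPV", cls)
        sensitivity = _safe_div(tp, tp + fn, "sensitivity", cls)
        f1_den = (precision + sensitivity) if np.isfinite(precision) else float("nan")
        report.per_class[cls] = {
            "accuracy": (tp + tn) / total,
            "precision": precision,
            "ppv": precision,
            "sensitivity": sensitivity,
            "specificity": _safe_div(tn, tn + fp, "specificity", cls),
            "f1": (
                2 * precision * sensitivity / f1_den
                if np.isfinite(f1_den) and f1_den > 0
                else float("nan")
            ),
            "fdr": _safe_div(fp, tp + fp, "FDR", cls),
            "support": int(cm[i].sum()),
        }
    for m in ("accuracy", "precision", "sensitivity", "specificity", "f1", "ppv", "fdr"):
        report.macro[m] = float(np.mean([report.per_class[c][m] for c in CLASSES]))
    report.overall_accuracy = float(np.trace(cm) / total)
    return report


def roc_auc_ovr(
    truths: Sequence[str], probabilities: np.ndarray
) -> dict[str, float]:
    """One-vs-rest AUC per class via the rank (Mann-Whitney) statistic.

    ``probabilities`` is (n, 3) in CLASSES order.  For class c with n+
    positives and n- negatives, AUC = (R+ - n+(n+ + 1)/2) / (n+ n-), where R+
    is the rank-sum of the positive scores (average ranks, so score ties
    contribute one half).
    """
    truths = np.asarray(list(truths))
    probs = np.asarray(probabilities, dtype=np.float64)
    if probs.shape != (truths.size, len(CLASSES)):
        raise ValidationError(
            f"probabilities must be (n, {len(CLASSES)}), got {probs.shape}"
        )
    if len(set(truths)) < 2:
        raise ValidationError("AUC is degenerate with single-class truths")
    out: dict[str, float] = {}
    for i, cls in enumerate(CLASSES):
        pos = truths == cls
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0:
            continue  # class absent: its one-vs-rest AUC is undefined, omit
        ranks = rankdata(probs[:, i])
        out[cls] = float(
            (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        )
    return out


def stratified_split(
    labels: Sequence[str], test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class shuffled split; the test count per class is rounded half-up.

    With the 611-image class mix 132/169/310 at 10% this yields per-class
    test counts 13/17/31, i.e. a 550/61 train/test partition.
    """
    labels = np.asarray(list(labels))
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for cls in sorted(set(labels)):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValidationError(f"class {cls!r} has < 2 samples; cannot split")
        n_test = int(np.floor(test_fraction * idx.size + 0.5))
        n_test = min(max(n_test, 1), idx.size - 1)
        test_idx.extend(rng.permutation(idx)[:n_test].tolist())
    test = np.sort(np.asarray(test_idx, dtype=np.intp))
    train = np.setdiff1d(np.arange(labels.size, dtype=np.intp), test)
    return train, test


@dataclass
class EvaluationResult:
    """Co-reported resubstitution (training-data) and held-out evaluations."""

    model: Pipeline
    resubstitution: MetricsReport
    heldout: MetricsReport
    cm_resubstitution: np.ndarray
    cm_heldout: np.ndarray
    auc_resubstitution: dict
    auc_heldout: dict
    n_train: int = 0
    n_test: int = 0


def evaluate_split(
    table: pd.DataFrame, config: MLPConfig = MLPConfig()
) -> EvaluationResult:
    """Stratified 90/10 train/test evaluation of the screening MLP.

    Trains on the 90% portion and reports resubstitution metrics (the
    training data scored by its own model) alongside held-out metrics on the
    10% test portion.  Deterministic given (table, config.seed).
    """
    y = table["label"].to_numpy()
    train_idx, test_idx = stratified_split(y, config.test_fraction, config.seed)
    train_tab = table.iloc[train_idx]
    test_tab = table.iloc[test_idx]
    model = train_classifier(train_tab, config)

    def _score(tab: pd.DataFrame):
        X = _feature_matrix(tab)
        truths = tab["label"].to_numpy()
        raw = model.predict_proba(X)
        order = {c: i for i, c in enumerate(model[-1].classes_)}
        probs = raw[:, [order[c] for c in CLASSES]]
        preds = [CLASSES[i] for i in np.argmax(probs, axis=1)]
        cm = confusion_matrix(truths, preds)
        return cm, classification_metrics(cm), roc_auc_ovr(truths, probs)

    cm_res, met_res, auc_res = _score(train_tab)
    cm_out, met_out, auc_out = _score(test_tab)
    return EvaluationResult(
        model=model,
        resubstitution=met_res,
        heldout=met_out,
        cm_resubstitution=cm_res,
        cm_heldout=cm_out,
        auc_resubstitution=auc_res,
        auc_heldout=auc_out,
        n_train=len(train_idx),
        n_test=len(test_idx),
    )


def save_model(model: Pipeline, path: str, config: MLPConfig | None = None) -> None:
    """Persist the fitted pipeline plus a JSON sidecar (config, class order)."""
    joblib.dump(model, path)
    scaler = model["scaler"]
    sidecar = {
        "format_version": 1,
        "classes": list(CLASSES),
        "feature_names": list(FEATURE_NAMES),
        "config": asdict(config) if config is not None else None,
        "scaler_mean": scaler.mean_.tolist(),
        "scaler_scale": scaler.scale_.tolist(),
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_model(path: str) -> Pipeline:
    model = joblib.load(path)
    if not hasattr(model[-1], "coefs_"):
        raise ModelStateError(f"artifact at {path} holds an untrained model")
    return model
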