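"""Multiclass beat classification and the evaluation metric suite.

Three candidate models — a decision tree, multinomial logistic regression,
and a random forest of 10 trees — are trained on the M x 25 feature matrix
with L = 3 classes.  The random forest predicts by strict majority vote over
its trees; score vectors are the vote fractions.  Ties (and probability ties
for the other models) break to the first class in the fixed class order.

Evaluation builds per-class one-vs-rest confusion counts and reports
accuracy, sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision, F1,
macro one-vs-rest AUC and the false-positive rate, with macro (unweighted)
averaging across classes.  Specificity is computed as (1 - FPR) x 100, so
the complement identity holds exactly per class and in the macro average.
"""

from __future__ import annotations

import io as _io
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

from .errors import DegenerateTrainingError, ModelLoadError, SpecificationError
from .study import CLASS_ORDER, N_FEATURES

MODEL_KINDS = ("decision_tree", "logistic_regression", "random_forest")
_MAGIC = b"ECGSMODL"
_ARTIFACT_VERSION = 1


@dataclass
class LabeledDataset:
    """Feature matrix (M x 25) with per-row class labels and provenance."""

    features: np.ndarray
    labels: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.features.ndim != 2 or self.features.shape[1] != N_FEATURES:
            raise SpecificationError(f"features must be M x {N_FEATURES}")
        if self.features.shape[0] == 0:
            raise SpecificationError("dataset is empty")
        if len(self.labels) != self.features.shape[0]:
            raise SpecificationError("labels must align with feature rows")
        if not np.all(np.isfinite(self.features)):
            raise SpecificationError("features contain missing values")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]


@dataclass
class TrainedModel:
    kind: str
    estimator: object
    class_order: tuple[str, ...] = CLASS_ORDER
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0


def labels_from_scores(
    scores: np.ndarray, class_order: Sequence[str] = CLASS_ORDER
) -> np.ndarray:
    """Argmax with deterministic tie-break: earliest class in class_order."""
    scores = np.asarray(scores, dtype=np.float64)
    idx = np.argmax(scores, axis=1)  # first maximum wins
    order = np.asarray(class_order, dtype=object)
    return order[idx]


def train(dataset: LabeledDataset, kind: str, seed: int = 0) -> TrainedModel:
    """Fit one candidate model; deterministic given the seed."""
    if kind not in MODEL_KINDS:
        raise SpecificationError(f"unknown model kind {kind!r}")
    classes = set(map(str, dataset.labels))
    if len(classes) < 2:
        raise DegenerateTrainingError(
            f"training data holds a single class {classes}; a multiclass "
            "model cannot be fit"
        )
    hyperparams: dict = {}
    if kind == "decision_tree":
        est = DecisionTreeClassifier(random_state=seed)
    elif kind == "logistic_regression":
        hyperparams = {"max_iter": 2000}
        est = LogisticRegression(max_iter=2000, random_state=seed)
    else:
        hyperparams = {"n_trees": 10}
        est = RandomForestClassifier(n_estimators=10, random_state=seed)
    est.fit(dataset.features, dataset.labels.astype(str))
    return TrainedModel(
        kind=kind, estimator=est, hyperparams=hyperparams, seed=seed
    )


def predict(
    model: TrainedModel, features: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and per-class scores (columns follow class_order).

    Random-forest scores are the per-tree vote fractions (they sum to 1);
    the predicted label is the majority vote with ties broken to the first
    class in class_order.  Other models use class probabilities.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[1] != N_FEATURES:
        raise SpecificationError(
            f"expected {N_FEATURES} features, got {X.shape[1]}"
        )
    est = model.estimator
    order = list(model.class_order)
    if model.kind == "random_forest":
        counts = np.zeros((X.shape[0], len(order)))
        col = {c: j for j, c in enumerate(order)}
        for tree in est.estimators_:
            proba = tree.predict_proba(X)
            votes = est.classes_[np.argmax(proba, axis=1)]
            for i, v in enumerate(votes):
                counts[i, col[str(v)]] += 1
        scores = counts / len(est.estimators_)
    else:
        proba = est.predict_proba(X)
        scores = np.zeros((X.shape[0], len(order)))
        for j, cls in enumerate(est.classes_):
            scores[:, order.index(str(cls))] = proba[:, j]
    return labels_from_scores(scores, order), scores


@dataclass
class MetricReport:
    """One-vs-rest confusion counts plus the Table-style metric suite.

    Percentages in [0, 100]; ``fpr`` is a fraction.  ``per_class`` maps each
    class to its counts and metrics; the top-level numbers are the overall
    accuracy and the macro (unweighted) averages.
    """

    per_class: dict[str, dict[str, float]]
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    fpr: float
    auc: float | None = None
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "accuracy_pct": self.accuracy,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "precision_pct": self.precision,
            "f1_pct": self.f1,
            "auc_pct": self.auc,
            "false_positive_rate": self.fpr,
            "per_class": self.per_class,
        }

    def to_table(self) -> str:
        cols = [
            ("Accuracy (%)", self.accuracy),
            ("Sensitivity (%)", self.sensitivity),
            ("Specificity (%)", self.specificity),
            ("F1-score (%)", self.f1),
            ("Precision (%)", self.precision),
            ("AUC score (%)", self.auc),
            ("False positive rate", self.fpr),
        ]
        head = "  ".join(f"{name:>20s}" for name, _ in cols)
        vals = "  ".join(
            f"{('--' if v is None else format(v, '.4g')):>20s}" for _, v in cols
        )
        return head + "\n" + vals


def evaluate(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    scores: np.ndarray | None = None,
    class_order: Sequence[str] = CLASS_ORDER,
) -> MetricReport:
    """Compute the multiclass metric suite from pooled per-beat labels."""
    yt = np.asarray([str(v) for v in y_true], dtype=object)
    yp = np.asarray([str(v) for v in y_pred], dtype=object)
    if len(yt) != len(yp):
        raise SpecificationError("truth and prediction lengths differ")
    if len(set(yt)) < 2:
        raise SpecificationError("need at least two classes in the truth labels")
    m = len(yt)

    per_class: dict[str, dict[str, float]] = {}
    sens_l, prec_l, f1_l, fpr_l = [], [], [], []
    for cls in class_order:
        tp = int(np.sum((yt == cls) & (yp == cls)))
        fp = int(np.sum((yt != cls) & (yp == cls)))
        fn = int(np.sum((yt == cls) & (yp != cls)))
        tn = m - tp - fp - fn
        sens = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        prec = 100.0 * tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
        fpr = fp / (fp + tn) if fp + tn else 0.0
        spec = 100.0 * (1.0 - fpr)  # exact complement identity
        per_class[cls] = {
            "tp": tp,
            "fp": fp,
            "tn": tn,
            "fn": fn,
            "sensitivity_pct": sens,
            "specificity_pct": spec,
            "precision_pct": prec,
            "f1_pct": f1,
            "fpr": fpr,
        }
        sens_l.append(sens)
        prec_l.append(prec)
        f1_l.append(f1)
        fpr_l.append(fpr)

    macro_fpr = float(np.mean(fpr_l))
    auc = None
    if scores is not None:
        scores = np.asarray(scores, dtype=np.float64)
        present = [c for c in class_order if np.any(yt == c)]
        if len(present) >= 2:
            ybin = np.stack(
                [(yt == c).astype(int) for c in class_order], axis=1
            )
            keep = [i for i, c in enumerate(class_order) if c in present]
            auc = 100.0 * float(
                roc_auc_score(
                    ybin[:, keep], scores[:, keep], average="macro"
                )
            )
    return MetricReport(
        per_class=per_class,
        accuracy=100.0 * float(np.sum(yt == yp)) / m,
        sensitivity=float(np.mean(sens_l)),
        specificity=100.0 * (1.0 - macro_fpr),
        precision=float(np.mean(prec_l)),
        f1=float(np.mean(f1_l)),
        fpr=macro_fpr,
        auc=auc,
        n=m,
    )


def model_select(
    candidates: list[TrainedModel], validation: LabeledDataset
) -> tuple[TrainedModel, pd.DataFrame]:
    """Pick the candidate with the best validation macro F1.

    Ties break on higher accuracy, then declaration order.  Returns the
    winner and a comparison table over all candidates.
    """
    if len(candidates) < 2:
        raise SpecificationError("model selection needs at least two candidates")
    if validation.n_samples == 0:
        raise SpecificationError("validation set is empty")
    rows = []
    reports = []
    for mdl in candidates:
        labels, scores = predict(mdl, validation.features)
        rep = evaluate(validation.labels, labels, scores, mdl.class_order)
        reports.append(rep)
        rows.append(
            {
                "kind": mdl.kind,
                "macro_f1_pct": rep.f1,
                "accuracy_pct": rep.accuracy,
                "sensitivity_pct": rep.sensitivity,
                "specificity_pct": rep.specificity,
                "auc_pct": rep.auc,
            }
        )
    best_i = 0
    for i in range(1, len(candidates)):
        if (reports[i].f1, reports[i].accuracy) > (
            reports[best_i].f1,
            reports[best_i].accuracy,
        ):
            best_i = i
    return candidates[best_i], pd.DataFrame(rows)


def save_model(model: TrainedModel, path: str | Path) -> Path:
    """Persist a model: magic + JSON header + joblib payload."""
    path = Path(path)
    header = json.dumps(
        {
            "format": "ecgstream-model",
            "version": _ARTIFACT_VERSION,
            "kind": model.kind,
            "class_order": list(model.class_order),
            "hyperparams": model.hyperparams,
            "seed": model.seed,
            "n_features": N_FEATURES,
        }
    ).encode()
    buf = _io.BytesIO()
    joblib.dump(model.estimator, buf)
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<I", len(header)))
        fh.write(header)
        fh.write(buf.getvalue())
    return path


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    try:
        raw = path.read_bytes()
        if raw[: len(_MAGIC)] != _MAGIC:
            raise ModelLoadError(f"{path} is not an ecgstream model artifact")
        (hlen,) = struct.unpack_from("<I", raw, len(_MAGIC))
        hstart = len(_MAGIC) + 4
        header = json.loads(raw[hstart : hstart + hlen])
        if header.get("version") != _ARTIFACT_VERSION:
            raise ModelLoadError(
                f"artifact version {header.get('version')} unsupported"
            )
        estimator = joblib.load(_io.BytesIO(raw[hstart + hlen :]))
    except ModelLoadError:
        raise
    except Exception as exc:  # truncated/corrupt payload, bad JSON, ...
        raise ModelLoadError(f"cannot load model from {path}: {exc}") from exc
    return TrainedModel(
        kind=header["kind"],
        estimator=estimator,
        class_order=tuple(header["class_order"]),
        hyperparams=header.get("hyperparams", {}),
        seed=header.get("seed", 0),
    )
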