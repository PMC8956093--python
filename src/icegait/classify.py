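"""One-vs-rest linear SVM slip classifiers and the binary slip decision.

Two 3-class classifiers operate per step: the toe-slip classifier (classes
NTS / BTS / FTS) and the heel-slip classifier (NHS / BHS / FHS), each built
from three binary linear SVMs (class vs rest) over its own selected feature
subset. Each binary SVM's decision value is mapped to a probability-like
score by Platt's sigmoid, fitted on the training decision values; the class
with the largest score wins, with ties resolved conservatively to the
no-slip class. A step is a slip iff either classifier reports a slip class:

    slip = BTS or FTS or BHS or FHS

Class imbalance (non-slips dominate on ice) is handled by random
under-sampling of the no-slip class down to the total slip count, repeated
with fresh draws to average out the sampling variance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.svm import LinearSVC

from .config import ClassifierConfig, DEFAULT_CONFIG
from .features import HEEL_CLASSIFIER_FEATURES, TOE_CLASSIFIER_FEATURES

TOE_CLASSES = ("NTS", "BTS", "FTS")
HEEL_CLASSES = ("NHS", "BHS", "FHS")
NO_SLIP = {"toe": "NTS", "heel": "NHS"}


@dataclass(frozen=True)
class SlipLabel:
    """A step's class under both taxonomies; the slip flag is derived."""

    toe_class: str = "NTS"
    heel_class: str = "NHS"

    def __post_init__(self) -> None:
        if self.toe_class not in TOE_CLASSES:
            raise ValueError(f"toe_class must be one of {TOE_CLASSES}")
        if self.heel_class not in HEEL_CLASSES:
            raise ValueError(f"heel_class must be one of {HEEL_CLASSES}")

    @property
    def slip(self) -> bool:
        return self.toe_class != "NTS" or self.heel_class != "NHS"


def slip_disjunction(bts: bool, fts: bool, bhs: bool, fhs: bool) -> bool:
    """The overall binary slip decision: inclusive-or of the four slip types."""
    return bts or fts or bhs or fhs


@dataclass
class Normalization:
    """Per-feature z-score parameters fitted on training data only."""

    mean: np.ndarray
    scale: np.ndarray  # std; zero-variance features get scale 0 -> mapped to 0

    @classmethod
    def fit(cls, X: np.ndarray) -> "Normalization":
        if len(X) == 0:
            raise ValueError("cannot fit normalization on an empty table")
        mean = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        return cls(mean=mean, scale=scale)

    def apply(self, X: np.ndarray) -> np.ndarray:
        safe = np.where(self.scale > 0, self.scale, 1.0)
        Z = (X - self.mean) / safe
        Z[:, self.scale == 0] = 0.0
        return Z


def normalize_fit_apply(
    train: np.ndarray, apply_to: np.ndarray
) -> tuple[np.ndarray, np.ndarray, Normalization]:
    """Fit z-scoring on ``train``; apply to both arrays."""
    if train.shape[1] != apply_to.shape[1]:
        raise ValueError("feature schema mismatch between train and apply_to")
    norm = Normalization.fit(train)
    return norm.apply(train), norm.apply(apply_to), norm


def _platt_fit(decision: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Platt scaling: fit P(y=1|f) = sigmoid(-(A f + B)) by regularised
    maximum likelihood with Platt's target smoothing."""
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(params):
        a, b = params
        z = a * decision + b
        p = expit(-z)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -np.sum(t * np.log(p) + (1 - t) * np.log(1 - p))

    res = minimize(nll, x0=np.array([-1.0, 0.0]), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
    return float(res.x[0]), float(res.x[1])


@dataclass
class OvrLinearSvm:
    """A 3-class one-vs-rest linear SVM with Platt-calibrated scores."""

    classes: tuple[str, ...]
    no_slip_class: str
    weights: np.ndarray        # (n_classes, n_features)
    intercepts: np.ndarray     # (n_classes,)
    platt: np.ndarray          # (n_classes, 2): A, B per class
    C: float
    score: str = "platt"

    def decision_values(self, Z: np.ndarray) -> np.ndarray:
        return Z @ self.weights.T + self.intercepts

    def scores(self, Z: np.ndarray) -> np.ndarray:
        f = self.decision_values(Z)
        if self.score == "margin":
            return f
        return expit(-(self.platt[:, 0] * f + self.platt[:, 1]))

    def predict(self, Z: np.ndarray) -> np.ndarray:
        s = self.scores(Z)
        best = np.argmax(s, axis=1)
        # conservative tie-break: prefer the no-slip class at exact ties
        ns = self.classes.index(self.no_slip_class)
        ties = s[np.arange(len(s)), best] == s[:, ns]
        best[ties] = ns
        return np.asarray(self.classes)[best]


def train_ovr_linear_svm(
    Z: np.ndarray,
    labels: np.ndarray,
    classes: tuple[str, ...],
    no_slip_class: str,
    C: float = 1.0,
    seed: int = 0,
    score: str = "platt",
    max_iter: int = 5000,
) -> OvrLinearSvm:
    """Fit one binary linear SVM per class (class vs rest) on normalised data."""
    labels = np.asarray(labels)
    present = [c for c in classes if (labels == c).sum() >= 2]
    if len(present) < 2:
        raise ValueError("need at least 2 classes with >= 2 samples each")
    n_feat = Z.shape[1]
    weights = np.zeros((len(classes), n_feat))
    intercepts = np.full(len(classes), -np.inf)
    platt = np.tile([1.0, 0.0], (len(classes), 1))
    for i, cls in enumerate(classes):
        y = (labels == cls).astype(int)
        if y.sum() < 2 or y.sum() > len(y) - 2:
            # class absent (or rest absent): leave a never-winning classifier
            intercepts[i] = -1e9 if y.sum() < 2 else 1e9
            weights[i] = 0.0
            platt[i] = (-1.0, 0.0)
            continue
        svm = LinearSVC(C=C, max_iter=max_iter, random_state=seed, dual=False)
        svm.fit(Z, y)
        weights[i] = svm.coef_[0]
        intercepts[i] = svm.intercept_[0]
        platt[i] = _platt_fit(svm.decision_function(Z), y)
    return OvrLinearSvm(
        classes=tuple(classes), no_slip_class=no_slip_class,
        weights=weights, intercepts=intercepts, platt=platt, C=C, score=score,
    )


def undersample(
    labels: np.ndarray,
    no_slip_class: str,
    seed: int,
    repeat_index: int = 0,
) -> np.ndarray:
    """Indices of a balanced subset: the no-slip class is randomly
    down-sampled to the total slip count; slip classes are kept in full.
    Deterministic given (seed, repeat_index)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(np.random.SeedSequence([seed, repeat_index]))
    slip_idx = np.flatnonzero(labels != no_slip_class)
    ns_idx = np.flatnonzero(labels == no_slip_class)
    n_keep = min(len(slip_idx), len(ns_idx))
    keep = rng.choice(ns_idx, size=n_keep, replace=False) if n_keep < len(ns_idx) else ns_idx
    return np.sort(np.concatenate([slip_idx, keep]))


@dataclass
class TrainedSlipModel:
    """The full two-taxonomy model, serialisable to plain JSON."""

    toe: OvrLinearSvm
    heel: OvrLinearSvm
    toe_norm: Normalization
    heel_norm: Normalization
    toe_features: tuple[int, ...] = TOE_CLASSIFIER_FEATURES
    heel_features: tuple[int, ...] = HEEL_CLASSIFIER_FEATURES
    metadata: dict = field(default_factory=dict)

    def predict_frame(self, features: pd.DataFrame) -> pd.DataFrame:
        """Predict toe/heel classes and the slip flag for a feature table."""
        Xt = features[[f"f{i}" for i in self.toe_features]].to_numpy(float)
        Xh = features[[f"f{i}" for i in self.heel_features]].to_numpy(float)
        toe_pred = self.toe.predict(self.toe_norm.apply(Xt))
        heel_pred = self.heel.predict(self.heel_norm.apply(Xh))
        slip = (toe_pred != "NTS") | (heel_pred != "NHS")
        return pd.DataFrame(
            {"toe_class": toe_pred, "heel_class": heel_pred, "slip": slip},
            index=features.index,
        )

    def predict_step(self, fv) -> SlipLabel:
        """Classify one StepFeatureVector."""
        row = {f"f{i}": fv.values[i] for i in range(1, 37)}
        out = self.predict_frame(pd.DataFrame([row])).iloc[0]
        return SlipLabel(toe_class=out.toe_class, heel_class=out.heel_class)

    def save(self, path: str | Path) -> None:
        def svm_dict(m: OvrLinearSvm, norm: Normalization, feats):
            return {
                "classes": list(m.classes),
                "no_slip_class": m.no_slip_class,
                "weights": m.weights.tolist(),
                "intercepts": m.intercepts.tolist(),
                "platt": m.platt.tolist(),
                "C": m.C,
                "score": m.score,
                "normalization": {"mean": norm.mean.tolist(), "scale": norm.scale.tolist()},
                "feature_ids": list(feats),
            }

        doc = {
            "toe": svm_dict(self.toe, self.toe_norm, self.toe_features),
            "heel": svm_dict(self.heel, self.heel_norm, self.heel_features),
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedSlipModel":
        doc = json.loads(Path(path).read_text())

        def parse(d):
            m = OvrLinearSvm(
                classes=tuple(d["classes"]), no_slip_class=d["no_slip_class"],
                weights=np.asarray(d["weights"]), intercepts=np.asarray(d["intercepts"]),
                platt=np.asarray(d["platt"]), C=d["C"], score=d["score"],
            )
            n = Normalization(
                mean=np.asarray(d["normalization"]["mean"]),
                scale=np.asarray(d["normalization"]["scale"]),
            )
            return m, n, tuple(d["feature_ids"])

        toe, toe_norm, toe_f = parse(doc["toe"])
        heel, heel_norm, heel_f = parse(doc["heel"])
        return cls(
            toe=toe, heel=heel, toe_norm=toe_norm, heel_norm=heel_norm,
            toe_features=toe_f, heel_features=heel_f,
            metadata=doc.get("metadata", {}),
        )


def _macro_f1(y_true: np.ndarray, y_pred: np.ndarray, classes) -> float:
    f1s = []
    for c in classes:
        tp = int(np.sum((y_pred == c) & (y_true == c)))
        fp = int(np.sum((y_pred == c) & (y_true != c)))
        fn = int(np.sum((y_pred != c) & (y_true == c)))
        if tp + fp == 0 or tp + fn == 0:
            continue
        p = tp / (tp + fp)
        r = tp / (tp + fn)
        f1s.append(0.0 if p + r == 0 else 2 * p * r / (p + r))
    return float(np.mean(f1s)) if f1s else 0.0


def fit_taxonomy_classifier(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    classes: tuple[str, ...],
    no_slip_class: str,
    config: ClassifierConfig = DEFAULT_CONFIG.classifier,
    seed: int = 0,
) -> tuple[OvrLinearSvm, Normalization, float]:
    """Tune C on the validation split (macro-F1, raw-margin prediction for
    speed), then fit the final Platt-calibrated model on the training split.
    Returns (model, normalization, best C)."""
    Z_train, Z_val, norm = normalize_fit_apply(X_train, X_val)
    best_c, best_f1 = config.c_grid[0], -1.0
    for C in config.c_grid:
        m = train_ovr_linear_svm(
            Z_train, y_train, classes, no_slip_class, C=C, seed=seed,
            score="margin", max_iter=config.max_iter,
        )
        f1 = _macro_f1(y_val, m.predict(Z_val), classes)
        if f1 > best_f1:
            best_c, best_f1 = C, f1
    model = train_ovr_linear_svm(
        Z_train, y_train, classes, no_slip_class, C=best_c, seed=seed,
        score=config.score, max_iter=config.max_iter,
    )
    return model, norm, best_c
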