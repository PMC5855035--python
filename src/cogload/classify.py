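"""Workload classification: RF-RFE feature selection, three classifiers and
a repeated stratified evaluation protocol with chance-corrected metrics.

Models: softmax multinomial logistic regression (m-LR), a one-vs-rest
RBF-kernel SVM (m-SVM) and a two-hidden-layer rectified-linear MLP. Each
repetition draws a stratified 70/30 split, optionally runs a stratified
k-fold cross-validation inside the training portion as a sanity score,
fits on the training portion and reports held-out accuracy, macro recall,
macro precision and Cohen's kappa; the report averages over repetitions.

Pupil features define the workload labels, so by default they are excluded
from the classifier inputs (including them leaks the target); the original
protocol fed all 44 features to the MLP, and that mode remains available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import (StratifiedKFold, cross_val_score,
                                     train_test_split)
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_NAMES, SENSOR_GROUPS


@dataclass(frozen=True)
class ModelSpec:
    """Immutable hyperparameters of one classifier."""

    kind: str                      # "m-LR" | "m-SVM" | "MLP"
    hidden_layers: int = 2
    units: int = 1000
    epochs: int = 500
    l2: float = 1e-5               # λ2 of the penalty mix; the MLP backend
    #                                supports an L2 penalty only, so λ1 = 0

    @staticmethod
    def mlr() -> "ModelSpec":
        return ModelSpec(kind="m-LR")

    @staticmethod
    def msvm() -> "ModelSpec":
        return ModelSpec(kind="m-SVM")

    @staticmethod
    def mlp(units: int = 1000, epochs: int = 500) -> "ModelSpec":
        return ModelSpec(kind="MLP", units=units, epochs=epochs)


@dataclass(frozen=True)
class EvaluationProtocol:
    train_fraction: float = 0.70
    folds: int = 10                # stratified CV inside the training part
    repetitions: int = 100
    stratified: bool = True
    seed: int = 0
    run_cv: bool = True            # skip the sanity CV to halve the cost


@dataclass
class EvaluationReport:
    """Per-model metrics in percent, mean ± sd over repetitions."""

    model: str
    accuracy: tuple[float, float]
    recall: tuple[float, float]
    precision: tuple[float, float]
    kappa: tuple[float, float]
    cv_accuracy: tuple[float, float] | None
    confusion: np.ndarray          # last repetition's held-out confusion
    n_repetitions: int
    features: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "n_repetitions": self.n_repetitions,
            "confusion": self.confusion.tolist(),
            "features": self.features,
        }
        for name in ("accuracy", "recall", "precision", "kappa"):
            m, s = getattr(self, name)
            d[name] = {"mean": float(m), "sd": float(s)}
        if self.cv_accuracy is not None:
            d["cv_accuracy"] = {"mean": float(self.cv_accuracy[0]),
                                "sd": float(self.cv_accuracy[1])}
        return d


def build_model(spec: ModelSpec, seed: int):
    if spec.kind == "m-LR":
        clf = LogisticRegression(max_iter=2000, C=1.0)
    elif spec.kind == "m-SVM":
        clf = OneVsRestClassifier(SVC(kernel="rbf", gamma="scale"))
    elif spec.kind == "MLP":
        clf = MLPClassifier(
            hidden_layer_sizes=(spec.units,) * spec.hidden_layers,
            activation="relu", alpha=spec.l2, max_iter=spec.epochs,
            random_state=seed, solver="adam",
        )
    else:
        raise ValueError(f"unknown model kind {spec.kind!r}")
    return make_pipeline(StandardScaler(), clf)


def cohen_kappa(confusion: np.ndarray) -> float:
    """(p_o − p_e)/(1 − p_e) from a KxK confusion matrix's marginals.

    p_o is the observed accuracy; p_e the accuracy a random classifier with
    the same row/column marginals would achieve. Degenerate case p_e = 1
    (all mass in one row+column) is defined as 0.
    """
    c = np.asarray(confusion, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    if (c < 0).any():
        raise ValueError("negative counts")
    p_o = np.trace(c) / total
    p_e = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / total ** 2
    if p_e >= 1.0:
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray,
               classes: np.ndarray) -> np.ndarray:
    k = len(classes)
    pos = {c: i for i, c in enumerate(classes)}
    out = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        out[pos[t], pos[p]] += 1
    return out


def _macro_metrics(conf: np.ndarray) -> tuple[float, float, float]:
    """(accuracy, macro recall, macro precision) from a confusion matrix."""
    total = conf.sum()
    acc = np.trace(conf) / total
    with np.errstate(invalid="ignore", divide="ignore"):
        rec = np.diag(conf) / conf.sum(axis=1)
        prec = np.diag(conf) / conf.sum(axis=0)
    return float(acc), float(np.nanmean(rec)), float(np.nanmean(prec))


def check_stratification(y_full: np.ndarray, y_part: np.ndarray,
                         tolerance: int = 2) -> bool:
    """Class counts of a split within ±tolerance of the global proportion."""
    classes, counts = np.unique(y_full, return_counts=True)
    frac = len(y_part) / len(y_full)
    for c, n in zip(classes, counts):
        expected = n * frac
        got = int(np.sum(y_part == c))
        if abs(got - expected) > tolerance:
            return False
    return True


def train_eval(features: pd.DataFrame | np.ndarray, labels: np.ndarray,
               spec: ModelSpec, protocol: EvaluationProtocol) -> EvaluationReport:
    """Repeated stratified 70/30 evaluation of one model."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("single-class data cannot be evaluated")
    if protocol.run_cv and counts.min() < protocol.folds:
        raise ValueError(
            f"class {classes[np.argmin(counts)]!r} has fewer members than "
            f"{protocol.folds} folds")

    accs, recs, precs, kappas, cvs = [], [], [], [], []
    conf = None
    for rep in range(protocol.repetitions):
        rep_seed = protocol.seed * 100003 + rep
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=protocol.train_fraction,
            stratify=y if protocol.stratified else None,
            random_state=rep_seed % (2 ** 32 - 1))
        model = build_model(spec, rep_seed % (2 ** 31 - 1))
        if protocol.run_cv:
            skf = StratifiedKFold(n_splits=protocol.folds, shuffle=True,
                                  random_state=rep_seed % (2 ** 31 - 1))
            cvs.append(float(np.mean(
                cross_val_score(model, X_tr, y_tr, cv=skf))))
        model.fit(X_tr, y_tr)
        y_pred = model.predict(X_te)
        conf = _confusion(y_te, y_pred, classes)
        acc, rec, prec = _macro_metrics(conf)
        accs.append(acc)
        recs.append(rec)
        precs.append(prec)
        kappas.append(cohen_kappa(conf))

    def stat(v):
        a = 100.0 * np.asarray(v)
        return (float(a.mean()), float(a.std(ddof=1)) if len(a) > 1 else 0.0)

    names = (list(features.columns) if isinstance(features, pd.DataFrame)
             else [])
    return EvaluationReport(
        model=spec.kind,
        accuracy=stat(accs), recall=stat(recs), precision=stat(precs),
        kappa=stat(kappas),
        cv_accuracy=stat(cvs) if cvs else None,
        confusion=conf, n_repetitions=protocol.repetitions,
        features=names,
    )


def rf_rfe(features: pd.DataFrame, labels: np.ndarray, seed: int = 0,
           n_estimators: int = 100, cv_folds: int = 5,
           min_features: int = 1) -> tuple[list[str], pd.DataFrame]:
    """Recursive feature elimination driven by random-forest importances.

    At each step a forest is fitted, cross-validated accuracy recorded and
    the least important feature dropped. Returns the smallest feature set
    whose CV accuracy is within one sd of the best, plus the elimination
    trace (subset size, accuracy mean/sd, dropped feature).
    """
    X = features.copy()
    y = np.asarray(labels)
    trace = []
    subsets: list[list[str]] = []
    rng_seed = seed % (2 ** 31 - 1)
    while X.shape[1] >= max(min_features, 1):
        rf = RandomForestClassifier(n_estimators=n_estimators,
                                    random_state=rng_seed)
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                              random_state=rng_seed)
        scores = cross_val_score(rf, X.to_numpy(), y, cv=skf)
        rf.fit(X.to_numpy(), y)
        subsets.append(list(X.columns))
        worst = X.columns[int(np.argmin(rf.feature_importances_))]
        trace.append({"n_features": X.shape[1],
                      "cv_accuracy": float(scores.mean()),
                      "cv_sd": float(scores.std(ddof=1)),
                      "dropped": worst})
        if X.shape[1] == max(min_features, 1):
            break
        X = X.drop(columns=[worst])

    df = pd.DataFrame(trace)
    best = df["cv_accuracy"].max()
    best_sd = float(df.loc[df["cv_accuracy"].idxmax(), "cv_sd"])
    ok = df["cv_accuracy"] >= best - best_sd
    # smallest subset within one sd of the best
    chosen_row = df[ok]["n_features"].idxmin()
    chosen = subsets[int(chosen_row)]
    # no-signal guard: the best subset must beat the majority-class baseline
    # by more than selection noise
    _, counts = np.unique(y, return_counts=True)
    chance = counts.max() / counts.sum()
    chance_sd = float(np.sqrt(chance * (1 - chance) / len(y)))
    if best <= chance + 2 * max(best_sd, chance_sd):
        df.attrs["degenerate"] = True
    return chosen, df


ABLATION_GROUPS = ("EDA", "T", "ECG", "PPG", "EEG", "EDA+PPG", "EDA+EEG",
                   "PPG+EEG", "EDA+PPG+EEG", "All")


def group_features(group: str, include_pupil_in_all: bool = False) -> list[str]:
    """Feature names of one sensor group or '+'-combination."""
    if group == "All":
        names = []
        for g in ("EDA", "T", "ECG", "PPG", "EEG"):
            names += list(SENSOR_GROUPS[g])
        if include_pupil_in_all:
            names = list(SENSOR_GROUPS["pupil"]) + names
        return names
    names = []
    for part in group.split("+"):
        if part not in SENSOR_GROUPS:
            raise ValueError(f"unknown sensor group {part!r}")
        names += list(SENSOR_GROUPS[part])
    return names


def per_sensor_ablation(features: pd.DataFrame, labels: np.ndarray,
                        spec: ModelSpec, protocol: EvaluationProtocol,
                        groups: tuple[str, ...] = ABLATION_GROUPS,
                        include_pupil_in_all: bool = False,
                        ) -> dict[str, EvaluationReport]:
    """One evaluation per sensor group/combination."""
    out = {}
    for g in groups:
        cols = group_features(g, include_pupil_in_all)
        out[g] = train_eval(features[cols], labels, spec, protocol)
    return out
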