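"""Classifiers over the selected token-score features.

Four algorithm families are supported, mirroring common practice for
small bag-of-words feature tables:

* ``nb``         — Gaussian naive Bayes (per-class, per-feature normal
  likelihoods; variances floored to survive constant columns);
* ``ibk``        — k-nearest neighbour with inverse-distance weighting,
  k chosen by an internal stratified cross-validated AUC search over
  k = 1..10 (ties to the smaller k);
* ``svm_linear`` — support vector machine, linear kernel, C = 1;
* ``svm_rbf``    — support vector machine, RBF kernel, C = 1,
  gamma = 1 / (n_features × feature variance).

Feature values are the per-drug token scores (cdf / ctf / ctf-icdf) of
the top-ranked tokens.  cdf features are already in [0, 1] and are used
as-is; for the unbounded measures the SVMs standardize columns (the
scaler is stored with the model).  Models return a continuous ranking
score per drug — a positive-class probability for nb/ibk, a decision
value for the SVMs — suitable as ROC input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .feature_selection import CharacteristicLabels, _mann_whitney_auc
from .frequency import FrequencyMatrix

__all__ = [
    "ALGORITHMS",
    "FeatureTable",
    "TrainedModel",
    "build_feature_table",
    "train",
    "score",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

ALGORITHMS = ("nb", "ibk", "svm_linear", "svm_rbf")

NB_VAR_SMOOTHING = 1e-6
SVM_C = 1.0
IBK_K_RANGE = tuple(range(1, 11))


@dataclass
class FeatureTable:
    """Drugs × selected-token score table with binary labels.

    Column order equals the token-ranking order; a drug lacking a token
    scores 0.  ``y`` may be None for unlabeled (prediction-time) tables.
    """

    X: pd.DataFrame
    y: pd.Series | None = None
    measure: str = "cdf"

    @property
    def tokens(self) -> list[str]:
        return list(self.X.columns)

    @property
    def drugs(self) -> list[str]:
        return list(self.X.index)


def build_feature_table(
    matrix: FrequencyMatrix,
    tokens: Sequence[str],
    labels: CharacteristicLabels | None = None,
    drugs: Sequence[str] | None = None,
) -> FeatureTable:
    """Extract the columns of ``tokens`` for ``drugs`` (default: all)."""
    if drugs is None:
        drugs = matrix.drugs
    sub = matrix.restrict_drugs(list(drugs))
    token_pos = {t: i for i, t in enumerate(sub.tokens)}
    data = np.zeros((len(drugs), len(tokens)))
    dense = None
    rows = [token_pos[t] for t in tokens if t in token_pos]
    if rows:
        dense = np.asarray(sub.scores[rows].todense())
    k = 0
    for j, token in enumerate(tokens):
        if token in token_pos:
            data[:, j] = dense[k]
            k += 1
    X = pd.DataFrame(data, index=[d.lower() for d in drugs], columns=list(tokens))
    y = None
    if labels is not None:
        y = pd.Series(labels.mask(X.index), index=X.index, name="label")
    return FeatureTable(X=X, y=y, measure=matrix.measure)


@dataclass
class TrainedModel:
    algorithm: str
    estimator: object
    tokens: list[str]
    seed: int
    measure: str = "cdf"
    scaler: StandardScaler | None = None
    score_kind: str = "probability"
    metadata: dict = field(default_factory=dict)

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        values = X.to_numpy(dtype=float)
        if self.scaler is not None:
            values = self.scaler.transform(values)
        return values


def _select_k(
    X: np.ndarray, y: np.ndarray, seed: int
) -> tuple[int, dict[int, float]]:
    """Internal stratified CV over k; selection by mean AUC, ties → small k."""
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    n_splits = min(5, n_pos, n_neg)
    ks = [k for k in IBK_K_RANGE if k < len(y)] or [1]
    if n_splits < 2:
        return ks[0], {}
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    mean_auc: dict[int, float] = {}
    folds = list(cv.split(X, y))
    for k in ks:
        aucs = []
        for train_idx, test_idx in folds:
            if k >= len(train_idx):
                continue
            est = KNeighborsClassifier(n_neighbors=k, weights="distance")
            est.fit(X[train_idx], y[train_idx])
            prob = est.predict_proba(X[test_idx])[:, 1]
            if 0 < y[test_idx].sum() < len(test_idx):
                aucs.append(_mann_whitney_auc(prob, y[test_idx].astype(bool)))
        if aucs:
            mean_auc[k] = float(np.mean(aucs))
    if not mean_auc:
        return ks[0], {}
    best = max(mean_auc.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    return best, mean_auc


def train(
    table: FeatureTable, algorithm: str, seed: int = 0
) -> TrainedModel:
    """Fit one algorithm on a labeled feature table; deterministic given seed."""
    if algorithm not in ALGORITHMS:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}"
        )
    if table.y is None:
        raise ValueError("training requires a labeled table")
    y = table.y.to_numpy(dtype=bool)
    if y.all() or not y.any():
        raise ValueError("training table has a single class")
    X = table.X.to_numpy(dtype=float)

    scaler = None
    if algorithm.startswith("svm") and table.measure != "cdf":
        scaler = StandardScaler()
        X = scaler.fit_transform(X)

    metadata: dict = {"seed": seed, "measure": table.measure}
    if algorithm == "nb":
        est = GaussianNB(var_smoothing=NB_VAR_SMOOTHING)
        score_kind = "probability"
        metadata["var_smoothing"] = NB_VAR_SMOOTHING
    elif algorithm == "ibk":
        k, search = _select_k(X, y, seed)
        est = KNeighborsClassifier(n_neighbors=k, weights="distance")
        score_kind = "probability"
        metadata["k"] = k
        metadata["k_search_auc"] = search
    elif algorithm == "svm_linear":
        est = SVC(kernel="linear", C=SVM_C, random_state=seed)
        score_kind = "decision"
        metadata["C"] = SVM_C
    else:  # svm_rbf
        est = SVC(kernel="rbf", C=SVM_C, gamma="scale", random_state=seed)
        score_kind = "decision"
        metadata["C"] = SVM_C
        metadata["gamma"] = "scale"

    est.fit(X, y)
    return TrainedModel(
        algorithm=algorithm,
        estimator=est,
        tokens=table.tokens,
        seed=seed,
        measure=table.measure,
        scaler=scaler,
        score_kind=score_kind,
        metadata=metadata,
    )


def score(
    model: TrainedModel, table: FeatureTable, kind: str | None = None
) -> pd.Series:
    """Continuous per-drug ranking score (higher = more likely positive).

    ``kind`` may force "probability" or "decision" where the estimator
    supports it; the default is the model's native score.
    """
    if table.tokens != model.tokens:
        extra = sorted(set(table.tokens) - set(model.tokens))
        missing = sorted(set(model.tokens) - set(table.tokens))
        raise ValueError(
            f"feature mismatch: table lacks {missing[:5]}, "
            f"has unexpected {extra[:5]}"
        )
    X = model.transform(table.X)
    kind = kind or model.score_kind
    if kind == "probability":
        if not hasattr(model.estimator, "predict_proba"):
            raise ValueError(
                f"{model.algorithm} exposes no probability score"
            )
        values = model.estimator.predict_proba(X)[:, 1]
    elif kind == "decision":
        if not hasattr(model.estimator, "decision_function"):
            # NB / kNN: use the positive-class probability as the margin
            values = model.estimator.predict_proba(X)[:, 1]
        else:
            values = model.estimator.decision_function(X)
    else:
        raise ValueError(f"unknown score kind {kind!r}")
    return pd.Series(values, index=table.X.index, name="score")


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize model + metadata to a single archive file."""
    joblib.dump(
        {
            "algorithm": model.algorithm,
            "estimator": model.estimator,
            "tokens": model.tokens,
            "seed": model.seed,
            "measure": model.measure,
            "scaler": model.scaler,
            "score_kind": model.score_kind,
            "metadata": model.metadata,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    return TrainedModel(**payload)
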