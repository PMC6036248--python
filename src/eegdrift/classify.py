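"""Pluggable multiclass classifier used identically by every protocol.

Default backend: soft-margin RBF-kernel SVM (one-vs-one multiclass), with
per-feature standardisation fitted on the training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestCentroid
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from eegdrift.features import METADATA_COLUMNS, feature_columns


@dataclass(frozen=True)
class ClassifierConfig:
    """Classifier settings.

    ``backend`` is one of ``"svm-rbf"``, ``"svm-linear"`` or ``"centroid"``
    (a nearest-centroid reference).  ``gamma`` follows scikit-learn's
    ``"scale"`` rule (inverse of feature count times pooled variance) by
    default.  ``standardize`` z-scores features on training statistics.
    """

    backend: str = "svm-rbf"
    C: float = 1.0
    gamma: str | float = "scale"
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("regularization constant C must be positive")
        if self.backend not in ("svm-rbf", "svm-linear", "centroid"):
            raise ValueError(f"unknown classifier backend {self.backend!r}")


def build_estimator(cfg: ClassifierConfig):
    """Construct the scikit-learn estimator described by ``cfg``."""
    if cfg.backend == "svm-rbf":
        clf = SVC(C=cfg.C, kernel="rbf", gamma=cfg.gamma, random_state=cfg.seed)
    elif cfg.backend == "svm-linear":
        clf = SVC(C=cfg.C, kernel="linear", random_state=cfg.seed)
    else:
        clf = NearestCentroid()
    if cfg.standardize:
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])
    return clf


def _as_xy(table: pd.DataFrame, cols: list[str]) -> tuple[np.ndarray, np.ndarray]:
    return table[cols].to_numpy(dtype=float), table["class"].to_numpy()


def fit_predict(
    train: pd.DataFrame,
    test: pd.DataFrame,
    cfg: ClassifierConfig | None = None,
    columns: list[str] | None = None,
) -> tuple[np.ndarray, float]:
    """Fit on ``train``, predict ``test``; return predicted labels and accuracy.

    Both tables must be feature tables (metadata columns plus a shared
    feature-column set).  ``columns`` optionally restricts the features used.
    Standardisation statistics come from the training rows only.
    """
    cfg = cfg or ClassifierConfig()
    cols = columns if columns is not None else feature_columns(train)
    if not cols:
        raise ValueError("no feature columns to train on")
    missing = [c for c in cols if c not in test.columns or c not in train.columns]
    if missing:
        raise ValueError(f"feature columns missing from train/test tables: {missing[:5]}")
    x_train, y_train = _as_xy(train, list(cols))
    x_test, y_test = _as_xy(test, list(cols))
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    est = build_estimator(cfg)
    est.fit(x_train, y_train)
    pred = est.predict(x_test)
    accuracy = float(np.mean(pred == y_test))
    return pred, accuracy


__all__ = ["ClassifierConfig", "build_estimator", "fit_predict"]
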