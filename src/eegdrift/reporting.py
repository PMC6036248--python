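"""Result summaries, statistics, serialization and run provenance.

Confusion matrices follow the predicted-label-rows / true-label-columns
convention with row normalisation; paired accuracy comparisons use the
paired t-test with explicit degenerate-case conventions.  All tables are
written as delimited text with headers; every results directory carries a
provenance sidecar embedding the full run configuration and its hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from eegdrift.classify import ClassifierConfig
from eegdrift.features import EpochArray, METADATA_COLUMNS

DEFAULT_LABEL_ORDER = ("positive", "neutral", "negative")


@dataclass
class ConfusionMatrix:
    """3x3 (or kxk) confusion matrix: rows = predicted, columns = true."""

    counts: pd.DataFrame
    normalized: pd.DataFrame

    @property
    def labels(self) -> list:
        return list(self.counts.index)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts.to_numpy()) / self.counts.to_numpy().sum())


def confusion_matrix(
    true_labels: Sequence,
    predicted_labels: Sequence,
    labels: Sequence | None = None,
) -> ConfusionMatrix:
    """Accumulate (predicted, true) counts and row-normalise.

    Rows are predicted labels, columns true labels, ordered
    (positive, neutral, negative) by default.  Rows with no predictions
    normalise to zero.
    """
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences differ in length")
    if labels is None:
        seen = set(true_labels) | set(predicted_labels)
        labels = list(DEFAULT_LABEL_ORDER) if seen <= set(DEFAULT_LABEL_ORDER) else sorted(seen)
    unknown = (set(true_labels) | set(predicted_labels)) - set(labels)
    if unknown:
        raise ValueError(f"unknown label(s): {sorted(unknown)}")
    index = {l: i for i, l in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        counts[index[p], index[t]] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(row_sums > 0, counts / np.maximum(row_sums, 1), 0.0)
    frame = lambda a: pd.DataFrame(a, index=list(labels), columns=list(labels))
    return ConfusionMatrix(counts=frame(counts), normalized=frame(normalized))


def paired_comparison(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Paired t-test on per-subject accuracy differences.

    Conventions: identical vectors give ``(0.0, 1.0)``; a constant nonzero
    difference (zero variance) gives an infinite statistic with p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors differ in length")
    if a.size < 2:
        raise ValueError("paired comparison needs at least 2 pairs")
    d = a - b
    if np.allclose(d, 0.0):
        return 0.0, 1.0
    if np.isclose(d.std(ddof=1), 0.0):
        return math.copysign(math.inf, d.mean()), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


@dataclass
class RunConfig:
    """Complete run configuration; round-trips losslessly through YAML."""

    seed: int = 0
    bands: list = field(
        default_factory=lambda: [
            ["delta", 0.5, 4.0],
            ["theta", 4.0, 8.0],
            ["alpha", 8.0, 13.0],
            ["beta", 13.0, 30.0],
            ["low_gamma", 30.0, 44.0],
            ["high_gamma", 44.0, 100.0],
        ]
    )
    classifier: dict = field(
        default_factory=lambda: {"backend": "svm-rbf", "C": 1.0, "gamma": "scale",
                                 "standardize": True}
    )
    protocols: dict = field(
        default_factory=lambda: {"wdc_repetitions": 5, "scdc_repetitions": 5,
                                 "lndi_repetitions": 10, "top_m": 100, "vote_threshold": 3,
                                 "rfe_step": 1}
    )
    synthetic: dict = field(default_factory=dict)
    output_dir: str = "results"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Stable hash of the configuration, embedded in every results file."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def classifier_config(self) -> ClassifierConfig:
        return ClassifierConfig(seed=self.seed, **self.classifier)


def save_feature_table(table: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a feature table as delimited text, metadata columns first."""
    meta = [c for c in METADATA_COLUMNS if c in table.columns]
    rest = [c for c in table.columns if c not in meta]
    table[meta + rest].to_csv(path, sep=sep, index=False)


def load_feature_table(path: str | Path, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)


def save_epochs(epochs: Sequence[EpochArray], directory: str | Path) -> None:
    """Write epochs as plain-text matrices plus a JSON metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, ep in enumerate(epochs):
        name = f"epoch_{i:05d}.txt"
        np.savetxt(directory / name, ep.data)
        manifest.append(
            {
                "file": name,
                "fs": ep.fs,
                "channel_names": list(ep.channel_names),
                "metadata": {k: _jsonable(v) for k, v in ep.metadata.items()},
            }
        )
    (directory / "epochs.json").write_text(json.dumps(manifest, indent=1))


def load_epochs(directory: str | Path) -> list[EpochArray]:
    directory = Path(directory)
    manifest = json.loads((directory / "epochs.json").read_text())
    epochs = []
    for entry in manifest:
        data = np.loadtxt(directory / entry["file"], ndmin=2)
        epochs.append(
            EpochArray(
                data=data,
                fs=entry["fs"],
                channel_names=tuple(entry["channel_names"]),
                metadata=dict(entry["metadata"]),
            )
        )
    return epochs


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def write_result(cells: pd.DataFrame, path: str | Path, config: RunConfig | None = None) -> None:
    """Write a tidy result table; sidecar ``<stem>.provenance.yaml`` echoes config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cells.to_csv(path, index=False)
    if config is not None:
        sidecar = path.with_suffix(".provenance.yaml")
        payload = config.to_dict()
        payload["config_hash"] = config.digest()
        sidecar.write_text(yaml.safe_dump(payload, sort_keys=True))


__all__ = [
    "ConfusionMatrix",
    "DEFAULT_LABEL_ORDER",
    "RunConfig",
    "confusion_matrix",
    "load_epochs",
    "load_feature_table",
    "paired_comparison",
    "save_epochs",
    "save_feature_table",
    "write_result",
]
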