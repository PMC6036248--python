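"""Calibration / evaluation protocols over a subject's multi-day study.

Three strategies are implemented:

* **WDC** (within-day): train and test on the same day, stratified 80/20
  splits, 5 repetitions per day.
* **SCDC** (standard cross-day): train on one day's 80 % pool, test on each
  other day in full; training size matched to WDC.
* **LNDI** (learning-N-days information): train on equal sample quotas drawn
  from N days, test on equal quotas from the remaining 5-N days, averaged
  over all C(5, N) day combinations and (by default) 10 repetitions.

plus a window-width analysis that alternates consecutive temporal blocks
between training and testing within each day.

All random draws derive from one master seed through documented
per-(repetition, combination) seed sequences, so any single cell is
reproducible in isolation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb, floor
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from eegdrift.classify import ClassifierConfig, fit_predict
from eegdrift.features import METADATA_COLUMNS, feature_columns

#: Stream tags keeping the protocols' random draws decorrelated.
_WDC_TAG, _SCDC_TAG, _LNDI_TAG, _SPLIT_TAG = 11, 13, 17, 19


@dataclass
class SubjectStudy:
    """The per-day feature tables of one subject.

    ``tables`` maps day index (1-based) to that day's feature table.  All
    days must share the same feature columns and contain every class.
    """

    tables: dict[int, pd.DataFrame]
    subject: object = None

    def __post_init__(self) -> None:
        if not self.tables:
            raise ValueError("study has no days")
        self.tables = {int(d): t.reset_index(drop=True) for d, t in sorted(self.tables.items())}
        cols = feature_columns(next(iter(self.tables.values())))
        for d, t in self.tables.items():
            if feature_columns(t) != cols:
                raise ValueError(f"day {d} has inconsistent feature columns")
            if t.empty:
                raise ValueError(f"day {d} is empty")

    @classmethod
    def from_table(cls, table: pd.DataFrame, subject: object = None) -> "SubjectStudy":
        """Split a combined feature table into per-day tables on its ``day`` column."""
        if subject is None and "subject" in table.columns:
            subjects = table["subject"].unique()
            if len(subjects) == 1:
                subject = subjects[0]
        return cls(
            {int(d): g.reset_index(drop=True) for d, g in table.groupby("day")},
            subject=subject,
        )

    def to_table(self) -> pd.DataFrame:
        return pd.concat(self.tables.values(), ignore_index=True)

    @property
    def days(self) -> list[int]:
        return list(self.tables)

    @property
    def n_days(self) -> int:
        return len(self.tables)

    @property
    def feature_columns(self) -> list[str]:
        return feature_columns(next(iter(self.tables.values())))

    @property
    def classes(self) -> list:
        return sorted(next(iter(self.tables.values()))["class"].unique())

    def day_counts(self) -> dict[int, int]:
        return {d: len(t) for d, t in self.tables.items()}

    def restrict(self, columns: Sequence[str]) -> "SubjectStudy":
        """A copy keeping only the given feature columns (metadata retained)."""
        keep = list(METADATA_COLUMNS) + [c for c in self.feature_columns if c in set(columns)]
        return SubjectStudy(
            {d: t[keep].copy() for d, t in self.tables.items()}, subject=self.subject
        )


@dataclass(frozen=True)
class SampleBudget:
    """Per-condition sample budget ``M_min = floor(min day count / 12) * 12``."""

    m_min: int

    def __post_init__(self) -> None:
        if self.m_min < 12 or self.m_min % 12:
            raise ValueError("M_min must be a positive multiple of 12")

    def train_quota(self, n_train_days: int) -> int:
        return self.m_min // n_train_days

    def test_quota(self, n_test_days: int) -> int:
        return self.m_min // n_test_days


def compute_sample_budget(day_counts: Sequence[int] | Mapping[int, int]) -> SampleBudget:
    """Budget from the five per-day sample counts: ``floor(min/12) * 12``."""
    counts = list(day_counts.values()) if isinstance(day_counts, Mapping) else list(day_counts)
    if len(counts) != 5:
        raise ValueError(f"expected 5 day counts, got {len(counts)}")
    if any(c <= 0 for c in counts):
        raise ValueError("day counts must be positive")
    m_min = floor(min(counts) / 12) * 12
    if m_min == 0:
        raise ValueError(
            f"insufficient samples: minimum day count {min(counts)} < 12 yields a zero budget"
        )
    return SampleBudget(m_min)


@dataclass
class ProtocolResult:
    """Tidy per-cell accuracies of one protocol run plus its provenance."""

    protocol: str
    cells: pd.DataFrame
    seed: int
    repetitions: int
    classifier: ClassifierConfig
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        acc = self.cells["accuracy"]
        if ((acc < 0) | (acc > 1)).any():
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def mean_accuracy(self) -> float:
        return float(self.cells["accuracy"].mean())

    def per_day_accuracy(self) -> pd.Series:
        key = "test_day" if "test_day" in self.cells.columns else "day"
        return self.cells.groupby(key)["accuracy"].mean()


@dataclass
class LndiResult:
    """Learning-N-days accuracies over all day combinations and repetitions."""

    n_days_learned: int
    cells: pd.DataFrame  # columns: repetition, train_days, accuracy
    seed: int
    repetitions: int
    classifier: ClassifierConfig
    budget: SampleBudget

    @property
    def mean_accuracy(self) -> float:
        """Mean over combinations and repetitions (the reported Acc_LNDI)."""
        return float(self.cells["accuracy"].mean())

    def per_repetition_means(self) -> pd.Series:
        return self.cells.groupby("repetition")["accuracy"].mean()


def _rng(*keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(k) & 0xFFFFFFFF for k in keys]))


def stratified_sample(
    table: pd.DataFrame, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw exactly ``n`` rows, split as evenly as possible across classes.

    Per-class counts are ``n // k`` each with the remainder spread over a
    random rotation of the classes.  Raises if any class runs short.
    """
    classes = sorted(table["class"].unique())
    k = len(classes)
    base, rem = divmod(n, k)
    order = list(rng.permutation(k))
    quotas = {classes[i]: base + (1 if order.index(i) < rem else 0) for i in range(k)}
    parts = []
    for cls in classes:
        pool = table.index[table["class"] == cls].to_numpy()
        q = quotas[cls]
        if q > len(pool):
            raise ValueError(
                f"class {cls!r} has {len(pool)} rows, cannot draw {q}"
            )
        parts.append(table.loc[rng.choice(pool, size=q, replace=False)])
    return pd.concat(parts)


def _matched_train_quota(study: SubjectStudy, fraction: float = 0.8) -> dict:
    """Per-class training quota shared by WDC and SCDC.

    The smaller of the per-(day, class) 80 % pools, per class, so both
    protocols train on identical sample counts.
    """
    quota: dict = {}
    for cls in study.classes:
        sizes = [int((t["class"] == cls).sum()) for t in study.tables.values()]
        q = floor(fraction * min(sizes))
        if q < 1:
            raise ValueError(f"class {cls!r} too small for an {fraction:.0%} training split")
        quota[cls] = q
    return quota


def _draw_quota(table: pd.DataFrame, quota: dict, rng: np.random.Generator) -> pd.DataFrame:
    parts = []
    for cls, q in quota.items():
        pool = table.index[table["class"] == cls].to_numpy()
        if q > len(pool):
            raise ValueError(f"class {cls!r}: quota {q} exceeds pool of {len(pool)}")
        parts.append(table.loc[rng.choice(pool, size=q, replace=False)])
    return pd.concat(parts)


def wdc_evaluate(
    study: SubjectStudy,
    cfg: ClassifierConfig | None = None,
    seed: int = 0,
    repetitions: int = 5,
    columns: Sequence[str] | None = None,
) -> ProtocolResult:
    """Within-day classification: stratified 80/20 split per day, repeated.

    Per day and repetition the training set is a class-stratified random
    draw (size matched to SCDC's) from that day; the held-out rows form the
    test set.  Per-day accuracy is the mean over repetitions.
    """
    cfg = cfg or ClassifierConfig()
    quota = _matched_train_quota(study)
    records = []
    for rep in range(repetitions):
        for day, table in study.tables.items():
            rng = _rng(seed, _WDC_TAG, rep, day)
            train = _draw_quota(table, quota, rng)
            test = table.drop(index=train.index)
            if test.empty or test["class"].nunique() < len(study.classes):
                raise ValueError(f"day {day}: too few rows left for a stratified test set")
            _, acc = fit_predict(train, test, cfg, columns=list(columns) if columns else None)
            records.append({"repetition": rep, "day": day, "accuracy": acc})
    return ProtocolResult("WDC", pd.DataFrame(records), seed, repetitions, cfg)


def scdc_evaluate(
    study: SubjectStudy,
    cfg: ClassifierConfig | None = None,
    seed: int = 0,
    repetitions: int = 5,
    columns: Sequence[str] | None = None,
) -> ProtocolResult:
    """Standard cross-day classification: train on one day, test on each other.

    Training draws the same per-class quota as WDC from the training day;
    each of the 4 remaining days is tested in full, giving a 5 x 4 grid per
    repetition.
    """
    cfg = cfg or ClassifierConfig()
    quota = _matched_train_quota(study)
    records = []
    for rep in range(repetitions):
        for train_day, table in study.tables.items():
            rng = _rng(seed, _SCDC_TAG, rep, train_day)
            train = _draw_quota(table, quota, rng)
            for test_day, test_table in study.tables.items():
                if test_day == train_day:
                    continue
                _, acc = fit_predict(
                    train, test_table, cfg, columns=list(columns) if columns else None
                )
                records.append(
                    {
                        "repetition": rep,
                        "train_day": train_day,
                        "test_day": test_day,
                        "accuracy": acc,
                    }
                )
    return ProtocolResult("SCDC", pd.DataFrame(records), seed, repetitions, cfg)


def lndi_evaluate(
    study: SubjectStudy,
    n_days_learned: int,
    cfg: ClassifierConfig | None = None,
    repetitions: int = 10,
    seed: int = 0,
    columns: Sequence[str] | None = None,
    budget: SampleBudget | None = None,
) -> LndiResult:
    """Learning-N-days information over all C(5, N) day combinations.

    Per repetition and combination, ``M_min / N`` rows are drawn (class
    stratified) from each training day and ``M_min / (5 - N)`` rows from
    each held-out day; the final accuracy averages every combination and
    repetition.
    """
    cfg = cfg or ClassifierConfig()
    if not 1 <= n_days_learned <= 4:
        raise ValueError("n_days_learned must be in 1..4")
    if study.n_days != 5:
        raise ValueError(f"LNDI requires a 5-day study, got {study.n_days} days")
    budget = budget or compute_sample_budget(study.day_counts())
    n = n_days_learned
    train_quota = budget.train_quota(n)
    test_quota = budget.test_quota(5 - n)
    days = study.days
    combos = list(itertools.combinations(days, n))
    assert len(combos) == comb(5, n)
    records = []
    for rep in range(repetitions):
        for k, train_days in enumerate(combos):
            rng = _rng(seed, _LNDI_TAG, n, rep, k)
            test_days = [d for d in days if d not in train_days]
            train = pd.concat(
                [stratified_sample(study.tables[d], train_quota, rng) for d in train_days]
            )
            test = pd.concat(
                [stratified_sample(study.tables[d], test_quota, rng) for d in test_days]
            )
            _, acc = fit_predict(train, test, cfg, columns=list(columns) if columns else None)
            records.append(
                {
                    "repetition": rep,
                    "train_days": "+".join(map(str, train_days)),
                    "accuracy": acc,
                }
            )
    return LndiResult(n, pd.DataFrame(records), seed, repetitions, cfg, budget)


#: Window widths in epochs (5-s epochs): 5 s, 1 min, 5 min; "half" is special.
WINDOW_WIDTHS: dict[str, int] = {"5s": 1, "1min": 12, "5min": 60}


def _block_mask(n_rows: int, block: int) -> np.ndarray:
    """Alternating train(True)/test(False) mask over consecutive blocks."""
    idx = np.arange(n_rows) // block
    return idx % 2 == 0


def window_width_evaluate(
    study: SubjectStudy,
    width: str,
    cfg: ClassifierConfig | None = None,
    columns: Sequence[str] | None = None,
) -> ProtocolResult:
    """Alternate consecutive temporal blocks between train and test within days.

    ``width`` is one of ``"5s"``, ``"1min"``, ``"5min"`` (blocks of 1, 12 and
    60 five-second epochs) or ``"half"`` (first half of each day/class trains,
    second half tests).  Rows must be in within-day temporal order.  The
    classifier is fit and scored separately per day.
    """
    cfg = cfg or ClassifierConfig()
    if width not in WINDOW_WIDTHS and width != "half":
        raise ValueError(f"width must be one of {list(WINDOW_WIDTHS) + ['half']}, got {width!r}")
    records = []
    for day, table in study.tables.items():
        train_parts, test_parts = [], []
        for cls, group in table.groupby("class", sort=False):
            n = len(group)
            block = n // 2 if width == "half" else WINDOW_WIDTHS[width]
            # a partial trailing block is fine; only a width that leaves no
            # test rows at all exceeds the session
            if block < 1 or n <= block:
                raise ValueError(
                    f"day {day} class {cls!r}: window of {block} epochs exceeds "
                    f"the session ({n} epochs leave no test block)"
                )
            mask = _block_mask(n, block)
            train_parts.append(group.iloc[mask])
            test_parts.append(group.iloc[~mask])
        train = pd.concat(train_parts)
        test = pd.concat(test_parts)
        _, acc = fit_predict(train, test, cfg, columns=list(columns) if columns else None)
        records.append({"day": day, "accuracy": acc, "width": width})
    return ProtocolResult(
        "window-width", pd.DataFrame(records), seed=0, repetitions=1, classifier=cfg,
        extras={"width": width},
    )


__all__ = [
    "LndiResult",
    "ProtocolResult",
    "SampleBudget",
    "SubjectStudy",
    "WINDOW_WIDTHS",
    "compute_sample_budget",
    "lndi_evaluate",
    "scdc_evaluate",
    "stratified_sample",
    "wdc_evaluate",
    "window_width_evaluate",
]
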