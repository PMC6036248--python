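"""Accuracy-loss recursive feature elimination with cross-fold consensus.

The ranking is a wrapper, not a weight-based RFE: at every round, each
surviving feature is removed in turn, a classifier is refit on the rest and
scored on the held-out day, and the feature whose removal loses the least
accuracy is eliminated.  Running this once per held-out day under the
4-days-train / 1-day-test budget yields five top-M lists; features appearing
in at least three of them form the salient subset.

A 50/50 day-stratified split keeps a validation half that ranking never
touches; :func:`audit_disjoint` proves the two halves share no row ids.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from eegdrift.classify import ClassifierConfig, build_estimator
from eegdrift.features import BandScheme, feature_columns, feature_names
from eegdrift.protocols import (
    LndiResult,
    SampleBudget,
    SubjectStudy,
    compute_sample_budget,
    lndi_evaluate,
    stratified_sample,
)

_SELECT_TAG, _FOLD_TAG = 23, 29


def _ensure_row_ids(study: SubjectStudy) -> SubjectStudy:
    """Attach globally unique row ids (day * 10^6 + row position) if absent."""
    tables = {}
    for day, table in study.tables.items():
        t = table.copy()
        if "row_id" not in t.columns:
            t["row_id"] = day * 1_000_000 + np.arange(len(t))
        tables[day] = t
    return SubjectStudy(tables, subject=study.subject)


def split_selection_validation(
    study: SubjectStudy, fraction: float = 0.5, seed: int = 0
) -> tuple[SubjectStudy, SubjectStudy]:
    """Per-day, class-stratified random split into selection and validation halves.

    The two halves are disjoint and their union is the input; the validation
    half is never touched by ranking.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    study = _ensure_row_ids(study)
    sel_tables, val_tables = {}, {}
    for day, table in study.tables.items():
        rng = np.random.default_rng(np.random.SeedSequence([seed, _SELECT_TAG, day]))
        sel_parts, val_parts = [], []
        for cls, group in table.groupby("class", sort=True):
            n = len(group)
            n_sel = int(np.floor(fraction * n))
            if n_sel < 1 or n - n_sel < 1:
                raise ValueError(
                    f"day {day} class {cls!r}: {n} rows cannot be split {fraction:.0%}"
                )
            perm = rng.permutation(n)
            sel_parts.append(group.iloc[perm[:n_sel]])
            val_parts.append(group.iloc[perm[n_sel:]])
        sel_tables[day] = pd.concat(sel_parts).reset_index(drop=True)
        val_tables[day] = pd.concat(val_parts).reset_index(drop=True)
    return (
        SubjectStudy(sel_tables, subject=study.subject),
        SubjectStudy(val_tables, subject=study.subject),
    )


def audit_disjoint(selection: SubjectStudy, validation: SubjectStudy) -> bool:
    """Prove by row id that the selection and validation halves share no rows."""
    sel_ids = set(selection.to_table()["row_id"])
    val_ids = set(validation.to_table()["row_id"])
    overlap = sel_ids & val_ids
    if overlap:
        raise AssertionError(f"selection/validation leak: {len(overlap)} shared row ids")
    return True


@dataclass
class RfeRanking:
    """One fold's elimination order (position 0 = first eliminated = least useful)."""

    fold: int
    elimination_order: list[str]
    trace: list[float]
    n_fits: int = 0
    row_ids_used: frozenset = frozenset()

    def top(self, m: int) -> list[str]:
        """The last ``m`` features eliminated (or surviving): the top-``m`` list."""
        if m > len(self.elimination_order):
            raise ValueError(f"top-{m} requested but only {len(self.elimination_order)} features")
        return self.elimination_order[-m:]


@dataclass
class SalientSubset:
    """Consensus vote counts over fold top-M lists and the selected features."""

    votes: dict[str, int]
    selected: list[str]
    m: int
    threshold: int = 3

    @property
    def size(self) -> int:
        return len(self.selected)


def rank_features_loo(
    train: pd.DataFrame,
    test: pd.DataFrame,
    cfg: ClassifierConfig | None = None,
    step: int = 1,
    stop_at: int = 1,
) -> RfeRanking:
    """Rank features by recursive leave-one-feature-out accuracy loss.

    At each round, with F surviving features, F classifiers are fit — each
    omitting one feature — and scored on ``test``; the omission with the
    highest remaining accuracy (minimum loss) is eliminated.  Ties break to
    the lowest feature index.  ``step`` eliminates that many features per
    round (tractability mode); ``stop_at`` halts early with that many
    survivors, which are appended to the order in index order.
    """
    cfg = cfg or ClassifierConfig()
    cols = feature_columns(train)
    if len(cols) < 2:
        raise ValueError("ranking needs at least 2 features")
    if step < 1:
        raise ValueError("step must be >= 1")
    x_train = train[cols].to_numpy(dtype=float)
    y_train = train["class"].to_numpy()
    x_test = test[cols].to_numpy(dtype=float)
    y_test = test["class"].to_numpy()
    active = list(range(len(cols)))
    order: list[int] = []
    trace: list[float] = []
    n_fits = 0
    while len(active) > max(stop_at, 1):
        accs = np.empty(len(active))
        for pos in range(len(active)):
            keep = active[:pos] + active[pos + 1 :]
            est = build_estimator(cfg)
            est.fit(x_train[:, keep], y_train)
            accs[pos] = np.mean(est.predict(x_test[:, keep]) == y_test)
            n_fits += 1
        if not np.isfinite(accs).all():
            raise ValueError("non-finite accuracy encountered during ranking")
        n_out = min(step, len(active) - max(stop_at, 1))
        # highest remaining accuracy first; ties to the lowest feature index
        ranked = sorted(range(len(active)), key=lambda p: (-accs[p], active[p]))
        for pos in ranked[:n_out]:
            order.append(active[pos])
        trace.append(float(accs[ranked[0]]))
        for pos in sorted(ranked[:n_out], reverse=True):
            del active[pos]
    order.extend(active)  # survivors, most important last
    fold = test["day"].iloc[0] if "day" in test.columns else -1
    used = frozenset()
    if "row_id" in train.columns and "row_id" in test.columns:
        used = frozenset(train["row_id"]) | frozenset(test["row_id"])
    return RfeRanking(
        fold=int(fold),
        elimination_order=[cols[i] for i in order],
        trace=trace,
        n_fits=n_fits,
        row_ids_used=used,
    )


def consensus_vote(
    top_lists: Sequence[Sequence[str]], threshold: int = 3, m: int | None = None
) -> SalientSubset:
    """Count appearances across fold top-M lists; keep features at/above threshold."""
    votes = Counter()
    for lst in top_lists:
        votes.update(set(lst))
    selected = sorted([f for f, v in votes.items() if v >= threshold])
    m = m if m is not None else max(len(lst) for lst in top_lists)
    return SalientSubset(votes=dict(votes), selected=selected, m=m, threshold=threshold)


def run_l4di_selection(
    selection_study: SubjectStudy,
    cfg: ClassifierConfig | None = None,
    m: int = 100,
    seed: int = 0,
    step: int = 1,
    threshold: int = 3,
) -> tuple[list[RfeRanking], SalientSubset]:
    """Rank features in 5 leave-one-day-out folds and vote a salient subset.

    Each fold trains on budgeted quotas from 4 days and tests on the
    held-out day (the 4-days-learned sample-budget convention); the last
    ``m`` features eliminated per fold form that fold's list, and features
    on at least ``threshold`` of the 5 lists are selected.
    """
    cfg = cfg or ClassifierConfig()
    n_features = len(selection_study.feature_columns)
    if m > n_features:
        raise ValueError(f"top-{m} exceeds the {n_features} available features")
    budget = compute_sample_budget(selection_study.day_counts())
    train_quota = budget.train_quota(4)
    test_quota = budget.test_quota(1)
    rankings = []
    for k, held_out in enumerate(selection_study.days):
        rng = np.random.default_rng(np.random.SeedSequence([seed, _FOLD_TAG, k]))
        train = pd.concat(
            [
                stratified_sample(selection_study.tables[d], train_quota, rng)
                for d in selection_study.days
                if d != held_out
            ]
        )
        test = stratified_sample(selection_study.tables[held_out], test_quota, rng)
        rankings.append(rank_features_loo(train, test, cfg, step=step))
    subset = consensus_vote([r.top(m) for r in rankings], threshold=threshold, m=m)
    return rankings, subset


def validate_subset(
    validation_study: SubjectStudy,
    subset: Sequence[str],
    cfg: ClassifierConfig | None = None,
    conditions: Sequence[int] = (1, 2, 3, 4),
    repetitions: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired all-features vs subset accuracies under each learning-N-days condition.

    The same seed drives both runs of every condition, so the comparison is
    paired repetition by repetition and combination by combination.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("feature subset is empty")
    missing = set(subset) - set(validation_study.feature_columns)
    if missing:
        raise ValueError(f"subset features absent from the study: {sorted(missing)[:5]}")
    records = []
    for n in conditions:
        full = lndi_evaluate(validation_study, n, cfg, repetitions=repetitions, seed=seed)
        restricted = lndi_evaluate(
            validation_study, n, cfg, repetitions=repetitions, seed=seed, columns=subset
        )
        records.append(
            {
                "n_days_learned": n,
                "accuracy_all": full.mean_accuracy,
                "accuracy_subset": restricted.mean_accuracy,
            }
        )
    return pd.DataFrame(records)


def contribution_rates(
    subsets: Iterable[Iterable[str]],
    n_channels: int,
    bands: BandScheme | None = None,
) -> pd.DataFrame:
    """Fraction of subjects whose salient subset contains each (channel, band).

    Returns a ``channels x bands`` table (rows ``CH1..CHn``, columns band
    names) with entries in [0, 1].
    """
    bands = bands or BandScheme()
    valid = set(feature_names(n_channels, bands))
    subsets = [set(s) for s in subsets]
    if not subsets:
        raise ValueError("no subject subsets supplied")
    for s in subsets:
        unknown = s - valid
        if unknown:
            raise ValueError(f"features outside the declared space: {sorted(unknown)[:5]}")
    cr = np.zeros((n_channels, len(bands)))
    for s in subsets:
        for name in s:
            ch_part, band_name = name.split("_", 1)
            cr[int(ch_part[2:]) - 1, bands.names.index(band_name)] += 1
    cr /= len(subsets)
    return pd.DataFrame(
        cr, index=[f"CH{i + 1}" for i in range(n_channels)], columns=list(bands.names)
    )


__all__ = [
    "RfeRanking",
    "SalientSubset",
    "audit_disjoint",
    "consensus_vote",
    "contribution_rates",
    "rank_features_loo",
    "run_l4di_selection",
    "split_selection_validation",
    "validate_subset",
]
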