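"""Stratified cross-validation, AUC aggregation and significance.

The evaluation protocol: label, randomise, stratify.  Characteristics
with 10 or more positive drugs get five cycles of stratified 10-fold
cross-validation; with 2–9 positives the fold count is reduced to the
number of positives so every test fold holds exactly one positive; with
fewer than 2 positives the characteristic is non-evaluable and refused
explicitly.

Rare/common token elimination and ROC token ranking run *inside* each
training split — never on the full data — so no information leaks from
the test fold into feature selection.  Each cycle's pooled test-fold
scores give one ROC AUC; the reported AUC is the arithmetic mean over
cycles.  Its standard error uses the Hanley–McNeil closed form and a
characteristic is flagged significant when the one-sided 95% lower
confidence bound exceeds chance (mean AUC − 1.645·SE > 0.5).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import classify
from .classify import build_feature_table
from .feature_selection import (
    CharacteristicLabels,
    _mann_whitney_auc,
    eliminate_common,
    eliminate_rare,
    rank_tokens,
)
from .frequency import FrequencyMatrix

__all__ = [
    "NonEvaluableError",
    "FoldPlan",
    "CVResult",
    "make_fold_plan",
    "cross_validate",
    "hanley_mcneil_se",
    "summarize",
    "N_CYCLES",
    "MAX_FOLDS",
    "Z_ONE_SIDED_95",
]

logger = logging.getLogger(__name__)

N_CYCLES = 5
MAX_FOLDS = 10
Z_ONE_SIDED_95 = 1.645


class NonEvaluableError(ValueError):
    """Raised for characteristics with fewer than 2 positive examples."""


@dataclass(frozen=True)
class FoldPlan:
    """One cross-validation cycle: a stratified partition of the drugs."""

    cycle: int
    n_folds: int
    assignment: dict[str, int]
    seed: int

    def fold_drugs(self, fold: int) -> list[str]:
        return [d for d, f in self.assignment.items() if f == fold]

    def split(self, fold: int) -> tuple[list[str], list[str]]:
        """(training drugs, test drugs) for one fold."""
        train = [d for d, f in self.assignment.items() if f != fold]
        return train, self.fold_drugs(fold)


def _cycle_seed(seed: int, cycle: int) -> int:
    # documented counter scheme: cycle c shuffles with seed*100 + c
    return (seed * 100 + cycle) % (2**31 - 1)


def make_fold_plan(
    labels: CharacteristicLabels, seed: int = 0
) -> list[FoldPlan]:
    """Stratified fold plans for one characteristic.

    ≥10 positives: 5 independent shuffles, each split into 10 stratified
    folds.  2–9 positives: one cycle of |C| folds, one positive per
    fold.  <2 positives: refused (non-evaluable).
    """
    n_pos = labels.n_pos
    if n_pos < 2:
        raise NonEvaluableError(
            f"characteristic {labels.characteristic_id!r} has {n_pos} "
            "positive example(s); at least 2 are required"
        )
    if labels.n_neg < 1:
        raise NonEvaluableError("characteristic has no negative examples")
    if n_pos >= MAX_FOLDS:
        n_folds, n_cycles = MAX_FOLDS, N_CYCLES
    else:
        n_folds, n_cycles = n_pos, 1

    drugs = np.array(labels.universe)
    y = labels.mask(drugs)
    plans = []
    for cycle in range(n_cycles):
        cs = _cycle_seed(seed, cycle)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=cs)
        assignment: dict[str, int] = {}
        for fold, (_, test_idx) in enumerate(skf.split(drugs.reshape(-1, 1), y)):
            for i in test_idx:
                assignment[str(drugs[i])] = fold
        plans.append(
            FoldPlan(cycle=cycle, n_folds=n_folds, assignment=assignment, seed=cs)
        )
    return plans


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Closed-form standard error of a ROC AUC (Hanley–McNeil).

    Q1 = A/(2−A), Q2 = 2A²/(1+A);
    SE² = [A(1−A) + (n_pos−1)(Q1−A²) + (n_neg−1)(Q2−A²)] / (n_pos·n_neg).
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC out of range: {auc}")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one positive and one negative")
    a = auc
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (
        a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


@dataclass
class CVResult:
    """Cross-validation outcome for one characteristic × algorithm."""

    characteristic_id: str
    algorithm: str
    measure: str
    cycle_aucs: list[float]
    fold_aucs: list[float]
    mean_auc: float
    se: float
    significant: bool
    n_pos: int
    n_neg: int
    category: str = ""
    selected_tokens: list[list[str]] = field(default_factory=list)
    seed: int = 0

    @property
    def ci_lower(self) -> float:
        return self.mean_auc - Z_ONE_SIDED_95 * self.se


def _select_features(
    train_matrix: FrequencyMatrix,
    train_labels: CharacteristicLabels,
    top_n: int,
    min_abstracts: int,
    r2_cutoff: float,
) -> list[str]:
    vocab = eliminate_rare(train_matrix, min_abstracts=min_abstracts)
    reduced = train_matrix.restrict_tokens(vocab)
    vocab = eliminate_common(reduced, r2_cutoff=r2_cutoff)
    ranking = rank_tokens(
        train_matrix, train_labels, top_n=top_n, vocabulary=vocab
    )
    return ranking.tokens


def cross_validate(
    matrix: FrequencyMatrix,
    labels: CharacteristicLabels,
    algorithm: str,
    top_n: int = 20,
    seed: int = 0,
    min_abstracts: int = 2,
    r2_cutoff: float = 0.33,
    leak_features: bool = False,
) -> CVResult:
    """Leakage-free stratified cross-validation of one characteristic.

    Per training split the full feature-selection pipeline is re-run
    (rare filter, common filter, ROC ranking, top-``top_n``); the model
    is trained on the training drugs and scores the test drugs.  Test
    scores are pooled per cycle into one ROC AUC; the mean over cycles
    is reported with its Hanley–McNeil standard error.

    ``leak_features=True`` is a deliberate bug mode — selection on all
    drugs including the test folds — kept for quantifying the benefit
    of the per-fold guard; never use it for real estimates.
    """
    plans = make_fold_plan(labels, seed=seed)
    universe = list(labels.universe)
    leak_tokens: list[str] | None = None
    if leak_features:
        leak_tokens = _select_features(
            matrix.restrict_drugs(universe), labels, top_n,
            min_abstracts, r2_cutoff,
        )

    cycle_aucs: list[float] = []
    fold_aucs: list[float] = []
    selected: list[list[str]] = []
    for plan in plans:
        pooled_scores: list[float] = []
        pooled_truth: list[bool] = []
        for fold in range(plan.n_folds):
            train_drugs, test_drugs = plan.split(fold)
            train_labels = CharacteristicLabels(
                characteristic_id=labels.characteristic_id,
                positives=labels.positives & set(train_drugs),
                universe=tuple(train_drugs),
                category=labels.category,
            )
            assert train_labels.n_pos > 0, "fold plan lost all positives"
            if leak_tokens is not None:
                tokens = leak_tokens
            else:
                tokens = _select_features(
                    matrix.restrict_drugs(train_drugs), train_labels,
                    top_n, min_abstracts, r2_cutoff,
                )
            selected.append(tokens)
            table = build_feature_table(
                matrix, tokens, labels=train_labels, drugs=train_drugs
            )
            model = classify.train(table, algorithm, seed=plan.seed)
            test_table = build_feature_table(
                matrix, tokens, labels=None, drugs=test_drugs
            )
            scores = classify.score(model, test_table)
            truth = [d in labels.positives for d in scores.index]
            pooled_scores.extend(scores.to_numpy())
            pooled_truth.extend(truth)
            if any(truth) and not all(truth):
                fold_aucs.append(
                    _mann_whitney_auc(
                        scores.to_numpy(), np.array(truth)
                    )
                )
        cycle_aucs.append(
            _mann_whitney_auc(
                np.array(pooled_scores), np.array(pooled_truth)
            )
        )

    mean_auc = float(np.mean(cycle_aucs))
    se = hanley_mcneil_se(mean_auc, labels.n_pos, labels.n_neg)
    return CVResult(
        characteristic_id=labels.characteristic_id,
        algorithm=algorithm,
        measure=matrix.measure,
        cycle_aucs=cycle_aucs,
        fold_aucs=fold_aucs,
        mean_auc=mean_auc,
        se=se,
        significant=mean_auc - Z_ONE_SIDED_95 * se > 0.5,
        n_pos=labels.n_pos,
        n_neg=labels.n_neg,
        category=labels.category,
        selected_tokens=selected,
        seed=seed,
    )


def summarize(
    results: Sequence[CVResult],
    thresholds: Sequence[float] = (0.80, 0.90, 0.95),
) -> pd.DataFrame:
    """Count characteristics exceeding each AUC threshold per algorithm.

    Rows: category × threshold (category "all" totals included when
    several are present); columns: one per algorithm plus best-of-all;
    cells hold "count (percent)"-style counts and percentages as a
    multi-column frame.
    """
    if not results:
        raise ValueError("no results to summarize")
    rows = []
    frame = pd.DataFrame(
        {
            "characteristic_id": [r.characteristic_id for r in results],
            "category": [r.category or "all" for r in results],
            "algorithm": [r.algorithm for r in results],
            "mean_auc": [r.mean_auc for r in results],
        }
    )
    algorithms = sorted(frame["algorithm"].unique())
    categories = sorted(frame["category"].unique())
    if len(categories) > 1:
        categories.append("all")

    def _block(sub: pd.DataFrame, category: str) -> None:
        n_char = sub["characteristic_id"].nunique()
        best = sub.groupby("characteristic_id")["mean_auc"].max()
        for thr in thresholds:
            row: dict[str, object] = {
                "category": category,
                "threshold": thr,
                "n_characteristics": n_char,
            }
            for algo in algorithms:
                per = sub[sub["algorithm"] == algo]
                count = int((per["mean_auc"] > thr).sum())
                row[f"count_{algo}"] = count
                row[f"pct_{algo}"] = 100.0 * count / n_char if n_char else 0.0
            count_best = int((best > thr).sum())
            row["count_best"] = count_best
            row["pct_best"] = 100.0 * count_best / n_char if n_char else 0.0
            rows.append(row)

    for category in categories:
        sub = frame if category == "all" else frame[frame["category"] == category]
        _block(sub, category)
    return pd.DataFrame(rows)
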