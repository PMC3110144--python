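"""Token filtering and ROC-based token ranking.

Two unsupervised filters shrink the vocabulary before ranking:

* rare tokens — occurring in fewer than two abstracts summed over all
  drugs — carry no reusable evidence and are dropped;
* common tokens — whose per-drug scores correlate linearly with the
  drug's abstract count N(d) (Pearson r² > 0.33) — track corpus size
  rather than drug identity and are dropped.

Surviving tokens are ranked by the area under the ROC curve obtained by
sweeping a threshold over the per-drug scores, positives being the
drugs carrying the characteristic.  AUC is computed as the normalized
Mann–Whitney statistic with half credit for tied pairs, which is
exactly the trapezoidal area of the threshold sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .frequency import FrequencyMatrix

__all__ = [
    "CharacteristicLabels",
    "TokenRanking",
    "load_labels",
    "eliminate_rare",
    "eliminate_common",
    "token_auc",
    "rank_tokens",
    "index_keyword_percentile",
    "ELIMINATED",
    "ABSENT",
]

logger = logging.getLogger(__name__)

#: sentinels returned by :func:`index_keyword_percentile`
ELIMINATED = "eliminated"
ABSENT = "absent"


@dataclass(frozen=True)
class CharacteristicLabels:
    """A binary drug characteristic defined by its positive examples.

    Every drug in ``universe`` that is not in ``positives`` is a
    negative example by definition.
    """

    characteristic_id: str
    positives: frozenset[str]
    universe: tuple[str, ...]
    category: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "positives", frozenset(d.lower() for d in self.positives)
        )
        object.__setattr__(
            self, "universe", tuple(d.lower() for d in self.universe)
        )
        if not self.positives:
            raise ValueError("characteristic needs at least one positive drug")
        missing = self.positives - set(self.universe)
        if missing:
            raise ValueError(
                f"positives not in drug universe: {sorted(missing)[:5]}"
            )

    @property
    def negatives(self) -> frozenset[str]:
        return frozenset(self.universe) - self.positives

    @property
    def n_pos(self) -> int:
        return len(self.positives)

    @property
    def n_neg(self) -> int:
        return len(self.universe) - len(self.positives)

    def mask(self, drugs: Sequence[str]) -> np.ndarray:
        return np.array([d.lower() in self.positives for d in drugs])


def load_labels(
    path: str | Path, universe: Sequence[str]
) -> list[CharacteristicLabels]:
    """Read a label TSV: characteristic_id, positive_drugs (pipe-separated),
    optional category column."""
    out: list[CharacteristicLabels] = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "characteristic_id":
            raise ValueError(f"{path}: expected 'characteristic_id' column")
        for line in fh:
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            positives = frozenset(
                p for p in cols[1].split("|") if p.strip()
            )
            out.append(
                CharacteristicLabels(
                    characteristic_id=cols[0],
                    positives=positives,
                    universe=tuple(universe),
                    category=cols[2] if len(cols) > 2 else "",
                )
            )
    return out


# ---------------------------------------------------------------------------
# vocabulary filters


def eliminate_rare(
    matrix: FrequencyMatrix, min_abstracts: int = 2
) -> np.ndarray:
    """Drop tokens present in fewer than ``min_abstracts`` abstracts
    summed over every drug's matched set; returns the surviving tokens."""
    total_df = np.asarray(matrix.df.sum(axis=1)).ravel()
    keep = total_df >= min_abstracts
    return matrix.tokens[keep]


def eliminate_common(
    matrix: FrequencyMatrix, r2_cutoff: float = 0.33
) -> np.ndarray:
    """Drop tokens whose scores correlate linearly with N(d).

    Pearson r is computed per token between its score vector across all
    drugs (zeros included for drugs lacking the token) and the abstract
    counts N(d).  Tokens with zero variance in either vector are
    retained (r is undefined; a constant score is no evidence of
    corpus-size dependence).  With fewer than 3 drugs the filter is a
    no-op.
    """
    n = len(matrix.drugs)
    if n < 3:
        logger.warning(
            "common-token filter skipped: only %d drugs (need >= 3)", n
        )
        return matrix.tokens.copy()
    y = matrix.n_abstracts.astype(float)
    var_y = y.var()
    if var_y == 0.0:
        return matrix.tokens.copy()

    scores = matrix.scores
    sum_x = np.asarray(scores.sum(axis=1)).ravel()
    sum_x2 = np.asarray(scores.multiply(scores).sum(axis=1)).ravel()
    sum_xy = np.asarray(scores @ y).ravel()
    mean_x = sum_x / n
    var_x = sum_x2 / n - mean_x**2
    cov = sum_xy / n - mean_x * y.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(var_x > 1e-12, cov**2 / (var_x * var_y), 0.0)
    keep = r2 <= r2_cutoff
    return matrix.tokens[keep]


# ---------------------------------------------------------------------------
# ROC ranking


def _mann_whitney_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """AUC as normalized rank-sum; ties get half credit."""
    n_pos = int(positive.sum())
    n_neg = len(positive) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores)
    rank_sum = ranks[positive].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def token_auc(
    scores: Mapping[str, float], labels: CharacteristicLabels
) -> float:
    """AUC of one token's scores against the characteristic labels.

    Drugs absent from ``scores`` contribute a score of 0.  Equivalent
    to sweeping the decision threshold through every observed score and
    integrating TPR over FPR.
    """
    values = np.array(
        [scores.get(d, 0.0) for d in labels.universe], dtype=float
    )
    return _mann_whitney_auc(values, labels.mask(labels.universe))


def _auc_all_tokens(
    dense_scores: np.ndarray, positive: np.ndarray
) -> np.ndarray:
    """Row-wise AUC of a tokens × drugs score array (vectorized)."""
    n_pos = int(positive.sum())
    n_neg = len(positive) - n_pos
    ranks = rankdata(dense_scores, axis=1)
    rank_sum = ranks[:, positive].sum(axis=1)
    return (rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


@dataclass
class TokenRanking:
    """Tokens ordered by descending AUC, ties broken lexicographically."""

    entries: list[tuple[str, float]] = field(default_factory=list)

    @property
    def tokens(self) -> list[str]:
        return [t for t, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("rank\ttoken\tauc\n")
            for i, (token, auc) in enumerate(self.entries, 1):
                fh.write(f"{i}\t{token}\t{auc!r}\n")


def rank_tokens(
    matrix: FrequencyMatrix,
    labels: CharacteristicLabels,
    top_n: int | None = 20,
    vocabulary: Iterable[str] | None = None,
) -> TokenRanking:
    """Rank tokens by per-token AUC against the characteristic.

    ``vocabulary`` restricts ranking to the given (already filtered)
    tokens; by default the full matrix vocabulary is ranked.  Pass
    ``top_n=None`` for the complete ranking.
    """
    sub = (
        matrix.restrict_tokens(list(vocabulary))
        if vocabulary is not None
        else matrix
    )
    if sub.n_tokens == 0:
        logger.warning("empty vocabulary; empty ranking")
        return TokenRanking([])
    positive = labels.mask(sub.drugs)
    dense = np.asarray(sub.scores.todense())
    aucs = _auc_all_tokens(dense, positive)
    order = np.lexsort((sub.tokens.astype(str), -aucs))
    if top_n is not None:
        if top_n > len(order):
            logger.warning(
                "requested top %d of only %d tokens", top_n, len(order)
            )
        order = order[:top_n]
    return TokenRanking(
        [(str(sub.tokens[i]), float(aucs[i])) for i in order]
    )


def index_keyword_percentile(
    ranking: TokenRanking,
    keyword: str,
    eliminated: Iterable[str] = (),
    seen_vocabulary: Iterable[str] | None = None,
) -> float | str:
    """Position of a characteristic's index keyword in the full ranking.

    Returns the keyword's rank as a percentile of the post-elimination
    ranking (1.0 = top 1%), the sentinel ``ELIMINATED`` when the keyword
    was removed by the rare/common filters, or ``ABSENT`` when it never
    occurred in the corpus.
    """
    keyword = keyword.lower()
    positions = {token: i for i, (token, _) in enumerate(ranking.entries)}
    if keyword in positions:
        return 100.0 * (positions[keyword] + 1) / len(ranking)
    if keyword in set(eliminated):
        return ELIMINATED
    if seen_vocabulary is not None and keyword in set(seen_vocabulary):
        return ELIMINATED
    return ABSENT
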