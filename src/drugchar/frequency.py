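"""Per-drug token frequency measures: cdf, ctf and ctf-icdf.

For a drug d with N(d) matched abstracts, token w:

* ``cdf``      — conditional document frequency: the fraction of d's
  abstracts containing w, df(w,d) / N(d); bounded in [0, 1].
* ``ctf``      — conditional term frequency: occurrences of w counted
  with multiplicity across d's abstracts, normalized by T(d), the total
  token count of those abstracts, so drugs with different corpus sizes
  stay comparable.
* ``ctf_icdf`` — ctf weighted by ln(N(d) / df(w,d)), the inverse
  document frequency computed within the drug's own abstract
  sub-corpus (a per-drug tf-idf analogue).  A token present in every
  abstract scores 0.

Scores are sparse: tokens absent from all of a drug's abstracts are
simply absent from the map (implicitly 0).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .corpus import DrugAbstractIndex

__all__ = [
    "MEASURES",
    "FrequencyMatrix",
    "compute_cdf",
    "compute_ctf",
    "compute_ctf_icdf",
    "build_matrix",
]

logger = logging.getLogger(__name__)

MEASURES = ("cdf", "ctf", "ctf_icdf")


def _doc_and_term_counts(index: DrugAbstractIndex, drug: str):
    """(df map, term-count map, N_d, T_d) for one drug."""
    drug = drug.lower()
    ids = index.matches[drug]
    df: dict[str, int] = {}
    tf: dict[str, int] = {}
    total = 0
    for aid in ids:
        bag = index.token_bags[aid]
        for token, n in bag.items():
            df[token] = df.get(token, 0) + 1
            tf[token] = tf.get(token, 0) + n
            total += n
    return df, tf, len(ids), total


def _require_abstracts(index: DrugAbstractIndex, drug: str) -> bool:
    if not index.matches[drug.lower()]:
        logger.info("drug %r has no matched abstracts; empty score map", drug)
        return False
    return True


def compute_cdf(index: DrugAbstractIndex, drug: str) -> dict[str, float]:
    """cdf(w,d) = df(w,d) / N(d) for every token in the drug's abstracts."""
    if not _require_abstracts(index, drug):
        return {}
    df, _, n_d, _ = _doc_and_term_counts(index, drug)
    return {w: c / n_d for w, c in df.items()}


def compute_ctf(index: DrugAbstractIndex, drug: str) -> dict[str, float]:
    """ctf(w,d) = Σ_i n_i(w) / T(d), occurrences with multiplicity."""
    if not _require_abstracts(index, drug):
        return {}
    _, tf, _, total = _doc_and_term_counts(index, drug)
    return {w: c / total for w, c in tf.items()}


def compute_ctf_icdf(index: DrugAbstractIndex, drug: str) -> dict[str, float]:
    """ctf(w,d) × ln(N(d) / df(w,d)); 0 for saturated tokens."""
    if not _require_abstracts(index, drug):
        return {}
    df, tf, n_d, total = _doc_and_term_counts(index, drug)
    return {
        w: (tf[w] / total) * math.log(n_d / df[w]) for w in df
    }


_MEASURE_FN = {
    "cdf": compute_cdf,
    "ctf": compute_ctf,
    "ctf_icdf": compute_ctf_icdf,
}


@dataclass
class FrequencyMatrix:
    """Sparse token × drug score matrix plus the counts behind it.

    ``scores`` holds the chosen measure; ``df`` the per-(token, drug)
    abstract counts needed by the rare/common token filters regardless
    of measure.  Token order is lexicographic and deterministic.
    """

    measure: str
    tokens: np.ndarray            # (n_tokens,) unicode, sorted
    drugs: list[str]              # column order
    scores: sp.csr_matrix         # tokens × drugs
    df: sp.csr_matrix             # tokens × drugs, integer counts
    n_abstracts: np.ndarray       # N_d per drug
    total_tokens: np.ndarray      # T_d per drug

    def __post_init__(self) -> None:
        self._token_pos = {t: i for i, t in enumerate(self.tokens)}
        self._drug_pos = {d: j for j, d in enumerate(self.drugs)}

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)

    def column(self, drug: str) -> dict[str, float]:
        """Sparse score map for one drug (absent tokens omitted)."""
        j = self._drug_pos[drug.lower()]
        col = self.scores.getcol(j).tocoo()
        return {self.tokens[i]: v for i, v in zip(col.row, col.data)}

    def row(self, token: str) -> np.ndarray:
        """Dense score vector of one token across all drugs."""
        i = self._token_pos[token]
        return np.asarray(self.scores[i].todense()).ravel()

    def restrict_tokens(self, keep: "list[str] | np.ndarray") -> "FrequencyMatrix":
        idx = np.array(sorted(self._token_pos[t] for t in keep), dtype=int)
        return FrequencyMatrix(
            measure=self.measure,
            tokens=self.tokens[idx],
            drugs=list(self.drugs),
            scores=self.scores[idx],
            df=self.df[idx],
            n_abstracts=self.n_abstracts,
            total_tokens=self.total_tokens,
        )

    def restrict_drugs(self, keep: list[str]) -> "FrequencyMatrix":
        """Column subset in the given drug order (e.g. a training fold)."""
        idx = np.array([self._drug_pos[d.lower()] for d in keep], dtype=int)
        return FrequencyMatrix(
            measure=self.measure,
            tokens=self.tokens,
            drugs=[self.drugs[j] for j in idx],
            scores=self.scores[:, idx].tocsr(),
            df=self.df[:, idx].tocsr(),
            n_abstracts=self.n_abstracts[idx],
            total_tokens=self.total_tokens[idx],
        )

    # -- persistence: triplet TSV + JSON sidecar -------------------------

    def vocabulary_hash(self) -> str:
        h = hashlib.sha256("\n".join(self.tokens).encode()).hexdigest()
        return h[:16]

    def to_tsv(self, path: str | Path) -> None:
        """Loss-free triplet export (token, drug, score, df) + sidecar."""
        path = Path(path)
        coo = self.scores.tocoo()
        df_lookup = self.df.todok()
        order = np.lexsort((coo.col, coo.row))
        with path.open("w") as fh:
            fh.write("token\tdrug\tscore\tdf\n")
            for k in order:
                i, j = int(coo.row[k]), int(coo.col[k])
                fh.write(
                    f"{self.tokens[i]}\t{self.drugs[j]}\t"
                    f"{float(coo.data[k])!r}\t{int(df_lookup[i, j])}\n"
                )
        meta = {
            "measure": self.measure,
            "drugs": self.drugs,
            "n_abstracts": [int(n) for n in self.n_abstracts],
            "total_tokens": [int(n) for n in self.total_tokens],
            "tokens": list(map(str, self.tokens)),
            "vocabulary_hash": self.vocabulary_hash(),
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, sort_keys=True, indent=0) + "\n"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencyMatrix":
        path = Path(path)
        meta = json.loads(
            path.with_suffix(path.suffix + ".meta.json").read_text()
        )
        tokens = np.array(meta["tokens"], dtype=object)
        token_pos = {t: i for i, t in enumerate(tokens)}
        drug_pos = {d: j for j, d in enumerate(meta["drugs"])}
        rows, cols, vals, dfs = [], [], [], []
        with path.open() as fh:
            fh.readline()
            for line in fh:
                token, drug, score, df = line.rstrip("\n").split("\t")
                rows.append(token_pos[token])
                cols.append(drug_pos[drug])
                vals.append(float(score))
                dfs.append(int(df))
        shape = (len(tokens), len(meta["drugs"]))
        matrix = cls(
            measure=meta["measure"],
            tokens=tokens,
            drugs=list(meta["drugs"]),
            scores=sp.csr_matrix((vals, (rows, cols)), shape=shape),
            df=sp.csr_matrix((dfs, (rows, cols)), shape=shape),
            n_abstracts=np.array(meta["n_abstracts"]),
            total_tokens=np.array(meta["total_tokens"]),
        )
        if matrix.vocabulary_hash() != meta["vocabulary_hash"]:
            raise ValueError(f"{path}: vocabulary hash mismatch")
        return matrix


def build_matrix(
    index: DrugAbstractIndex,
    drug_list: list[str],
    measure: str = "cdf",
) -> FrequencyMatrix:
    """Assemble the sparse token × drug matrix for one measure.

    The vocabulary is the union over all listed drugs, ordered
    lexicographically; construction is deterministic.
    """
    if measure not in _MEASURE_FN:
        raise ValueError(
            f"unknown measure {measure!r}; expected one of {MEASURES}"
        )
    drug_list = [d.lower() for d in drug_list]
    for drug in drug_list:
        if drug not in index.matches:
            raise KeyError(f"drug {drug!r} not in index")

    score_fn = _MEASURE_FN[measure]
    columns: list[dict[str, float]] = []
    df_columns: list[dict[str, int]] = []
    n_abstracts = np.zeros(len(drug_list), dtype=int)
    total_tokens = np.zeros(len(drug_list), dtype=int)
    vocab: set[str] = set()
    for j, drug in enumerate(drug_list):
        df, _, n_d, t_d = _doc_and_term_counts(index, drug)
        n_abstracts[j] = n_d
        total_tokens[j] = t_d
        columns.append(score_fn(index, drug))
        df_columns.append(df)
        vocab.update(df)

    tokens = np.array(sorted(vocab), dtype=object)
    token_pos = {t: i for i, t in enumerate(tokens)}
    rows, cols, vals, dfs = [], [], [], []
    for j, (scores, dfc) in enumerate(zip(columns, df_columns)):
        for token, value in scores.items():
            rows.append(token_pos[token])
            cols.append(j)
            vals.append(value)
            dfs.append(dfc[token])
    shape = (len(tokens), len(drug_list))
    return FrequencyMatrix(
        measure=measure,
        tokens=tokens,
        drugs=drug_list,
        scores=sp.csr_matrix((vals, (rows, cols)), shape=shape),
        df=sp.csr_matrix((dfs, (rows, cols)), shape=shape),
        n_abstracts=n_abstracts,
        total_tokens=total_tokens,
    )
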