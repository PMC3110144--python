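"""Hand-constructed toy corpora and matrices for unit tests."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from drugchar import (
    AbstractRecord,
    DrugLexicon,
    FrequencyMatrix,
    build_drug_index,
)


def make_corpus(drug_docs: dict[str, list[str]]):
    """One record per doc, body = '<drug> <doc text>'; returns (records, lexicon)."""
    records = []
    for drug, docs in drug_docs.items():
        for i, doc in enumerate(docs):
            records.append(
                AbstractRecord(
                    abstract_id=f"{drug}-{i}",
                    title=f"{drug} study",
                    body=doc,
                )
            )
    lexicon = DrugLexicon.from_pairs([(d, []) for d in drug_docs])
    return records, lexicon


def make_index(drug_docs: dict[str, list[str]], **kwargs):
    records, lexicon = make_corpus(drug_docs)
    return build_drug_index(records, lexicon, **kwargs)


def make_matrix(
    columns: dict[str, dict[str, float]],
    n_abstracts: dict[str, int],
    df: dict[str, dict[str, int]] | None = None,
    measure: str = "cdf",
) -> FrequencyMatrix:
    """Build a FrequencyMatrix directly from per-drug score maps.

    ``df`` defaults to round(score * N_d) per entry, which is exact for
    cdf-valued toys.
    """
    drugs = list(columns)
    vocab = sorted({t for col in columns.values() for t in col})
    token_pos = {t: i for i, t in enumerate(vocab)}
    rows, cols, vals, dfs = [], [], [], []
    for j, drug in enumerate(drugs):
        for token, value in columns[drug].items():
            rows.append(token_pos[token])
            cols.append(j)
            vals.append(value)
            if df is not None:
                dfs.append(df[drug].get(token, 0))
            else:
                dfs.append(int(round(value * n_abstracts[drug])))
    shape = (len(vocab), len(drugs))
    return FrequencyMatrix(
        measure=measure,
        tokens=np.array(vocab, dtype=object),
        drugs=drugs,
        scores=sp.csr_matrix((vals, (rows, cols)), shape=shape),
        df=sp.csr_matrix((dfs, (rows, cols)), shape=shape),
        n_abstracts=np.array([n_abstracts[d] for d in drugs]),
        total_tokens=np.array(
            [100 for _ in drugs]
        ),
    )


def brute_force_auc(pos_scores, neg_scores) -> float:
    """Pairwise Mann-Whitney count: 1 per win, 0.5 per tie."""
    total = 0.0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos_scores) * len(neg_scores))
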