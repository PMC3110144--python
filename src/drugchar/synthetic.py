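"""Synthetic corpora with planted statistical structure.

The generator emulates the statistical shape of a drug-centred
abstract corpus without any linguistic realism: each drug owns a
log-normally sized set of abstracts; each abstract is a bag of tokens
sampled from a Zipf-weighted background vocabulary with the drug's own
name inserted (guaranteeing the index match).  Three token families are
planted on top, each recorded in a truth manifest:

* rare tokens    — exactly one global occurrence, so the rare filter
  must remove them;
* common tokens  — per-abstract occurrence probability increasing
  linearly with the drug's abstract count N(d), so their cdf correlates
  with N(d) and the common filter must remove them;
* signal tokens  — per-abstract occurrence probability p_pos in the
  abstracts of a characteristic's positive drugs versus p_neg in
  negatives', so ROC ranking must surface them.

Everything is deterministic given the master seed; written files are
byte-identical across runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .corpus import AbstractRecord, DrugLexicon
from .feature_selection import CharacteristicLabels

__all__ = [
    "GeneratorConfig",
    "TruthManifest",
    "SyntheticDataset",
    "generate",
    "null_characteristic",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Defaults give 200 drugs, a median of ~30 abstracts per drug
    (log-normal, enough to exercise every code path at test speed),
    Poisson abstract lengths around 80 tokens over a Zipf-weighted
    background vocabulary, and one characteristic with 20 positive
    drugs whose 20 signal tokens occur with probability 0.6 per
    positive-drug abstract versus 0.05 per negative-drug abstract.
    """

    n_drugs: int = 200
    n_characteristics: int = 1
    n_pos: int = 20
    p_pos: float = 0.6
    p_neg: float = 0.05
    n_signal_tokens: int = 20
    n_rare_tokens: int = 20
    n_common_tokens: int = 20
    vocab_size: int = 1500
    zipf_exponent: float = 1.1
    mean_abstract_len: int = 80
    abstracts_median: float = 30.0
    abstracts_sigma: float = 0.6
    min_abstracts: int = 5
    common_base: float = 0.15
    common_slope: float = 0.7
    rare_occurrences: int = 1
    synonym_extra_frac: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "p_pos": self.p_pos,
            "p_neg": self.p_neg,
            "common_base": self.common_base,
            "common_base+slope": self.common_base + self.common_slope,
            "synonym_extra_frac": self.synonym_extra_frac,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {p}")
        if self.p_pos <= self.p_neg:
            raise ValueError(
                f"planted signal needs p_pos > p_neg "
                f"(got {self.p_pos} <= {self.p_neg})"
            )
        if self.rare_occurrences >= 2:
            raise ValueError(
                "rare tokens must occur in fewer than 2 abstracts; "
                f"rare_occurrences={self.rare_occurrences} would survive "
                "the rare filter"
            )
        if self.n_pos >= self.n_drugs:
            raise ValueError("n_pos must leave at least one negative drug")
        if self.n_pos < 2:
            raise ValueError("n_pos < 2 is non-evaluable")


@dataclass
class TruthManifest:
    """Ground truth of one generated corpus."""

    rare_tokens: list[str]
    common_tokens: list[str]
    signal_tokens: dict[str, list[str]]     # characteristic id → tokens
    positives: dict[str, list[str]]         # characteristic id → drugs
    config: dict
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), sort_keys=True, indent=1) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SyntheticDataset:
    records: list[AbstractRecord]
    lexicon: DrugLexicon
    labels: list[CharacteristicLabels]
    manifest: TruthManifest

    @property
    def drugs(self) -> list[str]:
        return self.lexicon.drugs

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write corpus JSONL, lexicon TSV, label TSV and manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "corpus": out / "corpus.jsonl",
            "lexicon": out / "lexicon.tsv",
            "labels": out / "labels.tsv",
            "manifest": out / "manifest.json",
        }
        with paths["corpus"].open("w") as fh:
            for rec in self.records:
                fh.write(
                    json.dumps(
                        {
                            "abstract_id": rec.abstract_id,
                            "title": rec.title,
                            "abstract": rec.body,
                        },
                        sort_keys=True,
                    )
                    + "\n"
                )
        with paths["lexicon"].open("w") as fh:
            fh.write("drug_name\tsynonyms\n")
            for drug, synonyms in self.lexicon.entries.items():
                fh.write(f"{drug}\t{'|'.join(synonyms)}\n")
        with paths["labels"].open("w") as fh:
            fh.write("characteristic_id\tpositive_drugs\tcategory\n")
            for lab in self.labels:
                fh.write(
                    f"{lab.characteristic_id}\t"
                    f"{'|'.join(sorted(lab.positives))}\t{lab.category}\n"
                )
        self.manifest.to_json(paths["manifest"])
        return paths


def _zipf_weights(size: int, exponent: float) -> np.ndarray:
    weights = 1.0 / np.arange(1, size + 1) ** exponent
    return weights / weights.sum()


def generate(config: GeneratorConfig = GeneratorConfig()) -> SyntheticDataset:
    """Generate a corpus + lexicon + labels + truth manifest."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    drugs = [f"drug{i:03d}" for i in range(config.n_drugs)]
    synonyms = {d: (f"syn{i:03d}",) for i, d in enumerate(drugs)}
    background = [f"w{i:04d}" for i in range(config.vocab_size)]
    weights = _zipf_weights(config.vocab_size, config.zipf_exponent)
    rare_tokens = [f"rareword{i:02d}" for i in range(config.n_rare_tokens)]
    common_tokens = [
        f"commonword{i:02d}" for i in range(config.n_common_tokens)
    ]

    # abstracts per drug: log-normal around the configured median
    mu = math.log(config.abstracts_median)
    n_abs = np.maximum(
        config.min_abstracts,
        np.round(
            rng.lognormal(mean=mu, sigma=config.abstracts_sigma,
                          size=config.n_drugs)
        ).astype(int),
    )
    # common-token probability: linear in N(d)
    lo, hi = n_abs.min(), n_abs.max()
    span = max(hi - lo, 1)
    p_common = config.common_base + config.common_slope * (n_abs - lo) / span

    # characteristics: positive drugs and signal tokens
    characteristics: list[CharacteristicLabels] = []
    signal_tokens: dict[str, list[str]] = {}
    positives_map: dict[str, list[str]] = {}
    signal_of_drug: dict[str, list[tuple[str, float]]] = {d: [] for d in drugs}
    for c in range(config.n_characteristics):
        cid = f"char{c:02d}"
        pos = sorted(
            rng.choice(drugs, size=config.n_pos, replace=False).tolist()
        )
        tokens = [
            f"sigword{c:02d}x{i:02d}" for i in range(config.n_signal_tokens)
        ]
        signal_tokens[cid] = tokens
        positives_map[cid] = pos
        pos_set = set(pos)
        for d in drugs:
            p = config.p_pos if d in pos_set else config.p_neg
            signal_of_drug[d].extend((t, p) for t in tokens)
        characteristics.append(
            CharacteristicLabels(
                characteristic_id=cid,
                positives=frozenset(pos),
                universe=tuple(drugs),
                category="synthetic",
            )
        )

    records: list[AbstractRecord] = []
    generic_idx: list[int] = []  # rare tokens go into name-matched abstracts
    aid = 0
    for j, drug in enumerate(drugs):
        n_extra = int(round(config.synonym_extra_frac * n_abs[j]))
        for i in range(n_abs[j] + n_extra):
            name = drug if i < n_abs[j] else synonyms[drug][0]
            if i < n_abs[j]:
                generic_idx.append(aid)
            length = max(1, rng.poisson(config.mean_abstract_len))
            body_tokens = list(
                np.array(background, dtype=object)[
                    rng.choice(config.vocab_size, size=length, p=weights)
                ]
            )
            for token, p in signal_of_drug[drug]:
                if rng.random() < p:
                    body_tokens.append(token)
            for token in common_tokens:
                if rng.random() < p_common[j]:
                    body_tokens.append(token)
            records.append(
                AbstractRecord(
                    abstract_id=f"abs{aid:06d}",
                    title=f"{name} study",
                    body=" ".join(body_tokens),
                )
            )
            aid += 1

    # rare tokens: appended to exactly `rare_occurrences` abstracts
    for token in rare_tokens:
        for k in rng.choice(generic_idx, size=config.rare_occurrences,
                            replace=False):
            rec = records[k]
            records[k] = AbstractRecord(
                abstract_id=rec.abstract_id,
                title=rec.title,
                body=f"{rec.body} {token}",
            )

    lexicon = DrugLexicon.from_pairs(
        [(d, list(synonyms[d])) for d in drugs]
    )
    manifest = TruthManifest(
        rare_tokens=rare_tokens,
        common_tokens=common_tokens,
        signal_tokens=signal_tokens,
        positives=positives_map,
        config=asdict(config),
        seed=config.seed,
    )
    return SyntheticDataset(
        records=records,
        lexicon=lexicon,
        labels=characteristics,
        manifest=manifest,
    )


def null_characteristic(
    config: GeneratorConfig, n_pos: int, seed: int,
    characteristic_id: str | None = None,
) -> CharacteristicLabels:
    """Labels with no relation to any token distribution (the null)."""
    if n_pos >= config.n_drugs:
        raise ValueError("null characteristic needs at least one negative")
    if n_pos < 2:
        raise ValueError("n_pos < 2 is non-evaluable")
    rng = np.random.default_rng(seed)
    drugs = [f"drug{i:03d}" for i in range(config.n_drugs)]
    pos = sorted(rng.choice(drugs, size=n_pos, replace=False).tolist())
    return CharacteristicLabels(
        characteristic_id=characteristic_id or f"null_seed{seed}",
        positives=frozenset(pos),
        universe=tuple(drugs),
        category="null",
    )
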