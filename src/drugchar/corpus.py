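"""Corpus reading, tokenization and the drug→abstract index.

An abstract (title + body) is turned into a bag of tokens: maximal runs
between whitespace/comma/semicolon delimiters, lower-cased, with
sentence punctuation stripped from the ends but internal hyphens and
digits preserved ("st-segment", "5-ht3", "pge2" survive intact).  A drug
matches an abstract when its name — or, optionally, a normalized trade
name — occurs as a contiguous token sequence in the abstract's token
stream before stop-word removal; this is the offline analogue of a
keyword query against a literature database.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from lxml import etree

from ._porter import porter_stem

__all__ = [
    "AbstractRecord",
    "TokenBag",
    "DrugLexicon",
    "DrugAbstractIndex",
    "load_corpus",
    "load_term_list",
    "default_stopwords",
    "default_formulation_suffixes",
    "tokenize",
    "token_counts",
    "raw_token_stream",
    "porter_stem",
    "normalize_trade_name",
    "build_drug_index",
]

logger = logging.getLogger(__name__)

_DELIMITERS = re.compile(r"[\s,;]+")
_EDGE_PUNCT = ".()[]{}:\"'?!"
# strength tokens on trade names: "100", "12.5", "100mg", "5ml", "40%"
_STRENGTH = re.compile(r"^\d+(\.\d+)?(mg|mcg|g|ml|l|iu|u|%)?$")


@dataclass(frozen=True)
class AbstractRecord:
    """One citation: opaque identifier, title and abstract body."""

    abstract_id: str
    title: str = ""
    body: str = ""

    @property
    def text(self) -> str:
        """Title and body concatenated — the tokenization unit."""
        return f"{self.title} {self.body}".strip()


@dataclass(frozen=True)
class TokenBag:
    abstract_id: str
    tokens: frozenset[str]


def _packaged_terms(name: str) -> frozenset[str]:
    text = resources.files("drugchar.data").joinpath(name).read_text()
    return frozenset(_parse_term_list(text.splitlines()))


def _parse_term_list(lines: Iterable[str]) -> set[str]:
    terms: set[str] = set()
    for line in lines:
        term = line.split("#", 1)[0].strip().lower()
        if term:
            terms.add(term)
    return terms


def load_term_list(path: str | Path) -> frozenset[str]:
    """Load a one-term-per-line list ('#' starts a comment)."""
    return frozenset(_parse_term_list(Path(path).read_text().splitlines()))


def default_stopwords() -> frozenset[str]:
    """The packaged English stop-word list."""
    return _packaged_terms("stopwords.txt")


def default_formulation_suffixes() -> frozenset[str]:
    """The packaged trade-name formulation-suffix vocabulary."""
    return _packaged_terms("formulation_suffixes.txt")


def raw_token_stream(text: str) -> list[str]:
    """Ordered lower-cased tokens before stop-word removal.

    Used for drug-name matching, where stop words inside multi-word
    names must not break the contiguous sequence.
    """
    stream = []
    for piece in _DELIMITERS.split(text):
        token = piece.strip(_EDGE_PUNCT).lower()
        if token:
            stream.append(token)
    return stream


def tokenize(
    text: str,
    stopwords: Iterable[str] | None = None,
    stemming: bool = False,
) -> frozenset[str]:
    """Bag-of-tokens of ``text``: unordered, deduplicated, stop-word free."""
    return frozenset(token_counts(text, stopwords=stopwords, stemming=stemming))


def token_counts(
    text: str,
    stopwords: Iterable[str] | None = None,
    stemming: bool = False,
) -> Counter[str]:
    """Token multiplicities of ``text`` after stop-word removal.

    The multiset view backs conditional term frequencies; its key set is
    exactly ``tokenize(text, ...)``.
    """
    if stopwords is None:
        stopwords = default_stopwords()
    stop = stopwords if isinstance(stopwords, (set, frozenset)) else set(stopwords)
    counts: Counter[str] = Counter()
    for token in raw_token_stream(text):
        if token in stop:
            continue
        if stemming:
            token = porter_stem(token)
        counts[token] += 1
    return counts


def normalize_trade_name(
    raw: str, suffixes: Iterable[str] | None = None
) -> str:
    """Strip trailing strength and formulation tokens from a trade name.

    "Zydol SR 100" and "Zydol SR 200" both reduce to "zydol";
    "Zofran syrup" reduces to "zofran".  If stripping would consume the
    whole name, the original (lower-cased) name is kept and a warning
    logged.
    """
    if suffixes is None:
        suffixes = default_formulation_suffixes()
    suffix_set = {s.lower() for s in suffixes}
    tokens = raw.lower().split()
    kept = list(tokens)
    while kept and (_STRENGTH.match(kept[-1]) or kept[-1] in suffix_set):
        kept.pop()
    if not kept:
        logger.warning(
            "trade name %r empty after suffix stripping; keeping as-is", raw
        )
        return " ".join(tokens)
    return " ".join(kept)


# ---------------------------------------------------------------------------
# corpus readers


def load_corpus(
    path: str | Path, format: str = "jsonl"
) -> list[AbstractRecord]:
    """Read a corpus of abstract records.

    ``jsonl``: one JSON object per line with keys ``abstract_id``,
    ``title``, ``abstract``.  ``medline_xml``: a PubmedArticleSet
    citation XML (PMID / ArticleTitle / AbstractText).  Malformed
    records are skipped with a logged warning; records with a missing
    abstract are retained title-only.
    """
    path = Path(path)
    if format == "jsonl":
        return _load_jsonl(path)
    if format == "medline_xml":
        return _load_medline_xml(path)
    raise ValueError(f"unknown corpus format: {format!r}")


def _load_jsonl(path: Path) -> list[AbstractRecord]:
    records: list[AbstractRecord] = []
    skipped = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                abstract_id = str(obj["abstract_id"])
            except (json.JSONDecodeError, KeyError, TypeError):
                skipped += 1
                logger.warning("%s:%d: malformed record skipped", path, lineno)
                continue
            records.append(
                AbstractRecord(
                    abstract_id=abstract_id,
                    title=str(obj.get("title", "") or ""),
                    body=str(obj.get("abstract", "") or ""),
                )
            )
    if skipped:
        logger.warning("%s: %d malformed records skipped", path, skipped)
    return records


def _load_medline_xml(path: Path) -> list[AbstractRecord]:
    tree = etree.parse(str(path))
    records: list[AbstractRecord] = []
    skipped = 0
    for article in tree.iter("PubmedArticle"):
        pmid = article.findtext(".//PMID")
        if not pmid:
            skipped += 1
            continue
        title = article.findtext(".//ArticleTitle") or ""
        sections = [
            "".join(node.itertext())
            for node in article.iter("AbstractText")
        ]
        records.append(
            AbstractRecord(
                abstract_id=pmid.strip(),
                title=title,
                body=" ".join(s for s in sections if s),
            )
        )
    if skipped:
        logger.warning("%s: %d citations without PMID skipped", path, skipped)
    return records


# ---------------------------------------------------------------------------
# drug lexicon and index


@dataclass
class DrugLexicon:
    """Generic drug names with optional normalized trade-name synonyms."""

    entries: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, Sequence[str]]],
        suffixes: Iterable[str] | None = None,
    ) -> "DrugLexicon":
        entries: dict[str, tuple[str, ...]] = {}
        for name, synonyms in pairs:
            key = name.strip().lower()
            if key in entries:
                raise ValueError(f"duplicate drug name: {key!r}")
            entries[key] = tuple(
                normalize_trade_name(s, suffixes) for s in synonyms if s.strip()
            )
        return cls(entries)

    @property
    def drugs(self) -> list[str]:
        return list(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, drug: str) -> bool:
        return drug.lower() in self.entries


def load_lexicon(
    path: str | Path, suffixes: Iterable[str] | None = None
) -> DrugLexicon:
    """Read a lexicon TSV: columns drug_name, synonyms (pipe-separated)."""
    pairs: list[tuple[str, list[str]]] = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:1] != ["drug_name"]:
            raise ValueError(f"{path}: expected a 'drug_name' column first")
        for line in fh:
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            name = cols[0]
            synonyms = cols[1].split("|") if len(cols) > 1 and cols[1] else []
            pairs.append((name, synonyms))
    return DrugLexicon.from_pairs(pairs, suffixes)


@dataclass
class DrugAbstractIndex:
    """Per-drug matched abstracts plus per-abstract token multisets."""

    matches: dict[str, frozenset[str]]
    token_bags: dict[str, Counter[str]]
    stemming: bool = False
    use_synonyms: bool = False

    @property
    def drugs(self) -> list[str]:
        return list(self.matches)

    def n_abstracts(self, drug: str) -> int:
        """N(d): number of abstracts matched by the drug's name(s)."""
        return len(self.matches[drug.lower()])

    def bag(self, abstract_id: str) -> frozenset[str]:
        return frozenset(self.token_bags[abstract_id])


def _match_sequence(stream: Sequence[str], query: Sequence[str]) -> bool:
    if len(query) == 1:
        return query[0] in stream
    n = len(query)
    for i in range(len(stream) - n + 1):
        if stream[i : i + n] == list(query):
            return True
    return False


def build_drug_index(
    records: Iterable[AbstractRecord],
    lexicon: DrugLexicon,
    use_synonyms: bool = False,
    stemming: bool = False,
    stopwords: Iterable[str] | None = None,
) -> DrugAbstractIndex:
    """Match every lexicon drug against every abstract and tokenize.

    Matching runs on the pre-stop-word token stream so multi-word names
    survive; the stored token bags are post-stop-word (and post-stem,
    when enabled).  Drugs matching nothing are retained with an empty
    set so the drug universe stays fixed.
    """
    if not len(lexicon):
        raise ValueError("empty lexicon")
    if stopwords is None:
        stopwords = default_stopwords()

    queries: dict[str, list[tuple[str, ...]]] = {}
    for drug, synonyms in lexicon.entries.items():
        names = [drug] + (list(synonyms) if use_synonyms else [])
        queries[drug] = [tuple(raw_token_stream(n)) for n in names if n]

    matches: dict[str, set[str]] = {d: set() for d in lexicon.entries}
    token_bags: dict[str, Counter[str]] = {}
    single = {
        drug: {q[0] for q in qs if len(q) == 1} for drug, qs in queries.items()
    }
    multi = {
        drug: [q for q in qs if len(q) > 1] for drug, qs in queries.items()
    }

    for record in records:
        stream = raw_token_stream(record.text)
        stream_set = set(stream)
        counts: Counter[str] = Counter()
        for token in stream:
            if token in stopwords:
                continue
            counts[porter_stem(token) if stemming else token] += 1
        token_bags[record.abstract_id] = counts
        for drug in lexicon.entries:
            if single[drug] & stream_set or any(
                _match_sequence(stream, q) for q in multi[drug]
            ):
                matches[drug].add(record.abstract_id)

    for drug, ids in matches.items():
        if not ids:
            logger.info("drug %r matched no abstracts (N=0)", drug)
    return DrugAbstractIndex(
        matches={d: frozenset(ids) for d, ids in matches.items()},
        token_bags=token_bags,
        stemming=stemming,
        use_synonyms=use_synonyms,
    )
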