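"""Corpus loading, tokenization, stemming, trade names, drug indexing."""

import json

import pytest

from drugchar import (
    DrugLexicon,
    build_drug_index,
    load_corpus,
    normalize_trade_name,
    porter_stem,
    tokenize,
)
from drugchar.corpus import (
    load_lexicon,
    load_term_list,
    raw_token_stream,
    token_counts,
)

from util import make_index


# ---------------------------------------------------------------------------
# corpus readers


def test_jsonl_round_trip_counts(tmp_path):
    path = tmp_path / "corpus.jsonl"
    rows = [
        {"abstract_id": "a1", "title": "t1", "abstract": "body one"},
        {"abstract_id": "a2", "title": "t2", "abstract": "body two"},
        {"abstract_id": "a3", "title": "t3", "abstract": "body three"},
    ]
    path.write_text("\n".join(json.dumps(r) for r in rows) + "\n")
    records = load_corpus(path, format="jsonl")
    assert [r.abstract_id for r in records] == ["a1", "a2", "a3"]
    assert records[1].body == "body two"


def test_jsonl_missing_abstract_is_title_only(tmp_path, caplog):
    path = tmp_path / "corpus.jsonl"
    path.write_text(json.dumps({"abstract_id": "a1", "title": "only"}) + "\n")
    records = load_corpus(path)
    assert len(records) == 1
    assert records[0].body == ""
    assert records[0].text == "only"


def test_jsonl_malformed_record_skipped_with_warning(tmp_path, caplog):
    path = tmp_path / "corpus.jsonl"
    path.write_text('{"title": "no id"}\n{"abstract_id": "ok"}\nnot json\n')
    with caplog.at_level("WARNING"):
        records = load_corpus(path)
    assert [r.abstract_id for r in records] == ["ok"]
    assert sum("malformed" in m for m in caplog.messages) >= 2


def test_empty_corpus_file_is_empty_collection(tmp_path):
    path = tmp_path / "corpus.jsonl"
    path.write_text("")
    assert load_corpus(path) == []


def test_medline_xml_reader(tmp_path):
    xml = """<?xml version="1.0"?>
    <PubmedArticleSet>
      <PubmedArticle><MedlineCitation>
        <PMID>123</PMID>
        <Article>
          <ArticleTitle>Warfarin and bleeding</ArticleTitle>
          <Abstract>
            <AbstractText Label="BACKGROUND">Part one.</AbstractText>
            <AbstractText Label="RESULTS">Part two.</AbstractText>
          </Abstract>
        </Article>
      </MedlineCitation></PubmedArticle>
    </PubmedArticleSet>"""
    path = tmp_path / "cites.xml"
    path.write_text(xml)
    records = load_corpus(path, format="medline_xml")
    assert len(records) == 1
    assert records[0].abstract_id == "123"
    assert records[0].title == "Warfarin and bleeding"
    assert "Part one." in records[0].body and "Part two." in records[0].body


def test_unknown_format_raises(tmp_path):
    with pytest.raises(ValueError, match="format"):
        load_corpus(tmp_path / "x", format="csv")


# ---------------------------------------------------------------------------
# tokenization


@pytest.mark.parametrize(
    "text, stopwords, expected",
    [
        (
            "The ST-segment and PGE2 levels",
            {"the", "and"},
            {"st-segment", "pge2", "levels"},
        ),
        ("", {"the"}, set()),
        ("warfarin, warfarin; WARFARIN", set(), {"warfarin"}),
        ("(aspirin). [5-ht3]: 'quote'!", set(), {"aspirin", "5-ht3", "quote"}),
        ("dose of 20 mg/day", {"of"}, {"dose", "20", "mg/day"}),
    ],
)
def test_tokenize_examples(text, stopwords, expected):
    assert tokenize(text, stopwords=stopwords) == expected


def test_tokenize_is_idempotent_on_tokenized_output():
    text = "The ST-segment, and; PGE2 (levels)."
    first = tokenize(text, stopwords={"the", "and"})
    again = tokenize(" ".join(sorted(first)), stopwords={"the", "and"})
    assert first == again


def test_token_counts_multiplicity_matches_bag():
    counts = token_counts("alpha beta alpha; beta, alpha", stopwords=set())
    assert counts == {"alpha": 3, "beta": 2}
    assert set(counts) == tokenize("alpha beta alpha; beta, alpha", set())


def test_default_stopwords_removed():
    assert tokenize("it is the drug and an option") == {"drug", "option"}


# ---------------------------------------------------------------------------
# Porter stemming


@pytest.mark.parametrize(
    "word, stem",
    [
        # plurals and -ed/-ing
        ("caresses", "caress"), ("ponies", "poni"), ("ties", "ti"),
        ("caress", "caress"), ("cats", "cat"),
        ("feed", "feed"), ("agreed", "agre"), ("plastered", "plaster"),
        ("bled", "bled"), ("motoring", "motor"), ("sing", "sing"),
        ("hopping", "hop"), ("tanned", "tan"), ("falling", "fall"),
        ("hissing", "hiss"), ("failing", "fail"), ("filing", "file"),
        ("happy", "happi"), ("sky", "sky"),
        # derivational suffixes (traced through the full pipeline)
        ("relational", "relat"), ("conditional", "condit"),
        ("rational", "ration"), ("valenci", "valenc"),
        ("digitizer", "digit"), ("operator", "oper"),
        ("feudalism", "feudal"), ("electriciti", "electr"),
        ("hopeful", "hope"), ("goodness", "good"),
        ("revival", "reviv"), ("allowance", "allow"),
        ("inference", "infer"), ("adjustable", "adjust"),
        ("replacement", "replac"), ("adoption", "adopt"),
        ("communism", "commun"), ("activate", "activ"),
        ("effective", "effect"),
        ("probate", "probat"), ("rate", "rate"), ("cease", "ceas"),
        ("controlling", "control"),
        # canonical full-pipeline examples
        ("generalizations", "gener"), ("oscillators", "oscil"),
        # tokens with digits: no suffix rule fires
        ("pge2", "pge2"), ("5-ht3", "5-ht3"),
    ],
)
def test_porter_stem_reference_pairs(word, stem):
    assert porter_stem(word) == stem


def test_stemming_never_enlarges_vocabulary(dataset):
    texts = [r.text for r in dataset.records[:200]]
    raw = set()
    stemmed = set()
    for text in texts:
        raw_bag = tokenize(text)
        stem_bag = tokenize(text, stemming=True)
        assert len(stem_bag) <= len(raw_bag)
        raw |= raw_bag
        stemmed |= stem_bag
    assert len(stemmed) <= len(raw)


# ---------------------------------------------------------------------------
# trade names and lexicon


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("Zydol SR 100", "zydol"),
        ("Zydol SR 200", "zydol"),
        ("Zofran syrup", "zofran"),
        ("Zofran", "zofran"),
        ("Augmentin Duo Forte", "augmentin"),
        ("Panadol 500mg", "panadol"),
    ],
)
def test_normalize_trade_name(raw, expected):
    assert normalize_trade_name(raw) == expected


def test_normalize_trade_name_empty_result_keeps_original(caplog):
    with caplog.at_level("WARNING"):
        assert normalize_trade_name("SR 100") == "sr 100"
    assert any("suffix" in m for m in caplog.messages)


def test_lexicon_tsv_round_trip(tmp_path):
    path = tmp_path / "lexicon.tsv"
    path.write_text(
        "drug_name\tsynonyms\n"
        "Tramadol\tZydol SR 100|Zydol SR 200\n"
        "ondansetron\tZofran syrup\n"
        "warfarin\t\n"
    )
    lexicon = load_lexicon(path)
    assert lexicon.entries["tramadol"] == ("zydol", "zydol")
    assert lexicon.entries["ondansetron"] == ("zofran",)
    assert lexicon.entries["warfarin"] == ()


def test_term_list_loader_ignores_comments(tmp_path):
    path = tmp_path / "stop.txt"
    path.write_text("# comment\nThe\nand  # inline\n\nIT\n")
    assert load_term_list(path) == {"the", "and", "it"}


# ---------------------------------------------------------------------------
# drug indexing


def test_index_counts_matching_abstracts():
    docs = {"warfarin": ["bleeding risk"] * 5}
    docs["aspirin"] = ["platelet effect"] * 3
    index = make_index(docs)
    assert index.n_abstracts("warfarin") == 5
    assert index.n_abstracts("aspirin") == 3


def test_absent_drug_retained_with_zero_count():
    records_docs = {"warfarin": ["text"]}
    from util import make_corpus

    records, _ = make_corpus(records_docs)
    lexicon = DrugLexicon.from_pairs([("warfarin", []), ("ghostdrug", [])])
    index = build_drug_index(records, lexicon)
    assert index.n_abstracts("ghostdrug") == 0
    assert "ghostdrug" in index.matches


def test_multiword_name_requires_contiguous_sequence():
    from drugchar import AbstractRecord

    records = [
        AbstractRecord("a1", "", "valproic acid levels measured"),
        AbstractRecord("a2", "", "acid reflux and valproic compounds"),
    ]
    lexicon = DrugLexicon.from_pairs([("valproic acid", [])])
    index = build_drug_index(records, lexicon)
    assert index.matches["valproic acid"] == {"a1"}


def test_matching_survives_stopword_removal_and_punctuation():
    from drugchar import AbstractRecord

    records = [AbstractRecord("a1", "A study of (Warfarin).", "")]
    lexicon = DrugLexicon.from_pairs([("warfarin", [])])
    index = build_drug_index(records, lexicon)
    assert index.n_abstracts("warfarin") == 1


def test_synonyms_match_is_superset(dataset):
    plain = build_drug_index(dataset.records, dataset.lexicon,
                             use_synonyms=False)
    with_syn = build_drug_index(dataset.records, dataset.lexicon,
                                use_synonyms=True)
    strictly_larger = 0
    for drug in dataset.drugs:
        assert plain.matches[drug] <= with_syn.matches[drug]
        if len(with_syn.matches[drug]) > len(plain.matches[drug]):
            strictly_larger += 1
    assert strictly_larger > 0


def test_synonym_matches_add_counts():
    from drugchar import AbstractRecord

    records = [
        AbstractRecord("a1", "", "tramadol relieves pain"),
        AbstractRecord("a2", "", "zydol relieves pain"),
        AbstractRecord("a3", "", "zydol dosing"),
    ]
    lexicon = DrugLexicon.from_pairs([("tramadol", ["Zydol SR 100"])])
    plain = build_drug_index(records, lexicon, use_synonyms=False)
    with_syn = build_drug_index(records, lexicon, use_synonyms=True)
    assert plain.n_abstracts("tramadol") == 1
    assert with_syn.n_abstracts("tramadol") == 3


def test_empty_lexicon_raises():
    with pytest.raises(ValueError, match="lexicon"):
        build_drug_index([], DrugLexicon())


def test_raw_stream_keeps_order_and_case_folds():
    assert raw_token_stream("The (ST-segment), PGE2; Levels.") == [
        "the", "st-segment", "pge2", "levels",
    ]
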