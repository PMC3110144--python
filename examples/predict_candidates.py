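"""Train on known positives and rank every drug as a candidate.

After cross-validation has identified the best classifier, a model is
trained on all labeled drugs and every lexicon drug is ranked by its
continuous score — the screening mode: top-ranked unlabeled drugs are
the candidates to review for the characteristic.
"""

from drugchar import (
    GeneratorConfig,
    build_drug_index,
    build_feature_table,
    build_matrix,
    generate,
    rank_tokens,
    score,
    train,
)

config = GeneratorConfig(n_drugs=80, n_pos=12, vocab_size=600, seed=7)
dataset = generate(config)
index = build_drug_index(dataset.records, dataset.lexicon)
matrix = build_matrix(index, dataset.drugs, measure="cdf")
labels = dataset.labels[0]

tokens = rank_tokens(matrix, labels, top_n=20).tokens
table = build_feature_table(matrix, tokens, labels=labels)
model = train(table, "ibk", seed=7)
ranked = score(model, table).sort_values(ascending=False)

print("rank  drug       score  known-positive")
for i, (drug, value) in enumerate(ranked.head(15).items(), 1):
    mark = "yes" if drug in labels.positives else ""
    print(f"{i:4d}  {drug:<9s} {value:6.3f}  {mark}")
print(f"\n{len(set(ranked.head(12).index) & labels.positives)} of the "
      f"{labels.n_pos} known positives sit in the top 12; unlabeled"
      "\ndrugs ranked above known positives would be screening leads.")
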