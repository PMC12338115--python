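"""Train skip-gram embeddings on a planted corpus and rank compounds by
cosine similarity to the toxicity token.

Compounds that co-mention the endpoint share sentence vocabulary with it,
so their vectors drift toward the toxicity vector during training.
"""

from scipy.stats import spearmanr

from toxlitscore import (
    GeneratorConfig,
    TrainingConfig,
    cosine_similarity,
    generate_corpus,
    generate_sentences,
    train_embeddings,
)

config = GeneratorConfig(n_compounds=15, n_documents=2000, seed=1)
corpus, truth = generate_corpus(config)
sentences = list(generate_sentences(corpus, config))
print(f"training on {len(sentences)} sentences")

space = train_embeddings(
    sentences, TrainingConfig(dimension=32, epochs=5, window=3), seed=1
)

scores = {
    cid: cosine_similarity(space, cid, config.tox_concept_id)
    for cid in truth.compounds()
    if cid in space
}
print("\ncompound   level  cosine(compound, toxicity)")
for cid, s in sorted(scores.items(), key=lambda kv: -kv[1])[:5]:
    print(f"{cid}   {truth.levels[cid]}      {s:+.3f}")

rho = spearmanr(
    [scores[c] for c in scores], [truth.levels[c] for c in scores]
).statistic
print(f"\nSpearman(cosine, planted level) = {rho:.2f}")
print("a positive rank correlation means the embedding geometry recovered")
print("the planted co-mention gradient without any labels.")
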