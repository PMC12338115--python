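"""Two-stage retrieval of prompt context for one compound.

Stage 1 ranks the compound+endpoint documents by cumulative cosine
relevance to three templated questions (top 20); stage 2 reranks with a
pair scorer against a specialized symptom query (top 5, 100-word cap).
"""

from toxlitscore import GeneratorConfig, build_context, generate_corpus

config = GeneratorConfig(n_compounds=8, n_documents=1500, seed=3)
corpus, truth = generate_corpus(config)
tox_docs = corpus.index[config.tox_concept_id]

cid = max(truth.compounds(), key=lambda c: truth.pub_counts[c])
name = truth.compound_names[cid]
ctx = build_context(corpus, cid, name, tox_docs)

print(f"compound {name}: {len(ctx.candidates)} first-stage candidates, "
      f"{len(ctx.reranked)} reranked")
print("\nfinal context documents (doc_id, rerank score):")
for (doc_id, score), text in zip(ctx.reranked, ctx.texts):
    print(f"  {doc_id}  {score:5.1f}  '{text[:60]}...'")
print("\nthese truncated abstracts form the context block of the scoring")
print("prompt; an empty pool would produce the no-context ablation prompt.")
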