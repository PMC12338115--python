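"""Confidence and hepatotoxicity scoring through the logprob provider.

Uses the deterministic mock provider: its knowledge table is derived from
a planted truth, so scores are exactly interpretable.  The same calls
work against any real backend implementing the provider contract.
"""

from toxlitscore import (
    ChoiceDistribution,
    GeneratorConfig,
    MockProvider,
    build_prompt,
    confidence_score,
    expected_toxicity_score,
    extract_choice_distribution,
    generate_corpus,
    generate_mock_knowledge,
)

# the published cysteine example: P(class 1) = 0.74, P(class 2) = 0.26
dist = ChoiceDistribution((0.0, 0.74, 0.26, 0.0, 0.0))
print(f"expected-value score for the example distribution: "
      f"{expected_toxicity_score(dist):.3f}")

config = GeneratorConfig(n_compounds=10, n_documents=600, seed=2)
_, truth = generate_corpus(config)
provider = MockProvider(generate_mock_knowledge(truth, seed=2, dispersion=0.4))

print("\ncompound        level  confidence  LLM score")
for cid in truth.compounds()[:6]:
    name = truth.compound_names[cid]
    conf = confidence_score(provider, name)
    prompt = build_prompt(name, ["synthetic abstract text about liver injury"])
    score = expected_toxicity_score(extract_choice_distribution(provider, prompt))
    print(f"{name:<15} {truth.levels[cid]}      {conf:.2f}        {score:.2f}")

print("\nconfidence tracks how much literature exists for the compound;")
print("the LLM score is the probability-weighted mean of risk classes 0-4")
print("rescaled to [0, 1].")
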