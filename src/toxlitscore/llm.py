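"""Prompt construction and logprob-based scoring with a language model.

Two scores are derived from single-token generation probabilities:

* a *confidence score* — the probability of the model answering "A"
  ("yes, I know this compound") to a knowledge question, used to flag
  compounds the model cannot reliably assess;
* a *hepatotoxicity score* — the expected value of a 0-4 severity class
  under the model's choice distribution, linearly rescaled to [0, 1] with
  class weight ``f(k) = 0.25 k``.

Any backend satisfying :class:`LogprobProvider` can drive the scores; the
repository ships :class:`MockProvider`, a deterministic table-backed
provider for testing and synthetic studies.  Adapters for hosted models
are external plugins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Protocol, Sequence

logger = logging.getLogger(__name__)

#: Single-token answer labels for the five risk classes.
CLASS_LABELS: tuple[str, ...] = ("0", "1", "2", "3", "4")
#: Class weight step: class k contributes weight 0.25*k.
CLASS_WEIGHT_STEP = 0.25
#: Affirmative answer token for the confidence prompt.
CONFIDENCE_TOKEN = "A"
#: Default cut for "high confidence" filtering.
CONFIDENCE_THRESHOLD = 0.9
#: A score exactly at the scale midpoint is read as the model declining to
#: commit either way.
INDECISIVE_SCORE = 0.5


def _template(name: str) -> str:
    return (
        resources.files("toxlitscore").joinpath("templates", name).read_text("utf-8")
    )


class ScoringError(RuntimeError):
    """Raised when a provider response cannot be turned into a score."""


@dataclass(frozen=True)
class ChoiceDistribution:
    """Probabilities over risk classes 0-4 from generation logprobs.

    ``probs`` may sum to less than one before renormalization (mass can
    leak to tokens outside the label set); ``raw_mass`` preserves that
    pre-normalization total as a diagnostic.
    """

    probs: tuple[float, float, float, float, float]
    raw_mass: float | None = None

    def __post_init__(self) -> None:
        if len(self.probs) != 5:
            raise ValueError("need exactly 5 class probabilities")
        if any(p < 0 for p in self.probs):
            raise ValueError("probabilities must be non-negative")
        if sum(self.probs) <= 0:
            raise ValueError("all-zero choice distribution")
        if sum(self.probs) > 1 + 1e-9:
            raise ValueError("probabilities must sum to at most 1")

    @classmethod
    def from_mapping(
        cls, probs: Mapping[int, float], raw_mass: float | None = None
    ) -> "ChoiceDistribution":
        return cls(tuple(float(probs.get(k, 0.0)) for k in range(5)), raw_mass)

    def renormalized(self) -> "ChoiceDistribution":
        total = sum(self.probs)
        return ChoiceDistribution(
            tuple(p / total for p in self.probs),
            raw_mass=total if self.raw_mass is None else self.raw_mass,
        )

    @property
    def mode(self) -> int:
        return max(range(5), key=lambda k: self.probs[k])


def expected_toxicity_score(dist: ChoiceDistribution) -> float:
    """Expected value of the linear class weighting, ``sum 0.25 k P(X=k)``.

    The distribution is renormalized first, making the score a proper
    expectation in [0, 1].
    """
    d = dist.renormalized()
    return sum(CLASS_WEIGHT_STEP * k * p for k, p in enumerate(d.probs))


def is_indecisive(score: float, tol: float = 1e-9) -> bool:
    """A score at exactly the midpoint carries no directional judgment."""
    return abs(score - INDECISIVE_SCORE) <= tol


@dataclass(frozen=True)
class PromptBundle:
    """A fully instantiated chat prompt for one compound.

    The user message carries the multiple-choice task, the (possibly
    empty) retrieved-context block and the compound name; the assistant
    prefix nudges single-token generation.  Construction is deterministic:
    identical inputs yield byte-identical bundles.
    """

    system: str
    user: str
    assistant_prefix: str
    compound_name: str
    n_context: int = 0

    @property
    def messages(self) -> list[dict[str, str]]:
        msgs = [
            {"role": "system", "content": self.system},
            {"role": "user", "content": self.user},
        ]
        if self.assistant_prefix:
            msgs.append({"role": "assistant", "content": self.assistant_prefix})
        return msgs


class LogprobProvider(Protocol):
    """Backend contract: log-probabilities of candidate next tokens.

    Implementations return, for each candidate single token, the log of
    its generation probability as the next token after ``prompt``.  All
    returned values must be <= 0.  The mock provider is stateless and
    deterministic; real model adapters should declare their own
    determinism properties.
    """

    def logprobs(
        self, prompt: PromptBundle, candidates: Sequence[str]
    ) -> dict[str, float]: ...


def build_confidence_prompt(compound_name: str) -> PromptBundle:
    return PromptBundle(
        system=_template("confidence_system.txt"),
        user=_template("confidence_user.txt").format(compound=compound_name),
        assistant_prefix="",
        compound_name=compound_name,
    )


def build_prompt(
    compound_name: str, context_texts: Sequence[str] | None = None
) -> PromptBundle:
    """Instantiate the risk-scoring prompt, with or without retrieved context.

    ``context_texts`` are the (already truncated) abstracts from the
    retrieval stage; with none supplied the context block explicitly states
    that no context is available (the ablation mode used to probe how much
    the retrieved literature contributes).
    """
    if context_texts:
        block = "\n".join(
            f"[{i}] {text}" for i, text in enumerate(context_texts, start=1)
        )
    else:
        block = "No additional context is available for this compound."
    return PromptBundle(
        system=_template("scoring_system.txt"),
        user=_template("scoring_user.txt").format(
            compound=compound_name, context=block
        ),
        assistant_prefix="",
        compound_name=compound_name,
        n_context=len(context_texts) if context_texts else 0,
    )


def confidence_score(provider: LogprobProvider, compound_name: str) -> float:
    """Generation probability of the affirmative token, unnormalized.

    Deliberately *not* renormalized over the other choice tokens: the raw
    probability of committing to "A" is the knowledge signal.
    """
    prompt = build_confidence_prompt(compound_name)
    lp = provider.logprobs(prompt, (CONFIDENCE_TOKEN,))
    if CONFIDENCE_TOKEN not in lp:
        raise ScoringError(
            f"provider returned no logprob for token {CONFIDENCE_TOKEN!r}"
        )
    return math.exp(lp[CONFIDENCE_TOKEN])


def extract_choice_distribution(
    provider: LogprobProvider, prompt: PromptBundle
) -> ChoiceDistribution:
    """Query the five class labels and renormalize into a distribution.

    The pre-normalization probability mass on the labels is preserved in
    ``raw_mass``; a label missing from the provider response is a scoring
    error naming that label.
    """
    lp = provider.logprobs(prompt, CLASS_LABELS)
    missing = [lab for lab in CLASS_LABELS if lab not in lp]
    if missing:
        raise ScoringError(f"provider returned no logprob for label(s) {missing}")
    raw = [math.exp(lp[lab]) for lab in CLASS_LABELS]
    mass = sum(raw)
    if mass <= 0:
        raise ScoringError("provider assigned zero mass to every class label")
    return ChoiceDistribution(
        tuple(p / mass for p in raw), raw_mass=mass
    )


def hepatotoxicity_score(
    provider: LogprobProvider,
    compound_name: str,
    context_texts: Sequence[str] | None = None,
) -> float:
    """End-to-end: prompt, choice distribution, expected-value score."""
    prompt = build_prompt(compound_name, context_texts)
    return expected_toxicity_score(extract_choice_distribution(provider, prompt))


# ---------------------------------------------------------------------------
# Mock provider


@dataclass
class MockProvider:
    """Deterministic table-backed provider for tests and synthetic studies.

    ``knowledge`` maps a compound name (or ID) to its confidence value and
    choice distribution.  The prompt type is recognized from the candidate
    tokens: a request containing the confidence token is answered from the
    confidence column, a request for the class labels from the
    distribution.  Unknown compounds fall back to a minimal-knowledge
    answer: low confidence, near-uniform choice distribution.
    """

    knowledge: dict[str, tuple[float, ChoiceDistribution]]
    unknown_confidence: float = 0.05
    context_required: bool = False

    _uniform: ChoiceDistribution = field(
        default=ChoiceDistribution((0.2, 0.2, 0.2, 0.2, 0.2)), repr=False
    )

    def logprobs(
        self, prompt: PromptBundle, candidates: Sequence[str]
    ) -> dict[str, float]:
        entry = self.knowledge.get(prompt.compound_name)
        if CONFIDENCE_TOKEN in candidates:
            conf = entry[0] if entry is not None else self.unknown_confidence
            conf = min(max(conf, 1e-12), 1.0)
            return {CONFIDENCE_TOKEN: math.log(conf)}
        if entry is None or (self.context_required and prompt.n_context == 0):
            dist = self._uniform
        else:
            dist = entry[1]
        out: dict[str, float] = {}
        for lab in candidates:
            if lab in CLASS_LABELS:
                p = dist.probs[int(lab)]
                out[lab] = math.log(p) if p > 0 else -float("inf")
        return out


def write_mock_knowledge(
    knowledge: Mapping[str, tuple[float, ChoiceDistribution]], path: str | Path
) -> None:
    """Persist a mock-knowledge table as TSV (name, confidence, p0..p4)."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("compound\tconfidence\tp0\tp1\tp2\tp3\tp4\n")
        for name in sorted(knowledge):
            conf, dist = knowledge[name]
            probs = "\t".join(f"{p:.10g}" for p in dist.probs)
            fh.write(f"{name}\t{conf:.10g}\t{probs}\n")


def read_mock_knowledge(
    path: str | Path,
) -> dict[str, tuple[float, ChoiceDistribution]]:
    table: dict[str, tuple[float, ChoiceDistribution]] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            name, conf, *probs = line.split("\t")
            table[name] = (
                float(conf),
                ChoiceDistribution(tuple(float(p) for p in probs)),
            )
    return table
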