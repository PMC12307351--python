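"""Deterministic rule-based paraphrase bank for prompt augmentation.

Template sentences are expanded into lexically diverse but semantically
consistent variants by substituting synonymous words and phrases.  The bank is
a fixed table of phrase → alternatives rules; a variant corresponds to one
choice per rule that applies to the sentence, so the number of available
paraphrases is the product of the option counts minus the identity choice.
Severity labels (capitalised words like "Moderate") never appear in any rule,
so they survive every substitution verbatim — the round-trip guarantee the
prompt generator relies on.

Sampling is without replacement from the enumerated combination space with a
seeded generator, so the output is a pure function of (sentence, n, seed).

External paraphrasers (e.g. an LLM-backed service) can be plugged in through
the :class:`Augmenter` protocol.
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np

from .exceptions import CapacityError

__all__ = ["Augmenter", "RuleBasedParaphraser", "augment_sentence"]


# phrase -> synonymous alternatives (identity is always option 0)
_RULES: list[tuple[str, list[str]]] = [
    ("The subject", ["The patient", "This subject", "This individual", "The participant"]),
    ("showed", ["exhibited", "demonstrated", "presented with"]),
    ("reported", ["described", "indicated", "communicated"]),
    ("noted", ["reported", "described", "mentioned"]),
    ("displayed", ["showed signs of", "exhibited", "demonstrated"]),
    ("motor impairment", ["impairment of motor function", "motor dysfunction"]),
    ("on examination", ["during the examination", "upon clinical assessment"]),
    ("anxiety levels", ["levels of anxiety", "anxiety symptoms"]),
    ("drowsiness", ["sleepiness", "somnolence"]),
    ("during the day", ["in the daytime", "throughout the day", "over the course of the day"]),
    ("impairment in the clock drawing task",
     ["difficulty with the clock drawing task", "deficits on the clock drawing test"]),
]


@runtime_checkable
class Augmenter(Protocol):
    """Anything that can paraphrase a sentence ``k`` ways, deterministically."""

    def paraphrases(self, sentence: str, k: int, seed: int) -> list[str]:
        """Return ``k`` distinct paraphrases of ``sentence`` (none equal to it)."""
        ...


class RuleBasedParaphraser:
    """The built-in substitution-bank augmenter."""

    def __init__(self, rules: list[tuple[str, list[str]]] | None = None):
        self.rules = list(rules) if rules is not None else list(_RULES)

    def _applicable(self, sentence: str) -> list[tuple[int, str, list[str]]]:
        """Rules whose phrase occurs in the sentence, ordered by position.

        Overlapping matches are resolved greedily left-to-right by longest
        phrase, so at most one rule fires per span of text.
        """
        hits = []
        for phrase, alts in self.rules:
            pos = sentence.find(phrase)
            if pos >= 0:
                hits.append((pos, phrase, alts))
        hits.sort(key=lambda h: (h[0], -len(h[1])))
        chosen: list[tuple[int, str, list[str]]] = []
        end = -1
        for pos, phrase, alts in hits:
            if pos >= end:
                chosen.append((pos, phrase, alts))
                end = pos + len(phrase)
        return chosen

    def capacity(self, sentence: str) -> int:
        """Number of distinct paraphrases available (identity excluded)."""
        total = 1
        for _, _, alts in self._applicable(sentence):
            total *= 1 + len(alts)
        return total - 1

    def _render(self, sentence: str, hits, choices) -> str:
        out = []
        cursor = 0
        for (pos, phrase, alts), c in zip(hits, choices):
            out.append(sentence[cursor:pos])
            out.append(phrase if c == 0 else alts[c - 1])
            cursor = pos + len(phrase)
        out.append(sentence[cursor:])
        return "".join(out)

    def paraphrases(self, sentence: str, k: int, seed: int) -> list[str]:
        hits = self._applicable(sentence)
        radices = [1 + len(alts) for _, _, alts in hits]
        total = 1
        for r in radices:
            total *= r
        if k > total - 1:
            raise CapacityError(
                f"paraphrase bank holds {total - 1} variants for this sentence "
                f"but {k} were requested; reduce n or supply a plugin augmenter"
            )
        rng = np.random.default_rng(seed)
        # combination index 0 is the identity; sample from 1..total-1
        picks = rng.choice(total - 1, size=k, replace=False) + 1
        out = []
        for combo in picks:
            choices = []
            for r in radices:
                choices.append(int(combo % r))
                combo //= r
            out.append(self._render(sentence, hits, choices))
        return out


def augment_sentence(
    sentence: str,
    n: int,
    augmenter: Augmenter | None = None,
    seed: int = 0,
) -> list[str]:
    """Expand ``sentence`` into ``n`` variants; element 0 is the original.

    Variants 1..n-1 are distinct paraphrases from ``augmenter`` (the built-in
    rule bank by default).  Deterministic given (sentence, n, seed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return [sentence]
    aug = augmenter if augmenter is not None else RuleBasedParaphraser()
    variants = aug.paraphrases(sentence, n - 1, seed)
    if len(set(variants)) != n - 1 or sentence in variants:
        raise CapacityError("augmenter returned duplicate or identity variants")
    return [sentence] + list(variants)
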