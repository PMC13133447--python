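"""Backoff n-gram language modelling and word surprisal.

Word surprisal quantifies how unexpected a word is given its local lexical
context: ``S(w_k) = -log2 p(w_k | w_{k-n+1} .. w_{k-1})``.  A 5-gram model
(four words of context) is the conventional choice for continuous-speech
neural-tracking work, where surprisal serves as a linguistic regressor
alongside acoustic features.

The module provides

* :func:`train_ngram` -- count-based n-gram model with interpolated add-k
  smoothing (default), interpolated Kneser-Ney, or raw maximum likelihood;
* :func:`surprisal_of` / :func:`annotate_tokens` -- per-word surprisal in bits;
* :class:`SubstitutionPlan` / :func:`validate_plan` -- checking of
  high-surprisal word-substitution designs (the "incongruent word every 45 s"
  manipulation) against spacing, surprisal-floor, part-of-speech and
  clause-position criteria.

Unknown words map onto a single ``UNK`` symbol that receives smoothed
probability mass, so surprisal is finite for any replacement word.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "UNK",
    "BOUNDARY",
    "Token",
    "NGramModel",
    "SubstitutionPlan",
    "PlanReport",
    "tokenize",
    "train_ngram",
    "surprisal_of",
    "annotate_tokens",
    "validate_plan",
    "validate_tokens",
]

#: Symbol standing in for out-of-vocabulary words.
UNK = "<unk>"
#: Clause/sentence boundary marker produced by :func:`tokenize`.
BOUNDARY = "</s>"

_TOKEN_RE = re.compile(r"[a-z0-9']+|[.!?;:,]")
_BOUNDARY_CHARS = set(".!?;:,")


@dataclass(frozen=True)
class Token:
    """A spoken word with timing, surprisal and substitution metadata.

    ``onset``/``offset`` are in seconds; ``surprisal`` in bits (``None``
    until annotated); ``altered`` marks words substituted into the story.
    """

    text: str
    onset: float
    offset: float
    surprisal: float | None = None
    pos: str | None = None
    altered: bool = False

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"token onset must be >= 0, got {self.onset}")
        if not self.offset > self.onset:
            raise ValueError(
                f"token offset must exceed onset ({self.text!r}: "
                f"{self.onset} .. {self.offset})"
            )
        if self.surprisal is not None and not (
            math.isfinite(self.surprisal) and self.surprisal >= 0
        ):
            raise ValueError(f"surprisal must be finite and >= 0, got {self.surprisal}")


def validate_tokens(tokens: Sequence[Token]) -> None:
    """Raise ``ValueError`` unless tokens are onset-sorted and non-overlapping."""
    for i in range(1, len(tokens)):
        if tokens[i].onset < tokens[i - 1].onset:
            raise ValueError(
                f"tokens out of order at index {i}: onset {tokens[i].onset} "
                f"< {tokens[i - 1].onset}"
            )
        if tokens[i].onset < tokens[i - 1].offset - 1e-9:
            raise ValueError(
                f"tokens overlap at index {i}: onset {tokens[i].onset} "
                f"< previous offset {tokens[i - 1].offset}"
            )


def tokenize(text: str) -> list[str]:
    """Lowercase and split text; punctuation becomes :data:`BOUNDARY` markers.

    Boundary markers count as context tokens for the language model but carry
    no timing and receive no regressor events.
    """
    out = []
    for tok in _TOKEN_RE.findall(text.lower()):
        out.append(BOUNDARY if tok in _BOUNDARY_CHARS else tok)
    return out


@dataclass
class NGramModel:
    """Count-based n-gram model with proper (sum-to-one) smoothed distributions.

    ``counts[n]`` maps n-tuples to occurrence counts; ``context_totals[n]``
    maps n-length contexts to the number of observed continuations, i.e.
    ``sum_w counts[n+1][ctx + (w,)]``.

    Smoothing schemes
    -----------------
    ``add_k``
        Interpolated additive smoothing,
        ``p_n(w|ctx) = (c(ctx,w) + k * p_{n-1}(w|ctx[1:])) / (c(ctx) + k)``,
        grounded in an add-k unigram over vocabulary + UNK.  Exactly
        hand-computable, proper at every order, and backs off exactly to the
        lower order on unseen contexts.
    ``kneser_ney``
        Interpolated Kneser-Ney with absolute discount ``discount``; the
        unigram base is the same add-k unigram so that UNK stays inside the
        distribution.
    ``mle``
        Raw relative frequencies at the longest seen context (diagnostic use;
        may assign probability 0 and hence infinite surprisal).
    """

    order: int
    vocabulary: frozenset[str]
    counts: dict[int, Counter]
    context_totals: dict[int, Counter]
    smoothing: str = "add_k"
    add_k: float = 0.01
    discount: float = 0.75
    _continuations: dict[int, Counter] = field(default_factory=dict, repr=False)

    # -- probabilities -----------------------------------------------------

    def _map(self, word: str) -> str:
        return word if word in self.vocabulary else UNK

    @property
    def _vsize(self) -> int:
        # vocabulary plus the UNK symbol
        return len(self.vocabulary) + 1

    def _p_unigram(self, word: str) -> float:
        k = self.add_k if self.smoothing != "mle" else 0.0
        n_total = self.context_totals[0][()]
        c = self.counts[1][(word,)]
        if self.smoothing == "mle":
            return c / n_total
        return (c + k) / (n_total + k * self._vsize)

    def _p_interp(self, word: str, ctx: tuple[str, ...]) -> float:
        if not ctx:
            return self._p_unigram(word)
        lower = self._p_interp(word, ctx[1:])
        n = len(ctx)
        tot = self.context_totals[n][ctx]
        c = self.counts[n + 1][ctx + (word,)]
        if self.smoothing == "kneser_ney":
            if tot == 0:
                return lower
            d = self.discount
            n1plus = self._n1plus(ctx)
            return max(c - d, 0.0) / tot + d * n1plus / tot * lower
        k = self.add_k
        return (c + k * lower) / (tot + k)

    def _n1plus(self, ctx: tuple[str, ...]) -> int:
        n = len(ctx)
        cache = self._continuations.setdefault(n, Counter())
        if not cache:
            for gram in self.counts[n + 1]:
                cache[gram[:-1]] += 1
        return cache[ctx]

    def _p_mle(self, word: str, ctx: tuple[str, ...]) -> float:
        # back off to the longest context with observations
        for start in range(len(ctx) + 1):
            sub = ctx[start:]
            if not sub:
                return self._p_unigram(word)
            if self.context_totals[len(sub)][sub] > 0:
                tot = self.context_totals[len(sub)][sub]
                return self.counts[len(sub) + 1][sub + (word,)] / tot
        return self._p_unigram(word)

    def probability(self, word: str, context: Sequence[str] = ()) -> float:
        """Smoothed ``p(word | context)``; context is truncated to order-1."""
        word = self._map(word)
        ctx = tuple(self._map(w) for w in context)
        if self.order > 1:
            ctx = ctx[-(self.order - 1) :]
        else:
            ctx = ()
        if self.smoothing == "mle":
            return self._p_mle(word, ctx)
        return self._p_interp(word, ctx)

    def surprisal(self, word: str, context: Sequence[str] = ()) -> float:
        """Surprisal in bits, ``-log2 p(word|context)``."""
        p = self.probability(word, context)
        if p <= 0.0:
            return math.inf
        return -math.log2(p)

    def truncated(self, order: int) -> "NGramModel":
        """A copy of the model restricted to a lower maximum order."""
        if not 1 <= order <= self.order:
            raise ValueError(f"order must be in 1..{self.order}")
        return replace(
            self,
            order=order,
            counts={n: c for n, c in self.counts.items() if n <= order},
            context_totals={
                n: c for n, c in self.context_totals.items() if n < order
            },
            _continuations={},
        )


def train_ngram(
    corpus: Iterable[str] | str,
    order: int,
    smoothing: str = "add_k",
    *,
    add_k: float = 0.01,
    discount: float = 0.75,
) -> NGramModel:
    """Count n-grams of orders ``1..order`` over a token stream.

    ``corpus`` is either raw text (tokenized with :func:`tokenize`) or an
    already-tokenized sequence of strings.  Boundary markers participate in
    contexts like ordinary tokens.
    """
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    if smoothing not in ("add_k", "kneser_ney", "mle"):
        raise ValueError(f"unknown smoothing scheme {smoothing!r}")
    tokens = tokenize(corpus) if isinstance(corpus, str) else list(corpus)
    if not tokens:
        raise ValueError("corpus is empty")
    counts: dict[int, Counter] = {n: Counter() for n in range(1, order + 1)}
    for n in range(1, order + 1):
        for i in range(len(tokens) - n + 1):
            counts[n][tuple(tokens[i : i + n])] += 1
    context_totals: dict[int, Counter] = {0: Counter({(): len(tokens)})}
    for n in range(1, order):
        totals = Counter()
        for gram, c in counts[n + 1].items():
            totals[gram[:-1]] += c
        context_totals[n] = totals
    # the boundary marker is modeled like any other token type so that the
    # smoothed distribution closes over vocabulary + UNK exactly
    vocab = frozenset(set(tokens))
    return NGramModel(
        order=order,
        vocabulary=vocab,
        counts=counts,
        context_totals=context_totals,
        smoothing=smoothing,
        add_k=add_k,
        discount=discount,
    )


def surprisal_of(model: NGramModel, context: Sequence[str], word: str) -> float:
    """Surprisal of ``word`` after ``context`` in bits (>= 0; 0 iff p = 1)."""
    if not word:
        raise ValueError("word must be non-empty")
    return model.surprisal(word, context)


def annotate_tokens(model: NGramModel, tokens: Sequence[Token]) -> list[Token]:
    """Fill every token's surprisal from the preceding story words.

    Context is the up-to ``order-1`` preceding word tokens; shorter story-
    initial contexts back off naturally.  Timing fields are untouched, so the
    operation is idempotent.
    """
    validate_tokens(tokens)
    n_ctx = model.order - 1
    out: list[Token] = []
    words = [t.text for t in tokens]
    for i, tok in enumerate(tokens):
        ctx = words[max(0, i - n_ctx) : i]
        out.append(replace(tok, surprisal=surprisal_of(model, ctx, tok.text)))
    return out


@dataclass(frozen=True)
class SubstitutionPlan:
    """Planned word substitutions for a high-surprisal story variant."""

    story_id: str
    replacements: tuple[tuple[int, str], ...]
    min_spacing_s: float = 45.0
    surprisal_threshold_bits: float = 20.0

    def __post_init__(self) -> None:
        idx = [i for i, _ in self.replacements]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("replacement indices must be strictly increasing")


@dataclass
class PlanReport:
    """Per-replacement criterion outcomes plus an overall verdict.

    Each check is ``"pass"``, ``"fail"`` or ``"not evaluated"`` (when the
    required annotation -- part-of-speech tags or clause boundaries -- is
    absent).  ``overall_pass`` requires every evaluated check to pass.
    """

    checks: list[dict[str, str]]
    surprisals: list[float]
    overall_pass: bool


def validate_plan(
    tokens: Sequence[Token],
    plan: SubstitutionPlan,
    model: NGramModel,
    clause_final_indices: set[int] | None = None,
) -> PlanReport:
    """Check a substitution plan against the stimulus-design criteria.

    Criteria: replacement surprisal above the threshold (default 20 bits),
    spacing between consecutive replacements at least ``min_spacing_s``
    (default 45 s), noun-for-noun substitution when part-of-speech tags are
    available, and clause-final position when clause boundaries are provided.
    """
    n_ctx = model.order - 1
    words = [t.text for t in tokens]
    checks: list[dict[str, str]] = []
    surprisals: list[float] = []
    prev_onset: float | None = None
    for idx, replacement in plan.replacements:
        if not 0 <= idx < len(tokens):
            raise IndexError(f"replacement index {idx} outside token range")
        tok = tokens[idx]
        ctx = words[max(0, idx - n_ctx) : idx]
        s = surprisal_of(model, ctx, replacement)
        surprisals.append(s)
        row = {
            "surprisal": "pass" if s > plan.surprisal_threshold_bits else "fail"
        }
        if prev_onset is None:
            row["spacing"] = "pass"
        else:
            row["spacing"] = (
                "pass" if tok.onset - prev_onset >= plan.min_spacing_s else "fail"
            )
        prev_onset = tok.onset
        if tok.pos is None:
            row["noun_for_noun"] = "not evaluated"
        else:
            row["noun_for_noun"] = (
                "pass" if tok.pos.upper().startswith("N") else "fail"
            )
        if clause_final_indices is None:
            row["clause_final"] = "not evaluated"
        else:
            row["clause_final"] = (
                "pass" if idx in clause_final_indices else "fail"
            )
        checks.append(row)
    overall = all(
        v != "fail" for row in checks for v in row.values()
    )
    return PlanReport(checks=checks, surprisals=surprisals, overall_pass=overall)
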