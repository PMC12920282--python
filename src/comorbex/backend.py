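"""Classifier-backend contract and reference backends.

A backend answers one classification request about one document: a
binary presence question for a single category, a multi-choice subtype
question, or a joint multi-label question.  The production system the
design emulates used a fine-tuned instruction-following language model;
this package ships deterministic desk-scale backends implementing the
same contract:

* :class:`LexiconBackend` — surface-form matching with a sentence-scoped
  negation window; deterministic, confidence 100.
* :class:`NoisyBackend` — wraps another backend and flips each binary
  decision independently with probability ``flip_rate`` using a seeded,
  per-(document, category) deterministic stream.
* :class:`CountingBackend` — transparent wrapper recording every request
  (used for call-count contracts).
* :class:`ScriptedBackend` — answers from an explicit (document,
  category) table; used to stage contradiction scenarios.

Raw reply tokens are mapped to binary decisions through a response
lexicon: replies in the positive set {"True", "Yes", "__YES__"} map to
1, replies in the negative set {"False", "No", "__NO__"} map to 0, and
anything else is *unmapped* (an error in strict mode, recorded and
treated as negative in lenient mode).
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from typing import Protocol

from .taxonomy import Category, Taxonomy

__all__ = [
    "BackendRequest",
    "BackendResponse",
    "ResponseLexicon",
    "CostLedger",
    "Backend",
    "MappingError",
    "map_response",
    "DEFAULT_NEGATION_CUES",
    "LexiconBackend",
    "NoisyBackend",
    "CountingBackend",
    "ScriptedBackend",
    "record_cost",
]

POSITIVE = "positive"
NEGATIVE = "negative"
UNMAPPED = "unmapped"


class MappingError(ValueError):
    """A raw reply token fell outside both response token sets (strict)."""

    def __init__(self, raw_token: str):
        self.raw_token = raw_token
        super().__init__(f"unmappable reply token {raw_token!r}")


@dataclass(frozen=True)
class ResponseLexicon:
    """Token sets that map raw classifier replies to binary decisions."""

    positives: frozenset[str] = frozenset({"True", "Yes", "__YES__"})
    negatives: frozenset[str] = frozenset({"False", "No", "__NO__"})

    def __post_init__(self) -> None:
        pos = {_normalize_token(t) for t in self.positives}
        neg = {_normalize_token(t) for t in self.negatives}
        if pos & neg:
            raise ValueError(
                f"response token sets overlap after normalization: {pos & neg}"
            )


@dataclass(frozen=True)
class BackendRequest:
    """One classification question about one document."""

    document_text: str
    category_id: str
    question_text: str
    kind: str = "binary"  # "binary" | "multi_choice" | "joint"
    options: tuple[str, ...] = ()  # candidate category ids for multi/joint
    forwarded_context: str | None = None
    examples: tuple[tuple[str, str], ...] = ()
    document_id: str | None = None

    def __post_init__(self) -> None:
        if not self.question_text:
            raise ValueError("question_text must be non-empty")
        if self.kind not in ("binary", "multi_choice", "joint"):
            raise ValueError(f"unknown request kind {self.kind!r}")


@dataclass(frozen=True)
class BackendResponse:
    """One classifier decision with confidence and cost accounting."""

    raw_token: str
    decision: str  # positive | negative | unmapped
    confidence: float  # 0..100
    prompt_tokens: int
    completion_tokens: int
    evidence_span: str | None = None
    flipped: bool = False

    def __post_init__(self) -> None:
        if self.decision not in (POSITIVE, NEGATIVE, UNMAPPED):
            raise ValueError(f"bad decision {self.decision!r}")
        if not 0 <= self.confidence <= 100:
            raise ValueError("confidence must lie in [0, 100]")
        if self.prompt_tokens < 0 or self.completion_tokens < 0:
            raise ValueError("token counts must be non-negative")


class Backend(Protocol):
    """Backend contract: a callable from request to response."""

    def __call__(self, req: BackendRequest) -> BackendResponse: ...


# ---------------------------------------------------------------------------
# response mapping


_TERMINAL_PUNCT = ".,!?;:"


def _normalize_token(token: str) -> str:
    return token.strip().rstrip(_TERMINAL_PUNCT).strip().casefold()


DEFAULT_RESPONSE_LEXICON = ResponseLexicon()


def map_response(
    raw_token: str,
    lexicon: ResponseLexicon = DEFAULT_RESPONSE_LEXICON,
    strict: bool = False,
) -> str:
    """Map a raw reply token to positive / negative / unmapped.

    Normalization: trim whitespace, strip terminal punctuation, compare
    case-insensitively.  In strict mode an unrecognized token raises
    :class:`MappingError`; in lenient mode it is returned as unmapped
    (downstream code treats unmapped as negative and sets a flag).
    """
    norm = _normalize_token(raw_token)
    if norm in {_normalize_token(t) for t in lexicon.positives}:
        return POSITIVE
    if norm in {_normalize_token(t) for t in lexicon.negatives}:
        return NEGATIVE
    if strict:
        raise MappingError(raw_token)
    return UNMAPPED


def _count_tokens(text: str) -> int:
    """Whitespace token count — the cost proxy used by mock backends."""
    return len(text.split())


# ---------------------------------------------------------------------------
# lexicon backend


DEFAULT_NEGATION_CUES: tuple[str, ...] = (
    "no history of",
    "no evidence of",
    "denies",
    "without",
    "kein",
    "keine",
    "ruled out",
    "excluded",
    "previously",
    "formerly",
    "no longer",
    "resolved",
)

_SENTENCE_SPLIT = re.compile(r"(?<=[.!?])\s+|\n+")


def _term_pattern(term: str) -> re.Pattern[str]:
    # Short all-caps abbreviations ("AF", "HTN", "OSA") are matched
    # case-sensitively to avoid firing inside ordinary words; everything
    # else is case-insensitive.  Word boundaries on both sides.
    flags = 0 if (term.isupper() and len(term) <= 5) else re.IGNORECASE
    return re.compile(rf"(?<!\w){re.escape(term)}(?!\w)", flags)


def split_sentences(text: str) -> list[str]:
    return [s for s in _SENTENCE_SPLIT.split(text) if s.strip()]


def find_mention(
    text: str,
    category: Category,
    negation_cues: tuple[str, ...] = DEFAULT_NEGATION_CUES,
) -> str | None:
    """First asserted (non-negated) mention of the category in the text.

    A lexicon term counts only if its sentence contains none of the
    negation/temporality cues; the window is the whole sentence.
    Returns the matched surface text, or None.
    """
    cues = [c.casefold() for c in negation_cues]
    for sentence in split_sentences(text):
        low = sentence.casefold()
        if any(cue in low for cue in cues):
            continue
        for entry in category.lexicon:
            hit = _term_pattern(entry.term).search(sentence)
            if hit:
                return hit.group(0)
    return None


class LexiconBackend:
    """Deterministic surface-form backend with a negation window.

    Scans the document for the category's lexicon entries; matches in a
    sentence containing a negation or resolved-temporality cue do not
    count.  Confidence is fixed (default 100).  Prompt cost is the
    whitespace token count of question + document; completion cost is 1
    token per decision (or one per named id for multi replies).
    """

    def __init__(
        self,
        taxonomy: Taxonomy,
        negation_cues: tuple[str, ...] = DEFAULT_NEGATION_CUES,
        confidence: float = 100.0,
    ):
        self.taxonomy = taxonomy
        self.negation_cues = tuple(negation_cues)
        self.confidence = float(confidence)

    def _positive_ids(self, text: str, option_ids: tuple[str, ...]) -> list[str]:
        out = []
        for cid in option_ids:
            if find_mention(text, self.taxonomy.get(cid), self.negation_cues):
                out.append(cid)
        return out

    def __call__(self, req: BackendRequest) -> BackendResponse:
        prompt_tokens = _count_tokens(req.question_text) + _count_tokens(
            req.document_text
        )
        if req.kind == "binary":
            span = find_mention(
                req.document_text,
                self.taxonomy.get(req.category_id),
                self.negation_cues,
            )
            return BackendResponse(
                raw_token="True" if span else "False",
                decision=POSITIVE if span else NEGATIVE,
                confidence=self.confidence,
                prompt_tokens=prompt_tokens,
                completion_tokens=1,
                evidence_span=span,
            )
        # multi_choice / joint: reply is a comma-delimited list of ids
        hits = self._positive_ids(req.document_text, req.options)
        return BackendResponse(
            raw_token=", ".join(hits),
            decision=POSITIVE if hits else NEGATIVE,
            confidence=self.confidence,
            prompt_tokens=prompt_tokens,
            completion_tokens=max(1, len(hits)),
            evidence_span=None,
        )


# ---------------------------------------------------------------------------
# noisy backend


def _unit_uniform(seed: int, *keys: str) -> float:
    """Deterministic uniform in [0, 1) keyed by seed and strings;
    platform-independent (SHA-256, not Python's salted hash)."""
    payload = ("|".join((str(seed),) + keys)).encode("utf-8")
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:8], "big") / 2**64


class NoisyBackend:
    """Flip each binary decision of an inner backend with probability
    ``flip_rate`` using a seeded per-(document, category) stream.

    For multi-choice/joint requests each option's membership in the
    reply list is flipped independently with the same per-(document,
    option) stream, so flat and gated paradigms see identical noise for
    a given (document, category) pair.  Flipped answers carry a reduced
    confidence (default 55).
    """

    def __init__(
        self,
        inner: Backend,
        flip_rate: float,
        seed: int,
        flipped_confidence: float = 55.0,
    ):
        if not 0.0 <= flip_rate <= 1.0:
            raise ValueError("flip_rate must lie in [0, 1]")
        self.inner = inner
        self.flip_rate = float(flip_rate)
        self.seed = int(seed)
        self.flipped_confidence = float(flipped_confidence)

    def _flip(self, doc_key: str, category_id: str) -> bool:
        return (
            _unit_uniform(self.seed, doc_key, category_id) < self.flip_rate
        )

    def __call__(self, req: BackendRequest) -> BackendResponse:
        resp = self.inner(req)
        doc_key = req.document_id or req.document_text
        if req.kind == "binary":
            if resp.decision in (POSITIVE, NEGATIVE) and self._flip(
                doc_key, req.category_id
            ):
                flipped = POSITIVE if resp.decision == NEGATIVE else NEGATIVE
                return BackendResponse(
                    raw_token="True" if flipped == POSITIVE else "False",
                    decision=flipped,
                    confidence=self.flipped_confidence,
                    prompt_tokens=resp.prompt_tokens,
                    completion_tokens=resp.completion_tokens,
                    evidence_span=None,
                    flipped=True,
                )
            return resp
        # list replies: toggle each option independently
        named = {t.strip() for t in resp.raw_token.split(",") if t.strip()}
        out, any_flip = [], False
        for cid in req.options:
            member = cid in named
            if self._flip(doc_key, cid):
                member = not member
                any_flip = True
            if member:
                out.append(cid)
        return BackendResponse(
            raw_token=", ".join(out),
            decision=POSITIVE if out else NEGATIVE,
            confidence=self.flipped_confidence if any_flip else resp.confidence,
            prompt_tokens=resp.prompt_tokens,
            completion_tokens=max(1, len(out)),
            evidence_span=None if any_flip else resp.evidence_span,
            flipped=any_flip,
        )


# ---------------------------------------------------------------------------
# instrumentation backends


class CountingBackend:
    """Wrapper that records every request passing through it."""

    def __init__(self, inner: Backend):
        self.inner = inner
        self.requests: list[BackendRequest] = []

    @property
    def calls(self) -> int:
        return len(self.requests)

    def reset(self) -> None:
        self.requests.clear()

    def __call__(self, req: BackendRequest) -> BackendResponse:
        self.requests.append(req)
        return self.inner(req)


class ScriptedBackend:
    """Answers binary requests from an explicit table.

    ``script`` maps ``(document_id, category_id)`` to a ``(decision,
    confidence)`` pair; unscripted requests fall through to ``fallback``
    (default: a fixed negative at confidence 100).  Used to stage
    contradiction and uncertainty scenarios deterministically.
    """

    def __init__(
        self,
        script: dict[tuple[str, str], tuple[str, float]],
        fallback: Backend | None = None,
    ):
        self.script = dict(script)
        self.fallback = fallback

    def __call__(self, req: BackendRequest) -> BackendResponse:
        key = (req.document_id or "", req.category_id)
        if req.kind == "binary" and key in self.script:
            decision, confidence = self.script[key]
            raw = {POSITIVE: "True", NEGATIVE: "False"}.get(decision, "???")
            return BackendResponse(
                raw_token=raw,
                decision=decision,
                confidence=confidence,
                prompt_tokens=_count_tokens(req.question_text)
                + _count_tokens(req.document_text),
                completion_tokens=1,
            )
        if self.fallback is not None:
            return self.fallback(req)
        return BackendResponse(
            raw_token="False",
            decision=NEGATIVE,
            confidence=100.0,
            prompt_tokens=_count_tokens(req.question_text)
            + _count_tokens(req.document_text),
            completion_tokens=1,
        )


# ---------------------------------------------------------------------------
# cost accounting


@dataclass
class CostLedger:
    """Aggregated call and token totals over recorded responses."""

    calls: int = 0
    prompt_tokens: int = 0
    completion_tokens: int = 0
    documents: int = 1

    def __post_init__(self) -> None:
        if self.documents < 1:
            raise ValueError("documents must be >= 1")

    @property
    def total_tokens(self) -> int:
        return self.prompt_tokens + self.completion_tokens

    @property
    def tokens_per_document(self) -> float:
        return self.total_tokens / self.documents

    def add(self, resp: BackendResponse) -> None:
        self.calls += 1
        self.prompt_tokens += resp.prompt_tokens
        self.completion_tokens += resp.completion_tokens

    def merge(self, other: "CostLedger") -> "CostLedger":
        return CostLedger(
            calls=self.calls + other.calls,
            prompt_tokens=self.prompt_tokens + other.prompt_tokens,
            completion_tokens=self.completion_tokens + other.completion_tokens,
            documents=self.documents + other.documents,
        )


def record_cost(
    responses: list[BackendResponse], documents: int
) -> CostLedger:
    """Sum calls and tokens over responses; exposes tokens/document."""
    if documents < 1:
        raise ValueError("documents must be >= 1")
    ledger = CostLedger(documents=documents)
    for resp in responses:
        ledger.add(resp)
    return ledger
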