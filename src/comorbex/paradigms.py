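"""Classification paradigms and hierarchical prompting strategies.

Three paradigms over the same taxonomy and backend:

* **flat** — one independent binary question per category (all parents
  and all children; ``d`` calls, no gating);
* **two-level** — binary questions for the ``m`` parents first, then
  children only of positive parents (children of negative parents are
  set to 0 without a call);
* **strategy-based** — per parent-with-subtypes unit, one of three
  prompting strategies whose per-document call counts define their cost
  profile: context-forwarding multi-step binary (1 + n calls),
  sequential refinement (binary parent + one multi-choice refinement;
  2 calls in the typical case), and joint label inference (a single
  multi-label call; 1 call).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .backend import (
    Backend,
    BackendRequest,
    BackendResponse,
    CostLedger,
    MappingError,
    NEGATIVE,
    POSITIVE,
)
from .taxonomy import Category, LabelVector, Taxonomy

__all__ = [
    "StrategyKind",
    "DocumentPrediction",
    "build_prompt",
    "classify_flat",
    "classify_two_level",
    "classify_with_strategy",
    "classify_joint_document",
    "parse_id_list",
]


class StrategyKind(str, Enum):
    """Hierarchical prompting strategies with fixed call-count contracts."""

    CONTEXT_FORWARDING = "context_forwarding_multistep_binary"  # 1 + n calls
    SEQUENTIAL_REFINEMENT = "sequential_refinement"  # 2 calls typical
    JOINT_LABEL_INFERENCE = "joint_label_inference"  # 1 call


@dataclass
class DocumentPrediction:
    """Predicted labels for one document plus full response audit trail."""

    labels: LabelVector
    per_category_responses: dict[str, BackendResponse]
    cost: CostLedger
    flags: set[str] = field(default_factory=set)
    document_id: str | None = None


# ---------------------------------------------------------------------------
# prompt construction


_BINARY_INSTRUCTION = (
    'Is comorbidity "{name}" present in the following medical text? '
    "Answer True or False."
)
_MULTI_INSTRUCTION = (
    'Which of the following subtypes of "{name}" are present in the '
    "medical text? Answer with a comma-separated list of ids from "
    "[{options}], or None."
)
_JOINT_INSTRUCTION = (
    "Which of the following comorbidity categories are present in the "
    "medical text? Answer with a comma-separated list of ids from "
    "[{options}], or None."
)


def build_prompt(
    doc: str,
    c: Category,
    examples: tuple[tuple[str, str], ...] = (),
    context: str | None = None,
    instruction: str | None = None,
) -> str:
    """Render the deterministic question text for one category.

    Layout: instruction, optional few-shot example block, optional
    forwarded parent context (verbatim), then the document.  Identical
    inputs yield byte-identical prompts.
    """
    parts = [
        instruction
        if instruction is not None
        else _BINARY_INSTRUCTION.format(name=c.display_name)
    ]
    for ex_text, ex_label in examples:
        parts.append(f"Example:\n{ex_text}\nAnswer: {ex_label}")
    if context is not None:
        parts.append(f"Parent context: {context}")
    parts.append(f"Text:\n{doc}")
    return "\n\n".join(parts)


def parse_id_list(
    raw: str, valid_ids: tuple[str, ...], strict: bool = False
) -> tuple[list[str], set[str]]:
    """Parse a comma-delimited id-list reply from a multi-choice call.

    Unknown ids raise in strict mode; in lenient mode they are dropped
    and reported in the returned flag set.  "None"/empty means no ids.
    """
    flags: set[str] = set()
    text = raw.strip().rstrip(".")
    if not text or text.casefold() in ("none", "no", "false"):
        return [], flags
    out = []
    for token in text.split(","):
        cid = token.strip()
        if not cid:
            continue
        if cid in valid_ids:
            if cid not in out:
                out.append(cid)
        elif strict:
            raise MappingError(cid)
        else:
            flags.add(f"unknown-id:{cid}")
    return out, flags


# ---------------------------------------------------------------------------
# shared helpers


def _decide(
    resp: BackendResponse, category_id: str, strict: bool, flags: set[str]
) -> int:
    if resp.decision == POSITIVE:
        return 1
    if resp.decision == NEGATIVE:
        return 0
    if strict:
        raise MappingError(f"{category_id}: {resp.raw_token}")
    flags.add(f"unmapped:{category_id}")
    return 0


def _binary_request(
    doc: str,
    c: Category,
    doc_id: str | None,
    examples: tuple[tuple[str, str], ...] = (),
    context: str | None = None,
) -> BackendRequest:
    return BackendRequest(
        document_text=doc,
        category_id=c.id,
        question_text=build_prompt(doc, c, examples, context),
        kind="binary",
        forwarded_context=context,
        examples=examples,
        document_id=doc_id,
    )


def _finish(
    t: Taxonomy,
    positive: set[str],
    responses: dict[str, BackendResponse],
    flags: set[str],
    doc_id: str | None,
) -> DocumentPrediction:
    ledger = CostLedger(documents=1)
    for resp in responses.values():
        ledger.add(resp)
    return DocumentPrediction(
        labels=t.encode_labels(positive),
        per_category_responses=responses,
        cost=ledger,
        flags=flags,
        document_id=doc_id,
    )


# ---------------------------------------------------------------------------
# paradigms


def classify_flat(
    doc: str,
    t: Taxonomy,
    b: Backend,
    strict: bool = False,
    doc_id: str | None = None,
) -> DocumentPrediction:
    """One independent binary query per category — exactly ``d`` calls,
    parents and children alike, with no hierarchical gating."""
    responses: dict[str, BackendResponse] = {}
    flags: set[str] = set()
    positive: set[str] = set()
    for cat in t.all_categories():
        resp = b(_binary_request(doc, cat, doc_id))
        responses[cat.id] = resp
        if _decide(resp, cat.id, strict, flags):
            positive.add(cat.id)
    return _finish(t, positive, responses, flags, doc_id)


def classify_two_level(
    doc: str,
    t: Taxonomy,
    b: Backend,
    strict: bool = False,
    doc_id: str | None = None,
) -> DocumentPrediction:
    """Parent-gated two-step classification.

    Step 1 queries all ``m`` parents; step 2 queries the children of
    parents predicted positive.  Children of negative parents are set
    to 0 without a call, so the output can never contain a positive
    child under a negative parent.  Call count:
    ``m + sum(n_i for positive parents i)``.
    """
    responses: dict[str, BackendResponse] = {}
    flags: set[str] = set()
    positive: set[str] = set()
    for parent in t.top_categories:
        resp = b(_binary_request(doc, parent, doc_id))
        responses[parent.id] = resp
        if not _decide(resp, parent.id, strict, flags):
            continue
        positive.add(parent.id)
        for child in t.sub_categories(parent.id):
            kid_resp = b(_binary_request(doc, child, doc_id))
            responses[child.id] = kid_resp
            if _decide(kid_resp, child.id, strict, flags):
                positive.add(child.id)
    return _finish(t, positive, responses, flags, doc_id)


# ---------------------------------------------------------------------------
# prompting strategies (per parent-with-subtypes unit)


def _multi_choice_request(
    doc: str,
    parent: Category,
    options: tuple[str, ...],
    doc_id: str | None,
) -> BackendRequest:
    instruction = _MULTI_INSTRUCTION.format(
        name=parent.display_name, options=", ".join(options)
    )
    return BackendRequest(
        document_text=doc,
        category_id=parent.id,
        question_text=build_prompt(doc, parent, instruction=instruction),
        kind="multi_choice",
        options=options,
        document_id=doc_id,
    )


def classify_with_strategy(
    doc: str,
    parent: Category,
    t: Taxonomy,
    b: Backend,
    s: StrategyKind,
    strict: bool = False,
    doc_id: str | None = None,
) -> DocumentPrediction:
    """Classify one parent and its subtypes with a prompting strategy.

    Call counts in the typical case (one positive parent needing one
    refinement round): context forwarding ``1 + n``; sequential
    refinement ``2``; joint label inference ``1``.
    """
    children = t.sub_categories(parent.id)
    child_ids = tuple(c.id for c in children)
    responses: dict[str, BackendResponse] = {}
    flags: set[str] = set()
    positive: set[str] = set()

    if s is StrategyKind.CONTEXT_FORWARDING:
        parent_resp = b(_binary_request(doc, parent, doc_id))
        responses[parent.id] = parent_resp
        parent_bit = _decide(parent_resp, parent.id, strict, flags)
        if parent_bit:
            positive.add(parent.id)
        context = (
            f"{parent.display_name}: "
            f"{'present' if parent_bit else 'absent'}"
            + (
                f' (evidence: "{parent_resp.evidence_span}")'
                if parent_resp.evidence_span
                else ""
            )
        )
        for child in children:
            resp = b(_binary_request(doc, child, doc_id, context=context))
            responses[child.id] = resp
            if _decide(resp, child.id, strict, flags):
                positive.add(child.id)

    elif s is StrategyKind.SEQUENTIAL_REFINEMENT:
        parent_resp = b(_binary_request(doc, parent, doc_id))
        responses[parent.id] = parent_resp
        if _decide(parent_resp, parent.id, strict, flags):
            positive.add(parent.id)
            if children:
                multi = b(_multi_choice_request(doc, parent, child_ids, doc_id))
                responses[f"{parent.id}::refinement"] = multi
                ids, parse_flags = parse_id_list(
                    multi.raw_token, child_ids, strict
                )
                flags |= parse_flags
                positive.update(ids)

    elif s is StrategyKind.JOINT_LABEL_INFERENCE:
        options = (parent.id,) + child_ids
        instruction = _JOINT_INSTRUCTION.format(options=", ".join(options))
        req = BackendRequest(
            document_text=doc,
            category_id=parent.id,
            question_text=build_prompt(doc, parent, instruction=instruction),
            kind="joint",
            options=options,
            document_id=doc_id,
        )
        resp = b(req)
        responses[f"{parent.id}::joint"] = resp
        ids, parse_flags = parse_id_list(resp.raw_token, options, strict)
        flags |= parse_flags
        positive.update(ids)
        # a positive subtype implies its parent in the joint reading
        if any(cid in child_ids for cid in ids):
            positive.add(parent.id)
    else:  # pragma: no cover - exhaustive over the enum
        raise ValueError(f"unknown strategy {s!r}")

    # restrict encoding to this unit: other categories stay 0
    return _finish(t, positive, responses, flags, doc_id)


def classify_joint_document(
    doc: str,
    t: Taxonomy,
    b: Backend,
    strict: bool = False,
    doc_id: str | None = None,
) -> DocumentPrediction:
    """Single-shot joint inference over the whole taxonomy: one
    multi-label call covering every parent and subtype."""
    options = tuple(c.id for c in t.all_categories())
    instruction = _JOINT_INSTRUCTION.format(options=", ".join(options))
    anchor = t.top_categories[0]
    req = BackendRequest(
        document_text=doc,
        category_id=anchor.id,
        question_text=build_prompt(doc, anchor, instruction=instruction),
        kind="joint",
        options=options,
        document_id=doc_id,
    )
    resp = b(req)
    flags: set[str] = set()
    ids, parse_flags = parse_id_list(resp.raw_token, options, strict)
    flags |= parse_flags
    positive = set(ids)
    return _finish(t, positive, {"::joint": resp}, flags, doc_id)
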