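"""Multi-agent execution graph: parent agents, sub-agents, early judge,
and contradiction solver.

The graph generalizes the gated two-level paradigm.  Stages:

1. **Parent agents** — one binary call per top-level category.
2. **Result judger** (optional) — flags parents whose decision is
   unmapped or whose confidence falls below a threshold τ as
   *uncertain*; uncertain negative parents still get their sub-agents
   scheduled.  This is the mechanism by which child-positive /
   parent-negative states can arise at all under a gated architecture.
3. **Sub-agents** — binary calls for the children of every positive or
   uncertain parent, optionally carrying the forwarded parent decision
   and evidence snippet (*context forwarding*).
4. **Contradiction solver** (optional) — reconciles child-OR=1 /
   parent=0 pairs, either by promoting the parent when some child is
   confidently positive (the preferred rule: a confident subtype is
   evidence for its parent) or by suppressing the offending children.

With ``hierarchy_enabled=False`` the graph degenerates to a single-pass
flat classifier: one joint multi-label call predicts all parents and
subtypes together (no gating, judging, solving, or forwarding); an
optional token budget cap supports matched-cost comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .backend import Backend, BackendResponse, CostLedger, UNMAPPED
from .paradigms import (
    DocumentPrediction,
    _binary_request,
    _decide,
    classify_joint_document,
)
from .taxonomy import Taxonomy

__all__ = [
    "GraphConfig",
    "ParentTrace",
    "ExecutionTrace",
    "BudgetExceededError",
    "run_graph",
    "result_judger",
    "contradiction_solver",
    "count_contradictions",
]

PROMOTE_PARENT = "promote_parent"
SUPPRESS_CHILDREN = "suppress_children"


class BudgetExceededError(RuntimeError):
    def __init__(self, document_id: str, tokens: int, cap: int):
        self.document_id = document_id
        super().__init__(
            f"document {document_id!r}: token budget exceeded "
            f"({tokens} > cap {cap})"
        )


@dataclass(frozen=True)
class GraphConfig:
    """Switches and thresholds for one graph variant.

    ``hierarchy_enabled=False`` selects the flat matched-cost variant,
    which forces the judger, solver, and context forwarding off.
    ``no_forwarding_parents`` disables context forwarding for selected
    parents only (the targeted forwarding ablation).
    """

    judger_enabled: bool = True
    solver_enabled: bool = True
    context_forwarding_enabled: bool = True
    hierarchy_enabled: bool = True
    judger_confidence_threshold: float = 60.0
    solver_rule: str = PROMOTE_PARENT
    solver_confidence_threshold: float = 70.0
    token_budget_cap: int | None = None
    no_forwarding_parents: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.solver_rule not in (PROMOTE_PARENT, SUPPRESS_CHILDREN):
            raise ValueError(f"unknown solver rule {self.solver_rule!r}")
        for name in ("judger_confidence_threshold",
                     "solver_confidence_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must lie in [0, 100]")
        if not self.hierarchy_enabled:
            # flat variant has no gating machinery to switch on
            object.__setattr__(self, "judger_enabled", False)
            object.__setattr__(self, "solver_enabled", False)
            object.__setattr__(self, "context_forwarding_enabled", False)


@dataclass
class ParentTrace:
    """Everything the graph recorded about one (document, parent) pair."""

    parent_id: str
    parent_bit: int
    parent_confidence: float
    uncertain: bool = False  # judger flag
    children_evaluated: bool = False
    child_bits_pre: dict[str, int] = field(default_factory=dict)
    child_confidence: dict[str, float] = field(default_factory=dict)
    child_bits_post: dict[str, int] = field(default_factory=dict)
    parent_bit_post: int = 0
    contradiction_pre: bool = False
    contradiction_post: bool = False
    solver_action: str | None = None

    @property
    def child_or_pre(self) -> int:
        return int(any(self.child_bits_pre.values()))

    @property
    def child_or_post(self) -> int:
        return int(any(self.child_bits_post.values()))


@dataclass
class ExecutionTrace:
    """Per-document record of all agent calls and solver decisions."""

    document_id: str
    parents: dict[str, ParentTrace] = field(default_factory=dict)
    responses: dict[str, BackendResponse] = field(default_factory=dict)
    cost: CostLedger = field(default_factory=lambda: CostLedger(documents=1))
    flags: set[str] = field(default_factory=set)
    pre_solver_logged: bool = True
    solver_ran: bool = False

    def pairs_post(self) -> list[tuple[int, int]]:
        """(parent bit, child-OR bit) pairs on post-solver state."""
        return [
            (pt.parent_bit_post, pt.child_or_post)
            for pt in self.parents.values()
        ]


def count_contradictions(trace: ExecutionTrace, stage: str) -> int:
    """Number of (document, parent) pairs with child-OR=1 and parent=0."""
    if stage == "pre":
        if not trace.pre_solver_logged:
            raise ValueError("pre-solver stage was not logged")
        return sum(
            1
            for pt in trace.parents.values()
            if pt.child_or_pre == 1 and pt.parent_bit == 0
        )
    if stage == "post":
        return sum(
            1
            for pt in trace.parents.values()
            if pt.child_or_post == 1 and pt.parent_bit_post == 0
        )
    raise ValueError(f"unknown stage {stage!r}")


def result_judger(
    trace: ExecutionTrace, tau: float, enabled: bool = True
) -> ExecutionTrace:
    """Flag uncertain parent decisions and contradiction candidates.

    A parent is *uncertain* when its reply was unmapped or its
    confidence is below τ; uncertain negative parents get sub-agent
    evaluation despite the negative decision.  Disabled judger sets no
    flags regardless of confidence.
    """
    if not enabled:
        return trace
    for pid, pt in trace.parents.items():
        resp = trace.responses.get(pid)
        unmapped = resp is not None and resp.decision == UNMAPPED
        if unmapped or pt.parent_confidence < tau:
            pt.uncertain = True
    return trace


def contradiction_solver(
    trace: ExecutionTrace,
    rule: str = PROMOTE_PARENT,
    threshold: float = 70.0,
) -> ExecutionTrace:
    """Reconcile child-OR=1 / parent=0 pairs in place.

    ``promote_parent``: if the most confident positive child reaches the
    threshold, set the parent to 1 (a confidently positive subtype is
    evidence for its parent); otherwise zero the offending children.
    ``suppress_children``: always zero the offending children.
    Non-contradicting pairs are never altered.
    """
    if rule not in (PROMOTE_PARENT, SUPPRESS_CHILDREN):
        raise ValueError(f"unknown solver rule {rule!r}")
    for pt in trace.parents.values():
        if not (pt.parent_bit == 0 and pt.child_or_pre == 1):
            continue
        pt.contradiction_pre = True
        max_child_conf = max(
            (
                pt.child_confidence.get(cid, 0.0)
                for cid, bit in pt.child_bits_pre.items()
                if bit == 1
            ),
            default=0.0,
        )
        if rule == PROMOTE_PARENT and max_child_conf >= threshold:
            pt.parent_bit_post = 1
            pt.solver_action = "promoted_parent"
        else:
            pt.child_bits_post = {cid: 0 for cid in pt.child_bits_pre}
            pt.solver_action = "suppressed_children"
        pt.contradiction_post = (
            pt.parent_bit_post == 0 and pt.child_or_post == 1
        )
    trace.solver_ran = True
    return trace


def run_graph(
    doc: str,
    t: Taxonomy,
    b: Backend,
    g: GraphConfig,
    doc_id: str = "",
    strict: bool = False,
) -> tuple[DocumentPrediction, ExecutionTrace]:
    """Execute the configured agent graph on one document.

    Returns the final prediction (parents plus post-solver children)
    and the full execution trace from which C_pre/C_post, agreement
    statistics, and cost are countable.
    """
    if not g.hierarchy_enabled:
        return _run_flat(doc, t, b, g, doc_id, strict)

    trace = ExecutionTrace(document_id=doc_id or "")

    # stage 1: parent agents
    flags: set[str] = set()
    for parent in t.top_categories:
        resp = b(_binary_request(doc, parent, doc_id or None))
        trace.responses[parent.id] = resp
        trace.cost.add(resp)
        bit = _decide(resp, parent.id, strict, flags)
        trace.parents[parent.id] = ParentTrace(
            parent_id=parent.id,
            parent_bit=bit,
            parent_confidence=resp.confidence,
            parent_bit_post=bit,
        )

    # stage 2: early judge flags uncertain parents for evaluation
    result_judger(
        trace, g.judger_confidence_threshold, enabled=g.judger_enabled
    )

    # stage 3: sub-agents for positive or uncertain parents
    for parent in t.top_categories:
        pt = trace.parents[parent.id]
        if not (pt.parent_bit == 1 or pt.uncertain):
            continue
        children = t.sub_categories(parent.id)
        if not children:
            continue
        pt.children_evaluated = True
        forward = (
            g.context_forwarding_enabled
            and parent.id not in g.no_forwarding_parents
        )
        context = None
        if forward:
            resp = trace.responses[parent.id]
            context = (
                f"{parent.display_name}: "
                f"{'present' if pt.parent_bit else 'absent'}"
                + (
                    f' (evidence: "{resp.evidence_span}")'
                    if resp.evidence_span
                    else ""
                )
            )
        for child in children:
            resp = b(_binary_request(doc, child, doc_id or None, context=context))
            trace.responses[child.id] = resp
            trace.cost.add(resp)
            bit = _decide(resp, child.id, strict, flags)
            pt.child_bits_pre[child.id] = bit
            pt.child_bits_post[child.id] = bit
            pt.child_confidence[child.id] = resp.confidence
        pt.contradiction_pre = pt.parent_bit == 0 and pt.child_or_pre == 1
        pt.contradiction_post = pt.contradiction_pre

    _check_budget(trace, g, doc_id)

    # stage 4: contradiction solver
    if g.solver_enabled:
        contradiction_solver(
            trace, g.solver_rule, g.solver_confidence_threshold
        )

    positive = {
        pt.parent_id
        for pt in trace.parents.values()
        if pt.parent_bit_post == 1
    }
    for pt in trace.parents.values():
        positive.update(
            cid for cid, bit in pt.child_bits_post.items() if bit == 1
        )
    pred = DocumentPrediction(
        labels=t.encode_labels(positive),
        per_category_responses=dict(trace.responses),
        cost=trace.cost,
        flags=flags,
        document_id=doc_id or None,
    )
    trace.flags = flags
    return pred, trace


def _run_flat(
    doc: str,
    t: Taxonomy,
    b: Backend,
    g: GraphConfig,
    doc_id: str,
    strict: bool,
) -> tuple[DocumentPrediction, ExecutionTrace]:
    """Flat matched-cost variant: one single-pass joint call predicting
    every parent and subtype, with no gating or reconciliation."""
    pred = classify_joint_document(doc, t, b, strict=strict,
                                   doc_id=doc_id or None)
    trace = ExecutionTrace(
        document_id=doc_id or "",
        responses=dict(pred.per_category_responses),
        cost=pred.cost,
        flags=set(pred.flags),
        pre_solver_logged=False,
    )
    labels = t.decode_labels(pred.labels)
    for parent in t.top_categories:
        bit = int(parent.id in labels)
        pt = ParentTrace(
            parent_id=parent.id,
            parent_bit=bit,
            parent_confidence=next(
                iter(pred.per_category_responses.values())
            ).confidence,
            parent_bit_post=bit,
        )
        for child in t.sub_categories(parent.id):
            cb = int(child.id in labels)
            pt.child_bits_pre[child.id] = cb
            pt.child_bits_post[child.id] = cb
        trace.parents[parent.id] = pt
    _check_budget(trace, g, doc_id)
    return pred, trace


def _check_budget(trace: ExecutionTrace, g: GraphConfig, doc_id: str) -> None:
    if (
        g.token_budget_cap is not None
        and trace.cost.total_tokens > g.token_budget_cap
    ):
        raise BudgetExceededError(
            doc_id or "?", trace.cost.total_tokens, g.token_budget_cap
        )
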