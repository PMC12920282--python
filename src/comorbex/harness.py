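"""Experiment harness: corpus-level runs, agreement reports, and the
component ablation protocol.

The ablation removes one graph component at a time — early judging,
contradiction solving, the hierarchy itself (flat single-pass variant at
matched cost), and parent→child context forwarding for atrial
fibrillation subtypes — and reports, per variant, top-level macro-F1,
post-solver hierarchical consistency (HCR; not applicable to the flat
variant), tokens per document, and deltas against the full-graph
baseline.  Deltas are always computed, never entered by hand.
"""

from __future__ import annotations

from dataclasses import dataclass

from .agent_graph import (
    ExecutionTrace,
    GraphConfig,
    count_contradictions,
    run_graph,
)
from .backend import Backend, CostLedger
from .metrics import (
    AgreementReport,
    cohen_kappa,
    contingency_from_pairs,
    cre,
    evaluate,
    hcr,
)
from .paradigms import DocumentPrediction
from .synthetic import SyntheticDocument
from .taxonomy import Taxonomy

__all__ = [
    "AblationResult",
    "ablation_variants",
    "run_graph_on_corpus",
    "agreement_report",
    "run_ablation",
]


def ablation_variants() -> dict[str, GraphConfig]:
    """The named graph variants of the component ablation."""
    return {
        "full": GraphConfig(),
        "no_judger": GraphConfig(judger_enabled=False),
        "no_solver": GraphConfig(solver_enabled=False),
        "flat_matched_cost": GraphConfig(hierarchy_enabled=False),
        "two_level_no_solver": GraphConfig(
            judger_enabled=False, solver_enabled=False
        ),
        "no_context_forwarding_af": GraphConfig(
            no_forwarding_parents=frozenset({"atrial_fibrillation"})
        ),
    }


def run_graph_on_corpus(
    corpus: list[SyntheticDocument],
    t: Taxonomy,
    b: Backend,
    g: GraphConfig,
) -> tuple[list[DocumentPrediction], list[ExecutionTrace]]:
    preds: list[DocumentPrediction] = []
    traces: list[ExecutionTrace] = []
    for doc in corpus:
        pred, trace = run_graph(doc.text, t, b, g, doc_id=doc.id)
        preds.append(pred)
        traces.append(trace)
    return preds, traces


def agreement_report(traces: list[ExecutionTrace]) -> AgreementReport:
    """Parent vs. child-OR agreement over all (document, parent) pairs
    of a run: percent agreement, Cohen's κ, HCR on post-solver output,
    and CRE when pre-solver states were logged."""
    pairs = [p for tr in traces for p in tr.pairs_post()]
    if not pairs:
        raise ValueError("no (document, parent) pairs in traces")
    kap = cohen_kappa(contingency_from_pairs(pairs))
    pre_logged = all(tr.pre_solver_logged for tr in traces)
    c_pre = (
        sum(count_contradictions(tr, "pre") for tr in traces)
        if pre_logged
        else 0
    )
    c_post = sum(count_contradictions(tr, "post") for tr in traces)
    return AgreementReport(
        p_o=kap.p_o,
        p_e=kap.p_e,
        kappa=kap.kappa,
        hcr=hcr(pairs),
        cre=cre(c_pre, c_post) if pre_logged else None,
        c_pre=c_pre,
        c_post=c_post,
    )


@dataclass(frozen=True)
class AblationResult:
    """One row of the ablation report: absolute metrics and deltas
    against the full-graph baseline."""

    variant: str
    macro_f1: float
    hcr: float | None  # None = n/a (flat variant has no hierarchy)
    cre: float | None
    tokens_per_doc: float
    delta_macro_f1: float
    delta_hcr: float | None
    delta_tokens_per_doc: float


def run_ablation(
    corpus: list[SyntheticDocument],
    t: Taxonomy,
    b: Backend,
    variants: dict[str, GraphConfig] | None = None,
    baseline: str = "full",
) -> list[AblationResult]:
    """Run every variant on the identical corpus and backend and report
    top-level macro-F1, post-solver HCR, tokens/document, CRE where
    pre-solver logs exist, and deltas versus the baseline variant."""
    if variants is None:
        variants = ablation_variants()
    if baseline not in variants:
        raise ValueError(f"baseline variant {baseline!r} missing")
    if not corpus:
        raise ValueError("empty corpus")

    top_ids = [c.id for c in t.top_categories]
    raw: dict[str, tuple[float, float | None, float | None, float]] = {}
    # baseline first so deltas are available
    order = [baseline] + [v for v in variants if v != baseline]
    for name in order:
        cfg = variants[name]
        preds, traces = run_graph_on_corpus(corpus, t, b, cfg)
        report = evaluate(
            preds, [d.gold for d in corpus], t, classes=top_ids
        )
        ledger = CostLedger(documents=len(corpus))
        for pred in preds:
            ledger = CostLedger(
                calls=ledger.calls + pred.cost.calls,
                prompt_tokens=ledger.prompt_tokens + pred.cost.prompt_tokens,
                completion_tokens=ledger.completion_tokens
                + pred.cost.completion_tokens,
                documents=len(corpus),
            )
        if cfg.hierarchy_enabled:
            agg = agreement_report(traces)
            hcr_value: float | None = agg.hcr
            cre_value = agg.cre
        else:
            hcr_value = None
            cre_value = None
        raw[name] = (
            report.macro_f1,
            hcr_value,
            cre_value,
            ledger.tokens_per_document,
        )

    base_f1, base_hcr, _, base_tok = raw[baseline]
    results = []
    for name in order:
        f1, hcr_value, cre_value, tok = raw[name]
        results.append(
            AblationResult(
                variant=name,
                macro_f1=f1,
                hcr=hcr_value,
                cre=cre_value,
                tokens_per_doc=tok,
                delta_macro_f1=f1 - base_f1,
                delta_hcr=(
                    hcr_value - base_hcr
                    if hcr_value is not None and base_hcr is not None
                    else None
                ),
                delta_tokens_per_doc=tok - base_tok,
            )
        )
    return results


def ablation_table(results: list[AblationResult]) -> str:
    """Render ablation results as an aligned TSV table
    (variant, M-F1, ΔM-F1, HCR, ΔHCR, tok/doc, Δtok/doc)."""
    lines = ["variant\tmacro_f1\td_macro_f1\thcr\td_hcr\ttok_per_doc\td_tok_per_doc"]
    for r in results:
        hcr_cell = "n/a" if r.hcr is None else f"{r.hcr:.3f}"
        dhcr_cell = "n/a" if r.delta_hcr is None else f"{r.delta_hcr:+.3f}"
        lines.append(
            f"{r.variant}\t{r.macro_f1:.3f}\t{r.delta_macro_f1:+.3f}"
            f"\t{hcr_cell}\t{dhcr_cell}"
            f"\t{r.tokens_per_doc:.1f}\t{r.delta_tokens_per_doc:+.1f}"
        )
    return "\n".join(lines) + "\n"
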