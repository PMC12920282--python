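"""Losses, agreement statistics, and evaluation reports.

Implements the full metric suite for hierarchical multi-label
comorbidity classification:

* **Hamming loss** — fraction of mismatched bits over parents and
  children jointly;
* **hierarchical consistency penalty** — count of child-positive /
  parent-negative positions in a single prediction vector;
* **Cohen's κ** with percent agreement ``p_o`` and expected agreement
  ``p_e`` over the parent vs. child-OR 2×2 contingency table;
* **HCR** (hierarchical consistency rate) — 1 minus the fraction of
  (document, parent) pairs where the child OR is positive but the
  parent is negative, computed on post-solver predictions;
* **CRE** (contradiction resolution efficacy) — fraction of pre-solver
  contradictions the solver eliminated; undefined when none existed;
* per-class precision/recall/F1 with support, macro and micro averages.

Degenerate cases carry explicit *undefined* markers (``None``, rendered
as an em-dash in tables) rather than imputed numbers: κ when expected
agreement is 1, CRE when no pre-solver contradictions existed, and
per-class P/R/F1 when a class has zero positive gold instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .taxonomy import LabelVector, Taxonomy

__all__ = [
    "Contingency2x2",
    "KappaResult",
    "AgreementReport",
    "ClassMetrics",
    "MetricsReport",
    "hamming_loss",
    "hier_penalty",
    "cohen_kappa",
    "hcr",
    "cre",
    "contingency_from_pairs",
    "evaluate",
    "UNDEFINED_MARK",
]

UNDEFINED_MARK = "—"  # em-dash used when rendering undefined metrics


@dataclass(frozen=True)
class Contingency2x2:
    """Parent vs. child-OR agreement table over (document, parent) pairs.

    ``a``: parent=1, child-OR=1; ``b``: parent=1, child-OR=0;
    ``c``: parent=0, child-OR=1 (the contradiction cell);
    ``d_cell``: parent=0, child-OR=0.
    """

    a: int
    b: int
    c: int
    d_cell: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d_cell) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d_cell


@dataclass(frozen=True)
class KappaResult:
    p_o: float
    p_e: float
    kappa: float | None  # None when p_e == 1 (chance agreement saturated)


def cohen_kappa(tbl: Contingency2x2) -> KappaResult:
    """Cohen's κ between the parent rater and the child-OR rater.

    ``p_o = (a + d)/n``;
    ``p_e = ((a+b)/n)((a+c)/n) + ((c+d)/n)((b+d)/n)``;
    ``κ = (p_o - p_e)/(1 - p_e)``, undefined when ``p_e = 1``.
    """
    n = tbl.n
    if n == 0:
        raise ValueError("empty contingency table")
    p_o = (tbl.a + tbl.d_cell) / n
    p_e = ((tbl.a + tbl.b) / n) * ((tbl.a + tbl.c) / n) + (
        (tbl.c + tbl.d_cell) / n
    ) * ((tbl.b + tbl.d_cell) / n)
    if p_e == 1.0:
        return KappaResult(p_o=p_o, p_e=p_e, kappa=None)
    return KappaResult(p_o=p_o, p_e=p_e, kappa=(p_o - p_e) / (1.0 - p_e))


def contingency_from_pairs(
    pairs: list[tuple[int, int]]
) -> Contingency2x2:
    """Build the 2×2 table from (parent bit, child-OR bit) pairs."""
    a = sum(1 for p, c in pairs if p == 1 and c == 1)
    b = sum(1 for p, c in pairs if p == 1 and c == 0)
    c_ = sum(1 for p, c in pairs if p == 0 and c == 1)
    d = sum(1 for p, c in pairs if p == 0 and c == 0)
    return Contingency2x2(a=a, b=b, c=c_, d_cell=d)


def hcr(pairs: list[tuple[int, int]]) -> float:
    """Hierarchical consistency rate over (parent, child-OR) bit pairs:
    1 − (#pairs with child-OR=1 and parent=0)/N, on post-solver output."""
    if not pairs:
        raise ValueError("HCR needs at least one (parent, child-OR) pair")
    contradictions = sum(1 for p, c in pairs if c == 1 and p == 0)
    return 1.0 - contradictions / len(pairs)


def cre(c_pre: int, c_post: int) -> float | None:
    """Fraction of pre-solver contradictions the solver eliminated.

    Returns ``None`` (undefined) when ``c_pre == 0``; raises if the
    solver *added* contradictions (``c_post > c_pre``).
    """
    if c_pre < 0 or c_post < 0:
        raise ValueError("contradiction counts must be non-negative")
    if c_post > c_pre:
        raise ValueError(
            f"solver added contradictions: C_post={c_post} > C_pre={c_pre}"
        )
    if c_pre == 0:
        return None
    return (c_pre - c_post) / c_pre


@dataclass(frozen=True)
class AgreementReport:
    """Agreement and consistency statistics over a prediction set."""

    p_o: float
    p_e: float
    kappa: float | None
    hcr: float
    cre: float | None
    c_pre: int
    c_post: int


# ---------------------------------------------------------------------------
# vector losses


def _check_aligned(pred: LabelVector, gold: LabelVector) -> None:
    if len(pred) != len(gold):
        raise ValueError(
            f"dimension mismatch: pred d={len(pred)}, gold d={len(gold)}"
        )


def hamming_loss(pred: LabelVector, gold: LabelVector) -> float:
    """Fraction of mismatched bits over parents and children jointly."""
    _check_aligned(pred, gold)
    return float(np.mean(pred.bits != gold.bits))


def hier_penalty(pred: LabelVector, t: Taxonomy) -> int:
    """Number of child positions set to 1 while their parent is 0."""
    bits = pred.bits
    if len(bits) != t.dimension():
        raise ValueError("vector does not match taxonomy dimension")
    penalty = 0
    for i, cat in enumerate(t.all_categories()):
        if cat.level == "sub" and bits[i] == 1:
            if bits[t.position(cat.parent_id)] == 0:
                penalty += 1
    return penalty


# ---------------------------------------------------------------------------
# classification reports


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class precision/recall/F1; all undefined when support is 0."""

    precision: float | None
    recall: float | None
    f1: float | None
    support: int
    accuracy: float
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def defined(self) -> bool:
        return self.support > 0


@dataclass
class MetricsReport:
    per_class: dict[str, ClassMetrics]
    macro_accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    accuracy: float
    hamming: float
    hier_penalty_total: int
    mode: str = "multi_label"
    flags: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        def cell(v: float | None) -> float | str:
            return UNDEFINED_MARK if v is None else round(float(v), 6)

        return {
            "mode": self.mode,
            "per_class": {
                cid: {
                    "precision": cell(cm.precision),
                    "recall": cell(cm.recall),
                    "f1": cell(cm.f1),
                    "support": cm.support,
                    "accuracy": round(cm.accuracy, 6),
                }
                for cid, cm in self.per_class.items()
            },
            "macro_accuracy": round(self.macro_accuracy, 6),
            "macro_precision": round(self.macro_precision, 6),
            "macro_recall": round(self.macro_recall, 6),
            "macro_f1": round(self.macro_f1, 6),
            "micro_precision": round(self.micro_precision, 6),
            "micro_recall": round(self.micro_recall, 6),
            "micro_f1": round(self.micro_f1, 6),
            "accuracy": round(self.accuracy, 6),
            "hamming": round(self.hamming, 6),
            "hier_penalty_total": self.hier_penalty_total,
        }

    def to_tsv(self) -> str:
        """Aligned per-class table plus the macro/micro block."""
        def cell(v: float | None) -> str:
            return UNDEFINED_MARK if v is None else f"{v:.3f}"

        lines = ["class\tprecision\trecall\tf1\tsupport"]
        for cid, cm in self.per_class.items():
            lines.append(
                f"{cid}\t{cell(cm.precision)}\t{cell(cm.recall)}"
                f"\t{cell(cm.f1)}\t{cm.support}"
            )
        lines.append("")
        for label, value in [
            ("macro_accuracy", self.macro_accuracy),
            ("macro_precision", self.macro_precision),
            ("macro_recall", self.macro_recall),
            ("macro_f1", self.macro_f1),
            ("micro_precision", self.micro_precision),
            ("micro_recall", self.micro_recall),
            ("micro_f1", self.micro_f1),
            ("accuracy", self.accuracy),
            ("hamming", self.hamming),
        ]:
            lines.append(f"{label}\t{value:.3f}")
        lines.append(f"hier_penalty_total\t{self.hier_penalty_total}")
        return "\n".join(lines) + "\n"


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def evaluate(
    preds,
    golds,
    t: Taxonomy,
    mode: str = "multi_label",
    classes: list[str] | None = None,
) -> MetricsReport:
    """Score predictions against gold labels over the taxonomy's classes.

    ``preds``/``golds`` are aligned lists of :class:`LabelVector` (or
    objects with a ``labels`` attribute holding one).  ``classes``
    restricts scoring to a subset of category ids (e.g. top level only);
    default is every category.

    Per-class precision/recall/F1 follow the zero-support convention:
    a class with no positive gold instance has all three undefined and
    is excluded from the macro averages.  With support but no predicted
    positives, precision is 0 (and F1 is 0 when P + R = 0).  Micro
    metrics pool TP/FP/FN across classes.  In
    ``exclusive_single_label`` mode each document must carry exactly
    one positive bit in gold and prediction; micro precision, recall
    and F1 then all equal overall accuracy.
    """
    if mode not in ("multi_label", "exclusive_single_label"):
        raise ValueError(f"unknown evaluation mode {mode!r}")
    pred_vecs = [p.labels if hasattr(p, "labels") else p for p in preds]
    gold_vecs = [g.labels if hasattr(g, "labels") else g for g in golds]
    if len(pred_vecs) != len(gold_vecs):
        raise ValueError(
            f"{len(pred_vecs)} predictions vs {len(gold_vecs)} golds"
        )
    if not pred_vecs:
        raise ValueError("nothing to evaluate")

    order = [c.id for c in t.all_categories()]
    if classes is None:
        classes = order
    else:
        unknown = [c for c in classes if c not in order]
        if unknown:
            raise ValueError(f"unknown class ids: {unknown}")
    col = {cid: i for i, cid in enumerate(order)}
    cols = [col[cid] for cid in classes]

    P = np.stack([v.bits for v in pred_vecs])[:, cols]
    G = np.stack([v.bits for v in gold_vecs])[:, cols]
    n_docs = P.shape[0]

    if mode == "exclusive_single_label":
        if not ((P.sum(axis=1) == 1).all() and (G.sum(axis=1) == 1).all()):
            raise ValueError(
                "exclusive_single_label mode requires exactly one positive "
                "label per document in both gold and prediction"
            )

    per_class: dict[str, ClassMetrics] = {}
    tp_sum = fp_sum = fn_sum = 0
    for j, cid in enumerate(classes):
        tp = int(np.sum((P[:, j] == 1) & (G[:, j] == 1)))
        fp = int(np.sum((P[:, j] == 1) & (G[:, j] == 0)))
        fn = int(np.sum((P[:, j] == 0) & (G[:, j] == 1)))
        tn = int(np.sum((P[:, j] == 0) & (G[:, j] == 0)))
        support = tp + fn
        acc = (tp + tn) / n_docs
        if support == 0:
            cm = ClassMetrics(None, None, None, 0, acc, tp, fp, fn, tn)
        else:
            prec = _safe_div(tp, tp + fp)
            rec = tp / support
            f1 = _safe_div(2 * prec * rec, prec + rec)
            cm = ClassMetrics(prec, rec, f1, support, acc, tp, fp, fn, tn)
        per_class[cid] = cm
        tp_sum += tp
        fp_sum += fp
        fn_sum += fn

    defined = [cm for cm in per_class.values() if cm.defined]
    macro_precision = (
        float(np.mean([cm.precision for cm in defined])) if defined else 0.0
    )
    macro_recall = (
        float(np.mean([cm.recall for cm in defined])) if defined else 0.0
    )
    macro_f1 = float(np.mean([cm.f1 for cm in defined])) if defined else 0.0
    macro_accuracy = float(np.mean([cm.accuracy for cm in per_class.values()]))

    micro_precision = _safe_div(tp_sum, tp_sum + fp_sum)
    micro_recall = _safe_div(tp_sum, tp_sum + fn_sum)
    micro_f1 = _safe_div(
        2 * micro_precision * micro_recall, micro_precision + micro_recall
    )

    if mode == "exclusive_single_label":
        accuracy = float(np.mean((P == G).all(axis=1)))
    else:
        accuracy = float(np.mean(P == G))  # bitwise accuracy = 1 - hamming

    ham = float(np.mean(P != G))
    penalty = sum(
        hier_penalty(v, t) for v in pred_vecs
    ) if classes == order else 0

    return MetricsReport(
        per_class=per_class,
        macro_accuracy=macro_accuracy,
        macro_precision=macro_precision,
        macro_recall=macro_recall,
        macro_f1=macro_f1,
        micro_precision=micro_precision,
        micro_recall=micro_recall,
        micro_f1=micro_f1,
        accuracy=accuracy,
        hamming=ham,
        hier_penalty_total=penalty,
        mode=mode,
    )
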