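"""Seeded synthetic clinical-note corpora with known gold labels.

The generator emulates the documented hard phenomena of comorbidity
extraction from sleep-medicine narratives: multimorbidity co-occurrence,
lexical variability and abbreviations ("HTN"), German surface forms
("arterielle Hypertonie"), medication/device/metric proxy mentions
("PAP therapy", "AHI 32/h", "on statin"), negated mentions ("no history
of hypertension"), and resolved-temporality mentions ("previously
diagnosed with ..., now controlled").  Negated and resolved mentions are
*label-0 traps*: they put the surface form in the text without setting
the gold bit.

Gold labels are hierarchy-consistent by construction (a positive child
forces its parent), every positive bit has at least one generating
sentence, and identical spec + seed yields a byte-identical corpus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .taxonomy import Category, LabelVector, Taxonomy

__all__ = [
    "CorpusSpec",
    "SyntheticDocument",
    "default_corpus_spec",
    "generate_corpus",
    "read_corpus",
    "write_corpus",
    "CorpusFormatError",
]


class CorpusFormatError(ValueError):
    """Malformed corpus file or record."""


_RATE_FIELDS = (
    "negation_rate",
    "abbreviation_rate",
    "proxy_rate",
    "temporality_rate",
    "distractor_rate",
    "language_mix",
)


@dataclass(frozen=True)
class CorpusSpec:
    """Generation parameters for one synthetic corpus.

    ``prevalence`` maps top-level category ids to marginal probabilities;
    ``child_given_parent`` maps child ids to conditional probabilities
    (``default_child_rate`` fills the rest); ``cooccurrence_boost`` maps
    unordered parent-id pairs to multiplicative prevalence boosts applied
    once a partner has been sampled positive.
    """

    n_documents: int = 250
    prevalence: dict[str, float] = field(default_factory=dict)
    child_given_parent: dict[str, float] = field(default_factory=dict)
    default_child_rate: float = 0.25
    cooccurrence_boost: dict[tuple[str, str], float] = field(
        default_factory=dict
    )
    negation_rate: float = 0.2
    abbreviation_rate: float = 0.2
    proxy_rate: float = 0.15
    temporality_rate: float = 0.1
    distractor_rate: float = 0.3
    language_mix: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_documents < 0:
            raise ValueError("n_documents must be >= 0")
        for name in _RATE_FIELDS + ("default_child_rate",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for cid, p in {**self.prevalence, **self.child_given_parent}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {cid!r} outside [0, 1]")


def default_corpus_spec(n_documents: int = 250, seed: int = 0) -> CorpusSpec:
    """Study-condition corpus: class prevalences typical of a tertiary
    sleep-clinic cohort, modest cardiometabolic co-occurrence, and all
    hard phenomena at their default rates."""
    return CorpusSpec(
        n_documents=n_documents,
        prevalence={
            "sleep_disordered_breathing": 0.55,
            "hypertension": 0.35,
            "dyslipidemia": 0.25,
            "diabetes": 0.15,
            "atrial_fibrillation": 0.10,
            "ischemic_stroke_tia": 0.10,
        },
        child_given_parent={
            "osa": 0.70,
            "central_sleep_apnoea": 0.10,
            "diabetes_type_2": 0.60,
            "diabetes_type_1": 0.05,
            "essential_hypertension": 0.30,
        },
        cooccurrence_boost={
            ("sleep_disordered_breathing", "hypertension"): 1.3,
            ("diabetes", "dyslipidemia"): 1.4,
            ("atrial_fibrillation", "ischemic_stroke_tia"): 1.5,
        },
        seed=seed,
    )


@dataclass(frozen=True)
class SyntheticDocument:
    """One generated note: text, gold labels, and per-sentence tags."""

    id: str
    text: str
    gold: LabelVector
    provenance: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# sentence banks

_OPENERS = (
    "Patient referred for evaluation of a suspected sleep disorder.",
    "Follow-up visit at the sleep laboratory.",
    "Polysomnography report and clinical history.",
)
_POSITIVE_TEMPLATES = (
    "History of {term}.",
    "Known {term}.",
    "The patient has {term}.",
    "Diagnosis: {term}.",
)
_PROXY_TEMPLATES = (
    "Ongoing treatment: {term}.",
    "Currently {term}.",
    "Note: {term}.",
)
_NEGATION_TEMPLATES = (
    "No history of {term}.",
    "Denies {term}.",
    "No evidence of {term}.",
    "Kein Hinweis auf {term}.",
)
_TEMPORALITY_TEMPLATES = (
    "Previously diagnosed with {term}, now controlled.",
    "History of {term}, resolved.",
)
_DISTRACTORS = (
    "Reports excessive daytime sleepiness.",
    "Non-smoker, moderate alcohol consumption.",
    "Epworth Sleepiness Scale score 11/24.",
    "Normal thyroid function tests.",
    "Works rotating night shifts.",
    "Family history unremarkable.",
)


def _pick_term(
    cat: Category, spec: CorpusSpec, rng: np.random.Generator
) -> tuple[str, str]:
    """Choose a surface form for a positive mention; returns
    (term, provenance tag).  One uniform draw selects the variant kind
    by the spec rates; kinds without entries fall back to canonical."""
    u = rng.random()
    kind = "canonical"
    if u < spec.proxy_rate and cat.terms(("proxy",)):
        kind = "proxy"
    elif u < spec.proxy_rate + spec.abbreviation_rate and cat.terms(
        ("abbreviation",)
    ):
        kind = "abbreviation"
    elif (
        u < spec.proxy_rate + spec.abbreviation_rate + spec.language_mix
        and cat.terms(("german",))
    ):
        kind = "german"
    terms = cat.terms((kind,)) or cat.terms(("canonical",)) or cat.terms()
    term = terms[int(rng.integers(len(terms)))]
    tag = "proxy" if kind == "proxy" else "positive-mention"
    return term, tag


def _trap_term(cat: Category, rng: np.random.Generator) -> str:
    terms = cat.terms(("canonical",)) or cat.terms()
    return terms[int(rng.integers(len(terms)))]


def _sample_parents(
    t: Taxonomy, spec: CorpusSpec, rng: np.random.Generator
) -> set[str]:
    positive: set[str] = set()
    boost_index: dict[str, list[tuple[str, float]]] = {}
    for (x, y), mult in spec.cooccurrence_boost.items():
        boost_index.setdefault(x, []).append((y, mult))
        boost_index.setdefault(y, []).append((x, mult))
    for parent in t.top_categories:
        p = spec.prevalence.get(parent.id, 0.0)
        for partner, mult in boost_index.get(parent.id, []):
            if partner in positive:
                p *= mult
        if rng.random() < min(p, 1.0):
            positive.add(parent.id)
    return positive


def generate_corpus(
    spec: CorpusSpec, t: Taxonomy
) -> list[SyntheticDocument]:
    """Generate ``spec.n_documents`` seeded synthetic notes.

    Per document: sample parent labels by prevalence (with co-occurrence
    boosts), sample children conditionally on their parent, render one
    sentence per positive label in a surface form chosen by the spec
    rates, then inject negation traps and resolved-temporality traps for
    gold-negative top-level categories and distractor sentences, and
    shuffle the body.  Deterministic under ``spec.seed``.
    """
    unknown = [
        cid
        for cid in list(spec.prevalence) + list(spec.child_given_parent)
        if cid not in t
    ]
    if unknown:
        raise ValueError(f"spec references unknown categories: {unknown}")
    bad_parents = [
        cid for cid in spec.prevalence if t.get(cid).level != "top"
    ]
    if bad_parents:
        raise ValueError(f"prevalence given for non-top categories: {bad_parents}")

    rng = np.random.default_rng(spec.seed)
    docs: list[SyntheticDocument] = []
    for idx in range(spec.n_documents):
        positive = _sample_parents(t, spec, rng)
        for pid in sorted(positive):
            for child in t.sub_categories(pid):
                p = spec.child_given_parent.get(
                    child.id, spec.default_child_rate
                )
                if rng.random() < p:
                    positive.add(child.id)

        body: list[tuple[str, str]] = []  # (sentence, provenance tag)
        for cat in t.all_categories():
            if cat.id not in positive:
                continue
            term, tag = _pick_term(cat, spec, rng)
            templates = (
                _PROXY_TEMPLATES if tag == "proxy" else _POSITIVE_TEMPLATES
            )
            tpl = templates[int(rng.integers(len(templates)))]
            body.append((tpl.format(term=term), tag))

        for parent in t.top_categories:
            if parent.id in positive:
                continue
            if rng.random() < spec.negation_rate:
                tpl = _NEGATION_TEMPLATES[
                    int(rng.integers(len(_NEGATION_TEMPLATES)))
                ]
                body.append(
                    (tpl.format(term=_trap_term(parent, rng)), "negated")
                )
            if rng.random() < spec.temporality_rate:
                tpl = _TEMPORALITY_TEMPLATES[
                    int(rng.integers(len(_TEMPORALITY_TEMPLATES)))
                ]
                body.append(
                    (tpl.format(term=_trap_term(parent, rng)), "negated")
                )
        if rng.random() < spec.distractor_rate:
            body.append(
                (
                    _DISTRACTORS[int(rng.integers(len(_DISTRACTORS)))],
                    "distractor",
                )
            )

        rng.shuffle(body)
        opener = _OPENERS[int(rng.integers(len(_OPENERS)))]
        sentences = [(opener, "distractor")] + body
        docs.append(
            SyntheticDocument(
                id=f"doc{idx:05d}",
                text=" ".join(s for s, _ in sentences),
                gold=t.encode_labels(positive),
                provenance=tuple(tag for _, tag in sentences),
            )
        )
    return docs


# ---------------------------------------------------------------------------
# corpus I/O (line-delimited JSON)


def write_corpus(corpus: list[SyntheticDocument], path, t: Taxonomy) -> None:
    """Write a corpus as line-delimited JSON records
    ``{id, text, labels, provenance}``."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus:
            record = {
                "id": doc.id,
                "text": doc.text,
                "labels": sorted(t.decode_labels(doc.gold)),
                "provenance": list(doc.provenance),
            }
            fh.write(json.dumps(record, ensure_ascii=False) + "\n")


def read_corpus(path, t: Taxonomy) -> list[SyntheticDocument]:
    """Read a line-delimited corpus; rejects malformed lines and unknown
    label ids with the offending line number."""
    docs: list[SyntheticDocument] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(
                    f"line {lineno}: invalid JSON ({exc})"
                ) from exc
            for key in ("id", "text", "labels"):
                if key not in record:
                    raise CorpusFormatError(
                        f"line {lineno}: missing field {key!r}"
                    )
            labels = record["labels"]
            unknown = [cid for cid in labels if cid not in t]
            if unknown:
                raise CorpusFormatError(
                    f"line {lineno}: unknown label ids {unknown}"
                )
            docs.append(
                SyntheticDocument(
                    id=str(record["id"]),
                    text=str(record["text"]),
                    gold=t.encode_labels(labels),
                    provenance=tuple(record.get("provenance", ())),
                )
            )
    return docs
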