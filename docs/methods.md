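# Methods

## Problem and scope

`comorbex` treats comorbidity extraction from a clinical note as
multi-label classification over a fixed two-level taxonomy: `m`
top-level comorbidity categories, each with `n_i` subtypes, encoded as a
binary vector of length `d = m + Σ n_i` (parents first, then each
parent's children contiguously, in configuration order).  The shipped
taxonomy covers the six comorbidity groups most relevant to sleep-wake
disorder cohorts — ischemic stroke/TIA, diabetes, dyslipidemia,
hypertension, atrial fibrillation, and sleep-disordered breathing — with
29 subtypes (d = 35).  The package's subject is the *architecture* of
the extraction pipeline: how gating, uncertainty handling, contradiction
resolution, and prompting strategy shape accuracy, internal consistency,
and cost.  It does not ship or require a language model; the classifier
is an injectable backend contract, and all shipped backends are
deterministic desk-scale reference implementations.

## Classifier backends

A backend maps one request (document, category, rendered question; kind
binary, multi-choice, or joint) to one response (raw reply token, mapped
decision, confidence 0–100, token counts, optional evidence span).  Raw
reply tokens are normalized (trim, strip terminal punctuation,
case-fold) and mapped through disjoint response-token sets — positives
{True, Yes, \_\_YES\_\_}, negatives {False, No, \_\_NO\_\_}; anything
else is *unmapped*.  Lenient mode records unmapped replies as negative
with a flag so pipelines complete; strict mode raises.  The lenient
default mirrors conservative production behaviour (precision preserved,
failures visible); the choice is this package's convention.

**Lexicon backend.**  Scans the document for the category's surface
forms (canonical terms, abbreviations, German variants, and
treatment/measurement proxies, shipped in the taxonomy configuration).
Matching is word-boundary-aware; short all-caps abbreviations (≤5
characters, e.g. "AF", "HTN") match case-sensitively so they cannot fire
inside ordinary words.  A match does not count when its *sentence*
contains a negation or resolved-temporality cue ("no history of",
"denies", "kein", "previously", "resolved", …); the sentence is the
negation window, a deliberate simplification of scope detection that
emulates the effect of negation instructions rather than their
mechanism.  Decisions carry confidence 100 (configurable) — the
confidence channel is synthetic, standing in for token-probability
scores a language model would provide; this keeps the
confidence-thresholded judge and solver fully testable.

**Noisy backend.**  Wraps any backend and flips each binary decision
independently with probability ε, using a SHA-256-keyed uniform draw per
(seed, document, category) — bit-reproducible across runs and platforms
and identical for a given (document, category) pair regardless of
paradigm.  Flipped answers carry confidence 55 (default), i.e. below the
default judger threshold.  List-type replies flip each option's
membership with the same per-option stream.

**Cost model.**  Prompt cost is the whitespace-token count of question +
document; completions count 1 token per decision (one per named id for
list replies).  This is a monotone proxy for model-tokenizer counts — it
preserves relative cost orderings between variants, which is what the
ablation compares; absolute token figures are not comparable to any
production system.

## Paradigms and call-count contracts

* `classify_flat`: d independent binary calls, no gating.
* `classify_two_level`: m parent calls, then children of positive
  parents only; the output structurally cannot contain a positive child
  under a negative parent.
* `classify_with_strategy` (per parent unit): context-forwarding
  multi-step binary issues 1+n calls and embeds the parent decision and
  evidence snippet verbatim in each subtype request; sequential
  refinement issues a binary parent call plus, if positive, one
  multi-choice call whose reply is a comma-delimited list of subtype ids
  (2 calls typical, 1 for a negative parent); joint label inference
  issues one multi-label call covering the parent and its subtypes.
  `classify_joint_document` extends joint inference to the whole
  taxonomy in one call.  The delimited-id reply format is this package's
  definition (replies must be machine-checkable and ids avoid synonym
  ambiguity); a parser validates ids, dropping unknown ones with a flag
  in lenient mode.

These counts are contracts, enforced by property tests over random
taxonomies with a counting backend.

## Agent graph

The graph generalizes the two-level paradigm into four stages: parent
agents; an optional *result judger* that flags parents as uncertain when
their reply was unmapped or their confidence is below τ (default 60);
sub-agents for every positive **or uncertain** parent, with optional
context forwarding (globally or per-parent disabled); and an optional
*contradiction solver*.  Under strict gating a child-positive/
parent-negative state could never arise; the judger's scheduling of
uncertain negative parents is the package's mechanism for producing the
pre-solver contradictions the consistency metrics then quantify.  The
solver rule `promote_parent` sets the parent to 1 when the most
confident positive child reaches the solver threshold (default 70) —
the preferred rule, on the view that a confidently documented subtype is
evidence for its parent — and otherwise zeroes the offending children;
`suppress_children` always zeroes them.  The solver never touches
non-contradicting pairs, and with the threshold at 0, `C_post = 0` holds
identically.  Re-querying the backend from the judge is intentionally
not implemented (single-pass flagging only).

With `hierarchy_enabled=False` the graph becomes the flat matched-cost
variant: a **single-pass joint call** predicting all d labels at once —
no gating, judging, solving, or forwarding, and an optional token-budget
cap for matched-cost comparisons.  This single-pass reading is the
package's resolution of how a "flat" comparison can cost *less* than a
gated run: d separate binary calls would each re-send the document and
dominate any gated variant, whereas single-pass inference sends it once.
The d-call flat paradigm remains available separately as
`classify_flat`.

## Metrics

Hamming loss is the mismatched-bit fraction over all d positions.  The
hierarchical penalty counts child positions set to 1 under a parent set
to 0.  Agreement between the parent decision and the OR-merge of its
children is summarized over all (document, parent) pairs in a 2×2 table
(cells a, b, c, d): `p_o = (a+d)/n`,
`p_e = ((a+b)/n)((a+c)/n) + ((c+d)/n)((b+d)/n)`,
`κ = (p_o − p_e)/(1 − p_e)`, undefined (explicit marker, not a number)
when `p_e = 1`.  `HCR = 1 − c/n` on post-solver predictions;
`CRE = (C_pre − C_post)/C_pre`, undefined when `C_pre = 0` and an error
if a solver ever *added* contradictions.

Per-class precision/recall/F1 carry support (positive gold count); a
zero-support class has all three undefined, rendered as an em-dash and
**excluded from macro averages** rather than imputed as 0.  With support
but no predicted positives, precision is 0; F1 is 0 when P + R = 0.
Per-class accuracy is (TP+TN)/N over documents, and macro accuracy
averages it over all classes (accuracy is defined regardless of
support).  Micro metrics pool TP/FP/FN.  In the exclusive single-label
mode (one positive label per document in gold and prediction, validated)
micro precision = micro recall = micro F1 = overall accuracy; the
implementation asserts this identity on every such evaluation.  All
metric implementations are cross-checked in the test suite against
scikit-learn and brute-force positional counts to 1e-12; scikit-learn is
used only as an independent oracle, never as the implementation.

## Synthetic corpus generator

The generator produces seeded notes with known gold labels.  Parent
labels are sampled from configured marginal prevalences, with optional
pairwise co-occurrence boosts (multiplicative, applied once a partner is
already positive, probabilities clipped to 1); children are sampled
conditionally on a positive parent, so gold labels are
hierarchy-consistent by construction.  Each positive label generates
exactly one sentence whose surface form is chosen by configurable rates
among canonical term, abbreviation, German variant, and proxy.
Gold-negative top-level categories receive negation traps ("No history
of hypertension.") and resolved-temporality traps ("Previously diagnosed
with …, now controlled.") at configurable rates; distractor sentences
add label-free filler.  Gold follows document-level assertion semantics:
negated and resolved mentions are label 0.  Sentence order is shuffled
under the seed; identical spec + seed yields a byte-identical corpus.

The default study spec uses prevalences chosen as realistic for a
tertiary sleep-clinic cohort — sleep-disordered breathing 0.55,
hypertension 0.35, dyslipidemia 0.25, diabetes 0.15, atrial fibrillation
0.10, ischemic stroke/TIA 0.10 — with modest cardiometabolic
co-occurrence boosts and all trap phenomena active.  No public
prevalence table exists for the restricted registries this emulates;
these are the package's own fixed choices and are not tuned thereafter.

The shipped lexicons are constructed to be collision-free: no category's
surface form can fire inside a sentence generated for an unrelated
category (parent terms inside their own children's terms are fine, since
a positive child forces a positive parent in gold).  This makes the
lexicon backend on a trap-free corpus an *exact oracle* — two-level
classification recovers gold with F1 = 1.0 — which in turn makes
downstream tests sharp: any deviation from perfect recovery localizes a
defect in gating, solving, or encoding, and injected noise or disabled
negation handling produce exactly calibrated degradations (recall ≈ 1−ε
under flip rate ε; precision loss proportional to trap rate).

**What passing these tests does not show:** real clinical text has
misspellings, unseen synonyms, cross-sentence negation scope, hedging,
and family-history attribution that neither the generator nor the
lexicon backend models.  Results on synthetic corpora validate the
*pipeline machinery*, not extraction quality on real notes.

## Numerical and design choices

* Judger threshold τ = 60, solver threshold 70, rule `promote_parent` —
  package defaults for the confidence scale [0, 100], not empirical
  values.
* Undefined statistics are `None` in reports and em-dashes in tables;
  they are never silently coerced to 0.
* Ablation variants (`full`, `no_judger`, `no_solver`,
  `flat_matched_cost`, `two_level_no_solver`,
  `no_context_forwarding_af`) all run on the identical corpus, backend,
  and seed; deltas are recomputed from the measured values.
* Test problem sizes (500-document corpora for recovery and noise
  checks, 1000 random instances for metric equivalence, 2000 documents
  for prevalence calibration) were chosen as the smallest sizes at which
  the binomial 3-standard-deviation bands are informative.
* Category ids are fixed lowercase snake-case slugs; stable join keys
  across corpora, predictions, and reports.
* The taxonomy ships all 29 subtypes; narrower profiles can be expressed
  as alternative configuration files without code changes.

## Known limitations

* The sentence-scoped negation window cannot represent sub-sentence
  scope ("no diabetes but known hypertension" in one sentence would
  suppress both) or cross-sentence anaphora.
* Whitespace token counts understate multi-byte/tokenizer effects; only
  relative costs are meaningful.
* The solver resolves one level; deeper hierarchies would need
  transitive promotion.
* German coverage is surface-form substitution only; no inflection or
  word-order modeling.
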