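"""Compare the per-document call counts of the three hierarchical
prompting strategies on one document, using a counting backend.

Expected counts: context-forwarding multi-step binary 1+n (n subtypes),
sequential refinement 2 (positive parent, one refinement round), joint
label inference 1 (single-shot multi-label).
"""

import comorbex as cx

taxonomy = cx.load_default_taxonomy()
doc = "Known persistent atrial fibrillation, anticoagulated with apixaban."
af = taxonomy.get("atrial_fibrillation")  # 3 subtypes

counting = cx.CountingBackend(cx.LexiconBackend(taxonomy))

for strategy in cx.StrategyKind:
    counting.reset()
    if strategy is cx.StrategyKind.JOINT_LABEL_INFERENCE:
        pred = cx.classify_joint_document(doc, taxonomy, counting)
    else:
        pred = cx.classify_with_strategy(doc, af, taxonomy, counting,
                                         strategy)
    labels = sorted(taxonomy.decode_labels(pred.labels))
    print(f"{strategy.value:40s} calls={counting.calls}  labels={labels}")

print()
print("Fewer calls mean lower token cost but less contextual grounding:")
print("context forwarding spends 1+n calls and hands the parent decision")
print("and evidence to each subtype query; joint inference answers")
print("everything in one shot.")
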