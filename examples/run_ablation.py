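"""Component ablation of the agent graph on a staged corpus.

Removes one component at a time (early judge, contradiction solver,
hierarchy, context forwarding for atrial-fibrillation subtypes) and
prints top-level macro-F1, hierarchical consistency (HCR), tokens per
document, and deltas against the full-graph baseline.
"""

import comorbex as cx
from comorbex.backend import NEGATIVE
from comorbex.harness import ablation_table

taxonomy = cx.load_default_taxonomy()
inner = cx.LexiconBackend(taxonomy)


def under_confident_sdb(req):
    """Stages contradictions: the SDB parent agent is wrong and unsure."""
    resp = inner(req)
    if (req.kind == "binary"
            and req.category_id == "sleep_disordered_breathing"):
        return cx.BackendResponse(
            raw_token="False", decision=NEGATIVE, confidence=55.0,
            prompt_tokens=resp.prompt_tokens, completion_tokens=1)
    return resp


spec = cx.default_corpus_spec(n_documents=80, seed=17)
corpus = cx.generate_corpus(spec, taxonomy)
results = cx.run_ablation(corpus, taxonomy, under_confident_sdb)

print(ablation_table(results))
print("Disabling the solver leaves child-positive/parent-negative pairs")
print("unresolved (lower HCR); disabling the judge also removes the")
print("recovery path for the under-confident parent (lower macro-F1);")
print("the flat single-pass variant is cheapest in tokens but has no")
print("notion of hierarchical consistency (HCR n/a).")
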