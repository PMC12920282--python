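"""Agreement and consistency metrics on a staged contradiction scenario.

Runs the agent graph over a small corpus with a backend whose
sleep-disordered-breathing parent agent is systematically
under-confident (negative at confidence 55).  The early judge schedules
the sub-agents anyway, the subtype agents fire on the textual evidence,
and the contradiction solver promotes the parent.  The run is summarized
as percent agreement, Cohen's kappa, HCR, and CRE.
"""

import comorbex as cx
from comorbex.backend import NEGATIVE

taxonomy = cx.load_default_taxonomy()
inner = cx.LexiconBackend(taxonomy)


def under_confident_sdb(req):
    resp = inner(req)
    if (req.kind == "binary"
            and req.category_id == "sleep_disordered_breathing"):
        return cx.BackendResponse(
            raw_token="False", decision=NEGATIVE, confidence=55.0,
            prompt_tokens=resp.prompt_tokens, completion_tokens=1)
    return resp


spec = cx.default_corpus_spec(n_documents=100, seed=9)
corpus = cx.generate_corpus(spec, taxonomy)

_, traces = cx.run_graph_on_corpus(corpus, taxonomy, under_confident_sdb,
                                   cx.GraphConfig())
report = cx.agreement_report(traces)

print(f"(document, parent) pairs: {len(corpus) * taxonomy.m}")
print(f"percent agreement p_o = {report.p_o:.3f}")
print(f"expected agreement p_e = {report.p_e:.3f}")
print(f"Cohen's kappa          = {report.kappa:.3f}")
print(f"HCR (post-solver)      = {report.hcr:.3f}")
print(f"C_pre = {report.c_pre}, C_post = {report.c_post}, "
      f"CRE = {report.cre}")
print()
print("Every pre-solver contradiction (child subtype positive while the")
print("parent agent said no) was resolved by promoting the parent, so")
print("HCR is 1.0 and CRE is 1.0; kappa measures how well the parent")
print("decisions agree with the OR of their subtype decisions.")
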