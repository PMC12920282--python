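"""Call-count contracts, gating behavior, and prompt construction."""

import pytest
from hypothesis import given, settings, strategies as st

import comorbex as cx
from comorbex.backend import NEGATIVE, POSITIVE


class ConstantBackend:
    """Answers every binary question with a fixed decision; multi-label
    questions name all options (positive) or none (negative)."""

    def __init__(self, decision):
        self.decision = decision

    def __call__(self, req):
        positive = self.decision == POSITIVE
        raw = ", ".join(req.options) if (req.options and positive) else (
            "True" if positive else "False"
        )
        return cx.BackendResponse(
            raw_token=raw if req.options else ("True" if positive else "False"),
            decision=self.decision,
            confidence=100,
            prompt_tokens=len(req.question_text.split())
            + len(req.document_text.split()),
            completion_tokens=1,
        )


def random_taxonomy(m, n_per_parent):
    lines = ["categories:"]
    for i in range(m):
        lines.append(f"  - {{id: p{i}, name: P{i}}}")
        for j in range(n_per_parent[i]):
            lines.append(f"  - {{id: p{i}c{j}, name: P{i}C{j}, parent: p{i}}}")
    return cx.load_taxonomy("\n".join(lines))


class TestFlatParadigm:
    def test_issues_exactly_d_calls(self, taxonomy, lexicon_backend):
        counting = cx.CountingBackend(lexicon_backend)
        cx.classify_flat("Known hypertension.", taxonomy, counting)
        assert counting.calls == taxonomy.dimension() == 35

    def test_empty_document_all_zero(self, taxonomy, lexicon_backend):
        pred = cx.classify_flat("", taxonomy, lexicon_backend)
        assert pred.labels.bits.sum() == 0

    def test_no_gating_suppresses_children(self, taxonomy, lexicon_backend):
        # flat mode answers the child question even under a negative parent
        doc = "Hypertensive heart disease."
        pred = cx.classify_flat(doc, taxonomy, lexicon_backend)
        labels = taxonomy.decode_labels(pred.labels)
        assert labels == {"hypertensive_heart_disease"}


class TestTwoLevelParadigm:
    def test_all_parents_negative_short_circuits(self, taxonomy):
        counting = cx.CountingBackend(ConstantBackend(NEGATIVE))
        pred = cx.classify_two_level("anything", taxonomy, counting)
        assert counting.calls == taxonomy.m == 6
        assert pred.labels.bits.sum() == 0

    def test_positive_parent_opens_its_children_only(
        self, taxonomy, lexicon_backend
    ):
        counting = cx.CountingBackend(lexicon_backend)
        pred = cx.classify_two_level(
            "Patient has obstructive sleep apnoea.", taxonomy, counting
        )
        n_sdb = taxonomy.n_children("sleep_disordered_breathing")
        assert counting.calls == 6 + n_sdb
        labels = taxonomy.decode_labels(pred.labels)
        assert labels == {"sleep_disordered_breathing", "osa"}

    def test_gated_output_never_contradicts(self, taxonomy, clean_corpus):
        backend = cx.NoisyBackend(
            cx.LexiconBackend(taxonomy), flip_rate=0.2, seed=3
        )
        for doc in clean_corpus[:100]:
            pred = cx.classify_two_level(doc.text, taxonomy, backend,
                                         doc_id=doc.id)
            assert cx.hier_penalty(pred.labels, taxonomy) == 0

    def test_parent_bits_agree_with_flat(self, taxonomy, clean_corpus):
        b = cx.LexiconBackend(taxonomy)
        for doc in clean_corpus[:50]:
            flat = cx.classify_flat(doc.text, taxonomy, b)
            gated = cx.classify_two_level(doc.text, taxonomy, b)
            assert (
                flat.labels.parent_bits.tolist()
                == gated.labels.parent_bits.tolist()
            )

    def test_flat_cost_at_least_two_level(self, taxonomy, clean_corpus):
        b = cx.LexiconBackend(taxonomy)
        for doc in clean_corpus[:20]:
            flat = cx.classify_flat(doc.text, taxonomy, b)
            gated = cx.classify_two_level(doc.text, taxonomy, b)
            assert flat.cost.calls >= gated.cost.calls

    @given(
        m=st.integers(min_value=1, max_value=5),
        data=st.data(),
        all_positive=st.booleans(),
    )
    @settings(max_examples=40, derandomize=True)
    def test_call_count_contract_random_taxonomies(
        self, m, data, all_positive
    ):
        n_per = [
            data.draw(st.integers(min_value=0, max_value=4)) for _ in range(m)
        ]
        t = random_taxonomy(m, n_per)
        decision = POSITIVE if all_positive else NEGATIVE
        counting = cx.CountingBackend(ConstantBackend(decision))
        cx.classify_two_level("doc", t, counting)
        expected = m + (sum(n_per) if all_positive else 0)
        assert counting.calls == expected
        counting.reset()
        cx.classify_flat("doc", t, counting)
        assert counting.calls == t.dimension()


class TestPromptingStrategies:
    def test_sequential_refinement_two_calls_typical(self, taxonomy):
        counting = cx.CountingBackend(cx.LexiconBackend(taxonomy))
        af = taxonomy.get("atrial_fibrillation")
        pred = cx.classify_with_strategy(
            "Known persistent atrial fibrillation.",
            af,
            taxonomy,
            counting,
            cx.StrategyKind.SEQUENTIAL_REFINEMENT,
        )
        assert counting.calls == 2
        assert taxonomy.decode_labels(pred.labels) == {
            "atrial_fibrillation",
            "af_persistent",
        }

    def test_sequential_refinement_negative_parent_single_call(
        self, taxonomy
    ):
        counting = cx.CountingBackend(cx.LexiconBackend(taxonomy))
        af = taxonomy.get("atrial_fibrillation")
        cx.classify_with_strategy(
            "Nothing relevant.", af, taxonomy, counting,
            cx.StrategyKind.SEQUENTIAL_REFINEMENT,
        )
        assert counting.calls == 1

    def test_joint_label_inference_single_call(self, taxonomy):
        counting = cx.CountingBackend(cx.LexiconBackend(taxonomy))
        af = taxonomy.get("atrial_fibrillation")
        pred = cx.classify_with_strategy(
            "Known persistent atrial fibrillation.",
            af,
            taxonomy,
            counting,
            cx.StrategyKind.JOINT_LABEL_INFERENCE,
        )
        assert counting.calls == 1
        assert "atrial_fibrillation" in taxonomy.decode_labels(pred.labels)

    def test_context_forwarding_one_plus_n_with_evidence(self, taxonomy):
        counting = cx.CountingBackend(cx.LexiconBackend(taxonomy))
        af = taxonomy.get("atrial_fibrillation")  # 3 subtypes
        cx.classify_with_strategy(
            "Known persistent atrial fibrillation.",
            af,
            taxonomy,
            counting,
            cx.StrategyKind.CONTEXT_FORWARDING,
        )
        assert counting.calls == 1 + 3
        child_requests = counting.requests[1:]
        for req in child_requests:
            assert req.forwarded_context is not None
            # the parent evidence snippet is forwarded verbatim
            assert "atrial fibrillation" in req.forwarded_context
            assert req.forwarded_context in req.question_text

    def test_joint_whole_document_single_call(self, taxonomy):
        counting = cx.CountingBackend(cx.LexiconBackend(taxonomy))
        pred = cx.classify_joint_document(
            "Known hypertension and type 2 diabetes mellitus.",
            taxonomy,
            counting,
        )
        assert counting.calls == 1
        labels = taxonomy.decode_labels(pred.labels)
        assert {"hypertension", "diabetes", "diabetes_type_2"} <= labels


class TestBuildPrompt:
    def test_minimal_prompt_contains_question_and_document(self, taxonomy):
        cat = taxonomy.get("hypertension")
        text = cx.build_prompt("Some note.", cat)
        assert "Hypertension" in text and "Some note." in text

    def test_forwarded_context_rendered_verbatim(self, taxonomy):
        cat = taxonomy.get("af_persistent")
        ctx = 'Atrial fibrillation: present (evidence: "AFib")'
        text = cx.build_prompt("Doc.", cat, context=ctx)
        assert ctx in text

    def test_byte_identical_for_identical_inputs(self, taxonomy):
        cat = taxonomy.get("osa")
        ex = (("Snoring and apnoeas.", "True"),)
        a = cx.build_prompt("Doc.", cat, examples=ex, context="ctx")
        b = cx.build_prompt("Doc.", cat, examples=ex, context="ctx")
        assert a == b
        assert "Snoring and apnoeas." in a

    def test_unknown_id_in_multi_reply_flagged_lenient(self, taxonomy):
        from comorbex.paradigms import parse_id_list

        ids, flags = parse_id_list("osa, bogus_id", ("osa", "csa"))
        assert ids == ["osa"]
        assert flags == {"unknown-id:bogus_id"}
        with pytest.raises(cx.MappingError):
            parse_id_list("bogus_id", ("osa",), strict=True)
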