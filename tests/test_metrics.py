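"""Metric formulas, degenerate-case contracts, and equivalence with
independent reference implementations."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, precision_recall_fscore_support

import comorbex as cx
from comorbex.metrics import Contingency2x2, contingency_from_pairs


class TestHammingLoss:
    def test_identical_vectors_zero(self, taxonomy):
        v = taxonomy.encode_labels({"hypertension", "osa"})
        assert cx.hamming_loss(v, v) == 0.0

    def test_all_bits_differ_one(self, taxonomy):
        all_ids = {c.id for c in taxonomy.all_categories()}
        full = taxonomy.encode_labels(all_ids)
        empty = taxonomy.encode_labels(set())
        assert cx.hamming_loss(full, empty) == 1.0

    def test_two_mismatches_over_35(self, taxonomy):
        gold = taxonomy.encode_labels({"hypertension"})
        pred = taxonomy.encode_labels({"diabetes"})
        assert cx.hamming_loss(pred, gold) == pytest.approx(2 / 35)

    def test_dimension_mismatch_rejected(self, taxonomy, tiny_taxonomy):
        with pytest.raises(ValueError, match="mismatch"):
            cx.hamming_loss(
                taxonomy.encode_labels(set()), tiny_taxonomy.encode_labels(set())
            )

    def test_matches_brute_force_positional_count(self, taxonomy):
        rng = np.random.default_rng(5)
        ids = [c.id for c in taxonomy.all_categories()]
        for _ in range(200):
            a = {i for i in ids if rng.random() < 0.3}
            b = {i for i in ids if rng.random() < 0.3}
            va, vb = taxonomy.encode_labels(a), taxonomy.encode_labels(b)
            brute = sum(
                int(x != y) for x, y in zip(va.bits, vb.bits)
            ) / taxonomy.dimension()
            assert cx.hamming_loss(va, vb) == pytest.approx(brute, abs=1e-12)


class TestHierPenalty:
    def test_consistent_vector_zero(self, taxonomy):
        v = taxonomy.encode_labels({"sleep_disordered_breathing", "osa"})
        assert cx.hier_penalty(v, taxonomy) == 0

    def test_two_orphan_children_count_two(self, taxonomy):
        v = taxonomy.encode_labels({"osa", "central_sleep_apnoea"})
        assert cx.hier_penalty(v, taxonomy) == 2

    def test_all_parents_positive_zero(self, taxonomy):
        ids = {c.id for c in taxonomy.all_categories()}
        v = taxonomy.encode_labels(ids)
        assert cx.hier_penalty(v, taxonomy) == 0


class TestCohenKappa:
    def test_perfect_agreement(self):
        r = cx.cohen_kappa(Contingency2x2(a=50, b=0, c=0, d_cell=50))
        assert r.p_o == 1.0 and r.kappa == 1.0

    def test_chance_level_agreement(self):
        r = cx.cohen_kappa(Contingency2x2(a=25, b=25, c=25, d_cell=25))
        assert r.p_o == 0.5 and r.p_e == 0.5 and r.kappa == 0.0

    def test_hand_computed_example(self):
        # p_o=0.85, p_e=0.5 -> kappa = 0.35/0.5 = 0.7
        r = cx.cohen_kappa(Contingency2x2(a=40, b=10, c=5, d_cell=45))
        assert r.p_o == pytest.approx(0.85)
        assert r.p_e == pytest.approx(0.5)
        assert r.kappa == pytest.approx(0.7)

    def test_saturated_chance_agreement_undefined(self):
        r = cx.cohen_kappa(Contingency2x2(a=10, b=0, c=0, d_cell=0))
        assert r.p_e == 1.0 and r.kappa is None

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            cx.cohen_kappa(Contingency2x2(a=0, b=0, c=0, d_cell=0))

    def test_kappa_one_iff_no_disagreement_cells(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 30, size=4)
            if a + b + c + d == 0:
                continue
            r = cx.cohen_kappa(Contingency2x2(int(a), int(b), int(c), int(d)))
            if r.kappa is None:
                continue
            assert -1.0 <= r.kappa <= 1.0 + 1e-12
            assert (r.kappa == pytest.approx(1.0)) == (b == 0 and c == 0)

    def test_matches_sklearn_on_random_tables(self):
        rng = np.random.default_rng(2)
        checked = 0
        while checked < 300:
            a, b, c, d = rng.integers(0, 40, size=4)
            n = a + b + c + d
            if n == 0:
                continue
            rater1 = np.repeat([1, 1, 0, 0], [a, b, c, d])
            rater2 = np.repeat([1, 0, 1, 0], [a, b, c, d])
            if len(set(rater1)) == 1 and len(set(rater2)) == 1:
                continue  # sklearn returns nan for degenerate raters
            r = cx.cohen_kappa(Contingency2x2(int(a), int(b), int(c), int(d)))
            ref = cohen_kappa_score(rater1, rater2)
            if np.isnan(ref):
                assert r.kappa is None or r.kappa == pytest.approx(0.0)
            else:
                assert r.kappa == pytest.approx(ref, abs=1e-12)
            checked += 1


class TestHcrCre:
    def test_hcr_examples(self):
        assert cx.hcr([(1, 1)] * 20) == 1.0
        assert cx.hcr([(0, 1)] * 5) == 0.0
        pairs = [(0, 1)] * 3 + [(1, 1)] * 17
        assert cx.hcr(pairs) == pytest.approx(0.85)

    def test_hcr_empty_rejected(self):
        with pytest.raises(ValueError):
            cx.hcr([])

    def test_cre_examples(self):
        assert cx.cre(4, 1) == pytest.approx(0.75)
        assert cx.cre(7, 0) == 1.0
        assert cx.cre(0, 0) is None  # undefined without pre-solver conflicts

    def test_cre_added_contradictions_rejected(self):
        with pytest.raises(ValueError, match="added"):
            cx.cre(1, 3)

    def test_contingency_from_pairs_counts_cells(self):
        pairs = [(1, 1), (1, 0), (0, 1), (0, 0), (0, 1)]
        tbl = contingency_from_pairs(pairs)
        assert (tbl.a, tbl.b, tbl.c, tbl.d_cell) == (1, 1, 2, 1)

    def test_penalty_bounds_contradiction_count(self, taxonomy):
        """Summed hier_penalty >= number of contradicting (doc, parent)
        pairs, with equality when at most one child fires per pair."""
        rng = np.random.default_rng(3)
        ids = [c.id for c in taxonomy.all_categories()]
        for _ in range(100):
            labels = {i for i in ids if rng.random() < 0.25}
            v = taxonomy.encode_labels(labels)
            penalty = cx.hier_penalty(v, taxonomy)
            contradicting_parents = sum(
                1
                for p in taxonomy.top_categories
                if p.id not in labels
                and any(
                    k.id in labels for k in taxonomy.sub_categories(p.id)
                )
            )
            assert penalty >= contradicting_parents


class TestEvaluate:
    def test_perfect_predictions_all_ones(self, taxonomy):
        vs = [
            taxonomy.encode_labels({"hypertension"}),
            taxonomy.encode_labels({"diabetes", "diabetes_type_2"}),
        ]
        rep = cx.evaluate(vs, vs, taxonomy)
        assert rep.macro_f1 == 1.0 and rep.micro_f1 == 1.0
        assert rep.hamming == 0.0

    def test_zero_support_class_undefined_and_excluded(self, taxonomy):
        gold = [taxonomy.encode_labels({"hypertension"})] * 4
        pred = [taxonomy.encode_labels({"hypertension"})] * 3 + [
            taxonomy.encode_labels({"hypertension", "diabetes"})
        ]
        rep = cx.evaluate(pred, gold, taxonomy)
        dm = rep.per_class["dyslipidemia"]
        assert dm.support == 0
        assert dm.precision is None and dm.recall is None and dm.f1 is None
        # diabetes has support 0 but a false positive; still excluded
        assert rep.per_class["diabetes"].f1 is None
        # macro averages only over defined classes
        assert rep.macro_f1 == 1.0
        assert rep.to_dict()["per_class"]["dyslipidemia"]["f1"] == "—"

    def test_f1_zero_when_no_overlap_but_support_positive(self, taxonomy):
        gold = [taxonomy.encode_labels({"hypertension"})]
        pred = [taxonomy.encode_labels(set())]
        rep = cx.evaluate(pred, gold, taxonomy)
        cm = rep.per_class["hypertension"]
        assert cm.f1 == 0.0 and cm.recall == 0.0

    def test_exclusive_mode_micro_equals_accuracy(self, taxonomy):
        rng = np.random.default_rng(8)
        tops = [c.id for c in taxonomy.top_categories]
        for _ in range(100):
            n = int(rng.integers(5, 40))
            gold = [taxonomy.encode_labels({rng.choice(tops)}) for _ in range(n)]
            pred = [taxonomy.encode_labels({rng.choice(tops)}) for _ in range(n)]
            rep = cx.evaluate(pred, gold, taxonomy,
                              mode="exclusive_single_label", classes=tops)
            assert rep.micro_precision == pytest.approx(rep.accuracy)
            assert rep.micro_recall == pytest.approx(rep.accuracy)
            assert rep.micro_f1 == pytest.approx(rep.accuracy)

    def test_exclusive_mode_rejects_multi_label_rows(self, taxonomy):
        tops = [c.id for c in taxonomy.top_categories]
        gold = [taxonomy.encode_labels({"hypertension", "diabetes"})]
        with pytest.raises(ValueError, match="exactly one"):
            cx.evaluate(gold, gold, taxonomy,
                        mode="exclusive_single_label", classes=tops)

    def test_matches_sklearn_per_class_prf(self, taxonomy):
        rng = np.random.default_rng(9)
        ids = [c.id for c in taxonomy.all_categories()]
        for _ in range(20):
            n = 50
            G = (rng.random((n, 35)) < 0.3).astype(int)
            P = (rng.random((n, 35)) < 0.3).astype(int)
            gold = [
                taxonomy.encode_labels({ids[j] for j in range(35) if G[i, j]})
                for i in range(n)
            ]
            pred = [
                taxonomy.encode_labels({ids[j] for j in range(35) if P[i, j]})
                for i in range(n)
            ]
            rep = cx.evaluate(pred, gold, taxonomy)
            prec, rec, f1, supp = precision_recall_fscore_support(
                G, P, zero_division=0
            )
            for j, cid in enumerate(ids):
                cm = rep.per_class[cid]
                assert cm.support == supp[j]
                if cm.defined:
                    assert cm.precision == pytest.approx(prec[j], abs=1e-12)
                    assert cm.recall == pytest.approx(rec[j], abs=1e-12)
                    assert cm.f1 == pytest.approx(f1[j], abs=1e-12)
            # micro metrics against pooled sklearn
            mp, mr, mf, _ = precision_recall_fscore_support(
                G, P, average="micro", zero_division=0
            )
            assert rep.micro_precision == pytest.approx(mp, abs=1e-12)
            assert rep.micro_recall == pytest.approx(mr, abs=1e-12)
            assert rep.micro_f1 == pytest.approx(mf, abs=1e-12)

    def test_mismatched_lengths_rejected(self, taxonomy):
        v = taxonomy.encode_labels(set())
        with pytest.raises(ValueError):
            cx.evaluate([v], [v, v], taxonomy)

    def test_tsv_rendering_has_per_class_rows(self, taxonomy):
        v = [taxonomy.encode_labels({"hypertension"})]
        rep = cx.evaluate(v, v, taxonomy)
        tsv = rep.to_tsv()
        assert "hypertension\t" in tsv and "macro_f1" in tsv
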