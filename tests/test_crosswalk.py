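"""Crosswalk fusion: answer-scale consolidation, translation engine and
reporting statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rosetta.crosswalk import (
    Crosswalk,
    CrosswalkParseError,
    ItemMapping,
    RosettaMatrix,
    TranslationError,
    answer_code_count,
    default_answer_map,
    fusion_summary,
    overlap_matrix,
    translate,
    validate_crosswalk,
)

from conftest import brute_force_fusion, brute_force_overlap, make_toy_crosswalk


class TestAnswerCodeCount:
    @pytest.mark.parametrize("sizes, expected", [
        ([4, 4, 3, 3, 4], 3),  # the routine-change consolidation
        ([4], 4),
        ([3, 3], 3),
    ])
    def test_minimum_rule(self, sizes, expected):
        assert answer_code_count(sizes) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            answer_code_count([])

    def test_degenerate_scale_rejected(self):
        with pytest.raises(ValueError):
            answer_code_count([3, 1])


class TestDefaultAnswerMap:
    @pytest.mark.parametrize("k, m, expected", [
        (4, 3, (1, 2, 3, 3)),  # severe-end collapse of a 4-choice scale
        (3, 3, (1, 2, 3)),     # one-to-one
        (5, 3, (1, 2, 3, 3, 3)),
    ])
    def test_severe_end_collapse(self, k, m, expected):
        assert default_answer_map(k, m) == expected

    def test_coarser_source_has_no_default(self):
        with pytest.raises(ValueError, match="explicit map"):
            default_answer_map(2, 3)

    @given(m=st.integers(2, 8), extra=st.integers(0, 6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_and_surjective(self, m, extra):
        k = m + extra
        amap = default_answer_map(k, m)
        assert len(amap) == k
        assert all(b >= a for a, b in zip(amap, amap[1:]))
        assert set(amap) == set(range(1, m + 1))


class TestValidation:
    def test_packaged_excerpt_valid(self, adaptability, hierarchy):
        assert validate_crosswalk(adaptability, hierarchy) == []

    def test_double_mapping_reported(self, adaptability):
        extra = ItemMapping(
            item_key=adaptability.mappings[0].item_key,
            question_id=adaptability.questions[1].id,
            answer_map=(1, 2, 3, 4),
        )
        cw = Crosswalk(adaptability.registry, adaptability.items,
                       adaptability.questions,
                       adaptability.mappings + [extra])
        assert any("multiple mapping" in v for v in cw.validate())

    def test_non_monotone_map_reported(self, adaptability):
        first = adaptability.mappings[0]
        bad = ItemMapping(item_key=first.item_key,
                          question_id=first.question_id,
                          answer_map=(2, 1, 3, 3))
        cw = Crosswalk(adaptability.registry, adaptability.items,
                       adaptability.questions,
                       [bad] + adaptability.mappings[1:])
        assert any("non-monotone" in v for v in cw.validate())

    def test_every_packaged_map_monotone_exhaustively(self, adaptability,
                                                      synth_cw):
        for cw in (adaptability, synth_cw):
            for mp in cw.mappings:
                assert all(b >= a for a, b in
                           zip(mp.answer_map, mp.answer_map[1:]))

    def test_parse_error_distinct(self, tmp_path):
        p = tmp_path / "cw.json"
        p.write_text("{]")
        with pytest.raises(CrosswalkParseError):
            Crosswalk.from_json(p)

    def test_round_trip(self, adaptability, tmp_path):
        p = tmp_path / "cw.json"
        adaptability.to_json(p)
        back = Crosswalk.from_json(p)
        assert back.validate() == []
        assert len(back.items) == len(adaptability.items)
        assert {q.id for q in back.questions} == {
            q.id for q in adaptability.questions
        }


ROUTINE_CHANGE = "Cognoa_Cognitive_Behavioral_Emotional_Adaptability_RoutineChange"


class TestTranslate:
    def test_most_severe_source_choice_maps_to_top_code(self, adaptability):
        """The most severe of the four descriptive choices lands on
        consolidated code 3."""
        responses = pd.DataFrame([
            {"child_id": "c1", "instrument": "ADI-R", "version": "Standard",
             "item": "74", "raw": 4},
        ])
        mat = translate(adaptability, responses)
        assert mat.codes.at["c1", ROUTINE_CHANGE] == 3.0

    def test_unanswered_questions_stay_missing(self, adaptability):
        responses = pd.DataFrame([
            {"child_id": "c1", "instrument": "ADI-R", "version": "Standard",
             "item": "74", "raw": 1},
        ])
        mat = translate(adaptability, responses)
        row = mat.codes.loc["c1"]
        assert row.notna().sum() == 1

    def test_unknown_item_reported_with_context(self, adaptability):
        responses = pd.DataFrame([
            {"child_id": "c9", "instrument": "ADI-R", "version": "Standard",
             "item": "999", "raw": 1},
        ])
        with pytest.raises(TranslationError, match="c9"):
            translate(adaptability, responses)

    def test_out_of_range_raw_reported(self, adaptability):
        responses = pd.DataFrame([
            {"child_id": "c1", "instrument": "BRIEF2", "version": "Parent",
             "item": "11", "raw": 4},  # BRIEF2 has 3 choices
        ])
        with pytest.raises(TranslationError, match="1..3"):
            translate(adaptability, responses)

    @pytest.mark.parametrize("policy", ["max", "mean", "first"])
    def test_aggregation_matches_brute_force(self, adaptability, policy):
        """Multi-item cells match an independent re-aggregation over the
        grouped long table."""
        rng = np.random.default_rng(4)
        items = [(mp.item_key, mp) for mp in adaptability.mappings]
        rows = []
        for c in range(12):
            for key, mp in items:
                if rng.random() < 0.5:
                    k = adaptability.item(key).scale.size
                    rows.append({"child_id": f"c{c}",
                                 "instrument": key[0], "version": key[1],
                                 "item": key[2],
                                 "raw": int(rng.integers(1, k + 1))})
        responses = pd.DataFrame(rows)
        mat = translate(adaptability, responses, policy=policy)

        # oracle: group mapped codes by (child, question) and re-aggregate
        expected = {}
        for r in rows:
            mp = adaptability.mapping_for_item(
                (r["instrument"], r["version"], r["item"])
            )
            code = mp.answer_map[r["raw"] - 1]
            expected.setdefault((r["child_id"], mp.question_id), []).append(code)
        for (child, qid), codes in expected.items():
            if policy == "max":
                want = max(codes)
            elif policy == "mean":
                want = int(np.floor(np.mean(codes) + 0.5))
            else:
                want = codes[0]
            assert mat.codes.at[child, qid] == want

    def test_row_order_invariance(self, adaptability):
        rng = np.random.default_rng(9)
        rows = []
        for c in range(8):
            for mp in adaptability.mappings[::3]:
                k = adaptability.item(mp.item_key).scale.size
                rows.append({"child_id": f"c{c}", "instrument": mp.item_key[0],
                             "version": mp.item_key[1], "item": mp.item_key[2],
                             "raw": int(rng.integers(1, k + 1))})
        responses = pd.DataFrame(rows)
        shuffled = responses.sample(frac=1.0, random_state=3)
        a = translate(adaptability, responses)
        b = translate(adaptability, shuffled)
        pd.testing.assert_frame_equal(
            a.codes.sort_index(), b.codes.sort_index()
        )

    def test_values_within_code_ranges(self, adaptability):
        rng = np.random.default_rng(2)
        rows = [{"child_id": "c0", "instrument": mp.item_key[0],
                 "version": mp.item_key[1], "item": mp.item_key[2],
                 "raw": int(rng.integers(
                     1, adaptability.item(mp.item_key).scale.size + 1))}
                for mp in adaptability.mappings]
        mat = translate(adaptability, pd.DataFrame(rows))
        assert mat.check() == []


class TestMatrixIO:
    def test_csv_round_trip_with_ranges(self, tmp_path):
        codes = pd.DataFrame(
            {"Q1": [1.0, np.nan, 3.0], "Q2": [np.nan, 2.0, 2.0]},
            index=pd.Index(["a", "b", "c"], name="child_id"),
        )
        mat = RosettaMatrix(codes, {"Q1": 3, "Q2": 4})
        p, rp = tmp_path / "m.csv", tmp_path / "r.json"
        mat.to_csv(p, rp)
        back = RosettaMatrix.from_csv(p, ranges_path=rp)
        pd.testing.assert_frame_equal(back.codes, codes)
        assert back.code_ranges == {"Q1": 3, "Q2": 4}


class TestReports:
    def test_adaptability_fusion_counts(self, adaptability):
        fs = fusion_summary(adaptability)
        row = fs.loc["Cognitive/Behavioral/Emotional/Adaptability"]
        assert (row["n_instruments"], row["n_items"], row["n_questions"]) \
            == (6, 32, 4)

    def test_unmapped_leaf_reports_zeroes(self, adaptability, hierarchy):
        fs = fusion_summary(adaptability, hierarchy)
        row = fs.loc["Somatic/Sleep"]
        assert tuple(row) == (0, 0, 0)

    def test_disjoint_instruments_have_zero_off_diagonal(self):
        rng = np.random.default_rng(0)
        cw = make_toy_crosswalk(rng)
        # keep each question's items from one instrument only
        keep_inst = {q.id: f"I{i % len(cw.instruments)}"
                     for i, q in enumerate(cw.questions)}
        single = [mp for mp in cw.mappings
                  if mp.item_key[0] == keep_inst[mp.question_id]]
        kept_keys = {mp.item_key for mp in single}
        cw2 = Crosswalk(cw.registry,
                        [it for it in cw.items if it.key in kept_keys],
                        cw.questions, single)
        mat, totals = overlap_matrix(cw2)
        off = mat.to_numpy().copy()
        np.fill_diagonal(off, 0)
        assert (off == 0).all()
        assert (totals >= np.diag(mat.to_numpy())).all()

    @pytest.mark.parametrize("seed", range(6))
    def test_overlap_and_fusion_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        cw = make_toy_crosswalk(rng)
        mat, totals = overlap_matrix(cw)
        bmat, btotals = brute_force_overlap(cw)
        pd.testing.assert_frame_equal(mat, bmat)
        assert (totals == btotals).all()
        assert (mat.to_numpy() == mat.to_numpy().T).all()

        fs = fusion_summary(cw)
        for leaf, (ni, nit, nq) in brute_force_fusion(cw).items():
            row = fs.loc[leaf]
            assert tuple(row) == (ni, nit, nq)
        assert fs.loc["TOTAL", "n_questions"] == len(cw.questions)

    def test_many_to_one(self, adaptability, synth_cw):
        for cw in (adaptability, synth_cw):
            assert len(cw.items) >= len(cw.questions)
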