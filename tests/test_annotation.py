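"""Hierarchical coding validation, kappa agreement, adjudication, summaries."""

import numpy as np
import pytest

from aqsurveil.annotation import (
    CODES,
    PARENT,
    AnnotationRecord,
    adjudicate,
    agreement,
    kappa_from_table,
    record_from_bools,
    summarize_codes,
    summary_to_dict,
    validate_records,
)
from aqsurveil.errors import (
    DuplicateRecordError,
    KappaUndefinedError,
    MissingAdjudicationError,
)


def random_record(rng, mid, coder, valid=True):
    if valid:
        return record_from_bools(
            mid,
            coder,
            relevant=bool(rng.random() < 0.6),
            firsthand=bool(rng.random() < 0.7),
            behavior=bool(rng.random() < 0.4),
            concern=bool(rng.random() < 0.3),
            request_action=bool(rng.random() < 0.1),
        )
    codes = {c: ("y", "n", "na")[rng.integers(0, 3)] for c in CODES}
    return AnnotationRecord(mid, coder, codes)


def oracle_valid(record):
    """Brute-force rule checker: walk every code's ancestor chain."""
    for code in CODES:
        v = record.codes.get(code)
        if v not in ("y", "n", "na"):
            return False
        parent = PARENT[code]
        applicable = True
        while parent is not None:
            if record.codes.get(parent) != "y":
                applicable = False
                break
            parent = PARENT[parent]
        if applicable and v == "na":
            return False
        if not applicable and v != "na":
            return False
    return False if record.codes.get("relevant") == "na" else True


class TestValidate:
    def test_tree_breach_reported(self):
        rec = AnnotationRecord(
            "m1",
            "a",
            {
                "relevant": "n",
                "request_action": "na",
                "firsthand": "y",
                "behavior": "na",
                "concern": "na",
            },
        )
        valid, violations = validate_records([rec])
        assert valid == []
        assert any(v.code == "firsthand" for v in violations)

    def test_fully_na_chain_under_irrelevant_is_valid(self):
        rec = record_from_bools("m1", "a", relevant=False)
        valid, violations = validate_records([rec])
        assert valid == [rec]
        assert violations == []

    def test_fuzz_agrees_with_bruteforce_rule_checker(self, rng):
        records = [
            random_record(rng, f"m{i}", "a", valid=bool(rng.random() < 0.5))
            for i in range(300)
        ]
        valid, _ = validate_records(records)
        valid_ids = {r.message_id for r in valid}
        for r in records:
            assert (r.message_id in valid_ids) == oracle_valid(r)

    def test_duplicate_pair_raises(self):
        rec = record_from_bools("m1", "a", relevant=True, firsthand=True)
        with pytest.raises(DuplicateRecordError):
            validate_records([rec, rec])


class TestAgreement:
    def test_identical_records_perfect_kappa(self, rng):
        recs = [random_record(rng, f"m{i}", "a") for i in range(60)]
        clones = [AnnotationRecord(r.message_id, "b", dict(r.codes)) for r in recs]
        for code in CODES:
            try:
                res = agreement(recs, clones, code)
            except KappaUndefinedError:
                continue  # a constant code column has no chance correction
            assert res.p_o == pytest.approx(1.0)
            assert res.kappa == pytest.approx(1.0)

    def test_constant_coder_gives_zero_kappa(self):
        a = [
            record_from_bools(f"m{i}", "a", relevant=(i % 2 == 0))
            for i in range(40)
        ]
        b = [record_from_bools(f"m{i}", "b", relevant=True) for i in range(40)]
        res = agreement(a, b, "relevant")
        assert res.kappa == pytest.approx(0.0, abs=1e-12)

    def test_fixed_table_matches_hand_formula(self):
        p_o, p_e, kappa = kappa_from_table(np.array([[80, 10], [5, 5]]))
        n = 100.0
        assert p_o == pytest.approx(85 / n, abs=1e-15)
        expected_pe = (90 / n) * (85 / n) + (10 / n) * (15 / n)
        assert p_e == pytest.approx(expected_pe, abs=1e-15)
        assert kappa == pytest.approx(
            (0.85 - expected_pe) / (1 - expected_pe), abs=1e-12
        )

    def test_matches_sklearn_cohen_kappa(self, rng):
        """Independent cross-check of our contingency-table kappa."""
        from sklearn.metrics import cohen_kappa_score

        a = rng.integers(0, 2, size=200)
        flips = rng.random(200) < 0.2
        b = a ^ flips
        table = np.zeros((2, 2), dtype=int)
        for x, y in zip(a, b):
            table[1 - x, 1 - y] += 1
        _, _, kappa = kappa_from_table(table)
        assert kappa == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_symmetric_in_coders(self, rng):
        a = [random_record(rng, f"m{i}", "a") for i in range(80)]
        b = [random_record(rng, f"m{i}", "b") for i in range(80)]
        res_ab = agreement(a, b, "relevant")
        res_ba = agreement(b, a, "relevant")
        assert res_ab.kappa == pytest.approx(res_ba.kappa, abs=1e-12)
        assert res_ab.n == res_ba.n

    def test_kappa_never_exceeds_observed_agreement(self, rng):
        for trial in range(20):
            a = [random_record(rng, f"m{i}", "a") for i in range(50)]
            b = [random_record(rng, f"m{i}", "b") for i in range(50)]
            try:
                res = agreement(a, b, "firsthand")
            except (KappaUndefinedError, Exception):
                continue
            assert res.kappa <= res.p_o + 1e-12

    def test_n_shrinks_down_the_tree(self, rng):
        a = [random_record(rng, f"m{i}", "a") for i in range(400)]
        b = [random_record(rng, f"m{i}", "b") for i in range(400)]
        n_rel = agreement(a, b, "relevant").n
        n_fh = agreement(a, b, "firsthand").n
        n_beh = agreement(a, b, "behavior").n
        assert n_rel >= n_fh >= n_beh

    def test_both_constant_raises_kappa_undefined_with_po(self):
        a = [record_from_bools(f"m{i}", "a", relevant=True) for i in range(10)]
        b = [record_from_bools(f"m{i}", "b", relevant=True) for i in range(10)]
        with pytest.raises(KappaUndefinedError) as exc:
            agreement(a, b, "relevant")
        assert exc.value.p_o == pytest.approx(1.0)


class TestAdjudicate:
    def test_agreeing_coders_pass_through(self, rng):
        a = [random_record(rng, f"m{i}", "a") for i in range(30)]
        b = [AnnotationRecord(r.message_id, "b", dict(r.codes)) for r in a]
        resolved = adjudicate(a, b, [])
        by_id = {r.message_id: r for r in resolved}
        for r in a:
            assert by_id[r.message_id].codes == r.codes

    def test_single_disagreement_taken_from_tiebreaker(self):
        a = [record_from_bools("m1", "a", relevant=True, firsthand=True)]
        b = [record_from_bools("m1", "b", relevant=True, firsthand=False)]
        c = [record_from_bools("m1", "c", relevant=True, firsthand=True,
                               behavior=True)]
        resolved = adjudicate(a, b, c)
        assert resolved[0].codes["firsthand"] == "y"
        # only coder A actually coded behavior (B's parent was 'n'), so A's
        # value stands without consulting the tie-breaker
        assert resolved[0].codes["behavior"] == "n"

    def test_uncovered_disagreement_raises(self):
        a = [record_from_bools("m1", "a", relevant=True)]
        b = [record_from_bools("m1", "b", relevant=False)]
        with pytest.raises(MissingAdjudicationError):
            adjudicate(a, b, [])

    def test_random_triples_match_per_cell_merge_and_validate(self, rng):
        a = [random_record(rng, f"m{i}", "a") for i in range(100)]
        b = [random_record(rng, f"m{i}", "b") for i in range(100)]
        c = [random_record(rng, f"m{i}", "c") for i in range(100)]
        resolved = adjudicate(a, b, c)
        _, violations = validate_records(resolved)
        assert violations == []
        by = {
            coder: {r.message_id: r for r in recs}
            for coder, recs in (("a", a), ("b", b), ("c", c))
        }
        order = ("relevant", "request_action", "firsthand", "behavior", "concern")
        for r in resolved:
            codes = {}
            for code in order:
                parent = PARENT[code]
                if parent is not None and codes[parent] != "y":
                    codes[code] = "na"
                    continue
                va = by["a"][r.message_id].codes[code]
                vb = by["b"][r.message_id].codes[code]
                opinions = [v for v in (va, vb) if v != "na"]
                if len(set(opinions)) == 1:
                    v = opinions[0]
                elif not opinions:
                    v = "n"
                else:
                    vc = by["c"][r.message_id].codes[code]
                    v = "n" if vc == "na" else vc
                codes[code] = v
            assert r.codes == codes


class TestSummarize:
    def test_study_shaped_counts_give_printed_proportions(self):
        """170 → 114 relevant → 90 firsthand → {32 behavior, 17 concern},
        3 action: conditional percentages 67.1, ~79, ~36, ~19, 2.6."""
        records = []
        for i in range(170):
            rel = i < 114
            fh = i < 90
            records.append(
                record_from_bools(
                    f"m{i}",
                    "resolved",
                    relevant=rel,
                    firsthand=fh,
                    behavior=i < 32,
                    concern=32 <= i < 49,
                    request_action=111 <= i < 114,
                )
            )
        tree = summarize_codes(records)
        rel = tree.children["relevant"]
        fh = rel.children["firsthand"]
        assert (tree.count, rel.count, fh.count) == (170, 114, 90)
        assert rel.percent == pytest.approx(67.1)
        assert round(100 * fh.proportion) == 79
        assert round(100 * fh.children["behavior"].proportion) == 36
        assert round(100 * fh.children["concern"].proportion) == 19
        assert rel.children["request_action"].percent == pytest.approx(2.6)

    def test_zero_relevant_children_undefined_not_zero(self):
        records = [
            record_from_bools(f"m{i}", "r", relevant=False) for i in range(5)
        ]
        tree = summarize_codes(records)
        rel = tree.children["relevant"]
        assert rel.count == 0
        assert rel.children["firsthand"].proportion is None
        assert rel.children["firsthand"].percent is None

    def test_counts_match_bruteforce_tallies_and_conserve(self, rng):
        records = [random_record(rng, f"m{i}", "r") for i in range(200)]
        tree = summarize_codes(records)
        rel = tree.children["relevant"]
        fh = rel.children["firsthand"]
        assert rel.count == sum(r.codes["relevant"] == "y" for r in records)
        assert fh.count == sum(r.codes.get("firsthand") == "y" for r in records)
        assert fh.children["behavior"].count == sum(
            r.codes.get("behavior") == "y" for r in records
        )
        # conservation: child counts never exceed parents
        assert fh.count <= rel.count <= tree.count
        assert fh.children["behavior"].count <= fh.count
        assert fh.children["concern"].count <= fh.count
        d = summary_to_dict(tree)
        assert d["children"]["relevant"]["count"] == rel.count
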