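"""Name normalization, the ±20% similarity rule, and tiered matching.

The tiered matcher is checked against an independently coded exhaustive
oracle that scans every candidate."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutrikit import (
    MISSING,
    FoodRecord,
    SourceTable,
    integrate_food_lists,
    is_similar,
    match_food,
    normalize_name,
    relative_difference,
)
from nutrikit.matching import COMPARISON_NUTRIENTS

from conftest import make_food, make_table


class TestNormalizeName:
    def test_tokenizes_case_and_punctuation(self):
        assert normalize_name("Chicken, Meat and skin, Stewed") == (
            "chicken", "meat", "and", "skin", "stewed",
        )

    def test_collapses_whitespace(self):
        assert normalize_name("  Rice  ") == ("rice",)

    def test_deterministic(self):
        raw = "Beans, black; BOILED"
        assert normalize_name(raw) == normalize_name(raw)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            normalize_name("   ")


class TestRelativeDifference:
    @pytest.mark.parametrize(
        "q, c, expected",
        [
            (100.0, 100.0, 0.0),
            (100.0, 121.0, 0.21),  # breaches the 20% rule
            (100.0, MISSING, MISSING),
            (MISSING, 5.0, MISSING),
            (0.0, 0.0, 0.0),
            (0.0, 3.0, 1.0),  # zero query vs positive candidate: max dissimilarity
        ],
    )
    def test_cases(self, q, c, expected):
        result = relative_difference(q, c)
        if expected is MISSING:
            assert result is MISSING
        else:
            assert result == pytest.approx(expected)

    def test_negative_is_error(self):
        with pytest.raises(ValueError):
            relative_difference(-1.0, 5.0)


def _macro_food(food_id, energy, carbohydrate, protein, fat, water, state="cooked", name="x"):
    return make_food(
        food_id, name, state,
        energy=energy, carbohydrate=carbohydrate, protein=protein, fat=fat, water=water,
    )


class TestIsSimilar:
    def test_identical_records_similar(self):
        a = _macro_food("a", 100, 20, 5, 2, 70)
        assert is_similar(a, a)

    def test_single_nutrient_breach_fails(self):
        # brute force over the five diffs confirms only protein breaches
        a = _macro_food("a", 100, 20, 8.0, 2, 70)
        b = _macro_food("b", 100, 20, 10.0, 2, 70)  # protein +25%
        diffs = [
            relative_difference(a.get(n), b.get(n)) for n in COMPARISON_NUTRIENTS
        ]
        assert sum(d >= 0.20 for d in diffs) == 1
        assert not is_similar(a, b)

    def test_insufficient_evidence_fails(self):
        a = make_food("a", values=dict(energy=100.0))
        b = make_food("b", values=dict(energy=100.0))
        assert not is_similar(a, b)  # 4 of 5 comparisons MISSING


# ---------------------------------------------------------------------------
# independent exhaustive oracle


def oracle_match(query, target, threshold=0.20):
    """Brute-force reimplementation of the tier rules by exhaustive scan."""

    def diffs(c):
        out = []
        for n in COMPARISON_NUTRIENTS:
            q, v = query.get(n), c.get(n)
            if q is None or v is None:
                continue
            if q == 0:
                out.append(0.0 if v == 0 else 1.0)
            else:
                out.append(abs(q - v) / q)
        return out

    def similar(c):
        d = diffs(c)
        return len(d) >= 3 and all(x < threshold for x in d)

    def names_equal(c):
        def norm(s):
            import re, unicodedata
            s = unicodedata.normalize("NFKC", s).casefold()
            return tuple(re.sub(r"[^\w\s]", " ", s).split())

        return (
            bool(query.name_ko.strip()) and bool(c.name_ko.strip())
            and norm(c.name_ko) == norm(query.name_ko)
        ) or (
            bool(query.name_en.strip()) and bool(c.name_en.strip())
            and norm(c.name_en) == norm(query.name_en)
        )

    def best(cands):
        pool = [c for c in cands if similar(c)]
        if not pool:
            return None
        return min(
            pool,
            key=lambda c: (
                sum(diffs(c)) / len(diffs(c)),
                c.state != query.state,
                c.food_id,
            ),
        )

    named = [c for c in target if names_equal(c)]
    if named:
        chosen = best(named)
        if chosen is not None:
            return chosen.food_id, "name_exact"
        chosen = best(list(target))
        if chosen is not None:
            return chosen.food_id, "name_exact_substituted"
        return None, "unmatched"
    chosen = best([c for c in target if c.state == query.state])
    if chosen is not None:
        return chosen.food_id, "state_relaxed"
    return None, "unmatched"


def random_table(rng, n, with_name_from=None):
    foods = []
    for i in range(n):
        name = (
            rng.choice(with_name_from)
            if with_name_from and rng.random() < 0.4
            else f"name {rng.randrange(1000)}"
        )
        foods.append(
            _macro_food(
                f"f{i:03d}",
                energy=rng.uniform(10, 400),
                carbohydrate=rng.uniform(0, 80) if rng.random() > 0.2 else None,
                protein=rng.uniform(0, 30),
                fat=rng.uniform(0, 25) if rng.random() > 0.2 else None,
                water=rng.uniform(1, 95),
                state=rng.choice(["raw", "cooked", "dried", "processed"]),
                name=name,
            )
        )
    return make_table("target", foods)


class TestMatchFood:
    def test_identical_food_is_name_exact_with_zero_diffs(self):
        a = _macro_food("q", 100, 20, 5, 2, 70, name="rice cooked")
        target = make_table("t", [_macro_food("c", 100, 20, 5, 2, 70, name="rice cooked")])
        result = match_food(a, target)
        assert result.tier == "name_exact"
        assert not result.needs_review
        assert all(d == 0.0 for d in result.rel_diffs.values())

    def test_substitution_picks_similar_food_over_same_name(self):
        # same-name candidate differs 30% in fat; a "breast" record is
        # within 20% on all five, so it is substituted
        query = _macro_food("q", 200, 0.0, 25, 10, 60, state="cooked",
                            name="chicken meat and skin stewed")
        same_name_bad = _macro_food("c1", 200, 0.0, 25, 13.0, 60, state="cooked",
                                    name="chicken meat and skin stewed")
        breast = _macro_food("c2", 190, 0.0, 27, 9.0, 63, state="cooked",
                             name="chicken meat breast stewed")
        target = make_table("t", [same_name_bad, breast])
        result = match_food(query, target)
        assert result.tier == "name_exact_substituted"
        assert result.candidate_food_id == "c2"
        assert result.needs_review
        # agreement with the exhaustive oracle on this constructed fixture
        assert oracle_match(query, target) == ("c2", "name_exact_substituted")

    def test_no_similar_candidate_is_unmatched(self):
        rng = random.Random(7)
        query = _macro_food("q", 1e6, 1e6, 1e6, 1e6, 1e6, name="nothing like me")
        target = random_table(rng, 50)
        result = match_food(query, target)
        assert result.tier == "unmatched"
        assert result.candidate_food_id is None
        assert oracle_match(query, target) == (None, "unmatched")

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=150)
    def test_oracle_equivalence_random_tables(self, seed):
        rng = random.Random(seed)
        target = random_table(rng, rng.randrange(1, 40))
        names = [c.name_en for c in target]
        query = random_table(rng, 1, with_name_from=names).foods[0]
        result = match_food(query, target)
        assert (result.candidate_food_id, result.tier) == oracle_match(query, target)

    @given(st.integers(min_value=0, max_value=5_000))
    @settings(max_examples=50)
    def test_row_order_independence(self, seed):
        rng = random.Random(seed)
        target = random_table(rng, 25)
        query = random_table(rng, 1, with_name_from=[c.name_en for c in target]).foods[0]
        shuffled = list(target.foods)
        rng.shuffle(shuffled)
        r1 = match_food(query, target)
        r2 = match_food(query, make_table("target", shuffled))
        assert (r1.candidate_food_id, r1.tier) == (r2.candidate_food_id, r2.tier)

    def test_every_non_exact_result_needs_review(self):
        rng = random.Random(11)
        target = random_table(rng, 30)
        for _ in range(50):
            query = random_table(rng, 1, with_name_from=[c.name_en for c in target]).foods[0]
            r = match_food(query, target)
            if r.tier != "name_exact":
                assert r.needs_review


class TestIntegrateFoodLists:
    def _recall(self, n=10):
        return make_table(
            "recall",
            [_macro_food(f"r{i}", 100 + i, 20, 5, 2, 70, name=f"recall food {i}")
             for i in range(n)],
        )

    def test_matched_ffq_foods_become_cross_references(self):
        recall = self._recall(10)
        # 3 FFQ foods identical to recall foods, 1 new
        ffq_foods = [
            _macro_food(f"q{i}", 100 + i, 20, 5, 2, 70, name=f"recall food {i}")
            for i in range(3)
        ] + [_macro_food("q_new", 999, 1, 1, 1, 1, name="totally new food")]
        unified = integrate_food_lists(make_table("ffq", ffq_foods), recall)
        assert len(unified) == 11  # |recall| + |unmatched FFQ|
        assert len(unified.cross_references) == 3
        assert unified.cross_references["q0"] == "r0"

    def test_disjoint_lists_add(self):
        recall = self._recall(5)
        ffq = make_table(
            "ffq",
            [_macro_food(f"q{i}", 1000 + 500 * i, 1, 1, 1, 1, name=f"ffq only {i}",
                         state="dried")
             for i in range(4)],
        )
        unified = integrate_food_lists(ffq, recall)
        assert len(unified) == 9
        assert unified.cross_references == {}

    def test_empty_ffq_leaves_recall_unchanged(self):
        recall = self._recall(6)
        unified = integrate_food_lists(make_table("ffq", []), recall)
        assert [f.food_id for f in unified.foods] == [f.food_id for f in recall]
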