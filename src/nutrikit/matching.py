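"""Match foods across composition tables.

Matching follows the procedure used when harmonizing heterogeneous
composition tables: food names (Korean first, then English) are compared
after normalization, and a name match is accepted only if the two records
agree on the five reference nutrients — energy, carbohydrate, protein,
fat and water — to within a relative-difference threshold (default 20%).
When a same-name candidate fails the similarity rule, a different food
with similar nutrient content is substituted (e.g. stewed chicken with
skin matched to stewed chicken breast); when no name matches at all, the
search is restricted to candidates in the same preparation state.

Every non-exact outcome is flagged ``needs_review`` so a human reviewer
can audit substitutions, mirroring the expert-review step of the manual
procedure.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from typing import Optional

from .model import MISSING, FoodRecord, SourceTable

#: The five reference nutrients compared when deciding whether two foods
#: are "the same food" nutritionally.
COMPARISON_NUTRIENTS = ("energy", "carbohydrate", "protein", "fat", "water")

#: Relative-difference threshold above which two values are significantly
#: different (the ±20% rule).
DEFAULT_THRESHOLD = 0.20

#: Minimum number of non-MISSING pairwise comparisons required before a
#: similarity verdict is trusted at all.
MIN_COMPARISONS = 3

_PUNCT = re.compile(r"[^\w\s]", re.UNICODE)


def normalize_name(raw_name: str) -> tuple[str, ...]:
    """Case-fold, strip punctuation and collapse whitespace into tokens.

    >>> normalize_name("Chicken, Meat and skin, Stewed")
    ('chicken', 'meat', 'and', 'skin', 'stewed')
    """
    if not raw_name or not raw_name.strip():
        raise ValueError("cannot normalize an empty food name")
    text = unicodedata.normalize("NFKC", raw_name).casefold()
    text = _PUNCT.sub(" ", text)
    return tuple(text.split())


def relative_difference(
    query_value: Optional[float], candidate_value: Optional[float]
) -> Optional[float]:
    """|q − c| / q, with the query food as the reference denominator.

    Returns MISSING if either side is MISSING, 0 when both are 0, and 1.0
    (maximal dissimilarity) when the query is 0 but the candidate is not.
    """
    if query_value is MISSING or candidate_value is MISSING:
        return MISSING
    if query_value < 0 or candidate_value < 0:
        raise ValueError("nutrient values must be non-negative")
    if query_value == 0:
        return 0.0 if candidate_value == 0 else 1.0
    return abs(query_value - candidate_value) / query_value


def comparison_diffs(
    query: FoodRecord, candidate: FoodRecord
) -> dict[str, Optional[float]]:
    """Relative differences over the five reference nutrients."""
    return {
        nid: relative_difference(query.get(nid), candidate.get(nid))
        for nid in COMPARISON_NUTRIENTS
    }


def is_similar(
    query: FoodRecord,
    candidate: FoodRecord,
    threshold: float = DEFAULT_THRESHOLD,
) -> bool:
    """True iff every available reference-nutrient difference is below threshold.

    At least :data:`MIN_COMPARISONS` of the five comparisons must be
    non-MISSING; with less evidence the pair is never considered similar.
    """
    diffs = [d for d in comparison_diffs(query, candidate).values() if d is not MISSING]
    if len(diffs) < MIN_COMPARISONS:
        return False
    return all(d < threshold for d in diffs)


def _mean_diff(query: FoodRecord, candidate: FoodRecord) -> float:
    diffs = [d for d in comparison_diffs(query, candidate).values() if d is not MISSING]
    return sum(diffs) / len(diffs)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one query food into a target table."""

    query_food_id: str
    candidate_food_id: Optional[str]
    tier: str
    rel_diffs: dict[str, Optional[float]] = field(default_factory=dict, hash=False)
    needs_review: bool = True

    def __post_init__(self) -> None:
        if self.tier == "unmatched" and self.candidate_food_id is not None:
            raise ValueError("unmatched result cannot carry a candidate")


def _best_candidate(
    query: FoodRecord, candidates: list[FoodRecord], threshold: float
) -> Optional[FoodRecord]:
    """Argmin of mean reference-nutrient difference among similar candidates.

    Ties broken by preparation-state equality with the query, then by
    lexicographic food_id, so the result is independent of row order.
    """
    similar = [c for c in candidates if is_similar(query, c, threshold)]
    if not similar:
        return None
    return min(
        similar,
        key=lambda c: (_mean_diff(query, c), c.state != query.state, c.food_id),
    )


def match_food(
    query: FoodRecord,
    target: SourceTable,
    threshold: float = DEFAULT_THRESHOLD,
) -> MatchResult:
    """Match one food into a target table, deterministically.

    Tier 1 (``name_exact``): a candidate with an equal normalized name
    (Korean compared first, then English) that also passes the
    similarity rule.  Tier 2 (``name_exact_substituted``): a same-name
    candidate exists but is nutritionally different, so the most similar
    food overall is substituted.  Tier 3 (``state_relaxed``): no name
    matches; the most similar food in the same preparation state is
    taken.  Otherwise ``unmatched``.
    """
    q_ko = normalize_name(query.name_ko) if query.name_ko.strip() else None
    q_en = normalize_name(query.name_en) if query.name_en.strip() else None

    def name_equal(c: FoodRecord) -> bool:
        if q_ko is not None and c.name_ko.strip():
            if normalize_name(c.name_ko) == q_ko:
                return True
        if q_en is not None and c.name_en.strip():
            if normalize_name(c.name_en) == q_en:
                return True
        return False

    name_matches = [c for c in target if name_equal(c)]

    if name_matches:
        best = _best_candidate(query, name_matches, threshold)
        if best is not None:
            return _result(query, best, "name_exact")
        # same name but different nutrients: substitute a similar food
        best = _best_candidate(query, list(target), threshold)
        if best is not None:
            return _result(query, best, "name_exact_substituted")
        return _result(query, None, "unmatched")

    same_state = [c for c in target if c.state == query.state]
    best = _best_candidate(query, same_state, threshold)
    if best is not None:
        return _result(query, best, "state_relaxed")
    return _result(query, None, "unmatched")


def _result(
    query: FoodRecord, candidate: Optional[FoodRecord], tier: str
) -> MatchResult:
    if candidate is None:
        diffs: dict[str, Optional[float]] = {n: MISSING for n in COMPARISON_NUTRIENTS}
        return MatchResult(query.food_id, None, tier, diffs, needs_review=True)
    return MatchResult(
        query.food_id,
        candidate.food_id,
        tier,
        comparison_diffs(query, candidate),
        needs_review=(tier != "name_exact"),
    )


def match_table(
    query_table: SourceTable,
    target: SourceTable,
    threshold: float = DEFAULT_THRESHOLD,
) -> dict[str, MatchResult]:
    """Match every food of a query table into a target table."""
    return {f.food_id: match_food(f, target, threshold) for f in query_table}


@dataclass
class IntegratedFoodList:
    """Union of recall-table foods and FFQ foods, deduplicated by matching.

    ``cross_references`` maps an FFQ food_id to the recall food_id it was
    matched to; unmatched FFQ foods appear as new records in ``foods``.
    """

    foods: list[FoodRecord]
    cross_references: dict[str, str]

    def __len__(self) -> int:
        return len(self.foods)


def integrate_food_lists(
    ffq_foods: SourceTable,
    recall_table: SourceTable,
    threshold: float = DEFAULT_THRESHOLD,
) -> IntegratedFoodList:
    """Build the unified target food list for update and expansion.

    FFQ foods that match into the recall table carry a cross-reference
    instead of a duplicate entry; the rest are appended, so the output
    size is |recall| + |unmatched FFQ|.
    """
    foods = list(recall_table.foods)
    existing_ids = {f.food_id for f in foods}
    crossrefs: dict[str, str] = {}
    for f in ffq_foods:
        result = match_food(f, recall_table, threshold)
        if result.candidate_food_id is not None:
            crossrefs[f.food_id] = result.candidate_food_id
        else:
            if f.food_id in existing_ids:
                raise ValueError(
                    f"food_id collision: unmatched FFQ food {f.food_id!r} "
                    "already exists in the recall table"
                )
            foods.append(f)
            existing_ids.add(f.food_id)
    return IntegratedFoodList(foods=foods, cross_references=crossrefs)
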