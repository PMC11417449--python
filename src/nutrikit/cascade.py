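"""Priority-cascade nutrient updates with per-value provenance.

Each food's nutrients are refreshed from an ordered stack of source
tables, newest (rank 1) first: the value applied is the one from the
highest-priority source whose matched food reports it.  If no source
covers a nutrient, the pre-existing database's value is retained, and a
retained MISSING stays MISSING.  Every resolved cell records which source
supplied it and through which match tier, so sensitivity analyses can
exclude, say, values obtained through substituted matches.

Derived nutrients (vitamin A as RE/RAE) are by default recomputed from
retinol and β-carotene after the cascade rather than cascaded directly;
see :mod:`nutrikit.units`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import (
    MISSING,
    FoodRecord,
    NutrientRegistry,
    ProvenancedValue,
    SourceTable,
)
from .matching import MatchResult
from .units import derive_all

#: match_results type: (food_id, source_id) -> MatchResult
MatchMap = dict[tuple[str, str], MatchResult]


def match_sources(
    existing_db: SourceTable,
    ordered_sources: list[SourceTable],
    threshold: float = 0.20,
) -> MatchMap:
    """Match every database food into every source table.

    The cascade consumes this map; precomputing it keeps matching (slow,
    name-based) separate from resolution (fast, rank-based) and lets a
    reviewer audit the matches before any value moves.
    """
    from .matching import match_food

    results: MatchMap = {}
    for source in ordered_sources:
        for food in existing_db:
            results[(food.food_id, source.source_id)] = match_food(
                food, source, threshold
            )
    return results


@dataclass
class UpdatedDatabase:
    foods: list[FoodRecord]
    provenance: dict[tuple[str, str], ProvenancedValue] = field(default_factory=dict)
    semantics: dict[str, str] = field(default_factory=dict)

    def by_id(self) -> dict[str, FoodRecord]:
        return {f.food_id: f for f in self.foods}

    def as_table(self, source_id: str = "updated") -> SourceTable:
        return SourceTable(
            source_id=source_id,
            label=source_id,
            priority_rank=1,
            foods=self.foods,
            semantics=dict(self.semantics),
        )


@dataclass(frozen=True)
class CoverageRow:
    nutrient_id: str
    n_foods_with_value: int
    n_foods_total: int

    @property
    def coverage_percent(self) -> float:
        return round(100.0 * self.n_foods_with_value / self.n_foods_total, 1)


@dataclass
class CoverageReport:
    rows: dict[str, CoverageRow]

    def percent(self, nutrient_id: str) -> float:
        return self.rows[nutrient_id].coverage_percent


def resolve_value(
    food: FoodRecord,
    nutrient_id: str,
    ordered_sources: list[SourceTable],
    existing_db: SourceTable,
    match_results: MatchMap,
) -> ProvenancedValue:
    """Resolve one (food, nutrient) cell through the source cascade.

    Sources are scanned in priority order; the first non-MISSING value of
    the matched food wins.  With no provider the existing database's
    value is retained (source_id ``"retained"``), MISSING included.
    """
    for source in sorted(ordered_sources, key=lambda s: s.priority_rank):
        result = match_results.get((food.food_id, source.source_id))
        if result is None or result.candidate_food_id is None:
            continue
        candidate = source.get(result.candidate_food_id)
        if candidate is None:
            raise ValueError(
                f"match for food {food.food_id!r} references unknown food "
                f"{result.candidate_food_id!r} in source {source.source_id!r}"
            )
        value = candidate.get(nutrient_id)
        if value is not MISSING:
            return ProvenancedValue(nutrient_id, value, source.source_id, result.tier)
    existing = existing_db.get(food.food_id)
    value = existing.get(nutrient_id) if existing is not None else MISSING
    return ProvenancedValue(nutrient_id, value, "retained", "retained")


def update_database(
    existing_db: SourceTable,
    ordered_sources: list[SourceTable],
    match_results: MatchMap,
    registry: NutrientRegistry,
    *,
    recompute_derived: bool = True,
) -> UpdatedDatabase:
    """Apply the cascade to every (food, nutrient) cell of the database.

    The output food list is identical to the input food list: no food
    gains or loses identity through an update.  Derived nutrients are
    recomputed from their inputs after resolution when
    ``recompute_derived`` is true (the default), otherwise cascaded like
    any other column.
    """
    known = {f.food_id for f in existing_db}
    for (food_id, _sid) in match_results:
        if food_id not in known:
            raise ValueError(f"match result references unknown food {food_id!r}")

    measured = registry.measured_ids()
    derived = registry.derived_ids()
    cascade_ids = measured if recompute_derived else measured + derived

    foods: list[FoodRecord] = []
    provenance: dict[tuple[str, str], ProvenancedValue] = {}
    for food in existing_db:
        values: dict[str, Optional[float]] = {}
        for nid in cascade_ids:
            pv = resolve_value(food, nid, ordered_sources, existing_db, match_results)
            values[nid] = pv.value
            provenance[(food.food_id, nid)] = pv
        foods.append(
            FoodRecord(
                food_id=food.food_id,
                name_ko=food.name_ko,
                name_en=food.name_en,
                state=food.state,
                brand=food.brand,
                values=values,
            )
        )

    db = UpdatedDatabase(
        foods=foods, provenance=provenance, semantics=dict(existing_db.semantics)
    )
    if recompute_derived and derived:
        derive_all(db.foods, registry, provenance=db.provenance)
    return db


def coverage(
    db: SourceTable | UpdatedDatabase,
    nutrient_ids: list[str],
    food_subset: Optional[list[str]] = None,
) -> CoverageReport:
    """Percent of foods with a non-MISSING value, per nutrient.

    ``food_subset`` restricts the denominator (e.g. the FFQ food list
    within a larger database); it defaults to every food in the database.
    """
    foods = db.foods if isinstance(db, UpdatedDatabase) else list(db)
    by_id = {f.food_id: f for f in foods}
    if food_subset is None:
        subset = list(by_id)
    else:
        unknown = [fid for fid in food_subset if fid not in by_id]
        if unknown:
            raise ValueError(f"food_subset contains unknown foods: {unknown}")
        subset = list(food_subset)
    if not subset:
        raise ValueError("coverage is undefined for an empty food subset")
    rows = {}
    for nid in nutrient_ids:
        n_with = sum(1 for fid in subset if by_id[fid].get(nid) is not MISSING)
        rows[nid] = CoverageRow(nid, n_with, len(subset))
    return CoverageReport(rows)
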