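"""Domain types for food composition databases.

A composition table stores nutrient values per 100 g of edible portion,
one row per food.  A value may be MISSING (the food was never analysed for
that nutrient), which is deliberately distinct from 0 (the food was
analysed and contains none): coverage statistics and the source cascade
both hinge on that distinction.

MISSING is represented as ``None`` throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: Sentinel for an absent nutrient value.  Kept as a named alias so call
#: sites read ``value is MISSING`` rather than a bare ``None`` check.
MISSING = None

VALID_UNITS = frozenset({"kcal", "g", "mg", "µg", "RE", "RAE"})
VALID_CATEGORIES = frozenset(
    {
        "macronutrient",
        "fiber",
        "vitamin",
        "mineral",
        "amino_acid",
        "fatty_acid",
        "sterol",
        "derived",
    }
)
VALID_STATES = frozenset({"raw", "cooked", "dried", "processed", "unspecified"})

#: Match tiers, best first.  ``unmatched`` is a value, not an error.
MATCH_TIERS = ("name_exact", "name_exact_substituted", "state_relaxed", "unmatched")


@dataclass(frozen=True)
class NutrientDef:
    """One nutrient's identity, unit and derivation class.

    ``derived`` is true only for nutrients computed from others, such as
    vitamin A expressed as retinol equivalents (RE = retinol + β-carotene/6)
    or retinol activity equivalents (RAE = retinol + β-carotene/12).
    """

    nutrient_id: str
    display_name: str
    unit: str
    category: str
    derived: bool = False

    def __post_init__(self) -> None:
        if not self.nutrient_id:
            raise ValueError("nutrient_id must be non-empty")
        if self.unit not in VALID_UNITS:
            raise ValueError(
                f"unknown unit {self.unit!r} for nutrient {self.nutrient_id!r}; "
                f"expected one of {sorted(VALID_UNITS)}"
            )
        if self.category not in VALID_CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r} for nutrient "
                f"{self.nutrient_id!r}"
            )

    @property
    def column(self) -> str:
        """CSV column header: nutrient id with the unit as suffix."""
        return f"{self.nutrient_id}_{self.unit}"


class NutrientRegistry:
    """Ordered collection of nutrient definitions, unique by id."""

    def __init__(self, nutrients: list[NutrientDef]):
        self._by_id: dict[str, NutrientDef] = {}
        for n in nutrients:
            if n.nutrient_id in self._by_id:
                raise ValueError(f"duplicate nutrient_id {n.nutrient_id!r}")
            self._by_id[n.nutrient_id] = n

    def __contains__(self, nutrient_id: str) -> bool:
        return nutrient_id in self._by_id

    def __getitem__(self, nutrient_id: str) -> NutrientDef:
        return self._by_id[nutrient_id]

    def __iter__(self):
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    @property
    def ids(self) -> list[str]:
        return list(self._by_id)

    def measured_ids(self) -> list[str]:
        return [n.nutrient_id for n in self if not n.derived]

    def derived_ids(self) -> list[str]:
        return [n.nutrient_id for n in self if n.derived]

    def column_map(self) -> dict[str, str]:
        """Map CSV column header -> nutrient_id."""
        return {n.column: n.nutrient_id for n in self}


@dataclass
class FoodRecord:
    """One food with its per-100 g nutrient values.

    ``values`` maps nutrient_id to a non-negative quantity per 100 g of the
    edible portion, or MISSING.  Keys must be known to the registry the
    record was read with; readers enforce this.
    """

    food_id: str
    name_ko: str
    name_en: str
    state: str = "unspecified"
    brand: Optional[str] = None
    values: dict[str, Optional[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.food_id:
            raise ValueError("food_id must be non-empty")
        if self.state not in VALID_STATES:
            raise ValueError(
                f"unknown state {self.state!r} for food {self.food_id!r}"
            )
        for nid, v in self.values.items():
            if v is not MISSING and v < 0:
                raise ValueError(
                    f"negative value {v} for nutrient {nid!r} in food "
                    f"{self.food_id!r}"
                )

    def get(self, nutrient_id: str) -> Optional[float]:
        return self.values.get(nutrient_id, MISSING)


@dataclass
class SourceTable:
    """A prioritized composition table; rank 1 is applied first (newest).

    ``semantics`` carries optional per-nutrient measurement-semantics
    labels (e.g. ``fiber -> "crude"`` vs ``"total_dietary"``) so that
    pre/post comparisons can warn when a nutrient's meaning, not just its
    value, changed between databases.
    """

    source_id: str
    label: str
    priority_rank: int
    foods: list[FoodRecord] = field(default_factory=list)
    semantics: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.priority_rank < 1:
            raise ValueError("priority_rank must be a positive integer")
        seen: set[str] = set()
        for f in self.foods:
            if f.food_id in seen:
                raise ValueError(
                    f"duplicate food_id {f.food_id!r} in source "
                    f"{self.source_id!r}"
                )
            seen.add(f.food_id)

    def __iter__(self):
        return iter(self.foods)

    def __len__(self) -> int:
        return len(self.foods)

    def by_id(self) -> dict[str, FoodRecord]:
        return {f.food_id: f for f in self.foods}

    def get(self, food_id: str) -> Optional[FoodRecord]:
        for f in self.foods:
            if f.food_id == food_id:
                return f
        return None


@dataclass(frozen=True)
class ProvenancedValue:
    """One resolved nutrient value with its origin.

    ``source_id`` is a registered source id when the value came from the
    cascade, ``"retained"`` when the pre-existing database's value was
    kept (including a retained MISSING), or ``"derived"`` when the value
    was recomputed from other nutrients after the cascade.
    """

    nutrient_id: str
    value: Optional[float]
    source_id: str
    match_tier: str

    def __post_init__(self) -> None:
        if self.match_tier not in MATCH_TIERS + ("retained", "derived"):
            raise ValueError(f"unknown match tier {self.match_tier!r}")
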