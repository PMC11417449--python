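"""Unit harmonization and derived vitamin-A equivalents.

Vitamin A activity is expressed on two scales, both computed from retinol
and β-carotene contents (µg per 100 g):

    RE  (retinol equivalent)          = retinol + β-carotene / 6
    RAE (retinol activity equivalent) = retinol + β-carotene / 12

RAE is the scale used by current dietary reference intakes; RE is kept
for continuity with older databases, and RAE ≤ RE always holds since the
β-carotene conversion factor halves.  Only β-carotene contributes here;
other provitamin-A carotenoids are not modelled.

Fiber and vitamin B6 need *semantic* tags rather than arithmetic: crude
fiber versus total dietary fiber, and pyridoxine-only versus total B6,
are different measurements sharing a column name.  ``tag_semantics``
attaches the label so pre/post comparisons can warn when a nutrient's
meaning changed between databases (switching crude → total dietary fiber
alone inflates apparent fiber intake severalfold).
"""

from __future__ import annotations

from typing import Optional

from .model import MISSING, FoodRecord, NutrientRegistry, ProvenancedValue, SourceTable

#: Mass units convertible by pure power-of-1000 scaling.
_MASS_FACTORS = {"g": 1.0, "mg": 1e-3, "µg": 1e-6}

#: formula id -> (β-carotene divisor)
DERIVATIONS = {"RE": 6.0, "RAE": 12.0}

#: default derived-column wiring: nutrient_id -> (formula, retinol id, carotene id)
DEFAULT_DERIVED_INPUTS = {
    "vitamin_a_re": ("RE", "retinol", "beta_carotene"),
    "vitamin_a_rae": ("RAE", "retinol", "beta_carotene"),
}


def _vitamin_a(
    retinol_ug: Optional[float],
    beta_carotene_ug: Optional[float],
    divisor: float,
    missing_carotene_as_zero: bool,
) -> Optional[float]:
    if retinol_ug is not MISSING and retinol_ug < 0:
        raise ValueError("retinol must be non-negative")
    if beta_carotene_ug is not MISSING and beta_carotene_ug < 0:
        raise ValueError("beta-carotene must be non-negative")
    if beta_carotene_ug is MISSING and missing_carotene_as_zero:
        beta_carotene_ug = 0.0
    if retinol_ug is MISSING or beta_carotene_ug is MISSING:
        return MISSING
    return retinol_ug + beta_carotene_ug / divisor


def compute_re(
    retinol_ug: Optional[float],
    beta_carotene_ug: Optional[float],
    *,
    missing_carotene_as_zero: bool = False,
) -> Optional[float]:
    """Retinol equivalents: retinol + β-carotene/6 (µg basis).

    A MISSING input yields MISSING by default; set
    ``missing_carotene_as_zero`` to treat an unreported β-carotene as 0.
    """
    return _vitamin_a(retinol_ug, beta_carotene_ug, 6.0, missing_carotene_as_zero)


def compute_rae(
    retinol_ug: Optional[float],
    beta_carotene_ug: Optional[float],
    *,
    missing_carotene_as_zero: bool = False,
) -> Optional[float]:
    """Retinol activity equivalents: retinol + β-carotene/12 (µg basis)."""
    return _vitamin_a(retinol_ug, beta_carotene_ug, 12.0, missing_carotene_as_zero)


def convert_unit(value: float, from_unit: str, to_unit: str) -> float:
    """Exact power-of-1000 scaling within the g/mg/µg family.

    Identity when units are equal; any other pairing (kcal → g, RE → mg)
    is incompatible and raises.
    """
    if from_unit == to_unit:
        return value
    if from_unit not in _MASS_FACTORS or to_unit not in _MASS_FACTORS:
        raise ValueError(f"cannot convert {from_unit!r} to {to_unit!r}")
    return value * (_MASS_FACTORS[from_unit] / _MASS_FACTORS[to_unit])


def derive_all(
    foods: list[FoodRecord],
    registry: NutrientRegistry,
    *,
    derived_inputs: Optional[dict[str, tuple[str, str, str]]] = None,
    missing_carotene_as_zero: bool = False,
    provenance: Optional[dict[tuple[str, str], ProvenancedValue]] = None,
) -> None:
    """Recompute every derived nutrient column in place.

    ``derived_inputs`` wires each derived nutrient_id to its formula and
    input columns; the default covers vitamin A as RE and RAE.  When a
    provenance map is given, recomputed cells are recorded with
    source_id ``"derived"``.
    """
    wiring = derived_inputs or DEFAULT_DERIVED_INPUTS
    for nid in registry.derived_ids():
        if nid not in wiring:
            raise ValueError(f"no derivation declared for derived nutrient {nid!r}")
        formula, retinol_id, carotene_id = wiring[nid]
        divisor = DERIVATIONS[formula]
        for food in foods:
            value = _vitamin_a(
                food.get(retinol_id),
                food.get(carotene_id),
                divisor,
                missing_carotene_as_zero,
            )
            food.values[nid] = value
            if provenance is not None:
                provenance[(food.food_id, nid)] = ProvenancedValue(
                    nid, value, "derived", "derived"
                )


def tag_semantics(db: SourceTable, nutrient_id: str, semantics_label: str) -> SourceTable:
    """Attach a measurement-semantics label to a nutrient (in place).

    Typical labels: ``fiber`` tagged ``crude`` versus ``total_dietary``;
    ``vitamin_b6`` tagged ``pyridoxine`` versus ``total``.  Tagging twice
    with the same label is idempotent.
    """
    if not _known(db, nutrient_id):
        raise ValueError(f"unknown nutrient {nutrient_id!r}")
    db.semantics[nutrient_id] = semantics_label
    return db


def _known(db: SourceTable, nutrient_id: str) -> bool:
    return any(nutrient_id in f.values for f in db)


def semantics_warnings(pre: SourceTable, post: SourceTable) -> dict[str, str]:
    """Nutrients whose measurement semantics differ between two databases."""
    warnings = {}
    for nid, pre_label in pre.semantics.items():
        post_label = post.semantics.get(nid)
        if post_label is not None and post_label != pre_label:
            warnings[nid] = (
                f"semantics changed from {pre_label!r} to {post_label!r}; "
                "pre/post intake differences partly reflect a definition "
                "change, not a content change"
            )
    return warnings
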