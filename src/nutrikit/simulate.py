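"""Synthetic composition tables, instruments and survey responses.

The generator emulates the statistical shape of a database-revision
study at desk scale: a pre-revision composition table for a few dozen
foods; a stack of partially overlapping, noisier source tables with a
priority order; a handful of large injected per-food nutrient changes
planted in the newest source (a staple vegetable's sodium falling from
1146 to 624 mg/100 g, a staple grain's fiber rising from 0.1 to
1.2 g/100 g, a legume's fiber rising from 4.0 to 20.8 g/100 g while its
vitamin B6 collapses — the kind of shift that dominates population-level
intake changes); and FFQ/recall responses with skewed frequency and
portion distributions.

Every cell's expected post-cascade value and provenance is recorded in
``truth`` by construction, so the match → update pipeline can be checked
end to end.  Truth assumes name-exact matching: a source row whose name
was perturbed (or whose macronutrients were made deliberately outlying)
is treated as not matched in that source, so truth is exact whenever
``name_perturbation_rate`` is 0 and no outliers are configured — the
default — and those knobs exist purely to stress the matcher.

All randomness flows from the single config seed through independent
named streams, so outputs are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .intake import (
    DEFAULT_FREQUENCY_LEVELS,
    DEFAULT_PORTION_LEVELS,
    FFQInstrument,
    FFQItem,
    FFQResponse,
    RecallRecord,
    ResponseEntry,
)
from .model import MISSING, FoodRecord, NutrientDef, NutrientRegistry, SourceTable
from .units import derive_all

COMPARISON = ("energy", "carbohydrate", "protein", "fat", "water")

#: typical per-100 g ranges used to draw baseline values, (low, high)
_VALUE_RANGES: dict[str, tuple[float, float]] = {
    "carbohydrate": (1.0, 80.0),
    "protein": (0.5, 30.0),
    "fat": (0.1, 25.0),
    "water": (5.0, 95.0),
    "fiber": (0.1, 8.0),
    "sodium": (2.0, 1500.0),
    "calcium": (5.0, 300.0),
    "potassium": (30.0, 600.0),
    "vitamin_b6": (0.01, 1.0),
    "vitamin_c": (0.0, 60.0),
    "retinol": (0.0, 150.0),
    "beta_carotene": (0.0, 3000.0),
}

#: Energy and water are laid out on a multiplicative grid so that any two
#: distinct synthetic foods differ by well over the 20% similarity
#: threshold on at least one reference nutrient, even after ±10%
#: multiplicative noise.  This makes cross-food similarity impossible by
#: construction, which is what lets the generator state each cell's
#: post-cascade truth exactly.
_GRID_FACTOR = 1.4
_ENERGY_LEVELS = 10
_ENERGY_BASE = 25.0
_WATER_BASE = 5.0


def _grid_macros(i: int) -> tuple[float, float]:
    energy = _ENERGY_BASE * _GRID_FACTOR ** (i % _ENERGY_LEVELS)
    water = _WATER_BASE * _GRID_FACTOR ** (i // _ENERGY_LEVELS)
    return float(np.round(energy, 3)), float(np.round(water, 3))


def default_registry() -> NutrientRegistry:
    """A compact registry: the five reference macronutrients, the nutrients
    whose revisions dominate intake changes, and derived vitamin A."""
    return NutrientRegistry(
        [
            NutrientDef("energy", "Energy", "kcal", "macronutrient"),
            NutrientDef("carbohydrate", "Carbohydrate", "g", "macronutrient"),
            NutrientDef("protein", "Protein", "g", "macronutrient"),
            NutrientDef("fat", "Fat", "g", "macronutrient"),
            NutrientDef("water", "Water", "g", "macronutrient"),
            NutrientDef("fiber", "Fiber", "g", "fiber"),
            NutrientDef("sodium", "Sodium", "mg", "mineral"),
            NutrientDef("calcium", "Calcium", "mg", "mineral"),
            NutrientDef("potassium", "Potassium", "mg", "mineral"),
            NutrientDef("vitamin_b6", "Vitamin B6", "mg", "vitamin"),
            NutrientDef("vitamin_c", "Vitamin C", "mg", "vitamin"),
            NutrientDef("retinol", "Retinol", "µg", "vitamin"),
            NutrientDef("beta_carotene", "β-carotene", "µg", "vitamin"),
            NutrientDef("vitamin_a_re", "Vitamin A (RE)", "RE", "derived", derived=True),
            NutrientDef("vitamin_a_rae", "Vitamin A (RAE)", "RAE", "derived", derived=True),
        ]
    )


@dataclass(frozen=True)
class InjectedChange:
    """A planted per-food revision: pre value in the old database, post
    value in the highest-priority source."""

    food_id: str
    nutrient_id: str
    pre_value: float
    post_value: float


def default_injected_changes() -> list[InjectedChange]:
    # staple-food revisions of the magnitude that drives population intake
    # shifts: fermented cabbage sodium, cooked grain fiber, legume fiber/B6
    return [
        InjectedChange("food_000", "sodium", 1146.0, 624.0),
        InjectedChange("food_001", "fiber", 0.1, 1.2),
        InjectedChange("food_002", "fiber", 4.0, 20.8),
        InjectedChange("food_002", "vitamin_b6", 0.54, 0.05),
    ]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_foods: int = 60
    n_sources: int = 3
    #: per-source probability that a food appears in the source at all
    source_coverage: float = 0.8
    #: per-cell probability that a covered food's non-reference nutrient
    #: is still unreported in a source
    cell_missing_rate: float = 0.10
    #: probability that a pre-database non-reference nutrient is missing
    pre_missing_rate: float = 0.10
    #: fraction of source rows whose names are garbled (stress knob;
    #: breaks the truth guarantee for the affected cells)
    name_perturbation_rate: float = 0.0
    #: multiplicative macronutrient noise, uniform in ±scale; must stay
    #: below the 0.20 similarity threshold for name matches to hold
    noise_scale: float = 0.05
    injected_changes: list[InjectedChange] = field(
        default_factory=default_injected_changes
    )
    #: foods whose source-row macronutrients are scaled far beyond the
    #: similarity threshold (stress knob for the ±20% rule)
    macro_outlier_food_ids: list[str] = field(default_factory=list)
    n_persons: int = 500
    n_items: int = 40
    seasonal_fraction: float = 0.15
    frequency_weights: list[float] = field(
        default_factory=lambda: [0.25, 0.15, 0.13, 0.15, 0.12, 0.08, 0.07, 0.03, 0.02]
    )
    portion_weights: list[float] = field(default_factory=lambda: [0.25, 0.5, 0.25])
    recall_n_days: int = 2
    recall_foods_per_day: int = 8
    recall_grams_log_mean: float = 4.1  # exp(4.1) ≈ 60 g
    recall_grams_log_sd: float = 0.6

    def __post_init__(self) -> None:
        for frac in (
            self.source_coverage,
            self.cell_missing_rate,
            self.pre_missing_rate,
            self.name_perturbation_rate,
            self.seasonal_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if not 0.0 <= self.noise_scale <= 0.10:
            raise ValueError(
                "noise_scale must lie in [0, 0.10]: beyond that the "
                "macronutrient grid no longer guarantees cross-food "
                "dissimilarity and the truth map would be unreliable"
            )
        if self.n_foods > _ENERGY_LEVELS * _ENERGY_LEVELS:
            raise ValueError("at most 100 synthetic foods are supported")

    def stream(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, tag])


@dataclass
class SimulatedTables:
    registry: NutrientRegistry
    pre_db: SourceTable
    sources: list[SourceTable]
    #: (food_id, nutrient_id) -> (expected post-cascade value, source_id)
    truth: dict[tuple[str, str], tuple[Optional[float], str]]


_STATES = ("raw", "cooked", "processed", "dried")
_NAME_WORDS = ("braised", "steamed", "pickled", "fresh", "fried", "dried", "boiled")


def _food_names(i: int) -> tuple[str, str]:
    word = _NAME_WORDS[i % len(_NAME_WORDS)]
    return f"sikpum {i:03d} {word}", f"food {i:03d} {word}"


def generate_food_tables(config: SimulationConfig) -> SimulatedTables:
    """Generate the pre-revision database, the prioritized source stack
    and the per-cell expected post-cascade truth."""
    registry = default_registry()
    rng = config.stream(0)
    measured = registry.measured_ids()
    injected_by_cell = {(c.food_id, c.nutrient_id): c for c in config.injected_changes}

    food_ids = [f"food_{i:03d}" for i in range(config.n_foods)]
    for change in config.injected_changes:
        if change.food_id not in food_ids:
            raise ValueError(
                f"injected change references unknown food {change.food_id!r}"
            )

    # --- pre-revision database
    pre_foods = []
    for i, fid in enumerate(food_ids):
        name_ko, name_en = _food_names(i)
        energy, water = _grid_macros(i)
        values: dict[str, Optional[float]] = {"energy": energy, "water": water}
        for nid in measured:
            if nid in ("energy", "water"):
                continue
            low, high = _VALUE_RANGES[nid]
            v = float(np.round(rng.uniform(low, high), 3))
            if (fid, nid) in injected_by_cell:
                v = injected_by_cell[(fid, nid)].pre_value
            elif nid not in COMPARISON and rng.random() < config.pre_missing_rate:
                values[nid] = MISSING
                continue
            values[nid] = v
        pre_foods.append(
            FoodRecord(
                food_id=fid,
                name_ko=name_ko,
                name_en=name_en,
                state=_STATES[i % len(_STATES)],
                values=values,
            )
        )
    derive_all(pre_foods, registry)
    pre_db = SourceTable("pre", "pre-revision database", 1, pre_foods)

    # --- source stack, rank 1 = newest
    sources: list[SourceTable] = []
    clean: dict[tuple[str, str], bool] = {}  # (food_id, source_id) -> row usable in truth
    for rank in range(1, config.n_sources + 1):
        sid = f"source_{rank}"
        rows = []
        for i, food in enumerate(pre_foods):
            fid = food.food_id
            has_injection = rank == 1 and any(
                c.food_id == fid for c in config.injected_changes
            )
            if not has_injection and rng.random() > config.source_coverage:
                continue
            outlier = fid in config.macro_outlier_food_ids
            perturbed_name = rng.random() < config.name_perturbation_rate
            clean[(fid, sid)] = not (outlier or perturbed_name)
            values: dict[str, Optional[float]] = {}
            for nid in measured:
                base = food.get(nid)
                cell = injected_by_cell.get((fid, nid))
                if cell is not None and rank == 1:
                    values[nid] = cell.post_value
                    continue
                if base is MISSING:
                    values[nid] = MISSING
                    continue
                if nid not in COMPARISON and rng.random() < config.cell_missing_rate:
                    values[nid] = MISSING
                    continue
                noisy = base * (1.0 + rng.uniform(-config.noise_scale, config.noise_scale))
                if outlier and nid in COMPARISON:
                    noisy = base * 1.5  # far beyond the similarity threshold
                values[nid] = float(np.round(noisy, 6))
            name_ko, name_en = food.name_ko, food.name_en
            if perturbed_name:
                name_ko = f"{name_ko} byeonhyeong"
                name_en = f"{name_en} variant"
            rows.append(
                FoodRecord(
                    food_id=f"{sid}_{fid}",
                    name_ko=name_ko,
                    name_en=name_en,
                    state=food.state,
                    values=values,
                )
            )
        sources.append(SourceTable(sid, f"synthetic source rank {rank}", rank, rows))

    # --- truth: first non-missing value in priority order over clean rows
    truth: dict[tuple[str, str], tuple[Optional[float], str]] = {}
    tainted = {fid for (fid, _sid), ok in clean.items() if not ok}
    for food in pre_foods:
        fid = food.food_id
        if fid in tainted:
            continue  # matching outcome not guaranteed by construction
        for nid in measured:
            resolved: tuple[Optional[float], str] | None = None
            for source in sources:
                if not clean.get((fid, source.source_id), False):
                    continue
                row = source.get(f"{source.source_id}_{fid}")
                if row is not None and row.get(nid) is not MISSING:
                    resolved = (row.get(nid), source.source_id)
                    break
            if resolved is None:
                resolved = (food.get(nid), "retained")
            truth[(fid, nid)] = resolved

    return SimulatedTables(registry=registry, pre_db=pre_db, sources=sources, truth=truth)


def generate_instrument(config: SimulationConfig, pre_db: SourceTable) -> FFQInstrument:
    """An FFQ instrument over the first ``n_items`` foods of the database."""
    rng = config.stream(1)
    items = []
    foods = pre_db.foods[: config.n_items]
    for i, food in enumerate(foods):
        items.append(
            FFQItem(
                item_id=f"item_{i:03d}",
                food_id=food.food_id,
                serving_size_g=float(np.round(rng.uniform(30.0, 150.0), 1)),
                seasonal=bool(rng.random() < config.seasonal_fraction),
            )
        )
    return FFQInstrument(items=items)


def generate_responses(
    config: SimulationConfig, instrument: FFQInstrument
) -> list[FFQResponse]:
    """FFQ responses: categorical frequency/portion draws per item, four
    quarterly draws for seasonal items."""
    rng = config.stream(2)
    freq_levels = list(DEFAULT_FREQUENCY_LEVELS)
    portion_levels = list(DEFAULT_PORTION_LEVELS)
    fw = np.asarray(config.frequency_weights, dtype=float)
    fw = fw / fw.sum()
    pw = np.asarray(config.portion_weights, dtype=float)
    pw = pw / pw.sum()
    responses = []
    for p in range(config.n_persons):
        resp = FFQResponse(person_id=f"person_{p:04d}")
        for item in instrument.items:
            n_entries = 4 if item.seasonal else 1
            entries = []
            for q in range(n_entries):
                entries.append(
                    ResponseEntry(
                        frequency_level=freq_levels[int(rng.choice(9, p=fw))],
                        portion_level=portion_levels[int(rng.choice(3, p=pw))],
                        quarter=(q + 1) if item.seasonal else None,
                    )
                )
            resp.entries[item.item_id] = entries
        responses.append(resp)
    return responses


def generate_recalls(
    config: SimulationConfig, pre_db: SourceTable
) -> dict[str, list[RecallRecord]]:
    """Multi-day 24-hour-recall records with log-normal gram amounts."""
    rng = config.stream(3)
    food_ids = [f.food_id for f in pre_db]
    records: dict[str, list[RecallRecord]] = {}
    for p in range(config.n_persons):
        pid = f"person_{p:04d}"
        days = []
        for day in range(1, config.recall_n_days + 1):
            chosen = rng.choice(
                len(food_ids),
                size=min(config.recall_foods_per_day, len(food_ids)),
                replace=False,
            )
            consumed = [
                (
                    food_ids[int(j)],
                    float(
                        np.round(
                            rng.lognormal(
                                config.recall_grams_log_mean, config.recall_grams_log_sd
                            ),
                            1,
                        )
                    ),
                )
                for j in sorted(chosen)
            ]
            days.append(RecallRecord(person_id=pid, day_index=day, consumed=consumed))
        records[pid] = days
    return records
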