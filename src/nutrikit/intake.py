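"""Per-person daily nutrient intake from FFQ and 24-hour-recall data.

FFQ estimation is the classical semi-quantitative product form: for each
questionnaire item,

    intake = frequency weight (times/day) × portion multiplier
             × reference serving (g) × nutrient per 100 g / 100

summed over items.  Frequencies come from a 9-category scale mapped to
daily equivalents by the midpoint convention; portions are small, medium
or large multipliers of the reference serving.  Seasonal items (fruits,
some vegetables) are asked once per quarter and averaged over four
quarters, an unreported quarter counting as zero intake.

24-hour recall is direct: grams consumed × nutrient per 100 g, summed
within a day and averaged over the available days (typically two
non-consecutive days).

A MISSING composition value contributes nothing to intake but is counted
in the result's coverage deficit, since intakes of sparsely covered
nutrients are underestimates, not zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import yaml

from .model import MISSING, SourceTable

#: 9-level frequency scale -> daily-equivalent weights (midpoint convention).
DEFAULT_FREQUENCY_LEVELS: dict[str, float] = {
    "never": 0.0,
    "once_per_month": 1.0 / 30.0,
    "2_3_per_month": 2.5 / 30.0,
    "1_2_per_week": 1.5 / 7.0,
    "3_4_per_week": 3.5 / 7.0,
    "5_6_per_week": 5.5 / 7.0,
    "once_per_day": 1.0,
    "twice_per_day": 2.0,
    "3plus_per_day": 3.0,
}

DEFAULT_PORTION_LEVELS: dict[str, float] = {"small": 0.5, "medium": 1.0, "large": 1.5}

N_QUARTERS = 4


@dataclass(frozen=True)
class FFQItem:
    item_id: str
    food_id: str
    serving_size_g: float  # mass of one medium portion
    seasonal: bool = False


@dataclass
class FFQInstrument:
    """Questionnaire definition: items plus frequency/portion level tables."""

    items: list[FFQItem]
    frequency_levels: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FREQUENCY_LEVELS)
    )
    portion_levels: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PORTION_LEVELS)
    )

    def __post_init__(self) -> None:
        if len(self.frequency_levels) != 9:
            raise ValueError("an FFQ instrument needs exactly 9 frequency levels")
        if len(self.portion_levels) != 3:
            raise ValueError("an FFQ instrument needs exactly 3 portion levels")
        weights = list(self.frequency_levels.values())
        if any(w < 0 for w in weights):
            raise ValueError("frequency daily equivalents must be non-negative")
        if any(b < a for a, b in zip(weights, weights[1:])):
            raise ValueError("frequency daily equivalents must be non-decreasing")
        seen: set[str] = set()
        for item in self.items:
            if item.item_id in seen:
                raise ValueError(f"duplicate item_id {item.item_id!r}")
            seen.add(item.item_id)
            if item.serving_size_g < 0:
                raise ValueError(f"negative serving size for item {item.item_id!r}")

    def by_id(self) -> dict[str, FFQItem]:
        return {i.item_id: i for i in self.items}


@dataclass(frozen=True)
class ResponseEntry:
    """One (frequency, portion) answer; quarter is set for seasonal items."""

    frequency_level: str
    portion_level: str
    quarter: Optional[int] = None


@dataclass
class FFQResponse:
    person_id: str
    #: item_id -> entries; one entry for ordinary items, 1-4 quarterly
    #: entries for seasonal items
    entries: dict[str, list[ResponseEntry]] = field(default_factory=dict)


@dataclass
class RecallRecord:
    person_id: str
    day_index: int
    consumed: list[tuple[str, float]] = field(default_factory=list)  # (food_id, grams)

    def __post_init__(self) -> None:
        for food_id, grams in self.consumed:
            if grams < 0:
                raise ValueError(
                    f"negative grams for food {food_id!r}, person "
                    f"{self.person_id!r} day {self.day_index}"
                )


@dataclass
class IntakeResult:
    """Per-person daily intake with per-item/food breakdown.

    ``intakes`` maps nutrient_id to total daily intake in the nutrient's
    own unit; totals equal the sum of ``contributions`` (additivity).
    ``daily_grams`` is the mean grams/day of each underlying food, the
    consumption weight used by contribution analyses.  ``coverage_deficit``
    counts, per nutrient, how many consumed foods had a MISSING value and
    therefore contributed nothing.
    """

    person_id: str
    intakes: dict[str, float] = field(default_factory=dict)
    contributions: dict[str, dict[str, float]] = field(default_factory=dict)
    daily_grams: dict[str, float] = field(default_factory=dict)
    coverage_deficit: dict[str, int] = field(default_factory=dict)


def _food_contribution(
    food_values: dict[str, Optional[float]],
    grams_per_day: float,
    nutrient_ids: list[str],
    deficit: dict[str, int],
) -> dict[str, float]:
    contrib = {}
    for nid in nutrient_ids:
        per_100g = food_values.get(nid, MISSING)
        if per_100g is MISSING:
            if grams_per_day > 0:
                deficit[nid] = deficit.get(nid, 0) + 1
            contrib[nid] = 0.0
        else:
            contrib[nid] = grams_per_day * per_100g / 100.0
    return contrib


def item_daily_grams(
    item: FFQItem, entry: ResponseEntry, instrument: FFQInstrument
) -> float:
    """Daily grams implied by one answer: frequency × portion × serving."""
    try:
        freq = instrument.frequency_levels[entry.frequency_level]
    except KeyError:
        raise ValueError(f"unknown frequency level {entry.frequency_level!r}") from None
    try:
        mult = instrument.portion_levels[entry.portion_level]
    except KeyError:
        raise ValueError(f"unknown portion level {entry.portion_level!r}") from None
    return freq * mult * item.serving_size_g


def item_daily_intake(
    item: FFQItem,
    entry: ResponseEntry,
    db: SourceTable,
    instrument: FFQInstrument,
    nutrient_ids: Optional[list[str]] = None,
    deficit: Optional[dict[str, int]] = None,
) -> dict[str, float]:
    """Per-nutrient daily contribution of one non-seasonal answer."""
    food = db.get(item.food_id)
    if food is None:
        raise ValueError(f"item {item.item_id!r} links to unknown food {item.food_id!r}")
    grams = item_daily_grams(item, entry, instrument)
    nids = nutrient_ids if nutrient_ids is not None else sorted(food.values)
    return _food_contribution(food.values, grams, nids, deficit if deficit is not None else {})


def seasonal_item_grams(
    item: FFQItem, entries: list[ResponseEntry], instrument: FFQInstrument
) -> float:
    """Mean daily grams over four quarters; missing quarters count as zero."""
    if not item.seasonal:
        raise ValueError(f"item {item.item_id!r} is not seasonal")
    if not entries:
        raise ValueError(f"seasonal item {item.item_id!r} needs at least one entry")
    if len(entries) > N_QUARTERS:
        raise ValueError(f"seasonal item {item.item_id!r} has more than 4 entries")
    total = sum(item_daily_grams(item, e, instrument) for e in entries)
    return total / N_QUARTERS


def seasonal_item_intake(
    item: FFQItem,
    quarterly_entries: list[ResponseEntry],
    db: SourceTable,
    instrument: FFQInstrument,
    nutrient_ids: Optional[list[str]] = None,
    deficit: Optional[dict[str, int]] = None,
) -> dict[str, float]:
    """Per-nutrient contribution of a seasonal item (quarterly average)."""
    food = db.get(item.food_id)
    if food is None:
        raise ValueError(f"item {item.item_id!r} links to unknown food {item.food_id!r}")
    grams = seasonal_item_grams(item, quarterly_entries, instrument)
    nids = nutrient_ids if nutrient_ids is not None else sorted(food.values)
    return _food_contribution(food.values, grams, nids, deficit if deficit is not None else {})


def ffq_intake(
    response: FFQResponse,
    instrument: FFQInstrument,
    db: SourceTable,
    nutrient_ids: Optional[list[str]] = None,
) -> IntakeResult:
    """Daily nutrient intake of one person: sum over all item contributions."""
    items = instrument.by_id()
    if nutrient_ids is None:
        nutrient_ids = sorted({nid for f in db for nid in f.values})
    result = IntakeResult(
        person_id=response.person_id,
        intakes={nid: 0.0 for nid in nutrient_ids},
    )
    for item_id, entries in response.entries.items():
        if item_id not in items:
            raise ValueError(f"response references unknown item {item_id!r}")
        item = items[item_id]
        if item.seasonal:
            grams = seasonal_item_grams(item, entries, instrument)
        else:
            if len(entries) != 1:
                raise ValueError(
                    f"non-seasonal item {item_id!r} must have exactly one entry"
                )
            grams = item_daily_grams(item, entries[0], instrument)
        food = db.get(item.food_id)
        if food is None:
            raise ValueError(
                f"item {item_id!r} links to unknown food {item.food_id!r}"
            )
        contrib = _food_contribution(
            food.values, grams, nutrient_ids, result.coverage_deficit
        )
        result.contributions[item_id] = contrib
        result.daily_grams[item.food_id] = result.daily_grams.get(item.food_id, 0.0) + grams
        for nid, v in contrib.items():
            result.intakes[nid] += v
    return result


def recall_intake(
    records: list[RecallRecord],
    db: SourceTable,
    nutrient_ids: Optional[list[str]] = None,
) -> IntakeResult:
    """Daily intake of one person from 24-hour recalls: mean over days.

    All records must belong to the same person; an empty day contributes
    zero and still counts in the day denominator.
    """
    if not records:
        raise ValueError("at least one recall day is required")
    persons = {r.person_id for r in records}
    if len(persons) != 1:
        raise ValueError(f"records span multiple persons: {sorted(persons)}")
    days = {r.day_index for r in records}
    if len(days) != len(records):
        raise ValueError("duplicate day_index for person")
    if nutrient_ids is None:
        nutrient_ids = sorted({nid for f in db for nid in f.values})
    n_days = len(records)
    by_id = db.by_id()
    result = IntakeResult(
        person_id=records[0].person_id,
        intakes={nid: 0.0 for nid in nutrient_ids},
    )
    for record in records:
        for food_id, grams in record.consumed:
            food = by_id.get(food_id)
            if food is None:
                raise ValueError(f"recall references unknown food {food_id!r}")
            daily_grams = grams / n_days
            contrib = _food_contribution(
                food.values, daily_grams, nutrient_ids, result.coverage_deficit
            )
            fc = result.contributions.setdefault(food_id, {n: 0.0 for n in nutrient_ids})
            for nid, v in contrib.items():
                fc[nid] += v
                result.intakes[nid] += v
            result.daily_grams[food_id] = result.daily_grams.get(food_id, 0.0) + daily_grams
    return result


def population_mean_grams(results: list[IntakeResult]) -> dict[str, float]:
    """Population-mean daily grams per food (the consumption weights
    used by contribution analyses)."""
    if not results:
        return {}
    totals: dict[str, float] = {}
    for r in results:
        for food_id, g in r.daily_grams.items():
            totals[food_id] = totals.get(food_id, 0.0) + g
    n = len(results)
    return {fid: g / n for fid, g in totals.items()}


# --------------------------------------------------------------------------
# file formats


def read_instrument(path) -> FFQInstrument:
    """Read an instrument YAML (items, frequency/portion level tables)."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    items = [
        FFQItem(
            item_id=i["item_id"],
            food_id=i["food_id"],
            serving_size_g=float(i["serving_size_g"]),
            seasonal=bool(i.get("seasonal", False)),
        )
        for i in data["items"]
    ]
    return FFQInstrument(
        items=items,
        frequency_levels={k: float(v) for k, v in data["frequency_levels"].items()},
        portion_levels={k: float(v) for k, v in data["portion_levels"].items()},
    )


def write_instrument(instrument: FFQInstrument, path) -> None:
    data = {
        "items": [
            {
                "item_id": i.item_id,
                "food_id": i.food_id,
                "serving_size_g": i.serving_size_g,
                "seasonal": i.seasonal,
            }
            for i in instrument.items
        ],
        "frequency_levels": instrument.frequency_levels,
        "portion_levels": instrument.portion_levels,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False, allow_unicode=True)


def read_responses(path) -> list[FFQResponse]:
    """Read responses CSV: person_id,item_id,quarter,frequency_level,portion_level."""
    import csv

    by_person: dict[str, FFQResponse] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            pid = row["person_id"]
            resp = by_person.setdefault(pid, FFQResponse(person_id=pid))
            quarter = row.get("quarter", "").strip()
            entry = ResponseEntry(
                frequency_level=row["frequency_level"],
                portion_level=row["portion_level"],
                quarter=int(quarter) if quarter else None,
            )
            resp.entries.setdefault(row["item_id"], []).append(entry)
    return list(by_person.values())


def write_responses(responses: list[FFQResponse], path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["person_id", "item_id", "quarter", "frequency_level", "portion_level"])
        for resp in responses:
            for item_id, entries in resp.entries.items():
                for e in entries:
                    writer.writerow(
                        [resp.person_id, item_id,
                         "" if e.quarter is None else e.quarter,
                         e.frequency_level, e.portion_level]
                    )


def read_recalls(path) -> dict[str, list[RecallRecord]]:
    """Read recall CSV (person_id,day,food_id,grams) grouped by person."""
    import csv

    grouped: dict[str, dict[int, RecallRecord]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            pid, day = row["person_id"], int(row["day"])
            days = grouped.setdefault(pid, {})
            rec = days.setdefault(day, RecallRecord(pid, day))
            rec.consumed.append((row["food_id"], float(row["grams"])))
    return {pid: list(days.values()) for pid, days in grouped.items()}


def write_recalls(records: dict[str, list[RecallRecord]], path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["person_id", "day", "food_id", "grams"])
        for recs in records.values():
            for rec in recs:
                for food_id, grams in rec.consumed:
                    writer.writerow([rec.person_id, rec.day_index, food_id, grams])
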