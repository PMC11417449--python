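"""Delimited-text readers and writers for composition tables and registries.

File dialect: UTF-8, comma-delimited, dot decimal, header row mandatory.
An empty cell is MISSING; ``0.0`` is a real zero.  Thousands separators
("1,146.0") are accepted on input and never written on output.  Nutrient
columns carry the unit as a suffix (``sodium_mg``) and are validated
against the nutrient registry, so a unit mismatch between a file and the
registry is a hard error rather than a silent reinterpretation.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Union

import yaml

from .model import (
    MISSING,
    FoodRecord,
    NutrientDef,
    NutrientRegistry,
    SourceTable,
)

META_COLUMNS = ["food_id", "name_ko", "name_en", "state", "brand"]

PathLike = Union[str, Path]


def _parse_number(raw: str, *, context: str) -> float:
    """Parse a decimal number, stripping thousands separators."""
    cleaned = raw.strip().replace(",", "")
    try:
        value = float(cleaned)
    except ValueError as exc:
        raise ValueError(f"unparseable number {raw!r} ({context})") from exc
    if value < 0:
        raise ValueError(f"negative value {raw!r} ({context})")
    return value


def _format_number(value: float) -> str:
    # repr round-trips floats exactly; integers stay readable
    return repr(float(value))


def read_nutrient_registry(path: PathLike) -> NutrientRegistry:
    """Read a nutrient registry CSV: nutrient_id,display_name,unit,category,derived."""
    nutrients = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            nutrients.append(
                NutrientDef(
                    nutrient_id=row["nutrient_id"].strip(),
                    display_name=row["display_name"].strip(),
                    unit=row["unit"].strip(),
                    category=row["category"].strip(),
                    derived=row["derived"].strip().lower() in ("true", "1", "yes"),
                )
            )
    return NutrientRegistry(nutrients)


def write_nutrient_registry(registry: NutrientRegistry, path: PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["nutrient_id", "display_name", "unit", "category", "derived"])
        for n in registry:
            writer.writerow(
                [n.nutrient_id, n.display_name, n.unit, n.category,
                 "true" if n.derived else "false"]
            )


def read_food_table(
    path: PathLike,
    registry: NutrientRegistry,
    *,
    source_id: str = "table",
    label: str = "",
    priority_rank: int = 1,
) -> SourceTable:
    """Read a composition table CSV into a :class:`SourceTable`.

    Every row becomes a :class:`FoodRecord`; empty nutrient cells become
    MISSING, never 0.  Unknown nutrient columns, negative values and
    duplicate food ids are hard errors naming the offender.
    """
    column_map = registry.column_map()
    foods: list[FoodRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, header row is mandatory")
        nutrient_cols: list[tuple[str, str]] = []
        for col in reader.fieldnames:
            if col in META_COLUMNS:
                continue
            if col not in column_map:
                raise ValueError(
                    f"{path}: unknown nutrient column {col!r}; registry "
                    f"expects headers like "
                    f"{', '.join(sorted(column_map)[:3])}, ..."
                )
            nutrient_cols.append((col, column_map[col]))
        for row in reader:
            food_id = row["food_id"].strip()
            values: dict[str, float | None] = {}
            for col, nid in nutrient_cols:
                raw = (row.get(col) or "").strip()
                if raw == "":
                    values[nid] = MISSING
                else:
                    values[nid] = _parse_number(
                        raw, context=f"{path} food {food_id!r} column {col!r}"
                    )
            brand = row.get("brand", "").strip()
            foods.append(
                FoodRecord(
                    food_id=food_id,
                    name_ko=row.get("name_ko", "").strip(),
                    name_en=row.get("name_en", "").strip(),
                    state=row.get("state", "unspecified").strip() or "unspecified",
                    brand=brand or None,
                    values=values,
                )
            )
    return SourceTable(
        source_id=source_id,
        label=label or source_id,
        priority_rank=priority_rank,
        foods=foods,
    )


def write_food_table(
    table: SourceTable, path: PathLike, registry: NutrientRegistry
) -> None:
    """Write a composition table CSV that round-trips exactly.

    MISSING becomes an empty cell; 0.0 is written as ``0.0`` so the
    missing/zero distinction survives every read/write cycle.
    """
    columns = [n.column for n in registry]
    ids = registry.ids
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(META_COLUMNS + columns)
        for food in table:
            row = [
                food.food_id,
                food.name_ko,
                food.name_en,
                food.state,
                food.brand or "",
            ]
            for nid in ids:
                v = food.get(nid)
                row.append("" if v is MISSING else _format_number(v))
            writer.writerow(row)


def read_source_registry(
    path: PathLike, registry: NutrientRegistry
) -> list[SourceTable]:
    """Read an ordered source registry YAML and load each referenced table.

    The YAML is a list of ``{source_id, label, path}``; list order defines
    priority_rank (first entry = rank 1 = newest, applied first).
    """
    base = Path(path).parent
    with open(path, encoding="utf-8") as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list):
        raise ValueError(f"{path}: source registry must be a YAML list")
    sources = []
    seen: set[str] = set()
    for rank, entry in enumerate(entries, start=1):
        sid = entry["source_id"]
        if sid in seen:
            raise ValueError(f"{path}: duplicate source_id {sid!r}")
        seen.add(sid)
        table_path = Path(entry["path"])
        if not table_path.is_absolute():
            table_path = base / table_path
        sources.append(
            read_food_table(
                table_path,
                registry,
                source_id=sid,
                label=entry.get("label", sid),
                priority_rank=rank,
            )
        )
    return sources


def write_source_registry(
    sources: list[SourceTable], path: PathLike, registry: NutrientRegistry
) -> None:
    """Write each source table next to a registry YAML listing them in rank order."""
    base = Path(path).parent
    entries = []
    for src in sorted(sources, key=lambda s: s.priority_rank):
        fname = f"{src.source_id}.csv"
        write_food_table(src, base / fname, registry)
        entries.append({"source_id": src.source_id, "label": src.label, "path": fname})
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False, allow_unicode=True)
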