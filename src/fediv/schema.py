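"""Trait vocabularies, species records, and functional entities.

A functional entity (FE) is a unique combination of categorical trait
values; every species carrying that combination belongs to the same FE.
This module defines the trait schema (trait names, ordered level codes,
and an optional fine-to-crude collapse map), validates species records
read from CSV, and aggregates them into an entity table with
per-assemblage occupancy counts.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import SchemaError, ValidationError

__all__ = [
    "TraitDefinition",
    "TraitSchema",
    "SpeciesRecord",
    "EntityTable",
    "default_fine_schema",
    "load_trait_table",
    "build_entities",
    "theoretical_combinations",
    "collapse_schema",
    "collapse_records",
]

#: Default regional assemblages, ordered by decreasing species richness.
DEFAULT_ASSEMBLAGES = ("South", "East", "West", "North")

#: Name used for the pooled (union of all regions) assemblage.
POOLED = "pooled"


@dataclass(frozen=True)
class TraitDefinition:
    """One categorical trait: its name, ordered level codes, and options.

    Parameters
    ----------
    name:
        Trait name; also the CSV column header for this trait.
    levels:
        Level codes in display order. For ordered traits the order is the
        rank order used by the Gower dissimilarity.
    ordered:
        Whether the levels are rank-ordered (e.g. body-size classes).
    collapse_map:
        Optional mapping from each fine level to a crude level, used by
        the category-collapse sensitivity analysis.
    """

    name: str
    levels: tuple[str, ...]
    ordered: bool = False
    collapse_map: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.levels)) != len(self.levels):
            raise SchemaError(f"trait {self.name!r}: duplicate level codes")
        if not self.levels:
            raise SchemaError(f"trait {self.name!r}: no levels declared")
        if self.collapse_map is not None:
            missing = [lv for lv in self.levels if lv not in self.collapse_map]
            if missing:
                raise SchemaError(
                    f"trait {self.name!r}: collapse_map lacks levels {missing}"
                )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def rank(self, level: str) -> int:
        return self.levels.index(level)

    def crude_levels(self) -> tuple[str, ...]:
        """Crude levels in order of first appearance along the fine levels."""
        if self.collapse_map is None:
            raise SchemaError(f"trait {self.name!r}: no collapse_map defined")
        seen: "OrderedDict[str, None]" = OrderedDict()
        for lv in self.levels:
            seen.setdefault(self.collapse_map[lv], None)
        return tuple(seen)


@dataclass(frozen=True)
class TraitSchema:
    """An ordered collection of trait definitions."""

    traits: tuple[TraitDefinition, ...]

    def __post_init__(self) -> None:
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate trait names in schema")
        if not self.traits:
            raise SchemaError("schema has no traits")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.traits)

    @property
    def n_combinations(self) -> int:
        return math.prod(t.n_levels for t in self.traits)

    def __len__(self) -> int:
        return len(self.traits)

    def __getitem__(self, name: str) -> TraitDefinition:
        for t in self.traits:
            if t.name == name:
                return t
        raise KeyError(name)

    def validate_tuple(self, values: Sequence[str], context: str = "") -> tuple[str, ...]:
        """Check one trait-value tuple against the schema; return it as a tuple."""
        if len(values) != len(self.traits):
            raise ValidationError(
                f"{context}: expected {len(self.traits)} trait values, got {len(values)}"
            )
        for trait, value in zip(self.traits, values):
            if value not in trait.levels:
                raise ValidationError(
                    f"{context}: unknown level {value!r} for trait {trait.name!r}"
                )
        return tuple(values)

    def crude(self) -> "TraitSchema":
        """The collapsed schema implied by the traits' collapse maps."""
        crude_traits = []
        for t in self.traits:
            crude_traits.append(
                TraitDefinition(name=t.name, levels=t.crude_levels(), ordered=t.ordered)
            )
        return TraitSchema(tuple(crude_traits))

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        out = {"traits": []}
        for t in self.traits:
            d: dict = {"name": t.name, "levels": list(t.levels), "ordered": t.ordered}
            if t.collapse_map is not None:
                d["collapse_map"] = dict(t.collapse_map)
            out["traits"].append(d)
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "TraitSchema":
        traits = []
        for d in data["traits"]:
            traits.append(
                TraitDefinition(
                    name=d["name"],
                    levels=tuple(d["levels"]),
                    ordered=bool(d.get("ordered", False)),
                    collapse_map=dict(d["collapse_map"]) if d.get("collapse_map") else None,
                )
            )
        return cls(tuple(traits))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TraitSchema":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_fine_schema() -> TraitSchema:
    """The default six-trait reef-fish schema (5,670 fine / 216 crude combos).

    Six traits describe a reef fish's role in the ecosystem: maximum body
    size (6 ordered classes), diet (7), mobility (3), gregariousness
    (5 ordered classes), period of activity (3), and vertical position in
    the water column (3). The bundled fine-to-crude collapse map reduces
    the level counts to 3, 3, 2, 3, 2, 2; the exact grouping of levels is
    a configurable convention, only the counts are fixed.
    """
    return TraitSchema(
        (
            TraitDefinition(
                "size",
                ("S1", "S2", "S3", "S4", "S5", "S6"),
                ordered=True,
                collapse_map={
                    "S1": "small", "S2": "small",
                    "S3": "medium", "S4": "medium",
                    "S5": "large", "S6": "large",
                },
            ),
            TraitDefinition(
                "diet",
                ("HD", "HM", "OM", "IS", "IM", "PK", "FC"),
                collapse_map={
                    "HD": "herbivore", "HM": "herbivore", "OM": "herbivore",
                    "IS": "invertivore", "IM": "invertivore", "PK": "invertivore",
                    "FC": "piscivore",
                },
            ),
            TraitDefinition(
                "mobility",
                ("sedentary", "mobile", "wide-ranging"),
                collapse_map={
                    "sedentary": "low",
                    "mobile": "high",
                    "wide-ranging": "high",
                },
            ),
            TraitDefinition(
                "gregariousness",
                ("solitary", "pairing", "small-group", "medium-group", "large-group"),
                ordered=True,
                collapse_map={
                    "solitary": "solitary",
                    "pairing": "pairing",
                    "small-group": "grouping",
                    "medium-group": "grouping",
                    "large-group": "grouping",
                },
            ),
            TraitDefinition(
                "activity",
                ("diurnal", "nocturnal", "both"),
                collapse_map={
                    "diurnal": "day-active",
                    "both": "day-active",
                    "nocturnal": "night-active",
                },
            ),
            TraitDefinition(
                "position",
                ("bottom", "low-water", "high-water"),
                collapse_map={
                    "bottom": "benthic",
                    "low-water": "benthic",
                    "high-water": "pelagic",
                },
            ),
        )
    )


@dataclass(frozen=True)
class SpeciesRecord:
    """One validated species: identifier, trait values, and occupancy."""

    species_id: str
    trait_values: tuple[str, ...]
    occupancy: frozenset[str]

    def __post_init__(self) -> None:
        if not self.occupancy:
            raise ValidationError(
                f"species {self.species_id!r}: occupies no assemblage"
            )


@dataclass
class EntityTable:
    """Realized functional entities with per-assemblage occupancy counts.

    Attributes
    ----------
    schema:
        The trait schema the entities were built under.
    assemblages:
        Regional assemblage names, in input order.
    trait_tuples:
        One trait-value tuple per entity; pairwise distinct.
    members:
        Species identifiers per entity (pooled membership).
    counts:
        Entities x assemblages integer DataFrame of occupancy counts n_i;
        the pooled column counts each species once.
    species_occupancy:
        Mapping species_id -> set of assemblages it occurs in.
    """

    schema: TraitSchema
    assemblages: tuple[str, ...]
    trait_tuples: list[tuple[str, ...]]
    members: list[tuple[str, ...]]
    counts: pd.DataFrame
    species_occupancy: dict[str, frozenset[str]] = field(repr=False, default_factory=dict)

    @property
    def n_entities(self) -> int:
        return len(self.trait_tuples)

    def assemblage_names(self, include_pooled: bool = True) -> tuple[str, ...]:
        return self.assemblages + ((POOLED,) if include_pooled else ())

    def _col(self, assemblage: str) -> pd.Series:
        if assemblage not in self.counts.columns:
            raise ValidationError(f"unknown assemblage {assemblage!r}")
        return self.counts[assemblage]

    def occupancy(self, assemblage: str = POOLED):
        """Positive occupancy counts n_i for the entities present in `assemblage`."""
        col = self._col(assemblage)
        return col[col > 0].to_numpy()

    def present(self, assemblage: str = POOLED):
        """Integer indices of the entities present in `assemblage`."""
        return self._col(assemblage).to_numpy().nonzero()[0]

    def species_count(self, assemblage: str = POOLED) -> int:
        return int(self._col(assemblage).sum())

    def entity_count(self, assemblage: str = POOLED) -> int:
        return int((self._col(assemblage) > 0).sum())

    def to_frame(self) -> pd.DataFrame:
        """Entities as a DataFrame: trait columns, counts, member list."""
        rows = pd.DataFrame(self.trait_tuples, columns=self.schema.names)
        out = pd.concat([rows, self.counts.reset_index(drop=True)], axis=1)
        out["members"] = [";".join(m) for m in self.members]
        return out


def load_trait_table(
    path: str | Path,
    schema: TraitSchema,
    assemblages: Sequence[str] | None = None,
) -> list[SpeciesRecord]:
    """Read and validate a species x trait CSV.

    The CSV must have a header with a ``species_id`` column, one column per
    schema trait, and one 0/1 presence column per assemblage. If
    `assemblages` is None, every non-trait, non-id column (except an
    optional ``imputed`` flag, accepted and ignored) is taken as an
    assemblage.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    if "species_id" not in df.columns:
        raise SchemaError("missing required column 'species_id'")
    for name in schema.names:
        if name not in df.columns:
            raise SchemaError(f"missing required trait column {name!r}")
    if assemblages is None:
        reserved = {"species_id", "imputed", *schema.names}
        assemblages = [c for c in df.columns if c not in reserved]
    if not assemblages:
        raise SchemaError("no assemblage presence columns found")
    for a in assemblages:
        if a not in df.columns:
            raise SchemaError(f"missing assemblage column {a!r}")

    dup = df["species_id"][df["species_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicated species_id values: {sorted(set(dup))}")

    records: list[SpeciesRecord] = []
    for _, row in df.iterrows():
        sid = row["species_id"]
        values = schema.validate_tuple(
            [row[name] for name in schema.names], context=f"species {sid!r}"
        )
        occ = []
        for a in assemblages:
            flag = str(row[a]).strip()
            if flag not in {"0", "1"}:
                raise ValidationError(
                    f"species {sid!r}: presence flag for {a!r} must be 0 or 1, got {flag!r}"
                )
            if flag == "1":
                occ.append(a)
        if not occ:
            raise ValidationError(f"species {sid!r}: occupies no assemblage")
        records.append(SpeciesRecord(sid, values, frozenset(occ)))
    return records


def build_entities(
    records: Iterable[SpeciesRecord],
    schema: TraitSchema,
    assemblages: Sequence[str] | None = None,
) -> EntityTable:
    """Aggregate species into functional entities.

    One entity is created per distinct trait-value tuple observed in
    `records`; entities are ordered lexicographically by level rank so the
    table is invariant to record order. The pooled column counts each
    species once regardless of how many regions it occupies.
    """
    records = list(records)
    if not records:
        raise ValidationError("cannot build entities from an empty record list")
    if assemblages is None:
        seen: "OrderedDict[str, None]" = OrderedDict()
        for r in records:
            for a in sorted(r.occupancy):
                seen.setdefault(a, None)
        assemblages = tuple(seen)
    else:
        assemblages = tuple(assemblages)

    groups: dict[tuple[str, ...], list[SpeciesRecord]] = {}
    for r in records:
        schema.validate_tuple(r.trait_values, context=f"species {r.species_id!r}")
        groups.setdefault(r.trait_values, []).append(r)

    rank_key = lambda tup: tuple(
        trait.rank(v) for trait, v in zip(schema.traits, tup)
    )
    tuples = sorted(groups, key=rank_key)

    count_rows = []
    members = []
    species_occupancy: dict[str, frozenset[str]] = {}
    for tup in tuples:
        group = sorted(groups[tup], key=lambda r: r.species_id)
        members.append(tuple(r.species_id for r in group))
        row = {a: sum(1 for r in group if a in r.occupancy) for a in assemblages}
        row[POOLED] = len(group)
        count_rows.append(row)
        for r in group:
            if r.species_id in species_occupancy:
                raise ValidationError(f"duplicated species_id {r.species_id!r}")
            species_occupancy[r.species_id] = r.occupancy

    counts = pd.DataFrame(count_rows, columns=list(assemblages) + [POOLED], dtype=int)
    return EntityTable(
        schema=schema,
        assemblages=assemblages,
        trait_tuples=list(tuples),
        members=members,
        counts=counts,
        species_occupancy=species_occupancy,
    )


def theoretical_combinations(schema: TraitSchema) -> int:
    """Number of theoretically possible entities: the product of level counts."""
    return schema.n_combinations


def collapse_records(
    records: Iterable[SpeciesRecord], schema: TraitSchema
) -> list[SpeciesRecord]:
    """Re-label every record's trait values through the schema's collapse maps."""
    out = []
    for r in records:
        crude_values = []
        for trait, value in zip(schema.traits, r.trait_values):
            if trait.collapse_map is None:
                raise SchemaError(f"trait {trait.name!r}: no collapse_map defined")
            try:
                crude_values.append(trait.collapse_map[value])
            except KeyError:
                raise SchemaError(
                    f"trait {trait.name!r}: level {value!r} has no crude mapping"
                ) from None
        out.append(SpeciesRecord(r.species_id, tuple(crude_values), r.occupancy))
    return out


def collapse_schema(
    records: Iterable[SpeciesRecord],
    schema: TraitSchema,
    assemblages: Sequence[str] | None = None,
) -> tuple[TraitSchema, EntityTable]:
    """Collapse fine categories to crude ones and rebuild the entity table.

    Species counts per assemblage are conserved exactly; the number of
    entities can only shrink (distinct fine tuples may map to one crude
    tuple).
    """
    records = list(records)
    crude = schema.crude()
    crude_records = collapse_records(records, schema)
    if assemblages is None and records:
        # preserve the original assemblage ordering
        seen: "OrderedDict[str, None]" = OrderedDict()
        for r in records:
            for a in sorted(r.occupancy):
                seen.setdefault(a, None)
        assemblages = tuple(seen)
    return crude, build_entities(crude_records, crude, assemblages)
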