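"""Assemblage-level diversity statistics over functional entities.

With S species spread over FE entities with occupancies n_1..n_FE:

* redundancy          FR  = S / FE, the mean number of species per entity;
* vulnerability       FV  = % of entities supported by exactly one species;
* over-redundancy     FOR = 100 * sum_i max(n_i - FR, 0) / S, the share of
  species packed into entities richer than the mean.

FRic (convex-hull richness) comes from :mod:`fediv.space`; `summarize`
assembles all of them into one report per assemblage plus the pooled
fauna.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateHullError, ValidationError
from .schema import POOLED, EntityTable
from .space import TraitSpace, fric

__all__ = [
    "percent",
    "redundancy",
    "vulnerability",
    "over_redundancy",
    "unique_species_fv_contribution",
    "DiversityReport",
    "summarize",
    "report_frame",
]

REPORT_COLUMNS = [
    "assemblage", "S", "FE", "FRic_pct", "FR", "FR_se",
    "FV_pct", "FOR_pct", "uniqueFV_pct",
]


def percent(part: float, whole: float, decimals: int | None = None) -> float:
    """part/whole as a percentage, optionally rounded for reporting."""
    if whole == 0:
        raise ValidationError("percentage with zero denominator")
    value = 100.0 * part / whole
    return value if decimals is None else round(value, decimals)


def _check_occupancy(occupancy) -> np.ndarray:
    n = np.asarray(occupancy, dtype=float)
    if n.size == 0:
        raise ValidationError("empty occupancy vector")
    if (n < 1).any():
        raise ValidationError("occupancy counts must all be >= 1")
    return n


def redundancy(occupancy) -> tuple[float, float]:
    """Mean species per entity (FR = S/FE) and its standard error.

    The SE is sd(n_i)/sqrt(FE) across entities (NaN for a single entity).
    """
    n = _check_occupancy(occupancy)
    fe = n.size
    fr = float(n.sum() / fe)
    se = float(np.std(n, ddof=1) / np.sqrt(fe)) if fe > 1 else float("nan")
    return fr, se


def vulnerability(occupancy) -> float:
    """Percent of entities supported by exactly one species (FV)."""
    n = _check_occupancy(occupancy)
    return percent((n == 1).sum(), n.size)


def over_redundancy(occupancy) -> float:
    """Percent of species in excess of the mean redundancy (FOR)."""
    n = _check_occupancy(occupancy)
    fr = n.sum() / n.size
    return percent(np.maximum(n - fr, 0.0).sum(), n.sum())


def unique_species_fv_contribution(entities: EntityTable, assemblage: str) -> float:
    """Share of an assemblage's entities that are singletons held by a unique species.

    A species is unique when it occurs in exactly one regional assemblage.
    The denominator is the assemblage's entity count, the same as FV's, so
    the value is the part of FV at risk from the loss of a single,
    regionally-endemic species. For the pooled assemblage, a singleton
    entity counts when its sole species occupies exactly one region.
    """
    col = entities._col(assemblage)
    fe = int((col > 0).sum())
    if fe == 0:
        raise ValidationError(f"assemblage {assemblage!r} holds no entities")
    unique_singletons = 0
    for i in np.nonzero(col.to_numpy() == 1)[0]:
        if assemblage == POOLED:
            present = list(entities.members[i])
        else:
            present = [
                s for s in entities.members[i]
                if assemblage in entities.species_occupancy[s]
            ]
        (sole,) = present
        if len(entities.species_occupancy[sole]) == 1:
            unique_singletons += 1
    return percent(unique_singletons, fe)


@dataclass
class DiversityReport:
    """All indices for one assemblage; FRic is NaN when its hull is degenerate."""

    assemblage: str
    S: int
    FE: int
    FRic_pct: float
    FR: float
    FR_se: float
    FV_pct: float
    FOR_pct: float
    uniqueFV_pct: float

    def to_dict(self) -> dict:
        return {c: getattr(self, c) for c in REPORT_COLUMNS}


def summarize(
    entities: EntityTable,
    space: TraitSpace | None = None,
) -> list[DiversityReport]:
    """One report per regional assemblage, plus the pooled fauna (FRic = 100%).

    When a trait space is given, FRic is the assemblage hull volume as a
    percentage of the pooled hull; a degenerate assemblage hull yields
    NaN rather than a fabricated value. Without a space, FRic is NaN
    throughout.
    """
    if space is not None and space.n_points != entities.n_entities:
        raise ValidationError("trait space does not match the entity table")
    reports = []
    pool_idx = entities.present(POOLED)
    for name in entities.assemblage_names():
        occ = entities.occupancy(name)
        fr, se = redundancy(occ)
        if space is None:
            fric_pct = float("nan")
        elif name == POOLED:
            fric_pct = 100.0
        else:
            try:
                fric_pct = fric(
                    space, entities.present(name), pool_idx, assemblage=name
                ).fric_percent
            except DegenerateHullError:
                fric_pct = float("nan")
        reports.append(
            DiversityReport(
                assemblage=name,
                S=entities.species_count(name),
                FE=entities.entity_count(name),
                FRic_pct=fric_pct,
                FR=fr,
                FR_se=se,
                FV_pct=vulnerability(occ),
                FOR_pct=over_redundancy(occ),
                uniqueFV_pct=unique_species_fv_contribution(entities, name),
            )
        )
    return reports


def report_frame(reports: list[DiversityReport], decimals: int | None = 1) -> pd.DataFrame:
    """Reports as a DataFrame; percent/index columns rounded for output files."""
    df = pd.DataFrame([r.to_dict() for r in reports], columns=REPORT_COLUMNS)
    if decimals is not None:
        for c in REPORT_COLUMNS[2:]:
            df[c] = df[c].round(decimals)
    return df
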