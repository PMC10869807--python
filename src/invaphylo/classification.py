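"""Exotic vs translocated classification of non-native occurrence records.

A non-native species in a basin is *translocated* when it is also recorded
as native somewhere else in the same administrative unit — by default the
country the basin is assigned to, optionally the whole biogeographical
realm — and *exotic* otherwise.  The rule is applied per unit, so the same
species can be exotic in one country and translocated in another.  Because
countries nest inside realms, any record translocated at country scope is
necessarily translocated at realm scope as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .occurrence_db import NATIVE, NONNATIVE, OccurrenceDatabase


class Scope(str, Enum):
    """Geographic scope used to decide within-unit native presence."""

    COUNTRY = "country"
    REALM = "realm"


EXOTIC = "exotic"
TRANSLOCATED = "translocated"


@dataclass
class StatusAssignment:
    """Per-(species, basin) labels under a fixed scope.

    ``labels`` maps every occurrence record to native / exotic / translocated;
    exotic and translocated partition the non-native records.
    """

    scope: Scope
    labels: dict[tuple[str, str], str]

    def label(self, species: str, basin_id: str) -> str:
        return self.labels[(species, basin_id)]

    def records_with(self, label: str) -> list[tuple[str, str]]:
        return [k for k, v in self.labels.items() if v == label]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"species": s, "basin_id": b, "label": v}
            for (s, b), v in self.labels.items()
        ]
        return pd.DataFrame(rows, columns=["species", "basin_id", "label"])


def _unit_of(db: OccurrenceDatabase, basin_id: str, scope: Scope) -> str:
    if scope is Scope.COUNTRY:
        return db.country_of(basin_id)
    return db.realm_of(basin_id)


def _unit_basins(db: OccurrenceDatabase, unit: str, scope: Scope) -> set[str]:
    if scope is Scope.COUNTRY:
        return db.basins_of_country(unit)
    return db.basins_of_realm(unit)


def classify_nonnatives(db: OccurrenceDatabase, scope: Scope) -> StatusAssignment:
    """Label every occurrence record native, exotic, or translocated.

    A non-native record (s, b) in unit U is translocated iff s is recorded
    native in at least one basin of U; otherwise it is exotic.
    """
    scope = Scope(scope)
    labels: dict[tuple[str, str], str] = {}
    # species -> set of units where it has >=1 native basin
    native_units: dict[str, set[str]] = {}
    for species, basin, status in db.records.itertuples(index=False):
        if status == NATIVE:
            native_units.setdefault(species, set()).add(_unit_of(db, basin, scope))
    for species, basin, status in db.records.itertuples(index=False):
        if status == NATIVE:
            labels[(species, basin)] = NATIVE
        else:
            unit = _unit_of(db, basin, scope)
            if unit in native_units.get(species, set()):
                labels[(species, basin)] = TRANSLOCATED
            else:
                labels[(species, basin)] = EXOTIC
    return StatusAssignment(scope=scope, labels=labels)


def origin_basins(
    db: OccurrenceDatabase,
    assignment: StatusAssignment,
    species: str,
    unit: str,
) -> set[str]:
    """Native basins of a translocated species within its unit.

    These are the basins the species is presumed to have been moved from;
    they are excluded from its candidate set when building success/failure
    records.  Raises if the species is not translocated anywhere in the unit.
    """
    scope = assignment.scope
    basins = _unit_basins(db, unit, scope)
    is_translocated = any(
        assignment.labels.get((species, b)) == TRANSLOCATED for b in basins
    )
    if not is_translocated:
        raise ValueError(
            f"species {species!r} is not translocated in {scope.value} {unit!r}"
        )
    return {b for b in basins if species in db.natives_of(b)}
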