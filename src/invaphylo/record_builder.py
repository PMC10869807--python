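"""Construction of the success/failure modeling table.

For every non-native species in a given group (exotic or translocated) and
every administrative unit where it carries that label, one row is emitted
per *candidate* basin of the unit: presence is 1 where the species is
established and 0 where it is not.  Exotic species are paired with every
basin of the unit; translocated species skip the basins where they are
recorded native (the basins they are presumed to have been moved from).
Each row carries the nonnative–native MPD and MNTD of the focal species in
that basin, the native richness and community diversity of the basin, and
the basin surface area.

Cleaning precedes record construction: administrative units with no
non-native record are removed (relatedness cannot be evaluated there), as
are species missing from the phylogeny.  Rows whose relatedness is
undefined (no natives in the basin) are dropped.
"""

from __future__ import annotations

import math

import dendropy
import numpy as np
import pandas as pd

from .classification import (
    EXOTIC,
    TRANSLOCATED,
    Scope,
    StatusAssignment,
    classify_nonnatives,
    origin_basins,
)
from .occurrence_db import NONNATIVE, OccurrenceDatabase
from .phylometrics import (
    DistanceMatrix,
    native_diversity,
    relatedness_to_natives,
    tip_labels,
)

#: continuous columns standardized before modeling; basin area is
#: log-transformed first because areas span orders of magnitude
STANDARDIZE_COLUMNS = [
    "mpd",
    "mntd",
    "native_richness",
    "native_mpd",
    "native_mntd",
    "log_area",
]

RECORD_COLUMNS = [
    "species",
    "basin_id",
    "country",
    "realm",
    "group",
    "presence",
    "mpd",
    "mntd",
    "native_richness",
    "native_mpd",
    "native_mntd",
    "basin_area",
    "log_area",
]


class CleaningError(ValueError):
    pass


def clean_database(
    db: OccurrenceDatabase,
    assignment: StatusAssignment,
    tree: dendropy.Tree,
) -> tuple[OccurrenceDatabase, dict]:
    """Apply the pre-modeling cleaning rules.

    1. Drop every basin of administrative units (countries or realms,
       following the assignment's scope) that contain zero non-native
       records.
    2. Drop all records of species absent from the phylogeny.

    Returns the cleaned database and a report of what was removed.
    """
    scope = assignment.scope
    unit_col = "country" if scope is Scope.COUNTRY else "realm"

    recs = db.records
    basin_unit = db.basins[unit_col]
    rec_unit = recs["basin_id"].map(basin_unit)
    units_with_nonnative = set(rec_unit[recs["status"] == NONNATIVE])
    all_units = set(basin_unit)
    dropped_units = sorted(all_units - units_with_nonnative)

    keep_basins = set(basin_unit.index[basin_unit.isin(units_with_nonnative)])
    step1 = recs[recs["basin_id"].isin(keep_basins)]

    tree_species = set(tip_labels(tree))
    in_tree = step1["species"].isin(tree_species)
    dropped_species = sorted(set(step1.loc[~in_tree, "species"]))
    step2 = step1[in_tree]

    if step2.empty:
        raise CleaningError("cleaning removed every record")

    basins = db.basins.loc[sorted(keep_basins)]
    cleaned = OccurrenceDatabase(basins=basins.copy(), records=step2.reset_index(drop=True))
    report = {
        "scope": scope.value,
        "units_dropped": len(dropped_units),
        "dropped_units": dropped_units,
        "basins_dropped": len(db.basins) - len(basins),
        "species_dropped": len(dropped_species),
        "dropped_species": dropped_species,
        "records_dropped": len(recs) - len(step2),
    }
    return cleaned, report


def _units_of(db: OccurrenceDatabase, scope: Scope) -> pd.Series:
    return db.basins["country"] if scope is Scope.COUNTRY else db.basins["realm"]


def build_records(
    db: OccurrenceDatabase,
    assignment: StatusAssignment,
    D: DistanceMatrix,
    group: str,
) -> pd.DataFrame:
    """Emit one success/failure row per (species, unit, candidate basin).

    ``group`` selects the exotic or the translocated table.  Basin-level
    metrics (native diversity, area) are computed once per basin and shared
    across focal species.  Rows where relatedness is undefined (basins
    without natives) are dropped.
    """
    if group not in (EXOTIC, TRANSLOCATED):
        raise ValueError(f"group must be 'exotic' or 'translocated', got {group!r}")
    scope = assignment.scope
    unit_of_basin = _units_of(db, scope)

    labelled = [
        (s, b) for (s, b), lab in assignment.labels.items() if lab == group
    ]
    if not labelled:
        raise ValueError(f"assignment contains no {group!r} records")

    # species -> units where the species carries the group label
    species_units: dict[str, set[str]] = {}
    for s, b in labelled:
        species_units.setdefault(s, set()).add(unit_of_basin[b])

    basins_by_unit: dict[str, list[str]] = {}
    for b, u in unit_of_basin.items():
        basins_by_unit.setdefault(u, []).append(b)

    # per-basin community metrics, computed once
    basin_cache: dict[str, tuple] = {}

    def basin_metrics(b: str):
        if b not in basin_cache:
            natives = sorted(db.natives_of(b))
            div = native_diversity(natives, D)
            basin_cache[b] = (natives, div)
        return basin_cache[b]

    rows = []
    for species in sorted(species_units):
        for unit in sorted(species_units[species]):
            candidates = sorted(basins_by_unit[unit])
            if group == TRANSLOCATED:
                origins = origin_basins(db, assignment, species, unit)
                candidates = [b for b in candidates if b not in origins]
            for b in candidates:
                natives, div = basin_metrics(b)
                native_set = [n for n in natives if n != species]
                rel = relatedness_to_natives(species, native_set, D)
                if not rel.defined:
                    continue
                present = b in db.nonnative_basins(species)
                info = db.basins.loc[b]
                rows.append(
                    {
                        "species": species,
                        "basin_id": b,
                        "country": info["country"],
                        "realm": info["realm"],
                        "group": group,
                        "presence": int(present),
                        "mpd": rel.mpd,
                        "mntd": rel.mntd,
                        "native_richness": div.richness,
                        "native_mpd": div.native_mpd,
                        "native_mntd": div.native_mntd,
                        "basin_area": float(info["area_km2"]),
                        "log_area": math.log(float(info["area_km2"])),
                    }
                )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def standardize_records(
    table: pd.DataFrame, columns: list[str] | None = None
) -> pd.DataFrame:
    """Append z-scored copies (``<col>_z``) of the named numeric columns.

    Sample (n−1) standard deviation; NaN entries are ignored when computing
    the mean/SD and stay NaN in the z-scored column.  A zero-SD column is an
    error — it cannot carry information into the model and its z-score is
    undefined.
    """
    if columns is None:
        columns = [c for c in STANDARDIZE_COLUMNS if c in table.columns]
    out = table.copy()
    for col in columns:
        x = pd.to_numeric(out[col], errors="raise")
        sd = x.std(ddof=1, skipna=True)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {col!r} has zero or undefined SD; cannot z-score")
        out[col + "_z"] = (x - x.mean(skipna=True)) / sd
    return out


def build_model_table(
    db: OccurrenceDatabase,
    tree: dendropy.Tree,
    scope: Scope,
    group: str,
    D: DistanceMatrix | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Convenience wrapper: classify → clean → build → standardize.

    Returns the standardized modeling table and the cleaning report.
    """
    from .phylometrics import cophenetic_distances, prune_to_database

    assignment = classify_nonnatives(db, scope)
    cleaned, report = clean_database(db, assignment, tree)
    assignment = classify_nonnatives(cleaned, scope)
    if D is None:
        pruned, _ = prune_to_database(tree, cleaned)
        D = cophenetic_distances(pruned)
    table = build_records(cleaned, assignment, D, group)
    if table.empty:
        return table, report
    # z-score every continuous column that carries information; degenerate
    # columns (constant, or <2 defined values on tiny inputs) are skipped
    # here — passing them to standardize_records explicitly still errors
    usable = []
    for col in STANDARDIZE_COLUMNS:
        x = table[col].dropna()
        if len(x) >= 2 and x.std(ddof=1) > 0:
            usable.append(col)
    return standardize_records(table, usable), report
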