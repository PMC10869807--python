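"""Descriptive summaries: colonization, richness, and spread tables.

These reproduce the descriptive layer of the analysis — how many basins
each realm has lost to exotic vs translocated fishes, per-basin non-native
richness and its share of total richness, per-country species tallies, and
the most widespread non-native species.  Percentages are reported to two
decimals with half-up rounding.  Denominators always count every basin (or
species) of the unit in the database handed in: pass the raw database for
global-pattern tables and the cleaned one for modeling-era tables.
"""

from __future__ import annotations

import math

import pandas as pd

from .classification import EXOTIC, TRANSLOCATED, StatusAssignment
from .occurrence_db import NONNATIVE, OccurrenceDatabase


def round2(x: float) -> float:
    """Round half-up to 2 decimals (0.005 -> 0.01)."""
    if math.isnan(x):
        return x
    return math.floor(x * 100.0 + 0.5) / 100.0


def _pct(num: int, den: int) -> float:
    return round2(100.0 * num / den) if den else float("nan")


def _label_frame(db: OccurrenceDatabase, assignment: StatusAssignment) -> pd.DataFrame:
    recs = db.records.copy()
    recs["label"] = [
        assignment.labels[(s, b)] for s, b in zip(recs["species"], recs["basin_id"])
    ]
    recs["country"] = recs["basin_id"].map(db.basins["country"])
    recs["realm"] = recs["basin_id"].map(db.basins["realm"])
    return recs


def realm_colonization(
    db: OccurrenceDatabase, assignment: StatusAssignment
) -> pd.DataFrame:
    """Percent of each realm's basins holding ≥1 non-native / exotic /
    translocated record.  Denominator: all basins of the realm."""
    recs = _label_frame(db, assignment)
    rows = []
    for realm, basins in db.basins.groupby("realm").groups.items():
        basins = set(basins)
        in_realm = recs[recs["basin_id"].isin(basins)]
        nn = in_realm[in_realm["status"] == NONNATIVE]
        n_nn = nn["basin_id"].nunique()
        n_ex = nn.loc[nn["label"] == EXOTIC, "basin_id"].nunique()
        n_tr = nn.loc[nn["label"] == TRANSLOCATED, "basin_id"].nunique()
        rows.append(
            {
                "realm": realm,
                "n_basins": len(basins),
                "n_colonized": n_nn,
                "pct_colonized": _pct(n_nn, len(basins)),
                "n_exotic_colonized": n_ex,
                "pct_exotic_colonized": _pct(n_ex, len(basins)),
                "n_translocated_colonized": n_tr,
                "pct_translocated_colonized": _pct(n_tr, len(basins)),
            }
        )
    return pd.DataFrame(rows).sort_values("realm").reset_index(drop=True)


def basin_summary(db: OccurrenceDatabase, assignment: StatusAssignment) -> pd.DataFrame:
    """Per-basin exotic/translocated richness and share of total richness."""
    recs = _label_frame(db, assignment)
    rows = []
    for basin in db.basins.index:
        here = recs[recs["basin_id"] == basin]
        total = here["species"].nunique()
        n_ex = here.loc[here["label"] == EXOTIC, "species"].nunique()
        n_tr = here.loc[here["label"] == TRANSLOCATED, "species"].nunique()
        rows.append(
            {
                "basin_id": basin,
                "total_richness": total,
                "native_richness": here.loc[here["label"] == "native", "species"].nunique(),
                "exotic_richness": n_ex,
                "pct_exotic": _pct(n_ex, total),
                "translocated_richness": n_tr,
                "pct_translocated": _pct(n_tr, total),
            }
        )
    return pd.DataFrame(rows)


def country_summary(
    db: OccurrenceDatabase, assignment: StatusAssignment
) -> pd.DataFrame:
    """Per-country non-native species counts and shares of total richness.

    Requires a country-scope assignment, under which every non-native
    record of a species within one country carries the same label, so
    species-level exotic/translocated counts are well defined.
    """
    recs = _label_frame(db, assignment)
    rows = []
    for country, group in recs.groupby("country"):
        total = group["species"].nunique()
        nonnative = group.loc[group["status"] == NONNATIVE, "species"].nunique()
        n_ex = group.loc[group["label"] == EXOTIC, "species"].nunique()
        n_tr = group.loc[group["label"] == TRANSLOCATED, "species"].nunique()
        rows.append(
            {
                "country": country,
                "total_species": total,
                "nonnative_species": nonnative,
                "exotic_species": n_ex,
                "pct_exotic": _pct(n_ex, total),
                "translocated_species": n_tr,
                "pct_translocated": _pct(n_tr, total),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["nonnative_species", "country"], ascending=[False, True]
    ).reset_index(drop=True)


def species_spread(db: OccurrenceDatabase) -> pd.DataFrame:
    """Countries and basins colonized per non-native species, widest first."""
    recs = db.records
    nn = recs[recs["status"] == NONNATIVE].copy()
    nn["country"] = nn["basin_id"].map(db.basins["country"])
    rows = []
    for species, group in nn.groupby("species"):
        rows.append(
            {
                "species": species,
                "n_countries": group["country"].nunique(),
                "n_basins": group["basin_id"].nunique(),
            }
        )
    out = pd.DataFrame(rows, columns=["species", "n_countries", "n_basins"])
    return out.sort_values(
        ["n_basins", "n_countries", "species"], ascending=[False, False, True]
    ).reset_index(drop=True)
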