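"""Species-by-basin occurrence database: data model, validation, and I/O.

The occurrence database pairs two delimited-text tables:

* an occurrence table with one row per (species, basin) and a status of
  ``native`` or ``nonnative``;
* a basin metadata table giving, for every basin, the country it is
  assigned to (the primary country for basins shared between countries),
  the biogeographical realm of that country, the basin surface area in
  km^2, and the centroid coordinates in decimal degrees.

Basins nest in countries and countries nest in one of the seven
zoogeographic realms; both nestings are validated on load.  Species names
are normalised so that underscore-labelled phylogeny tips (``Cyprinus_carpio``)
and space-separated occurrence names (``Cyprinus carpio``) refer to the same
species.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

REALMS = frozenset(
    {
        "Afrotropic",
        "Australasia",
        "Indo-Malay",
        "Nearctic",
        "Neotropic",
        "Oceania",
        "Palearctic",
    }
)

NATIVE = "native"
NONNATIVE = "nonnative"

OCCURRENCE_COLUMNS = ["species", "basin_id", "status"]
BASIN_COLUMNS = ["basin_id", "country", "realm", "area_km2", "lat", "lon"]


class SchemaError(ValueError):
    """A required column is missing or a value is outside its domain."""


class IntegrityError(ValueError):
    """Cross-record consistency violated (duplicates, unknown basins, ...)."""


_WS = re.compile(r"\s+")


def normalize_species(name: str) -> str:
    """Canonical species key: trimmed, single spaces, underscores == spaces."""
    return _WS.sub(" ", str(name).replace("_", " ").strip())


@dataclass(frozen=True)
class BasinInfo:
    """Metadata for a single river basin."""

    basin_id: str
    country: str
    realm: str
    area_km2: float
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if self.realm not in REALMS:
            raise SchemaError(
                f"unknown realm {self.realm!r} for basin {self.basin_id!r}; "
                f"expected one of {sorted(REALMS)}"
            )
        if not self.area_km2 > 0:
            raise SchemaError(f"basin {self.basin_id!r}: area must be > 0")
        if not -90 <= self.lat <= 90:
            raise SchemaError(f"basin {self.basin_id!r}: latitude out of range")
        if not -180 <= self.lon <= 180:
            raise SchemaError(f"basin {self.basin_id!r}: longitude out of range")


@dataclass
class OccurrenceDatabase:
    """Validated occurrence records plus the basin→country→realm hierarchy.

    ``records`` has columns species, basin_id, status; ``basins`` is indexed
    by basin_id with columns country, realm, area_km2, lat, lon.
    """

    basins: pd.DataFrame
    records: pd.DataFrame
    _by_basin: dict[tuple[str, str], set[str]] = field(default_factory=dict, repr=False)
    _by_species: dict[tuple[str, str], set[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.validate()
        self._reindex()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        recs = self.records
        bad_status = set(recs["status"].unique()) - {NATIVE, NONNATIVE}
        if bad_status:
            raise SchemaError(f"invalid status values: {sorted(bad_status)}")
        dup = recs.duplicated(subset=["species", "basin_id"])
        if dup.any():
            pair = recs.loc[dup.idxmax(), ["species", "basin_id"]].tolist()
            raise IntegrityError(
                f"duplicate (species, basin) record: {tuple(pair)} — a species "
                "cannot be listed twice (e.g. both native and non-native) in one basin"
            )
        missing = set(recs["basin_id"]) - set(self.basins.index)
        if missing:
            raise IntegrityError(
                f"occurrence records reference basins absent from metadata: "
                f"{sorted(missing)[:5]}"
            )
        # one country per basin is structural (basins indexed by id); check
        # one realm per country
        cr = self.basins.groupby("country")["realm"].nunique()
        multi = cr[cr > 1]
        if not multi.empty:
            raise IntegrityError(
                f"countries mapped to multiple realms: {list(multi.index)}"
            )

    def _reindex(self) -> None:
        self._by_basin = {}
        self._by_species = {}
        for species, basin, status in self.records.itertuples(index=False):
            self._by_basin.setdefault((basin, status), set()).add(species)
            self._by_species.setdefault((species, status), set()).add(basin)

    # -- accessors --------------------------------------------------------

    @property
    def species(self) -> set[str]:
        return set(self.records["species"].unique())

    @property
    def countries(self) -> set[str]:
        return set(self.basins["country"].unique())

    @property
    def realms(self) -> set[str]:
        return set(self.basins["realm"].unique())

    def natives_of(self, basin_id: str) -> set[str]:
        return set(self._by_basin.get((basin_id, NATIVE), set()))

    def nonnatives_of(self, basin_id: str) -> set[str]:
        return set(self._by_basin.get((basin_id, NONNATIVE), set()))

    def native_basins(self, species: str) -> set[str]:
        return set(self._by_species.get((species, NATIVE), set()))

    def nonnative_basins(self, species: str) -> set[str]:
        return set(self._by_species.get((species, NONNATIVE), set()))

    def basins_of_country(self, country: str) -> set[str]:
        return set(self.basins.index[self.basins["country"] == country])

    def basins_of_realm(self, realm: str) -> set[str]:
        return set(self.basins.index[self.basins["realm"] == realm])

    def country_of(self, basin_id: str) -> str:
        return self.basins.at[basin_id, "country"]

    def realm_of(self, basin_id: str) -> str:
        return self.basins.at[basin_id, "realm"]

    def basin_info(self, basin_id: str) -> BasinInfo:
        row = self.basins.loc[basin_id]
        return BasinInfo(
            basin_id=basin_id,
            country=row["country"],
            realm=row["realm"],
            area_km2=float(row["area_km2"]),
            lat=float(row["lat"]),
            lon=float(row["lon"]),
        )

    def summary(self) -> dict[str, int]:
        """Counts of basins, countries, realms, species and record statuses."""
        status = self.records["status"]
        return {
            "basins": int(len(self.basins)),
            "countries": int(self.basins["country"].nunique()),
            "realms": int(self.basins["realm"].nunique()),
            "species": int(self.records["species"].nunique()),
            "native_records": int((status == NATIVE).sum()),
            "nonnative_records": int((status == NONNATIVE).sum()),
        }

    def replace_records(self, records: pd.DataFrame) -> "OccurrenceDatabase":
        return OccurrenceDatabase(self.basins.copy(), records.reset_index(drop=True))


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def load_occurrence_database(
    occurrence_path: str | Path,
    basin_path: str | Path,
    *,
    sep: str = ",",
) -> OccurrenceDatabase:
    """Read and validate the two tables of an occurrence database.

    Parameters
    ----------
    occurrence_path, basin_path
        Delimited text files with headers ``species,basin_id,status`` and
        ``basin_id,country,realm,area_km2,lat,lon`` respectively.
    sep
        Field delimiter; pass ``"\\t"`` for tab-delimited files.
    """
    occ = pd.read_csv(occurrence_path, sep=sep, dtype=str)
    _require_columns(occ, OCCURRENCE_COLUMNS, str(occurrence_path))
    basins = pd.read_csv(basin_path, sep=sep, dtype=str)
    _require_columns(basins, BASIN_COLUMNS, str(basin_path))

    occ = occ[OCCURRENCE_COLUMNS].copy()
    occ["species"] = occ["species"].map(normalize_species)
    occ["basin_id"] = occ["basin_id"].str.strip()
    occ["status"] = occ["status"].str.strip().str.lower()
    # accept the "non-native" spelling seen in prose
    occ.loc[occ["status"] == "non-native", "status"] = NONNATIVE

    basins = basins[BASIN_COLUMNS].copy()
    basins["basin_id"] = basins["basin_id"].str.strip()
    if basins["basin_id"].duplicated().any():
        raise IntegrityError(f"{basin_path}: duplicate basin_id rows")
    for col in ("area_km2", "lat", "lon"):
        basins[col] = pd.to_numeric(basins[col], errors="raise")
    basins = basins.set_index("basin_id")
    for basin_id, row in basins.iterrows():
        BasinInfo(
            basin_id=basin_id,
            country=row["country"],
            realm=row["realm"],
            area_km2=float(row["area_km2"]),
            lat=float(row["lat"]),
            lon=float(row["lon"]),
        )
    return OccurrenceDatabase(basins=basins, records=occ.reset_index(drop=True))


def write_database(
    db: OccurrenceDatabase,
    occurrence_path: str | Path,
    basin_path: str | Path,
    *,
    sep: str = ",",
) -> None:
    """Write the database back out in the schema ``load_occurrence_database`` reads."""
    db.records[OCCURRENCE_COLUMNS].to_csv(occurrence_path, sep=sep, index=False)
    db.basins.reset_index()[BASIN_COLUMNS].to_csv(basin_path, sep=sep, index=False)


def subset_database(
    db: OccurrenceDatabase,
    drop_families: set[str],
    family_map: Mapping[str, str],
) -> OccurrenceDatabase:
    """Remove non-native records of species belonging to the given families.

    Used for the sensitivity analysis that excludes the families dominating
    the non-native pool (carps and salmonids, whose strong thermal
    preferences could drive the global relatedness signal on their own).
    Native records are never touched.
    """
    if not drop_families:
        return db
    family_map = {normalize_species(k): v for k, v in family_map.items()}
    recs = db.records
    nonnative = recs["status"] == NONNATIVE
    unmapped = sorted(
        s for s in recs.loc[nonnative, "species"].unique() if s not in family_map
    )
    if unmapped:
        raise SchemaError(
            f"non-native species without a family assignment: {unmapped[:5]} — "
            "family_map must cover every non-native species when dropping families"
        )
    dropped = nonnative & recs["species"].map(family_map).isin(drop_families)
    return db.replace_records(recs[~dropped])
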