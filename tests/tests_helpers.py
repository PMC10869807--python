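"""Small constructors shared across test modules."""

import pandas as pd

from invaphylo.occurrence_db import OccurrenceDatabase
from invaphylo.phylometrics import read_newick


def make_db(basins, records):
    bas = pd.DataFrame(
        basins, columns=["basin_id", "country", "realm", "area_km2", "lat", "lon"]
    ).set_index("basin_id")
    recs = pd.DataFrame(records, columns=["species", "basin_id", "status"])
    return OccurrenceDatabase(basins=bas, records=recs)


def make_two_country_db():
    """Country X has a non-native record; country Y holds natives only."""
    basins = [
        ("x1", "X", "Palearctic", 10, 0, 0),
        ("x2", "X", "Palearctic", 10, 0, 0),
        ("y1", "Y", "Palearctic", 10, 0, 0),
    ]
    records = [
        ("a", "x1", "native"),
        ("b", "x2", "native"),
        ("c", "x2", "nonnative"),
        ("c", "y1", "native"),
        ("d", "y1", "native"),
    ]
    tree = read_newick("(((a:1,b:1):1,c:2):1,d:3);", from_string=True)
    return make_db(basins, records), tree
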