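"""Exotic vs translocated classification and the effect of scope.

A species native in one country but introduced into a neighboring country
of the same biogeographical realm is *exotic* at country scope but
*translocated* at realm scope.  This example builds the three-country
fixture that exhibits the flip and prints both label sets.
"""

import tempfile

from invaphylo import Scope, classify_nonnatives, load_occurrence_database
from invaphylo.synthetic_data import make_fixture

with tempfile.TemporaryDirectory() as tmp:
    paths = make_fixture("realm-scope", tmp)
    db = load_occurrence_database(paths["occurrences"], paths["basins"])

for scope in (Scope.COUNTRY, Scope.REALM):
    assignment = classify_nonnatives(db, scope)
    print(f"\n{scope.value} scope:")
    for (species, basin), label in sorted(assignment.labels.items()):
        if label != "native":
            print(f"  {species} in {basin}: {label}")

print(
    "\nSpecies S is native in country Y (basin y1).  Its record in x1\n"
    "(country X, same realm) is exotic by country but translocated by\n"
    "realm; its record in z1 (another realm) stays exotic under both."
)
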