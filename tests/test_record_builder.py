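import numpy as np
import pandas as pd
import pytest

from invaphylo.classification import Scope, classify_nonnatives
from invaphylo.occurrence_db import NONNATIVE
from invaphylo.phylometrics import cophenetic_distances, prune_to_database, read_newick
from invaphylo.record_builder import (
    CleaningError,
    build_records,
    clean_database,
    standardize_records,
)


@pytest.fixture
def toy_setup(toy_country):
    db, tree, _ = toy_country
    assignment = classify_nonnatives(db, Scope.COUNTRY)
    D = cophenetic_distances(tree)
    return db, assignment, D


class TestCleanDatabase:
    def test_units_without_nonnatives_dropped(self, tmp_path):
        from tests_helpers import make_two_country_db

        db, tree = make_two_country_db()
        assignment = classify_nonnatives(db, Scope.COUNTRY)
        cleaned, report = clean_database(db, assignment, tree)
        # country Y holds only natives -> all its basins removed
        assert report["units_dropped"] == 1
        assert "Y" not in set(cleaned.basins["country"])

    def test_species_missing_from_tree_dropped(self, toy_country):
        db, _, _ = toy_country
        smaller = read_newick("(((N1:1,N2:1):1,N3:2):1,E:3);", from_string=True)
        assignment = classify_nonnatives(db, Scope.COUNTRY)
        cleaned, report = clean_database(db, assignment, smaller)
        assert report["species_dropped"] == 1
        assert report["dropped_species"] == ["T"]
        assert "T" not in cleaned.species

    def test_identity_when_nothing_to_drop(self, toy_setup):
        db, assignment, _ = toy_setup
        tree = read_newick("(((N1:1,E:1):1,N2:2):1,(N3:1,T:1):2);", from_string=True)
        cleaned, report = clean_database(db, assignment, tree)
        assert report["units_dropped"] == 0
        assert report["species_dropped"] == 0
        pd.testing.assert_frame_equal(
            cleaned.records.reset_index(drop=True), db.records.reset_index(drop=True)
        )

    def test_everything_dropped_is_error(self, tiny):
        db, _, _ = tiny
        foreign = read_newick("(Q1:1,Q2:1);", from_string=True)
        assignment = classify_nonnatives(db, Scope.COUNTRY)
        with pytest.raises(CleaningError):
            clean_database(db, assignment, foreign)


class TestBuildRecords:
    def test_exotic_gets_all_unit_basins(self, toy_setup):
        db, assignment, D = toy_setup
        table = build_records(db, assignment, D, "exotic")
        ex = table[table["species"] == "E"]
        assert len(ex) == 3
        assert dict(zip(ex["basin_id"], ex["presence"])) == {"b1": 1, "b2": 0, "b3": 0}

    def test_translocated_origin_basin_excluded(self, toy_setup):
        db, assignment, D = toy_setup
        table = build_records(db, assignment, D, "translocated")
        tr = table[table["species"] == "T"]
        assert len(tr) == 2
        assert set(tr["basin_id"]) == {"b2", "b3"}
        assert dict(zip(tr["basin_id"], tr["presence"])) == {"b2": 1, "b3": 0}

    def test_species_exotic_in_two_countries_counts_per_unit(self):
        from tests_helpers import make_db

        basins = [
            ("x1", "X", "Palearctic", 10, 0, 0),
            ("x2", "X", "Palearctic", 10, 0, 0),
            ("y1", "Y", "Nearctic", 10, 0, 0),
            ("y2", "Y", "Nearctic", 10, 0, 0),
            ("y3", "Y", "Nearctic", 10, 0, 0),
        ]
        records = [("n%d" % i, b, "native") for i, b in enumerate(
            ["x1", "x2", "y1", "y2", "y3"])]
        records += [("inv", "x1", "nonnative"), ("inv", "y1", "nonnative")]
        db = make_db(basins, records)
        tree = read_newick(
            "((n0:1,(n1:1,inv:1)a:1)b:1,((n2:1,n3:1)c:1,n4:2)d:1);", from_string=True
        )
        assignment = classify_nonnatives(db, Scope.COUNTRY)
        D = cophenetic_distances(tree)
        table = build_records(db, assignment, D, "exotic")
        assert len(table) == 5
        assert set(table["country"]) == {"X", "Y"}

    def test_record_count_matches_brute_force_triple_loop(self, simulated):
        db, tree, _ = simulated
        assignment = classify_nonnatives(db, Scope.COUNTRY)
        cleaned, _ = clean_database(db, assignment, tree)
        assignment = classify_nonnatives(cleaned, Scope.COUNTRY)
        pruned, _ = prune_to_database(tree, cleaned)
        D = cophenetic_distances(pruned)
        for group in ("exotic", "translocated"):
            table = build_records(cleaned, assignment, D, group)
            # oracle: enumerate (species, country, basin) directly
            expected = 0
            for country in cleaned.countries:
                basins = cleaned.basins_of_country(country)
                labelled = {
                    s
                    for b in basins
                    for s in cleaned.nonnatives_of(b)
                    if assignment.labels[(s, b)] == group
                }
                for s in labelled:
                    for b in basins:
                        if s in cleaned.natives_of(b):
                            continue
                        if len(cleaned.natives_of(b) - {s}) == 0:
                            continue
                        expected += 1
            assert len(table) == expected

    def test_presence_sum_equals_nonnative_pairs(self, simulated):
        db, tree, _ = simulated
        assignment = classify_nonnatives(db, Scope.COUNTRY)
        cleaned, _ = clean_database(db, assignment, tree)
        assignment = classify_nonnatives(cleaned, Scope.COUNTRY)
        pruned, _ = prune_to_database(tree, cleaned)
        D = cophenetic_distances(pruned)
        for group in ("exotic", "translocated"):
            table = build_records(cleaned, assignment, D, group)
            n_pairs = sum(
                1 for (s, b), lab in assignment.labels.items() if lab == group
            )
            assert table["presence"].sum() == n_pairs

    def test_no_record_pairs_species_with_its_native_basin(self, simulated):
        db, tree, _ = simulated
        assignment = classify_nonnatives(db, Scope.COUNTRY)
        cleaned, _ = clean_database(db, assignment, tree)
        assignment = classify_nonnatives(cleaned, Scope.COUNTRY)
        pruned, _ = prune_to_database(tree, cleaned)
        D = cophenetic_distances(pruned)
        table = build_records(cleaned, assignment, D, "translocated")
        for s, b in table[["species", "basin_id"]].itertuples(index=False):
            assert s not in cleaned.natives_of(b)

    def test_invariant_to_input_row_order(self, toy_country):
        db, tree, _ = toy_country
        shuffled = db.replace_records(
            db.records.sample(frac=1.0, random_state=7).reset_index(drop=True)
        )
        D = cophenetic_distances(tree)
        a1 = classify_nonnatives(db, Scope.COUNTRY)
        a2 = classify_nonnatives(shuffled, Scope.COUNTRY)
        t1 = build_records(db, a1, D, "exotic").reset_index(drop=True)
        t2 = build_records(shuffled, a2, D, "exotic").reset_index(drop=True)
        pd.testing.assert_frame_equal(t1, t2)

    def test_unknown_group_rejected(self, toy_setup):
        db, assignment, D = toy_setup
        with pytest.raises(ValueError, match="group"):
            build_records(db, assignment, D, "alien")


class TestStandardize:
    def test_sample_sd_convention(self):
        t = pd.DataFrame({"mpd": [1.0, 2.0, 3.0]})
        out = standardize_records(t, ["mpd"])
        assert np.allclose(out["mpd_z"], [-1.0, 0.0, 1.0])

    def test_idempotent_on_standardized_column(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        x = (x - x.mean()) / x.std(ddof=1)
        out = standardize_records(pd.DataFrame({"mpd": x}), ["mpd"])
        assert np.allclose(out["mpd_z"], x, atol=1e-12)

    def test_constant_column_is_error(self):
        with pytest.raises(ValueError, match="mpd"):
            standardize_records(pd.DataFrame({"mpd": [2.0, 2.0]}), ["mpd"])

    def test_zscores_have_zero_mean_unit_sd(self, simulated):
        db, tree, _ = simulated
        assignment = classify_nonnatives(db, Scope.COUNTRY)
        cleaned, _ = clean_database(db, assignment, tree)
        assignment = classify_nonnatives(cleaned, Scope.COUNTRY)
        pruned, _ = prune_to_database(tree, cleaned)
        D = cophenetic_distances(pruned)
        table = standardize_records(
            build_records(cleaned, assignment, D, "translocated")
        )
        for col in ("mpd_z", "mntd_z", "native_richness_z", "log_area_z"):
            assert abs(table[col].mean()) < 1e-8
            assert abs(table[col].std(ddof=1) - 1.0) < 1e-8

    def test_undefined_diversity_retained_as_nan(self, single_native_basin):
        db, tree, _ = single_native_basin
        assignment = classify_nonnatives(db, Scope.COUNTRY)
        D = cophenetic_distances(tree)
        table = build_records(db, assignment, D, "exotic")
        # b2 has one native: community diversity undefined but row retained
        b2 = table[table["basin_id"] == "b2"].iloc[0]
        assert np.isnan(b2["native_mpd"]) and np.isnan(b2["native_mntd"])
        assert b2["native_richness"] == 1
        assert table["mpd"].notna().all()
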