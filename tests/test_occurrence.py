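"""Record validation, year imputation, background classing, gambiae-old rule."""

import pytest
from hypothesis import given
from hypothesis import strategies as st
from shapely.geometry import box

from vectorsdm.occurrence import (
    DetectionCapability,
    OccurrenceRecord,
    assign_weights,
    classify_background,
    extract_presence,
    impute_collection_year,
    location_id,
    records_from_dataframe,
    records_to_dataframe,
    resolve_gambiae_old,
    validate_records,
)
from vectorsdm.ranges import SpeciesRange, buffer_range
from vectorsdm.raster import Grid

CAP = DetectionCapability({
    "PCR_ALL": frozenset({"gambiae", "coluzzii", "arabiensis"}),
    "PCR_OTHER": frozenset({"coluzzii"}),
})


def rec(rid="r0", species="gambiae", x=50.0, y=50.0, ys=2005, ye=2005,
        pub=2007, methods=("PCR_ALL",), molecular=True):
    return OccurrenceRecord(
        record_id=rid, species_label=species, x=x, y=y, year_start=ys,
        year_end=ye, publication_year=pub, id_methods=frozenset(methods),
        is_molecular=molecular,
    )


class TestValidateRecords:
    def test_complete_record_at_grid_centre_is_valid(self):
        grid = Grid(width=20, height=20)
        valid, report = validate_records([rec()], grid)
        assert len(valid) == 1 and report.empty

    def test_latitude_out_of_range_rejected(self):
        extent = box(-180, -90, 180, 90)
        bad = rec(x=10.0, y=95.0)
        valid, report = validate_records([bad], extent)
        assert not valid
        assert report.reasons.iloc[0] == "coordinate_out_of_range"

    def test_corrupted_records_found_exactly(self, rng):
        grid = Grid(width=20, height=20)
        records = [rec(rid=f"r{i}", x=float(rng.uniform(1, 99)), y=float(rng.uniform(1, 99)))
                   for i in range(100)]
        corrupt = {3: "coord", 17: "coord", 31: "years", 48: "nodate", 59: "coord",
                   72: "years", 91: "nodate"}
        for i, kind in corrupt.items():
            r = records[i]
            if kind == "coord":
                records[i] = rec(rid=r.record_id, x=500.0, y=r.y)
            elif kind == "years":
                records[i] = rec(rid=r.record_id, x=r.x, y=r.y, ys=2010, ye=2005)
            else:
                records[i] = OccurrenceRecord(record_id=r.record_id, species_label="gambiae",
                                              x=r.x, y=r.y)
        valid, report = validate_records(records, grid)
        # brute-force re-application of each rule
        expected_bad = set()
        for r in records:
            if not (0 <= r.x <= 100 and 0 <= r.y <= 100):
                expected_bad.add(r.record_id)
            if r.year_start is not None and r.year_end is not None and r.year_start > r.year_end:
                expected_bad.add(r.record_id)
            if r.year_start is None and r.publication_year is None:
                expected_bad.add(r.record_id)
        assert set(report.record_id) == expected_bad == {records[i].record_id for i in corrupt}
        assert len(valid) == 93


class TestImputeCollectionYear:
    def test_publication_year_minus_two(self):
        r = OccurrenceRecord(record_id="r", species_label="s", x=0, y=0,
                             publication_year=2010)
        assert impute_collection_year(r) == 2008

    def test_known_collection_year_passes_through(self):
        assert impute_collection_year(rec(ys=2005, ye=2005)) == 2005

    def test_multi_year_collection_uses_floor_midpoint(self):
        assert impute_collection_year(rec(ys=2003, ye=2005)) == 2004
        assert impute_collection_year(rec(ys=2003, ye=2006)) == 2004

    def test_missing_all_dating_information_errors(self):
        r = OccurrenceRecord(record_id="r", species_label="s", x=0, y=0)
        with pytest.raises(ValueError):
            impute_collection_year(r)


class TestBackgroundClassing:
    def test_capable_method_gets_class1_at_double_weight(self):
        pts = classify_background(
            [rec(rid="a", methods=("PCR_ALL",)), rec(rid="b", methods=("MORPH",), molecular=False)],
            "gambiae", CAP,
        )
        by_id = {p.record_id: p for p in pts}
        assert by_id["a"].background_class == 1
        assert by_id["b"].background_class == 2
        assert by_id["a"].weight / by_id["b"].weight == 2.0

    def test_unknown_or_nonmolecular_methods_are_class2(self):
        pts = classify_background([rec(methods=("MYSTERY_CODE",))], "gambiae", CAP)
        assert pts[0].background_class == 2

    def test_incapable_molecular_method_is_class2(self):
        # PCR_OTHER detects coluzzii only: class 2 for a gambiae model
        pts = classify_background([rec(methods=("PCR_OTHER",))], "gambiae", CAP)
        assert pts[0].background_class == 2

    def test_mixed_table_counts_match_membership_brute_force(self, rng):
        records = []
        for i in range(50):
            methods = ("PCR_ALL",) if i < 20 else (("PCR_OTHER",) if i % 2 else ("MORPH",))
            records.append(rec(rid=f"r{i}", methods=methods))
        order = rng.permutation(50)
        records = [records[i] for i in order]
        pts = classify_background(records, "gambiae", CAP)
        expected_c1 = sum(
            1 for r in records if any("gambiae" in CAP.methods.get(m, set()) for m in r.id_methods)
        )
        assert expected_c1 == 20
        assert sum(1 for p in pts if p.background_class == 1) == 20
        assert all(p.background_class in (1, 2) for p in pts)

    @given(n1=st.integers(0, 40), n2=st.integers(0, 40), npres=st.integers(1, 60))
    def test_weight_ratio_is_two_for_any_composition(self, n1, n2, npres):
        records = [rec(rid=f"c1_{i}", methods=("PCR_ALL",)) for i in range(n1)]
        records += [rec(rid=f"c2_{i}", methods=("MORPH",), molecular=False) for i in range(n2)]
        bg = classify_background(records, "gambiae", CAP)
        presences = extract_presence([rec(rid=f"p{i}") for i in range(npres)], "gambiae", CAP)
        pres, bg = assign_weights(presences, bg, mode="balanced")
        w1 = {p.weight for p in bg if p.background_class == 1}
        w2 = {p.weight for p in bg if p.background_class == 2}
        if w1 and w2:
            assert (next(iter(w1)) / next(iter(w2))) == pytest.approx(2.0)
        if bg:
            assert sum(p.weight for p in bg) == pytest.approx(sum(p.weight for p in pres))

    def test_classification_is_idempotent_on_reordered_input(self):
        records = [rec(rid=f"r{i}", methods=("PCR_ALL",) if i % 3 else ("MORPH",))
                   for i in range(12)]
        a = classify_background(records, "gambiae", CAP)
        b = classify_background(list(reversed(records)), "gambiae", CAP)
        assert {(p.record_id, p.background_class) for p in a} == \
               {(p.record_id, p.background_class) for p in b}


class TestExtractPresence:
    def test_morphology_only_presence_excluded(self):
        pts = extract_presence([rec(methods=("MORPH",), molecular=False)], "gambiae", CAP)
        assert pts == []

    def test_molecular_presence_included_with_unit_weight(self):
        pts = extract_presence([rec()], "gambiae", CAP)
        assert len(pts) == 1 and pts[0].label == 1 and pts[0].weight == 1.0

    def test_presence_count_matches_generator_ground_truth(self, small_world):
        from vectorsdm.pipeline import default_capability

        records = records_from_dataframe(small_world.occurrence)
        cap = default_capability(records, small_world.config.focal_species)
        pts = extract_presence(records, small_world.config.focal_species, cap)
        assert len(pts) == int(small_world.occurrence.is_presence_truth.sum())


class TestResolveGambiaeOld:
    def setup_method(self):
        self.col = buffer_range(SpeciesRange("coluzzii", box(0, 0, 10, 10)), 1.0)
        self.gam = buffer_range(SpeciesRange("gambiae", box(5, 5, 15, 15)), 1.0)

    def old(self, x, y, rid="g"):
        return rec(rid=rid, species="gambiae_old", x=x, y=y)

    def test_point_outside_buffered_coluzzii_assigned_gambiae(self):
        assigned, discarded = resolve_gambiae_old([self.old(20, 20)], self.col, self.gam)
        assert not discarded
        assert assigned[0].species_label == "gambiae"

    def test_point_in_overlap_discarded(self):
        assigned, discarded = resolve_gambiae_old([self.old(7, 7)], self.col, self.gam)
        assert not assigned and len(discarded) == 1

    def test_point_in_coluzzii_only_discarded(self):
        assigned, discarded = resolve_gambiae_old([self.old(2, 2)], self.col, self.gam)
        assert not assigned and len(discarded) == 1

    def test_partition_and_passthrough(self):
        records = [self.old(20, 20, "a"), self.old(7, 7, "b"), self.old(2, 2, "c"),
                   rec(rid="d", species="arabiensis", x=7, y=7)]
        assigned, discarded = resolve_gambiae_old(records, self.col, self.gam)
        assert {r.record_id for r in assigned} | {r.record_id for r in discarded} == {"a", "b", "c", "d"}
        assert {r.record_id for r in assigned} & {r.record_id for r in discarded} == set()
        assert [r.species_label for r in assigned if r.record_id == "d"] == ["arabiensis"]

    def test_missing_range_errors(self):
        with pytest.raises(ValueError):
            resolve_gambiae_old([self.old(1, 1)], None, self.gam)


def test_colocated_records_share_location_id():
    assert location_id(1.2345678, 5.0) == location_id(1.2345679, 5.0)
    assert location_id(1.2, 5.0) != location_id(1.3, 5.0)


def test_occurrence_csv_round_trip(small_world, tmp_path):
    records = records_from_dataframe(small_world.occurrence)
    df = records_to_dataframe(records)
    back = records_from_dataframe(df)
    assert back == records
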