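import numpy as np
import pandas as pd
import pytest

from stoichiovar.resource import (
    ComplexDefinition,
    ComplexResource,
    ResourceParseError,
    filter_redundant,
    generate_decoys,
    map_orthologs,
    read_complexes,
    restrict_to_quantified,
    write_gmt,
)


def cdef(cid, members, source="user"):
    return ComplexDefinition(cid, cid, source, frozenset(members))


class TestReadComplexes:
    def test_gmt_line_parses_members(self, tmp_path):
        p = tmp_path / "r.gmt"
        p.write_text("C1\tdesc\tP1\tP2\tP3\tP4\tP5\n")
        res = read_complexes(p)
        assert len(res) == 1
        assert res["C1"].members == frozenset({"P1", "P2", "P3", "P4", "P5"})
        assert res["C1"].name == "desc"

    def test_tsv_duplicate_rows_collapse(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("C1\tP1\nC1\tP1\nC1\tP2\n")
        res = read_complexes(p)
        assert res["C1"].members == frozenset({"P1", "P2"})

    def test_inverse_index_lists_all_complexes(self, tmp_path):
        p = tmp_path / "r.gmt"
        p.write_text("C1\td\tP1\tP2\tP3\nC2\td\tP3\tP4\tP5\n")
        res = read_complexes(p)
        assert res.index["P3"] == ["C1", "C2"]
        assert res.index["P1"] == ["C1"]

    def test_malformed_gmt_line_names_line_number(self, tmp_path):
        p = tmp_path / "r.gmt"
        p.write_text("C1\td\tP1\nC2\tonly-description\n")
        with pytest.raises(ResourceParseError, match="line 2"):
            read_complexes(p)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "r.gmt"
        p.write_text("\n")
        with pytest.raises(ResourceParseError, match="empty"):
            read_complexes(p)

    def test_gmt_roundtrip(self, tmp_path):
        res = ComplexResource([cdef("C1", ["P1", "P2", "P3"]), cdef("C2", ["P4", "P5", "P6"])])
        out = tmp_path / "out.gmt"
        write_gmt(res, out)
        back = read_complexes(out)
        assert back.ids == res.ids
        assert all(back[c].members == res[c].members for c in res.ids)


class TestFilterRedundant:
    def test_exact_duplicate_keeps_higher_ranked_source(self):
        members = [f"P{i}" for i in range(5)]
        res = ComplexResource(
            [cdef("corum1", members, "corum"), cdef("manual1", members, "manual")]
        )
        kept = filter_redundant(res)
        assert kept.ids == ["manual1"]

    def test_worked_overlap_example(self):
        # B shares 3/5 = 60 % of its members with A -> removed;
        # C shares 1/5 with A (and only overlapped the removed B) -> kept.
        res = ComplexResource(
            [
                cdef("A", [f"P{i}" for i in range(1, 7)], "manual"),
                cdef("B", ["P1", "P2", "P3", "P7", "P8"], "corum"),
                cdef("C", [f"P{i}" for i in range(7, 12)], "corum"),
            ]
        )
        kept = filter_redundant(res, overlap_threshold=0.5, min_members=5)
        assert kept.ids == ["A", "C"]

    def test_min_members_filter_can_empty_resource(self):
        res = ComplexResource([cdef("C1", ["P1", "P2", "P3", "P4"])])
        assert len(filter_redundant(res, min_members=5)) == 0

    def test_kept_pairs_respect_threshold_exhaustively(self, random_resource_factory):
        # oracle: brute-force pairwise overlap check over all kept pairs
        rng = np.random.default_rng(7)
        for _ in range(50):
            res = random_resource_factory(rng)
            kept = filter_redundant(res, overlap_threshold=0.5, min_members=3)
            ranked = sorted(kept, key=lambda c: c.rank_key)
            for i, hi in enumerate(ranked):
                for lo in ranked[i + 1 :]:
                    frac = len(hi.members & lo.members) / lo.size
                    assert frac < 0.5

    def test_deterministic_ordering(self, random_resource_factory):
        rng = np.random.default_rng(11)
        res = random_resource_factory(rng)
        a = filter_redundant(res, min_members=3)
        b = filter_redundant(res, min_members=3)
        assert a.ids == b.ids


class TestGenerateDecoys:
    def test_single_complex_keeps_member_set(self, five_member_resource):
        decoy = generate_decoys(five_member_resource, seed=0)
        assert decoy.complexes[0].members == five_member_resource.complexes[0].members

    def test_sizes_and_occurrences_preserved(self):
        rng = np.random.default_rng(3)
        pool = [f"P{i:02d}" for i in range(40)]
        defs = []
        for i, size in enumerate([5, 7, 9]):
            defs.append(cdef(f"C{i}", rng.choice(pool, size=size, replace=False)))
        res = ComplexResource(defs)
        for seed in (0, 1, 2):
            decoy = generate_decoys(res, seed=seed)
            assert decoy.sizes == [5, 7, 9]
            orig = sorted(p for c in res for p in c.members)
            perm = sorted(p for c in decoy for p in c.members)
            assert orig == perm
            for c in decoy:
                assert len(c.members) == len(set(c.members))

    def test_seeded_determinism(self, random_resource_factory):
        res = random_resource_factory(np.random.default_rng(5), n_complexes=6)
        a = generate_decoys(res, seed=1)
        b = generate_decoys(res, seed=1)
        c = generate_decoys(res, seed=2)
        assert [x.members for x in a] == [x.members for x in b]
        assert [x.members for x in a] != [x.members for x in c]

    def test_infeasible_multiplicity_errors(self):
        # P1 appears in both complexes, which is fine; a protein appearing
        # more often than there are complexes cannot be placed duplicate-free
        res = ComplexResource(
            [cdef("C1", ["P1", "P2", "P3"]), cdef("C2", ["P1", "P4", "P5"]),
             cdef("C3", ["P1", "P6", "P7"])]
        )
        generate_decoys(res, seed=0)  # multiplicity 3 == 3 complexes: feasible
        res4 = ComplexResource(
            [cdef("C1", ["P1", "P2"]), cdef("C2", ["P1", "P3"])]
        )
        big = ComplexResource(
            [cdef("C1", ["P1", "P2"]), cdef("C2", ["P1", "P3"]),
             cdef("C3", ["P1", "P4"])]
        )
        assert len(generate_decoys(res4, seed=0)) == 2
        assert len(generate_decoys(big, seed=0)) == 3


class TestMapOrthologs:
    def test_identity_mapping_is_noop(self, five_member_resource):
        mapping = {p: p for p in five_member_resource.proteins}
        out = map_orthologs(five_member_resource, mapping)
        assert out.complexes[0].members == five_member_resource.complexes[0].members

    def test_unmapped_member_dropped(self, five_member_resource):
        mapping = {p: f"M_{p}" for p in ["P1", "P2", "P3", "P4"]}
        out = map_orthologs(five_member_resource, mapping)
        assert out["C1"].members == frozenset({"M_P1", "M_P2", "M_P3", "M_P4"})

    def test_one_to_many_expands(self):
        res = ComplexResource([cdef("C1", ["P1", "P2"])])
        out = map_orthologs(res, {"P1": {"M1a", "M1b"}, "P2": "M2"})
        assert out["C1"].members == frozenset({"M1a", "M1b", "M2"})

    def test_dataframe_mapping(self):
        res = ComplexResource([cdef("C1", ["P1", "P2"])])
        df = pd.DataFrame({"source_id": ["P1", "P2"], "target_id": ["M1", "M2"]})
        assert map_orthologs(res, df)["C1"].members == frozenset({"M1", "M2"})


class TestRestrictToQuantified:
    @pytest.mark.parametrize(
        "n_quantified,kept", [(5, True), (4, False), (6, True)]
    )
    def test_min_quantified_members_rule(self, n_quantified, kept):
        res = ComplexResource([cdef("C1", [f"P{i}" for i in range(6)])])
        quantified = {f"P{i}" for i in range(n_quantified)}
        out = restrict_to_quantified(res, quantified, min_members=5)
        if kept:
            assert out["C1"].members == frozenset(quantified & res["C1"].members)
        else:
            assert len(out) == 0

    def test_superset_is_identity(self, five_member_resource):
        out = restrict_to_quantified(
            five_member_resource, five_member_resource.proteins | {"X"}
        )
        assert out["C1"].members == five_member_resource["C1"].members
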