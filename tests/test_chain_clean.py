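"""Cleaning pipeline: alignment, MODRES restoration, pruning, altLoc
selection, filters, re-indexing."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import build_chain
from oracles import oracle_align, regions_of
from pdbkernel import chain_clean as cc
from pdbkernel import pdb_io
from pdbkernel.pdb_io import AtomRecord


class TestAlignRefCoord:
    def test_identity(self):
        aln = cc.align_ref_coord("ACDEFG", "ACDEFG")
        assert aln.mapping == [1, 2, 3, 4, 5, 6]
        assert aln.missing_regions == []
        assert aln.mismatches == []

    def test_interior_gap(self):
        aln = cc.align_ref_coord("ACDEFGHIK", "ACDHIK")
        assert aln.mapping == [1, 2, 3, 7, 8, 9]
        assert aln.missing_regions == [(4, 6)]

    def test_mismatch_beats_gap(self):
        aln = cc.align_ref_coord("ACMEF", "ACLEF")
        assert aln.mapping == [1, 2, 3, 4, 5]
        assert aln.mismatches == [3]
        assert aln.missing_regions == []

    def test_coord_longer_than_ref(self):
        with pytest.raises(cc.AlignmentError):
            cc.align_ref_coord("ACD", "ACDE")

    def test_empty_sequence(self):
        with pytest.raises(cc.AlignmentError):
            cc.align_ref_coord("", "A")

    def test_zero_match_flagged(self):
        aln = cc.align_ref_coord("AAAA", "CC")
        assert aln.flagged_zero_match

    def test_exhaustive_small_cases(self):
        """Agreement with the brute-force monotone-placement oracle on
        every sequence pair with reference length <= 3 over {A,C,G,T}."""
        alphabet = "ACGT"
        for rl in range(1, 4):
            for ref in map("".join, itertools.product(alphabet, repeat=rl)):
                for cl in range(1, rl + 1):
                    for coord in map("".join,
                                     itertools.product(alphabet, repeat=cl)):
                        expected, _ = oracle_align(ref, coord)
                        assert cc.align_ref_coord(ref, coord).mapping == \
                            expected, (ref, coord)

    def test_random_sample_against_oracle(self, rng):
        alphabet = "ACGT"
        for _ in range(800):
            rl = int(rng.integers(2, 13))
            cl = int(rng.integers(1, rl + 1))
            ref = "".join(rng.choice(list(alphabet), size=rl))
            coord = "".join(rng.choice(list(alphabet), size=cl))
            expected, matches = oracle_align(ref, coord)
            aln = cc.align_ref_coord(ref, coord)
            assert aln.mapping == expected, (ref, coord)
            assert aln.n_matches == matches

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.data())
    def test_partition_property(self, data):
        """Mapped positions and missing regions always partition the
        reference exactly; the mapping is strictly increasing."""
        ref = data.draw(st.text(alphabet="ACDEFG", min_size=1, max_size=30))
        m = data.draw(st.integers(1, len(ref)))
        coord = data.draw(st.text(alphabet="ACDEFG", min_size=m, max_size=m))
        aln = cc.align_ref_coord(ref, coord)
        assert all(a < b for a, b in zip(aln.mapping, aln.mapping[1:]))
        assert regions_of(aln.mapping, len(ref)) == aln.missing_regions
        covered = set(aln.mapping) | {
            p for s, e in aln.missing_regions for p in range(s, e + 1)}
        assert covered == set(range(1, len(ref) + 1))


class TestRestoreModres:
    def test_mapped_residue_restored(self):
        chain = build_chain("AMD", res_names={2: "MSE"})
        chain.modres_map = {"MSE": "MET"}
        out = cc.restore_modres(chain)
        assert out.residues[1].res_name == "MET"
        assert out.residues[1].is_modified

    def test_no_modified_residues_identity(self):
        chain = build_chain("ACD")
        out = cc.restore_modres(chain)
        assert [r.res_name for r in out.residues] == ["ALA", "CYS", "ASP"]
        assert not any(r.is_modified for r in out.residues)

    def test_unmapped_nonstandard_becomes_x(self):
        chain = build_chain("AXD", res_names={2: "ABC"})
        out = cc.restore_modres(chain)
        assert pdb_io.coord_sequence(out) == "AXD"


class TestPruneAtoms:
    def test_extra_atom_removed(self):
        chain = build_chain("AA", atoms=("N", "CA", "C", "O", "CB", "SE"))
        out = cc.prune_atoms(chain)
        assert {a.name for a in out.residues[0].atoms} == \
            {"N", "CA", "C", "O", "CB"}

    def test_standard_set_unchanged(self):
        chain = build_chain("AC", atoms=("N", "CA", "C", "O", "CB"))
        out = cc.prune_atoms(chain)
        assert cc.count_atoms(out) == cc.count_atoms(chain)

    def test_oxt_kept_on_terminal_residue_only(self):
        chain = build_chain("AA", atoms=("N", "CA", "C", "O", "OXT"))
        out = cc.prune_atoms(chain)
        assert "OXT" not in {a.name for a in out.residues[0].atoms}
        assert "OXT" in {a.name for a in out.residues[1].atoms}

    def test_hydrogens_always_removed(self):
        chain = build_chain("A", atoms=("N", "CA", "C", "O", "H", "HA"))
        out = cc.prune_atoms(chain)
        assert {a.name for a in out.residues[0].atoms} == {"N", "CA", "C", "O"}


class TestSelectAltloc:
    def _chain_with_alts(self):
        chain = build_chain("A", atoms=("N", "C", "O"))
        res = chain.residues[0]
        res.atoms.insert(1, AtomRecord(name="CA", element="C",
                                       coords=(1.0, 0.0, 0.0), alt_loc="A"))
        res.atoms.insert(2, AtomRecord(name="CA", element="C",
                                       coords=(2.0, 0.0, 0.0), alt_loc="B"))
        return chain

    def test_first_in_file_order_kept(self):
        out = cc.select_altloc(self._chain_with_alts())
        cas = [a for a in out.residues[0].atoms if a.name == "CA"]
        assert len(cas) == 1
        assert cas[0].coords == (1.0, 0.0, 0.0)
        assert cas[0].alt_loc == ""

    def test_no_alternates_identity(self):
        chain = build_chain("AC")
        out = cc.select_altloc(chain)
        assert [a.coords for r in out.residues for a in r.atoms] == \
               [a.coords for r in chain.residues for a in r.atoms]

    def test_every_atom_alternated_leaves_one_each(self):
        chain = build_chain("A", atoms=())
        res = chain.residues[0]
        for name in ("N", "CA", "C", "O"):
            for alt, x in (("A", 1.0), ("B", 2.0)):
                res.atoms.append(AtomRecord(name=name, element=name[0],
                                            coords=(x, 0.0, 0.0), alt_loc=alt))
        out = cc.select_altloc(chain)
        names = [a.name for a in out.residues[0].atoms]
        assert sorted(names) == ["C", "CA", "N", "O"]
        assert all(a.coords[0] == 1.0 for a in out.residues[0].atoms)


class TestFilters:
    def test_ca_only(self):
        chain = build_chain("A" * 40, atoms=("CA",))
        report = cc.apply_filters(chain)
        assert report.reasons == ["CA_ONLY"]
        assert not report.kept

    @pytest.mark.parametrize("length,kept", [(29, False), (30, True)])
    def test_length_boundary_strict(self, length, kept):
        chain = build_chain("A" * length)
        report = cc.apply_filters(chain)
        assert report.kept is kept
        if not kept:
            assert report.reasons == ["TOO_SHORT"]

    def test_no_x_kept(self):
        chain = build_chain("ACDEFGHIKLMNPQRSTVWYACDEFGHIKL")
        assert cc.apply_filters(chain).kept

    def test_too_many_x(self):
        seq = "X" * 5 + "A" * 35
        chain = build_chain(seq, res_names={i: "UNK" for i in range(1, 6)})
        report = cc.apply_filters(chain)
        assert "TOO_MANY_X" in report.reasons

    def test_x_fraction_boundary_not_strict(self):
        # exactly 10% unknowns is kept: removal needs strictly more
        seq = "X" * 4 + "A" * 36
        chain = build_chain(seq, res_names={i: "UNK" for i in range(1, 5)})
        assert cc.apply_filters(chain).kept


class TestReindex:
    def test_author_numbering_reset_to_alignment(self):
        chain = build_chain("ACDEF", coord_positions=[1, 2, 3, 4, 5])
        for res in chain.residues:
            res.seq_num += 41  # author numbering starting at 42
        aln = cc.align_ref_coord(chain.ref_seq, pdb_io.coord_sequence(chain))
        out = cc.reindex(chain, aln)
        assert [r.seq_num for r in out.residues] == [1, 2, 3, 4, 5]

    def test_gapped_mapping_applied(self):
        chain = build_chain("ACDEFGHIK", coord_positions=[1, 2, 3, 7, 8, 9])
        for i, res in enumerate(chain.residues):
            res.seq_num = i + 100
        aln = cc.align_ref_coord(chain.ref_seq, pdb_io.coord_sequence(chain))
        out = cc.reindex(chain, aln)
        assert [r.seq_num for r in out.residues] == [1, 2, 3, 7, 8, 9]


class TestCleanChain:
    def test_defect_free_chain_kept_unchanged(self, fixture_suite):
        from pdbkernel.fixtures import make_chain_fixture
        text, truth = make_chain_fixture("ACDEFGHIKLMNPQRSTVWYACDEFGHIKL")
        chain = pdb_io.parse_pdb(text)[0]
        result = cc.clean_chain(chain)
        assert result.report.kept
        assert result.alignment.missing_regions == []
        assert result.n_atoms_pruned == 0

    def test_fixture_ground_truth(self, fixture_suite):
        for text, truth, _ in fixture_suite:
            chain = pdb_io.parse_pdb(text)[0]
            result = cc.clean_chain(chain)
            assert chain.ref_seq == truth.ref_seq
            assert result.alignment.missing_regions == truth.missing_regions
            assert result.n_atoms_pruned == truth.n_atoms_pruned
            assert result.report.kept == truth.kept
            assert sorted(result.report.reasons) == sorted(truth.reasons)
            assert [r.seq_num for r in result.chain.residues] == \
                truth.coord_positions
            restored = [r.seq_num for r in result.chain.residues
                        if r.is_modified]
            assert restored == truth.restored_positions

    def test_idempotence(self, fixture_suite):
        for text, _, _ in fixture_suite[:20]:
            chain = pdb_io.parse_pdb(text)[0]
            once = cc.clean_chain(chain)
            twice = cc.clean_chain(once.chain)
            assert twice.chain == once.chain
            assert twice.alignment.missing_regions == \
                once.alignment.missing_regions
            assert twice.n_atoms_pruned == 0

    def test_conservation(self, fixture_suite):
        """Cleaning never fabricates or moves coordinates."""
        for text, _, _ in fixture_suite[:20]:
            chain = pdb_io.parse_pdb(text)[0]
            before = {a.coords for r in chain.residues for a in r.atoms}
            cleaned = cc.clean_chain(chain).chain
            after = {a.coords for r in cleaned.residues for a in r.atoms}
            assert after <= before
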