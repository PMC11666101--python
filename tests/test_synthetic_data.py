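"""Generators: determinism, ground truth, format validity, packaged tables."""

import numpy as np
import pandas as pd
import pytest

from glycoshield import io
from glycoshield.seq_sites import scan_sequons
from glycoshield.synthetic_data import (
    FamilyParams,
    MembraneSlab,
    PlantedColumn,
    ToyChannelParams,
    ToyComplexParams,
    load_reference_tables,
    make_isoform_context,
    make_membrane_slab,
    make_sequence_family,
    make_toy_channel,
    make_toy_complex,
    make_toy_ig,
    nav_family_params,
    nav_region_annotation,
)


class TestSequenceFamily:
    def test_deterministic_under_fixed_seed(self):
        p = nav_family_params(seed=3)
        a, ta = make_sequence_family(p)
        b, tb = make_sequence_family(nav_family_params(seed=3))
        assert [s.residues for s in a] == [s.residues for s in b]
        pd.testing.assert_frame_equal(ta, tb)

    def test_planted_table_is_complete_sequon_inventory(self):
        seqs, truth = make_sequence_family(nav_family_params(seed=1))
        for s in seqs:
            found = {q.asn_position for q in scan_sequons(s)}
            planted = set(
                truth.loc[truth["isoform"] == s.isoform_id, "asn_position"]
            )
            assert found == planted, s.isoform_id

    def test_zero_substitution_rate_identical_outside_plants(self):
        params = FamilyParams(
            member_ids=["a", "b"], length=100,
            planted=[PlantedColumn(40, ("a",))],
            substitution_rate=0.0, seed=0,
        )
        seqs, _ = make_sequence_family(params)
        ra, rb = seqs[0].residues, seqs[1].residues
        diff = [i for i in range(100) if ra[i] != rb[i]]
        # differences confined to the planted motif window (plant vs destroy)
        assert diff and all(39 <= i <= 41 for i in diff)

    def test_colliding_planted_columns_rejected(self):
        with pytest.raises(ValueError, match="collide"):
            FamilyParams(
                member_ids=["a"], length=100,
                planted=[PlantedColumn(40, ("a",)), PlantedColumn(41, ("a",))],
            )

    def test_nav_family_region_counts(self):
        seqs, truth = make_sequence_family(nav_family_params(seed=0))
        ann = nav_region_annotation("NaV1.4")
        from glycoshield.seq_sites import count_region_sequons

        nav14 = next(s for s in seqs if s.isoform_id == "NaV1.4")
        assert count_region_sequons(nav14, ann, "ECTL_I") == 7

    def test_fasta_roundtrip(self, tmp_path):
        seqs, _ = make_sequence_family(nav_family_params(seed=2))
        path = tmp_path / "family.fasta"
        io.write_fasta(seqs, path)
        back = io.read_fasta(path)
        assert [(s.isoform_id, s.residues) for s in back] == [
            (s.isoform_id, s.residues) for s in seqs
        ]


class TestToyChannel:
    def test_planted_sites_detected_by_scanner(self, toy_channel):
        found = [q.asn_position for q in scan_sequons(toy_channel.sequence)]
        assert found == toy_channel.glycosites

    def test_zero_glycosite_loops_zero_sequons(self):
        tc = make_toy_channel(ToyChannelParams(glycosite_loops=()))
        assert scan_sequons(tc.sequence) == []

    def test_glycosites_above_membrane(self, toy_channel):
        struct = toy_channel.structure
        for site in toy_channel.glycosites:
            nd2 = struct.coord[(struct.res_id == site) & (struct.atom_name == "ND2")]
            assert nd2[0][2] > toy_channel.membrane.z_outer

    def test_pdb_roundtrip(self, toy_channel, tmp_path):
        path = tmp_path / "toy.pdb"
        io.write_structure(toy_channel.structure, path)
        back = io.read_structure(path)
        assert len(back) == len(toy_channel.structure)
        assert np.allclose(back.coord, toy_channel.structure.coord, atol=1e-2)

    def test_invalid_glycosite_loop_rejected(self):
        with pytest.raises(ValueError):
            ToyChannelParams(n_loops=2, glycosite_loops=(5,))


class TestToyComplexAndIg:
    def test_footprint_ground_truth(self):
        params = ToyComplexParams(footprint=tuple(range(10, 22)))
        complex_ = make_toy_complex(params)
        assert complex_.footprint == params.footprint

    def test_footprint_outside_chain_rejected(self):
        with pytest.raises(ValueError):
            make_toy_complex(ToyComplexParams(n_alpha=10, footprint=(15,)))

    def test_toy_ig_dimensions(self, toy_ig):
        # beta1-Ig scale: long axis ~4 nm
        assert 35.0 <= toy_ig.extent <= 50.0
        assert len(toy_ig.tip_residues) > 0 and len(toy_ig.base_residues) > 0


class TestPackagedTables:
    def test_nav11_variant_list_has_seven_missense(self):
        tables = load_reference_tables()
        nav11 = [v for v in tables.variants if v.isoform_id == "NaV1.1"]
        missense = [v for v in nav11 if v.kind == "missense"]
        assert len(missense) == 7
        assert {v.label for v in missense} == {
            "S340F", "S340P", "S340Y", "N1378H", "N1378T", "H1393P", "T1394I"
        }
        assert sum(v.kind == "frameshift" for v in nav11) == 3

    def test_leaflet_fractions_sum_to_hundred(self):
        tables = load_reference_tables()
        comp = tables.membrane_composition
        assert comp["upper_pct"].sum() == pytest.approx(100.0, abs=0.1)
        assert comp["inner_pct"].sum() == pytest.approx(100.0, abs=0.1)

    def test_membrane_slab_validates_composition(self):
        slab = make_membrane_slab()
        assert slab.half_thickness == pytest.approx(20.0)
        with pytest.raises(ValueError):
            MembraneSlab(z_inner=0.0, z_outer=-40.0)

    def test_representative_tree_loads_and_validates(self):
        tables = load_reference_tables()
        assert len(tables.glycan_tree) == 11

    def test_isoform_contexts_carry_documented_sequons(self):
        ctx = make_isoform_context("NaV1.1")
        positions = {q.asn_position for q in scan_sequons(ctx)}
        assert positions == {338, 1378, 1392}
        with pytest.raises(KeyError):
            make_isoform_context("NaV1.42")
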